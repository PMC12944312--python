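"""Voxelized finger-joint models.

The finger is a cylinder along the x axis (the detector/imaging axis): a
bone core, a joint annulus hugging the bone over a finite lateral extent
at the joint plane, generic soft tissue elsewhere, an optional epidermis
shell, and ambient (n = 1, non-scattering) outside.  Disease severity maps
linearly onto the joint-layer material, thickness, swelling and lateral
extent: at 0% the annulus is clear synovial fluid; from 25% upward it is
turbid pannus of growing thickness while the local outer radius swells.

Coordinates: x = detector axis, z = source-to-transmission axis, origin at
the grid corner, positions in mm, voxel centers at (index + 0.5) * voxel_size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .spectra import TissueOpticalProperties, load_materials

__all__ = [
    "AMBIENT", "GENERIC_TISSUE", "BONE", "SYNOVIAL_FLUID", "TURBID_PANNUS",
    "EPIDERMIS",
    "GeometrySpec", "FingerModelConfig", "VoxelGrid",
    "severity_to_geometry", "build_finger", "surface_normal",
    "save_grid", "load_grid",
]

# material labels (uint8 voxel values)
AMBIENT = 0
GENERIC_TISSUE = 1
BONE = 2
SYNOVIAL_FLUID = 3
TURBID_PANNUS = 4
EPIDERMIS = 5

_PHENOTYPE_MATERIAL = {
    "light": "epidermis_light",
    "medium": "epidermis_medium",
    "dark": "epidermis_dark",
}


@dataclass(frozen=True)
class GeometrySpec:
    """Severity-resolved joint geometry (one row of the severity mapping)."""

    joint_layer_material: str  # "synovial_fluid" | "turbid_pannus"
    layer_thickness: float  # mm
    joint_swelling: float  # mm
    lateral_extent: float  # mm
    severity: float  # percent, 0-100

    def __post_init__(self) -> None:
        if not 0.5 <= self.layer_thickness <= 1.5:
            raise ValueError("layer_thickness must be in [0.5, 1.5] mm")
        if not 0.0 <= self.joint_swelling <= 1.0:
            raise ValueError("joint_swelling must be in [0, 1] mm")
        if not 8.0 <= self.lateral_extent <= 10.0:
            raise ValueError("lateral_extent must be in [8, 10] mm")
        if (self.severity == 0) != (self.joint_layer_material == "synovial_fluid"):
            raise ValueError(
                "joint material must be synovial_fluid iff severity is 0"
            )


@dataclass(frozen=True)
class FingerModelConfig:
    """Anatomical and discretization parameters of the digital finger."""

    soft_tissue_radius: float = 7.5  # mm
    bone_radius: float = 3.0  # mm
    epidermis_thickness: float = 0.10  # mm
    skin_phenotype: str = "none"  # none | light | medium | dark
    voxel_size: float = 0.10  # mm
    grid_extent: tuple = (30.0, 24.0, 24.0)  # mm along (x, y, z)

    def __post_init__(self) -> None:
        if self.skin_phenotype not in ("none", *_PHENOTYPE_MATERIAL):
            raise ValueError(f"unknown skin phenotype {self.skin_phenotype!r}")
        if self.bone_radius + 1.5 + 1.0 >= self.soft_tissue_radius:
            raise ValueError(
                "bone_radius + max annulus thickness + max swelling must fit "
                "inside soft_tissue_radius"
            )
        if self.skin_phenotype != "none" and self.voxel_size > self.epidermis_thickness:
            raise ValueError(
                "voxel_size must not exceed epidermis_thickness when an "
                "epidermis shell is modelled"
            )


@dataclass
class VoxelGrid:
    """Dense 3-D lattice of material labels plus a label -> material map."""

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_size: float  # mm
    material_table: dict  # label -> (name, TissueOpticalProperties)
    _n_smooth: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        present = np.unique(self.labels)
        for lbl in present:
            if int(lbl) not in self.material_table:
                raise ValueError(f"label {int(lbl)} missing from material_table")

    @property
    def dims(self) -> tuple:
        return self.labels.shape

    @property
    def extent(self) -> tuple:
        return tuple(d * self.voxel_size for d in self.labels.shape)

    def property_arrays(self):
        """(mua, mus, g, n) float64 arrays indexed by label, for the engine."""
        nlab = max(self.material_table) + 1
        mua = np.zeros(nlab)
        mus = np.zeros(nlab)
        g = np.zeros(nlab)
        n = np.ones(nlab)
        for lbl, (_, props) in self.material_table.items():
            mua[lbl] = props.mua
            mus[lbl] = props.mus
            g[lbl] = props.g
            n[lbl] = props.n
        return mua, mus, g, n

    def index_field(self) -> np.ndarray:
        """Refractive index per voxel (float32)."""
        _, _, _, n = self.property_arrays()
        return n.astype(np.float32)[self.labels]

    def smoothed_index_field(self, sigma: float = 2.0) -> np.ndarray:
        """Gaussian-smoothed index field used for surface-normal estimation.

        sigma is in voxels; the default (2 voxels) keeps voxelized curved
        interfaces within ~4 degrees of their analytic normals at the
        default resolution.  The sigma = 2 result is cached.
        """
        if sigma == 2.0 and self._n_smooth is not None:
            return self._n_smooth
        ns = gaussian_filter(self.index_field(), sigma=sigma, mode="nearest")
        if sigma == 2.0:
            self._n_smooth = ns
        return ns


def severity_to_geometry(severity: float) -> GeometrySpec:
    """Map RA severity [0-100 %] to joint geometry.

    thickness = 0.5 + 0.01 * severity mm, swelling = 0.01 * severity mm,
    lateral extent = 8.0 + 0.02 * severity mm; the joint layer is clear
    synovial fluid only at severity 0, turbid pannus otherwise.
    """
    if not 0.0 <= severity <= 100.0:
        raise ValueError("severity must be in [0, 100] percent")
    material = "synovial_fluid" if severity == 0 else "turbid_pannus"
    return GeometrySpec(
        joint_layer_material=material,
        layer_thickness=0.5 + 0.01 * severity,
        joint_swelling=0.01 * severity,
        lateral_extent=8.0 + 0.02 * severity,
        severity=severity,
    )


def build_finger(
    geom: GeometrySpec,
    cfg: FingerModelConfig = FingerModelConfig(),
    materials: dict | None = None,
) -> VoxelGrid:
    """Voxelize the concentric finger-joint model.

    The joint annulus (thickness ``geom.layer_thickness``) hugs the bone over
    ``geom.lateral_extent`` centered at the joint plane (grid x-center).  The
    outer radius is locally increased by ``geom.joint_swelling`` with a cosine
    taper over the lateral extent, avoiding a step in the skin surface.  When
    ``cfg.skin_phenotype`` is not ``none`` the outermost shell of thickness
    ``cfg.epidermis_thickness`` is epidermis of that phenotype.
    """
    if materials is None:
        materials = load_materials()
    h = cfg.voxel_size
    nx, ny, nz = (int(round(e / h)) for e in cfg.grid_extent)
    xc, yc, zc = (d * h / 2.0 for d in (nx, ny, nz))

    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    dx = x - xc
    r = np.sqrt(
        (y[:, None] - yc) ** 2 + (z[None, :] - zc) ** 2
    )  # (ny, nz), radius from the finger axis

    half_ext = geom.lateral_extent / 2.0
    in_joint_span = np.abs(dx) <= half_ext
    taper = np.where(
        in_joint_span,
        0.5 * (1.0 + np.cos(np.pi * dx / half_ext)),
        0.0,
    )
    r_outer = cfg.soft_tissue_radius + geom.joint_swelling * taper  # (nx,)

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    inside = r[None, :, :] <= r_outer[:, None, None]
    labels[inside] = GENERIC_TISSUE

    if cfg.skin_phenotype != "none":
        epi = inside & (r[None, :, :] > (r_outer[:, None, None] - cfg.epidermis_thickness))
        labels[epi] = EPIDERMIS

    joint_label = (
        SYNOVIAL_FLUID if geom.joint_layer_material == "synovial_fluid"
        else TURBID_PANNUS
    )
    annulus = (
        in_joint_span[:, None, None]
        & (r[None, :, :] > cfg.bone_radius)
        & (r[None, :, :] <= cfg.bone_radius + geom.layer_thickness)
    )
    labels[annulus] = joint_label
    labels[(r <= cfg.bone_radius)[None, :, :] & inside] = BONE

    joint_name = geom.joint_layer_material
    epi_name = _PHENOTYPE_MATERIAL.get(cfg.skin_phenotype)
    table = {
        AMBIENT: ("ambient", materials["ambient"]),
        GENERIC_TISSUE: ("generic_tissue", materials["generic_tissue"]),
        BONE: ("bone", materials["bone"]),
        SYNOVIAL_FLUID: ("synovial_fluid", materials["synovial_fluid"]),
        TURBID_PANNUS: ("turbid_pannus", materials["turbid_pannus"]),
    }
    if epi_name is not None:
        table[EPIDERMIS] = (epi_name, materials[epi_name])
    # keep only labels present (plus ambient which is always meaningful)
    present = set(np.unique(labels).tolist()) | {AMBIENT}
    table = {k: v for k, v in table.items() if k in present}
    return VoxelGrid(labels=labels, voxel_size=h, material_table=table)


def surface_normal(
    grid: VoxelGrid, position, direction=None, eps: float = 1e-6
):
    """Estimate the unit interface normal at ``position`` [mm].

    The normal is the normalized gradient of the Gaussian-smoothed (sigma =
    2 voxels) refractive-index field, evaluated by central differences at the
    voxel containing ``position``.  If ``direction`` (the photon's travel
    direction) is given, the normal is oriented to point from the medium
    being exited toward the medium being entered (dot(normal, direction) >= 0);
    otherwise it points toward increasing refractive index.  When the local
    gradient magnitude falls below ``eps`` (homogeneous neighbourhood), the
    axis-aligned face normal of the dominant offset axis is returned.
    """
    h = grid.voxel_size
    idx = np.floor(np.asarray(position, dtype=float) / h).astype(int)
    nxyz = grid.dims
    if np.any(idx < 0) or np.any(idx >= np.array(nxyz)):
        raise ValueError("position outside grid")
    ns = grid.smoothed_index_field()
    grad = np.empty(3)
    for ax in range(3):
        lo = idx.copy()
        hi = idx.copy()
        lo[ax] = max(idx[ax] - 1, 0)
        hi[ax] = min(idx[ax] + 1, nxyz[ax] - 1)
        grad[ax] = (ns[tuple(hi)] - ns[tuple(lo)]) / ((hi[ax] - lo[ax]) or 1)
    norm = np.linalg.norm(grad)
    if norm < eps:
        # degenerate: fall back to the voxel-face normal of the dominant axis
        center = (idx + 0.5) * h
        off = np.asarray(position, dtype=float) - center
        ax = int(np.argmax(np.abs(off)))
        grad = np.zeros(3)
        grad[ax] = np.sign(off[ax]) if off[ax] != 0 else 1.0
    else:
        grad /= norm
    if direction is not None and float(np.dot(grad, direction)) < 0:
        grad = -grad
    return grad


def save_grid(grid: VoxelGrid, basepath) -> None:
    """Write a grid as raw uint8 labels (C order) plus a JSON sidecar."""
    basepath = Path(basepath)
    grid.labels.tofile(basepath.with_suffix(".bin"))
    meta = {
        "dims": list(grid.dims),
        "voxel_size_mm": grid.voxel_size,
        "order": "C",
        "materials": {
            str(lbl): {
                "name": name,
                "mua": p.mua, "musp": p.musp, "g": p.g, "n": p.n,
            }
            for lbl, (name, p) in grid.material_table.items()
        },
    }
    basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_grid(basepath) -> VoxelGrid:
    """Read a grid written by :func:`save_grid`."""
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    labels = np.fromfile(basepath.with_suffix(".bin"), dtype=np.uint8).reshape(
        meta["dims"]
    )
    table = {
        int(lbl): (
            entry["name"],
            TissueOpticalProperties(
                mua=entry["mua"], musp=entry["musp"], g=entry["g"], n=entry["n"]
            ),
        )
        for lbl, entry in meta["materials"].items()
    }
    return VoxelGrid(labels=labels, voxel_size=meta["voxel_size_mm"],
                     material_table=table)
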