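"""Continuous-wave voxel Monte Carlo photon transport.

High-level API over the numba kernels in :mod:`nirjoint._kernel`: sources,
simulation configuration, batched runs with per-batch substreams for error
estimation, and an exact weight ledger (launched = absorbed + escaped +
roulette_net).  Single-photon operations (launch, scattering, Fresnel events,
roulette) are exposed as plain functions for testing and composition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import fresnel_unpolarized, hg_cos, spin_direction
from .phantom import VoxelGrid

__all__ = [
    "SURFACE_NAMES", "Photon", "SourceSpec", "SimulationConfig",
    "EscapeRecord", "TransportResult",
    "launch", "scatter_direction", "fresnel_interface", "roulette",
    "propagate", "run_simulation", "fresnel_reflectance",
]

SURFACE_NAMES = {
    _kernel.SURF_TRANSMISSION: "transmission",
    _kernel.SURF_REFLECTANCE: "reflectance",
    _kernel.SURF_LATERAL: "lateral",
}


@dataclass
class Photon:
    """Monte Carlo photon state."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-6:
            raise ValueError("direction must be a unit vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")


@dataclass(frozen=True)
class SourceSpec:
    """Illumination geometry.

    ``kind`` is ``"disk"`` (collimated uniform circular beam entering along
    ``direction``) or ``"isotropic"`` (isotropic point source inside the
    medium, used for diffusion-theory cross-checks).
    """

    center: tuple
    direction: tuple = (0.0, 0.0, -1.0)
    beam_radius: float = 1.0  # mm
    wavelength: float = 850.0  # nm
    kind: str = "disk"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("source direction must be a unit vector")
        if self.beam_radius < 0:
            raise ValueError("beam_radius must be non-negative")
        if self.kind not in ("disk", "isotropic"):
            raise ValueError(f"unknown source kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    photon_count: int = 100_000
    seed: int = 0
    weight_threshold: float = 1e-4
    roulette_survival: float = 0.1
    batch_count: int = 10

    def __post_init__(self) -> None:
        if self.photon_count < 1:
            raise ValueError("photon_count must be >= 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must be in (0, 1)")
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")


@dataclass(frozen=True)
class EscapeRecord:
    """One photon leaving the model: where, whither, and how much weight."""

    position: tuple
    direction: tuple
    weight: float
    surface: str


@dataclass
class TransportResult:
    """Escape table, absorption map and weight ledger of one simulation."""

    escapes: pd.DataFrame  # columns x,y,z,ux,uy,uz,weight,surface,batch
    absorbed: np.ndarray  # deposited weight per voxel
    launched: float
    escaped_weight: float
    roulette_net: float
    aborted: int
    seed: int
    batch_count: int

    @property
    def absorbed_weight(self) -> float:
        return float(self.absorbed.sum())

    @property
    def conservation_residual(self) -> float:
        """|launched - absorbed - escaped - roulette_net| / launched."""
        return abs(
            self.launched - self.absorbed_weight - self.escaped_weight
            - self.roulette_net
        ) / self.launched

    def save(self, basepath) -> None:
        """Persist the escape table (CSV) and run metadata (JSON)."""
        basepath = Path(basepath)
        self.escapes.to_csv(basepath.with_suffix(".csv"), index=False)
        meta = {
            "launched": self.launched,
            "escaped_weight": self.escaped_weight,
            "absorbed_weight": self.absorbed_weight,
            "roulette_net": self.roulette_net,
            "aborted": self.aborted,
            "seed": self.seed,
            "batch_count": self.batch_count,
            "conservation_residual": self.conservation_residual,
            "rng": "xorshift64* with splitmix64 (seed, batch, photon) hashing",
        }
        basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def fresnel_reflectance(cos_incidence: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel reflectance at incidence cosine ``cos_incidence``."""
    R, _ = fresnel_unpolarized(float(cos_incidence), float(n1), float(n2))
    return R


def launch(source: SourceSpec, rng: np.random.Generator) -> Photon:
    """Sample one photon from the source: uniform over the beam disk (or at
    the point for isotropic sources), unit weight."""
    d = np.asarray(source.direction, dtype=float)
    c = np.asarray(source.center, dtype=float)
    if source.kind == "isotropic":
        ct = 2.0 * rng.random() - 1.0
        phi = 2.0 * math.pi * rng.random()
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        u = np.array([st * math.cos(phi), st * math.sin(phi), ct])
        return Photon(position=c, direction=u)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    r = source.beam_radius * math.sqrt(rng.random())
    phi = 2.0 * math.pi * rng.random()
    pos = c + r * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return Photon(position=pos, direction=d)


def scatter_direction(direction, g: float, rng: np.random.Generator):
    """Henyey-Greenstein scatter: new unit direction after one event."""
    ct = hg_cos(float(g), rng.random())
    phi = 2.0 * math.pi * rng.random()
    ux, uy, uz = (float(v) for v in direction)
    return np.array(spin_direction(ux, uy, uz, ct, phi))


def fresnel_interface(direction, normal, n1: float, n2: float,
                      rng: np.random.Generator):
    """Stochastic Fresnel event at an index-mismatched interface.

    The normal is re-oriented to point from the medium being exited toward
    the medium being entered.  Returns ("reflected" | "refracted", new unit
    direction).
    """
    u = np.asarray(direction, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    ci = float(np.dot(u, nrm))
    if ci < 0:
        nrm = -nrm
        ci = -ci
    ci = min(ci, 1.0)
    R, ct = fresnel_unpolarized(ci, float(n1), float(n2))
    if rng.random() < R:
        out = u - 2.0 * ci * nrm
        return "reflected", out / np.linalg.norm(out)
    eta = n1 / n2
    out = eta * u + (ct - eta * ci) * nrm
    return "refracted", out / np.linalg.norm(out)


def roulette(photon: Photon, config: SimulationConfig,
             rng: np.random.Generator) -> Photon:
    """Russian roulette below the weight threshold; expected weight preserved."""
    if photon.weight >= config.weight_threshold:
        return photon
    if rng.random() < config.roulette_survival:
        photon.weight = photon.weight / config.roulette_survival
    else:
        photon.weight = 0.0
        photon.alive = False
    return photon


def _run_batches(grid: VoxelGrid, source: SourceSpec, config: SimulationConfig,
                 batch_sizes, batch_ids):
    """Trace the given batches; returns (escape frame, absorbed, ledger)."""
    mua, mus, g, n = grid.property_arrays()
    nsm = grid.smoothed_index_field()
    labels = grid.labels
    h = grid.voxel_size
    zc = grid.extent[2] / 2.0
    absorbed = np.zeros(labels.shape)
    kind = 0 if source.kind == "disk" else 1
    sx, sy, sz = (float(v) for v in source.center)
    sdx, sdy, sdz = (float(v) for v in source.direction)

    frames = []
    esc_weight = 0.0
    roulette_net = 0.0
    aborted = 0
    launched = 0.0
    for nb, bid in zip(batch_sizes, batch_ids):
        ex = np.empty(nb); ey = np.empty(nb); ez = np.empty(nb)
        eux = np.empty(nb); euy = np.empty(nb); euz = np.empty(nb)
        ew = np.empty(nb); es = np.empty(nb, dtype=np.int8)
        n_esc, w_esc, r_net, n_ab = _kernel.trace_batch(
            labels, mua, mus, g, n, nsm, h,
            kind, sx, sy, sz, sdx, sdy, sdz, float(source.beam_radius),
            nb, config.seed, bid,
            config.weight_threshold, config.roulette_survival, zc,
            absorbed,
            ex, ey, ez, eux, euy, euz, ew, es,
        )
        frames.append(pd.DataFrame({
            "x": ex[:n_esc], "y": ey[:n_esc], "z": ez[:n_esc],
            "ux": eux[:n_esc], "uy": euy[:n_esc], "uz": euz[:n_esc],
            "weight": ew[:n_esc], "surface": es[:n_esc],
            "batch": np.full(n_esc, bid, dtype=np.int32),
        }))
        esc_weight += w_esc
        roulette_net += r_net
        aborted += n_ab
        launched += nb
    escapes = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return escapes, absorbed, launched, esc_weight, roulette_net, aborted


def propagate(photon: Photon, grid: VoxelGrid, rng: np.random.Generator,
              config: SimulationConfig | None = None):
    """Trace a single already-launched photon through the grid.

    Returns (final Photon, deposited-weight map, EscapeRecord or None).
    Implemented on the batch kernel with a one-photon batch whose substream
    is drawn from ``rng``.
    """
    config = config or SimulationConfig(photon_count=1)
    src = SourceSpec(center=tuple(photon.position), beam_radius=0.0,
                     direction=tuple(photon.direction), kind="disk")
    seed = int(rng.integers(0, 2**31 - 1))
    cfg = SimulationConfig(
        photon_count=1, seed=seed,
        weight_threshold=config.weight_threshold,
        roulette_survival=config.roulette_survival, batch_count=1,
    )
    escapes, absorbed, *_ = _run_batches(grid, src, cfg, [1], [0])
    if len(escapes):
        row = escapes.iloc[0]
        rec = EscapeRecord(
            position=(row.x, row.y, row.z),
            direction=(row.ux, row.uy, row.uz),
            weight=float(row.weight),
            surface=SURFACE_NAMES[int(row.surface)],
        )
        out = Photon(position=np.array(rec.position),
                     direction=np.array(rec.direction),
                     weight=min(rec.weight, 1.0), alive=False)
        return out, absorbed, rec
    photon = Photon(position=photon.position, direction=photon.direction,
                    weight=0.0, alive=False)
    return photon, absorbed, None


def run_simulation(grid: VoxelGrid, source: SourceSpec,
                   config: SimulationConfig) -> TransportResult:
    """Trace ``config.photon_count`` photons in ``config.batch_count``
    independent sub-runs; deterministic for a fixed seed."""
    base = config.photon_count // config.batch_count
    sizes = [base] * config.batch_count
    sizes[-1] += config.photon_count - base * config.batch_count
    escapes, absorbed, launched, esc_w, r_net, aborted = _run_batches(
        grid, source, config, sizes, list(range(config.batch_count))
    )
    return TransportResult(
        escapes=escapes, absorbed=absorbed, launched=launched,
        escaped_weight=esc_w, roulette_net=r_net, aborted=aborted,
        seed=config.seed, batch_count=config.batch_count,
    )
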