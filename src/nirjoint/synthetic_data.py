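"""Synthetic inputs and analytic oracles.

Everything the test battery needs without external data: detector profiles
with known closed-form metrics (emulating the diffuse, smooth, unimodal
broadening of multiply scattered transmission), slab fixtures with
Beer-Lambert ballistic transmission, an infinite-medium diffusion-theory
Green's function, and simple voxel grids (slab, homogeneous block) for
transport-engine cross-checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .detector import DetectorSpec, IntensityProfile
from .mc_engine import fresnel_reflectance
from .phantom import VoxelGrid
from .spectra import TissueOpticalProperties

__all__ = [
    "SyntheticProfileSpec", "SlabFixture",
    "synth_profile", "diffusion_oracle", "slab_transmission_oracle",
    "slab_grid", "homogeneous_grid",
]


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Recipe for a synthetic detector profile with known ground truth."""

    shape: str = "gaussian"  # flat | gaussian | triangular
    amplitude: float = 1.0
    width: float = 3.0  # mm: gaussian sigma or triangular base half-width
    noise_sigma: float = 0.05  # multiplicative lognormal sigma (median 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("flat", "gaussian", "triangular"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _truth(spec: SyntheticProfileSpec, det: DetectorSpec,
           roi_width: float = 5.0) -> dict:
    """Noiseless closed-form ybar_c and W for the given shape (continuous
    forms; discretization error is bounded by the profile tests)."""
    A = spec.amplitude
    L = det.imaging_length
    if spec.shape == "flat":
        ybar = A
        area = A * L
    elif spec.shape == "gaussian":
        s = spec.width
        area = A * s * math.sqrt(2.0 * math.pi) * float(erf(L / (2.0 * math.sqrt(2) * s)))
        ybar = (A * s * math.sqrt(2.0 * math.pi)
                * float(erf(roi_width / (2.0 * math.sqrt(2) * s))) / roi_width)
    else:  # triangular, base half-width b
        b = spec.width
        area = A * b if b <= L / 2 else A * (L - L * L / (4 * b))
        w = roi_width
        if w / 2 <= b:
            ybar = A * (1.0 - w / (4.0 * b))
        else:
            ybar = A * b / w
    return {"y_bar_c": ybar, "W_mm": area / ybar, "area": area}


def synth_profile(spec: SyntheticProfileSpec,
                  det: DetectorSpec | None = None) -> IntensityProfile:
    """Deterministic synthetic profile; closed-form metric ground truth is
    attached under ``profile.meta["truth"]``.

    Noise is multiplicative lognormal (median 1): values *= exp(sigma * Z).
    """
    det = det or DetectorSpec.centered(0.0)
    x = det.bin_centers() - (det.origin + det.imaging_length / 2.0)
    A = spec.amplitude
    if spec.shape == "flat":
        y = np.full_like(x, A)
    elif spec.shape == "gaussian":
        y = A * np.exp(-0.5 * (x / spec.width) ** 2)
    else:
        y = A * np.clip(1.0 - np.abs(x) / spec.width, 0.0, None)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y * np.exp(spec.noise_sigma * rng.standard_normal(y.shape))
    return IntensityProfile(
        centers=det.bin_centers(), values=y, pitch=det.effective_pitch,
        meta={"truth": _truth(spec, det), "spec": spec.__dict__.copy()},
    )


def diffusion_oracle(mua: float, musp: float, r) -> float | np.ndarray:
    """Infinite-medium point-source diffusion fluence phi(r) [mm^-2].

    phi(r) = exp(-mueff_d * r) / (4 pi D r), with D = 1/(3(mua + musp)) and
    mueff_d = sqrt(3 mua (mua + musp)) (the diffusion-theory convention,
    which includes the absorption term the simpler sqrt(3 mua musp') form
    drops).  Valid in the scattering-dominated regime musp >> mua; a
    warning is emitted outside it.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if musp < 10.0 * mua:
        warnings.warn("diffusion oracle outside musp >> mua regime",
                      stacklevel=2)
    D = 1.0 / (3.0 * (mua + musp))
    mueff_d = math.sqrt(3.0 * mua * (mua + musp))
    out = np.exp(-mueff_d * r) / (4.0 * math.pi * D * r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SlabFixture:
    """Homogeneous slab bounded in z; oracle geometry for the engine."""

    thickness: float  # mm
    mua: float  # mm^-1
    mus: float  # mm^-1
    g: float = 0.0
    n_inside: float = 1.0
    n_outside: float = 1.0


def slab_transmission_oracle(fix: SlabFixture) -> float:
    """Ballistic (unscattered) transmission through the slab at normal
    incidence: exp(-mua * d) times the two boundary Fresnel transmissions.

    Requires mus = 0 (ballistic case)."""
    if fix.mus != 0:
        raise ValueError("ballistic oracle requires mus = 0")
    T = 1.0 - fresnel_reflectance(1.0, fix.n_outside, fix.n_inside)
    T2 = 1.0 - fresnel_reflectance(1.0, fix.n_inside, fix.n_outside)
    return math.exp(-fix.mua * fix.thickness) * T * T2


def _ambient() -> TissueOpticalProperties:
    return TissueOpticalProperties(mua=0.0, musp=0.0, g=0.0, n=1.0)


def slab_grid(fix: SlabFixture, voxel_size: float = 0.2,
              lateral: float = 20.0, pad: float = 1.0) -> VoxelGrid:
    """Voxelize a slab perpendicular to z, ambient above and below.

    The slab spans z in [pad, pad + thickness]; the grid is ``lateral`` mm
    wide in x and y.
    """
    h = voxel_size
    nxy = int(round(lateral / h))
    nz = int(round((fix.thickness + 2 * pad) / h))
    labels = np.zeros((nxy, nxy, nz), dtype=np.uint8)
    k0 = int(round(pad / h))
    k1 = int(round((pad + fix.thickness) / h))
    labels[:, :, k0:k1] = 1
    musp = fix.mus * (1.0 - fix.g)
    mat = TissueOpticalProperties(mua=fix.mua, musp=musp, g=fix.g, n=fix.n_inside)
    amb = TissueOpticalProperties(mua=0.0, musp=0.0, g=0.0, n=fix.n_outside)
    return VoxelGrid(labels=labels, voxel_size=h,
                     material_table={0: ("ambient", amb), 1: ("slab", mat)})


def homogeneous_grid(props: TissueOpticalProperties, extent: float = 30.0,
                     voxel_size: float = 0.3) -> VoxelGrid:
    """Homogeneous cubic block filling the whole grid (no ambient): photons
    escape only at the grid boundary.  Used for diffusion cross-checks with
    an interior isotropic source and matched indices."""
    n = int(round(extent / voxel_size))
    labels = np.ones((n, n, n), dtype=np.uint8)
    return VoxelGrid(labels=labels, voxel_size=voxel_size,
                     material_table={0: ("ambient", _ambient()),
                                     1: ("medium", props)})
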