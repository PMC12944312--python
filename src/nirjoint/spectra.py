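"""Chromophore absorption spectra and tissue composition rules.

Tissue absorption in the near infrared is modelled as a volume-fraction
mixture of a small set of chromophores: water, whole blood (oxy- and
deoxy-hemoglobin), lipid, and, for the epidermis, melanosomes on top of a
melanin-free baseline.  The module regenerates the absorption coefficients
of the finger-joint materials (synovial fluid, turbid pannus, generic soft
tissue, three epidermis phenotypes) from their composition statements.

Internal unit system is mm and mm^-1.  The embedded literature spectra are
stored as plain-text tables in their native cm^-1 (or molar extinction)
units and converted at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ChromophoreSpectrum",
    "TissueOpticalProperties",
    "CompositionRule",
    "chromophore_mua",
    "blood_mua",
    "compose_tissue",
    "epidermis_mua",
    "musp_to_mus",
    "load_materials",
]

#: grams per mole of the hemoglobin tetramer (whole-blood convention)
HEMOGLOBIN_MOLAR_MASS = 64500.0
#: default total hemoglobin content of whole blood [g/L]
DEFAULT_CHB = 150.0

_LN10 = math.log(10.0)
_RANGE = (650.0, 950.0)  # nm, tabulated coverage required of every spectrum

CHROMOPHORES = ("water", "hb", "hbo2", "lipid", "melanosome", "skin_baseline")


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Tabulated absorption spectrum of one chromophore, in mm^-1 vs nm."""

    name: str
    wavelengths: np.ndarray
    mua: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        mu = np.asarray(self.mua, dtype=float)
        if wl.ndim != 1 or wl.shape != mu.shape:
            raise ValueError("wavelengths and mua must be matching 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly increasing")
        if np.any(mu < 0):
            raise ValueError(f"{self.name}: mua must be non-negative")
        if wl[0] > _RANGE[0] or wl[-1] < _RANGE[1]:
            raise ValueError(f"{self.name}: spectrum must cover {_RANGE} nm")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mua", mu)

    def __call__(self, wavelength: float) -> float:
        """Linearly interpolated mua [mm^-1] at ``wavelength`` [nm]."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(
                f"{self.name}: {wavelength} nm outside tabulated range "
                f"[{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.mua))


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Optical properties of one material at one wavelength.

    Attributes
    ----------
    mua : absorption coefficient [mm^-1]
    musp : reduced scattering coefficient [mm^-1]
    g : scattering anisotropy (mean cosine of deflection), |g| < 1
    n : refractive index, >= 1
    """

    mua: float
    musp: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0 or self.musp < 0:
            raise ValueError("mua and musp must be non-negative")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def mus(self) -> float:
        """Full scattering coefficient mus = musp/(1-g) [mm^-1]."""
        return musp_to_mus(self.musp, self.g)


@dataclass(frozen=True)
class CompositionRule:
    """Volume-fraction mixture of chromophores; remainder is non-absorbing.

    ``components`` maps chromophore names (or ``"blood"``) to volume
    fractions in [0, 1].  ``so2`` and ``chb`` apply to the blood component
    only: hemoglobin oxygen saturation (fraction) and total hemoglobin
    content (g/L).
    """

    components: Mapping[str, float]
    so2: float = 0.0
    chb: float = DEFAULT_CHB

    def __post_init__(self) -> None:
        for name, frac in self.components.items():
            if name != "blood" and name not in CHROMOPHORES:
                raise ValueError(f"unknown component {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction of {name!r} must be in [0, 1]")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must be a fraction in [0, 1]")
        if self.chb < 0:
            raise ValueError("chb must be non-negative")


def _load_table(filename: str) -> np.ndarray:
    with resources.files("nirjoint.data").joinpath(filename).open("rb") as fh:
        return np.loadtxt(fh)


def _water() -> ChromophoreSpectrum:
    tab = _load_table("water_absorption.tsv")
    return ChromophoreSpectrum("water", tab[:, 0], tab[:, 1] / 10.0)


def _lipid() -> ChromophoreSpectrum:
    tab = _load_table("lipid_absorption.tsv")
    return ChromophoreSpectrum("lipid", tab[:, 0], tab[:, 1] / 10.0)


def _hemoglobin_extinction() -> np.ndarray:
    """Columns: wavelength [nm], eps_HbO2, eps_Hb [cm^-1 / (mol/L)]."""
    return _load_table("hemoglobin_extinction.tsv")


_CACHE: dict[str, object] = {}


def _cached(key: str, builder):
    if key not in _CACHE:
        _CACHE[key] = builder()
    return _CACHE[key]


def melanosome_mua(wavelength: float) -> float:
    """Interior melanosome absorption, mua = 6.6e11 * lambda^-3.33 cm^-1.

    The single-power-law melanosome approximation used by voxel transport
    codes; converted to mm^-1.
    """
    return 6.6e11 * wavelength ** -3.33 / 10.0


def skin_baseline_mua(wavelength: float) -> float:
    """Melanin-free epidermal baseline absorption [mm^-1].

    Exponential-plus-constant baseline, (0.0244 + 8.53*exp(-(lambda-154)/66.2))
    cm^-1; at 850 nm this is ~0.0025 mm^-1, the value consistent with the
    composed epidermis rows of the material catalog.
    """
    return (0.0244 + 8.53 * math.exp(-(wavelength - 154.0) / 66.2)) / 10.0


def chromophore_mua(name: str, wavelength: float) -> float:
    """Absorption coefficient [mm^-1] of a pure chromophore at ``wavelength``.

    ``hb`` and ``hbo2`` are reported as whole blood at the default
    hemoglobin content (fully deoxygenated / oxygenated).
    """
    if not _RANGE[0] <= wavelength <= _RANGE[1]:
        raise ValueError(f"wavelength {wavelength} nm outside {_RANGE}")
    if name == "water":
        return _cached("water", _water)(wavelength)
    if name == "lipid":
        return _cached("lipid", _lipid)(wavelength)
    if name == "melanosome":
        return melanosome_mua(wavelength)
    if name == "skin_baseline":
        return skin_baseline_mua(wavelength)
    if name == "hb":
        return blood_mua(wavelength, so2=0.0)
    if name == "hbo2":
        return blood_mua(wavelength, so2=1.0)
    raise ValueError(f"unknown chromophore {name!r}")


def blood_mua(wavelength: float, so2: float, chb: float = DEFAULT_CHB) -> float:
    """Whole-blood absorption coefficient [mm^-1].

    mua = ln(10) * [so2*eps_HbO2 + (1-so2)*eps_Hb] * C_Hb / M_Hb, with the
    base-10 molar extinction compilation and the tetramer molar mass.

    Parameters
    ----------
    wavelength : nm
    so2 : hemoglobin oxygen saturation, fraction in [0, 1]
    chb : total hemoglobin content [g/L]
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("so2 must be in [0, 1]")
    if chb < 0:
        raise ValueError("chb must be non-negative")
    tab = _cached("hemoglobin", _hemoglobin_extinction)
    wl = tab[:, 0]
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ValueError(
            f"wavelength {wavelength} nm outside hemoglobin compilation "
            f"[{wl[0]}, {wl[-1]}]"
        )
    eps_hbo2 = np.interp(wavelength, wl, tab[:, 1])
    eps_hb = np.interp(wavelength, wl, tab[:, 2])
    eps = so2 * eps_hbo2 + (1.0 - so2) * eps_hb
    molarity = chb / HEMOGLOBIN_MOLAR_MASS  # mol/L
    return _LN10 * eps * molarity / 10.0  # cm^-1 -> mm^-1


def compose_tissue(
    rule: CompositionRule,
    wavelength: float,
    musp: float,
    g: float,
    n: float,
) -> TissueOpticalProperties:
    """Mix chromophore absorptions by volume fraction; pass scattering through.

    mua = sum_i f_i * mua_i(wavelength), the blood component evaluated via
    :func:`blood_mua` at the rule's oxygen saturation and hemoglobin content.
    """
    mua = 0.0
    for name, frac in rule.components.items():
        if name == "blood":
            mua += frac * blood_mua(wavelength, rule.so2, rule.chb)
        else:
            mua += frac * chromophore_mua(name, wavelength)
    return TissueOpticalProperties(mua=mua, musp=musp, g=g, n=n)


def epidermis_mua(fmel: float, wavelength: float) -> float:
    """Epidermal absorption [mm^-1] at melanosome volume fraction ``fmel``.

    mua = fmel * mua_melanosome + (1 - fmel) * mua_baseline.
    """
    if not 0.0 <= fmel <= 1.0:
        raise ValueError("fmel must be in [0, 1]")
    return fmel * melanosome_mua(wavelength) + (1.0 - fmel) * skin_baseline_mua(
        wavelength
    )


def musp_to_mus(musp: float, g: float) -> float:
    """Full scattering coefficient mus = musp/(1-g) [mm^-1]."""
    if g >= 1.0:
        raise ValueError("g must be < 1 to recover mus from musp")
    return musp / (1.0 - g)


def load_materials(path=None, wavelength: float | None = None):
    """Load the material catalog and realize it as optical properties.

    Parameters
    ----------
    path : optional path to a YAML catalog; defaults to the packaged
        850 nm finger-joint catalog.
    wavelength : evaluate composition rules at this wavelength [nm];
        defaults to the catalog's own ``wavelength_nm``.

    Returns
    -------
    dict mapping material name -> :class:`TissueOpticalProperties`.
    """
    if path is None:
        with resources.files("nirjoint.data").joinpath("materials.yaml").open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    wl = float(wavelength if wavelength is not None else cfg["wavelength_nm"])
    out: dict[str, TissueOpticalProperties] = {}
    for name, entry in cfg["materials"].items():
        if "literal" in entry:
            out[name] = TissueOpticalProperties(**entry["literal"])
        else:
            comp = entry["composition"]
            rule = CompositionRule(
                components=comp["components"],
                so2=float(comp.get("so2", 0.0)),
                chb=float(comp.get("chb_g_per_l", DEFAULT_CHB)),
            )
            out[name] = compose_tissue(
                rule, wl, musp=float(entry["musp"]), g=float(entry["g"]),
                n=float(entry["n"]),
            )
    return out
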