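"""Simulation campaigns: RA progression and skin-phenotype robustness.

Two campaigns mirror the study design: (1) disease progression from healthy
(0%) to grade-2 (100%) severity without an epidermis, tracking the central
transmission flux ybar_c, the equivalent width W and reflectance ROI fluxes;
(2) a skin-phenotype sweep (light/medium/dark melanosome fractions) probing
the robustness of both metrics, including the dark-skin beam-width
inversion.  Each run escalates its photon budget (doubling schedule) until
the Monte Carlo relative error of the monitored ROIs falls below the target
(default 5%), then reports per-photon-normalized metrics.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import DetectorSpec, IntensityProfile, ROISpec, relative_error, roi_flux
from .mc_engine import SimulationConfig, SourceSpec, _run_batches
from .metrics import MetricSet, central_flux, equivalent_width, percent_change, sensitivity_ratio
from .phantom import FingerModelConfig, build_finger, severity_to_geometry
from .spectra import load_materials
from . import detector as _det

__all__ = [
    "CampaignConfig", "ConvergenceReport", "ExperimentResult",
    "escalate_until_converged", "run_single_model",
    "run_progression", "run_skin_sweep",
]

#: reflectance ROI centers, mm from the source along +x
REFLECTANCE_ROI_OFFSETS = (5.0, 10.0, 15.0)
ROI_WIDTH = 5.0  # mm


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions of one simulation campaign."""

    severities: tuple = (0.0, 25.0, 50.0, 75.0, 100.0)
    phenotypes: tuple = ("none",)
    initial_photons: int = 100_000
    max_photons: int = 1_600_000
    min_photons: int = 0
    target_rel_err: float = 0.05
    batch_count: int = 10  # batches per schedule stage
    seed: int = 0
    voxel_size: float = 0.2  # mm
    beam_radius: float = 1.0  # mm
    grid_extent: tuple = (30.0, 24.0, 24.0)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if any(not 0 <= s <= 100 for s in self.severities):
            raise ValueError("severities must lie in [0, 100]")
        if not 0 < self.target_rel_err < 1:
            raise ValueError("target relative error must be in (0, 1)")
        if self.max_photons < self.initial_photons:
            raise ValueError("max_photons must be >= initial_photons")

    def schedule(self) -> list:
        """Doubling photon-budget schedule from initial to max."""
        out = [self.initial_photons]
        while out[-1] < self.max_photons:
            out.append(min(out[-1] * 2, self.max_photons))
        return out


@dataclass
class ConvergenceReport:
    photons_used: int
    rel_errors: dict
    converged: bool
    batch_fluxes: dict


@dataclass
class ExperimentResult:
    """Tidy per-(severity, phenotype) metric table plus derived summaries."""

    table: pd.DataFrame
    summary: pd.DataFrame
    profiles: dict  # (severity, phenotype) -> {"transmission": ..., "reflectance": ...}
    config: CampaignConfig

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "metrics.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        (outdir / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        for (sev, phen), profs in self.profiles.items():
            for surf, prof in profs.items():
                _det.write_profile(
                    prof, outdir / f"profile_{surf}_s{sev:g}_{phen}.csv"
                )


def escalate_until_converged(run_batch, batch_size: int, schedule,
                             target: float, min_photons: int = 0) -> ConvergenceReport:
    """Run batches until every monitored flux has relative error < target.

    ``run_batch(batch_index) -> dict[name, flux]`` executes one batch of
    ``batch_size`` photons.  Convergence is checked at each checkpoint of
    the doubling ``schedule``; the loop never stops before ``min_photons``.
    """
    fluxes: dict = defaultdict(list)
    total = 0
    bid = 0
    rels: dict = {}
    converged = False
    for checkpoint in schedule:
        while total < checkpoint:
            vals = run_batch(bid)
            bid += 1
            total += batch_size
            for k, v in vals.items():
                fluxes[k].append(v)
        rels = {k: relative_error(v) for k, v in fluxes.items()}
        if total >= min_photons and max(rels.values()) < target:
            converged = True
            break
    return ConvergenceReport(
        photons_used=total, rel_errors=rels, converged=converged,
        batch_fluxes={k: np.asarray(v) for k, v in fluxes.items()},
    )


def _finger_setup(severity: float, phenotype: str, cfg: CampaignConfig,
                  materials):
    geom = severity_to_geometry(severity)
    model = FingerModelConfig(
        skin_phenotype=phenotype,
        voxel_size=cfg.voxel_size,
        epidermis_thickness=max(0.10, cfg.voxel_size),
        grid_extent=cfg.grid_extent,
    )
    grid = build_finger(geom, model, materials=materials)
    ex, ey, ez = grid.extent
    source = SourceSpec(
        center=(ex / 2.0, ey / 2.0, ez - grid.voxel_size / 2.0),
        direction=(0.0, 0.0, -1.0),
        beam_radius=cfg.beam_radius,
    )
    trans_det = DetectorSpec.centered(ex / 2.0, transverse_center=ey / 2.0)
    refl_det = DetectorSpec.centered(ex / 2.0, transverse_center=ey / 2.0)
    return grid, source, trans_det, refl_det


def run_single_model(severity: float, phenotype: str, cfg: CampaignConfig,
                     run_seed: int, materials=None):
    """Escalating simulation of one finger model; returns
    (MetricSet, ConvergenceReport, profiles dict)."""
    if materials is None:
        materials = load_materials()
    grid, source, trans_det, refl_det = _finger_setup(
        severity, phenotype, cfg, materials
    )
    batch_size = max(cfg.initial_photons // cfg.batch_count, 1)
    sim = SimulationConfig(
        photon_count=batch_size, seed=run_seed, batch_count=1
    )
    source_x = source.center[0]
    central_roi = ROISpec(center=source_x, width=ROI_WIDTH)
    refl10 = ROISpec(center=source_x + 10.0, width=ROI_WIDTH)

    trans_profiles: list = []
    refl_profiles: list = []

    def run_batch(bid: int) -> dict:
        escapes, _, launched, *_ = _run_batches(
            grid, source, sim, [batch_size], [bid]
        )
        tp = _det.bin_escapes(escapes, trans_det, "transmission",
                              total_launched=launched)
        rp = _det.bin_escapes(escapes, refl_det, "reflectance",
                              total_launched=launched)
        trans_profiles.append(tp.values)
        refl_profiles.append(rp.values)
        return {
            "y_bar_c": central_flux(tp, width=ROI_WIDTH, center=source_x),
            "refl_10mm": roi_flux(rp, refl10),
        }

    report = escalate_until_converged(
        run_batch, batch_size, cfg.schedule(), cfg.target_rel_err,
        min_photons=cfg.min_photons,
    )

    tvals = np.mean(trans_profiles, axis=0)
    rvals = np.mean(refl_profiles, axis=0)
    tprof = IntensityProfile(
        centers=trans_det.bin_centers(), values=tvals,
        pitch=trans_det.effective_pitch,
        meta={"surface": "transmission", "per_photon": True,
              "roi_width_mm": ROI_WIDTH},
    )
    rprof = IntensityProfile(
        centers=refl_det.bin_centers(), values=rvals,
        pitch=refl_det.effective_pitch,
        meta={"surface": "reflectance", "per_photon": True},
    )
    refl_fluxes = {
        off: roi_flux(rprof, ROISpec(center=source_x + off, width=ROI_WIDTH))
        for off in REFLECTANCE_ROI_OFFSETS
    }
    ms = MetricSet(
        y_bar_c=central_flux(tprof, width=ROI_WIDTH, center=source_x),
        W=equivalent_width(tprof, width=ROI_WIDTH, center=source_x),
        reflectance=refl_fluxes,
        severity=severity,
        phenotype=phenotype,
    )
    return ms, report, {"transmission": tprof, "reflectance": rprof}


def _run_campaign(cfg: CampaignConfig) -> ExperimentResult:
    materials = load_materials()
    rows = []
    profiles = {}
    metric_sets = {}
    idx = 0
    for phen in cfg.phenotypes:
        for sev in cfg.severities:
            run_seed = (cfg.seed * 1_000_003 + idx * 97) % (2**31 - 1)
            idx += 1
            ms, rep, profs = run_single_model(sev, phen, cfg, run_seed,
                                              materials=materials)
            metric_sets[(sev, phen)] = ms
            profiles[(sev, phen)] = profs
            row = ms.as_row()
            row.update({
                "photons": rep.photons_used,
                "converged": rep.converged,
                **{f"rel_err_{k}": v for k, v in rep.rel_errors.items()},
            })
            rows.append(row)
    table = pd.DataFrame(rows)

    summary_rows = []
    for phen in cfg.phenotypes:
        sevs = sorted(s for (s, p) in metric_sets if p == phen)
        if 0.0 in sevs and 100.0 in sevs:
            m0 = metric_sets[(0.0, phen)]
            m100 = metric_sets[(100.0, phen)]
            ratio = sensitivity_ratio(m100.y_bar_c, m0.y_bar_c)
            summary_rows.append({
                "phenotype": phen,
                "sensitivity_ratio": ratio,
                "relative_drop_percent": 100.0 * (1.0 - ratio),
                "W_change_percent": percent_change(m0.W, m100.W),
            })
    summary = pd.DataFrame(summary_rows)
    result = ExperimentResult(table=table, summary=summary, profiles=profiles,
                              config=cfg)
    if cfg.output_dir:
        result.save(cfg.output_dir)
    return result


def plot_campaign(result: ExperimentResult, path) -> None:
    """Diagnostic figure: ybar_c and W versus severity per phenotype."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for phen, tab in result.table.groupby("phenotype"):
        tab = tab.sort_values("severity")
        ax1.semilogy(tab.severity, tab.y_bar_c, "o-", label=phen)
        ax2.plot(tab.severity, tab.W_mm, "s-", label=phen)
    ax1.set_xlabel("RA severity [%]")
    ax1.set_ylabel(r"central flux $\bar{y}_c$ [per photon]")
    ax2.set_xlabel("RA severity [%]")
    ax2.set_ylabel("equivalent width W [mm]")
    ax1.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_progression(cfg: CampaignConfig | None = None) -> ExperimentResult:
    """RA progression campaign (no epidermis): healthy to grade 2."""
    cfg = cfg or CampaignConfig()
    if tuple(cfg.phenotypes) != ("none",):
        raise ValueError("progression campaign models no epidermis")
    return _run_campaign(cfg)


def run_skin_sweep(cfg: CampaignConfig | None = None) -> ExperimentResult:
    """Skin-phenotype robustness campaign (epidermis shell per phenotype)."""
    cfg = cfg or CampaignConfig(phenotypes=("light", "medium", "dark"),
                                severities=(0.0, 100.0))
    if not set(cfg.phenotypes) <= {"light", "medium", "dark"}:
        raise ValueError("skin sweep phenotypes must be light/medium/dark")
    if not {0.0, 100.0} <= {float(s) for s in cfg.severities}:
        raise ValueError("skin sweep requires severities 0 and 100")
    return _run_campaign(cfg)
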