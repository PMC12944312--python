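"""Transport-engine operations and invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from nirjoint import _kernel
from nirjoint import mc_engine as mc
from nirjoint.spectra import TissueOpticalProperties
from nirjoint.synthetic_data import (
    SlabFixture,
    slab_grid,
    slab_transmission_oracle,
)


def test_launch_point_beam_and_determinism():
    src = mc.SourceSpec(center=(1.0, 2.0, 3.0), beam_radius=0.0)
    p = mc.launch(src, np.random.default_rng(7))
    assert np.allclose(p.position, [1, 2, 3])
    assert np.allclose(p.direction, [0, 0, -1])
    assert p.weight == 1.0
    a = mc.launch(mc.SourceSpec(center=(0, 0, 0), beam_radius=2.0),
                  np.random.default_rng(11))
    b = mc.launch(mc.SourceSpec(center=(0, 0, 0), beam_radius=2.0),
                  np.random.default_rng(11))
    assert np.array_equal(a.position, b.position)


def test_launch_mean_radius_uniform_disk(rng):
    src = mc.SourceSpec(center=(0.0, 0.0, 0.0), beam_radius=1.5)
    n = 20_000
    r = np.array([
        np.linalg.norm(mc.launch(src, rng).position[:2]) for _ in range(n)
    ])
    # uniform disk: E[r] = 2R/3, Var[r] = R^2/18
    se = 1.5 / math.sqrt(18 * n)
    assert abs(r.mean() - 2 * 1.5 / 3) < 3 * se


def test_scatter_direction_unit_norm_and_isotropic_limit(rng):
    for _ in range(100):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        out = mc.scatter_direction(u, 0.9, rng)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)
    # g = 0: deflection cosine uniform on [-1, 1]
    cts = _kernel.hg_cos_sample(0.0, 200_000, 42)
    assert abs(cts.mean()) < 3 / math.sqrt(3 * 200_000)
    assert cts.var() == pytest.approx(1 / 3, rel=0.02)


def test_hg_mean_cosine_matches_anisotropy():
    n = 1_000_000
    for g in (0.5, 0.9):
        cts = _kernel.hg_cos_sample(g, n, 7)
        # Var of HG cosine = 1 + g^2 - ((1-g^2)/(2g) * ln((1+g)/(1-g)))... use
        # the sample variance for the standard error
        se = cts.std() / math.sqrt(n)
        assert abs(cts.mean() - g) < 3 * se


def test_fresnel_normal_incidence_closed_form():
    assert mc.fresnel_reflectance(1.0, 1.0, 1.4) == pytest.approx(
        (0.4 / 2.4) ** 2, abs=1e-12
    )
    assert mc.fresnel_reflectance(1.0, 1.5, 1.5) == 0.0


def test_fresnel_interface_matched_and_tir(rng):
    u = np.array([0.0, 0.0, 1.0])
    event, out = mc.fresnel_interface(u, [0, 0, 1], 1.4, 1.4, rng)
    assert event == "refracted" and np.allclose(out, u)
    # 70 degrees incidence from n=1.55 into n=1.34: beyond the critical angle
    th = math.radians(70.0)
    u = np.array([math.sin(th), 0.0, math.cos(th)])
    for _ in range(50):
        event, out = mc.fresnel_interface(u, [0, 0, 1], 1.55, 1.34, rng)
        assert event == "reflected"
        assert out[2] == pytest.approx(-math.cos(th), abs=1e-9)


def test_snells_law_refraction(rng):
    th = math.radians(30.0)
    u = np.array([math.sin(th), 0.0, math.cos(th)])
    n1, n2 = 1.0, 1.4
    outs = []
    for _ in range(200):
        event, out = mc.fresnel_interface(u, [0, 0, 1], n1, n2, rng)
        if event == "refracted":
            outs.append(out)
    sin_t = np.array(outs)[:, 0]
    assert np.allclose(sin_t, n1 * math.sin(th) / n2, atol=1e-9)


def test_roulette_amplification_and_mean_preservation(rng):
    cfg = mc.SimulationConfig(weight_threshold=1e-2, roulette_survival=0.1)
    p = mc.Photon(position=np.zeros(3), direction=[0, 0, 1], weight=1e-3)
    out = mc.roulette(p, cfg, np.random.default_rng(0))
    assert out.weight in (0.0, pytest.approx(1e-2))
    # expected weight preserved across an ensemble
    n = 20_000
    w = 1e-3
    outs = np.array([
        mc.roulette(
            mc.Photon(position=np.zeros(3), direction=[0, 0, 1], weight=w),
            cfg, rng,
        ).weight
        for _ in range(n)
    ])
    se = outs.std() / math.sqrt(n)
    assert abs(outs.mean() - w) < 3 * se
    # above threshold: untouched
    p = mc.Photon(position=np.zeros(3), direction=[0, 0, 1], weight=0.5)
    assert mc.roulette(p, cfg, rng).weight == 0.5


@pytest.fixture(scope="module")
def ballistic_grid():
    fix = SlabFixture(thickness=2.0, mua=0.5, mus=0.0)
    return fix, slab_grid(fix, voxel_size=0.2, lateral=10.0)


def test_ballistic_beer_lambert(ballistic_grid):
    fix, grid = ballistic_grid
    ez = grid.extent[2]
    src = mc.SourceSpec(center=(5.0, 5.0, ez - 0.1), beam_radius=0.0)
    res = mc.run_simulation(grid, src,
                            mc.SimulationConfig(photon_count=40_000, seed=3))
    esc = res.escapes
    sel = esc.surface == _kernel.SURF_TRANSMISSION
    trans = esc.weight[sel].sum() / res.launched
    expected = slab_transmission_oracle(fix)
    se = math.sqrt(expected * (1 - expected) / res.launched)
    assert abs(trans - expected) < 3 * se
    assert res.conservation_residual < 1e-6


def test_vacuum_region_straight_line():
    amb = TissueOpticalProperties(mua=0.0, musp=0.0, g=0.0, n=1.0)
    labels = np.zeros((20, 20, 20), dtype=np.uint8)
    grid = mc.VoxelGrid(labels=labels, voxel_size=0.5,
                        material_table={0: ("ambient", amb)})
    start = mc.Photon(position=np.array([5.0, 5.0, 9.9]),
                      direction=np.array([0.0, 0.0, -1.0]))
    out, absorbed, rec = mc.propagate(start, grid, np.random.default_rng(1))
    assert rec is not None
    assert rec.weight == 1.0
    assert np.allclose(rec.direction, [0, 0, -1])
    assert absorbed.sum() == 0.0


def test_run_simulation_deterministic_and_conservative(ballistic_grid):
    _, grid = ballistic_grid
    ez = grid.extent[2]
    src = mc.SourceSpec(center=(5.0, 5.0, ez - 0.1), beam_radius=1.0)
    cfg = mc.SimulationConfig(photon_count=5_000, seed=99)
    a = mc.run_simulation(grid, src, cfg)
    b = mc.run_simulation(grid, src, cfg)
    pd.testing.assert_frame_equal(a.escapes, b.escapes)
    assert a.conservation_residual < 1e-6
    # distinct seeds give distinct substreams
    c = mc.run_simulation(grid, src,
                          mc.SimulationConfig(photon_count=5_000, seed=100))
    assert not np.array_equal(a.escapes.x.to_numpy(), c.escapes.x.to_numpy())


def test_result_save_roundtrip(tmp_path, ballistic_grid):
    _, grid = ballistic_grid
    ez = grid.extent[2]
    src = mc.SourceSpec(center=(5.0, 5.0, ez - 0.1))
    res = mc.run_simulation(grid, src,
                            mc.SimulationConfig(photon_count=1_000, seed=5))
    res.save(tmp_path / "run")
    back = pd.read_csv(tmp_path / "run.csv")
    assert len(back) == len(res.escapes)
    import json

    meta = json.loads((tmp_path / "run.json").read_text())
    assert meta["conservation_residual"] < 1e-6
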