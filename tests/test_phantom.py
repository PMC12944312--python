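"""Finger-joint voxel phantom construction."""

import math

import numpy as np
import pytest

from nirjoint import phantom as ph

TABLE2 = [
    (0, "synovial_fluid", 0.50, 0.00, 8.0),
    (25, "turbid_pannus", 0.75, 0.25, 8.5),
    (50, "turbid_pannus", 1.00, 0.50, 9.0),
    (75, "turbid_pannus", 1.25, 0.75, 9.5),
    (100, "turbid_pannus", 1.50, 1.00, 10.0),
]


@pytest.mark.parametrize("sev,mat,thick,swell,extent", TABLE2)
def test_severity_mapping_reference_rows(sev, mat, thick, swell, extent):
    g = ph.severity_to_geometry(sev)
    assert g.joint_layer_material == mat
    assert g.layer_thickness == pytest.approx(thick, abs=1e-12)
    assert g.joint_swelling == pytest.approx(swell, abs=1e-12)
    assert g.lateral_extent == pytest.approx(extent, abs=1e-12)


def test_severity_mapping_interpolates_between_rows():
    g = ph.severity_to_geometry(60)
    assert (g.layer_thickness, g.joint_swelling, g.lateral_extent) == (
        pytest.approx(1.10),
        pytest.approx(0.60),
        pytest.approx(9.2),
    )


def test_severity_out_of_range():
    with pytest.raises(ValueError):
        ph.severity_to_geometry(101)


@pytest.fixture(scope="module")
def grid50(materials_module):
    geom = ph.severity_to_geometry(50)
    cfg = ph.FingerModelConfig(voxel_size=0.2, epidermis_thickness=0.2)
    return ph.build_finger(geom, cfg, materials=materials_module)


@pytest.fixture(scope="module")
def materials_module():
    from nirjoint.spectra import load_materials

    return load_materials()


def test_core_and_annulus_labels(grid50):
    h = grid50.voxel_size
    nx, ny, nz = grid50.dims
    ic, jc, kc = nx // 2, ny // 2, nz // 2
    assert grid50.labels[ic, jc, kc] == ph.BONE
    # a voxel in the joint plane at radius bone_radius + thickness/2
    r = 3.0 + 0.5
    kk = int((nz * h / 2 + r) / h)
    assert grid50.labels[ic, jc, kk] == ph.TURBID_PANNUS


def test_label_partition_and_determinism(grid50, materials_module):
    # every voxel carries a label present in the material table
    present = set(np.unique(grid50.labels).tolist())
    assert present <= set(grid50.material_table)
    geom = ph.severity_to_geometry(50)
    cfg = ph.FingerModelConfig(voxel_size=0.2, epidermis_thickness=0.2)
    again = ph.build_finger(geom, cfg, materials=materials_module)
    assert np.array_equal(grid50.labels, again.labels)


def test_healthy_outer_radius_uniform(materials_module):
    geom = ph.severity_to_geometry(0)
    cfg = ph.FingerModelConfig(voxel_size=0.2, epidermis_thickness=0.2)
    grid = ph.build_finger(geom, cfg, materials=materials_module)
    counts = (grid.labels != ph.AMBIENT).sum(axis=(1, 2))
    assert counts.min() == counts.max()  # no swelling anywhere
    assert (grid.labels == ph.SYNOVIAL_FLUID).sum() > 0


def test_pannus_volume_matches_analytic_annulus(materials_module):
    geom = ph.severity_to_geometry(100)
    cfg = ph.FingerModelConfig(voxel_size=0.2, epidermis_thickness=0.2)
    grid = ph.build_finger(geom, cfg, materials=materials_module)
    vox = (grid.labels == ph.TURBID_PANNUS).sum() * grid.voxel_size**3
    rb, t, L = cfg.bone_radius, geom.layer_thickness, geom.lateral_extent
    analytic = math.pi * ((rb + t) ** 2 - rb**2) * L
    # surface-layer discretization error bound
    area = 2 * math.pi * (2 * rb + t) * L + 2 * math.pi * ((rb + t) ** 2 - rb**2)
    assert abs(vox - analytic) < 2 * grid.voxel_size * area


def test_epidermis_shell_is_outermost(materials_module):
    geom = ph.severity_to_geometry(0)
    cfg = ph.FingerModelConfig(voxel_size=0.2, epidermis_thickness=0.2,
                               skin_phenotype="dark")
    grid = ph.build_finger(geom, cfg, materials=materials_module)
    nx, ny, nz = grid.dims
    h = grid.voxel_size
    jc = ny // 2
    # walking inward from the top of the grid at the mid-slice: first
    # non-ambient voxel must be epidermis
    col = grid.labels[nx // 2, jc, :]
    top = np.nonzero(col != ph.AMBIENT)[0].max()
    assert col[top] == ph.EPIDERMIS


def test_surface_normal_slab_exact():
    from nirjoint.synthetic_data import SlabFixture, slab_grid

    grid = slab_grid(SlabFixture(thickness=2.0, mua=0.1, mus=0.0, n_inside=1.4),
                     voxel_size=0.2, lateral=6.0)
    # voxel just inside the upper slab face
    z_face = 1.0 + 2.0  # pad + thickness
    n = ph.surface_normal(grid, (3.0, 3.0, z_face - 0.1), direction=(0, 0, 1))
    assert np.allclose(n, [0, 0, 1], atol=1e-6)


def test_surface_normal_cylinder_radial(materials_module):
    # default-resolution grid: voxel size well under a tenth of the radius
    geom = ph.severity_to_geometry(50)
    grid = ph.build_finger(geom, ph.FingerModelConfig(voxel_size=0.1),
                           materials=materials_module)
    h = grid.voxel_size
    nx, ny, nz = grid.dims
    yc, zc = ny * h / 2, nz * h / 2
    R = 7.5
    worst = 0.0
    for theta in np.linspace(0, 2 * math.pi, 24, endpoint=False):
        # point just inside the outer surface, away from the joint plane
        y = yc + (R - 0.55 * h) * math.cos(theta)
        z = zc + (R - 0.55 * h) * math.sin(theta)
        n = ph.surface_normal(grid, (2.0, y, z),
                              direction=(0, math.cos(theta), math.sin(theta)))
        radial = np.array([0.0, math.cos(theta), math.sin(theta)])
        ang = math.degrees(math.acos(np.clip(np.dot(n, radial), -1, 1)))
        worst = max(worst, ang)
    assert worst < 5.0


def test_surface_normal_degenerate_interior(grid50):
    h = grid50.voxel_size
    nx, ny, nz = grid50.dims
    # deep inside the bone: homogeneous neighbourhood, axis-aligned fallback
    pos = (nx * h / 2 + 0.03, ny * h / 2, nz * h / 2)
    n = ph.surface_normal(grid50, pos)
    assert np.linalg.norm(n) == pytest.approx(1.0)
    assert np.sum(n != 0) == 1


def test_grid_roundtrip(tmp_path, grid50):
    ph.save_grid(grid50, tmp_path / "grid")
    back = ph.load_grid(tmp_path / "grid")
    assert np.array_equal(back.labels, grid50.labels)
    assert back.voxel_size == grid50.voxel_size
    assert back.material_table[ph.BONE][1].n == pytest.approx(1.55)
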