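"""Diagnostic metric definitions and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nirjoint import metrics as met
from nirjoint.detector import DetectorSpec, IntensityProfile
from nirjoint.synthetic_data import SyntheticProfileSpec, synth_profile


def _flat(v=1.0, spec=None):
    spec = spec or DetectorSpec.centered(0.0)
    return IntensityProfile(centers=spec.bin_centers(),
                            values=np.full(spec.effective_pixels, v),
                            pitch=spec.effective_pitch)


def test_central_flux_flat():
    assert met.central_flux(_flat(0.7)) == pytest.approx(0.7)


def test_central_flux_peaked_exceeds_global_mean():
    prof = synth_profile(SyntheticProfileSpec(shape="triangular", width=6.0,
                                              noise_sigma=0.0))
    assert met.central_flux(prof) > prof.values.mean()


def test_central_flux_gaussian_matches_quadrature():
    sigma = 3.0
    prof = synth_profile(SyntheticProfileSpec(shape="gaussian", width=sigma,
                                              noise_sigma=0.0))
    # independent fine-quadrature evaluation of the ROI mean
    f = lambda x: math.exp(-0.5 * (x / sigma) ** 2)
    oracle = quad(f, -2.5, 2.5)[0] / 5.0
    assert met.central_flux(prof) == pytest.approx(oracle, rel=0.01)


def test_equivalent_width_flat_identity():
    prof = _flat(3.2)
    assert met.equivalent_width(prof) == pytest.approx(28.672, rel=1e-12)


def test_equivalent_width_gaussian_matches_quadrature():
    sigma = 3.0
    prof = synth_profile(SyntheticProfileSpec(shape="gaussian", width=sigma,
                                              noise_sigma=0.0))
    f = lambda x: math.exp(-0.5 * (x / sigma) ** 2)
    L = 28.672
    area = quad(f, -L / 2, L / 2)[0]
    ybar = quad(f, -2.5, 2.5)[0] / 5.0
    assert met.equivalent_width(prof) == pytest.approx(area / ybar, rel=0.01)


def test_equivalent_width_scale_and_shift_invariance():
    prof = synth_profile(SyntheticProfileSpec(shape="gaussian", width=2.0,
                                              noise_sigma=0.05, seed=3))
    w = met.equivalent_width(prof)
    scaled = IntensityProfile(centers=prof.centers, values=prof.values * 17.0,
                              pitch=prof.pitch)
    assert met.equivalent_width(scaled) == pytest.approx(w, rel=1e-12)
    shifted = IntensityProfile(centers=prof.centers + 4.0, values=prof.values,
                               pitch=prof.pitch)
    assert met.equivalent_width(shifted) == pytest.approx(w, rel=1e-12)


def test_sensitivity_ratio():
    assert met.sensitivity_ratio(5.0, 5.0) == 1.0
    assert met.sensitivity_ratio(0.3, 1.0) == pytest.approx(0.3)
    assert met.sensitivity_ratio(3.0, 10.0) == pytest.approx(
        met.sensitivity_ratio(0.3, 1.0)
    )
    with pytest.raises(ValueError):
        met.sensitivity_ratio(1.0, 0.0)


@settings(deadline=None, max_examples=50)
@given(w0=st.floats(0.1, 100.0), w100=st.floats(0.01, 100.0))
def test_percent_change_sign_marks_inversion(w0, w100):
    pc = met.percent_change(w0, w100)
    assert (pc < 0) == (w100 < w0)


def test_percent_change_values():
    assert met.percent_change(10.0, 10.0) == 0.0
    assert met.percent_change(10.0, 15.0) == pytest.approx(50.0)


def test_mueff_values():
    assert met.mueff(0.0, 5.0) == 0.0
    # turbid pannus at the catalog scattering: hand evaluation
    assert met.mueff(0.04091, 1.288) == pytest.approx(0.39759, rel=1e-4)


@settings(deadline=None, max_examples=50)
@given(a=st.floats(1e-4, 1.0), b=st.floats(1e-3, 10.0),
       k=st.floats(1.1, 5.0))
def test_mueff_monotone(a, b, k):
    assert met.mueff(k * a, b) > met.mueff(a, b)
    assert met.mueff(a, k * b) > met.mueff(a, b)


def test_mueff_in_vivo_percent_increase():
    # healthy 0.46 -> diseased 0.59 is a ~28% elevation
    assert met.percent_change(0.46, 0.59) == pytest.approx(28.26, abs=0.01)


def test_estimate_mueff_from_transmission():
    assert met.estimate_mueff_from_transmission(1.0, 1.0, 15.0) == 0.0
    i = math.exp(-0.47 * 15.0)
    assert met.estimate_mueff_from_transmission(i, 1.0, 15.0) == pytest.approx(
        0.47, rel=1e-9
    )
    base = met.estimate_mueff_from_transmission(0.5, 1.0, 10.0)
    halved = met.estimate_mueff_from_transmission(0.25, 1.0, 10.0)
    assert halved - base == pytest.approx(math.log(2) / 10.0, rel=1e-9)
    with pytest.raises(ValueError):
        met.estimate_mueff_from_transmission(0.0, 1.0, 15.0)
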