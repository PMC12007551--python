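"""Threshold grids, averaged maps, recruitment sigmoids and their surfaces."""

import numpy as np
import pytest

from tmsresponse.cable_sim import SimConfig, find_threshold
from tmsresponse.errors import ConfigurationError, EmptyBinError, RangeError
from tmsresponse.field_coupling import FieldParams
from tmsresponse.response_model import (
    AverageThresholdMap,
    RecruitmentSigmoid,
    RecruitmentSurface,
    ThresholdGrid,
    average_map,
    build_threshold_grid,
    default_delta_axis,
    default_phi_axis,
    default_theta_axis,
    empirical_recruitment,
    fit_sigmoid,
    interpolate_threshold,
    load_grid,
    load_map,
    polar_sensitivity_curve,
    recruitment_surface,
    save_grid,
    save_map,
)


def _grid_from_array(thr, theta=None, phi=None, delta=None):
    c, nt, np_, nd = thr.shape
    theta = np.linspace(0, 180, nt) if theta is None else theta
    phi = np.arange(np_) * (360.0 / np_) if phi is None else phi
    delta = np.linspace(-100, 100, nd) if delta is None else delta
    return ThresholdGrid(theta, phi, delta, thr, "monophasic",
                         [f"c{i}" for i in range(c)])


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def test_default_axes_sizes():
    """The default sweep covers 61 x 60 x 21 field configurations per cell."""
    assert len(default_theta_axis()) == 61
    assert len(default_phi_axis()) == 60
    assert len(default_delta_axis()) == 21


def test_grid_single_triple_reproduces_find_threshold(bas_cm, mm, mono_wave, cfg):
    g = build_threshold_grid([bas_cm], mono_wave, cfg, mm,
                             theta_axis=np.array([30.0]),
                             phi_axis=np.array([12.0]),
                             delta_axis=np.array([-20.0]))
    direct = find_threshold(bas_cm, mm, FieldParams(theta=30.0, phi=12.0, delta=-20.0),
                            mono_wave, cfg)
    assert g.thresholds[0, 0, 0, 0] == direct.threshold


def test_grid_axisymmetric_cell_phi_independent(bas_cm, mm, mono_wave, cfg):
    """The straight ball-and-stick cell cannot depend on azimuth."""
    g = build_threshold_grid([bas_cm], mono_wave, cfg, mm,
                             theta_axis=np.array([45.0]),
                             phi_axis=np.arange(0.0, 360.0, 90.0),
                             delta_axis=np.array([0.0]))
    vals = g.thresholds[0, 0, :, 0]
    assert np.ptp(vals) <= 0.05 + 1e-12  # within the search precision


def test_grid_requires_cells(mono_wave):
    with pytest.raises(ConfigurationError):
        build_threshold_grid([], mono_wave)


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def test_average_single_cell_single_phi_identity():
    thr = np.random.default_rng(0).uniform(50, 150, (1, 4, 1, 3))
    m = average_map(_grid_from_array(thr))
    np.testing.assert_allclose(m.mean, thr[0, :, 0, :])
    np.testing.assert_allclose(m.ci95_halfwidth, 0.0)


def test_average_two_cells_arithmetic():
    thr = np.empty((2, 2, 2, 2))
    thr[0] = 100.0
    thr[1] = 200.0
    m = average_map(_grid_from_array(thr))
    np.testing.assert_allclose(m.mean, 150.0)
    # per bin: 4 samples {100,100,200,200}, sd=57.74, CI = 1.96*sd/2
    sd = np.std([100, 100, 200, 200], ddof=1)
    np.testing.assert_allclose(m.ci95_halfwidth, 1.96 * sd / 2.0)
    assert np.all(m.n_samples == 4)


def test_average_ci_shrinks_as_sqrt_n():
    """CI half-width decreases ~1/sqrt(n) on i.i.d. synthetic thresholds."""
    rng = np.random.default_rng(5)
    widths = {}
    for n_cells in (5, 30):
        thr = rng.lognormal(np.log(100), 0.3, (n_cells, 1, 20, 1))
        widths[n_cells] = average_map(_grid_from_array(thr)).ci95_halfwidth[0, 0]
    ratio = widths[5] / widths[30]
    assert ratio == pytest.approx(np.sqrt(30 / 5), rel=0.35)


def test_average_excludes_sentinels_and_flags_empty():
    thr = np.full((2, 1, 2, 2), 100.0)
    thr[:, 0, :, 1] = np.inf  # one bin entirely non-excitable
    thr[0, 0, 0, 0] = np.inf  # single sentinel in a mixed bin
    m = average_map(_grid_from_array(thr))
    assert m.mean[0, 0] == pytest.approx(100.0)
    assert m.n_samples[0, 0] == 3
    assert np.isinf(m.mean[0, 1])
    assert m.metadata["flagged_bins"] == 1
    assert m.excluded_fraction == pytest.approx(5 / 8)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _ramp_map():
    theta = np.array([0.0, 90.0, 180.0])
    delta = np.array([-50.0, 50.0])
    mean = theta[:, None] + delta[None, :]  # linear ramp
    return AverageThresholdMap(theta, delta, mean + 200.0, np.zeros_like(mean),
                               np.ones_like(mean, dtype=int))


def test_interpolation_exact_at_nodes_and_linear():
    m = _ramp_map()
    assert interpolate_threshold(m, 90.0, 50.0) == pytest.approx(340.0)
    assert interpolate_threshold(m, 45.0, 0.0) == pytest.approx(
        (interpolate_threshold(m, 0.0, 0.0) + interpolate_threshold(m, 90.0, 0.0)) / 2
    )


def test_interpolation_out_of_range():
    with pytest.raises(RangeError):
        interpolate_threshold(_ramp_map(), 200.0, 0.0)


# ---------------------------------------------------------------------------
# Recruitment
# ---------------------------------------------------------------------------

def test_empirical_cdf_shapes():
    thr = np.full((2, 1, 1, 1), 100.0)
    thr[1] = 200.0
    g = _grid_from_array(thr, theta=np.array([0.0]), phi=np.array([0.0]),
                         delta=np.array([0.0]))
    cdf = empirical_recruitment(g, 0.0, 0.0)
    assert cdf(150.0) == pytest.approx(0.5)
    assert cdf(99.0) == 0.0
    assert cdf(201.0) == 1.0


def test_empirical_cdf_step_and_empty_bin():
    thr = np.full((3, 1, 1, 2), 120.0)
    thr[:, :, :, 1] = np.inf
    g = _grid_from_array(thr, theta=np.array([0.0]), phi=np.array([0.0]),
                         delta=np.array([0.0, 10.0]))
    cdf = empirical_recruitment(g, 0.0, 0.0)
    assert cdf(119.99) == 0.0
    assert cdf(120.0) == 1.0
    with pytest.raises(EmptyBinError):
        empirical_recruitment(g, 0.0, 10.0)


def test_sigmoid_fit_noiseless_recovery():
    """Noiseless logistic data: parameters recovered to 4 significant digits."""
    r, E0 = 0.05, 150.0
    E = np.linspace(90.0, 210.0, 40)
    f = 1.0 / (1.0 + np.exp(-r * (E - E0)))
    sig = fit_sigmoid(E, f)
    assert sig.r == pytest.approx(r, rel=1e-4)
    assert sig.E0 == pytest.approx(E0, rel=1e-4)
    assert sig(sig.E0) == pytest.approx(0.5, abs=1e-12)


def test_sigmoid_fit_noisy_recovery():
    rng = np.random.default_rng(7)
    r, E0 = 0.05, 150.0
    E = rng.uniform(E0 - 3 / r, E0 + 3 / r, 50)
    f = 1.0 / (1.0 + np.exp(-r * (E - E0))) + rng.normal(0, 0.01, 50)
    sig = fit_sigmoid(E, f)
    assert sig.r == pytest.approx(r, rel=0.10)
    assert sig.E0 == pytest.approx(E0, rel=0.02)


def test_sigmoid_fit_underdetermined():
    with pytest.raises(ConfigurationError):
        fit_sigmoid(np.array([100.0, 200.0]), np.array([0.1, 0.9]))


def test_recruitment_surface_constant_grid():
    """All-equal thresholds give a constant E0 surface and step-like slopes."""
    thr = np.full((4, 2, 3, 2), 80.0)
    s = recruitment_surface(_grid_from_array(thr))
    np.testing.assert_allclose(s.E0, 80.0)
    assert np.all(s.r > 100.0)
    assert np.all(s.converged)


def test_recruitment_surface_matches_per_bin_fit():
    rng = np.random.default_rng(2)
    thr = rng.lognormal(np.log(100), 0.25, (6, 2, 10, 1))
    g = _grid_from_array(thr, theta=np.array([0.0, 90.0]), delta=np.array([0.0]))
    s = recruitment_surface(g)
    assert np.all(s.converged)
    assert np.all(s.residual_rms < 0.05)
    # direct per-bin fit reproduces the stored parameters
    sig = s.sigmoid_at(90.0, 0.0)
    assert sig.r == pytest.approx(s.r[1, 0])
    assert sig.E0 == pytest.approx(s.E0[1, 0])


def _synthetic_surface():
    """Surface with direction-dependent E0 (min at the poles, max at 90 deg)."""
    theta = np.arange(0.0, 180.1, 30.0)
    delta = np.array([0.0])
    E0 = 100.0 + 50.0 * np.sin(np.radians(theta))[:, None]
    r = np.full_like(E0, 0.08)
    ok = np.ones_like(E0, dtype=bool)
    return RecruitmentSurface(theta, delta, r, E0, np.zeros_like(E0), ok)


def test_polar_sensitivity_reference_is_half():
    s = _synthetic_surface()
    curves = polar_sensitivity_curve(s, [1.0], delta=0.0, theta_ref=0.0,
                                     normalize=False)
    assert curves[1.0][0] == pytest.approx(0.5)


def test_polar_sensitivity_monotone_and_flattening():
    """Higher intensities recruit more everywhere and are less direction-selective."""
    s = _synthetic_surface()
    curves = polar_sensitivity_curve(s, [1.1, 1.2, 1.4, 1.6], normalize=False)
    depths = {}
    prev = None
    for rel in (1.1, 1.2, 1.4, 1.6):
        c = curves[rel]
        if prev is not None:
            assert np.all(c >= prev - 1e-12)
        prev = c
        depths[rel] = (np.max(c) - np.min(c)) / np.max(c)
    assert depths[1.1] > depths[1.2] > depths[1.4] > depths[1.6]


def test_polar_sensitivity_rejects_nonpositive_intensity():
    with pytest.raises(ConfigurationError):
        polar_sensitivity_curve(_synthetic_surface(), [0.0])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_grid_and_map_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    thr = rng.uniform(50, 200, (2, 3, 4, 2))
    g = _grid_from_array(thr)
    save_grid(g, tmp_path / "grid.h5")
    g2 = load_grid(tmp_path / "grid.h5")
    np.testing.assert_array_equal(g2.thresholds, g.thresholds)
    assert g2.cell_ids == g.cell_ids

    m = average_map(g)
    save_map(m, tmp_path / "map.h5")
    m2 = load_map(tmp_path / "map.h5")
    np.testing.assert_array_equal(m2.mean, m.mean)
    np.testing.assert_array_equal(m2.ci95_halfwidth, m.ci95_halfwidth)
    assert m2.metadata["ci_rule"] == m.metadata["ci_rule"]
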