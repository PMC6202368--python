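import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString
from shapely.ops import polygonize, unary_union

from memskin import (
    AdmittanceMeasurement,
    DegenerateLoopError,
    InvalidIndexError,
    InvalidParameterError,
    InvalidPeriodError,
    Recording,
    StratumCorneumParams,
    UnsupportedStimulusError,
    VoltageStimulus,
    detect_pinch_points,
    extract_period,
    generate_waveform,
    lobe_area,
    lockin_admittance,
    max_current,
    non_linearity,
    phase_shift,
    simulate_batch,
    simulate_recording,
    state_dependent_phase_shift,
)
from memskin.stimuli import waveform_functions

from conftest import make_sine_recording


@pytest.fixture(scope="module")
def duct_rec(duct_only_params):
    """Canonical duct-memristor recording, 1.2 V at 0.05 Hz."""
    return simulate_recording(duct_only_params, VoltageStimulus("sinusoidal", 1.2, 0.05), seed=0)


# ---------------------------------------------------------------------- periods


def test_extract_period_partition(duct_rec):
    parts = [extract_period(duct_rec, k) for k in (1, 2, 3)]
    assert all(len(p) == 500 for p in parts)
    assert np.array_equal(np.concatenate([p.v for p in parts]), duct_rec.v)
    assert np.array_equal(np.concatenate([p.i for p in parts]), duct_rec.i)
    assert np.array_equal(parts[2].i, duct_rec.i[1000:1500])
    assert parts[2].t[0] == 0.0


def test_extract_period_bounds_and_kinds(duct_rec):
    with pytest.raises(InvalidIndexError):
        extract_period(duct_rec, 4)
    with pytest.raises(InvalidIndexError):
        extract_period(duct_rec, 0)
    stim = VoltageStimulus("decaying_sine", 1.2, 0.05)
    t, v = generate_waveform(stim)
    rec = Recording("s", "forehead", stim, t, v, 1e-6 * v)
    with pytest.raises(UnsupportedStimulusError):
        extract_period(rec, 1)


# ---------------------------------------------------------------------- NL


def test_nl_of_phase_shifted_linear_currents():
    """A purely linear current with a phase lead pulls NL below 2: 1.93 at a
    2.1 degree lead and 1.60 at 13.26 degrees (2.5 Hz sinusoid)."""
    w = 2 * np.pi * 2.5
    for phase_deg, expected in ((2.1, 1.93), (13.26, 1.60)):
        rec = make_sine_recording(
            lambda t: 1e-6 * np.sin(w * t + np.radians(phase_deg)), frequency=2.5)
        assert non_linearity(rec) == pytest.approx(expected, abs=0.005)


def test_nl_of_linear_in_phase_current_is_exactly_two():
    rec = make_sine_recording(lambda t: 3.3e-6 * np.sin(2 * np.pi * t))
    assert non_linearity(rec) == pytest.approx(2.0, abs=1e-9)
    # triangular stimulus, same linear response
    stim = VoltageStimulus("triangular", 1.0, 1.0, periods=1)
    t, v = generate_waveform(stim)
    rec_tri = Recording("s", "forehead", stim, t, v, 2e-6 * v)
    assert non_linearity(rec_tri) == pytest.approx(2.0, abs=1e-9)


def test_sign_flipped_stimulus_preserves_loop_geometry(duct_only_params):
    """For symmetric fill/drain gains the steady-state loop under a
    sign-flipped stimulus is the point-reflected image of the original:
    lobe area and pinch count are preserved.  (NL is *not* invariant - the
    flip swaps which duct phase meets the ascending-voltage branch.)"""
    stim = VoltageStimulus("sinusoidal", 1.2, 0.05)
    pos = simulate_recording(duct_only_params, stim, seed=0)
    neg = simulate_recording(duct_only_params, dataclasses.replace(stim, sign=-1), seed=0)
    a_pos, _ = lobe_area(extract_period(pos, 3))
    a_neg, _ = lobe_area(extract_period(neg, 3))
    assert a_neg == pytest.approx(a_pos, rel=2e-2)  # residual period-3 transient
    assert len(detect_pinch_points(extract_period(neg, 3))) == \
        len(detect_pinch_points(extract_period(pos, 3)))
    # NL remains well-defined on the sign-corrected positive half-cycle
    assert np.isfinite(non_linearity(extract_period(neg, 3)))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(offset=st.floats(-1e-5, 1e-5))
def test_nl_invariant_to_current_dc_offset(offset):
    """Adding a constant to the current shifts i_max and both reference
    currents equally, leaving NL unchanged."""
    w = 2 * np.pi
    base = make_sine_recording(lambda t: 1e-6 * np.sin(w * t) * (1 + 0.3 * np.cos(w * t)))
    shifted = Recording(base.subject_id, base.site, base.stimulus,
                        base.t, base.v, base.i + offset)
    assert non_linearity(shifted) == pytest.approx(non_linearity(base), rel=1e-6)


def test_nl_against_dense_resampling_oracle(duct_only_params):
    """NL at the native 500 samples/period agrees within 0.5% with the same
    statistic on a 20x-oversampled re-integration."""
    base = simulate_recording(
        duct_only_params, VoltageStimulus("sinusoidal", 1.2, 0.25), seed=0)
    dense = simulate_recording(
        duct_only_params,
        VoltageStimulus("sinusoidal", 1.2, 0.25, samples_per_period=10000),
        seed=0, substeps=1)
    nl = non_linearity(extract_period(base, 3))
    nl_oracle = non_linearity(extract_period(dense, 3))
    assert nl == pytest.approx(nl_oracle, rel=5e-3)


def test_nl_degenerate_and_unreachable_errors():
    rec = make_sine_recording(lambda t: np.full_like(t, 2e-6))
    with pytest.raises(DegenerateLoopError):
        non_linearity(rec)
    rec2 = make_sine_recording(lambda t: 1e-6 * np.sin(2 * np.pi * t))
    with pytest.raises(InvalidPeriodError):
        non_linearity(rec2, v_max=3.0)


# ---------------------------------------------------------------------- lobe area


def test_lobe_area_zero_for_single_valued_curve():
    rec = make_sine_recording(lambda t: 2e-6 * np.sin(2 * np.pi * t) ** 3)
    a, (a1, a2) = lobe_area(rec)
    assert a <= 1e-9 * 2e-6  # relative to the current scale
    assert a1 >= 0 and a2 >= 0


def test_lobe_area_of_linear_rc_ellipse():
    """v = sin, i = G sin + W cos encloses an ellipse of area pi*W."""
    w = 2 * np.pi
    G, W = 1e-6, 0.5e-6
    rec = make_sine_recording(lambda t: G * np.sin(w * t) + W * np.cos(w * t))
    a, _ = lobe_area(rec)
    assert a == pytest.approx(np.pi * W, rel=1e-2)


def test_lobe_area_of_pinched_loop_analytic_and_oracle():
    """i = sin*(1 + 0.3 cos): lobes of area 0.2 on each side, total 0.4."""
    w = 2 * np.pi
    rec = make_sine_recording(lambda t: 1e-6 * np.sin(w * t) * (1 + 0.3 * np.cos(w * t)))
    a, (a1, a2) = lobe_area(rec)
    assert a == pytest.approx(0.4e-6, rel=1e-2)
    assert a1 == pytest.approx(0.2e-6, rel=1e-2)
    assert a2 == pytest.approx(0.2e-6, rel=1e-2)
    # independent polygonization oracle on the same polyline
    ls = LineString(np.column_stack([np.append(rec.v, rec.v[0]),
                                     np.append(rec.i * 1e6, rec.i[0] * 1e6)]))
    oracle = sum(p.area for p in polygonize(unary_union(ls))) * 1e-6
    assert a == pytest.approx(oracle, rel=1e-2)


def test_lobe_area_scaling_invariance(duct_rec):
    per = extract_period(duct_rec, 3)
    a, _ = lobe_area(per)
    scaled_i = Recording(per.subject_id, per.site, per.stimulus, per.t, per.v, 3.0 * per.i)
    a_i, _ = lobe_area(scaled_i)
    assert a_i == pytest.approx(3.0 * a, rel=1e-12)


def test_lobe_area_fallback_on_self_looping_branch():
    """A voltage trace that wiggles (non-monotone branches) triggers the
    polygon-decomposition fallback, which still matches the oracle."""
    stim = VoltageStimulus("sinusoidal", 1.0, 1.0, periods=1)
    t = np.arange(500) / 500.0
    th = 2 * np.pi * t
    v = np.sin(th) + 0.05 * np.sin(7 * th)
    i = 1e-6 * (np.sin(th) + 0.4 * np.cos(th))
    rec = Recording("s", "forehead", stim, t, v, i)
    with pytest.warns(RuntimeWarning, match="non-monotone"):
        a, _ = lobe_area(rec)
    ls = LineString(np.column_stack([np.append(v, v[0]), np.append(i * 1e6, i[0] * 1e6)]))
    oracle = sum(p.area for p in polygonize(unary_union(ls))) * 1e-6
    assert a == pytest.approx(oracle, rel=1e-6)


# ---------------------------------------------------------------------- i_max


def test_max_current_angle_of_pure_sine():
    rec = make_sine_recording(lambda t: 1e-6 * np.sin(2 * np.pi * t))
    i_max, angle = max_current(rec)
    assert i_max == pytest.approx(1e-6)
    assert angle == pytest.approx(90.0)


def test_max_current_lags_voltage_peak_for_memristive_loop(duct_rec):
    """The duct state keeps filling past the voltage peak, so the current
    maximum falls at an angle beyond 90 degrees."""
    _, angle = max_current(extract_period(duct_rec, 3))
    assert 90.0 < angle < 180.0


def test_max_current_tie_breaks_to_earliest_sample():
    stim = VoltageStimulus("sinusoidal", 1.0, 1.0, periods=1, samples_per_period=500)
    t, v = generate_waveform(stim)
    i = np.zeros_like(t)
    i[100] = i[300] = 5e-6
    rec = Recording("s", "forehead", stim, t, v, i)
    _, angle = max_current(rec)
    assert angle == pytest.approx(360.0 * 100 / 500)


# ---------------------------------------------------------------------- pinch points


def test_ellipse_has_no_pinch():
    w = 2 * np.pi
    rec = make_sine_recording(lambda t: 1e-6 * (np.sin(w * t) + 0.5 * np.cos(w * t)))
    assert detect_pinch_points(rec) == []


def test_analytic_pinched_loop_single_transversal_pinch_at_origin():
    """i = sin*(1 + 0.3 cos) crosses itself once at the origin, with branch
    slopes 1 +/- 0.3 (transversal)."""
    w = 2 * np.pi
    rec = make_sine_recording(lambda t: np.sin(w * t) * (1 + 0.3 * np.cos(w * t)))
    pinches = detect_pinch_points(rec)
    assert len(pinches) == 1
    (pp,) = pinches
    assert abs(pp.v) < 0.01 and abs(pp.i) < 0.01
    assert not pp.tangential
    slopes = sorted([np.tan(np.radians(pp.slope_a_deg)), np.tan(np.radians(pp.slope_b_deg))])
    # normalized coordinates: v/2, i/ptp(i); slopes 0.7 and 1.3 rescale accordingly
    scale = 2.0 / np.ptp(rec.i)
    assert slopes[0] * scale == pytest.approx(0.7, rel=0.1)
    assert slopes[1] * scale == pytest.approx(1.3, rel=0.1)


def test_pinch_count_stable_under_resampling(duct_only_params, thermistor_params):
    for params, expected in ((duct_only_params, 1), (thermistor_params, 2)):
        for spp in (500, 1000):
            stim = VoltageStimulus("sinusoidal", 1.2, 0.05, samples_per_period=spp)
            rec = simulate_recording(params, stim, seed=0)
            assert len(detect_pinch_points(extract_period(rec, 3))) == expected


def test_thermistor_only_loop_is_tangential(thermistor_params):
    """Without the parallel capacitance the thermistor loop touches the
    origin with equal branch slopes."""
    p = dataclasses.replace(
        thermistor_params, sc=dataclasses.replace(thermistor_params.sc, c_s=0.0))
    rec = simulate_recording(p, VoltageStimulus("sinusoidal", 1.2, 0.05), seed=0)
    pinches = detect_pinch_points(extract_period(rec, 3))
    assert len(pinches) == 1
    assert pinches[0].tangential


# ---------------------------------------------------------------------- phase shift


@pytest.mark.parametrize("g, c, f, expected, decimals", [
    (6.7e-6, 15.6e-9, 0.05, 0.04, 2),
    (6.7e-6, 15.6e-9, 2.5, 2.1, 1),
    (2.0e-6, 30e-9, 0.05, 0.27, 2),
    (2.0e-6, 30e-9, 2.5, 13.26, 2),
])
def test_phase_shift_reference_values(g, c, f, expected, decimals):
    assert round(phase_shift(g, c, f), decimals) == pytest.approx(expected, abs=0.005)


def test_phase_shift_edge_cases():
    assert phase_shift(1e-6, 15e-9, 0.0) == 0.0
    with pytest.raises(InvalidParameterError):
        phase_shift(0.0, 15e-9, 1.0)
    with pytest.raises(InvalidParameterError):
        phase_shift(-1e-6, 15e-9, 1.0)


def test_state_dependent_phase_shift_properties(duct_only_params):
    g_traj = np.array([2e-6, 2e-6, 2e-6])
    alpha = state_dependent_phase_shift(lambda s: s, 30e-9, 2.5, g_traj)
    assert np.allclose(alpha, phase_shift(2e-6, 30e-9, 2.5))
    # doubling G strictly decreases the phase shift
    alpha2 = state_dependent_phase_shift(lambda s: s, 30e-9, 2.5, np.array([2e-6, 4e-6, 8e-6]))
    assert np.all(np.diff(alpha2) < 0)
    # along a simulated duct trajectory the phase shift stays inside the
    # bracket given by the extreme conductances
    _, xs, _ = simulate_batch([duct_only_params], VoltageStimulus("sinusoidal", 1.2, 2.5),
                              return_states=True)
    g = duct_only_params.duct.memductance(xs[0])
    a = state_dependent_phase_shift(duct_only_params.duct.memductance, 15e-9, 2.5, xs[0])
    assert np.all(a >= phase_shift(float(g.max()), 15e-9, 2.5) - 1e-12)
    assert np.all(a <= phase_shift(float(g.min()), 15e-9, 2.5) + 1e-12)


# ---------------------------------------------------------------------- lock-in


def _rc_recording(G, C, periods=40, noise_sd=0.0, seed=0):
    stim = VoltageStimulus("sinusoidal", 0.1, 20.0, periods=periods)
    t, v = generate_waveform(stim)
    _, dv = waveform_functions(stim)
    i = G * v + C * dv(t)
    if noise_sd:
        i = i + np.random.default_rng(seed).normal(0, noise_sd, len(i))
    return Recording("s", "forehead", stim, t, v, i)


def test_lockin_pure_conductance():
    adm = lockin_admittance(_rc_recording(10e-6, 0.0))
    assert adm.g == pytest.approx(10e-6, rel=1e-4)
    assert abs(adm.b) < 1e-4 * 10e-6


def test_lockin_quadrature_component():
    adm = lockin_admittance(_rc_recording(10e-6, 15.6e-9))
    assert adm.b == pytest.approx(2 * np.pi * 20 * 15.6e-9, rel=1e-3)
    assert adm.c == pytest.approx(15.6e-9, rel=1e-3)


def test_lockin_noise_rejection():
    """1% current noise averages out over 30 s of demodulation."""
    # 30 s at 20 Hz = 600 periods; noise sd = 1% of the 1 uA signal peak
    adm = lockin_admittance(_rc_recording(10e-6, 0.0, periods=600, noise_sd=1e-8, seed=4))
    assert adm.g == pytest.approx(10e-6, rel=1e-2)


def test_lockin_truncates_partial_periods_with_warning():
    rec = _rc_recording(10e-6, 0.0, periods=2)
    partial = Recording(rec.subject_id, rec.site, rec.stimulus,
                        rec.t[:750], rec.v[:750], rec.i[:750])
    with pytest.warns(RuntimeWarning, match="truncating"):
        adm = lockin_admittance(partial)
    assert adm.g == pytest.approx(10e-6, rel=1e-3)


def test_lockin_and_phase_shift_mutually_consistent():
    """Estimated (G, C) reproduce the generating phase lead within 0.1 deg."""
    G, C = 6.7e-6, 15.6e-9
    adm = lockin_admittance(_rc_recording(G, C))
    alpha_est = phase_shift(adm.g, adm.c, 20.0)
    alpha_true = phase_shift(G, C, 20.0)
    assert alpha_est == pytest.approx(alpha_true, abs=0.1)


def test_admittance_consistency_validated():
    with pytest.raises(InvalidParameterError):
        AdmittanceMeasurement(g=1e-6, b=1e-6, c=1.0, f=20.0)
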