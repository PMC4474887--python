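"""Feature extraction: maxima, collapse intervals, regime classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53cycle.dynamics_features import (
    MaximaSeries,
    RegimeTolerances,
    classify_regime,
    collapse_interval,
    find_maxima,
    maxima_dispersion,
    segment_regimes,
)
from p53cycle.synthetic_signals import LOGISTIC_R, SignalSpec, generate


def _series(values, amplitude_ref=None, times=None):
    values = np.asarray(values, float)
    times = np.arange(values.size, dtype=float) if times is None else times
    return MaximaSeries(
        species="test", times_h=times, values=values, transient_h=0.0,
        signal_range=(0.0, float(values.max(initial=1.0))),
        amplitude_ref=amplitude_ref if amplitude_ref is not None
        else float(values.max(initial=1.0)),
    )


# ----------------------------------------------------------------------
# find_maxima
# ----------------------------------------------------------------------

def test_sine_maxima_count_and_refined_heights():
    """A pure 2 h sine over 20 h has ten maxima; parabolic refinement pins
    the heights to the amplitude within 1e-6."""
    t = np.arange(0.0, 20.0, 0.01)
    v = 3.0 * np.sin(2 * np.pi * t / 2.0)
    mx = find_maxima((t, v), transient_h=0.0)
    assert len(mx) == 10
    assert np.max(np.abs(mx.values - 3.0)) < 1e-6 * 3.0
    expected = 0.5 + 2.0 * np.arange(10)
    assert np.max(np.abs(mx.times_h - expected)) < 0.01


def test_monotone_decay_has_no_maxima():
    t = np.linspace(0, 10, 500)
    mx = find_maxima((t, np.exp(-t)), transient_h=0.0)
    assert len(mx) == 0


def test_plateau_reported_once_at_midpoint():
    t = np.arange(0.0, 10.0, 0.1)
    v = np.minimum(np.sin(2 * np.pi * t / 5.0), 0.9)  # clipped tops
    mx = find_maxima((t, v), transient_h=0.0, refine=False)
    assert len(mx) == 2
    assert np.all(mx.values == 0.9)


def test_damped_envelope_matched_within_tenth_percent():
    spec = SignalSpec(kind="damped", period_h=2.0, amplitudes=(4.0,),
                      damping_h=30.0, horizon_h=60.0, dt_h=0.002)
    sig = generate(spec)
    mx = find_maxima(sig, transient_h=0.0)
    envelope = 4.0 * np.exp(-mx.times_h / 30.0)
    assert np.max(np.abs(mx.values / envelope - 1.0)) < 1e-3


def test_transient_removal_and_default_cutoff(traj_ir0):
    mx = find_maxima(traj_ir0, species="cyclin")
    assert mx.transient_h >= 0.1 * traj_ir0.horizon_h
    assert np.all(mx.times_h > mx.transient_h)


def test_window_shorter_than_transient_errors():
    t = np.linspace(0, 1, 50)
    with pytest.raises(ValueError, match="transient"):
        find_maxima((t, np.sin(t)), transient_h=2.0)


# ----------------------------------------------------------------------
# collapse_interval
# ----------------------------------------------------------------------

def test_sustained_sine_has_no_collapse():
    sig = generate(SignalSpec(kind="sustained", period_h=2.0, horizon_h=80.0))
    res = collapse_interval(sig)
    assert res.delta_t_h == 0.0 and not res.censored


def test_constructed_collapse_recovered_within_one_period():
    spec = SignalSpec(kind="collapse", period_h=2.0, collapse_start_h=50.0,
                      collapse_len_h=70.0, horizon_h=180.0)
    sig = generate(spec)
    res = collapse_interval(sig)
    assert abs(res.delta_t_h - sig.truth["delta_t_h"]) <= spec.period_h
    assert res.start_h == pytest.approx(sig.truth["collapse_start_h"], abs=2.0)


def test_randomized_collapse_constructions_recovered(rng):
    """100 seeded random constructions (random period, start, length) are
    all recovered within one oscillation period."""
    for _ in range(100):
        period = rng.uniform(0.5, 4.0)
        start = rng.uniform(3 * period + 1, 60)
        length = rng.uniform(3 * period, 80)
        horizon = start + length + rng.uniform(20, 60)
        sig = generate(SignalSpec(kind="collapse", period_h=period,
                                  collapse_start_h=start,
                                  collapse_len_h=length,
                                  horizon_h=horizon, dt_h=period / 80))
        res = collapse_interval(sig)
        assert abs(res.delta_t_h - sig.truth["delta_t_h"]) <= period


def test_quiescence_to_horizon_is_censored_not_measured():
    sig = generate(SignalSpec(kind="damped", period_h=2.0, damping_h=8.0,
                              horizon_h=120.0))
    res = collapse_interval(sig)
    assert res.censored
    assert res.delta_t_h == 0.0  # no completed collapse was measured
    assert res.end_h == pytest.approx(120.0, abs=1.0)


def test_flat_series_degenerate_input():
    t = np.linspace(0, 50, 1000)
    res = collapse_interval((t, np.ones_like(t)))
    assert res.delta_t_h == 0.0 and "flat" in res.note


# ----------------------------------------------------------------------
# classify_regime and maxima_dispersion
# ----------------------------------------------------------------------

def test_constant_signal_is_oscillation_death():
    s = MaximaSeries(species="x", times_h=np.array([]), values=np.array([]),
                     transient_h=0.0, signal_range=(1.0, 1.0), amplitude_ref=0.0)
    assert classify_regime(s).label == "oscillation_death"


def test_alternating_maxima_is_period_2():
    s = _series([1.0, 0.8] * 8)
    lab = classify_regime(s)
    assert lab.label == "period_2" and lab.cyclic


def test_three_cycle_is_period_3():
    s = _series([1.0, 0.7, 0.4] * 6)
    assert classify_regime(s).label == "period_3"


def test_equal_maxima_is_period_1():
    s = _series([1.0] * 12)
    assert classify_regime(s).label == "period_1"


def test_logistic_map_maxima_are_chaotic():
    u = np.empty(40)
    u[0] = 0.4
    for i in range(1, u.size):
        u[i] = LOGISTIC_R * u[i - 1] * (1 - u[i - 1])
    lab = classify_regime(_series(0.2 + 0.8 * u))
    assert lab.label == "chaotic"
    assert lab.dispersion > RegimeTolerances().dispersion_threshold


def test_decaying_peaks_are_damped():
    heights = 2.0 * np.exp(-np.arange(12) / 3.0)
    s = _series(heights, amplitude_ref=2.0)
    assert classify_regime(s).label == "damped"


def test_too_few_peaks_is_insufficient_evidence():
    s = _series([1.0, 0.5, 1.0])
    assert classify_regime(s).label == "insufficient_evidence"


def test_dispersion_zero_for_exact_period_3():
    h = np.array([1.0, 0.7, 0.4] * 5)
    assert maxima_dispersion(h) <= 1e-12


def test_dispersion_positive_for_logistic_maxima():
    u = np.empty(60)
    u[0] = 0.4
    for i in range(1, u.size):
        u[i] = LOGISTIC_R * u[i - 1] * (1 - u[i - 1])
    assert maxima_dispersion(0.2 + 0.8 * u) > 0.05


def test_noisy_period_2_dispersion_below_chaos_threshold(rng):
    h = np.array([1.0, 0.8] * 20) * (1 + 0.001 * rng.standard_normal(40))
    assert maxima_dispersion(h) < RegimeTolerances().dispersion_threshold


def test_dispersion_requires_ten_maxima():
    with pytest.raises(ValueError, match="10"):
        maxima_dispersion(np.ones(9))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(scale=st.floats(1e-3, 1e3), shift=st.floats(-100.0, 100.0))
def test_classification_invariant_to_scaling_and_translation(scale, shift):
    """Uniform value scaling and time translation never change the label."""
    patterns = {
        "period_2": [1.0, 0.8] * 8,
        "period_3": [1.0, 0.7, 0.4] * 6,
        "period_1": [1.0] * 12,
    }
    for expected, heights in patterns.items():
        base = _series(heights)
        moved = MaximaSeries(
            species="test",
            times_h=base.times_h + shift,
            values=base.values * scale,
            transient_h=base.transient_h + shift,
            signal_range=(base.signal_range[0] * scale,
                          base.signal_range[1] * scale),
            amplitude_ref=base.amplitude_ref * scale,
        )
        assert classify_regime(moved).label == expected


# ----------------------------------------------------------------------
# segment_regimes
# ----------------------------------------------------------------------

def test_pure_sine_is_one_sustained_segment():
    sig = generate(SignalSpec(kind="sustained", period_h=2.0, horizon_h=150.0))
    seg = segment_regimes(sig, window_h=25.0, hop_h=5.0, transient_h=0.0)
    assert seg.labels() == ["period_1"]
    a, b = seg.segments[0][:2]
    assert a == 0.0 and b == pytest.approx(150.0)


def test_piecewise_switch_located_within_one_window():
    spec = SignalSpec(kind="piecewise", period_h=2.0, horizon_h=200.0,
                      segments=((100.0, "period_2"),
                                (100.0, "chaotic_logistic")))
    seg = segment_regimes(generate(spec), window_h=30.0, hop_h=5.0,
                          transient_h=0.0)
    assert seg.labels() == ["period_2", "chaotic"]
    boundary = seg.segments[0][1]
    assert abs(boundary - 100.0) <= 30.0


def test_segments_cover_window_contiguously():
    sig = generate(SignalSpec(kind="piecewise", period_h=2.0, horizon_h=150.0,
                              segments=((75.0, "sustained"),
                                        (75.0, "period_2"))))
    seg = segment_regimes(sig, window_h=25.0, hop_h=5.0, transient_h=10.0)
    assert seg.segments[0][0] == 10.0
    assert seg.segments[-1][1] == pytest.approx(150.0)
    for (_, b, _), (c, _, _) in zip(seg.segments, seg.segments[1:]):
        assert b == c


def test_model_cyclin_normal_condition_is_sustained(traj_ir0):
    """Under normal conditions the cyclin limit cycle is one sustained
    (period-1) segment."""
    seg = segment_regimes(traj_ir0, species="cyclin")
    assert seg.labels() == ["period_1"]
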