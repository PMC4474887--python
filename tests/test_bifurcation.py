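"""Dose scans, phase boundary, collapse curve, fit and saturation."""

import numpy as np
import pytest

from p53cycle.bifurcation_analysis import (
    CollapseCurve,
    DoseScan,
    collapse_curve,
    fit_collapse_model,
    maxima_vs_dose,
    phase_boundary,
    run_dose_scan,
    saturation,
    time_resolved_bifurcation,
)
from p53cycle.integrator import integrate, make_initial_state
from p53cycle.synthetic_signals import SignalSpec, generate


def _synthetic_scan(doses, signal_for_dose, species="p53", horizon_h=150.0):
    """A DoseScan whose per-dose series come from constructed signals."""
    series, times = {}, None
    for d in doses:
        sig = signal_for_dose(float(d))
        times = sig.times_h
        series[float(d)] = {species: sig.values}
    return DoseScan(doses=np.asarray(doses, float), times_h=times,
                    series=series, params=None, horizon_h=horizon_h,
                    dt_s=1.0, sample_s=60.0)


# ----------------------------------------------------------------------
# run_dose_scan
# ----------------------------------------------------------------------

def test_single_dose_scan_equals_direct_integration(params):
    scan = run_dose_scan([2.0], params=params, horizon_h=30.0)
    direct = integrate(params, make_initial_state(2.0), 30.0)
    assert np.array_equal(scan.get(2.0, "p53")[1], direct.species("p53"))
    assert np.array_equal(scan.times_h, direct.times_h)


def test_scan_order_invariance(params):
    a = run_dose_scan([0.0, 1.0, 3.0], params=params, horizon_h=20.0)
    b = run_dose_scan([3.0, 0.0, 1.0], params=params, horizon_h=20.0)
    assert np.array_equal(a.doses, b.doses)
    for d in a.doses:
        assert np.array_equal(a.get(d, "cyclin")[1], b.get(d, "cyclin")[1])


def test_scan_determinism_bitwise(params):
    a = run_dose_scan([0.0, 2.0], params=params, horizon_h=25.0)
    b = run_dose_scan([0.0, 2.0], params=params, horizon_h=25.0)
    for d in a.doses:
        assert np.array_equal(a.get(d, "p53")[1], b.get(d, "p53")[1])


def test_scan_caches_trajectories(tmp_path, params):
    run_dose_scan([0.0, 1.0], params=params, horizon_h=5.0,
                  cache_dir=tmp_path)
    assert (tmp_path / "trajectory_ir0.csv").exists()
    assert (tmp_path / "trajectory_ir1.csv").exists()


def test_scan_rejects_bad_grids(params):
    with pytest.raises(ValueError, match="non-empty"):
        run_dose_scan([], params=params)
    with pytest.raises(ValueError, match="non-negative"):
        run_dose_scan([-1.0], params=params)


# ----------------------------------------------------------------------
# phase boundary (synthetic scans; no bisection refinement, which would
# re-integrate the kinetic model)
# ----------------------------------------------------------------------

def _death_or_osc(dose, threshold):
    if dose < threshold:
        # flat with invisible jitter: oscillation death
        return generate(SignalSpec(kind="sustained", period_h=2.0,
                                   amplitudes=(1e-9,), baseline=1.0,
                                   horizon_h=150.0, dt_h=0.05))
    return generate(SignalSpec(kind="sustained", period_h=2.0,
                               amplitudes=(1.0,), baseline=1.0,
                               horizon_h=150.0, dt_h=0.05))


def test_constructed_boundary_found_within_grid_resolution():
    doses = np.arange(0.0, 5.0, 0.5)
    scan = _synthetic_scan(doses, lambda d: _death_or_osc(d, 2.0))
    diagram = phase_boundary(scan, refine=False)
    assert diagram.boundary_gy == pytest.approx(1.75, abs=0.5)
    assert diagram.labels[0] == "oscillation_death"
    assert diagram.labels[-1] == "period_1"


def test_all_sustained_scan_has_no_boundary():
    doses = np.arange(0.0, 3.0, 0.5)
    scan = _synthetic_scan(doses, lambda d: _death_or_osc(d, -1.0))
    assert phase_boundary(scan, refine=False).boundary_gy is None


# ----------------------------------------------------------------------
# collapse curve
# ----------------------------------------------------------------------

def test_collapse_curve_slope_two_recovered():
    """Constructed trajectories with delta_t = 2 IR give back the slope."""
    def signal(dose):
        if dose == 0.0:
            return generate(SignalSpec(kind="sustained", period_h=2.0,
                                       horizon_h=200.0, dt_h=0.02))
        return generate(SignalSpec(kind="collapse", period_h=2.0,
                                   collapse_start_h=20.0,
                                   collapse_len_h=2.0 * dose,
                                   horizon_h=200.0, dt_h=0.02))
    doses = np.array([0.0, 10.0, 20.0, 40.0, 60.0])
    scan = _synthetic_scan(doses, signal, horizon_h=200.0)
    curve = collapse_curve(scan)
    assert curve.delta_t_h[0] == 0.0
    slope = np.polyfit(doses[1:], curve.delta_t_h[1:], 1)[0]
    assert slope == pytest.approx(2.0, rel=0.05)
    assert np.all(np.diff(curve.delta_t_h) >= -1e-9)


def test_censored_spells_flagged_and_excluded():
    def signal(dose):
        return generate(SignalSpec(kind="damped", period_h=2.0,
                                   damping_h=6.0, horizon_h=150.0,
                                   dt_h=0.02))
    scan = _synthetic_scan(np.arange(1.0, 6.0), signal)
    curve = collapse_curve(scan)
    assert np.all(curve.censored)
    with pytest.raises(ValueError, match="nothing to fit"):
        fit_collapse_model(curve)


# ----------------------------------------------------------------------
# fit
# ----------------------------------------------------------------------

def test_fit_permutation_invariance():
    rng = np.random.default_rng(5)
    doses = np.linspace(0, 12, 25)
    delta = 4000.0 / (0.02 + np.exp(-doses))
    order = rng.permutation(doses.size)
    a = fit_collapse_model(CollapseCurve(doses=doses, delta_t_h=delta,
                                         censored=np.zeros(25, bool), eps=0.1))
    b = fit_collapse_model(CollapseCurve(doses=doses[order],
                                         delta_t_h=delta[order],
                                         censored=np.zeros(25, bool), eps=0.1))
    assert a.A == pytest.approx(b.A, rel=1e-9)
    assert a.B == pytest.approx(b.B, rel=1e-9)


def test_fit_requires_four_uncensored_points():
    curve = CollapseCurve(doses=np.array([0.0, 1.0, 2.0]),
                          delta_t_h=np.array([1.0, 2.0, 3.0]),
                          censored=np.zeros(3, bool), eps=0.1)
    with pytest.raises(ValueError, match="nothing to fit"):
        fit_collapse_model(curve)


def test_fitted_curve_is_monotone_increasing():
    curve = CollapseCurve(doses=np.linspace(0, 12, 20),
                          delta_t_h=5000.0 / (0.01 + np.exp(-np.linspace(0, 12, 20))),
                          censored=np.zeros(20, bool), eps=0.1)
    fit = fit_collapse_model(curve)
    pred = fit.predict(np.linspace(0, 15, 100))
    assert np.all(np.diff(pred) > 0)
    assert fit.B > 0


# ----------------------------------------------------------------------
# saturation
# ----------------------------------------------------------------------

def _curve(doses, delta):
    return CollapseCurve(doses=np.asarray(doses, float),
                         delta_t_h=np.asarray(delta, float),
                         censored=np.zeros(len(doses), bool), eps=0.1)


def test_saturation_flat_above_seven():
    doses = np.arange(0.0, 12.5, 0.5)
    delta = np.where(doses < 7.0, 10.0 * doses, 70.0)
    sat = saturation(_curve(doses, delta))
    assert sat.saturated
    assert sat.r_c_gy == pytest.approx(7.0, abs=0.5)
    assert sat.delta_t_c_h == pytest.approx(70.0, rel=1e-6)


def test_strictly_increasing_curve_not_saturated():
    doses = np.arange(0.0, 12.5, 0.5)
    sat = saturation(_curve(doses, 10.0 * doses))
    assert not sat.saturated
    assert sat.r_c_gy is None and sat.delta_t_c_h is None


# ----------------------------------------------------------------------
# bifurcation diagrams
# ----------------------------------------------------------------------

def test_time_resolved_bifurcation_reuses_scan(params):
    scan = run_dose_scan([0.0], params=params, horizon_h=150.0)
    seg, scatter = time_resolved_bifurcation(0.0, species="cyclin", scan=scan)
    assert seg.labels() == ["period_1"]
    assert (scatter["ir_gy"] == 0.0).all()
    assert len(scatter) > 50


def test_maxima_vs_dose_one_branch_for_period_1():
    def signal(dose):
        return generate(SignalSpec(kind="sustained", period_h=2.0,
                                   amplitudes=(1.0 + dose,), horizon_h=60.0,
                                   dt_h=0.02))
    doses = np.arange(0.0, 4.0)
    scan = _synthetic_scan(doses, signal, species="mpf", horizon_h=60.0)
    df = maxima_vs_dose(scan, species="mpf", t_window=(0.0, 50.0))
    for d in doses:
        vals = df.loc[df.ir_gy == d, "maximum"]
        assert vals.size >= 20
        assert vals.max() - vals.min() < 1e-6 * (1.0 + d)


def test_maxima_vs_dose_branch_count_doubles():
    """A constructed period-doubling family doubles its branch count at the
    constructed dose."""
    def signal(dose):
        kind = "sustained" if dose < 2.0 else "period_2"
        return generate(SignalSpec(kind=kind, period_h=2.0,
                                   amplitudes=(1.0, 0.6), horizon_h=60.0,
                                   dt_h=0.02))
    doses = np.arange(0.0, 4.0)
    scan = _synthetic_scan(doses, signal, species="mpf", horizon_h=60.0)
    df = maxima_vs_dose(scan, species="mpf", t_window=(0.0, 50.0))

    def branches(d):
        vals = np.sort(df.loc[df.ir_gy == d, "maximum"].to_numpy())
        return 1 + int(np.sum(np.diff(vals) > 0.05))
    assert branches(1.0) == 1
    assert branches(2.0) == 2


def test_maxima_vs_dose_window_validation(params):
    scan = run_dose_scan([0.0], params=params, horizon_h=20.0)
    with pytest.raises(ValueError, match="horizon"):
        maxima_vs_dose(scan, t_window=(0.0, 50.0))
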