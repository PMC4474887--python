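"""Irradiation dose scans and the quantities read off them.

A :class:`DoseScan` integrates the model once per dose with identical
settings and keeps the sampled time courses of the species of interest.
From a scan the module derives

* the oscillation/oscillation-death phase diagram of late-time p53 dynamics
  and its boundary dose (:func:`phase_boundary`, bisection-refined),
* the collapse-time curve delta_t(IR) (:func:`collapse_curve`) with
  censoring for quiescent spells still running at the horizon,
* a two-parameter least-squares fit delta_t = A / (B + exp(-IR))
  (:func:`fit_collapse_model`) and its high-dose saturation
  (:func:`saturation`),
* time-resolved bifurcation diagrams (maxima scatter + regime segments,
  :func:`time_resolved_bifurcation`) and maxima-versus-dose scatters over a
  fixed early window (:func:`maxima_vs_dose`).

All computations are deterministic: an identical configuration yields
bitwise-identical summaries in fixed-step mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics_features import (
    CollapseResult,
    MaximaSeries,
    RegimeSegmentation,
    RegimeTolerances,
    classify_regime,
    collapse_interval,
    find_maxima,
    segment_regimes,
)
from .integrator import (
    DEFAULT_DT_S,
    DEFAULT_SAMPLE_S,
    IntegrationError,
    Trajectory,
    integrate,
    make_initial_state,
)
from .model_core import ParameterSet, default_parameters

__all__ = [
    "DoseScan",
    "PhaseDiagram",
    "CollapseCurve",
    "CollapseFit",
    "SaturationResult",
    "run_dose_scan",
    "phase_boundary",
    "collapse_curve",
    "fit_collapse_model",
    "saturation",
    "time_resolved_bifurcation",
    "maxima_vs_dose",
    "DEFAULT_DOSE_GRID",
    "DEFAULT_HORIZON_H",
]

log = logging.getLogger(__name__)

#: Default bifurcation-parameter grid: 0 to 12 Gy in 0.05 Gy steps.
DEFAULT_DOSE_GRID = np.round(np.arange(0.0, 12.0 + 1e-9, 0.05), 6)
#: Default integration horizon (hours), long enough for the slowest collapse
#: to complete with margin.
DEFAULT_HORIZON_H = 250.0
DEFAULT_SCAN_SPECIES = ("cyclin", "mpf", "p53", "mdm2")


@dataclass
class DoseScan:
    """One deterministic integration per dose, identical settings throughout."""

    doses: np.ndarray
    times_h: np.ndarray
    series: dict[float, dict[str, np.ndarray]]
    params: ParameterSet
    horizon_h: float
    dt_s: float
    sample_s: float
    errors: dict[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("dose grid must be strictly increasing")

    def get(self, dose: float, species: str) -> tuple[np.ndarray, np.ndarray]:
        return self.times_h, self.series[float(dose)][species]

    @property
    def species_kept(self) -> tuple[str, ...]:
        first = next(iter(self.series.values()))
        return tuple(first.keys())


def run_dose_scan(
    doses: Sequence[float] | np.ndarray = DEFAULT_DOSE_GRID,
    params: ParameterSet | None = None,
    horizon_h: float = DEFAULT_HORIZON_H,
    dt_s: float = DEFAULT_DT_S,
    sample_s: float = DEFAULT_SAMPLE_S,
    species: Sequence[str] = DEFAULT_SCAN_SPECIES,
    cache_dir: str | Path | None = None,
    progress: Callable[[float], None] | None = None,
) -> DoseScan:
    """Integrate the model at every dose of a strictly increasing grid.

    Integration failures are recorded per dose without aborting the scan.
    With ``cache_dir`` set, each trajectory is written as a CSV named by its
    dose.
    """
    doses = np.asarray(sorted(float(d) for d in doses))
    if doses.size == 0:
        raise ValueError("dose grid must be non-empty")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    params = params or default_parameters()
    series: dict[float, dict[str, np.ndarray]] = {}
    errors: dict[float, str] = {}
    times_h = None
    for dose in doses:
        try:
            traj = integrate(params, make_initial_state(dose), horizon_h,
                             dt_s=dt_s, sample_s=sample_s, ir_dose=dose)
        except IntegrationError as exc:
            errors[float(dose)] = str(exc)
            log.warning("dose %.4g Gy failed: %s", dose, exc)
            continue
        times_h = traj.times_h
        series[float(dose)] = {name: traj.species(name).copy()
                               for name in species}
        if cache_dir is not None:
            Path(cache_dir).mkdir(parents=True, exist_ok=True)
            traj.to_csv(Path(cache_dir) / f"trajectory_ir{dose:g}.csv")
        if progress is not None:
            progress(float(dose))
    if times_h is None:
        raise IntegrationError("every dose in the scan failed")
    kept = doses[np.isin(doses, list(series))]
    return DoseScan(doses=kept, times_h=times_h, series=series,
                    params=params, horizon_h=horizon_h,
                    dt_s=dt_s, sample_s=sample_s, errors=errors)


# ----------------------------------------------------------------------
# phase diagram
# ----------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Late-time maxima per dose and the oscillation/death partition."""

    doses: np.ndarray
    labels: list[str]
    late_maxima: dict[float, MaximaSeries]
    boundary_gy: float | None
    tail_h: float
    dose_tol: float
    species: str

    def oscillating(self) -> np.ndarray:
        return np.asarray([lab != "oscillation_death" for lab in self.labels])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dose in self.doses:
            for t, v in zip(self.late_maxima[float(dose)].times_h,
                            self.late_maxima[float(dose)].values):
                rows.append((dose, t, v))
        return pd.DataFrame(rows, columns=["ir_gy", "time_h", "maximum"])


def _post_transient_range(t: np.ndarray, v: np.ndarray) -> float:
    full = find_maxima((t, v))
    return full.amplitude_ref


def _tail_label(t: np.ndarray, v: np.ndarray, tail_h: float,
                tol: RegimeTolerances,
                eps: float | None = None) -> tuple[str, MaximaSeries]:
    """Regime label of the final ``tail_h`` hours of a series.

    ``eps`` is the absolute oscillation-death threshold; a phase diagram
    passes a scan-global value (a fraction of the species' largest
    post-transient amplitude across doses) so that death at one dose is
    judged against the species' oscillation scale, not against its own
    residual jitter.
    """
    full = find_maxima((t, v))
    t_cut = max(t[-1] - tail_h, full.transient_h)
    m = t >= t_cut
    sig_rng = (float(v[m].min()), float(v[m].max()))
    sub = full.window(t_cut, t[-1], signal_range=sig_rng)
    label = classify_regime(sub, tol, eps=eps)
    return label.label, sub


def phase_boundary(
    scan: DoseScan,
    species: str = "p53",
    tail_h: float = 50.0,
    tolerances: RegimeTolerances | None = None,
    dose_tol: float = 0.02,
    refine: bool = True,
) -> PhaseDiagram:
    """Partition the dose grid into oscillation-death / oscillating phases.

    Each dose's final ``tail_h`` hours are classified; the boundary is the
    midpoint between the two doses where the phase first changes, refined by
    bisection on the dose axis (new integrations at the scan's settings) to
    ``dose_tol`` Gy.  A single-phase scan reports ``boundary_gy = None``.
    """
    tol = tolerances or RegimeTolerances()
    # scan-global amplitude scale: the species' largest post-transient
    # excursion anywhere on the grid anchors the death threshold
    global_amp = max(
        _post_transient_range(*scan.get(d, species)) for d in scan.doses)
    eps = tol.eps_rel * global_amp
    labels, late = [], {}
    for dose in scan.doses:
        t, v = scan.get(dose, species)
        lab, sub = _tail_label(t, v, tail_h, tol, eps=eps)
        labels.append(lab)
        late[float(dose)] = sub

    osc = [lab != "oscillation_death" for lab in labels]
    boundary = None
    flips = [i for i in range(1, len(osc)) if osc[i] != osc[i - 1]]
    if flips:
        i = flips[0]
        lo, hi = float(scan.doses[i - 1]), float(scan.doses[i])
        if len(flips) > 1:
            log.warning("%s phase labels change %d times along the grid; "
                        "refining the first change", species, len(flips))
        if refine:
            lo_osc = osc[i - 1]

            def classify_at(dose: float) -> bool:
                traj = integrate(scan.params, make_initial_state(dose),
                                 scan.horizon_h, dt_s=scan.dt_s,
                                 sample_s=scan.sample_s, ir_dose=dose)
                lab, _ = _tail_label(traj.times_h, traj.species(species),
                                     tail_h, tol, eps=eps)
                return lab != "oscillation_death"

            while hi - lo > dose_tol:
                mid = 0.5 * (lo + hi)
                if classify_at(mid) == lo_osc:
                    lo = mid
                else:
                    hi = mid
        boundary = 0.5 * (lo + hi)
    return PhaseDiagram(doses=scan.doses, labels=labels, late_maxima=late,
                        boundary_gy=boundary, tail_h=tail_h,
                        dose_tol=dose_tol, species=species)


# ----------------------------------------------------------------------
# collapse curve, fit, saturation
# ----------------------------------------------------------------------

@dataclass
class CollapseCurve:
    """(IR, delta_t) pairs on the scan grid; censored points are quiescent
    spells that had not ended by the horizon."""

    doses: np.ndarray
    delta_t_h: np.ndarray
    censored: np.ndarray
    eps: float
    results: dict[float, CollapseResult] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.delta_t_h = np.asarray(self.delta_t_h, float)
        self.censored = np.asarray(self.censored, bool)
        if np.any(self.delta_t_h < 0):
            raise ValueError("collapse times must be non-negative")

    def uncensored(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~self.censored
        return self.doses[m], self.delta_t_h[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ir_gy": self.doses, "delta_t_h": self.delta_t_h,
                             "censored": self.censored})


def collapse_curve(scan: DoseScan, species: str = "p53",
                   eps_rel: float = 0.01,
                   min_duration_h: float | None = None) -> CollapseCurve:
    """delta_t per dose via the collapse detector; censoring is data, not
    failure."""
    delta, cens, results = [], [], {}
    eps_used = float("nan")
    for dose in scan.doses:
        t, v = scan.get(dose, species)
        eps = eps_rel * float(v.max() - v.min())
        res = collapse_interval((t, v), eps=eps if eps > 0 else None,
                                min_duration_h=min_duration_h)
        delta.append(res.delta_t_h)
        cens.append(res.censored)
        results[float(dose)] = res
        eps_used = eps
    return CollapseCurve(doses=scan.doses, delta_t_h=np.asarray(delta),
                         censored=np.asarray(cens), eps=eps_used,
                         results=results)


@dataclass
class CollapseFit:
    """Least-squares parameters of delta_t = A / (B + exp(-IR))."""

    A: float
    B: float
    residual_norm: float
    n_points: int
    starts_tried: int

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("fitted B must be positive")

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return self.A / (self.B + np.exp(-np.asarray(doses, float)))


def fit_collapse_model(curve: CollapseCurve,
                       min_points: int = 4) -> CollapseFit:
    """Fit delta_t = A / (B + exp(-IR)) to the uncensored curve points.

    Multi-start on B's order of magnitude (1e-4 .. 10); the best
    sum-of-squares solution wins.  Raises ``ValueError("nothing to fit")``
    on degenerate curves (all delta_t zero or fewer than ``min_points``
    uncensored points).
    """
    doses, delta = curve.uncensored()
    if doses.size < min_points or not np.any(delta > 0):
        raise ValueError(
            "nothing to fit: need at least "
            f"{min_points} uncensored points with a positive collapse time "
            f"(got {doses.size} uncensored, max delta_t "
            f"{delta.max() if delta.size else 0:g})"
        )
    e = np.exp(-doses)

    def resid(theta):
        logA, logB = theta
        return np.exp(logA) / (np.exp(logB) + e) - delta

    best = None
    starts = 0
    scale = float(delta.max())
    for b0 in (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0):
        a0 = scale * (b0 + np.exp(-doses.max()))
        sol = least_squares(resid, x0=[np.log(max(a0, 1e-12)), np.log(b0)],
                            method="lm", max_nfev=5000)
        starts += 1
        if best is None or sol.cost < best.cost:
            best = sol
    A, B = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    return CollapseFit(A=A, B=B,
                       residual_norm=float(np.sqrt(2.0 * best.cost)),
                       n_points=int(doses.size), starts_tried=starts)


@dataclass
class SaturationResult:
    """Plateau of the collapse curve: delta_t is within ``plateau_tol``
    (relative) of the terminal value for every dose >= ``r_c_gy``."""

    saturated: bool
    r_c_gy: float | None
    delta_t_c_h: float | None
    plateau_tol: float
    n_plateau: int = 0


def saturation(curve: CollapseCurve, plateau_tol: float = 0.02,
               min_plateau_points: int = 3) -> SaturationResult:
    """Detect the high-dose plateau of delta_t(IR).

    R_c is the smallest dose from which every subsequent uncensored delta_t
    lies within ``plateau_tol`` of the terminal value; delta_t_c is the mean
    over the plateau.  Curves whose plateau would be shorter than
    ``min_plateau_points`` grid points, or that only flatten at the last
    point, report "not saturated" rather than an error.
    """
    doses, delta = curve.uncensored()
    if doses.size < min_plateau_points or not np.any(delta > 0):
        return SaturationResult(False, None, None, plateau_tol)
    terminal = delta[-1]
    if terminal <= 0:
        return SaturationResult(False, None, None, plateau_tol)
    within = np.abs(delta - terminal) <= plateau_tol * terminal
    # longest suffix of points all within tolerance of the terminal value
    idx = np.flatnonzero(~within)
    start = int(idx[-1]) + 1 if idx.size else 0
    n_plateau = doses.size - start
    if n_plateau < min_plateau_points or start == 0 or start >= doses.size - 1:
        if not (start == 0 and n_plateau >= min_plateau_points):
            return SaturationResult(False, None, None, plateau_tol,
                                    n_plateau=n_plateau)
    return SaturationResult(
        saturated=True,
        r_c_gy=float(doses[start]),
        delta_t_c_h=float(np.mean(delta[start:])),
        plateau_tol=plateau_tol,
        n_plateau=n_plateau,
    )


# ----------------------------------------------------------------------
# time-resolved bifurcation diagrams and maxima-vs-dose scatters
# ----------------------------------------------------------------------

def time_resolved_bifurcation(
    dose: float,
    species: str = "cyclin",
    params: ParameterSet | None = None,
    horizon_h: float = DEFAULT_HORIZON_H,
    window_h: float = 25.0,
    hop_h: float = 5.0,
    tolerances: RegimeTolerances | None = None,
    dt_s: float = DEFAULT_DT_S,
    sample_s: float = DEFAULT_SAMPLE_S,
    trajectory: Trajectory | None = None,
    scan: DoseScan | None = None,
) -> tuple[RegimeSegmentation, pd.DataFrame]:
    """Integrate at one dose and segment the regimes of one species.

    Returns the segmentation plus the (time, maximum) scatter that makes up
    the right-hand bifurcation panels.  An existing trajectory or scan can
    be passed to avoid re-integration.
    """
    if scan is not None and float(dose) in scan.series:
        t, v = scan.get(dose, species)
    elif trajectory is not None:
        t, v = trajectory.times_h, trajectory.species(species)
    else:
        params = params or default_parameters()
        traj = integrate(params, make_initial_state(dose), horizon_h,
                         dt_s=dt_s, sample_s=sample_s, ir_dose=dose)
        t, v = traj.times_h, traj.species(species)
    seg = segment_regimes((t, v), species=species, window_h=window_h,
                          hop_h=hop_h, tolerances=tolerances)
    maxima = find_maxima((t, v), species=species)
    scatter = maxima.to_frame()
    scatter.insert(0, "ir_gy", float(dose))
    return seg, scatter


def maxima_vs_dose(scan: DoseScan, species: str = "mpf",
                   t_window: tuple[float, float] = (0.0, 50.0)) -> pd.DataFrame:
    """All maxima of one species inside a fixed time window, per dose.

    This is the bifurcation-diagram ordinate as a function of the dose:
    one row per (dose, maximum value) pair, tidy for plotting or CSV export.
    """
    lo, hi = t_window
    if hi <= lo:
        raise ValueError("t_window must be increasing")
    if hi > scan.horizon_h + 1e-9:
        raise ValueError("t_window extends past the scan horizon")
    rows = []
    for dose in scan.doses:
        t, v = scan.get(dose, species)
        maxima = find_maxima((t, v), species=species, transient_h=lo)
        m = maxima.times_h <= hi
        for val in maxima.values[m]:
            rows.append((float(dose), float(val)))
    return pd.DataFrame(rows, columns=["ir_gy", "maximum"])
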