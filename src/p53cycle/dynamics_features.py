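"""Oscillation features: maxima, collapse intervals and regime labels.

Everything downstream of the integrator rests on three observables extracted
from a sampled time series:

* the strict local maxima after transient removal (:func:`find_maxima`),
* the longest quiescent ("collapse") interval bracketed by oscillation
  (:func:`collapse_interval`),
* a dynamical regime label decided purely from the maxima and declared
  tolerances (:func:`classify_regime`), optionally swept over sliding
  windows (:func:`segment_regimes`).

Regime vocabulary: ``oscillation_death`` (excursion below a small fraction of
the species' amplitude), ``damped`` (monotonically decaying peaks reaching
the floor), ``period_1`` ("sustained"), ``period_2``, ``period_3``,
``period_k`` (k > 3), ``chaotic`` (many distinct peak levels *and* a
positive successive-maxima return-map dispersion), and
``insufficient_evidence`` when a window holds too few peaks to call.
A chaos call requires both conditions so that slowly modulated sustained
oscillation is not mislabeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .integrator import Trajectory

__all__ = [
    "MaximaSeries",
    "CollapseResult",
    "RegimeLabel",
    "RegimeSegmentation",
    "RegimeTolerances",
    "find_maxima",
    "collapse_interval",
    "classify_regime",
    "segment_regimes",
    "maxima_dispersion",
]

log = logging.getLogger(__name__)

PERIOD_LABELS = {1: "period_1", 2: "period_2", 3: "period_3"}


def _as_series(obj, species: str | None = None):
    """Coerce a Trajectory(+species), synthetic signal, or (t, v) pair."""
    if isinstance(obj, Trajectory):
        if species is None:
            raise ValueError("species required when passing a Trajectory")
        return obj.times_h, obj.species(species), species
    if hasattr(obj, "times_h") and hasattr(obj, "values"):
        return np.asarray(obj.times_h, float), np.asarray(obj.values, float), (
            species or getattr(obj, "name", "signal")
        )
    t, v = obj
    return np.asarray(t, float), np.asarray(v, float), (species or "signal")


@dataclass
class MaximaSeries:
    """Strict local maxima of one species after transient removal."""

    species: str
    times_h: np.ndarray
    values: np.ndarray
    transient_h: float
    #: (min, max) of the sampled signal after the transient cutoff.
    signal_range: tuple[float, float] = (0.0, 0.0)
    #: absolute amplitude reference (defaults to the post-transient signal
    #: excursion of the full series); regime calls use eps_rel * amplitude_ref.
    amplitude_ref: float = 0.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.values = np.asarray(self.values, float)
        if self.times_h.size and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("maxima times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_h.size

    @property
    def dominant_period_h(self) -> float:
        """Median spacing of successive maxima (NaN with < 2 maxima)."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.times_h)))

    def window(self, t_start: float, t_end: float,
               signal_range: tuple[float, float] | None = None) -> "MaximaSeries":
        m = (self.times_h >= t_start) & (self.times_h <= t_end)
        return MaximaSeries(
            species=self.species,
            times_h=self.times_h[m],
            values=self.values[m],
            transient_h=self.transient_h,
            signal_range=signal_range or self.signal_range,
            amplitude_ref=self.amplitude_ref,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times_h, "value": self.values})


def _strict_maxima_indices(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima; plateaus report their midpoint once.

    Returns (left_edge_index, right_edge_index) pairs; for non-plateau peaks
    the two coincide.
    """
    n = v.size
    lefts, rights = [], []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                lefts.append(i)
                rights.append(j)
            i = j + 1
        else:
            i += 1
    return np.asarray(lefts, int), np.asarray(rights, int)


def _parabolic_refine(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location via the parabola through (i-1, i, i+1)."""
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat or non-concave: keep the sample
        return float(t[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
    t_pk = float(t[i]) + delta * float(dt)
    v_pk = float(y1 - 0.25 * (y0 - y2) * delta)
    return t_pk, v_pk


def default_transient_h(horizon_h: float, period_h: float) -> float:
    """First 10% of the horizon or 5 dominant periods, whichever is larger.

    Barely-oscillating series can produce absurd period estimates, so the
    cutoff is capped at half the horizon to keep an analysis window.
    """
    periods = 5.0 * period_h if np.isfinite(period_h) else 0.0
    return max(0.1 * horizon_h, min(periods, 0.5 * horizon_h))


def find_maxima(obj, species: str | None = None,
                transient_h: float | None = None,
                refine: bool = True) -> MaximaSeries:
    """Strict local maxima of a sampled series after transient removal.

    ``transient_h = None`` applies the default cutoff (10% of the horizon or
    five dominant periods, whichever is larger, with the period estimated
    from a first full-series pass).  Peak times/heights are refined by a
    parabolic fit through the three samples around each peak; plateaus are
    reported once, at their midpoint, without refinement.
    """
    t, v, name = _as_series(obj, species)
    if t.size < 3:
        raise ValueError("series shorter than one sampling window")
    lefts, rights = _strict_maxima_indices(v)
    if transient_h is None:
        gaps = np.diff(t[(lefts + rights) // 2])
        period = float(np.median(gaps)) if gaps.size else float("nan")
        transient_h = default_transient_h(t[-1] - t[0], period)
        transient_h += float(t[0])
    if t[-1] <= transient_h:
        raise ValueError(
            f"trajectory (horizon {t[-1]:g} h) shorter than the transient "
            f"cutoff ({transient_h:g} h)"
        )
    times, values = [], []
    for il, ir in zip(lefts, rights):
        mid = (il + ir) // 2
        if t[mid] <= transient_h:
            continue
        if refine and il == ir:
            t_pk, v_pk = _parabolic_refine(t, v, il)
        else:
            t_pk, v_pk = float(t[mid]), float(v[mid])
        times.append(t_pk)
        values.append(v_pk)
    post = v[t > transient_h]
    rng = (float(post.min()), float(post.max())) if post.size else (0.0, 0.0)
    return MaximaSeries(
        species=name,
        times_h=np.asarray(times),
        values=np.asarray(values),
        transient_h=float(transient_h),
        signal_range=rng,
        amplitude_ref=rng[1] - rng[0],
    )


@dataclass
class CollapseResult:
    """The longest quiescent interval bracketed by oscillation.

    ``delta_t_h`` is the collapse duration in hours and is zero when no
    completed collapse exists.  A quiescent spell that is still running at
    the end of the series has not ended, so no finite collapse time can be
    measured: ``censored`` is set, ``delta_t_h`` stays 0, and the observed
    spell is reported via ``start_h``/``end_h``.
    """

    delta_t_h: float
    start_h: float
    end_h: float
    eps: float
    censored: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.delta_t_h < 0 or self.end_h < self.start_h:
            raise ValueError("invalid collapse interval")


def collapse_interval(obj, species: str | None = None,
                      eps: float | None = None,
                      min_duration_h: float | None = None,
                      period_factor: float = 1.5) -> CollapseResult:
    """Measure the oscillation-collapse interval of a series.

    The signal is scanned with a rolling peak-to-trough excursion over a
    window of ``period_factor`` dominant periods; an interval is quiescent
    where the excursion stays below ``eps`` (default: 1% of the signal's
    global range).  The longest quiescent run that is preceded by at least
    two oscillation maxima and followed by renewed activity is the collapse;
    runs reaching the end of the series are censored.  Runs shorter than
    ``min_duration_h`` (default: two dominant periods) are ignored.
    Degenerate inputs yield ``delta_t_h = 0`` with a logged note.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    t, v, name = _as_series(obj, species)
    if t.size < 3:
        return CollapseResult(0.0, t[0] if t.size else 0.0,
                              t[0] if t.size else 0.0, eps or 0.0,
                              note="degenerate input (too short)")
    rng = float(v.max() - v.min())
    if eps is None:
        eps = 0.01 * rng
    if eps <= 0 or rng == 0.0:
        log.info("collapse_interval: flat series %s, no collapse", name)
        return CollapseResult(0.0, float(t[0]), float(t[0]), float(max(eps or 0.0, 0.0)),
                              note="flat series")

    lefts, rights = _strict_maxima_indices(v)
    mids = (lefts + rights) // 2
    gaps = np.diff(t[mids])
    period = float(np.median(gaps)) if gaps.size else float("nan")
    if not np.isfinite(period) or period <= 0:
        log.info("collapse_interval: no oscillation detected in %s", name)
        return CollapseResult(0.0, float(t[0]), float(t[0]), float(eps),
                              note="no oscillation")
    if min_duration_h is None:
        min_duration_h = 2.0 * period
    if min_duration_h <= 0:
        raise ValueError("min_duration_h must be positive")

    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(period_factor * period / dt)))
    excursion = (maximum_filter1d(v, size=win, mode="nearest")
                 - minimum_filter1d(v, size=win, mode="nearest"))
    quiet = excursion < eps

    # maximal runs of quiet samples
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8)))
    starts = [0] if quiet[0] else []
    starts += [int(e) + 1 for e in edges if quiet[e + 1]]
    ends = [int(e) for e in edges if quiet[e]]
    if quiet[-1]:
        ends.append(quiet.size - 1)

    # quiet[i] certifies an excursion-free window centred on sample i, so the
    # true quiescent interval extends half a window beyond the run's samples
    half_w = (win // 2) * dt

    best: CollapseResult | None = None
    for a, b in zip(starts, ends):
        start_h = max(float(t[a]) - half_w, float(t[0]))
        end_h = min(float(t[b]) + half_w, float(t[-1]))
        length = end_h - start_h
        if length < min_duration_h:
            continue
        n_peaks_before = int(np.sum(t[mids] < start_h))
        if a == 0 or n_peaks_before < 2:
            continue  # no oscillation preceding: not a collapse of oscillation
        if b >= quiet.size - 1:
            cand = CollapseResult(0.0, start_h, end_h, float(eps),
                                  censored=True,
                                  note="quiescent to end of series")
        else:
            cand = CollapseResult(length, start_h, end_h, float(eps))
        key = cand.end_h - cand.start_h
        if best is None or key > (best.end_h - best.start_h):
            best = cand
    if best is None:
        return CollapseResult(0.0, float(t[0]), float(t[0]), float(eps),
                              note="no qualifying quiescent interval")
    return best


@dataclass
class RegimeLabel:
    """A dynamical regime call with its supporting evidence."""

    label: str
    n_maxima: int = 0
    n_clusters: int = 0
    cyclic: bool = False
    dispersion: float = float("nan")
    excursion: float = float("nan")
    eps: float = float("nan")

    def __eq__(self, other) -> bool:  # labels compare by name
        if isinstance(other, str):
            return self.label == other
        if isinstance(other, RegimeLabel):
            return self.label == other.label
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.label)


@dataclass(frozen=True)
class RegimeTolerances:
    """Declared thresholds for regime calls (none are given by the source
    figures, which were judged visually)."""

    delta_rel: float = 0.02        # relative peak-height clustering tolerance
    eps_rel: float = 0.01          # death excursion, fraction of amplitude_ref
    k_max: int = 6                 # above this many clusters: chaos candidate
    dispersion_threshold: float = 0.05  # scale-free return-map dispersion
    min_peaks: int = 4             # fewest maxima for a period-k call


def _cluster_heights(h: np.ndarray, delta_rel: float) -> np.ndarray:
    """Greedy 1-D clustering with maximum cluster diameter delta_rel*scale.

    Returns the cluster id of each height (ids ordered by ascending height).
    """
    scale = float(np.max(np.abs(h))) or 1.0
    order = np.argsort(h, kind="stable")
    ids = np.empty(h.size, dtype=int)
    cid = 0
    anchor = h[order[0]]
    for idx in order:
        if h[idx] - anchor > delta_rel * scale:
            cid += 1
            anchor = h[idx]
        ids[idx] = cid
    return ids


def _minimal_cycle(ids: np.ndarray, k_max: int) -> int | None:
    """Smallest p with ids[i + p] == ids[i] for all i, visiting every cluster
    in each consecutive window of p; None if no such p <= k_max exists."""
    n_clusters = ids.max() + 1
    for p in range(1, min(k_max, ids.size) + 1):
        if p < n_clusters:
            continue
        if np.all(ids[p:] == ids[:-p]) and len(set(ids[:p].tolist())) == n_clusters:
            return p
    return None


def _return_map_dispersion(h: np.ndarray, k_max: int) -> float:
    """Scale-free spread of the successive-maxima return map: the minimum
    over lags 1..k_max of rms(h[i+k] - h[i]) / max|h|.  Zero for any exact
    period-k sequence with k <= k_max."""
    scale = float(np.max(np.abs(h)))
    if scale == 0.0 or h.size < 3:
        return 0.0
    best = np.inf
    # cap the lag so each rms uses at least half the maxima as pairs
    max_lag = min(k_max, max(1, h.size // 2))
    for lag in range(1, max_lag + 1):
        d = h[lag:] - h[:-lag]
        best = min(best, float(np.sqrt(np.mean(d * d))) / scale)
    return best


def maxima_dispersion(series: MaximaSeries | np.ndarray, k_max: int = 6) -> float:
    """Public dispersion statistic; requires at least 10 maxima."""
    h = series.values if isinstance(series, MaximaSeries) else np.asarray(series, float)
    if h.size < 10:
        raise ValueError(f"need >= 10 maxima for a dispersion estimate, got {h.size}")
    return _return_map_dispersion(h, k_max)


def classify_regime(series: MaximaSeries,
                    tolerances: RegimeTolerances | None = None,
                    eps: float | None = None) -> RegimeLabel:
    """Label the dynamical regime of a maxima series (pure function).

    ``eps`` is the absolute oscillation-death excursion threshold; by default
    it is ``tolerances.eps_rel`` times the series' amplitude reference, which
    makes the call invariant to uniform scaling of the signal.
    """
    tol = tolerances or RegimeTolerances()
    if eps is None:
        eps = tol.eps_rel * series.amplitude_ref
    lo, hi = series.signal_range
    excursion = hi - lo
    ev = dict(n_maxima=len(series), excursion=float(excursion), eps=float(eps))

    if excursion <= eps or len(series) == 0:
        label = "oscillation_death" if excursion <= eps else "insufficient_evidence"
        return RegimeLabel(label, **ev)

    h = series.values
    if len(series) >= 3:
        drops = np.diff(h)
        scale = float(np.max(np.abs(h))) or 1.0
        monotone_down = np.all(drops < 0)
        if monotone_down and (h[0] - h[-1]) > 2.0 * tol.delta_rel * scale:
            return RegimeLabel("damped", **ev)

    if len(series) < tol.min_peaks:
        return RegimeLabel("insufficient_evidence", **ev)

    ids = _cluster_heights(h, tol.delta_rel)
    n_clusters = int(ids.max() + 1)
    dispersion = _return_map_dispersion(h, tol.k_max)
    ev.update(n_clusters=n_clusters, dispersion=dispersion)

    if n_clusters == 1:
        return RegimeLabel("period_1", cyclic=True, **ev)
    cycle = _minimal_cycle(ids, tol.k_max)
    if cycle is not None and cycle == n_clusters:
        return RegimeLabel(PERIOD_LABELS.get(cycle, "period_k"), cyclic=True, **ev)
    if n_clusters > tol.k_max and dispersion > tol.dispersion_threshold:
        return RegimeLabel("chaotic", **ev)
    if dispersion <= tol.dispersion_threshold:
        # many close levels with a tight return map: slow modulation of a
        # sustained oscillation, not chaos
        return RegimeLabel("period_1", **ev)
    return RegimeLabel("insufficient_evidence", **ev)


@dataclass
class RegimeSegmentation:
    """Contiguous, non-overlapping regime segments covering the window."""

    segments: list[tuple[float, float, RegimeLabel]]
    window_h: float
    hop_h: float
    species: str = ""

    def __post_init__(self) -> None:
        for (a, b, _), (c, _, _) in zip(self.segments, self.segments[1:]):
            if not np.isclose(b, c):
                raise ValueError("segments must be contiguous")

    def labels(self) -> list[str]:
        return [seg[2].label for seg in self.segments]

    def label_at(self, t_h: float) -> str:
        for a, b, lab in self.segments:
            if a <= t_h <= b:
                return lab.label
        raise ValueError(f"t = {t_h} h outside the segmentation window")

    def final_segment(self, label: str) -> tuple[float, float] | None:
        """(start, end) of the last segment with this label, if any."""
        for a, b, lab in reversed(self.segments):
            if lab.label == label:
                return (a, b)
        return None

    def has_label(self, label: str) -> bool:
        return any(lab.label == label for _, _, lab in self.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, lab.label) for a, b, lab in self.segments],
            columns=["t_start", "t_end", "label"],
        )


def segment_regimes(obj, species: str | None = None,
                    window_h: float = 25.0, hop_h: float = 5.0,
                    tolerances: RegimeTolerances | None = None,
                    transient_h: float | None = None,
                    eps: float | None = None) -> RegimeSegmentation:
    """Sliding-window regime classification merged into maximal segments.

    Windows of ``window_h`` hours advance by ``hop_h``; each window is
    classified from the maxima and signal excursion it contains, and runs of
    identical labels are merged.  Boundaries between merged runs sit midway
    between the adjacent window centers; the segmentation covers
    [transient cutoff, horizon].
    """
    t, v, name = _as_series(obj, species)
    tol = tolerances or RegimeTolerances()
    maxima = find_maxima((t, v), species=name, transient_h=transient_h)
    t0, t_end = maxima.transient_h, float(t[-1])
    if t_end - t0 < window_h:
        raise ValueError("analysis window shorter than one classification window")
    if eps is None:
        eps = tol.eps_rel * maxima.amplitude_ref

    centers, labels = [], []
    w0 = t0
    while w0 + window_h <= t_end + 1e-9:
        w1 = min(w0 + window_h, t_end)
        m = (t >= w0) & (t <= w1)
        sig_rng = (float(v[m].min()), float(v[m].max())) if m.any() else (0.0, 0.0)
        sub = maxima.window(w0, w1, signal_range=sig_rng)
        labels.append(classify_regime(sub, tol, eps=eps))
        centers.append(0.5 * (w0 + w1))
        w0 += hop_h
    if not centers:
        raise ValueError("no classification windows fit the series")

    # windows that straddle a regime change often hold a mixture too thin to
    # call; let them inherit the neighbouring call instead of fragmenting
    for i, lab in enumerate(labels):
        if lab.label == "insufficient_evidence" and i > 0:
            labels[i] = labels[i - 1]
    for i in range(len(labels) - 2, -1, -1):
        if labels[i].label == "insufficient_evidence":
            labels[i] = labels[i + 1]

    segments: list[tuple[float, float, RegimeLabel]] = []
    seg_start = t0
    for i in range(1, len(labels)):
        if labels[i].label != labels[i - 1].label:
            boundary = 0.5 * (centers[i - 1] + centers[i])
            segments.append((seg_start, boundary, labels[i - 1]))
            seg_start = boundary
    segments.append((seg_start, t_end, labels[-1]))
    return RegimeSegmentation(segments=segments, window_h=window_h,
                              hop_h=hop_h, species=name)
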