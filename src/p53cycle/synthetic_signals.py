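"""Constructed waveforms with known ground truth.

Every detector and fitter in the package is validated against signals whose
regime labels, collapse lengths, maxima and fit parameters are known by
construction, so the analysis chain is testable without running the kinetic
model.  Periodic signals are built from smooth one-cycle bumps whose heights
follow a prescribed pattern (constant, alternating, period-3, decaying
envelope, or a logistic map at r = 3.9 for provably aperiodic maxima);
``collapse`` signals insert a flat quiescent stretch of known length; and
``piecewise`` signals concatenate such segments.  Noise is additive Gaussian
on waveforms and multiplicative log-normal on positive quantities, both
seeded; a spec and its seed fix the realization exactly.

These fixtures emulate observable signal classes only, not the full
13-species coupling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import ParameterSet

__all__ = [
    "SignalSpec",
    "SyntheticSignal",
    "generate",
    "generate_collapse_family",
    "perturb_parameters",
    "LOGISTIC_R",
]

#: Logistic-map growth rate used for chaotic peak-height fixtures; 3.9 lies
#: well inside the chaotic band of the map.
LOGISTIC_R = 3.9

KINDS = ("sustained", "damped", "period_2", "period_3",
         "chaotic_logistic", "collapse", "piecewise")


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one synthetic waveform.

    ``amplitudes`` is the peak-height pattern (cycled); for ``damped`` the
    first amplitude decays with time constant ``damping_h``; ``collapse``
    inserts a flat interval of ``collapse_len_h`` hours starting at
    ``collapse_start_h``.  ``segments`` (piecewise only) is a sequence of
    (duration_h, kind) pairs re-using the other fields.
    """

    kind: str = "sustained"
    period_h: float = 2.0
    amplitudes: tuple[float, ...] = (1.0,)
    baseline: float = 0.0
    horizon_h: float = 100.0
    dt_h: float = 0.01
    noise: float = 0.0
    seed: int = 0
    damping_h: float = 20.0
    collapse_start_h: float = 40.0
    collapse_len_h: float = 30.0
    segments: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if self.period_h <= 0 or self.dt_h <= 0 or self.horizon_h <= 0:
            raise ValueError("period_h, dt_h and horizon_h must be positive")
        if self.kind == "collapse":
            if self.collapse_start_h + self.collapse_len_h >= self.horizon_h:
                raise ValueError(
                    "contradictory spec: collapse extends beyond the horizon"
                )
            if self.collapse_start_h <= 2 * self.period_h:
                raise ValueError(
                    "collapse must start after at least two oscillation cycles"
                )
        if self.kind == "piecewise" and not self.segments:
            raise ValueError("piecewise spec requires segments")


@dataclass
class SyntheticSignal:
    """A generated series plus its machine-readable truth record."""

    times_h: np.ndarray
    values: np.ndarray
    truth: dict
    spec: SignalSpec
    name: str = "synthetic"


def _bump_train(t: np.ndarray, period: float, heights: Sequence[float],
                baseline: float) -> np.ndarray:
    """Smooth oscillation whose k-th cycle peaks at heights[k % len].

    Each cycle is a raised-cosine bump: zero slope at cycle edges and at the
    mid-cycle peak, so the strict maxima are exactly the prescribed heights
    at times (k + 1/2) * period.
    """
    heights = np.asarray(heights, float)
    cycle = np.floor(t / period).astype(int)
    phase = t / period - cycle
    amp = heights[cycle % heights.size]
    return baseline + amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def _segment_values(kind: str, t: np.ndarray, spec: SignalSpec,
                    rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Values of one homogeneous segment on a local time axis from 0."""
    period, base = spec.period_h, spec.baseline
    amps = np.asarray(spec.amplitudes, float)
    if kind == "sustained":
        truth_label = "period_1"
        v = _bump_train(t, period, amps[:1], base)
        peak_pattern = amps[:1]
    elif kind == "period_2":
        a = amps if amps.size >= 2 else np.array([amps[0], 0.6 * amps[0]])
        v = _bump_train(t, period, a[:2], base)
        truth_label, peak_pattern = "period_2", a[:2]
    elif kind == "period_3":
        a = amps if amps.size >= 3 else amps[0] * np.array([1.0, 0.7, 0.4])
        v = _bump_train(t, period, a[:3], base)
        truth_label, peak_pattern = "period_3", a[:3]
    elif kind == "damped":
        n_cycles = int(np.ceil(t[-1] / period)) + 1
        cycle = np.floor(t / period).astype(int)
        peak_t = (np.arange(n_cycles) + 0.5) * period
        heights = amps[0] * np.exp(-peak_t / spec.damping_h)
        phase = t / period - cycle
        v = base + heights[cycle] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        truth_label, peak_pattern = "damped", heights
    elif kind == "chaotic_logistic":
        n_cycles = int(np.ceil(t[-1] / period)) + 1
        u = np.empty(n_cycles)
        u[0] = 0.35 + 0.3 * rng.random()
        for i in range(1, n_cycles):
            u[i] = LOGISTIC_R * u[i - 1] * (1.0 - u[i - 1])
        heights = amps[0] * (0.2 + 0.8 * u)   # keep heights bounded away from 0
        cycle = np.floor(t / period).astype(int)
        phase = t / period - cycle
        v = base + heights[cycle] * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        truth_label, peak_pattern = "chaotic", heights
    else:  # pragma: no cover
        raise ValueError(kind)
    return v, {"label": truth_label, "peak_pattern": np.asarray(peak_pattern)}


def generate(spec: SignalSpec) -> SyntheticSignal:
    """Build the waveform described by ``spec`` plus its truth record.

    The truth record holds the constructed regime label(s) per segment, the
    true collapse length (``delta_t_h``, 0 if none) and the exact peak times
    and heights of the noiseless construction.  The same (spec, seed) always
    yields the identical series.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.horizon_h + 0.5 * spec.dt_h, spec.dt_h)
    truth: dict = {"delta_t_h": 0.0, "segments": []}

    if spec.kind == "collapse":
        v = _bump_train(t, spec.period_h, spec.amplitudes[:1], spec.baseline)
        a, b = spec.collapse_start_h, spec.collapse_start_h + spec.collapse_len_h
        # cut on whole-cycle boundaries so the flat stretch joins smoothly
        a = np.floor(a / spec.period_h) * spec.period_h
        b = np.ceil(b / spec.period_h) * spec.period_h
        v = np.where((t >= a) & (t < b), spec.baseline, v)
        truth["delta_t_h"] = float(b - a)
        truth["collapse_start_h"], truth["collapse_end_h"] = float(a), float(b)
        truth["segments"] = [(0.0, a, "period_1"),
                             (a, b, "oscillation_death"),
                             (b, spec.horizon_h, "period_1")]
    elif spec.kind == "piecewise":
        v = np.empty_like(t)
        t_cursor = 0.0
        for duration, kind in spec.segments:
            m = (t >= t_cursor) & (t < t_cursor + duration)
            seg_v, seg_truth = _segment_values(
                kind, t[m] - t_cursor, spec, rng)
            v[m] = seg_v
            truth["segments"].append(
                (t_cursor, t_cursor + duration, seg_truth["label"]))
            t_cursor += duration
        m = t >= t_cursor
        if m.any():
            v[m] = spec.baseline
    else:
        v, seg_truth = _segment_values(spec.kind, t, spec, rng)
        truth["segments"] = [(0.0, spec.horizon_h, seg_truth["label"])]
        truth["peak_pattern"] = seg_truth["peak_pattern"]

    # exact maxima of the noiseless construction (mid-cycle peaks)
    if spec.kind != "piecewise":
        n_cycles = int(np.floor(spec.horizon_h / spec.period_h))
        peak_t = (np.arange(n_cycles) + 0.5) * spec.period_h
        peak_v = np.interp(peak_t, t, v)
        keep = peak_v > spec.baseline + 1e-12
        truth["peak_times_h"] = peak_t[keep]
        truth["peak_values"] = peak_v[keep]

    if spec.noise > 0:
        scale = float(np.max(np.abs(spec.amplitudes))) or 1.0
        v = v + rng.normal(0.0, spec.noise * scale, size=v.size)

    return SyntheticSignal(times_h=t, values=v, truth=truth, spec=spec,
                           name=spec.kind)


def generate_collapse_family(doses: np.ndarray, A: float, B: float,
                             noise: float = 0.0, seed: int = 0):
    """A collapse-time curve drawn from delta_t = A / (B + exp(-IR)).

    Optional multiplicative log-normal noise of coefficient of variation
    ``noise``; the truth record carries (A, B).  Returns a
    :class:`p53cycle.bifurcation_analysis.CollapseCurve`.
    """
    from .bifurcation_analysis import CollapseCurve

    if B <= 0:
        raise ValueError("B must be positive")
    doses = np.asarray(doses, float)
    delta = A / (B + np.exp(-doses))
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise ** 2))
        delta = delta * rng.lognormal(-0.5 * sigma ** 2, sigma, size=delta.size)
    return CollapseCurve(
        doses=doses, delta_t_h=delta,
        censored=np.zeros(doses.size, dtype=bool),
        eps=float("nan"),
        truth={"A": float(A), "B": float(B), "noise": float(noise),
               "seed": int(seed)},
    )


def perturb_parameters(base: ParameterSet, cv: float, seed: int = 0) -> ParameterSet:
    """Multiply every rate constant by an independent log-normal factor of
    coefficient of variation ``cv`` (cv = 0 returns ``base`` unchanged)."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return base
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    updates = {}
    for name in ParameterSet._K_NAMES:
        factor = rng.lognormal(-0.5 * sigma ** 2, sigma)
        updates[name] = getattr(base, name) * factor
    return base.replace(**updates)
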