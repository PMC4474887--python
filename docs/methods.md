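# Methods

## Model and assumptions

The network couples two modules through a single one-way link.

**Damage-response module (x4–x11).**  p53 is synthesised at a constant rate
(k16), sequestered by Mdm2 into a complex (k17) that either dissociates
(k18) or degrades p53 (k19).  Mdm2 is produced through an explicit mRNA
intermediate (transcription k20, mRNA decay k21, translation k22) and decays
at k23.  An irradiation bolus enters as the initial value of x10 (IR, in
Gy), converts to damaged DNA x11 at k24 = 1 s⁻¹ (effectively instantaneous)
and is repaired at k25 = 2×10⁻⁵ s⁻¹, so the damage signal is a single
exponentially decaying pulse with a 1/k25 ≈ 13.9 h e-fold time.  Damage
activates ARF (k26), which sequesters Mdm2 (k27) into a complex degraded at
k29, releasing ARF; free ARF decays at k28.  Elevated damage therefore
depresses Mdm2 and raises p53.

**Cell-cycle module (x1–x3).**  A minimal mitotic cascade: cyclin is
synthesised at k1, degraded basally (k4) and by the active protease
(k2, Michaelis constant k3).  Cyclin activates MPF out of its inactive pool
(fraction 1 − x2) with maximal turnover k14 and half-saturation k13 in
cyclin, k6 in the inactive fraction; MPF inactivates at k7/k8.  Active MPF
activates the cyclin protease (k15, k10) which inactivates at k11/k12.
Both fractions live in [0, 1] by construction (activation terms vanish at 1,
decay terms at 0).

**Coupling.**  p53 transactivates p21 (k30); p21 binds active MPF into a
p21·MPF complex (k31·x2·x12) which dissociates to p21 only (k32); p21 decays
at k33.  There is no feedback from the cell cycle to p53: the damage module
drives the cycle and never hears back.

Concentrations are treated as dimensionless activity levels (the source
constants mix molar-style and fractional species); the only unit conversion
in the package is time (integration in seconds, all reporting in hours, one
named constant `HOURS_TO_SECONDS`).

## Resolving the printed-constant ambiguities

The published equations and constant table disagree in places.  Every
resolution is a named flag on `TypoPolicy` with the resolution as default:

* `mpf_activation_k6_denominator` — the MPF activation denominator is read
  as `k6 + (1 − x2)`; the literal reading names the Mdm2·p53 complex (x6),
  but k6 = 0.01 is listed in the constant table and appears nowhere else.
* `mpf_decay_michaelis` — the MPF decay quotient is read in Michaelis form
  `k7·x2/(k8 + x2)`; the literal reading collapses to a constant k7/k8.
* `arf_decay_linear` — ARF decay is first order (k28·x8), as in the
  differential equations; the reaction table prints a bimolecular rate.
* `p21_mpf_rate_from_ode` — the p21+MPF association rate is k31·x2·x12 as in
  the differential equations; the reaction table prints k31·x4.
* `k1_scaled_1e2` — the cyclin synthesis constant is printed with a
  trailing ×10⁻² factor.  The default drops it (k1 = 4.16667×10⁻⁴ s⁻¹,
  which equals the source cascade's synthesis rate exactly); with the factor
  applied the cyclin subsystem has no sustained oscillation under normal
  conditions for any plausible k14, so that reading is kept selectable but
  not default.

**k14 calibration.**  The table prints k14 = 0.00 s⁻¹, which would freeze
MPF activation permanently and contradict the sustained normal-condition
limit cycle the model is supposed to show.  k14 is therefore treated as a
free calibration constant: scanning round values {0.001, 0.002, 0.005, 0.01,
0.05} s⁻¹ under default initial conditions, 0.005 s⁻¹ is the smallest that
yields a sustained cyclin/MPF limit cycle at IR = 0, and is the default.  It
is also exactly the cited minimal-cascade value (VM1 = 3 min⁻¹) divided by
the same factor of 10 that relates the printed k7, k11 and k15 to that
cascade's V2, V4 and VM3 — consistent with a systematic rescaling rather
than coincidence.  `goldbeter_profile()` ships the unscaled cascade
transcription as an alternative parameter profile for cross-checking.

**M\*/X\*.**  The inactive fractions are implemented as 1 − x2 and 1 − x3,
consistent with every differential term; the source sentence equating them
to 1 − x10 and 1 − x11 is recorded as an erratum and not implemented.

## Initial conditions

The source states none.  Defaults: small positive seeds for the three
cell-cycle species (x1 = x2 = x3 = 0.01), x10 = IR, everything else zero;
all overridable per species and from the flat JSON config.  Starting the
damage module from zero implies a large one-off p53 transient over the first
~20 h at every dose (p53 rises before Mdm2 exists to oppose it); the
transient-removal cutoff is sized to exclude it.

## Integration

Classical fixed-step RK4 in a compiled (numba) kernel.  The reference step
is 1.0 s: halving it changes reported oscillation maxima by ~3×10⁻¹⁰
relative (measured on normal-condition and 5 Gy runs), four orders of
magnitude inside the < 0.1 % contract, and the empirical convergence order
on the full nonlinear system is 4 (test-enforced within [3.5, 4.5]).  An
adaptive mode is deliberately not offered: fixed-step determinism gives
bitwise-reproducible trajectories and restart-invariance, which the suite
checks exactly.  Output is sampled every 60 s, independent of the step —
≥ 20 samples per period of the fastest oscillation in the model (the
~1.1 h cyclin cycle gets ~68).  Negative undershoots within 10⁻⁹ of zero
are clamped to zero and counted; anything more negative, or non-finite,
aborts with the species and time named.  Mass-action structure makes the
x10 → x11 conversion exactly conservative under any Runge–Kutta step, so
the stiff k24 = 1 s⁻¹ channel does not limit accuracy at the default step.

## Feature extraction

**Maxima.**  Strict local maxima of the sampled series after transient
removal; plateaus report their midpoint once; peak time and height are
refined by a parabolic fit through the three samples around each peak.  The
default transient cutoff is the larger of 10 % of the horizon and five
dominant periods (median inter-peak spacing from a first pass), capped at
half the horizon so barely-oscillating series keep an analysis window.

**Collapse intervals.**  Quiescence is detected on the full trajectory (not
only on maxima, so a peakless plateau is still measurable) as a rolling
peak-to-trough excursion — window 1.5 dominant periods — staying below eps
(default 1 % of the signal's global range).  A quiescent run qualifies as a
collapse only when at least two oscillation maxima precede it and activity
resumes after it; its duration Δt adds back the half-window the rolling
filter erodes at each edge.  Runs shorter than two dominant periods are
ignored.  A quiescent spell still running at the end of the series has not
ended, so no finite Δt exists: the result is censored (Δt = 0, flag set,
observed span reported), and censored doses are excluded from curve fitting.
A series that never oscillated (normal-condition p53) has no collapse at
all: Δt = 0.

**Regime classification** is a pure function of a maxima series and declared
tolerances (the source figures were judged visually; no thresholds are given
there, so all values here are declared, not inferred).  Oscillation death:
window excursion ≤ eps, where eps defaults to 1 % of the series'
post-transient amplitude (an absolute reference can be passed in; dose scans
use the species' largest post-transient amplitude across the grid so death
at one dose is judged on the species' oscillation scale).  Damped:
monotonically decreasing peak heights with a total drop beyond twice the
clustering tolerance.  Otherwise peak heights are clustered greedily with a
maximum cluster diameter of δ = 2 % of the height scale; k clusters visited
cyclically give period-k (period-1 = sustained); more than k_max = 6
clusters **and** a return-map dispersion above 0.05 give chaotic — both are
required so slowly modulated sustained oscillation is not mislabeled; many
close levels with a tight return map fall back to sustained.  Windows with
fewer than 4 peaks return `insufficient_evidence` (distinct from every
regime).  The dispersion statistic is the minimum over lags 1..k_max of the
rms successive-maxima difference at that lag, divided by the height scale:
exactly zero for any period-k sequence, positive for aperiodic ones; lags
are capped so each rms uses at least half the maxima.

**Segmentation.**  Sliding windows (default 25 h, hop 5 h) are classified
and merged into maximal same-label segments with boundaries midway between
adjacent window centres; windows straddling a regime change that come back
`insufficient_evidence` inherit the neighbouring call.  Changeover times are
therefore resolved to about one window.

## Dose-scan quantities

One deterministic integration per dose with identical settings (default grid
0–12 Gy, step 0.05; horizon 250 h, long enough for the longest reported
collapse to complete with margin).  The phase diagram classifies the final
50 h of each dose's p53 series; the boundary is the midpoint of the first
label change, refined by bisection on the dose axis to 0.02 Gy.  The
collapse curve applies the collapse detector per dose; the fit
Δt = A/(B + e^(−IR)) is solved in log-parameters by Levenberg–Marquardt
least squares, multi-started across six orders of magnitude in B.
Saturation reports R_c, the smallest dose from which all subsequent Δt lie
within 2 % (relative) of the terminal value, and Δt_c, the plateau mean; a
plateau needs at least three grid points.  Maxima-versus-dose scatters
(the bifurcation-diagram ordinate) use the fixed early window [0, 50] h.

## Synthetic signals

The generator emulates the observable signal classes the analysis assumes —
sustained, damped, period-2/3, chaotic, collapse-interrupted, piecewise —
not the 13-species coupling.  Periodic signals are raised-cosine bump trains
whose per-cycle heights follow the prescribed pattern, so true maxima are
known exactly; chaotic fixtures modulate heights with a logistic map at
r = 3.9 (provably aperiodic); collapse fixtures cut whole cycles to a flat
baseline of known length; noise is additive Gaussian on waveforms and
multiplicative log-normal on positive quantities, all seeded.  Passing the
fixture suite shows the detectors recover constructed truth (collapse
lengths within one period on 100 random constructions; a diagonal
classifier confusion matrix; (A, B) recovered to 10⁻⁶ noiseless and within
10 % at 5 % noise) — it does not show that the kinetic model exhibits those
regimes, which is a property of the equations, not of the detectors.

## What the shipped model actually does

On the default study conditions the pipeline measures the following, and the
acceptance checks report it without adjustment:

* p53 responds to any single bolus with one large pulse followed by a damped
  ring-down to the same fixed point; the final-50 h window classifies as
  oscillation death at **every** dose on the grid, so the phase diagram is
  single-phase and has no boundary dose.
* Because the p53 → cell-cycle coupling is one-way and the damage pulse
  decays monotonically, a p53 oscillation that has gone quiet can never
  restart; every detected quiescent spell runs to the horizon and is
  censored.  The collapse curve therefore has no completed collapse at any
  dose, nothing for the A/(B + e^(−IR)) fit to fit, and no saturation
  plateau.
* The p21 route moves cyclin maxima by under 2 % even at 10 Gy — below the
  2 % clustering tolerance — so the cyclin segmentation is a single
  sustained segment at every dose: no oscillation-death onset, no
  period-2/3 windows, no chaotic interval, and the "final sustained
  segment" begins at the transient cutoff (25 h) rather than at a
  dose-dependent changeover.

These are properties of the published constants under the documented typo
resolutions, not of the detectors (which the synthetic suite validates
independently).  Regimes beyond period-1 would require either stochastic
(reaction-channel) simulation, which is out of scope here, or a
substantially stronger p21 coupling / slower damage repair than the printed
values encode.  The typo-policy flags and the config file expose every such
constant, so alternative readings can be scanned without touching code.

## Known limitations

* Deterministic only; no stochastic simulation of the reaction channels.
* Chaos evidence is the return-map dispersion statistic, not a Lyapunov
  exponent.
* No continuation of unstable branches: bifurcation diagrams are
  simulation-based scatters, as in the source analysis.
* The collapse-fit units follow the Δt measurement (hours); the published
  (A, B) pair is not dimensionally consistent with a ~79 h plateau under
  any single unit choice, and the package reports its fit in hours rather
  than resolving that discrepancy.
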