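"""Species, rate constants and right-hand side of the p53 / cell-cycle network.

The model couples a p53--Mdm2--ARF damage-response module to a minimal
cyclin/MPF/protease mitotic oscillator through the Cdk inhibitor p21.
Thirteen species evolve under mass-action and Michaelis--Menten rate laws;
irradiation enters as the initial amount of species ``x10`` (IR), which is
converted into damaged DNA (``x11``) and slowly repaired.  All rates are in
per-second units; concentrations are dimensionless activity levels except the
MPF (``x2``) and cyclin-protease (``x3``) activation fractions, which live in
[0, 1].

The published constant table contains a handful of internal inconsistencies
(a denominator naming a species instead of its Michaelis constant, a garbled
Michaelis quotient, two reaction rows whose rate column disagrees with the
differential equations, a zero MPF-activation turnover and an ambiguous
power-of-ten on the cyclin synthesis rate).  Every resolution applied here is
an explicit, named flag on :class:`TypoPolicy`, so alternative readings can
be selected from a plain config file instead of by editing code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "N_SPECIES",
    "HOURS_TO_SECONDS",
    "TypoPolicy",
    "ParameterSet",
    "default_parameters",
    "goldbeter_profile",
    "composite_rates",
    "rhs",
    "validate_state",
    "StateValidationError",
    "default_config",
    "config_from_parameters",
    "parameters_from_config",
    "load_config",
    "save_config",
]

#: Species names in state-vector order x1..x13.
SPECIES = (
    "cyclin",       # x1  unbound cyclin
    "mpf",          # x2  active MPF fraction M (inactive fraction M* = 1 - x2)
    "protease",     # x3  active cyclin-protease fraction X (X* = 1 - x3)
    "p53",          # x4  unbound p53
    "mdm2",         # x5  unbound Mdm2
    "mdm2_p53",     # x6  Mdm2:p53 complex
    "mdm2_mrna",    # x7  Mdm2 messenger RNA
    "arf",          # x8  active ARF
    "arf_mdm2",     # x9  ARF:Mdm2 complex
    "ir",           # x10 irradiation load (Gy)
    "dam_dna",      # x11 damaged DNA
    "p21",          # x12 p21 protein
    "p21_mpf",      # x13 p21:MPF complex
)
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

#: One named constant for all time-unit conversion (integration is in
#: seconds, reporting in hours).
HOURS_TO_SECONDS = 3600.0

# Fractional species whose activation terms vanish at 1 and decay terms at 0.
_UNIT_INTERVAL_SPECIES = ("mpf", "protease")


@dataclass(frozen=True)
class TypoPolicy:
    """Named resolutions of the printed-table ambiguities.

    Every flag's default is the resolution used throughout the analysis;
    flipping a flag reproduces the alternative (printed) reading.

    mpf_activation_k6_denominator
        The MPF activation denominator is read as ``k6 + (1 - x2)`` (the
        constant k6 = 0.01 appears in the constant table and nowhere else);
        ``False`` uses the literally printed ``x6 + (1 - x2)``.
    mpf_decay_michaelis
        The MPF decay quotient is read in Michaelis form ``k7*x2/(k8 + x2)``;
        ``False`` uses the literal ``k7*x2/(k8*x2) = k7/k8`` constant rate.
    arf_decay_linear
        ARF decay is first order, ``k28*x8``, as in the differential
        equations; ``False`` uses the reaction-table bimolecular ``k28*x8*x9``.
    p21_mpf_rate_from_ode
        The p21+MPF association rate is ``k31*x2*x12`` as in the differential
        equations; ``False`` uses the reaction-table ``k31*x4``.
    k1_times_1e-2  (field name ``k1_scaled_1e2``)
        ``True`` multiplies the cyclin synthesis rate by the printed
        ``x 10^-2`` factor.  The default reading drops it: with the factor
        the cyclin subsystem has no sustained oscillation under normal
        conditions for any plausible MPF turnover, while without it the
        constant equals the source cascade's synthesis rate exactly.
    """

    mpf_activation_k6_denominator: bool = True
    mpf_decay_michaelis: bool = True
    arf_decay_linear: bool = True
    p21_mpf_rate_from_ode: bool = True
    k1_scaled_1e2: bool = False


# Table of rate constants (per-second units).  k5 and k9 are composite,
# state-dependent quantities and therefore not ParameterSet fields; see
# composite_rates().
@dataclass(frozen=True)
class ParameterSet:
    """All rate constants of the network, with documented typo policy.

    Units: k1, k16 are zeroth-order syntheses (conc s^-1); k17, k27, k31 are
    bimolecular (conc^-1 s^-1); k3, k6, k8, k10, k12, k13 are Michaelis-type
    constants (conc); everything else is first order (s^-1).  k14 is the
    maximal MPF-activation turnover whose printed value (0.00 s^-1) would
    freeze the cell cycle; its default is the smallest round value giving a
    sustained cyclin/MPF limit cycle under normal conditions (0.005 s^-1,
    which is also the cited minimal-cascade value scaled consistently with
    k7, k11 and k15).
    """

    k1: float = 0.000416667
    k2: float = 0.004166667
    k3: float = 0.02
    k4: float = 0.0000167
    k6: float = 0.01
    k7: float = 0.0025
    k8: float = 0.01
    k10: float = 0.01
    k11: float = 0.0008333
    k12: float = 0.01
    k13: float = 0.5
    k14: float = 0.005
    k15: float = 0.001667
    k16: float = 0.078
    k17: float = 1.155e-3
    k18: float = 1.155e-5
    k19: float = 8.25e-4
    k20: float = 1.0e-4
    k21: float = 1.0e-4
    k22: float = 4.95e-4
    k23: float = 4.33e-4
    k24: float = 1.0
    k25: float = 2.0e-5
    k26: float = 3.3e-5
    k27: float = 0.01
    k28: float = 0.001
    k29: float = 0.001
    k30: float = 0.001
    k31: float = 0.0001
    k32: float = 0.002
    k33: float = 0.005
    typo_policy: TypoPolicy = field(default_factory=TypoPolicy)

    _K_NAMES = tuple(
        f"k{i}" for i in range(1, 34) if i not in (5, 9)
    )

    def __post_init__(self) -> None:
        for name in self._K_NAMES:
            value = getattr(self, name)
            if not (value > 0.0) or not np.isfinite(value):
                raise ValueError(
                    f"rate constant {name} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    @property
    def k1_effective(self) -> float:
        """Cyclin synthesis rate after applying the power-of-ten flag."""
        return self.k1 * 1e-2 if self.typo_policy.k1_scaled_1e2 else self.k1

    def as_array(self) -> np.ndarray:
        """Constants as a float64 array, ``arr[i-1] == k_i``.

        Slots for the composite quantities k5 and k9 are zero; k1 carries
        the power-of-ten flag already applied.
        """
        arr = np.zeros(33, dtype=np.float64)
        for name in self._K_NAMES:
            arr[int(name[1:]) - 1] = getattr(self, name)
        arr[0] = self.k1_effective
        return arr

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)


def default_parameters() -> ParameterSet:
    """The published constant table with the documented typo resolutions."""
    return ParameterSet()


def goldbeter_profile() -> ParameterSet:
    """Alternative cell-cycle profile transcribing the cited minimal-cascade
    constants (Goldbeter 1991) in per-second units, for cross-checking.

    The damage-response constants are unchanged; only the cyclin/MPF/protease
    constants differ (they are exactly 10x the published table's values for
    k4, k7, k11, k14, k15, and use the cascade's Michaelis constants 0.005).
    """
    return ParameterSet(
        k1=0.000416667,   # vi = 0.025 conc/min
        k2=0.004166667,   # vd = 0.25 conc/min
        k3=0.02,          # Kd
        k4=1.6667e-4,     # kd = 0.01 min^-1
        k6=0.005,         # K1
        k7=0.025,         # V2 = 1.5 min^-1
        k8=0.005,         # K2
        k10=0.005,        # K3
        k11=0.008333,     # V4 = 0.5 min^-1
        k12=0.005,        # K4
        k13=0.5,          # Kc
        k14=0.05,         # VM1 = 3 min^-1
        k15=0.016667,     # VM3 = 1 min^-1
    )


def composite_rates(state: np.ndarray, params: ParameterSet) -> dict:
    """The seven composite (state-dependent) rates of the cell-cycle module.

    Returns a dict with keys ``k_star`` .. ``k_7star`` plus the intermediate
    turnovers ``k5`` and ``k9``.  Each quotient saturates in its substrate,
    is non-negative on the admissible state space, and vanishes when its
    driving species is zero.
    """
    x = np.asarray(state, dtype=float)
    p = params
    tp = p.typo_policy
    x1, x2, x3 = x[0], x[1], x[2]
    k5 = p.k14 * x1 / (p.k13 + x1)
    k9 = p.k15 * x2
    denom_act = (p.k6 if tp.mpf_activation_k6_denominator else x[5]) + (1.0 - x2)
    if tp.mpf_decay_michaelis:
        k_3star = p.k7 * x2 / (p.k8 + x2)
    else:
        k_3star = p.k7 / p.k8 * x2  # literal reading: constant specific rate
    return {
        "k5": k5,
        "k9": k9,
        "k_star": p.k2 * x1 * x3 / (p.k3 + x1),
        "k_2star": k5 * (1.0 - x2) / denom_act,
        "k_3star": k_3star,
        "k_4star": k9 * (1.0 - x3) / (p.k10 + (1.0 - x3)),
        "k_5star": p.k11 * x3 / (p.k12 + x3),
    }


class StateValidationError(ValueError):
    """A state component violates the model's admissible region."""


def validate_state(state: np.ndarray, tol: float = 0.0) -> list[str]:
    """Report invariant violations of a state vector (pure report).

    Returns a list of human-readable diagnostics: one entry per negative
    component and per activation fraction outside [0, 1], naming the species
    and the magnitude of the violation.  ``tol`` widens the admissible region
    by a small slack (useful after numerical integration).
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},), got {x.shape}")
    problems: list[str] = []
    for i, name in enumerate(SPECIES):
        if x[i] < -tol:
            problems.append(f"{name} (x{i + 1}) negative: {x[i]!r}")
    for name in _UNIT_INTERVAL_SPECIES:
        i = SPECIES_INDEX[name]
        if x[i] > 1.0 + tol:
            problems.append(
                f"{name} (x{i + 1}) above 1: {x[i]!r} (activation fraction)"
            )
    return problems


def rhs(state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Time derivative dx/dt of the 13-species network (per second).

    Raises :class:`StateValidationError` naming the offending species if any
    state component is negative.
    """
    x = np.asarray(state, dtype=float)
    neg = [
        f"{SPECIES[i]} (x{i + 1})={x[i]!r}" for i in range(N_SPECIES) if x[i] < 0
    ]
    if neg:
        raise StateValidationError(
            "rhs requires a non-negative state; got " + ", ".join(neg)
        )
    return _rhs_python(x, params.as_array(), params.typo_policy)


def _rhs_python(x: np.ndarray, k: np.ndarray, tp: TypoPolicy) -> np.ndarray:
    """Reference (uncompiled) right-hand side; ``k[i-1] == k_i``."""
    (x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11, x12, x13) = x
    k5 = k[13] * x1 / (k[12] + x1)            # k14 * x1 / (k13 + x1)
    k9 = k[14] * x2                            # k15 * x2
    denom_act = (k[5] if tp.mpf_activation_k6_denominator else x6) + (1.0 - x2)
    if tp.mpf_decay_michaelis:
        mpf_decay = k[6] * x2 / (k[7] + x2)
    else:
        mpf_decay = k[6] / k[7] * x2
    arf_decay = k[27] * x8 if tp.arf_decay_linear else k[27] * x8 * x9
    p21_mpf = k[30] * x2 * x12 if tp.p21_mpf_rate_from_ode else k[30] * x4

    d = np.empty(N_SPECIES, dtype=np.float64)
    d[0] = k[0] - k[1] * x1 * x3 / (k[2] + x1) - k[3] * x1
    d[1] = k5 * (1.0 - x2) / denom_act - mpf_decay - p21_mpf
    d[2] = k9 * (1.0 - x3) / (k[9] + (1.0 - x3)) - k[10] * x3 / (k[11] + x3)
    d[3] = k[15] + k[17] * x6 - k[16] * x4 * x5
    d[4] = (
        k[21] * x7 + k[18] * x6 + k[17] * x6
        - k[22] * x5 - k[16] * x4 * x5 - k[26] * x5 * x8
    )
    d[5] = k[16] * x4 * x5 - k[17] * x6 - k[18] * x6
    d[6] = k[19] * x4 - k[20] * x7
    d[7] = k[25] * x11 + k[28] * x9 - k[26] * x5 * x8 - arf_decay
    d[8] = k[26] * x5 * x8 - k[28] * x9
    d[9] = -k[23] * x10
    d[10] = k[23] * x10 - k[24] * x11
    d[11] = k[29] * x4 - p21_mpf + k[31] * x13 - k[32] * x12
    d[12] = p21_mpf - k[31] * x13
    return d


# ----------------------------------------------------------------------
# Flat JSON config: keys k1..k33 (no k5/k9), x1_0..x13_0, ir_dose and the
# typo-policy flags.  Floats survive a JSON round trip bit-identically.
# ----------------------------------------------------------------------

#: Default initial concentrations (see integrator.make_initial_state).
DEFAULT_INITIAL = {name: 0.0 for name in SPECIES}
DEFAULT_INITIAL.update({"cyclin": 0.01, "mpf": 0.01, "protease": 0.01})


def config_from_parameters(
    params: ParameterSet,
    initial: Mapping[str, float] | None = None,
    ir_dose: float = 0.0,
) -> dict:
    """Serialize parameters (+ optional initial condition) to a flat dict."""
    cfg: dict = {name: getattr(params, name) for name in ParameterSet._K_NAMES}
    cfg.update(dataclasses.asdict(params.typo_policy))
    init = dict(DEFAULT_INITIAL)
    if initial is not None:
        init.update(initial)
    for i, name in enumerate(SPECIES):
        cfg[f"x{i + 1}_0"] = float(init[name])
    cfg["ir_dose"] = float(ir_dose)
    return cfg


def default_config() -> dict:
    return config_from_parameters(default_parameters())


def parameters_from_config(cfg: Mapping) -> ParameterSet:
    """Rebuild a ParameterSet from a flat config mapping."""
    policy_fields = {f.name for f in dataclasses.fields(TypoPolicy)}
    policy = TypoPolicy(
        **{k: bool(cfg[k]) for k in policy_fields if k in cfg}
    )
    kwargs = {
        name: float(cfg[name])
        for name in ParameterSet._K_NAMES
        if name in cfg
    }
    return ParameterSet(typo_policy=policy, **kwargs)


def initial_state_from_config(cfg: Mapping) -> np.ndarray:
    x = np.array([float(cfg.get(f"x{i + 1}_0", DEFAULT_INITIAL[SPECIES[i]]))
                  for i in range(N_SPECIES)])
    if "ir_dose" in cfg:
        x[SPECIES_INDEX["ir"]] = float(cfg["ir_dose"])
    return x


def save_config(cfg: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(cfg), indent=1, sort_keys=True))


def load_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
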