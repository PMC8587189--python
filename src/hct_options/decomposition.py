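"""Proportional analysis: distribute a cohort-level outcome across factor levels.

Aggregate registry tables give one outcome probability per cohort plus hazard
ratios per factor level. To individualize, the cohort-level event probability
is decomposed into per-level probabilities whose fraction-weighted mixture
reproduces the cohort value (the mixture constraint), with between-level
contrasts pinned to the published hazard ratios. Two algebras are offered:

``relative_risk``
    Hazard ratios are read as relative risks held constant over follow-up:
    ``r_j = r_cohort * h_j / sum_k f_k h_k``. Linear, closed form, but can
    exceed 1 at high risks (clamped, flagged).

``proportional_hazards``
    Hazard ratios act as exponents on the reference survival:
    ``S_j = S_ref ** h_j`` with ``S_ref`` the unique root in (0, 1) of
    ``sum_j f_j S_ref**h_j = S_cohort``. Never needs clamping and respects
    the survival-scale semantics of a hazard ratio.

Multi-factor combinations assume independence of factor distributions (joint
fractions are unavailable in aggregate data).

All functions in this module work on EVENT probabilities; survival-scale
outcomes (OS, EFS) are converted at the caller's boundary via
:func:`hct_options.registry_model.to_event_probability`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

from scipy.optimize import brentq

from .registry_model import CohortTable, HazardRatioTable, to_event_probability

logger = logging.getLogger(__name__)

#: Absolute residual tolerance for the mixture root-solve.
ROOT_TOL = 1e-10


class DecompositionMode(str, Enum):
    RELATIVE_RISK = "relative_risk"
    PROPORTIONAL_HAZARDS = "proportional_hazards"


DEFAULT_MODE = DecompositionMode.RELATIVE_RISK


class DecompositionError(ValueError):
    pass


class UnknownLevelError(DecompositionError):
    pass


class RiskValue(float):
    """An event probability that remembers whether it was clamped to [0, 1]."""

    clamped: bool

    def __new__(cls, value: float, clamped: bool = False) -> "RiskValue":
        obj = super().__new__(cls, value)
        obj.clamped = clamped
        return obj


@dataclass(frozen=True)
class LevelRisks:
    """Per-level event probabilities for one factor.

    ``raw_risks`` are the pre-clamp values satisfying the mixture constraint
    exactly; ``risks`` are clamped to [0, 1] with ``clamped`` flagging whether
    any clamping occurred.
    """

    factor: Optional[str]
    risks: dict[str, float]
    raw_risks: dict[str, float]
    mode: DecompositionMode
    clamped: bool


def _validate_inputs(
    fractions: Mapping[str, float], hazard_ratios: Mapping[str, float], r_cohort: float
) -> None:
    s = sum(fractions.values())
    if abs(s - 1.0) > 1e-9:
        raise DecompositionError(f"level fractions sum to {s!r}, not 1")
    for level, h in hazard_ratios.items():
        if not h > 0:
            raise DecompositionError(f"hazard ratio {h} for level {level!r} is not > 0")
    if not 0.0 <= r_cohort <= 1.0:
        raise DecompositionError(f"cohort event probability {r_cohort} outside [0, 1]")


def _hr_for(hazard_ratios: Mapping[str, float], level: str) -> float:
    if level not in hazard_ratios:
        logger.warning("no hazard ratio for level %r; treating as 1", level)
        return 1.0
    return hazard_ratios[level]


def solve_reference_survival(
    fractions: Mapping[str, float],
    exponents: Mapping[str, float],
    s_cohort: float,
) -> float:
    """Root of ``sum_j f_j x**h_j = s_cohort`` on [0, 1].

    The left side is continuous and strictly increasing in x (all h_j > 0),
    so the root is unique; it is found by Brent's method to a residual below
    :data:`ROOT_TOL`. The endpoints s_cohort in {0, 1} are returned exactly.
    """
    if s_cohort <= 0.0:
        return 0.0
    if s_cohort >= 1.0:
        return 1.0
    levels = list(fractions)

    def f(x: float) -> float:
        return sum(fractions[j] * x ** exponents[j] for j in levels) - s_cohort

    root = brentq(f, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(f(root)) > ROOT_TOL:
        raise DecompositionError(f"mixture root residual {f(root):.2e} exceeds {ROOT_TOL}")
    return float(root)


def decompose_single_factor(
    r_cohort: float,
    fractions: Mapping[str, float],
    hazard_ratios: Mapping[str, float],
    mode: DecompositionMode = DEFAULT_MODE,
    factor: Optional[str] = None,
) -> LevelRisks:
    """Split a cohort event probability into per-level event probabilities.

    Parameters
    ----------
    r_cohort:
        Cohort-level event probability at follow-up.
    fractions:
        Fraction of the cohort at each level (must sum to 1).
    hazard_ratios:
        Published hazard ratio per level (reference level = 1). Levels with
        no published ratio are treated as 1 with a logged warning.
    """
    mode = DecompositionMode(mode)
    _validate_inputs(fractions, hazard_ratios, r_cohort)
    hrs = {level: _hr_for(hazard_ratios, level) for level in fractions}

    if mode is DecompositionMode.RELATIVE_RISK:
        denom = sum(fractions[j] * hrs[j] for j in fractions)
        raw = {j: r_cohort * hrs[j] / denom for j in fractions}
        clamped = any(not 0.0 <= r <= 1.0 for r in raw.values())
        risks = {j: min(1.0, max(0.0, r)) for j, r in raw.items()}
    else:
        s_ref = solve_reference_survival(fractions, hrs, 1.0 - r_cohort)
        raw = {j: 1.0 - s_ref ** hrs[j] for j in fractions}
        clamped = False
        risks = dict(raw)
    if clamped:
        logger.warning("relative-risk decomposition clamped to [0, 1] (factor %s)", factor)
    return LevelRisks(factor=factor, risks=risks, raw_risks=raw, mode=mode, clamped=clamped)


def _combo_hrs(
    cohort: CohortTable, hr: HazardRatioTable, combo: Mapping[str, str]
) -> dict[str, float]:
    out = {}
    for factor, level in combo.items():
        if factor not in cohort.level_fractions:
            raise UnknownLevelError(f"factor {factor!r} not present in cohort fractions")
        if level not in cohort.level_fractions[factor]:
            raise UnknownLevelError(f"unknown level {factor}={level!r}")
        out[factor] = hr.hazard_ratio(factor, level)
    return out

def combination_multiplier(
    cohort: CohortTable,
    hr: HazardRatioTable,
    combo: Mapping[str, str],
    mode: DecompositionMode = DEFAULT_MODE,
) -> float:
    """Multiplier for a multi-factor combination, assuming factor independence.

    ``relative_risk``: product over factors of ``h_level / sum_j f_j h_j`` —
    applied to the cohort event probability. ``proportional_hazards``: the
    plain product of hazard ratios — applied as the exponent on the reference
    survival.
    """
    mode = DecompositionMode(mode)
    combo_hrs = _combo_hrs(cohort, hr, combo)
    mult = 1.0
    for factor, h in combo_hrs.items():
        if mode is DecompositionMode.RELATIVE_RISK:
            fracs = cohort.level_fractions[factor]
            denom = sum(fracs[j] * hr.hazard_ratio(factor, j) for j in fracs)
            mult *= h / denom
        else:
            mult *= h
    return mult


def risk_for_combination(
    cohort: CohortTable,
    hr: HazardRatioTable,
    combo: Mapping[str, str],
    outcome: Optional[str] = None,
    mode: DecompositionMode = DEFAULT_MODE,
    baseline_event_probability: Optional[float] = None,
) -> RiskValue:
    """Event probability for one combination of factor levels.

    The baseline event probability defaults to the cohort's value for
    ``outcome`` (converted from the survival scale for OS/EFS); pass
    ``baseline_event_probability`` to decompose an age-subset baseline
    instead. The returned :class:`RiskValue` carries a ``clamped`` flag.
    """
    mode = DecompositionMode(mode)
    if baseline_event_probability is None:
        key = outcome if outcome is not None else hr.outcome
        if key not in cohort.baseline_outcomes:
            raise DecompositionError(f"cohort has no baseline for outcome {key!r}")
        r_base = to_event_probability(key, cohort.baseline_outcomes[key])
    else:
        r_base = baseline_event_probability
    if not 0.0 <= r_base <= 1.0:
        raise DecompositionError(f"baseline event probability {r_base} outside [0, 1]")

    combo_hrs = _combo_hrs(cohort, hr, combo)
    if mode is DecompositionMode.RELATIVE_RISK:
        mult = combination_multiplier(cohort, hr, combo, mode)
        raw = r_base * mult
        clamped = raw > 1.0 or raw < 0.0
        return RiskValue(min(1.0, max(0.0, raw)), clamped)

    # Joint mixture over the product distribution of the combo's factors:
    # sum over all level combinations c of (prod f) * s_ref ** (prod h) = S.
    factors = sorted(combo)
    level_sets = [sorted(cohort.level_fractions[f]) for f in factors]
    joint_fractions: dict[str, float] = {}
    joint_exponents: dict[str, float] = {}
    for cells in itertools.product(*level_sets):
        key = "|".join(cells)
        frac = math.prod(cohort.level_fractions[f][lvl] for f, lvl in zip(factors, cells))
        expo = math.prod(hr.hazard_ratio(f, lvl) for f, lvl in zip(factors, cells))
        joint_fractions[key] = frac
        joint_exponents[key] = expo
    s_cohort = 1.0 - r_base
    s_ref = solve_reference_survival(joint_fractions, joint_exponents, s_cohort)
    expo = math.prod(combo_hrs[f] for f in factors)
    return RiskValue(1.0 - s_ref ** expo, False)
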