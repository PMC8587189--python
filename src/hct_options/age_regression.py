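"""Age-trend regression for decomposed outcome probabilities.

Each combination of transplant characteristics yields two or three
(age, probability) points — one per age subset of the source cohort. A small
family of two-parameter regressions is fitted through those points and the
family with the highest coefficient of determination (computed on the
original probability scale, for cross-family comparability) is kept:

=============  =============================  ==========================
family         curve                          fitted by least squares on
=============  =============================  ==========================
exponential    ``a * exp(b * age)``           ln(value) vs age
linear         ``a + b * age``                value vs age
power          ``a * (age + 1) ** b``         ln(value) vs ln(age + 1)
logarithmic    ``a + b * ln(age + 1)``        value vs ln(age + 1)
=============  =============================  ==========================

The +1 offsets admit age 0. Predictions are clamped to [0, 1] and refused
above the model's valid age domain: extrapolating registry-derived pediatric
curves to older ages produces implausibly poor outcomes, so the domain cap is
a hard guard rather than a soft warning.

:func:`build_model_grid` drives the full pipeline: for every factor
combination and outcome it decomposes each age subset's baseline through
:mod:`hct_options.decomposition`, forms the age points at bin midpoints, and
selects the best-fitting family.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .decomposition import DecompositionMode, DEFAULT_MODE, risk_for_combination
from .registry_model import (
    SCHEMA_VERSION,
    CohortTable,
    HazardRatioTable,
    OUTCOMES,
    from_event_probability,
    representative_age,
    to_event_probability,
)

logger = logging.getLogger(__name__)

FAMILIES = ("exponential", "linear", "power", "logarithmic")

#: Two fits whose r2 differ by less than this are treated as tied.
R2_TIE_TOL = 1e-9


class FitError(ValueError):
    pass


class AgeOutOfDomainError(ValueError):
    def __init__(self, age: float, domain: tuple[float, float]):
        self.age = age
        self.domain = domain
        super().__init__(
            f"age {age:g} outside the model's valid age domain "
            f"[{domain[0]:g}, {domain[1]:g}] years"
        )


@dataclass(frozen=True)
class AgePoint:
    """One (age, outcome probability) observation for a factor combination."""

    age: float
    value: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age {self.age} is negative")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"value {self.value} outside [0, 1]")


@dataclass(frozen=True)
class FittedAgeModel:
    """A fitted two-parameter age curve for one outcome.

    ``r2`` is on the original probability scale. With only two points every
    family interpolates, so ``interpolatory`` marks r2 = 1 as non-informative.
    """

    family: str
    a: float
    b: float
    r2: float
    age_domain: tuple[float, float]
    outcome: Optional[str] = None
    n_points: int = 0

    @property
    def interpolatory(self) -> bool:
        return self.n_points <= 2

    def curve(self, age: float) -> float:
        """Raw (unclamped) curve value at an age; no domain check."""
        if self.family == "exponential":
            return self.a * math.exp(self.b * age)
        if self.family == "linear":
            return self.a + self.b * age
        if self.family == "power":
            return self.a * (age + 1.0) ** self.b
        if self.family == "logarithmic":
            return self.a + self.b * math.log(age + 1.0)
        raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return {
            "family": self.family, "a": self.a, "b": self.b, "r2": self.r2,
            "age_domain": list(self.age_domain), "outcome": self.outcome,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedAgeModel":
        return cls(
            family=d["family"], a=d["a"], b=d["b"], r2=d["r2"],
            age_domain=(d["age_domain"][0], d["age_domain"][1]),
            outcome=d.get("outcome"), n_points=d.get("n_points", 0),
        )


def _check_points(points: Sequence[AgePoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 2:
        raise FitError("at least 2 age points are required")
    ages = np.array([p.age for p in points], dtype=float)
    values = np.array([p.value for p in points], dtype=float)
    if len(set(ages.tolist())) < 2:
        raise FitError("age points must include at least 2 distinct ages")
    return ages, values


def fit_family(
    points: Sequence[AgePoint],
    family: str,
    weights: Optional[Sequence[float]] = None,
) -> FittedAgeModel:
    """Least-squares fit of one family; r2 on the original probability scale.

    ``weights`` (optional, e.g. age-subset patient counts) weight the squared
    residuals in the fitting space.
    """
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}; expected one of {FAMILIES}")
    ages, values = _check_points(points)
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    if family in ("exponential", "power") and np.any(values <= 0):
        raise FitError(f"{family} fit requires strictly positive values")
    if family == "exponential":
        x, y = ages, np.log(values)
    elif family == "linear":
        x, y = ages, values
    elif family == "power":
        x, y = np.log(ages + 1.0), np.log(values)
    else:  # logarithmic
        x, y = np.log(ages + 1.0), values
    slope, intercept = np.polyfit(x, y, 1, w=w)
    if family in ("exponential", "power"):
        a, b = float(np.exp(intercept)), float(slope)
    else:
        a, b = float(intercept), float(slope)
    model = FittedAgeModel(
        family=family, a=a, b=b, r2=math.nan,
        age_domain=(float(ages.min()), float(ages.max())),
        n_points=len(points),
    )
    return replace(model, r2=r_squared(points, model))


def r_squared(points: Sequence[AgePoint], model: FittedAgeModel) -> float:
    """``1 - SS_res / SS_tot`` on the original probability scale.

    Degenerate zero-variance data: a perfect fit scores 1; any residual on
    zero total variance scores -inf (worst possible fit).
    """
    ages, values = _check_points(points)
    predicted = np.array([model.curve(a) for a in ages])
    ss_res = float(np.sum((values - predicted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-20 else -math.inf
    return 1.0 - ss_res / ss_tot


def select_best_model(
    points: Sequence[AgePoint],
    families: Sequence[str] = FAMILIES,
    weights: Optional[Sequence[float]] = None,
) -> FittedAgeModel:
    """Fit every family and keep the one with the highest r2.

    Families that cannot be fitted on these points (e.g. a log-transform
    family on a zero value) are skipped with a logged note. Ties (within
    ``R2_TIE_TOL``) are broken in favor of the exponential family, then by
    position in ``families``.
    """
    fits: list[tuple[int, FittedAgeModel]] = []
    for i, family in enumerate(families):
        try:
            fits.append((i, fit_family(points, family, weights=weights)))
        except FitError as exc:
            logger.info("skipping family %s: %s", family, exc)
    if not fits:
        raise FitError("no regression family could be fitted to these points")
    best_r2 = max(m.r2 for _, m in fits)
    tied = [(i, m) for i, m in fits if m.r2 >= best_r2 - R2_TIE_TOL]
    for _, m in tied:
        if m.family == "exponential":
            return m
    return min(tied, key=lambda im: im[0])[1]


def predict(model: FittedAgeModel, age: float) -> float:
    """Evaluate a fitted model at an age, clamped to [0, 1].

    Ages outside ``model.age_domain`` raise :class:`AgeOutOfDomainError`
    (a distinct refusal naming the cap, not a silent extrapolation).
    """
    lo, hi = model.age_domain
    if not lo <= age <= hi:
        raise AgeOutOfDomainError(age, model.age_domain)
    raw = model.curve(age)
    if raw < 0.0 or raw > 1.0:
        logger.warning("prediction %.4f at age %g clamped to [0, 1]", raw, age)
    return min(1.0, max(0.0, raw))


# ---------------------------------------------------------------------------
# Model grid
# ---------------------------------------------------------------------------

ComboKey = tuple[tuple[str, str], ...]


def _combo_key(combo: Mapping[str, str]) -> ComboKey:
    return tuple(sorted(combo.items()))


@dataclass
class ModelGrid:
    """Fitted age models for every (donor type, factor combination, outcome).

    The grid is the serializable product of the whole analysis pipeline; the
    patient-facing predictor evaluates it without refitting.
    """

    models: dict[tuple[str, ComboKey, str], FittedAgeModel] = field(default_factory=dict)
    horizons: dict[str, float] = field(default_factory=dict)
    factor_levels: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    mode: DecompositionMode = DEFAULT_MODE

    def lookup(self, donor_type: str, combo: Mapping[str, str], outcome: str) -> FittedAgeModel:
        key = (donor_type, _combo_key(combo), outcome)
        if key not in self.models:
            raise KeyError(
                f"no model for donor_type={donor_type!r}, combo={dict(combo)!r}, "
                f"outcome={outcome!r}"
            )
        return self.models[key]

    def outcomes_for(self, donor_type: str) -> list[str]:
        present = {o for (d, _, o) in self.models if d == donor_type}
        return [o for o in OUTCOMES if o in present]

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        entries = [
            {"donor_type": d, "combo": dict(c), "outcome": o, **m.to_dict()}
            for (d, c, o), m in sorted(self.models.items())
        ]
        doc = {
            "schema_version": SCHEMA_VERSION,
            "mode": self.mode.value,
            "horizons": self.horizons,
            "factor_levels": self.factor_levels,
            "entries": entries,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ModelGrid":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = source
        doc = json.loads(text)
        grid = cls(
            horizons={k: float(v) for k, v in doc.get("horizons", {}).items()},
            factor_levels=doc.get("factor_levels", {}),
            mode=DecompositionMode(doc.get("mode", DEFAULT_MODE.value)),
        )
        for e in doc["entries"]:
            key = (e["donor_type"], _combo_key(e["combo"]), e["outcome"])
            grid.models[key] = FittedAgeModel.from_dict(e)
        return grid


def build_model_grid(
    cohorts: Iterable[CohortTable],
    hrs: Iterable[HazardRatioTable],
    mode: DecompositionMode = DEFAULT_MODE,
    families: Sequence[str] = FAMILIES,
    age_cap: Optional[float] = None,
    weighted: bool = False,
) -> ModelGrid:
    """Decompose, form age points, and fit a model per (combo, outcome).

    For each donor-type cohort: every combination of levels of the factors in
    ``cohort.level_fractions`` is paired with every outcome that has a
    cohort baseline. Each age bin contributes one point at its midpoint age;
    the bin's own outcome probability is used when present, otherwise the
    cohort-level baseline (flat age profile). ``age_cap`` overrides the upper
    end of every model's valid age domain. ``weighted=True`` weights fits by
    age-bin patient counts (off by default).
    """
    mode = DecompositionMode(mode)
    hr_list = list(hrs)
    grid = ModelGrid(mode=mode)
    for cohort in cohorts:
        donor = cohort.donor_type
        lo, hi = cohort.age_domain
        domain = (lo, hi if age_cap is None else age_cap)
        grid.horizons[donor] = cohort.follow_up_months
        grid.factor_levels[donor] = {
            f: sorted(levels) for f, levels in cohort.level_fractions.items()
        }
        factors = sorted(cohort.level_fractions)
        level_sets = [grid.factor_levels[donor][f] for f in factors]
        combos = [dict(zip(factors, cells)) for cells in itertools.product(*level_sets)] or [{}]
        for outcome in OUTCOMES:
            if outcome not in cohort.baseline_outcomes:
                continue
            hr_table = _hr_table_for(hr_list, donor, outcome)
            for combo in combos:
                try:
                    model = _fit_combo(
                        cohort, hr_table, combo, outcome, mode, families, weighted
                    )
                except (ValueError, FitError) as exc:
                    raise FitError(
                        f"failed for donor_type={donor!r}, combo={combo!r}, "
                        f"outcome={outcome!r}: {exc}"
                    ) from exc
                model = replace(model, age_domain=domain, outcome=outcome)
                grid.models[(donor, _combo_key(combo), outcome)] = model
    return grid


def _hr_table_for(
    hr_list: Sequence[HazardRatioTable], donor: str, outcome: str
) -> HazardRatioTable:
    for t in hr_list:
        if t.outcome == outcome and t.donor_type == donor:
            return t
    for t in hr_list:
        if t.outcome == outcome and t.donor_type is None:
            return t
    logger.warning(
        "no hazard-ratio table for donor_type=%s outcome=%s; all ratios taken as 1",
        donor, outcome,
    )
    return HazardRatioTable(outcome=outcome, entries={}, donor_type=donor)


def _fit_combo(
    cohort: CohortTable,
    hr_table: HazardRatioTable,
    combo: Mapping[str, str],
    outcome: str,
    mode: DecompositionMode,
    families: Sequence[str],
    weighted: bool,
) -> FittedAgeModel:
    points: list[AgePoint] = []
    weights: list[float] = []
    for b in cohort.age_bins:
        base_value = b.outcome_probabilities.get(outcome, cohort.baseline_outcomes[outcome])
        base_event = to_event_probability(outcome, base_value)
        if combo:
            risk = risk_for_combination(
                cohort, hr_table, combo, outcome=outcome, mode=mode,
                baseline_event_probability=base_event,
            )
        else:
            risk = base_event
        points.append(AgePoint(age=representative_age(b),
                               value=from_event_probability(outcome, float(risk))))
        weights.append(float(b.count))
    return select_best_model(points, families, weights=weights if weighted else None)
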