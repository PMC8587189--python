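"""Patient-facing prediction API: a 5-item profile in, a transplant summary out.

The profile mirrors the five questions a clinician answers about a pediatric
sickle cell patient considering allogeneic transplant: sex, age at transplant,
donor type, stem-cell source and conditioning regimen. The summary reports
the five modeled outcomes (overall survival, event-free survival, graft
failure, acute and chronic GVHD) at the source cohort's follow-up horizon,
plus an optional delayed-transplant comparison showing how each estimate
shifts if the transplant is postponed by a number of years.

Consistency is enforced on output: event-free survival can never exceed
overall survival (EFS counts the survivors who also avoided graft failure);
when the independently decomposed curves disagree, EFS is lowered to OS and
the adjustment is flagged rather than hidden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from pydantic import BaseModel, Field

from .age_regression import AgeOutOfDomainError, ModelGrid, predict
from .registry_model import OUTCOMES

logger = logging.getLogger(__name__)

#: Default maximum transplant delay offered, in years.
DEFAULT_MAX_DELAY_YEARS = 10.0


class UnknownProfileLevelError(ValueError):
    pass


class PatientProfile(BaseModel):
    """Answers to the five patient-characteristic questions."""

    sex: str
    age: float = Field(ge=0)
    donor_type: str
    stem_cell_source: str
    conditioning: str

    def combo(self) -> dict[str, str]:
        return {
            "sex": self.sex,
            "stem_cell_source": self.stem_cell_source,
            "conditioning": self.conditioning,
        }


@dataclass
class TransplantSummary:
    """Per-outcome probability estimates at the cohort follow-up horizon."""

    estimates: dict[str, float]
    horizon_months: float
    flags: list[str] = field(default_factory=list)


@dataclass
class DelayedComparison:
    """Side-by-side summaries for transplanting now versus after a delay."""

    now: TransplantSummary
    delayed: TransplantSummary
    delay_years: float
    deltas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.deltas:
            self.deltas = {
                o: self.delayed.estimates[o] - self.now.estimates[o]
                for o in self.now.estimates
                if o in self.delayed.estimates
            }


def summarize_combination(
    grid: ModelGrid,
    donor_type: str,
    combo: Mapping[str, str],
    age: float,
) -> TransplantSummary:
    """Evaluate every available outcome model for one factor combination.

    This is the engine behind :func:`summarize_transplant`; it accepts
    arbitrary factor combinations (e.g. from simulated registries whose
    factors are not the clinical five).
    """
    if donor_type not in grid.factor_levels:
        raise UnknownProfileLevelError(
            f"unknown donor type {donor_type!r}; grid covers "
            f"{sorted(grid.factor_levels)}"
        )
    known = grid.factor_levels[donor_type]
    for factor, level in combo.items():
        if factor not in known or level not in known[factor]:
            raise UnknownProfileLevelError(
                f"unknown level {factor}={level!r} for donor type {donor_type!r}; "
                f"known: {known.get(factor)}"
            )
    estimates: dict[str, float] = {}
    flags: list[str] = []
    for outcome in grid.outcomes_for(donor_type):
        model = grid.lookup(donor_type, combo, outcome)
        value = predict(model, age)  # raises AgeOutOfDomainError naming the cap
        if model.curve(age) != value:
            flags.append(f"clamped:{outcome}")
        estimates[outcome] = value
    summary = TransplantSummary(
        estimates=estimates,
        horizon_months=grid.horizons.get(donor_type, float("nan")),
        flags=flags,
    )
    return enforce_consistency(summary)


def summarize_transplant(grid: ModelGrid, p: PatientProfile) -> TransplantSummary:
    """Transplant summary for a patient profile (the 5-question path)."""
    return summarize_combination(grid, p.donor_type, p.combo(), p.age)


def enforce_consistency(s: TransplantSummary) -> TransplantSummary:
    """Lower EFS to OS when the decomposed curves cross, flagging the change."""
    os_, efs = s.estimates.get("OS"), s.estimates.get("EFS")
    if os_ is not None and efs is not None and efs > os_:
        logger.warning("EFS %.4f exceeded OS %.4f; adjusted down", efs, os_)
        s.estimates["EFS"] = os_
        s.flags.append("consistency_adjusted")
    return s


def delayed_comparison(
    grid: ModelGrid,
    p: PatientProfile,
    delay_years: float,
    max_delay_years: float = DEFAULT_MAX_DELAY_YEARS,
) -> DelayedComparison:
    """Summaries at the current age and at age + delay, with per-outcome deltas.

    The delayed age must still lie within the model's valid age domain;
    otherwise the same out-of-domain refusal as for a direct prediction is
    raised, naming the cap.
    """
    if delay_years < 0:
        raise ValueError(f"delay_years must be >= 0, got {delay_years}")
    if delay_years > max_delay_years:
        raise ValueError(
            f"delay_years {delay_years:g} exceeds the configured maximum "
            f"{max_delay_years:g}"
        )
    now = summarize_transplant(grid, p)
    delayed_profile = p.model_copy(update={"age": p.age + delay_years})
    delayed = summarize_transplant(grid, delayed_profile)
    return DelayedComparison(now=now, delayed=delayed, delay_years=delay_years)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _summary_payload(s: TransplantSummary) -> dict:
    ordered = [o for o in OUTCOMES if o in s.estimates]
    return {
        "horizon_months": s.horizon_months,
        "estimates": {o: s.estimates[o] for o in ordered},
        "percent": {o: round(100.0 * s.estimates[o], 1) for o in ordered},
        "flags": sorted(s.flags),
    }


def _summary_text(s: TransplantSummary, indent: str = "") -> list[str]:
    lines = [f"{indent}horizon: {s.horizon_months:g} months"]
    for o in OUTCOMES:
        if o in s.estimates:
            lines.append(f"{indent}{o}: {100.0 * s.estimates[o]:.1f}%")
    if s.flags:
        lines.append(f"{indent}flags: {', '.join(sorted(s.flags))}")
    return lines


def render_summary(
    s: Union[TransplantSummary, DelayedComparison], format: str = "json"
) -> str:
    """Deterministic serialization of a summary or delayed comparison.

    JSON carries both the raw probabilities (exact round-trip) and
    percentages rounded to one decimal; text lists the five outcomes in a
    fixed order. Flags are always included.
    """
    if format == "json":
        if isinstance(s, DelayedComparison):
            ordered = [o for o in OUTCOMES if o in s.deltas]
            payload = {
                "type": "delayed_comparison",
                "delay_years": s.delay_years,
                "now": _summary_payload(s.now),
                "delayed": _summary_payload(s.delayed),
                "deltas": {o: s.deltas[o] for o in ordered},
            }
        else:
            payload = {"type": "transplant_summary", **_summary_payload(s)}
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "text":
        if isinstance(s, DelayedComparison):
            lines = [f"transplant now vs delayed by {s.delay_years:g} years", "now:"]
            lines += _summary_text(s.now, "  ")
            lines.append("delayed:")
            lines += _summary_text(s.delayed, "  ")
            lines.append("change (delayed - now):")
            for o in OUTCOMES:
                if o in s.deltas:
                    lines.append(f"  {o}: {100.0 * s.deltas[o]:+.1f} points")
            return "\n".join(lines)
        return "\n".join(["transplant summary"] + _summary_text(s, "  "))
    raise ValueError(f"unknown format {format!r}; expected 'json' or 'text'")
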