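"""Aggregate transplant-registry summaries: schema, I/O, validation, age splitting.

Registry studies of allogeneic hematopoietic stem cell transplantation (HCT)
for sickle cell disease publish cohort-level summaries only: patient counts by
donor type, stem-cell source, conditioning regimen, sex and age bin; outcome
probabilities (overall survival, event-free survival, graft failure, acute and
chronic GVHD) at a stated follow-up horizon; and per-factor hazard ratios from
multivariable survival models. This module holds those summaries in validated
containers, reads and writes them as CSV (one row per factor/level) or as a
single versioned JSON document, checks printed percentages against counts, and
splits coarse age bins into equal-width subsets under a uniform-age assumption.

Outcome orientation convention: overall survival (``OS``) and event-free
survival (``EFS``) are stored on the survival scale (probability of being
alive, resp. alive without graft failure, at follow-up); graft failure and
GVHD are stored as event probabilities. Hazard ratios always act on the event
hazard, so :func:`to_event_probability` / :func:`from_event_probability`
convert at the decomposition boundary.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Patient/transplant factors an aggregate table may stratify on.
FACTORS = ("sex", "donor_type", "stem_cell_source", "conditioning")

#: The five outcomes reported by the registry cohorts, in canonical order.
OUTCOMES = ("OS", "EFS", "graft_failure", "acute_GVHD", "chronic_GVHD")

#: Outcomes stored on the survival (event-free) scale rather than event scale.
SURVIVAL_OUTCOMES = frozenset({"OS", "EFS"})

#: Default resolution for open-ended pediatric age bins such as ">15" years.
DEFAULT_AGE_CAP = 25.0

FRACTION_TOL = 1e-9


class SchemaError(ValueError):
    """A registry table violates the documented schema; message names the
    first violated constraint."""


class UnresolvedAgeBinError(ValueError):
    """An open-ended age bin has no explicit upper bound and no resolved cap."""


def to_event_probability(outcome: str, value: float) -> float:
    """Convert an outcome probability from its reported scale to event scale."""
    return 1.0 - value if outcome in SURVIVAL_OUTCOMES else value


def from_event_probability(outcome: str, event_probability: float) -> float:
    """Convert an event probability back to the outcome's reported scale."""
    return 1.0 - event_probability if outcome in SURVIVAL_OUTCOMES else event_probability


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class FactorLevel(BaseModel):
    """One level of a transplant factor, e.g. (conditioning, myeloablative)."""

    model_config = ConfigDict(frozen=True)

    factor: str
    level: str
    is_reference: bool = False

    @model_validator(mode="after")
    def _known_factor(self) -> "FactorLevel":
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}; expected one of {FACTORS}")
        return self


class AgeBin(BaseModel):
    """A published age row such as ``0-5  175 (23.8)``.

    Open-ended bins (``>15``) carry ``upper=None`` plus an explicit ``cap``
    giving the resolved upper bound in years. ``outcome_probabilities`` may
    hold per-bin outcome values (on each outcome's reported scale) when the
    source table, a user config, or the simulator's aggregation provides them.
    """

    lower: float = Field(ge=0)
    upper: Optional[float] = None
    cap: Optional[float] = None
    count: int = Field(ge=0)
    printed_percent: Optional[float] = None
    outcome_probabilities: dict[str, float] = Field(default_factory=dict)

    @property
    def resolved_upper(self) -> float:
        if self.upper is not None:
            return self.upper
        if self.cap is not None:
            return self.cap
        raise UnresolvedAgeBinError(
            f"age bin >{self.lower:g} is open-ended and has no configured cap"
        )

    @property
    def is_resolved(self) -> bool:
        return self.upper is not None or self.cap is not None

    def label(self) -> str:
        if self.upper is None:
            return f">{self.lower:g}"
        return f"{self.lower:g}-{self.upper:g}"

    @model_validator(mode="after")
    def _check(self) -> "AgeBin":
        if self.is_resolved and self.lower > self.resolved_upper:
            raise ValueError(f"age bin lower {self.lower} exceeds upper {self.resolved_upper}")
        for outcome, value in self.outcome_probabilities.items():
            if outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r} in age bin")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"age-bin {outcome} probability {value} outside [0, 1]")
        return self


class CohortTable(BaseModel):
    """Aggregate summary of one donor-type registry cohort.

    ``level_fractions`` maps factor -> level -> fraction of the cohort;
    fractions per factor must sum to 1. ``baseline_outcomes`` maps outcome ->
    probability at ``follow_up_months`` on the outcome's reported scale.
    """

    donor_type: str
    source_label: str = ""
    follow_up_months: float = Field(gt=0)
    n_total: int = Field(ge=1)
    age_bins: list[AgeBin] = Field(min_length=1)
    level_fractions: dict[str, dict[str, float]] = Field(default_factory=dict)
    baseline_outcomes: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "CohortTable":
        total = sum(b.count for b in self.age_bins)
        if total != self.n_total:
            raise ValueError(
                f"age-bin counts sum to {total}, not n_total={self.n_total}"
            )
        for factor, levels in self.level_fractions.items():
            if factor not in FACTORS:
                raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
            if not levels:
                raise ValueError(f"factor {factor!r} has no levels")
            s = sum(levels.values())
            if abs(s - 1.0) > FRACTION_TOL:
                raise ValueError(f"fractions for factor {factor!r} sum to {s!r}, not 1")
            for level, f in levels.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction {f} for {factor}={level} outside [0, 1]")
        for outcome, value in self.baseline_outcomes.items():
            if outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r}")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"baseline {outcome} probability {value} outside [0, 1]")
        os_, efs = self.baseline_outcomes.get("OS"), self.baseline_outcomes.get("EFS")
        if os_ is not None and efs is not None and efs > os_ + 1e-12:
            raise ValueError(f"EFS {efs} exceeds OS {os_}")
        return self

    @property
    def age_domain(self) -> tuple[float, float]:
        """[min, max] ages covered by the (resolved) bins, in years."""
        lo = min(b.lower for b in self.age_bins)
        hi = max(b.resolved_upper for b in self.age_bins)
        return lo, hi


class HazardRatioTable(BaseModel):
    """Per-outcome hazard ratios by factor level, reference level fixed at 1."""

    outcome: str
    entries: dict[str, dict[str, float]]
    donor_type: Optional[str] = None
    reference_levels: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "HazardRatioTable":
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        for factor, levels in self.entries.items():
            if factor not in FACTORS:
                raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
            for level, hr in levels.items():
                if not hr > 0:
                    raise ValueError(f"hazard ratio {hr} for {factor}={level} is not > 0")
            ref = self.reference_levels.get(factor)
            if ref is None:
                ones = [lvl for lvl, hr in levels.items() if hr == 1.0]
                if len(ones) != 1:
                    raise ValueError(
                        f"factor {factor!r}: cannot infer reference level "
                        f"({len(ones)} levels with HR exactly 1); set reference_levels"
                    )
                self.reference_levels[factor] = ones[0]
            else:
                if ref not in levels:
                    raise ValueError(f"reference level {ref!r} missing from factor {factor!r}")
                if levels[ref] != 1.0:
                    raise ValueError(
                        f"reference level {factor}={ref} has HR {levels[ref]}, expected 1"
                    )
        return self

    def hazard_ratio(self, factor: str, level: str) -> float:
        """HR for a level; absent levels count as 1 with a logged warning."""
        levels = self.entries.get(factor)
        if levels is None or level not in levels:
            logger.warning(
                "no hazard ratio for %s=%s (outcome %s); treating as 1",
                factor, level, self.outcome,
            )
            return 1.0
        return levels[level]


class Check(BaseModel):
    name: str
    passed: bool
    detail: str = ""


class ValidationReport(BaseModel):
    """Outcome of consistency checks on a cohort table."""

    checks: list[Check] = Field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append(Check(name=name, passed=passed, detail=detail))

    def __str__(self) -> str:
        lines = [
            f"[{'PASS' if c.passed else 'FAIL'}] {c.name}" + (f": {c.detail}" if c.detail else "")
            for c in self.checks
        ]
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'} ({len(self.checks)} checks)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Loading and saving
# ---------------------------------------------------------------------------

_COHORT_CSV_COLUMNS = (
    "section", "factor", "level", "lower", "upper", "cap",
    "count", "printed_percent", "value",
)
_HR_CSV_COLUMNS = ("outcome", "donor_type", "factor", "level", "hazard_ratio", "is_reference")


def _check_schema_version(doc: dict, where: str) -> None:
    version = doc.get("schema_version")
    if version is not None and str(version) != SCHEMA_VERSION:
        raise SchemaError(f"{where}: unsupported schema_version {version!r}")


def load_registry(path: Union[str, Path]) -> tuple[CohortTable, list[HazardRatioTable]]:
    """Load a combined JSON registry document: one cohort plus its HR tables."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "cohort" not in doc:
        raise SchemaError(f"{path}: expected a JSON object with a 'cohort' field")
    _check_schema_version(doc, str(path))
    try:
        cohort = CohortTable.model_validate(doc["cohort"])
        hr_tables = [HazardRatioTable.model_validate(h) for h in doc.get("hazard_ratios", [])]
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: {loc}: {first['msg']}") from exc
    return cohort, hr_tables


def save_registry(
    cohort: CohortTable,
    hr_tables: Sequence[HazardRatioTable],
    path: Union[str, Path],
) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "cohort": cohort.model_dump(),
        "hazard_ratios": [h.model_dump() for h in hr_tables],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_cohort_table(path: Union[str, Path], schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Load a cohort table from JSON (bare or combined document) or CSV.

    Raises :class:`SchemaError` naming the first violated constraint.
    """
    path = Path(path)
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {schema_version!r}")
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    if path.suffix.lower() == ".csv":
        return _read_cohort_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    _check_schema_version(doc, str(path))
    payload = doc.get("cohort", doc)
    payload = {k: v for k, v in payload.items() if k != "schema_version"}
    try:
        return CohortTable.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: {loc}: {first['msg']}") from exc


def save_cohort_table(t: CohortTable, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_cohort_csv(t, path)
        return
    doc = {"schema_version": SCHEMA_VERSION, "cohort": t.model_dump()}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _read_cohort_csv(path: Path) -> CohortTable:
    meta: dict[str, object] = {}
    fractions: dict[str, dict[str, float]] = {}
    baselines: dict[str, float] = {}
    bins: list[AgeBin] = []
    bin_outcomes: list[tuple[float, Optional[float], str, float]] = []

    def _opt_float(cell: str) -> Optional[float]:
        return float(cell) if cell not in ("", None) else None

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COHORT_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"{path}: missing CSV columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            section = row["section"]
            try:
                if section == "meta":
                    meta[row["factor"]] = row["value"]
                elif section == "fraction":
                    fractions.setdefault(row["factor"], {})[row["level"]] = float(row["value"])
                elif section == "baseline":
                    baselines[row["factor"]] = float(row["value"])
                elif section == "age_bin":
                    bins.append(AgeBin(
                        lower=float(row["lower"]),
                        upper=_opt_float(row["upper"]),
                        cap=_opt_float(row["cap"]),
                        count=int(row["count"]),
                        printed_percent=_opt_float(row["printed_percent"]),
                    ))
                elif section == "age_outcome":
                    bin_outcomes.append(
                        (float(row["lower"]), _opt_float(row["upper"]),
                         row["factor"], float(row["value"]))
                    )
                else:
                    raise SchemaError(f"{path}:{i}: unknown section {section!r}")
            except (TypeError, ValueError) as exc:
                if isinstance(exc, SchemaError):
                    raise
                raise SchemaError(f"{path}:{i}: malformed row ({exc})") from exc
    for lower, upper, outcome, value in bin_outcomes:
        matches = [b for b in bins if b.lower == lower and b.upper == upper]
        if not matches:
            raise SchemaError(f"{path}: age_outcome row refers to unknown bin [{lower}, {upper}]")
        matches[0].outcome_probabilities[outcome] = value
    required = ("donor_type", "follow_up_months", "n_total")
    for key in required:
        if key not in meta:
            raise SchemaError(f"{path}: missing meta row {key!r}")
    try:
        return CohortTable(
            donor_type=str(meta["donor_type"]),
            source_label=str(meta.get("source_label", "")),
            follow_up_months=float(meta["follow_up_months"]),  # type: ignore[arg-type]
            n_total=int(meta["n_total"]),  # type: ignore[arg-type]
            age_bins=bins,
            level_fractions=fractions,
            baseline_outcomes=baselines,
        )
    except (ValidationError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            first = exc.errors()[0]
            raise SchemaError(f"{path}: {first['msg']}") from exc
        raise SchemaError(f"{path}: {exc}") from exc


def _write_cohort_csv(t: CohortTable, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COHORT_CSV_COLUMNS)
        writer.writeheader()

        def row(**kwargs: object) -> None:
            writer.writerow({c: kwargs.get(c, "") for c in _COHORT_CSV_COLUMNS})

        row(section="meta", factor="donor_type", value=t.donor_type)
        row(section="meta", factor="source_label", value=t.source_label)
        row(section="meta", factor="follow_up_months", value=repr(t.follow_up_months))
        row(section="meta", factor="n_total", value=t.n_total)
        for b in t.age_bins:
            row(section="age_bin", lower=repr(b.lower),
                upper="" if b.upper is None else repr(b.upper),
                cap="" if b.cap is None else repr(b.cap),
                count=b.count,
                printed_percent="" if b.printed_percent is None else repr(b.printed_percent))
            for outcome, value in sorted(b.outcome_probabilities.items()):
                row(section="age_outcome", factor=outcome, lower=repr(b.lower),
                    upper="" if b.upper is None else repr(b.upper), value=repr(value))
        for factor in sorted(t.level_fractions):
            for level, f in sorted(t.level_fractions[factor].items()):
                row(section="fraction", factor=factor, level=level, value=repr(f))
        for outcome in OUTCOMES:
            if outcome in t.baseline_outcomes:
                row(section="baseline", factor=outcome,
                    value=repr(t.baseline_outcomes[outcome]))


def load_hazard_ratio_csv(path: Union[str, Path]) -> list[HazardRatioTable]:
    """Read hazard-ratio tables from CSV, one row per (outcome, factor, level)."""
    path = Path(path)
    grouped: dict[tuple[str, Optional[str]], dict[str, dict[str, float]]] = {}
    refs: dict[tuple[str, Optional[str]], dict[str, str]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_HR_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"{path}: missing CSV columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            key = (row["outcome"], row["donor_type"] or None)
            try:
                hr = float(row["hazard_ratio"])
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{i}: malformed hazard ratio ({exc})") from exc
            grouped.setdefault(key, {}).setdefault(row["factor"], {})[row["level"]] = hr
            if row["is_reference"].strip().lower() in ("1", "true", "yes"):
                refs.setdefault(key, {})[row["factor"]] = row["level"]
    tables = []
    for (outcome, donor_type), entries in grouped.items():
        try:
            tables.append(HazardRatioTable(
                outcome=outcome, donor_type=donor_type, entries=entries,
                reference_levels=refs.get((outcome, donor_type), {}),
            ))
        except ValidationError as exc:
            raise SchemaError(f"{path}: {exc.errors()[0]['msg']}") from exc
    return tables


def save_hazard_ratio_csv(tables: Iterable[HazardRatioTable], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_HR_CSV_COLUMNS)
        writer.writeheader()
        for t in tables:
            for factor in sorted(t.entries):
                for level, hr in sorted(t.entries[factor].items()):
                    writer.writerow({
                        "outcome": t.outcome,
                        "donor_type": t.donor_type or "",
                        "factor": factor,
                        "level": level,
                        "hazard_ratio": repr(hr),
                        "is_reference": "true" if t.reference_levels.get(factor) == level else "",
                    })


# ---------------------------------------------------------------------------
# Validation and age splitting
# ---------------------------------------------------------------------------


def validate_cohort_table(t: CohortTable, tol_percent: float = 0.05) -> ValidationReport:
    """Check internal consistency of a cohort table.

    The substantive check compares each age bin's printed percentage against
    the percentage recomputed from counts, at an absolute tolerance of
    ``tol_percent`` percentage points (default 0.05, half the last printed
    digit). Structural checks (count sums, fraction sums, EFS <= OS) are
    re-verified and included in the report.
    """
    report = ValidationReport()
    total = sum(b.count for b in t.age_bins)
    report.add("age-bin counts sum to n_total", total == t.n_total,
               f"{total} vs {t.n_total}")
    for b in t.age_bins:
        if b.printed_percent is None:
            continue
        computed = 100.0 * b.count / total if total else math.nan
        ok = abs(computed - b.printed_percent) <= tol_percent
        report.add(
            f"age bin {b.label()} printed percent", ok,
            f"computed {computed:.4f} vs printed {b.printed_percent:g} "
            f"(tol {tol_percent:g})",
        )
    for factor, levels in sorted(t.level_fractions.items()):
        s = sum(levels.values())
        report.add(f"fractions[{factor}] sum to 1", abs(s - 1.0) <= FRACTION_TOL, f"sum {s!r}")
    os_, efs = t.baseline_outcomes.get("OS"), t.baseline_outcomes.get("EFS")
    if os_ is not None and efs is not None:
        report.add("EFS <= OS", efs <= os_ + 1e-12, f"EFS {efs} vs OS {os_}")
    return report


def split_by_age_uniform(
    bin_range: tuple[float, float], n_subsets: int, count: int
) -> list[AgeBin]:
    """Split an age range into equal-width contiguous bins, apportioning counts.

    Under the uniform-age assumption each subset's expected share is
    proportional to its width; counts are integerized by largest-remainder
    rounding, ties broken toward the younger bin, so they always sum exactly
    to ``count``.
    """
    lower, upper = bin_range
    if not lower < upper:
        raise ValueError(f"invalid age range [{lower}, {upper}]")
    if n_subsets not in (2, 3):
        raise ValueError(f"n_subsets must be 2 or 3, got {n_subsets}")
    if count < n_subsets:
        raise ValueError(f"count {count} smaller than n_subsets {n_subsets}")
    width = (upper - lower) / n_subsets
    edges = [lower + i * width for i in range(n_subsets)] + [upper]
    quotas = [count * (edges[i + 1] - edges[i]) / (upper - lower) for i in range(n_subsets)]
    counts = [math.floor(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    leftover = count - sum(counts)
    # Largest remainder first; ties go to the younger (lower-index) bin.
    order = sorted(range(n_subsets), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        counts[i] += 1
    return [
        AgeBin(lower=edges[i], upper=edges[i + 1], count=counts[i])
        for i in range(n_subsets)
    ]


def representative_age(b: AgeBin) -> float:
    """Representative age of a bin: the midpoint of its resolved bounds.

    Under the uniform-age assumption the midpoint is the mean age of the bin.
    Raises :class:`UnresolvedAgeBinError` for open-ended bins without a cap.
    """
    return (b.lower + b.resolved_upper) / 2.0
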