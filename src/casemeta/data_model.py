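"""Domain types and tabular I/O for case-report meta-analysis.

The unit of analysis is a published narrative case report: a single
patient whose response to therapy is described in free text.  For each
analyzed outcome a curator records whether the outcome was reported at
all and, if so, at what documentation level (improvement mentioned,
evaluation method described, quantitative measure given, or -- for
infusion-related reactions -- whether the reaction forced a dose
change).  Everything downstream (scoring, futility testing, concordance)
consumes these curated flags; no free-text parsing happens here.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = [
    "Direction",
    "SoeGrade",
    "HarmCriterion",
    "PublicationType",
    "OutcomeSpec",
    "OutcomeObservation",
    "CaseReport",
    "AnalysisSetSpec",
    "CaseDataset",
    "SchemaError",
    "IntegrityError",
    "read_outcomes",
    "read_case_dataset",
    "write_case_dataset",
    "apply_analysis_set",
]

CASE_COLUMNS = [
    "case_id",
    "publication_id",
    "publication_date",
    "publication_type",
    "in_clinical_meta_analysis",
    "aggregated_form",
    "outcome_id",
    "reported",
    "improvement_mentioned",
    "method_described",
    "quantitative_measure",
    "irr_dose_change",
]

_CASE_META_COLUMNS = CASE_COLUMNS[:6]
_FLAG_COLUMNS = CASE_COLUMNS[7:]


class SchemaError(ValueError):
    """A tabular input is structurally invalid (e.g. missing column)."""


class IntegrityError(ValueError):
    """A tabular input violates a domain invariant (e.g. duplicate rows)."""


class Direction(str, Enum):
    BENEFIT = "benefit"
    HARM = "harm"


class SoeGrade(str, Enum):
    """GRADE-style strength-of-evidence grade assigned per outcome."""

    INSUFFICIENT = "insufficient"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def score(self) -> int:
        """Ordinal score: insufficient=1, low=2, moderate=3, high=4."""
        return _SOE_SCORE[self]

    @classmethod
    def from_score(cls, score: int) -> "SoeGrade":
        try:
            return _SOE_FROM_SCORE[score]
        except KeyError:
            raise ValueError(f"no SOE grade with ordinal score {score!r}")

    @property
    def is_acceptable(self) -> bool:
        """Moderate-to-high grades form the gold-standard positive class."""
        return self in (SoeGrade.MODERATE, SoeGrade.HIGH)


_SOE_SCORE = {
    SoeGrade.INSUFFICIENT: 1,
    SoeGrade.LOW: 2,
    SoeGrade.MODERATE: 3,
    SoeGrade.HIGH: 4,
}
_SOE_FROM_SCORE = {v: k for k, v in _SOE_SCORE.items()}


class HarmCriterion(str, Enum):
    """How positivity is established for a harm outcome.

    ``DOCUMENTED`` follows the benefit-shaped rule (documented event under
    the strong method, mere mention under the weak one); ``DOSE_CHANGE``
    counts only events that forced a change of therapy dose and is by
    construction identical under both scoring methods.
    """

    DOCUMENTED = "documented"
    DOSE_CHANGE = "dose_change"


class PublicationType(str, Enum):
    ARTICLE = "article"
    CONGRESS_COMMUNICATION = "congress_communication"


@dataclass(frozen=True)
class OutcomeSpec:
    """One analyzed outcome with its direction and gold-standard grade."""

    outcome_id: str
    label: str
    direction: Direction
    soe_grade: SoeGrade
    harm_criterion: HarmCriterion = HarmCriterion.DOCUMENTED

    def __post_init__(self) -> None:
        if not self.outcome_id:
            raise ValueError("outcome_id must be non-empty")
        if self.direction is Direction.BENEFIT and self.harm_criterion is not HarmCriterion.DOCUMENTED:
            raise ValueError("harm_criterion only applies to harm outcomes")

    @property
    def soe_score(self) -> int:
        return self.soe_grade.score


@dataclass(frozen=True)
class OutcomeObservation:
    """Curated reporting-quality flags for one case x outcome.

    Invariants: an unreported outcome carries no other flags (unreported
    observations are conservatively negative under every scoring method),
    and documentation flags imply the outcome was reported.
    """

    outcome_id: str
    reported: bool = False
    improvement_mentioned: bool = False
    method_described: bool = False
    quantitative_measure: bool = False
    irr_dose_change: bool = False

    def __post_init__(self) -> None:
        if not self.reported:
            if (
                self.improvement_mentioned
                or self.method_described
                or self.quantitative_measure
                or self.irr_dose_change
            ):
                raise IntegrityError(
                    f"observation of {self.outcome_id!r}: unreported outcome "
                    "cannot carry positivity/documentation flags"
                )


@dataclass(frozen=True)
class CaseReport:
    """A single published case with publication metadata and observations."""

    case_id: str
    publication_id: str
    publication_date: _dt.date
    publication_type: PublicationType = PublicationType.ARTICLE
    in_clinical_meta_analysis: bool = False
    aggregated_form: bool = False
    observations: Mapping[str, OutcomeObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for oid, obs in self.observations.items():
            if obs.outcome_id != oid:
                raise IntegrityError(
                    f"case {self.case_id!r}: observation keyed {oid!r} has "
                    f"outcome_id {obs.outcome_id!r}"
                )

    def observation(self, outcome_id: str) -> OutcomeObservation:
        """The case's observation for ``outcome_id``; unreported if absent."""
        return self.observations.get(outcome_id, OutcomeObservation(outcome_id))


@dataclass(frozen=True)
class AnalysisSetSpec:
    """Conjunctive case filters defining one analysis set.

    ``exclude_aggregated`` defaults to True: cases published only in
    aggregated (non-narrative) form are representable in a dataset but
    never analyzed.
    """

    name: str
    date_cutoff: Optional[_dt.date] = None
    exclude_congress: bool = False
    exclude_overlap: bool = False
    exclude_aggregated: bool = True

    def keeps(self, case: CaseReport) -> bool:
        if self.exclude_aggregated and case.aggregated_form:
            return False
        if self.date_cutoff is not None and case.publication_date > self.date_cutoff:
            return False
        if self.exclude_congress and case.publication_type is PublicationType.CONGRESS_COMMUNICATION:
            return False
        if self.exclude_overlap and case.in_clinical_meta_analysis:
            return False
        return True


@dataclass(frozen=True)
class CaseDataset:
    """An immutable collection of case reports plus the outcome configuration."""

    cases: tuple[CaseReport, ...]
    outcomes: tuple[OutcomeSpec, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        ids = [o.outcome_id for o in self.outcomes]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate outcome_id in outcome configuration")
        case_ids = [c.case_id for c in self.cases]
        if len(set(case_ids)) != len(case_ids):
            raise IntegrityError("duplicate case_id in dataset")
        known = set(ids)
        for case in self.cases:
            unknown = set(case.observations) - known
            if unknown:
                raise IntegrityError(
                    f"case {case.case_id!r} observes unknown outcome(s) {sorted(unknown)}"
                )

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_publications(self) -> int:
        return len({c.publication_id for c in self.cases})

    def outcome(self, outcome_id: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.outcome_id == outcome_id:
                return o
        raise KeyError(outcome_id)


# ---------------------------------------------------------------------------
# I/O


def _parse_bool(value: object, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0", "", "nan"):
        return False
    raise SchemaError(f"column {column!r}: cannot parse boolean from {value!r}")


def read_outcomes(path: Union[str, Path]) -> tuple[OutcomeSpec, ...]:
    """Read the outcome configuration from JSON (list of records) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, dtype=str)
        missing = {"outcome_id", "label", "direction", "soe_grade"} - set(df.columns)
        if missing:
            raise SchemaError(f"outcomes file missing column(s) {sorted(missing)}")
        records = df.to_dict(orient="records")
    specs = []
    for rec in records:
        specs.append(
            OutcomeSpec(
                outcome_id=str(rec["outcome_id"]),
                label=str(rec["label"]),
                direction=Direction(rec["direction"]),
                soe_grade=SoeGrade(rec["soe_grade"]),
                harm_criterion=HarmCriterion(rec.get("harm_criterion") or "documented"),
            )
        )
    return tuple(specs)


def read_case_dataset(
    path: Union[str, Path],
    outcomes_path: Union[str, Path],
    provenance: Optional[str] = None,
) -> CaseDataset:
    """Read a case-level CSV (one row per case x outcome) into a dataset.

    Rows sharing a ``case_id`` are merged into one :class:`CaseReport`;
    their publication metadata must agree.  Unknown outcome ids and
    duplicate (case_id, outcome_id) pairs raise :class:`IntegrityError`.
    """
    path = Path(path)
    outcomes = read_outcomes(outcomes_path)
    known = {o.outcome_id for o in outcomes}

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CASE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cases file missing column(s) {sorted(missing)}")

    cases: list[CaseReport] = []
    for case_id, group in df.groupby("case_id", sort=False):
        meta = group[_CASE_META_COLUMNS].drop_duplicates()
        if len(meta) != 1:
            raise IntegrityError(
                f"case {case_id!r}: inconsistent publication metadata across rows"
            )
        row = meta.iloc[0]
        try:
            pub_date = _dt.date.fromisoformat(row["publication_date"])
        except ValueError as exc:
            raise SchemaError(
                f"case {case_id!r}: unparseable publication_date "
                f"{row['publication_date']!r}"
            ) from exc
        observations: dict[str, OutcomeObservation] = {}
        seen: set[str] = set()
        for _, obs_row in group.iterrows():
            oid = obs_row["outcome_id"]
            if oid not in known:
                raise IntegrityError(f"case {case_id!r}: unknown outcome_id {oid!r}")
            if oid in seen:
                raise IntegrityError(
                    f"duplicate observation ({case_id!r}, {oid!r})"
                )
            seen.add(oid)
            obs = OutcomeObservation(
                outcome_id=oid,
                **{c: _parse_bool(obs_row[c], c) for c in _FLAG_COLUMNS},
            )
            # unreported observations are the implicit default; the
            # in-memory form stays sparse and canonical
            if obs.reported:
                observations[oid] = obs
        cases.append(
            CaseReport(
                case_id=str(case_id),
                publication_id=row["publication_id"],
                publication_date=pub_date,
                publication_type=PublicationType(row["publication_type"]),
                in_clinical_meta_analysis=_parse_bool(
                    row["in_clinical_meta_analysis"], "in_clinical_meta_analysis"
                ),
                aggregated_form=_parse_bool(row["aggregated_form"], "aggregated_form"),
                observations=observations,
            )
        )
    return CaseDataset(
        cases=tuple(cases),
        outcomes=outcomes,
        provenance=provenance if provenance is not None else str(path),
    )


def write_case_dataset(ds: CaseDataset, path: Union[str, Path]) -> None:
    """Write a dataset back to the one-row-per-case-x-outcome CSV schema.

    Every configured outcome is materialized for every case (unobserved
    outcomes as unreported rows), so write followed by read round-trips
    all flags exactly.
    """
    rows = []
    for case in ds.cases:
        for outcome in ds.outcomes:
            obs = case.observation(outcome.outcome_id)
            rows.append(
                {
                    "case_id": case.case_id,
                    "publication_id": case.publication_id,
                    "publication_date": case.publication_date.isoformat(),
                    "publication_type": case.publication_type.value,
                    "in_clinical_meta_analysis": str(case.in_clinical_meta_analysis).lower(),
                    "aggregated_form": str(case.aggregated_form).lower(),
                    "outcome_id": obs.outcome_id,
                    "reported": str(obs.reported).lower(),
                    "improvement_mentioned": str(obs.improvement_mentioned).lower(),
                    "method_described": str(obs.method_described).lower(),
                    "quantitative_measure": str(obs.quantitative_measure).lower(),
                    "irr_dose_change": str(obs.irr_dose_change).lower(),
                }
            )
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)


def apply_analysis_set(ds: CaseDataset, spec: AnalysisSetSpec) -> CaseDataset:
    """Filter a dataset down to one analysis set (idempotent, conjunctive)."""
    kept = tuple(c for c in ds.cases if spec.keeps(c))
    n_pubs = len({c.publication_id for c in kept})
    provenance = f"{spec.name}: {len(kept)} cases from {n_pubs} publications"
    return CaseDataset(cases=kept, outcomes=ds.outcomes, provenance=provenance)
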