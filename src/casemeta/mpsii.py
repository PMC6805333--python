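"""Reconstructed MPS-II idursulfase case-report corpus.

The corpus of 56 published case reports of males with MPS-II (Hunter
syndrome) treated with intravenous idursulfase is shipped as a packaged
fixture (``data/mpsii_cases.csv`` + ``data/mpsii_outcomes.json``).

This is a RECONSTRUCTION, not source data: the published analysis prints
only marginal totals (per-outcome positive counts in each analysis set,
set sizes, confusion tables), never the case-level flags.  The fixture
is constructed to satisfy every printed marginal simultaneously --
which specific case carries which positive is arbitrary and frozen
here.  One printed pair is unattainable: a corpus of 56 cases cannot
span 38 publications while its 44 pre-cutoff cases span 25, because the
12 remaining cases would need 13 publications; the reconstruction keeps
all case counts and the per-set publication counts (25/21/22) and has
37 publications in total.

Case groups (ids frozen):

* ``c01-c25``: primary-set articles unique to this corpus (18 publications)
* ``c26-c33``: congress communications (4 publications)
* ``c34-c44``: cases from publications also analyzed in the clinical-study
  meta-analysis used as gold standard (3 publications)
* ``c45-c56``: cases published after the gold standard's search cutoff
  of 2015-12-31 (12 publications)
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from pathlib import Path

from .data_model import (
    AnalysisSetSpec,
    CaseDataset,
    CaseReport,
    OutcomeObservation,
    OutcomeSpec,
    PublicationType,
    read_case_dataset,
    read_outcomes,
)

__all__ = [
    "OUTCOME_ORDER",
    "PRIMARY_SET",
    "ALL_CASES_SET",
    "EXCLUDE_OVERLAP_SET",
    "EXCLUDE_CONGRESS_SET",
    "ANALYSIS_SETS",
    "load_outcomes",
    "load_corpus",
    "reconstruct_corpus",
    "fixture_paths",
]

OUTCOME_ORDER = [
    "ugags",
    "liver",
    "antibodies",
    "6mwt",
    "jrom",
    "growth",
    "irr",
    "pulmonary",
    "cardiac",
    "qol",
    "sleep",
]

_CUTOFF = _dt.date(2015, 12, 31)

PRIMARY_SET = AnalysisSetSpec("primary", date_cutoff=_CUTOFF)
ALL_CASES_SET = AnalysisSetSpec("all")
EXCLUDE_OVERLAP_SET = AnalysisSetSpec(
    "no-overlap", date_cutoff=_CUTOFF, exclude_overlap=True
)
EXCLUDE_CONGRESS_SET = AnalysisSetSpec(
    "no-congress", date_cutoff=_CUTOFF, exclude_congress=True
)

ANALYSIS_SETS = {
    "primary": PRIMARY_SET,
    "all": ALL_CASES_SET,
    "no-overlap": EXCLUDE_OVERLAP_SET,
    "no-congress": EXCLUDE_CONGRESS_SET,
}

# Per-outcome strong positives by case group: (unique-article, congress,
# overlap, post-cutoff).  Group sums reproduce the printed per-set counts.
_STRONG = {
    "ugags": (14, 2, 4, 4),
    "liver": (5, 1, 2, 2),
    "antibodies": (4, 1, 1, 1),
    "6mwt": (4, 0, 0, 1),
    "jrom": (4, 0, 0, 0),
    "growth": (3, 0, 0, 1),
    "irr": (2, 0, 0, 0),
    "pulmonary": (1, 0, 0, 0),
    "cardiac": (0, 0, 0, 0),
    "qol": (0, 0, 0, 1),
    "sleep": (0, 0, 0, 0),
}

# Additional weak-only positives (improvement mentioned, undocumented).
_WEAK_ONLY = {
    "ugags": (0, 0, 0, 0),
    "liver": (3, 1, 1, 1),
    "antibodies": (0, 0, 0, 0),
    "6mwt": (6, 2, 3, 1),
    "jrom": (1, 0, 0, 0),
    "growth": (1, 0, 1, 0),
    "irr": (0, 0, 0, 0),
    "pulmonary": (2, 1, 0, 0),
    "cardiac": (0, 0, 0, 0),
    "qol": (5, 1, 2, 1),
    "sleep": (1, 0, 0, 0),
}

# (publication_id, n_cases, iso date, type, overlaps_gold_standard)
_PUBLICATIONS = (
    [(f"a{i:02d}", 2, f"{2008 + i % 8}-0{1 + (i % 3) * 4}-15", "article", False) for i in range(7)]
    + [(f"a{i:02d}", 1, f"{2008 + i % 8}-0{1 + (i % 3) * 3}-01", "article", False) for i in range(7, 18)]
    + [
        ("g01", 2, "2010-06-20", "congress_communication", False),
        ("g02", 2, "2012-09-05", "congress_communication", False),
        ("g03", 2, "2014-03-11", "congress_communication", False),
        ("g04", 2, "2015-10-02", "congress_communication", False),
        ("b01", 4, "2009-05-30", "article", True),
        ("b02", 4, "2011-11-18", "article", True),
        ("b03", 3, "2013-07-07", "article", True),
    ]
    + [(f"p{i:02d}", 1, f"{2016 + i % 3}-0{1 + i % 4}-10", "article", False) for i in range(12)]
)


def _group_slices() -> dict[str, list[int]]:
    """Case indices (0..55) of the four construction groups."""
    return {
        "unique": list(range(0, 25)),
        "congress": list(range(25, 33)),
        "overlap": list(range(33, 44)),
        "post": list(range(44, 56)),
    }


def reconstruct_corpus() -> CaseDataset:
    """Rebuild the fixture corpus in memory (identical to the shipped CSV)."""
    outcomes = load_outcomes()
    spec_by_id = {o.outcome_id: o for o in outcomes}

    # publication metadata per case, in case order
    meta: list[tuple[str, _dt.date, PublicationType, bool]] = []
    for pub_id, size, iso, ptype, overlap in _PUBLICATIONS:
        for _ in range(size):
            meta.append(
                (pub_id, _dt.date.fromisoformat(iso), PublicationType(ptype), overlap)
            )
    assert len(meta) == 56

    groups = _group_slices()
    group_names = ["unique", "congress", "overlap", "post"]
    observations: list[dict[str, OutcomeObservation]] = [dict() for _ in range(56)]

    for j, oid in enumerate(OUTCOME_ORDER):
        for g, gname in enumerate(group_names):
            members = groups[gname]
            s = _STRONG[oid][g]
            w = _WEAK_ONLY[oid][g]
            # deterministic spread: per-outcome offset walks the group
            offset = (j * 3) % len(members)
            chosen = [members[(offset + i) % len(members)] for i in range(s + w)]
            for i, case_idx in enumerate(chosen):
                strong = i < s
                observations[case_idx][oid] = _positive_observation(
                    spec_by_id[oid], strong=strong, alt=(case_idx + j) % 3
                )

    # a handful of reported-but-unchanged observations (negative under
    # both methods) so the corpus also exercises that state
    for case_idx, oid in [(0, "cardiac"), (1, "cardiac"), (2, "sleep"), (5, "irr")]:
        if oid not in observations[case_idx]:
            observations[case_idx][oid] = OutcomeObservation(
                outcome_id=oid, reported=True, improvement_mentioned=(oid == "irr")
            )

    cases = []
    for idx in range(56):
        pub_id, pub_date, ptype, overlap = meta[idx]
        cases.append(
            CaseReport(
                case_id=f"c{idx + 1:02d}",
                publication_id=pub_id,
                publication_date=pub_date,
                publication_type=ptype,
                in_clinical_meta_analysis=overlap,
                aggregated_form=False,
                observations=observations[idx],
            )
        )
    return CaseDataset(
        cases=tuple(cases),
        outcomes=outcomes,
        provenance="MPS-II idursulfase corpus (reconstruction)",
    )


def _positive_observation(
    outcome: OutcomeSpec, strong: bool, alt: int
) -> OutcomeObservation:
    if outcome.outcome_id == "irr":
        # dose-change criterion: identical under both scoring methods
        return OutcomeObservation(
            outcome_id="irr",
            reported=True,
            improvement_mentioned=True,
            irr_dose_change=True,
        )
    if strong:
        return OutcomeObservation(
            outcome_id=outcome.outcome_id,
            reported=True,
            improvement_mentioned=True,
            method_described=alt in (0, 2),
            quantitative_measure=alt in (1, 2),
        )
    return OutcomeObservation(
        outcome_id=outcome.outcome_id, reported=True, improvement_mentioned=True
    )


def fixture_paths() -> tuple[Path, Path]:
    """(cases CSV, outcomes JSON) paths of the packaged fixture."""
    root = resources.files("casemeta") / "data"
    return Path(str(root / "mpsii_cases.csv")), Path(str(root / "mpsii_outcomes.json"))


def load_outcomes() -> tuple[OutcomeSpec, ...]:
    """The 11 analyzed outcomes with their gold-standard SOE grades."""
    _, outcomes_path = fixture_paths()
    return read_outcomes(outcomes_path)


def load_corpus() -> CaseDataset:
    """Load the packaged 56-case fixture corpus."""
    cases_path, outcomes_path = fixture_paths()
    return read_case_dataset(
        cases_path,
        outcomes_path,
        provenance="MPS-II idursulfase corpus (reconstruction)",
    )
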