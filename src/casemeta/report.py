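"""Rendering of evidence tables, concordance reports and sweep summaries.

Tables are produced as pandas DataFrames (for CSV export) and as plain
text mirroring the column order of the published layouts, so a run can
be eyeballed against the originals.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .concordance import AgreementResult, ConfusionTable, IndexEstimate, ValidityResult, percent
from .data_model import OutcomeSpec
from .evidence import EvidenceRow, format_p_value
from .sensitivity import SweepResult

__all__ = [
    "evidence_table",
    "concordance_report",
    "sweep_table",
    "scatter_data",
]


def _fmt_ci(ci: Optional[tuple[float, float]]) -> str:
    if ci is None:
        return "undefined"
    return f"{percent(ci[0])} to {percent(ci[1])}%"


def _fmt_index(est: IndexEstimate) -> str:
    if not est.defined:
        return "undefined"
    return f"{percent(est.value)}% ({_fmt_ci(est.ci)})"


def evidence_table(
    rows: Sequence[EvidenceRow], outcomes: Sequence[OutcomeSpec]
) -> pd.DataFrame:
    """Evidence table: rank, outcome (SOE), k/n, p, critical value, group."""
    spec = {o.outcome_id: o for o in outcomes}
    records = []
    for row in rows:
        o = spec[row.outcome_id]
        records.append(
            {
                "rank": row.rank,
                "outcome": f"{o.label} ({o.soe_grade.value.capitalize()})",
                "positives": f"{row.k}/{row.n}",
                "p_value": format_p_value(row.p_value),
                "fdr_critical_value": f"{row.critical_value:.3f}",
                "evidence_group": row.group.value,
            }
        )
    return pd.DataFrame.from_records(records)


def concordance_report(
    ct: ConfusionTable, validity: ValidityResult, agreement: AgreementResult
) -> pd.DataFrame:
    """One-column report of the 2x2 cells, validity indices and rho."""
    rho = "undefined" if agreement.rho is None else f"{agreement.rho:.2f}"
    rho_ci = (
        "undefined"
        if agreement.ci is None
        else f"{agreement.ci[0]:.2f} to {agreement.ci[1]:.2f}"
    )
    rows = {
        "true_positives": ct.tp,
        "false_positives": ct.fp,
        "false_negatives": ct.fn,
        "true_negatives": ct.tn,
        "accuracy": _fmt_index(validity.accuracy),
        "sensitivity": _fmt_index(validity.sensitivity),
        "specificity": _fmt_index(validity.specificity),
        "ppv": _fmt_index(validity.ppv),
        "npv": _fmt_index(validity.npv),
        "spearman_rho": rho,
        "spearman_rho_95ci": rho_ci,
    }
    return pd.DataFrame({"value": rows})


def sweep_table(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Scenario x index summary (one row per sweep scenario)."""
    records = []
    for res in results:
        v = res.validity
        records.append(
            {
                "scenario": res.label,
                "publications": res.n_publications,
                "cases": res.n_cases,
                "tp": res.confusion.tp,
                "tn": res.confusion.tn,
                "fp": res.confusion.fp,
                "fn": res.confusion.fn,
                "accuracy_pct": percent(v.accuracy.value) if v.accuracy.defined else None,
                "se_pct": percent(v.sensitivity.value) if v.sensitivity.defined else None,
                "sp_pct": percent(v.specificity.value) if v.specificity.defined else None,
                "ppv_pct": percent(v.ppv.value) if v.ppv.defined else None,
                "npv_pct": percent(v.npv.value) if v.npv.defined else None,
                "rho": None if res.agreement.rho is None else round(res.agreement.rho, 2),
            }
        )
    return pd.DataFrame.from_records(records)


def scatter_data(
    counts: dict[str, tuple[int, int]], outcomes: Sequence[OutcomeSpec]
) -> pd.DataFrame:
    """Per-outcome (count, SOE score) pairs for the agreement scatter plot."""
    return pd.DataFrame.from_records(
        [
            {
                "outcome_id": o.outcome_id,
                "label": o.label,
                "positives": counts[o.outcome_id][0],
                "total_cases": counts[o.outcome_id][1],
                "soe_grade": o.soe_grade.value,
                "soe_score": o.soe_score,
            }
            for o in outcomes
        ]
    )
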