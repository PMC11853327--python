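"""Descriptive reporting statistics for per-drug aggregates.

Covers the summary quantities a pharmacovigilance report tabulates before
any disproportionality analysis: reactions per case, the share of reactions
attributable to each medical condition, the PT distribution within a
condition, and the outcome breakdown (unfavorable = fatal +
not-recovered; the fatal share is expressed out of the unfavorable group).

All reported ratios and percentages are rounded half-up to 2 decimals, the
convention of the summary tables they mirror; raw values stay available by
computing from the aggregate counts directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from ._rounding import round_half_up
from .errors import LookupError_, UndefinedRatioError
from .io import (
    DrugAggregate,
    ICSRDataset,
    Outcome,
    UNFAVORABLE_OUTCOMES,
    normalize_drug_name,
)
from .meddra import Condition, PTEntry, builtin_dictionary, classify_pt

__all__ = [
    "OutcomeBreakdown",
    "adrs_per_icsr",
    "condition_proportion",
    "outcome_breakdown",
    "pt_distribution",
    "descriptive_report",
]


@dataclass(frozen=True)
class OutcomeBreakdown:
    """Outcome summary for one drug × condition.

    ``n_cases`` counts ADR rows of the condition (the counting unit used
    throughout); ``pct_unfavorable`` is out of ``n_cases`` and
    ``pct_fatal_of_unfavorable`` out of ``n_unfavorable``.
    """

    condition: Condition
    n_cases: int
    n_unfavorable: int
    n_fatal: int
    pct_unfavorable: float
    pct_fatal_of_unfavorable: float


def adrs_per_icsr(agg: DrugAggregate) -> float:
    """Reactions per case, rounded half-up to 2 decimals."""
    if agg.n_icsrs == 0:
        raise UndefinedRatioError(f"{agg.drug}: no ICSRs")
    return round_half_up(agg.n_adrs / agg.n_icsrs)


def condition_proportion(
    agg: DrugAggregate, conditions: Iterable[Condition]
) -> float:
    """Percentage of the drug's reactions in the given condition set (2 dp)."""
    if agg.n_adrs == 0:
        raise UndefinedRatioError(f"{agg.drug}: no ADRs")
    selected = agg.condition_count(conditions)
    return round_half_up(100.0 * selected / agg.n_adrs)


def outcome_breakdown(agg: DrugAggregate, condition: Condition) -> OutcomeBreakdown:
    """Unfavorable/fatal outcome summary for one condition of one drug."""
    n_cases = agg.condition_counts[condition]
    if n_cases == 0:
        raise UndefinedRatioError(
            f"{agg.drug}: no reactions for condition {condition.value!r}"
        )
    n_fatal = agg.outcome_counts.get((condition, Outcome.FATAL), 0)
    n_unfavorable = sum(
        agg.outcome_counts.get((condition, o), 0) for o in UNFAVORABLE_OUTCOMES
    )
    pct_unfav = round_half_up(100.0 * n_unfavorable / n_cases)
    pct_fatal = (
        round_half_up(100.0 * n_fatal / n_unfavorable) if n_unfavorable else 0.0
    )
    return OutcomeBreakdown(
        condition=condition,
        n_cases=n_cases,
        n_unfavorable=n_unfavorable,
        n_fatal=n_fatal,
        pct_unfavorable=pct_unfav,
        pct_fatal_of_unfavorable=pct_fatal,
    )


def pt_distribution(
    dataset: ICSRDataset,
    drug: str,
    condition: Condition,
    dictionary: Optional[Sequence[PTEntry]] = None,
) -> dict[str, int]:
    """Reaction counts per dictionary PT of a condition, for one drug.

    Dictionary PTs with no reactions are reported as 0, so the result
    always covers the condition's full term set.  For ``Condition.OTHER``
    (no dictionary PTs) the observed PT names are returned as-is.
    """
    dictionary = tuple(dictionary) if dictionary is not None else builtin_dictionary()
    wanted = normalize_drug_name(drug)
    if wanted not in dataset.drugs():
        raise LookupError_(f"drug {wanted!r} not present in dataset")
    canonical = {e.name.strip().lower(): e.name for e in dictionary}
    counts: dict[str, int] = {
        e.name: 0 for e in dictionary if e.condition is condition
    }
    for r in dataset.records:
        if r.drug != wanted:
            continue
        if classify_pt(r.pt_code, r.pt_name, dictionary) is not condition:
            continue
        name = canonical.get(r.pt_name.strip().lower(), r.pt_name)
        counts[name] = counts.get(name, 0) + 1
    return counts


def descriptive_report(
    aggs: Sequence[DrugAggregate],
    conditions: Iterable[Condition] = (
        Condition.RESISTANCE,
        Condition.INEFFECTIVENESS,
    ),
) -> pd.DataFrame:
    """One summary row per drug: totals, ADRs/ICSR, condition percentages
    and outcome breakdowns, ready for CSV export."""
    conditions = list(conditions)
    rows = []
    for agg in aggs:
        row: dict[str, Union[str, int, float]] = {
            "drug": agg.drug,
            "n_icsrs": agg.n_icsrs,
            "n_adrs": agg.n_adrs,
            "adrs_per_icsr": adrs_per_icsr(agg) if agg.n_icsrs else float("nan"),
            "pct_selected_conditions": condition_proportion(agg, conditions),
        }
        for cond in conditions:
            prefix = cond.value
            row[f"n_{prefix}"] = agg.condition_counts[cond]
            if agg.condition_counts[cond] and agg.outcome_counts:
                b = outcome_breakdown(agg, cond)
                row[f"{prefix}_n_unfavorable"] = b.n_unfavorable
                row[f"{prefix}_n_fatal"] = b.n_fatal
                row[f"{prefix}_pct_unfavorable"] = b.pct_unfavorable
                row[f"{prefix}_pct_fatal_of_unfavorable"] = b.pct_fatal_of_unfavorable
        rows.append(row)
    return pd.DataFrame(rows)
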