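"""Reporting odds ratio disproportionality analysis.

For a target drug and a comparator, reactions of an evaluated condition
form the 2×2 table

    =============  ==================  ===============
                   evaluated reaction  other reactions
    =============  ==================  ===============
    target drug    a                   b
    comparator     c                   d
    =============  ==================  ===============

with the reporting odds ratio ROR = (a·d)/(b·c), the Woolf log-scale
standard error SE = √(1/a + 1/b + 1/c + 1/d), and the Wald interval
exp(ln ROR ± z·SE) with z = 1.96 for a 95% CI.  A pair is screened as a
*disproportionality signal* under the EMA criterion when the evaluated
reaction has at least 5 reports for the target drug and the lower CI bound
exceeds 1.  A two-sided p-value from the Wald z statistic is carried as a
convenience output; it plays no part in signal classification.

Zero cells make the ROR or its SE undefined; such pairs are flagged
``defined=False`` and excluded from signalling rather than
continuity-corrected, matching screening practice.

The module exposes both a functional surface (:func:`build_table`,
:func:`compute_ror`, :func:`classify_signal`, :func:`run_panel`) and a
model/results pair (:class:`DisproportionalityModel`,
:class:`DisproportionalityResults`) for panel analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from scipy.stats import norm

from .errors import ConsistencyError, UsageError
from .io import DrugAggregate, find_aggregate, normalize_drug_name
from .meddra import Condition

__all__ = [
    "ContingencyTable",
    "RORResult",
    "build_table",
    "compute_ror",
    "classify_signal",
    "run_panel",
    "DisproportionalityModel",
    "DisproportionalityResults",
]

SIGNAL_TABLE_COLUMNS = [
    "target",
    "comparator",
    "condition",
    "a",
    "b",
    "c",
    "d",
    "ror",
    "ci_low",
    "ci_high",
    "p_value",
    "n_reports",
    "signal",
    "defined",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 reaction counts for one target/comparator/condition triple."""

    a: int
    b: int
    c: int
    d: int
    target: str = ""
    comparator: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        for cell, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if not isinstance(v, int) or v < 0:
                raise ConsistencyError(
                    f"cell {cell} must be a non-negative integer, got {v!r}"
                )

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RORResult:
    """Point estimate, uncertainty and signal classification for one pair.

    When ``defined`` is False (some cell of the table is zero) the numeric
    fields are ``None`` and ``signal`` is False.
    """

    table: ContingencyTable
    ror: Optional[float]
    log_se: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    n_reports: int
    signal: bool
    defined: bool
    z: float = 1.96


def build_table(
    aggs: Sequence[DrugAggregate],
    target: str,
    comparator: str,
    conditions: Iterable[Condition],
) -> ContingencyTable:
    """Cross-tabulate evaluated-condition vs other reaction counts.

    ``a`` is the evaluated-condition count for the target, ``b`` the rest
    of the target's reactions; ``c``/``d`` likewise for the comparator.
    """
    if normalize_drug_name(target) == normalize_drug_name(comparator):
        raise UsageError(f"target and comparator are the same drug: {target!r}")
    conditions = set(conditions)
    t = find_aggregate(aggs, target)
    u = find_aggregate(aggs, comparator)
    a = t.condition_count(conditions)
    c = u.condition_count(conditions)
    return ContingencyTable(
        a=a,
        b=t.n_adrs - a,
        c=c,
        d=u.n_adrs - c,
        target=t.drug,
        comparator=u.drug,
        condition="+".join(sorted(co.value for co in conditions)),
    )


def compute_ror(
    table: ContingencyTable,
    z: float = 1.96,
    min_reports: int = 5,
) -> RORResult:
    """ROR, Woolf SE, Wald CI, Wald p-value and signal flag for one table.

    Zero cells yield ``defined=False`` — never an exception and never a
    continuity correction.
    """
    if table.has_zero_cell:
        return RORResult(
            table=table,
            ror=None,
            log_se=None,
            ci_low=None,
            ci_high=None,
            p_value=None,
            n_reports=table.a,
            signal=False,
            defined=False,
            z=z,
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    ror = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - z * log_se)
    ci_high = math.exp(log_ror + z * log_se)
    p_value = 2.0 * norm.sf(abs(log_ror) / log_se)
    return RORResult(
        table=table,
        ror=ror,
        log_se=log_se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=min(p_value, 1.0),
        n_reports=a,
        signal=a >= min_reports and ci_low > 1.0,
        defined=True,
        z=z,
    )


def classify_signal(result: RORResult, min_reports: int = 5) -> bool:
    """EMA screening rule: ``defined`` ∧ ``n_reports ≥ min_reports`` ∧
    ``ci_low > 1`` (strict)."""
    return bool(
        result.defined
        and result.n_reports >= min_reports
        and result.ci_low is not None
        and result.ci_low > 1.0
    )


def run_panel(
    aggs: Sequence[DrugAggregate],
    target: str,
    comparators: Sequence[str],
    conditions: Iterable[Condition],
    z: float = 1.96,
    min_reports: int = 5,
) -> list[RORResult]:
    """One ROR per comparator, in input order; missing comparators are all
    reported in one error."""
    conditions = set(conditions)
    known = {agg.drug for agg in aggs}
    missing = [
        cmp_
        for cmp_ in [target, *comparators]
        if normalize_drug_name(cmp_) not in known
    ]
    if missing:
        from .errors import LookupError_

        raise LookupError_(f"drugs not present in aggregates: {missing}")
    return [
        compute_ror(build_table(aggs, target, cmp_, conditions), z, min_reports)
        for cmp_ in comparators
    ]


class DisproportionalityModel:
    """Panel disproportionality model over per-drug aggregates.

    Parameters
    ----------
    aggregates : sequence of DrugAggregate
        Per-drug reaction counts (from ``aggregate`` or an aggregate table).
    target : str
        Drug whose reporting is evaluated.
    comparators : sequence of str
        Comparator drugs; one ROR per comparator.
    conditions : iterable of Condition
        Evaluated condition(s); their counts are pooled into cell ``a``/``c``.

    Examples
    --------
    >>> model = DisproportionalityModel(aggs, "panitumumab",
    ...                                 ["bevacizumab"],
    ...                                 [Condition.INEFFECTIVENESS])
    >>> res = model.fit()
    >>> res.to_frame()[["comparator", "ror", "ci_low", "ci_high", "signal"]]
    """

    def __init__(
        self,
        aggregates: Sequence[DrugAggregate],
        target: str,
        comparators: Sequence[str],
        conditions: Iterable[Condition],
    ) -> None:
        self.aggregates = list(aggregates)
        self.target = normalize_drug_name(target)
        self.comparators = [normalize_drug_name(c) for c in comparators]
        self.conditions = set(conditions)
        if not self.comparators:
            raise UsageError("comparator list is empty")

    @classmethod
    def from_dataset(cls, dataset, target, comparators, conditions, dictionary=None):
        """Build the model straight from an ICSR line listing."""
        from .io import aggregate as _aggregate

        return cls(_aggregate(dataset, dictionary), target, comparators, conditions)

    def fit(self, z: float = 1.96, min_reports: int = 5) -> "DisproportionalityResults":
        """Compute the panel of RORs; returns a results object."""
        results = run_panel(
            self.aggregates, self.target, self.comparators, self.conditions, z, min_reports
        )
        return DisproportionalityResults(self, results, z=z, min_reports=min_reports)


class DisproportionalityResults:
    """Fitted panel: one :class:`RORResult` per comparator.

    Provides a tidy frame (:meth:`to_frame`), a text summary
    (:meth:`summary`) and CSV/JSON writers whose column set is stable and
    forest-plot ready.
    """

    def __init__(
        self,
        model: DisproportionalityModel,
        results: Sequence[RORResult],
        z: float,
        min_reports: int,
    ) -> None:
        self.model = model
        self.results = list(results)
        self.z = z
        self.min_reports = min_reports

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self, ndigits: int = 4) -> pd.DataFrame:
        """Signal table, numeric columns rounded to ``ndigits`` decimals."""
        rows = []
        for r in self.results:
            t = r.table
            rows.append(
                {
                    "target": t.target,
                    "comparator": t.comparator,
                    "condition": t.condition,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "ror": round(r.ror, ndigits) if r.defined else None,
                    "ci_low": round(r.ci_low, ndigits) if r.defined else None,
                    "ci_high": round(r.ci_high, ndigits) if r.defined else None,
                    "p_value": round(r.p_value, 6) if r.defined else None,
                    "n_reports": r.n_reports,
                    "signal": r.signal,
                    "defined": r.defined,
                }
            )
        return pd.DataFrame(rows, columns=SIGNAL_TABLE_COLUMNS)

    def summary(self) -> str:
        """Human-readable panel summary."""
        cond = "+".join(sorted(c.value for c in self.model.conditions))
        lines = [
            "Reporting odds ratio panel",
            f"  target:      {self.model.target}",
            f"  condition:   {cond}",
            f"  z:           {self.z}   min reports: {self.min_reports}",
            "",
            f"  {'comparator':<24}{'a':>6}{'ROR':>10}{'95% CI':>20}"
            f"{'p':>10}  signal",
        ]
        for r in self.results:
            if r.defined:
                ci = f"({r.ci_low:.4f}, {r.ci_high:.4f})"
                lines.append(
                    f"  {r.table.comparator:<24}{r.n_reports:>6}"
                    f"{r.ror:>10.4f}{ci:>20}{r.p_value:>10.4f}"
                    f"  {'yes' if r.signal else 'no'}"
                )
            else:
                lines.append(
                    f"  {r.table.comparator:<24}{r.n_reports:>6}"
                    f"{'—':>10}{'(zero cell)':>20}{'—':>10}  no"
                )
        return "\n".join(lines)

    def to_csv(self, path: Union[str, Path], ndigits: int = 4) -> None:
        self.to_frame(ndigits).to_csv(path, index=False, lineterminator="\n")

    def to_json(self, path: Union[str, Path], ndigits: int = 4) -> None:
        self.to_frame(ndigits).to_json(path, orient="records", indent=2)
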