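"""Reading, writing and aggregating ICSR line listings.

An Individual Case Safety Report (ICSR) is one case report; it may carry
several adverse drug reactions (ADRs), each coded as a MedDRA PT and each
with a reported patient outcome.  This module handles the two delimited
formats the pipeline speaks:

* a *line listing* — one CSV row per reported reaction
  (``icsr_id,drug,pt_code,pt_name,outcome``), emulating the export of a
  spontaneous-reporting database;
* an *aggregate table* — long-form per-drug counts
  (``drug,n_icsrs,n_adrs,condition,outcome,count``), which lets printed
  summary counts be entered directly without any line listing.

The counting unit in all condition counts is the ADR row, not the case:
in a drug-vs-comparator 2×2 table, "other ADRs for the drug" is a count of
reactions, so condition counts must live on the same scale.  ``n_icsrs``
counts distinct case identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ConsistencyError, FormatError, InputError, LookupError_
from .meddra import Condition, PTEntry, builtin_dictionary, classify_pt

__all__ = [
    "Outcome",
    "ADRRecord",
    "ICSRDataset",
    "DrugAggregate",
    "normalize_drug_name",
    "read_line_listing",
    "write_line_listing",
    "aggregate",
    "read_aggregate_table",
    "write_aggregate_table",
]

LINE_LISTING_COLUMNS = ["icsr_id", "drug", "pt_code", "pt_name", "outcome"]
AGGREGATE_COLUMNS = ["drug", "n_icsrs", "n_adrs", "condition", "outcome", "count"]


class Outcome(str, Enum):
    """Reported patient outcome of a single ADR.

    ``FATAL`` and ``NOT_RECOVERED`` together form the *unfavorable* group;
    ``RECOVERED`` and ``RECOVERING`` the *favorable* group.
    """

    FATAL = "fatal"
    NOT_RECOVERED = "not_recovered"
    RECOVERED = "recovered"
    RECOVERING = "recovering"
    UNKNOWN = "unknown"


#: Outcomes counted as unfavorable in outcome breakdowns.
UNFAVORABLE_OUTCOMES = (Outcome.FATAL, Outcome.NOT_RECOVERED)

# Verbatim outcome strings used by EudraVigilance exports, mapped onto the
# enum.  The enum values themselves are also accepted so that files written
# by this package round-trip.
_OUTCOME_ALIASES = {
    "fatal": Outcome.FATAL,
    "not recovered/not resolved": Outcome.NOT_RECOVERED,
    "not_recovered": Outcome.NOT_RECOVERED,
    "recovered/resolved": Outcome.RECOVERED,
    "recovered": Outcome.RECOVERED,
    "recovering/resolving": Outcome.RECOVERING,
    "recovering": Outcome.RECOVERING,
    "unknown": Outcome.UNKNOWN,
}


def parse_outcome(raw: str) -> Outcome:
    """Map a reported outcome string to the enum; unknown strings raise.

    Unknown outcome strings are an error rather than being silently mapped
    to ``UNKNOWN``, so that a drifting export dialect is noticed.
    """
    key = str(raw).strip().lower()
    try:
        return _OUTCOME_ALIASES[key]
    except KeyError:
        raise InputError(f"unrecognized outcome string: {raw!r}") from None


def normalize_drug_name(raw: str) -> str:
    """Normalize an active-ingredient name for matching.

    Trims, lower-cases and collapses internal whitespace.  Slash-joined
    combination products (``trifluridine/tipiracil``) stay one token.
    """
    if raw is None or not str(raw).strip():
        raise InputError("drug name is empty")
    return " ".join(str(raw).strip().lower().split())


@dataclass(frozen=True)
class ADRRecord:
    """One reported reaction: a single row of a line listing."""

    icsr_id: str
    drug: str
    pt_name: str
    outcome: Outcome
    pt_code: Optional[int] = None

    def condition(self, dictionary: Optional[Sequence[PTEntry]] = None) -> Condition:
        """Condition label of this reaction's PT."""
        return classify_pt(self.pt_code, self.pt_name, dictionary)


@dataclass
class ICSRDataset:
    """An ordered collection of ADR records with a provenance tag."""

    records: list[ADRRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def drugs(self) -> list[str]:
        """Distinct drug names in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.drug, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "icsr_id": [r.icsr_id for r in self.records],
                "drug": [r.drug for r in self.records],
                "pt_code": [r.pt_code for r in self.records],
                "pt_name": [r.pt_name for r in self.records],
                "outcome": [r.outcome.value for r in self.records],
            }
        )


@dataclass
class DrugAggregate:
    """Per-drug counts: the input of every descriptive and 2×2 computation.

    Invariants (checked by :meth:`validate`):

    * ``n_adrs`` equals the sum of ``condition_counts`` over the three
      condition labels;
    * each condition count equals the sum of its outcome counts;
    * ``n_icsrs <= n_adrs`` (a case carries at least one reaction).
    """

    drug: str
    n_icsrs: int
    n_adrs: int
    condition_counts: dict[Condition, int] = field(default_factory=dict)
    outcome_counts: dict[tuple[Condition, Outcome], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in Condition:
            self.condition_counts.setdefault(c, 0)

    def validate(self) -> "DrugAggregate":
        if self.n_icsrs < 0 or self.n_adrs < 0:
            raise ConsistencyError(f"{self.drug}: negative totals")
        if any(v < 0 for v in self.condition_counts.values()) or any(
            v < 0 for v in self.outcome_counts.values()
        ):
            raise ConsistencyError(f"{self.drug}: negative counts")
        total = sum(self.condition_counts.values())
        if total != self.n_adrs:
            raise ConsistencyError(
                f"{self.drug}: condition counts sum to {total}, "
                f"but n_adrs = {self.n_adrs}"
            )
        if self.outcome_counts:
            for cond in Condition:
                by_outcome = sum(
                    n for (c, _o), n in self.outcome_counts.items() if c is cond
                )
                if by_outcome != self.condition_counts[cond]:
                    raise ConsistencyError(
                        f"{self.drug}/{cond.value}: outcome counts sum to "
                        f"{by_outcome}, condition count is "
                        f"{self.condition_counts[cond]}"
                    )
        if self.n_adrs > 0 and self.n_icsrs > self.n_adrs:
            raise ConsistencyError(
                f"{self.drug}: n_icsrs ({self.n_icsrs}) exceeds n_adrs "
                f"({self.n_adrs})"
            )
        return self

    def condition_count(self, conditions: Iterable[Condition]) -> int:
        return sum(self.condition_counts[c] for c in set(conditions))


def read_line_listing(
    path: Union[str, Path],
    dictionary: Optional[Sequence[PTEntry]] = None,
) -> ICSRDataset:
    """Read a line-listing CSV into an :class:`ICSRDataset`.

    Every data row becomes one :class:`ADRRecord`; drug names are
    normalized, outcome strings mapped onto the enum.  Rows that cannot be
    parsed are rejected with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LINE_LISTING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records: list[ADRRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        icsr_id = str(row.icsr_id).strip()
        if not icsr_id:
            raise FormatError(f"{path}: line {i}: empty icsr_id")
        pt_code_raw = str(row.pt_code).strip()
        pt_name = str(row.pt_name).strip()
        if not pt_code_raw and not pt_name:
            raise FormatError(f"{path}: line {i}: neither pt_code nor pt_name")
        try:
            drug = normalize_drug_name(row.drug)
            outcome = parse_outcome(row.outcome)
            pt_code = int(pt_code_raw) if pt_code_raw else None
        except (InputError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        records.append(
            ADRRecord(
                icsr_id=icsr_id,
                drug=drug,
                pt_code=pt_code,
                pt_name=pt_name,
                outcome=outcome,
            )
        )
    return ICSRDataset(records=records, provenance=str(path))


def write_line_listing(dataset: ICSRDataset, path: Union[str, Path]) -> None:
    """Write a dataset back to the line-listing CSV dialect."""
    df = dataset.to_frame()
    df["pt_code"] = df["pt_code"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, lineterminator="\n")


def aggregate(
    dataset: ICSRDataset,
    dictionary: Optional[Sequence[PTEntry]] = None,
) -> list[DrugAggregate]:
    """Aggregate a line listing into per-drug counts.

    One :class:`DrugAggregate` per distinct drug, in first-appearance
    order.  The counts are permutation-invariant; only the ordering of the
    returned list follows the input.
    """
    if not dataset.records:
        raise InputError("cannot aggregate an empty dataset")
    dictionary = tuple(dictionary) if dictionary is not None else builtin_dictionary()
    by_code = {e.code: e.condition for e in dictionary}
    by_name = {e.name.strip().lower(): e.condition for e in dictionary}

    out: dict[str, DrugAggregate] = {}
    cases: dict[str, set[str]] = {}
    for r in dataset.records:
        agg = out.get(r.drug)
        if agg is None:
            agg = DrugAggregate(drug=r.drug, n_icsrs=0, n_adrs=0)
            out[r.drug] = agg
            cases[r.drug] = set()
        cond = by_code.get(r.pt_code) if r.pt_code is not None else None
        if cond is None and r.pt_code is None:
            cond = by_name.get(r.pt_name.strip().lower())
        if cond is None:
            cond = Condition.OTHER
        agg.n_adrs += 1
        agg.condition_counts[cond] += 1
        key = (cond, r.outcome)
        agg.outcome_counts[key] = agg.outcome_counts.get(key, 0) + 1
        cases[r.drug].add(r.icsr_id)
    for drug, agg in out.items():
        agg.n_icsrs = len(cases[drug])
        agg.validate()
    return list(out.values())


def write_aggregate_table(
    aggs: Sequence[DrugAggregate], path: Union[str, Path]
) -> None:
    """Write aggregates as a long-form CSV, one row per (condition, outcome).

    Conditions or outcomes with zero counts are written only when the drug
    has no finer-grained rows at all, so the file stays small and the
    round-trip is exact.
    """
    rows = []
    for agg in aggs:
        agg.validate()
        if agg.outcome_counts:
            items = sorted(
                agg.outcome_counts.items(),
                key=lambda kv: (kv[0][0].value, kv[0][1].value),
            )
            for (cond, outcome), n in items:
                if n:
                    rows.append(
                        (agg.drug, agg.n_icsrs, agg.n_adrs, cond.value, outcome.value, n)
                    )
        else:
            for cond in Condition:
                n = agg.condition_counts[cond]
                if n:
                    rows.append((agg.drug, agg.n_icsrs, agg.n_adrs, cond.value, "", n))
        if agg.n_adrs == 0:
            rows.append((agg.drug, agg.n_icsrs, 0, "", "", 0))
    pd.DataFrame(rows, columns=AGGREGATE_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_aggregate_table(path: Union[str, Path]) -> list[DrugAggregate]:
    """Read a long-form aggregate CSV, validating every invariant.

    Rows with an empty ``outcome`` field carry a bare condition count (for
    hand-entered tables where per-outcome splits are unknown); such drugs
    get no ``outcome_counts``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in AGGREGATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    out: dict[str, DrugAggregate] = {}
    has_outcomes: dict[str, bool] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            drug = normalize_drug_name(row.drug)
            n_icsrs = int(row.n_icsrs)
            n_adrs = int(row.n_adrs)
            count = int(row.count)
        except (InputError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        if count < 0 or n_icsrs < 0 or n_adrs < 0:
            raise FormatError(f"{path}: line {i}: negative count")
        agg = out.get(drug)
        if agg is None:
            agg = DrugAggregate(drug=drug, n_icsrs=n_icsrs, n_adrs=n_adrs)
            out[drug] = agg
            has_outcomes[drug] = False
        elif (agg.n_icsrs, agg.n_adrs) != (n_icsrs, n_adrs):
            raise ConsistencyError(
                f"{path}: line {i}: totals for {drug!r} disagree with earlier rows"
            )
        if not str(row.condition).strip():
            if count:
                raise FormatError(f"{path}: line {i}: count without a condition")
            continue
        try:
            cond = Condition(str(row.condition).strip().lower())
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        agg.condition_counts[cond] += count
        outcome_raw = str(row.outcome).strip()
        if outcome_raw:
            outcome = parse_outcome(outcome_raw)
            key = (cond, outcome)
            agg.outcome_counts[key] = agg.outcome_counts.get(key, 0) + count
            has_outcomes[drug] = True
    for drug, agg in out.items():
        if has_outcomes[drug] and sum(agg.outcome_counts.values()) != sum(
            agg.condition_counts.values()
        ):
            raise ConsistencyError(
                f"{path}: {drug!r} mixes rows with and without outcomes"
            )
        agg.validate()
    return list(out.values())


def find_aggregate(aggs: Sequence[DrugAggregate], drug: str) -> DrugAggregate:
    """Look up one drug's aggregate by normalized name."""
    wanted = normalize_drug_name(drug)
    for agg in aggs:
        if agg.drug == wanted:
            return agg
    raise LookupError_(f"drug {wanted!r} not present in aggregates")
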