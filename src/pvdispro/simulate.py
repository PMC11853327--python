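"""Synthetic ICSR line listings with controlled statistical structure.

Spontaneous-reporting databases cannot be redistributed, so every pipeline
stage here is exercised on synthetic data.  A :class:`SyntheticSpec`
describes, per drug, how many cases and reactions to produce and how the
reactions split over conditions, preferred terms and outcomes.  Two modes:

``exact``
    Every target count is reproduced exactly: ``aggregate(generate(spec))``
    returns precisely the specified counts.  Reactions are dealt to cases
    round-robin, so the number of distinct case ids equals ``n_icsrs`` and
    the reactions-per-case ratio is as uniform as possible.

``sample``
    Condition, PT and outcome of each reaction are drawn from the target
    proportions (multinomial), reproducible for equal seeds.  Totals per
    drug stay fixed; only the composition is random.

The module also ships :func:`reference_study_spec`, an exact-mode spec
pinned to the published EudraVigilance aggregates for bevacizumab and
panitumumab in colorectal cancer (ICSR/ADR totals, resistance and
ineffectiveness counts, the dominant PT splits and the unfavorable-outcome
breakdowns), so the whole analysis can be re-run without any database
access.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, NonNegativeInt, model_validator

from .errors import SpecError
from .io import ADRRecord, ICSRDataset, Outcome, write_line_listing
from .meddra import Condition, PTEntry, builtin_dictionary

__all__ = [
    "DrugBlock",
    "SyntheticSpec",
    "generate",
    "reference_study_spec",
    "largest_remainder_allocation",
    "default_outcome_split",
]

#: PT name used for reactions outside the resistance/ineffectiveness
#: dictionary (classifies as ``other``).
GENERIC_OTHER_PT = "Other adverse reaction"


def largest_remainder_allocation(total: int, weights: Sequence[float]) -> list[int]:
    """Split ``total`` into integers proportional to ``weights``.

    Hamilton's method: floor the exact quotas, then give the leftover units
    to the largest fractional remainders (ties broken by position).
    Deterministic, sums exactly to ``total``.
    """
    if total < 0:
        raise SpecError("cannot allocate a negative total")
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        if total:
            raise SpecError("cannot allocate a positive total over no categories")
        return []
    if (w < 0).any() or w.sum() <= 0:
        raise SpecError("weights must be non-negative with a positive sum")
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    leftover = total - int(base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:leftover]:
        base[i] += 1
    return base.tolist()


def default_outcome_split(
    n: int, fatal: int = 0, not_recovered: int = 0
) -> dict[Outcome, int]:
    """Outcome counts for ``n`` reactions with a given unfavorable part.

    The remainder is split 50/50 between favorable and unknown; an odd
    remainder favors the favorable side, and within favorable, recovered
    before recovering.  This fills in what summary publications typically
    leave unreported (only unfavorable breakdowns tend to be printed).
    """
    if fatal + not_recovered > n:
        raise SpecError("unfavorable outcomes exceed the condition count")
    rest = n - fatal - not_recovered
    unknown = rest // 2
    favorable = rest - unknown
    recovered = favorable - favorable // 2
    recovering = favorable // 2
    return {
        Outcome.FATAL: fatal,
        Outcome.NOT_RECOVERED: not_recovered,
        Outcome.RECOVERED: recovered,
        Outcome.RECOVERING: recovering,
        Outcome.UNKNOWN: unknown,
    }


class DrugBlock(BaseModel):
    """Targets for one drug.

    ``pt_weights`` and ``outcome_counts`` are keyed by condition value
    (``"resistance"``, ``"ineffectiveness"``, ``"other"``).  In exact mode
    an ``outcome_counts`` entry must sum to its condition count and integer
    ``pt_weights`` summing to the condition count are reproduced verbatim;
    otherwise weights are proportions to be allocated (exact mode) or
    sampling probabilities (sample mode).
    """

    n_icsrs: NonNegativeInt
    n_adrs: NonNegativeInt
    condition_counts: dict[str, NonNegativeInt] = Field(default_factory=dict)
    pt_weights: dict[str, dict[str, float]] = Field(default_factory=dict)
    outcome_counts: dict[str, dict[str, NonNegativeInt]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "DrugBlock":
        for key in list(self.condition_counts) + list(self.pt_weights) + list(
            self.outcome_counts
        ):
            Condition(key)  # raises ValueError on an unknown label
        total = sum(self.condition_counts.values())
        if total != self.n_adrs:
            raise ValueError(
                f"condition counts sum to {total}, n_adrs = {self.n_adrs}"
            )
        if self.n_adrs == 0:
            if self.n_icsrs != 0:
                raise ValueError("n_icsrs > 0 with zero reactions")
        elif self.n_icsrs == 0 or self.n_icsrs > self.n_adrs:
            raise ValueError(
                f"need 1 <= n_icsrs <= n_adrs, got n_icsrs={self.n_icsrs}, "
                f"n_adrs={self.n_adrs}"
            )
        for cond_key, counts in self.outcome_counts.items():
            for o in counts:
                Outcome(o)
            s = sum(counts.values())
            if s != self.condition_counts.get(cond_key, 0):
                raise ValueError(
                    f"{cond_key}: outcome counts sum to {s}, condition count "
                    f"is {self.condition_counts.get(cond_key, 0)}"
                )
        for cond_key, weights in self.pt_weights.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{cond_key}: negative PT weight")
            if self.condition_counts.get(cond_key, 0) > 0 and not weights:
                raise ValueError(f"{cond_key}: empty PT weight map")
        return self


class SyntheticSpec(BaseModel):
    """Full generator specification: per-drug blocks, mode and seed."""

    drugs: dict[str, DrugBlock]
    mode: Literal["exact", "sample"] = "exact"
    seed: int = 0

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticSpec":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")


def _condition_pts(
    cond: Condition, dictionary: Sequence[PTEntry]
) -> list[tuple[str, Optional[int]]]:
    if cond is Condition.OTHER:
        return [(GENERIC_OTHER_PT, None)]
    return [(e.name, e.code) for e in dictionary if e.condition is cond]


def _resolve_pt_weights(
    block: DrugBlock, cond: Condition, dictionary: Sequence[PTEntry]
) -> tuple[list[tuple[str, Optional[int]]], list[float]]:
    """PT list and weights for one condition; defaults to uniform over the
    condition's dictionary PTs."""
    code_of = {e.name: e.code for e in dictionary}
    custom = block.pt_weights.get(cond.value)
    if custom:
        pts = [(name, code_of.get(name)) for name in custom]
        return pts, list(custom.values())
    pts = _condition_pts(cond, dictionary)
    return pts, [1.0] * len(pts)


def _resolve_outcomes(block: DrugBlock, cond: Condition, n: int) -> dict[Outcome, int]:
    custom = block.outcome_counts.get(cond.value)
    if custom is not None:
        return {Outcome(o): int(k) for o, k in custom.items()}
    return default_outcome_split(n)


def generate(
    spec: SyntheticSpec,
    dictionary: Optional[Sequence[PTEntry]] = None,
) -> ICSRDataset:
    """Generate a line listing satisfying (exact) or sampled around
    (sample) the spec's targets.

    Deterministic: equal spec + seed produce identical datasets, row for
    row.  Raises :class:`SpecError` for infeasible targets before any data
    is produced (pydantic validation happens at spec construction).
    """
    dictionary = tuple(dictionary) if dictionary is not None else builtin_dictionary()
    rng = np.random.default_rng(spec.seed)
    records: list[ADRRecord] = []

    for drug, block in spec.drugs.items():
        if spec.mode == "sample":
            rows = _sample_rows(block, dictionary, rng) if block.n_adrs else []
        else:
            rows = _exact_rows(drug, block, dictionary)
        if len(rows) != block.n_adrs:
            raise SpecError(
                f"{drug}: produced {len(rows)} rows for n_adrs={block.n_adrs}"
            )
        width = max(1, len(str(block.n_icsrs)))
        for i, (name, code, outcome) in enumerate(rows):
            case = i % block.n_icsrs + 1  # round-robin deal over cases
            records.append(
                ADRRecord(
                    icsr_id=f"{drug}-{case:0{width}d}",
                    drug=drug,
                    pt_code=code,
                    pt_name=name,
                    outcome=outcome,
                )
            )
    return ICSRDataset(records=records, provenance=f"synthetic:{spec.mode}:{spec.seed}")


def _exact_rows(
    drug: str,
    block: DrugBlock,
    dictionary: Sequence[PTEntry],
) -> list[tuple[str, Optional[int], Outcome]]:
    """Deterministic expansion of one drug's exact targets into rows.

    PTs within a condition are allocated by largest remainder over the
    (possibly integer) weights; outcome labels are expanded in enum order
    and paired with the PT stream positionally, which satisfies both
    margins exactly.
    """
    rows: list[tuple[str, Optional[int], Outcome]] = []
    for cond in Condition:
        n_cond = block.condition_counts.get(cond.value, 0)
        if n_cond == 0:
            continue
        pts, weights = _resolve_pt_weights(block, cond, dictionary)
        pt_counts = largest_remainder_allocation(n_cond, weights)
        outcome_counts = _resolve_outcomes(block, cond, n_cond)
        pt_stream = [pts[i] for i, k in enumerate(pt_counts) for _ in range(k)]
        outcome_stream = [o for o in Outcome for _ in range(outcome_counts.get(o, 0))]
        if len(outcome_stream) != len(pt_stream):
            raise SpecError(
                f"{drug}/{cond.value}: outcome counts do not cover the "
                f"condition count"
            )
        rows.extend(
            (name, code, o) for (name, code), o in zip(pt_stream, outcome_stream)
        )
    return rows


def _sample_rows(
    block: DrugBlock,
    dictionary: Sequence[PTEntry],
    rng: np.random.Generator,
) -> list[tuple[str, Optional[int], Outcome]]:
    """Multinomial draw of (condition, PT, outcome) for one drug."""
    conds = [c for c in Condition]
    cond_w = np.array(
        [block.condition_counts.get(c.value, 0) for c in conds], dtype=float
    )
    n_by_cond = rng.multinomial(block.n_adrs, cond_w / cond_w.sum())
    rows: list[tuple[str, Optional[int], Outcome]] = []
    for cond, n_cond in zip(conds, n_by_cond):
        if n_cond == 0:
            continue
        pts, weights = _resolve_pt_weights(block, cond, dictionary)
        w = np.asarray(weights, dtype=float)
        pt_idx = rng.choice(len(pts), size=n_cond, p=w / w.sum())
        oc = _resolve_outcomes(block, cond, block.condition_counts.get(cond.value, 0))
        o_names = [o for o in Outcome]
        o_w = np.array([oc.get(o, 0) for o in o_names], dtype=float)
        if o_w.sum() <= 0:
            o_w = np.array(
                [0.0, 0.0, 0.25, 0.25, 0.5]
            )  # favorable/unknown default when the target count was zero
        o_idx = rng.choice(len(o_names), size=n_cond, p=o_w / o_w.sum())
        rows.extend(
            (pts[i][0], pts[i][1], o_names[j]) for i, j in zip(pt_idx, o_idx)
        )
    return rows


def generate_to_csv(
    spec: SyntheticSpec,
    path: Union[str, Path],
    dictionary: Optional[Sequence[PTEntry]] = None,
) -> ICSRDataset:
    """Generate and write the line-listing CSV; returns the dataset."""
    ds = generate(spec, dictionary)
    write_line_listing(ds, path)
    return ds


# ---------------------------------------------------------------------------
# Reference study fixture: published EudraVigilance aggregates (data lock
# 1 December 2024) for bevacizumab and panitumumab in colorectal cancer.
# ---------------------------------------------------------------------------

_NAMED_RESISTANCE = {"bevacizumab": {"Drug resistance": 82}, "panitumumab": {"Drug resistance": 17}}
_NAMED_INEFFECTIVENESS = {
    "bevacizumab": {
        "Drug ineffective": 768,
        "Therapy partial responder": 179,
        "Therapy non-responder": 136,
        "Therapeutic product effect incomplete": 112,
    },
    "panitumumab": {
        "Drug ineffective": 60,
        "Therapy partial responder": 172,
        "Therapy non-responder": 14,
        "Therapeutic product effect incomplete": 52,
    },
}
_TOTALS = {
    # drug: (n_icsrs, n_adrs, resistance, ineffectiveness,
    #        resistance (fatal, not_recovered), ineffectiveness (fatal, nr))
    "bevacizumab": (59693, 107085, 91, 1414, (8, 2), (92, 89)),
    "panitumumab": (7178, 15051, 18, 328, (1, 0), (4, 12)),
}


def _fixture_pt_weights(drug: str, cond: Condition, total: int) -> dict[str, float]:
    """Integer PT split: published counts for the dominant PTs, the
    remainder spread uniformly (largest remainder, dictionary order) over
    the unnamed PTs of the condition."""
    named = (
        _NAMED_RESISTANCE if cond is Condition.RESISTANCE else _NAMED_INEFFECTIVENESS
    )[drug]
    all_pts = [e.name for e in builtin_dictionary() if e.condition is cond]
    unnamed = [p for p in all_pts if p not in named]
    remainder = total - sum(named.values())
    if remainder < 0:
        raise SpecError(f"{drug}/{cond.value}: named PT counts exceed the total")
    filled = dict(named)
    if unnamed:
        for p, k in zip(unnamed, largest_remainder_allocation(remainder, [1] * len(unnamed))):
            filled[p] = k
    return {p: float(k) for p, k in filled.items() if k > 0 or p in named}


def reference_study_spec(mode: Literal["exact", "sample"] = "exact", seed: int = 0) -> SyntheticSpec:
    """Exact-count spec pinned to the published bevacizumab/panitumumab
    EudraVigilance aggregates.

    Encodes the ICSR/ADR totals (59,693 / 107,085 for bevacizumab; 7,178 /
    15,051 for panitumumab), the resistance (91 / 18) and ineffectiveness
    (1,414 / 328) reaction counts, the published PT splits within each
    condition, and the unfavorable-outcome breakdowns (resistance: 10 of
    which 8 fatal / 1 of 1 fatal; ineffectiveness: 181 of which 92 fatal /
    16 of which 4 fatal).  Splits not published (favorable vs unknown, and
    the residual PT distribution) are filled by the module's deterministic
    defaults.
    """
    drugs: dict[str, DrugBlock] = {}
    for drug, (n_icsrs, n_adrs, n_res, n_ineff, res_unfav, ineff_unfav) in _TOTALS.items():
        n_other = n_adrs - n_res - n_ineff
        drugs[drug] = DrugBlock(
            n_icsrs=n_icsrs,
            n_adrs=n_adrs,
            condition_counts={
                Condition.RESISTANCE.value: n_res,
                Condition.INEFFECTIVENESS.value: n_ineff,
                Condition.OTHER.value: n_other,
            },
            pt_weights={
                Condition.RESISTANCE.value: _fixture_pt_weights(
                    drug, Condition.RESISTANCE, n_res
                ),
                Condition.INEFFECTIVENESS.value: _fixture_pt_weights(
                    drug, Condition.INEFFECTIVENESS, n_ineff
                ),
            },
            outcome_counts={
                Condition.RESISTANCE.value: {
                    o.value: k
                    for o, k in default_outcome_split(n_res, *res_unfav).items()
                },
                Condition.INEFFECTIVENESS.value: {
                    o.value: k
                    for o, k in default_outcome_split(n_ineff, *ineff_unfav).items()
                },
                Condition.OTHER.value: {
                    o.value: k for o, k in default_outcome_split(n_other).items()
                },
            },
        )
    return SyntheticSpec(drugs=drugs, mode=mode, seed=seed)
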