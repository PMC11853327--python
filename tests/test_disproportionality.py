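"""ROR engine: 2×2 construction, estimates, CIs, signal rule, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from pvdispro.disproportionality import (
    ContingencyTable,
    DisproportionalityModel,
    RORResult,
    build_table,
    classify_signal,
    compute_ror,
    run_panel,
)
from pvdispro.errors import LookupError_, UsageError
from pvdispro.io import ADRRecord, DrugAggregate, ICSRDataset, Outcome, aggregate
from pvdispro.meddra import Condition, builtin_dictionary, classify_pt

INEFF = {Condition.INEFFECTIVENESS}
RES = {Condition.RESISTANCE}

positive_cells = st.tuples(*[st.integers(min_value=1, max_value=2000)] * 4)


def _agg(drug, res, ineff, other, n_icsrs=None):
    n_adrs = res + ineff + other
    return DrugAggregate(
        drug=drug,
        n_icsrs=n_icsrs if n_icsrs is not None else max(1, n_adrs // 2),
        n_adrs=n_adrs,
        condition_counts={
            Condition.RESISTANCE: res,
            Condition.INEFFECTIVENESS: ineff,
            Condition.OTHER: other,
        },
    )


class TestBuildTable:
    def test_reference_ineffectiveness_cells(self, reference_aggregates):
        t = build_table(reference_aggregates, "panitumumab", "bevacizumab", INEFF)
        assert (t.a, t.b, t.c, t.d) == (328, 14723, 1414, 105671)

    def test_reference_resistance_cells(self, reference_aggregates):
        t = build_table(reference_aggregates, "panitumumab", "bevacizumab", RES)
        assert (t.a, t.b, t.c, t.d) == (18, 15033, 91, 106994)

    def test_zero_condition_count(self):
        aggs = [_agg("t", 0, 0, 10), _agg("u", 1, 0, 9)]
        t = build_table(aggs, "t", "u", RES)
        assert (t.a, t.b) == (0, 10)

    def test_same_drug_rejected(self, reference_aggregates):
        with pytest.raises(UsageError):
            build_table(reference_aggregates, "panitumumab", "Panitumumab", INEFF)

    def test_missing_drug_rejected(self, reference_aggregates):
        with pytest.raises(LookupError_):
            build_table(reference_aggregates, "panitumumab", "oxaliplatin", INEFF)


class TestComputeROR:
    def test_reference_ineffectiveness_point_and_ci(self):
        r = compute_ror(ContingencyTable(328, 14723, 1414, 105671))
        assert round(r.ror, 4) == 1.6649
        assert round(r.ci_low, 4) == 1.4746
        assert round(r.ci_high, 4) == 1.8797
        assert r.signal

    def test_reference_resistance_ci_spans_one(self):
        r = compute_ror(ContingencyTable(18, 15033, 91, 106994))
        assert r.ror == pytest.approx(1.4078, abs=5e-4)
        assert r.ci_low < 1.0 < r.ci_high
        assert not r.signal

    def test_symmetric_table_is_null(self):
        r = compute_ror(ContingencyTable(7, 100, 7, 100))
        assert r.ror == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(0, 1, 1, 1), (1, 0, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)])
    def test_zero_cell_undefined_not_raising(self, cells):
        r = compute_ror(ContingencyTable(*cells))
        assert not r.defined
        assert not r.signal
        assert r.ror is None and r.ci_low is None and r.ci_high is None

    @given(positive_cells)
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels_oddsratio_and_ci(self, cells):
        a, b, c, d = cells
        r = compute_ror(ContingencyTable(a, b, c, d))
        ref = Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
        assert r.ror == pytest.approx(ref.oddsratio, rel=1e-12)
        lo, hi = ref.oddsratio_confint(0.05)
        # statsmodels uses the exact normal quantile; z=1.96 is the printed
        # convention, so agreement is to ~4 significant figures
        assert r.ci_low == pytest.approx(lo, rel=1e-4)
        assert r.ci_high == pytest.approx(hi, rel=1e-4)
        assert r.p_value == pytest.approx(ref.oddsratio_pvalue(), rel=1e-6, abs=1e-12)

    @given(positive_cells)
    @settings(max_examples=100, deadline=None)
    def test_ci_log_symmetry(self, cells):
        r = compute_ror(ContingencyTable(*cells))
        assert math.log(r.ci_high) - math.log(r.ror) == pytest.approx(
            math.log(r.ror) - math.log(r.ci_low), abs=1e-9
        )

    @given(positive_cells)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_drug_swap(self, cells):
        a, b, c, d = cells
        fwd = compute_ror(ContingencyTable(a, b, c, d))
        rev = compute_ror(ContingencyTable(c, d, a, b))
        assert fwd.ror * rev.ror == pytest.approx(1.0, abs=1e-9)
        assert fwd.ci_low * rev.ci_high == pytest.approx(1.0, abs=1e-9)
        assert fwd.ci_high * rev.ci_low == pytest.approx(1.0, abs=1e-9)

    @given(positive_cells)
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_a_and_narrows_under_scaling(self, cells):
        a, b, c, d = cells
        base = compute_ror(ContingencyTable(a, b, c, d))
        bumped = compute_ror(ContingencyTable(a + 1, b, c, d))
        assert bumped.ror > base.ror
        scaled = compute_ror(ContingencyTable(3 * a, 3 * b, 3 * c, 3 * d))
        assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
        assert scaled.log_se < base.log_se

    def test_se_decreases_in_each_cell(self):
        base = compute_ror(ContingencyTable(10, 20, 30, 40)).log_se
        for bump in [(11, 20, 30, 40), (10, 21, 30, 40), (10, 20, 31, 40), (10, 20, 30, 41)]:
            assert compute_ror(ContingencyTable(*bump)).log_se < base


class TestClassifySignal:
    def _result(self, n_reports, ci_low, defined=True):
        return RORResult(
            table=ContingencyTable(n_reports, 1, 1, 1),
            ror=2.0,
            log_se=0.1,
            ci_low=ci_low,
            ci_high=4.0,
            p_value=0.01,
            n_reports=n_reports,
            signal=False,
            defined=defined,
        )

    def test_rule_requires_min_reports_and_lower_bound(self):
        assert classify_signal(self._result(5, 1.01))
        assert not classify_signal(self._result(4, 2.0))
        assert not classify_signal(self._result(100, 1.0))  # strict inequality
        assert not classify_signal(self._result(100, 2.0, defined=False))

    def test_min_reports_configurable(self):
        assert classify_signal(self._result(3, 1.5), min_reports=3)


class TestRunPanel:
    def _panel_aggs(self):
        aggs = [_agg("target", 5, 100, 9895)]
        for i in range(12):
            aggs.append(_agg(f"cmp{i}", 3, 50 + i, 5000 - i))
        return aggs

    def test_one_result_per_comparator_in_order(self):
        aggs = self._panel_aggs()
        comparators = [f"cmp{i}" for i in range(12)]
        results = run_panel(aggs, "target", comparators, INEFF)
        assert [r.table.comparator for r in results] == comparators

    def test_zero_cell_comparator_isolated(self):
        aggs = [_agg("t", 0, 100, 9900), _agg("c1", 0, 0, 5000), _agg("c2", 0, 50, 4950)]
        res = run_panel(aggs, "t", ["c1", "c2"], INEFF)
        assert not res[0].defined
        assert res[1].defined

    def test_missing_comparators_all_listed(self):
        aggs = self._panel_aggs()
        with pytest.raises(LookupError_, match="ghost1.*ghost2"):
            run_panel(aggs, "target", ["ghost1", "cmp0", "ghost2"], INEFF)

    def test_known_synthetic_cross_product(self):
        # target 100 evaluated of 10,000; comparator 50 of 10,000
        aggs = [_agg("t", 0, 100, 9900), _agg("c", 0, 50, 9950)]
        (r,) = run_panel(aggs, "t", ["c"], INEFF)
        assert r.ror == pytest.approx((100 * 9950) / (9900 * 50), rel=1e-12)


class TestBruteForceOracle:
    """build_table against exhaustive row enumeration on random listings."""

    drugs = ["alpha", "beta"]
    pts = ["Drug resistance", "Drug ineffective", "Treatment failure", "Nausea", "Headache"]

    @given(st.data())
    @settings(max_examples=120, deadline=None)
    def test_cells_and_ror_match_row_tally(self, data):
        n = data.draw(st.integers(min_value=4, max_value=60))
        rows = [
            ADRRecord(
                icsr_id=f"C{data.draw(st.integers(0, 30))}",
                drug=data.draw(st.sampled_from(self.drugs)),
                pt_code=None,
                pt_name=data.draw(st.sampled_from(self.pts)),
                outcome=Outcome.UNKNOWN,
            )
            for _ in range(n)
        ]
        ds = ICSRDataset(records=rows)
        if not {r.drug for r in rows} == set(self.drugs):
            return  # both drugs must appear for a 2×2 table
        conditions = data.draw(
            st.sampled_from([RES, INEFF, RES | INEFF])
        )
        dictionary = builtin_dictionary()
        # independent tally: classify each row from scratch
        def tally(drug):
            rows_d = [r for r in rows if r.drug == drug]
            a = sum(
                1
                for r in rows_d
                if classify_pt(name=r.pt_name, dictionary=dictionary) in conditions
            )
            return a, len(rows_d) - a
        a, b = tally("alpha")
        c, d = tally("beta")
        t = build_table(aggregate(ds), "alpha", "beta", conditions)
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        r = compute_ror(t)
        if 0 not in (a, b, c, d):
            assert r.ror == pytest.approx((a * d) / (b * c), rel=1e-12)
        else:
            assert not r.defined


class TestModelResults:
    def test_fit_matches_functional_surface(self, reference_aggregates):
        model = DisproportionalityModel(
            reference_aggregates, "panitumumab", ["bevacizumab"], INEFF
        )
        res = model.fit()
        direct = compute_ror(
            build_table(reference_aggregates, "panitumumab", "bevacizumab", INEFF)
        )
        assert res.results[0] == direct

    def test_frame_columns_and_values(self, reference_aggregates):
        res = DisproportionalityModel(
            reference_aggregates, "panitumumab", ["bevacizumab"], INEFF
        ).fit()
        df = res.to_frame()
        assert list(df.columns) == [
            "target", "comparator", "condition", "a", "b", "c", "d",
            "ror", "ci_low", "ci_high", "p_value", "n_reports", "signal", "defined",
        ]
        row = df.iloc[0]
        assert row["ror"] == 1.6649
        assert row["ci_low"] == 1.4746
        assert row["ci_high"] == 1.8797
        assert bool(row["signal"])

    def test_summary_mentions_target_and_comparator(self, reference_aggregates):
        res = DisproportionalityModel(
            reference_aggregates, "panitumumab", ["bevacizumab"], INEFF
        ).fit()
        text = res.summary()
        assert "panitumumab" in text and "bevacizumab" in text
        assert "1.6649" in text

    def test_from_dataset_constructor(self, reference_dataset):
        res = DisproportionalityModel.from_dataset(
            reference_dataset, "panitumumab", ["bevacizumab"], INEFF
        ).fit()
        assert round(res.results[0].ror, 4) == 1.6649

    def test_empty_comparator_list_rejected(self, reference_aggregates):
        with pytest.raises(UsageError):
            DisproportionalityModel(reference_aggregates, "panitumumab", [], INEFF)
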