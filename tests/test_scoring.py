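"""Set-agreement metrics, fold-change MAE, PCCs, and rank aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dpbench.scoring import (
    aggregate_ranks,
    f1_score,
    jaccard_index,
    log2fc,
    mae_log2fc,
    pcc_celltype,
    pcc_sample,
    pooled_jaccard_scenario3,
    round2,
    score_scenario1,
    score_scenario2,
    shared_dp,
)
from dpbench.worked_examples import (
    make_dp_table,
    scenario1_worked_scores,
    scenario2_worked_scores,
)

from oracles import jaccard_brute, pearson_direct


class TestF1:
    def test_printed_examples(self):
        assert round2(f1_score(8 / 12, 8 / 16)) == 0.57
        assert round2(f1_score(1 / 12, 1 / 5)) == 0.12

    def test_edges(self):
        assert f1_score(1.0, 1.0) == 1.0
        assert f1_score(0.0, 0.7) == 0.0
        assert f1_score(0.0, 0.0) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_harmonic_closed_form_and_symmetry(self, r, p):
        f = f1_score(r, p)
        assert f == f1_score(p, r)
        if r + p > 0:
            assert f == pytest.approx(2 * p * r / (p + r))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)


class TestJaccard:
    def test_printed_example(self):
        assert round2(jaccard_index(set(range(8)), set(range(15)))) == 0.53

    def test_edges(self):
        assert jaccard_index({"a"}, {"a"}) == 1.0
        assert jaccard_index(set(), {"a", "b"}) == 0.0
        assert jaccard_index(set(), set()) is None

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index({"a", "z"}, {"a", "b"})

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(200):
            a = set(rng.integers(0, 20, rng.integers(0, 10)).tolist())
            b = set(rng.integers(0, 20, rng.integers(1, 10)).tolist())
            got = jaccard_index(a & b, a | b)
            assert got == pytest.approx(jaccard_brute(a, b))


class TestScenario1:
    def test_worked_example_scores(self):
        scores = scenario1_worked_scores().set_index(["method", "mode"])
        expected = {
            ("BayesPrism", "conservative"): (0.50, 0.67, 0.57),
            ("BayesPrism", "permissive"): (0.69, 0.67, 0.68),
            ("ReCIDE", "conservative"): (0.50, 0.58, 0.54),
            ("ReCIDE", "permissive"): (0.71, 0.58, 0.64),
            ("MuSiC", "conservative"): (0.20, 0.08, 0.12),
            ("MuSiC", "permissive"): (0.40, 0.08, 0.14),
        }
        for key, (prec, rec, f1) in expected.items():
            row = scores.loc[key]
            assert round2(row["precision"]) == prec
            assert round2(row["recall"]) == rec
            assert round2(row["f1"]) == f1

    def test_perfect_agreement(self):
        calls = {f"t{i}": (True, True, 1) for i in range(5)}
        tab = make_dp_table(calls)
        for mode in ("conservative", "permissive"):
            rep = score_scenario1(tab, tab, mode)
            assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_empty_reference_flagged(self):
        deconv = make_dp_table({"a": (True, True, 1)})
        scrna = make_dp_table({"a": (True, False, 1)})
        rep = score_scenario1(deconv, scrna)
        assert rep.recall is None and any("empty_reference" in f for f in rep.flags)

    def test_opposite_direction_not_validated(self):
        deconv = make_dp_table({"a": (True, True, 1)})
        scrna = make_dp_table({"a": (True, True, -1)})
        rep = score_scenario1(deconv, scrna, "permissive")
        assert rep.precision == 0.0

    def test_direction_requirement_can_be_disabled(self):
        deconv = make_dp_table({"a": (True, True, 1)})
        scrna = make_dp_table({"a": (True, True, -1)})
        rep = score_scenario1(deconv, scrna, "conservative", require_direction=False)
        assert rep.precision == 1.0


class TestScenario2:
    def test_worked_example_scores(self):
        scores = scenario2_worked_scores().set_index(["method", "mode"])
        expected = {
            ("ReCIDE", "conservative"): (0.53, 0.63, 0.33, 0.43),
            ("ReCIDE", "permissive"): (0.73, 0.64, 0.50, 0.56),
            ("BayesPrism", "conservative"): (0.38, 0.50, 0.17, 0.25),
            ("BayesPrism", "permissive"): (0.56, 0.56, 0.33, 0.42),
            ("CIBERSORT", "conservative"): (0.25, 0.00, 0.00, 0.00),
            ("CIBERSORT", "permissive"): (0.50, 0.00, 0.00, 0.00),
        }
        for key, (jac, prec, rec, f1) in expected.items():
            row = scores.loc[key]
            assert round2(row["jaccard"]) == jac
            assert round2(row["precision"]) == prec
            assert round2(row["recall"]) == rec
            assert round2(row["f1"]) == f1

    def test_identical_tables_conservative_jaccard_one(self):
        tab = make_dp_table({f"t{i}": (True, i < 3, 1) for i in range(6)})
        shared, union = shared_dp(tab, tab, "conservative")
        assert jaccard_index(shared.keys(), union) == 1.0

    def test_opposite_directions_never_shared(self):
        a = make_dp_table({f"t{i}": (True, True, 1) for i in range(4)})
        b = make_dp_table({f"t{i}": (True, True, -1) for i in range(4)})
        for mode in ("conservative", "permissive"):
            shared, union = shared_dp(a, b, mode)
            assert shared == {} and len(union) == 4

    def test_untested_in_other_cohort_not_shared(self):
        a = make_dp_table({"t": (True, True, 1)})
        b = make_dp_table({"t": (False, False, 0)})
        shared, union = shared_dp(a, b, "permissive")
        assert shared == {} and union == {"t"}

    def test_empty_shared_reports_f1_zero(self):
        a = make_dp_table({"t": (True, True, 1)})
        b = make_dp_table({"t": (True, False, -1)})
        scrna = make_dp_table({"t": (True, True, 1)})
        shared, union = shared_dp(a, b, "conservative")
        rep = score_scenario2(shared, union, scrna, "conservative")
        assert rep.f1 == 0.0 and any("empty_shared" in f for f in rep.flags)


STATES = [  # (tested, significant, direction) single-table cell-type states
    (False, False, 0),
    (True, False, 1),
    (True, False, -1),
    (True, False, 0),
    (True, True, 1),
    (True, True, -1),
]


class TestModeMonotonicity:
    """Permissive criteria can only add agreement, never remove it.

    Set membership under both modes is decided per cell type from that
    type's (deconvolution, scRNA) or (cohort A, cohort B) states alone, so
    exhaustive enumeration of joint single-type states covers all
    multi-type configurations; random multi-type configurations are
    checked on top.
    """

    def test_scenario1_precision_exhaustive_single_type(self):
        for s_dec, s_ref in itertools.product(STATES, STATES):
            deconv = make_dp_table({"t": s_dec})
            scrna = make_dp_table({"t": s_ref})
            cons = score_scenario1(deconv, scrna, "conservative")
            perm = score_scenario1(deconv, scrna, "permissive")
            if cons.precision is not None and perm.precision is not None:
                assert perm.precision >= cons.precision

    def test_scenario2_shared_exhaustive_single_type(self):
        for s_a, s_b in itertools.product(STATES, STATES):
            a = make_dp_table({"t": s_a})
            b = make_dp_table({"t": s_b})
            shared_c, union_c = shared_dp(a, b, "conservative")
            shared_p, union_p = shared_dp(a, b, "permissive")
            assert set(shared_c) <= set(shared_p)
            assert union_c == union_p

    def test_random_six_type_configurations(self, rng):
        for _ in range(300):
            names = [f"t{i}" for i in range(6)]
            tab = lambda: make_dp_table({n: STATES[rng.integers(len(STATES))] for n in names})
            a, b, ref = tab(), tab(), tab()
            shared_c, union_c = shared_dp(a, b, "conservative")
            shared_p, union_p = shared_dp(a, b, "permissive")
            assert set(shared_c) <= set(shared_p)
            jc = jaccard_index(shared_c.keys(), union_c)
            jp = jaccard_index(shared_p.keys(), union_p)
            if jc is not None and jp is not None:
                assert jp >= jc
            cons = score_scenario1(a, ref, "conservative")
            perm = score_scenario1(a, ref, "permissive")
            if cons.precision is not None:
                assert perm.precision >= cons.precision


class TestScenario3:
    @staticmethod
    def pr_table(calls):
        rows = []
        for ct, (tested, is_pr, sign) in calls.items():
            rows.append(
                {
                    "cell_type": ct,
                    "beta": 0.5 * sign if tested else np.nan,
                    "hr": np.exp(0.5 * sign) if tested else np.nan,
                    "neg_ln_hr": -0.5 * sign if tested else np.nan,
                    "p_value": 0.001 if is_pr else 0.5,
                    "q_value": 0.01 if is_pr else 0.5,
                    "n_samples": 100,
                    "n_events": 40,
                    "tested": tested,
                    "is_pr": is_pr,
                    "reason": "",
                }
            )
        return pd.DataFrame(rows)

    def test_pooled_arithmetic(self):
        # entity 1: shared 1 of union 2; entity 2: shared 1 of union 1
        e1_a = self.pr_table({"x": (True, True, 1), "y": (True, True, 1)})
        e1_b = self.pr_table({"x": (True, True, 1), "y": (True, False, -1)})
        e2_a = self.pr_table({"z": (True, True, -1)})
        e2_b = self.pr_table({"z": (True, True, -1)})
        jac, _ = pooled_jaccard_scenario3([(e1_a, e1_b), (e2_a, e2_b)], "conservative")
        assert jac == pytest.approx(2 / 3)

    def test_all_empty_undefined_with_warning(self):
        t = self.pr_table({"x": (True, False, 1)})
        with pytest.warns(UserWarning):
            jac, _ = pooled_jaccard_scenario3([(t, t)], "conservative")
        assert jac is None

    def test_identical_sets_give_one(self):
        t = self.pr_table({"x": (True, True, 1), "y": (True, True, -1)})
        jac, _ = pooled_jaccard_scenario3([(t, t)], "conservative")
        assert jac == 1.0


class TestFoldChange:
    def test_examples(self):
        assert log2fc(0.2, 0.1, eps=0) == pytest.approx(1.0)
        assert log2fc(0.15, 0.15) == 0.0
        assert log2fc(0.3, 0.1, eps=0) == pytest.approx(np.log2(3))
        assert np.isnan(log2fc(0.0, 0.0, eps=0))

    def test_mae(self):
        a = pd.Series({"x": 1.0, "y": 2.0, "z": 0.0})
        assert mae_log2fc(a, a) == 0.0
        b = pd.Series({"x": 1.5, "y": 2.5, "z": 1.0})
        assert mae_log2fc(a, b) == 0.5
        assert mae_log2fc(a[["x"]], b[["x"]]) == 0.5
        assert mae_log2fc(a[[]], b[[]]) is None


class TestPCC:
    def test_identity_and_affine(self):
        v = [0.5, 0.3, 0.2]
        assert pcc_sample(v, v) == pytest.approx(1.0)
        w = [2 * x + 1 for x in v]
        assert pcc_sample(w, v) == pytest.approx(1.0)

    def test_hand_computed_reversal(self):
        assert pcc_sample([0.5, 0.3, 0.2], [0.2, 0.3, 0.5]) == pytest.approx(-0.9286, abs=5e-5)

    def test_constant_truth_undefined(self):
        assert np.isnan(pcc_celltype([0.1, 0.2, 0.3], [0.5, 0.5, 0.5]))

    def test_symmetric_reversal_sign_flip(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        assert pcc_celltype(v[::-1], v) == pytest.approx(pearson_direct(v[::-1], v))

    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=12),
        st.lists(st.floats(0, 1), min_size=3, max_size=12),
    )
    def test_matches_direct_formula(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        got = pcc_sample(a, b)
        want = pearson_direct(a, b)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


class TestRankAggregation:
    def test_dominating_method(self):
        table = pd.DataFrame({"m1": [0.9, 0.5], "m2": [0.8, 0.4]}, index=["best", "worst"]).T
        # build: methods x metrics
        table = pd.DataFrame(
            {"metric1": [0.9, 0.5, 0.3], "metric2": [0.8, 0.4, 0.2]},
            index=["best", "mid", "worst"],
        )
        ranks = aggregate_ranks(table)
        assert ranks["best"] == 1.0 and ranks["worst"] == 3.0

    def test_mean_of_ranks(self):
        table = pd.DataFrame(
            {"a": [0.9, 0.1], "b": [0.9, 0.1], "c": [0.1, 0.9]},
            index=["m1", "m2"],
        )
        ranks = aggregate_ranks(table)
        assert ranks["m1"] == pytest.approx((1 + 1 + 2) / 3, abs=0.005)

    def test_ties_get_mean_rank(self):
        table = pd.DataFrame({"a": [0.5, 0.5, 0.1]}, index=["m1", "m2", "m3"])
        ranks = aggregate_ranks(table)
        assert ranks["m1"] == ranks["m2"] == 1.5

    def test_undefined_ranks_last(self):
        table = pd.DataFrame({"a": [np.nan, 0.2, 0.9]}, index=["m1", "m2", "m3"])
        ranks = aggregate_ranks(table)
        assert ranks["m1"] == 3.0

    def test_lower_is_better_metric(self):
        table = pd.DataFrame({"err": [0.1, 0.9]}, index=["good", "bad"])
        ranks = aggregate_ranks(table, higher_is_better={"err": False})
        assert ranks["good"] == 1.0


def test_round2_half_up():
    assert round2(0.125) == 0.13
    assert round2(0.434) == 0.43
    assert round2(None) is None
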