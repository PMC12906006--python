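"""HR-matrix assembly, cross-entity sign consistency, indicators."""

import numpy as np
import pandas as pd
import pytest

from dpbench.io import CohortBundle, ProportionMatrix, SurvivalTable
from dpbench.pancancer import (
    HRMatrix,
    IndicatorSpec,
    build_hr_matrix,
    consistency_test,
    evaluate_indicator,
    indicator_score,
)
from dpbench.pr import CoxConfig
from dpbench.synthetic import SyntheticTruth, simulate_cohort_pair, simulate_survival

from oracles import exact_signed_rank_one_sided_p


def hrm_from(values: dict) -> HRMatrix:
    df = pd.DataFrame(values).T  # entities x subtypes
    return HRMatrix(values=df, missing_reason=df.isna().astype(str))


class TestConsistencyTest:
    def test_all_negative_ten_entities_exact_p(self, rng):
        vals = -np.abs(rng.normal(0.5, 0.2, 10))
        hrm = hrm_from({f"e{i}": {"sub": vals[i]} for i in range(10)})
        out = consistency_test(hrm).set_index("subtype").loc["sub"]
        assert out["direction"] == -1
        assert out["p_value"] == pytest.approx(1 / 2 ** 10)
        assert out["p_value"] == pytest.approx(
            exact_signed_rank_one_sided_p(vals, "less")
        )

    def test_matches_enumeration_on_mixed_signs(self, rng):
        for _ in range(10):
            vals = rng.normal(0.2, 1.0, 8)
            while len(np.unique(np.abs(vals))) < 8 or (vals == 0).any():
                vals = rng.normal(0.2, 1.0, 8)
            med = np.median(vals)
            if med == 0:
                continue
            side = "greater" if med > 0 else "less"
            hrm = hrm_from({f"e{i}": {"sub": vals[i]} for i in range(8)})
            out = consistency_test(hrm).set_index("subtype").loc["sub"]
            assert out["p_value"] == pytest.approx(
                exact_signed_rank_one_sided_p(vals, side)
            )

    def test_single_value_one_sided_half(self):
        hrm = hrm_from({"e0": {"sub": 0.4}})
        out = consistency_test(hrm, entity_floor=1).set_index("subtype").loc["sub"]
        assert out["p_value"] == pytest.approx(0.5)

    def test_below_entity_floor_untested(self):
        hrm = hrm_from({f"e{i}": {"sub": -0.5} for i in range(4)})
        out = consistency_test(hrm, entity_floor=5).set_index("subtype").loc["sub"]
        assert not out["tested"] and out["note"] == "below_entity_floor"

    def test_null_rarely_significant(self, rng):
        # symmetric values around 0: the one-sided test (post-hoc side)
        # behaves like a two-sided test at doubled level; BH across one
        # subtype leaves q = p.
        n_sig = 0
        reps = 200
        for _ in range(reps):
            vals = rng.normal(0.0, 1.0, 10)
            hrm = hrm_from({f"e{i}": {"sub": vals[i]} for i in range(10)})
            out = consistency_test(hrm).set_index("subtype").loc["sub"]
            n_sig += bool(out["consistent"])
        # one-sided with data-chosen side ~ two-sided at alpha -> expect ~2*0.05
        assert n_sig / reps <= 0.10 + 3 * np.sqrt(0.1 * 0.9 / reps)

    def test_two_sided_option(self, rng):
        vals = -np.abs(rng.normal(0.5, 0.2, 10))
        hrm = hrm_from({f"e{i}": {"sub": vals[i]} for i in range(10)})
        one = consistency_test(hrm).set_index("subtype").loc["sub", "p_value"]
        two = consistency_test(hrm, two_sided=True).set_index("subtype").loc["sub", "p_value"]
        assert two == pytest.approx(2 * one)


class TestBuildHRMatrix:
    @staticmethod
    def entity(seed, n=150, beta=1.0, low_events=False):
        truth = SyntheticTruth(
            cell_types=["ct1", "ct2", "ct3", "ct4", "ct5"],
            base_alpha=[5, 4, 3, 2, 2],
            pr_betas={"ct1": beta},
            seed=seed,
        )
        a, _, _ = simulate_cohort_pair(truth, n_per_condition=n // 2, cohort_names=(f"e{seed}", "unused"))
        target = (8, 10) if low_events else None
        surv = simulate_survival(a.proportions, truth, target_events=target)
        return CohortBundle(name=f"e{seed}", proportions=a.proportions, survival=surv)

    def test_planted_adverse_type_column_negative(self):
        cohorts = [self.entity(s) for s in (1, 2, 3)]
        hrm = build_hr_matrix(cohorts)
        assert (hrm.values["ct1"].dropna() < 0).all()  # adverse => -ln(HR) < 0

    def test_low_event_entity_missing_with_reason(self):
        cohorts = [self.entity(1), self.entity(2, low_events=True)]
        hrm = build_hr_matrix(cohorts)
        assert hrm.values.loc["e2"].isna().all()
        assert (hrm.missing_reason.loc["e2"] == "insufficient_events").all()

    def test_cohort_order_invariance(self):
        c = [self.entity(s) for s in (1, 2, 3)]
        h1 = build_hr_matrix(c)
        h2 = build_hr_matrix(c[::-1])
        pd.testing.assert_frame_equal(h1.values, h2.values)

    def test_clipping_is_display_only(self):
        hrm = hrm_from({"e0": {"sub": 2.5}, "e1": {"sub": -3.0}})
        assert hrm.values["sub"].abs().max() == 3.0
        assert hrm.clipped()["sub"].abs().max() == 1.0

    def test_missing_survival_rejected(self):
        c = self.entity(1)
        c.survival = None
        with pytest.raises(ValueError, match="survival"):
            build_hr_matrix([c])


class TestIndicator:
    @staticmethod
    def pm(values, names=("classical_mono", "mCAF", "other")):
        ids = [f"s{i}" for i in range(len(values))]
        df = pd.DataFrame(values, index=ids, columns=names)
        return ProportionMatrix(df, {i: "all" for i in ids})

    def test_sum_definition(self):
        pm = self.pm([[0.03, 0.02, 0.95]])
        score = indicator_score(pm, IndicatorSpec())
        assert score.iloc[0] == pytest.approx(0.05)

    def test_single_subtype_identity(self):
        pm = self.pm([[0.03, 0.02, 0.95], [0.1, 0.2, 0.7]])
        score = indicator_score(pm, IndicatorSpec(subtype_names=["mCAF"]))
        assert score.tolist() == pytest.approx([0.02, 0.2])

    def test_bounds(self, rng):
        vals = rng.dirichlet([2, 2, 2], 50)
        score = indicator_score(self.pm(vals), IndicatorSpec())
        assert ((score >= 0) & (score <= 1)).all()

    def test_missing_subtype_lists_available(self):
        pm = self.pm([[0.5, 0.3, 0.2]], names=("a", "b", "c"))
        with pytest.raises(KeyError, match="available"):
            indicator_score(pm, IndicatorSpec())


class TestEvaluateIndicator:
    @staticmethod
    def cohort(rng, n=300, beta=1.0):
        vals = rng.dirichlet([2, 2, 6], n)
        ids = [f"s{i}" for i in range(n)]
        pm = ProportionMatrix(
            pd.DataFrame(vals, index=ids, columns=["classical_mono", "mCAF", "other"]),
            {i: "all" for i in ids},
        )
        score = indicator_score(pm, IndicatorSpec())
        z = (score - score.mean()) / score.std(ddof=0)
        t = rng.exponential(1.0 / (0.1 * np.exp(beta * z)))
        c = rng.uniform(0, 2 * t.mean(), n)
        surv = SurvivalTable(
            pd.DataFrame(
                {"sample_id": ids, "time": np.minimum(t, c), "event": (t <= c).astype(int)}
            )
        )
        return score, surv

    def test_planted_indicator_recovered(self, rng):
        hits = 0
        for _ in range(30):
            score, surv = self.cohort(rng)
            ev = evaluate_indicator(score, surv)
            hits += ev.beta > 0 and ev.p_value < 0.05
        assert hits >= 27

    def test_median_split_halves_with_ties_low(self):
        k = 50
        score = pd.Series(np.arange(2 * k, dtype=float), index=[f"s{i}" for i in range(2 * k)])
        surv = SurvivalTable(
            pd.DataFrame(
                {
                    "sample_id": score.index,
                    "time": np.linspace(1, 10, 2 * k),
                    "event": [1] * (2 * k),
                }
            )
        )
        ev = evaluate_indicator(score, surv)
        counts = ev.groups.value_counts()
        assert counts["low"] == k and counts["high"] == k
        assert set(ev.km_data.columns) == {"sample_id", "group", "time", "event"}

    def test_constant_score_rejected(self):
        score = pd.Series([0.5] * 30, index=[f"s{i}" for i in range(30)])
        surv = SurvivalTable(
            pd.DataFrame({"sample_id": score.index, "time": range(1, 31), "event": [1] * 30})
        )
        with pytest.raises(ValueError, match="constant"):
            evaluate_indicator(score, surv)
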