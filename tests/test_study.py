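"""Statistics primitives, aggregation, ROC/classification and the study model."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methylclash import (MethylClashSummary, MethylationStudy,
                         aggregate_enzyme, classify_protection,
                         make_probe_environment, make_synthetic_study,
                         normality_test, rank_sum_test, roc_curve)
from methylclash.clash import ClashParams

from oracles import exact_ranksum_p, pair_counting_auc


class TestRankSum:
    def test_identical_groups(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_small_case(self):
        assert rank_sum_test([1, 2], [10, 11]) == pytest.approx(
            exact_ranksum_p([1, 2], [10, 11]))
        # complete separation of 2 vs 2: p = 2/C(4,2) = 1/3
        assert rank_sum_test([1, 2], [10, 11]) == pytest.approx(1 / 3)

    def test_matches_enumeration_for_all_small_splits(self):
        """Exact path equals full enumeration for every two-group split of
        up to 8 distinct values."""
        for n_total in (4, 5, 6, 7, 8):
            values = list(range(1, n_total + 1))
            for m in range(2, n_total - 1):
                for combo in itertools.combinations(values, m):
                    a = list(combo)
                    b = [v for v in values if v not in combo]
                    assert rank_sum_test(a, b) == pytest.approx(
                        exact_ranksum_p(a, b), abs=1e-12), (a, b)

    def test_degenerate_all_equal(self):
        assert rank_sum_test([5, 5, 5], [5, 5]) == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1], [2, 3])


class TestNormality:
    def test_uniform_p_under_null(self):
        """Under H0 (normal data) the p-values are uniform across seeds."""
        from scipy import stats
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ps.append(normality_test(rng.normal(size=50)))
        ks_p = stats.kstest(ps, "uniform").pvalue
        assert ks_p > 0.01

    def test_power_against_exponential(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            if normality_test(rng.exponential(size=50)) < 0.05:
                rejections += 1
        assert rejections >= 160  # >= 80 percent power

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_test([3.0, 3.0, 3.0, 3.0])


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_curve([0.1, 0.2, 0.9, 1.4], [False, False, True, True])
        assert auc == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5  # independent of the scores
        _, auc = roc_curve(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_matches_pair_counting_oracle(self):
        scores = [0.5, 1.2, 1.2, 0.3, 2.0, 0.9]
        labels = [False, True, False, False, True, True]
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        _, auc1 = roc_curve(scores, labels)
        _, auc2 = roc_curve(np.exp(3 * scores) + 7, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [True, True, True])


class TestClassify:
    def test_default_thresholds_strict(self):
        assert classify_protection(1.5, "max_delta_d") == "protective"
        assert classify_protection(0.0, "max_delta_d") == "tolerated"
        assert classify_protection(1.1, "max_delta_d") == "tolerated"  # strict >
        assert classify_protection(47.7, "sum_delta_V") == "tolerated"
        assert classify_protection(47.71, "sum_delta_V") == "protective"

    def test_unknown_measure_without_threshold(self):
        with pytest.raises(ValueError):
            classify_protection(1.0, "n_contacts")
        assert classify_protection(9, "n_contacts", threshold=5) == "protective"


class TestAggregate:
    def _summary(self, dd):
        s = MethylClashSummary()
        s.max_delta_d = dd
        s.sum_delta_d = 2 * dd
        s.max_delta_V = 3 * dd
        s.sum_delta_V = 4 * dd
        s.n_contacts = 2
        s.n_residues = 1
        return s

    def test_single_summary_identity(self):
        score, = aggregate_enzyme([self._summary(1.0)], enzyme="E")
        assert score.values["max_delta_d"] == 1.0

    def test_mean_over_copies(self):
        score, = aggregate_enzyme([self._summary(1.0), self._summary(2.0)],
                                  copies=[1, 2], enzyme="E")
        assert score.values["max_delta_d"] == pytest.approx(1.5)
        assert score.n_asu_copies == 2

    def test_strands_separate(self):
        scores = aggregate_enzyme([self._summary(1.0), self._summary(2.0)],
                                  policy="mean_over_copies_strands_separate",
                                  strands=["A", "B"], enzyme="E")
        assert len(scores) == 2
        assert {s.strand for s in scores} == {"A", "B"}

    def test_aggregate_within_bounds(self):
        score, = aggregate_enzyme([self._summary(x) for x in (0.5, 1.5, 2.5)])
        assert 0.5 <= score.values["max_delta_d"] <= 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_enzyme([])


@pytest.fixture(scope="module")
def fitted_study():
    manifest, complexes = make_synthetic_study(seed=2)
    study = MethylationStudy.from_complexes(manifest, complexes)
    return study, study.fit()


class TestStudyModel:
    def test_groups_separate(self, fitted_study):
        """Protective methylation clashes significantly harder than tolerated
        methylation at the published study size."""
        _, results = fitted_study
        tests = results.group_tests
        sub = tests[(tests.group_a == "cognate_protective")
                    & (tests.group_b == "noncognate_tolerated")]
        for m in ("max_delta_d", "sum_delta_V"):
            assert sub[sub.measure == m].p_value.iloc[0] < 5e-4

    def test_classifier_operating_points(self, fitted_study):
        """Threshold classifiers recover the protective/tolerated ordering."""
        _, results = fitted_study
        op = results.operating_point("max_delta_d")
        assert op["tp_rate"] > 0.8
        assert op["fp_rate"] < 0.2
        opv = results.operating_point("sum_delta_V")
        assert opv["tp_rate"] > 0.6
        assert opv["fp_rate"] < 0.2

    def test_auc_range(self, fitted_study):
        _, results = fitted_study
        for m in ("max_delta_d", "sum_delta_V"):
            assert 0.8 <= results.auc(m) <= 1.0

    def test_scores_monotone_in_epsilon(self, fitted_study):
        study, _ = fitted_study
        s1 = study.scores(0.1).set_index("instance_id")
        s4 = study.scores(0.4).set_index("instance_id")
        for m in ("max_delta_d", "sum_delta_d", "sum_delta_V", "n_contacts"):
            assert (s4[m] <= s1[m] + 1e-12).all()

    def test_allowance_sweep_stability(self, fitted_study):
        study, _ = fitted_study
        sweep = study.allowance_sweep(epsilons=(0.1, 0.2, 0.3, 0.4),
                                      measures=("max_delta_d", "sum_delta_V"))
        assert len(sweep) == 8
        assert (sweep.p_value < 0.01).all()  # separation survives the sweep

    def test_single_epsilon_sweep_equals_fit(self, fitted_study):
        study, _ = fitted_study
        sweep = study.allowance_sweep(epsilons=(0.1,), measures=("max_delta_d",))
        enzymes = study.enzyme_scores(0.1)
        a = enzymes[enzymes.group == "cognate_protective"]["max_delta_d"]
        b = enzymes[enzymes.group == "noncognate_tolerated"]["max_delta_d"]
        assert sweep.p_value.iloc[0] == pytest.approx(rank_sum_test(a, b))

    def test_sweep_p_rises_when_clashes_vanish(self):
        """If one group's clashes all vanish below eps=0.4 the comparison
        degrades toward p = 1."""
        rows_m, cxs = [], {}
        for i in range(10):
            group = "cognate_protective" if i < 5 else "noncognate_tolerated"
            # group A: small clashes that vanish by eps=0.4; group B: none at
            # all -- by 0.4 the two groups are indistinguishable
            dd = 0.25 if i < 5 else -0.5
            env = make_probe_environment([("C", 2.0 + 2.0 - 0.1 - dd)],
                                         "m5C", seed=100 + i,
                                         structure_id=f"S{i}")
            cxs[f"S{i}"] = env.complex
            rows_m.append({"enzyme": f"E{i}", "structure_id": f"S{i}",
                           "chain": "A", "resid": env.site[1],
                           "methyl_type": "m5C", "orientation": "trans",
                           "group": group})
        study = MethylationStudy.from_complexes(
            pd.DataFrame(rows_m), cxs, ClashParams(include_dna=False))
        sweep = study.allowance_sweep(epsilons=(0.1, 0.4),
                                      measures=("max_delta_d",))
        p_low = sweep[sweep.epsilon == 0.1].p_value.iloc[0]
        p_high = sweep[sweep.epsilon == 0.4].p_value.iloc[0]
        assert p_low < 0.05
        assert p_high == pytest.approx(1.0)

    def test_group_labels_never_inferred(self, fitted_study):
        study, _ = fitted_study
        assert set(study.instances.group.unique()) <= {
            "cognate_protective", "noncognate_tolerated",
            "noncognate_protective", "unknown"}

    def test_summary_renders(self, fitted_study):
        _, results = fitted_study
        text = results.summary()
        assert "Wilcoxon" in text and "AUC" in text
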