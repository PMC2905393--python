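import numpy as np
import pandas as pd
import pytest

from stresschip.expression_response import (
    ExpressionTimeCourse,
    ResponseParams,
    call_dependent,
    call_responsive,
    classify_dependency,
    permutation_fdr,
    permuted_d_matrix,
    response_rank,
    sam_d,
    time_to_fold,
)

TIMES = (0, 10, 30, 60, 120)


def make_course(profiles: dict[str, dict[int, float]], noise_sd=0.0,
                n_rep=3, seed=0, strain="wt") -> ExpressionTimeCourse:
    """Course from per-gene mean log2 profiles plus replicate noise."""
    rng = np.random.default_rng(seed)
    genes = list(profiles)
    cols = {}
    for t in TIMES:
        for r in range(n_rep):
            cols[(t, r)] = np.array(
                [profiles[g].get(t, 0.0) for g in genes]
            ) + rng.normal(0, noise_sd, len(genes))
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["time_min", "replicate"])
    return ExpressionTimeCourse(df, strain)


class TestSamD:
    def test_identical_groups_zero(self):
        a = np.array([[1.0, 1.0, 1.0]])
        assert sam_d(a, a.copy(), s0=0.5)[0] == pytest.approx(0.0)

    def test_direct_formula(self):
        # means 3 and 1, pooled SE 0.5, s0 0.5 -> d = 2/(0.5+0.5) = 2
        a = np.array([[3.0 - 0.6123724357, 3.0, 3.0 + 0.6123724357]])
        b = np.array([[1.0 - 0.6123724357, 1.0, 1.0 + 0.6123724357]])
        d = sam_d(a, b, s0=0.5)
        assert d[0] == pytest.approx(2.0, rel=1e-6)

    def test_scaling_behavior_documented(self):
        # scaling data by c scales mean diff and s by c, so d changes unless
        # s0 is rescaled too
        rng = np.random.default_rng(1)
        a = rng.normal(2, 0.3, size=(5, 3))
        b = rng.normal(0, 0.3, size=(5, 3))
        d1 = sam_d(a, b, s0=0.2)
        d2 = sam_d(3 * a, 3 * b, s0=0.2)
        d3 = sam_d(3 * a, 3 * b, s0=0.6)
        assert not np.allclose(d1, d2)
        assert np.allclose(d1, d3)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            sam_d(np.array([[1.0]]), np.array([[1.0, 2.0]]), 0.1)


class TestPermutationFdr:
    def test_null_data_calibrated(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(300, 3))
        b = rng.normal(0, 1, size=(300, 3))
        d = sam_d(a, b, 0.2)
        dp = permuted_d_matrix(a, b, 0.2, 100, rng)
        q = permutation_fdr(d, dp)
        assert np.mean(q < 0.05) <= 0.05 + 0.02

    def test_single_strong_gene_has_small_q(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.2, size=(200, 3))
        b = rng.normal(0, 0.2, size=(200, 3))
        a[0] += 10.0
        d = sam_d(a, b, 0.1)
        dp = permuted_d_matrix(a, b, 0.1, 100, rng)
        q = permutation_fdr(d, dp)
        assert q[0] < 0.05
        assert q[0] == q.min()

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(50, 3))
        b = rng.normal(0, 1, size=(50, 3))
        a[:10] += 3
        d = sam_d(a, b, 0.2)
        q = permutation_fdr(d, permuted_d_matrix(a, b, 0.2, 50, rng))
        order = np.argsort(-np.abs(d))
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallResponsive:
    def test_two_consecutive_timepoints_induced(self):
        course = make_course(
            {"hit": {10: 0.2, 30: 1.4, 60: 1.4, 120: 0.3},
             **{f"null{i}": {} for i in range(40)}},
            noise_sd=0.15,
        )
        status = call_responsive(course)
        assert status["hit"] == "induced"

    def test_single_timepoint_spike_unresponsive(self):
        course = make_course(
            {"spike": {30: 1.6}, **{f"null{i}": {} for i in range(40)}},
            noise_sd=0.15,
        )
        assert call_responsive(course)["spike"] == "unresponsive"

    def test_repressed_direction(self):
        course = make_course(
            {"down": {30: -1.5, 60: -1.5}, **{f"null{i}": {} for i in range(40)}},
            noise_sd=0.15,
        )
        assert call_responsive(course)["down"] == "repressed"

    def test_all_zero_ratios_unresponsive(self):
        course = make_course({f"g{i}": {} for i in range(20)}, noise_sd=0.0)
        assert (call_responsive(course) == "unresponsive").all()

    def test_monotone_in_fold_change_threshold(self):
        course = make_course(
            {f"g{i}": {30: 0.5 + 0.1 * i, 60: 0.5 + 0.1 * i} for i in range(30)},
            noise_sd=0.2,
        )
        loose = call_responsive(course, ResponseParams(fold_change_min=2.0))
        tight = call_responsive(course, ResponseParams(fold_change_min=3.0))
        assert set(tight[tight != "unresponsive"].index) <= set(
            loose[loose != "unresponsive"].index
        )

    def test_missing_timepoint_named_in_error(self):
        course = make_course({"g": {}})
        course.data = course.data.drop(columns=[60], level=0)
        with pytest.raises(ValueError, match="60"):
            call_responsive(course)


class TestCallDependent:
    def test_identical_strains_empty(self):
        wt = make_course({f"g{i}": {30: 1.5, 60: 1.5} for i in range(20)},
                         noise_sd=0.1, seed=5)
        mut = make_course({f"g{i}": {30: 1.5, 60: 1.5} for i in range(20)},
                          noise_sd=0.1, seed=6, strain="mut")
        assert call_dependent(mut, wt) == set()

    def test_ablated_response_detected(self):
        profiles_wt = {"dep": {10: 1.5, 30: 2.5, 60: 2.5, 120: 2.0},
                       **{f"null{i}": {} for i in range(30)}}
        profiles_mut = {"dep": {10: 0.2, 30: 0.3, 60: 0.3, 120: 0.2},
                        **{f"null{i}": {} for i in range(30)}}
        wt = make_course(profiles_wt, noise_sd=0.15, seed=7)
        mut = make_course(profiles_mut, noise_sd=0.15, seed=8, strain="mut")
        assert "dep" in call_dependent(mut, wt)

    def test_gene_mismatch_rejected(self):
        wt = make_course({"a": {}})
        mut = make_course({"b": {}}, strain="mut")
        with pytest.raises(ValueError):
            call_dependent(mut, wt)


class TestClassifyDependency:
    def test_labels(self):
        dep = classify_dependency({"a", "b"}, {"b", "c"}, ["a", "b", "c", "d"])
        assert dep["a"] == "atf1_specific"
        assert dep["b"] == "both"
        assert dep["c"] == "pcr1_specific"
        assert dep["d"] == "independent"

    def test_synthetic_recovery(self, pipeline_result):
        assert pipeline_result.metrics["dependency_balanced_accuracy"] >= 0.9


class TestTimeToFold:
    def test_exact_crossing_at_sample(self):
        assert time_to_fold({0: 0.0, 10: 2.0, 30: 2.5}) == pytest.approx(10.0)

    def test_interpolated_crossing(self):
        # 0 at t=0, 3.0 at t=30: log2(4)=2 crossed at 20 min
        assert time_to_fold({0: 0.0, 30: 3.0}) == pytest.approx(20.0)

    def test_flat_profile_never_crosses(self):
        assert time_to_fold({0: 0.0, 30: 0.1, 60: 0.0}) == np.inf

    def test_bound_group_crosses_before_delayed_group(self, pipeline_result):
        m = pipeline_result.metrics
        assert m["time_to_4fold_bound_min"] < m["time_to_4fold_unbound_min"]


class TestResponseRank:
    def test_single_gene_rank_one(self):
        course = make_course({"g": {30: 2.0, 60: 2.0, 120: 2.0}})
        assert response_rank(["g"], course)["g"] == 1

    def test_dense_ties_share_rank(self):
        course = make_course(
            {"a": {30: 3.0, 60: 3.0, 120: 3.0},
             "b": {30: 2.0, 60: 2.0, 120: 2.0},
             "c": {30: 2.0, 60: 2.0, 120: 2.0},
             "d": {30: 1.0, 60: 1.0, 120: 1.0}}
        )
        ranks = response_rank(["a", "b", "c", "d"], course)
        assert list(ranks[["a", "b", "c", "d"]]) == [1, 2, 2, 3]

    def test_order_invariance(self):
        course = make_course(
            {"a": {30: 3.0, 60: 3.0, 120: 3.0},
             "b": {30: 1.0, 60: 1.0, 120: 1.0}}
        )
        r1 = response_rank(["a", "b"], course)
        r2 = response_rank(["b", "a"], course)
        assert r1["a"] == r2["a"] and r1["b"] == r2["b"]


class TestNullCalibration:
    def test_no_effect_matrix_few_false_calls(self):
        course = make_course({f"g{i}": {} for i in range(300)}, noise_sd=0.25,
                             seed=11)
        status = call_responsive(course, ResponseParams(seed=11))
        frac = float((status != "unresponsive").mean())
        assert frac <= 0.05 + 0.02
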