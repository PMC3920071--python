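"""Permutation inference: component extraction, NBS, sign-bias ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from speechconn import (
    EffectSpec,
    NoiseSpec,
    PermutationPlan,
    ValidationError,
    extract_components,
    nbs_correlation,
    nbs_group,
    ranksum_edges,
    sign_bias_test,
    simulate_cohort,
)

from conftest import cohort_from_arrays


def _edge_table(edges, pvals, n_nodes):
    """Minimal stat table over a complete small graph with given one-tailed p's."""
    rows = []
    p_by_edge = dict(zip(edges, pvals))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_by_edge.get((i, j), 0.99)
            rows.append(
                {
                    "node_i": f"n{i}",
                    "node_j": f"n{j}",
                    "statistic": 0.0,
                    "sign": -1,
                    "p_two": min(1.0, 2 * p),
                    "p_one_neg": p,
                    "p_one_pos": 1 - p,
                    "sig_value": 0.0,
                }
            )
    return pd.DataFrame(rows)


class TestExtractComponents:
    def test_threshold_one_yields_single_full_component(self):
        table = _edge_table([], [], 5)
        comps = extract_components(table, threshold=1.0, tail="case_lt_control")
        assert len(comps) == 1
        assert comps[0].size == 10

    def test_threshold_below_minimum_yields_empty_list(self):
        table = _edge_table([], [], 5)
        assert extract_components(table, 1e-6, "case_lt_control") == []

    def test_two_disjoint_triangles(self):
        tri1 = [(0, 1), (1, 2), (0, 2)]
        tri2 = [(3, 4), (4, 5), (3, 5)]
        table = _edge_table(tri1 + tri2, [0.001] * 6, 7)
        comps = extract_components(table, 0.01, "case_lt_control")
        assert [c.size for c in comps] == [3, 3]
        assert comps[0].nodes == ["n0", "n1", "n2"]  # tie broken by smallest node
        assert comps[1].nodes == ["n3", "n4", "n5"]


class TestNbsGroup:
    def test_planted_component_detected_with_high_recall(self, planted_cohort):
        plan = PermutationPlan(n_iterations=500, edge_p_threshold=0.01, seed=21)
        comps = nbs_group(planted_cohort, "intra_left", plan)
        assert comps and comps[0].corrected_p < 0.05
        labels = planted_cohort.matrices["intra_left"][0].row_labels
        idx = {lab: k for k, lab in enumerate(labels)}
        found = {
            tuple(sorted((idx[a], idx[b]))) for a, b in comps[0].edges
        }
        planted = {tuple(e) for e in planted_cohort.meta["target_edges"]}
        assert len(planted & found) / len(planted) >= 0.8

    def test_corrected_p_floor_and_monotonicity(self, planted_cohort):
        plan = PermutationPlan(n_iterations=200, edge_p_threshold=0.05, seed=3)
        comps = nbs_group(planted_cohort, "intra_left", plan)
        sizes = [c.corrected_p for c in comps]
        assert all(p >= 1 / 201 for p in sizes)
        by_size = sorted(comps, key=lambda c: -c.size)
        ps = [c.corrected_p for c in by_size]
        assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_identical_group_copies_yield_no_components(self, rng):
        stack = rng.uniform(0.5, 1.5, size=(6, 8, 8))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for w in stack:
            np.fill_diagonal(w, 0)
        c = cohort_from_arrays(stack, stack.copy())
        plan = PermutationPlan(n_iterations=100, edge_p_threshold=0.01, seed=5)
        assert nbs_group(c, "intra_left", plan) == []

    def test_single_subject_group_rejected(self, rng):
        stack = np.zeros((1, 3, 3))
        other = np.zeros((3, 3, 3))
        c = cohort_from_arrays(stack, other)
        with pytest.raises(ValidationError):
            nbs_group(c, "intra_left", PermutationPlan(100, 0.01, "case_lt_control", 1))


class TestNbsCorrelation:
    def test_planted_severity_component_recovered(self, parcellation):
        c = simulate_cohort(
            parcellation,
            20,
            17,
            effect=EffectSpec(severity_edges=10, severity_slope=-0.05),
            noise=NoiseSpec(sigma=0.15),
            seed=31,
        )
        plan = PermutationPlan(500, 0.05, "negative_correlation", seed=32)
        comps = nbs_correlation(c, "intra_left", plan)
        assert comps and comps[0].corrected_p < 0.05
        labels = c.matrices["intra_left"][0].row_labels
        idx = {lab: k for k, lab in enumerate(labels)}
        found = {tuple(sorted((idx[a], idx[b]))) for a, b in comps[0].edges}
        planted = {tuple(e) for e in c.meta["severity_edges"]}
        assert len(planted & found) / len(planted) >= 0.8

    def test_reversed_severity_moves_signal_to_positive_tail(self, parcellation):
        c = simulate_cohort(
            parcellation,
            10,
            4,
            effect=EffectSpec(severity_edges=6, severity_slope=-0.06),
            noise=NoiseSpec(sigma=0.15),
            seed=33,
        )
        flipped = simulate_cohort(
            parcellation,
            10,
            4,
            effect=EffectSpec(severity_edges=6, severity_slope=-0.06),
            noise=NoiseSpec(sigma=0.15),
            seed=33,
        )
        for s in flipped.subjects:
            if s.severity is not None:
                s.severity = -s.severity
        neg = nbs_correlation(c, "intra_left", PermutationPlan(200, 0.05, "negative_correlation", 8))
        pos = nbs_correlation(
            flipped, "intra_left", PermutationPlan(200, 0.05, "positive_correlation", 8)
        )
        assert [c_.size for c_ in neg] == [c_.size for c_ in pos]
        assert [c_.corrected_p for c_ in neg] == [c_.corrected_p for c_ in pos]

    def test_requires_enough_severity_scores(self, rng):
        stack = np.zeros((3, 3, 3))
        c = cohort_from_arrays(stack, stack.copy(), severities=[13.0, 20.0, 30.0])
        with pytest.raises(ValidationError):
            nbs_correlation(c, "intra_left", PermutationPlan(100, 0.05, "negative_correlation", 1))


class TestSignBias:
    @pytest.mark.parametrize("n_neg,n_pos,expected", [(5, 5, 1.0), (23, 0, 24.0), (0, 23, 1 / 24)])
    def test_laplacian_ratio_formula(self, n_neg, n_pos, expected):
        assert (n_neg + 1) / (n_pos + 1) == pytest.approx(expected)

    def test_observed_counts_and_ratio_on_planted_cohort(self, planted_cohort):
        plan = PermutationPlan(n_iterations=200, seed=41)
        res = sign_bias_test(planted_cohort, "intra_left", plan, count_scope="significant_edges")
        table = ranksum_edges(planted_cohort, "intra_left", exact="never")
        sig = table[table.p_two < 0.05]
        assert res.n_neg == int((sig.sign < 0).sum())
        assert res.n_pos == int((sig.sign > 0).sum())
        assert res.ratio == pytest.approx((res.n_neg + 1) / (res.n_pos + 1))

    def test_broad_weakening_yields_significant_negative_bias(self, parcellation):
        """When many edges are mildly weakened in cases, the significant-edge
        signs are overwhelmingly negative and the ratio test rejects."""
        c = simulate_cohort(
            parcellation,
            20,
            17,
            effect=EffectSpec(target_edges=60, effect_multiplier=0.7),
            noise=NoiseSpec(sigma=0.2),
            seed=45,
        )
        res = sign_bias_test(
            c, "intra_left", PermutationPlan(n_iterations=300, seed=46),
            count_scope="significant_edges",
        )
        assert res.n_neg > res.n_pos
        assert res.corrected_p < 0.05

    def test_group_relabeling_swaps_counts(self, null_cohort):
        plan = PermutationPlan(n_iterations=100, seed=42)
        res = sign_bias_test(null_cohort, "intra_left", plan, count_scope="all_edges")
        swapped_subjects = []
        import copy

        swapped = copy.deepcopy(null_cohort)
        for s in swapped.subjects:
            s.group = "control" if s.group == "case" else "case"
        res_sw = sign_bias_test(swapped, "intra_left", plan, count_scope="all_edges")
        assert (res.n_neg, res.n_pos) == (res_sw.n_pos, res_sw.n_neg)

    def test_empty_scope_warns_and_returns_p_one(self, rng):
        stack = np.ones((4, 3, 3))
        for w in stack:
            np.fill_diagonal(w, 0)
        c = cohort_from_arrays(stack, stack.copy())
        with pytest.warns(UserWarning, match="empty count scope"):
            res = sign_bias_test(
                c, "intra_left", PermutationPlan(100, 0.01, "case_lt_control", 2)
            )
        assert res.corrected_p == 1.0

    def test_correlation_variant_detects_negative_bias(self, parcellation):
        c = simulate_cohort(
            parcellation,
            20,
            17,
            effect=EffectSpec(severity_edges=40, severity_slope=-0.04),
            noise=NoiseSpec(sigma=0.15),
            seed=43,
        )
        res = sign_bias_test(
            c,
            "intra_left",
            PermutationPlan(n_iterations=300, seed=44),
            count_scope="significant_edges",
            statistic="correlation",
        )
        assert res.n_neg > res.n_pos
        assert res.corrected_p < 0.05

    def test_permutation_p_differs_from_binomial_on_correlated_edges(self, small_parcellation):
        """Edges sharing subject-level factors are dependent; the binomial
        test overstates evidence while the permutation null absorbs the
        dependence."""
        diffs = []
        for rep in range(20):
            c = simulate_cohort(
                small_parcellation,
                10,
                10,
                noise=NoiseSpec(sigma=0.05, subject_sigma=0.5),
                seed=500 + rep,
            )
            res = sign_bias_test(
                c,
                "intra_left",
                PermutationPlan(n_iterations=300, seed=rep),
                count_scope="all_edges",
            )
            n = res.n_neg + res.n_pos
            p_binom = stats.binomtest(res.n_neg, n, 0.5, alternative="greater").pvalue
            diffs.append(abs(res.corrected_p - p_binom))
        # with one global factor per subject the 45 edges move together, so
        # the two nulls disagree grossly on most replicates
        assert np.median(diffs) > 0.05
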