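"""Composite score definitions against brute-force oracles and hand examples."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflamscore import (CohortConfig, GeneList, collapse_probes,
                         effective_tests, generate_cohort, pc1_score,
                         quartile_score, rank_score, select_inflammatory,
                         subpathway_scores)
from conftest import random_expression


def brute_force_quartile(expr: pd.DataFrame) -> pd.Series:
    """Independent per-gene loop implementation of the quartile score."""
    scores = {s: 0 for s in expr.columns}
    for g in expr.index:
        vals = expr.loc[g]
        thr = np.quantile(vals.to_numpy(), 0.75)
        for s in expr.columns:
            if vals[s] > thr:
                scores[s] += 1
    return pd.Series(scores)


def brute_force_rank(expr: pd.DataFrame, sep: pd.Series) -> pd.Series:
    """Oriented-rank score computed from per-gene covariances and explicit
    rank loops (direction = sign of cov(sep, expression))."""
    x = sep.to_numpy(float)
    per_gene = []
    for g in expr.index:
        y = expr.loc[g].to_numpy(float)
        c = np.cov(x, y)[0, 1]
        if c == 0:
            continue
        per_gene.append(stats.rankdata(y if c > 0 else -y))
    mat = np.array(per_gene)
    return pd.Series(np.median(mat, axis=0), index=expr.columns)


class TestQuartileScore:
    def test_hand_example(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                          columns=list("abcd"))
        # type-7 quantile threshold is 3.25; only the last value exceeds it
        np.testing.assert_array_equal(quartile_score(df), [0, 0, 0, 1])

    def test_constant_gene_contributes_zero(self):
        df = pd.DataFrame([[2.0] * 6, [1, 2, 3, 4, 5, 6]], index=["flat", "g"],
                          columns=list("abcdef"))
        total = quartile_score(df)
        only_g = quartile_score(df.loc[["g"]])
        np.testing.assert_array_equal(total, only_g)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            expr = random_expression(rng, n_genes=10, n_samples=20)
            got = quartile_score(expr)
            expected = brute_force_quartile(expr)
            pd.testing.assert_series_equal(got, expected, check_names=False,
                                           check_dtype=False)

    def test_exact_count_when_n_divisible_by_four(self, rng):
        expr = random_expression(rng, n_genes=40, n_samples=20)
        # tie-free continuous data: each gene marks exactly n/4 samples
        assert quartile_score(expr).sum() == 40 * 5
        assert quartile_score(expr).mean() == pytest.approx(40 / 4)

    def test_invariances(self, rng):
        expr = random_expression(rng, n_genes=8, n_samples=16)
        base = quartile_score(expr)
        shifted = quartile_score(expr + 3.7)
        pd.testing.assert_series_equal(base, shifted)
        perm = rng.permutation(expr.shape[1])
        reordered = quartile_score(expr.iloc[:, perm])
        pd.testing.assert_series_equal(base.iloc[perm], reordered)

    def test_needs_four_samples(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            quartile_score(random_expression(rng, n_genes=3, n_samples=3))


class TestSubpathwayScores:
    def test_partition_sums_to_total(self, rng):
        expr = random_expression(rng, n_genes=12, n_samples=20)
        genes = list(expr.index)
        gl = GeneList(genes=genes,
                      subpathway={g: f"SP{i % 3}" for i, g in enumerate(genes)})
        sub = subpathway_scores(expr, gl)
        assert sub.shape[1] == 3
        np.testing.assert_array_equal(sub.sum(axis=1), quartile_score(expr))

    def test_single_pathway_equals_total(self, rng):
        expr = random_expression(rng, n_genes=6, n_samples=12)
        gl = GeneList(genes=list(expr.index),
                      subpathway={g: "all" for g in expr.index})
        sub = subpathway_scores(expr, gl)
        np.testing.assert_array_equal(sub["all"], quartile_score(expr))

    def test_empty_subpathway_scores_zero(self, rng):
        expr = random_expression(rng, n_genes=4, n_samples=8)
        gl = GeneList(genes=list(expr.index) + ["unmeasured"],
                      subpathway={**{g: "a" for g in expr.index},
                                  "unmeasured": "ghost"})
        sub = subpathway_scores(expr, gl)
        assert (sub["ghost"] == 0).all()

    def test_effect_in_one_pathway_shows_largest_contrast(self):
        """Inject the SEP shift into the panel and label one third of it as
        the target pathway: across seeds, the labelled subsets all carry the
        effect, but a pathway-specific planted contrast is detected as the
        largest standardized group difference in most seeds."""
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(900 + s)
            n, m = 60, 30
            sep = (rng.random(n) < 0.5).astype(float)
            vals = rng.normal(0, 1, size=(m, n))
            vals[:10] += 0.8 * sep          # pathway "hot" carries the effect
            expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(m)],
                                columns=[f"s{i}" for i in range(n)])
            labels = {f"g{i}": ("hot" if i < 10 else ("warm" if i < 20 else "cold"))
                      for i in range(m)}
            gl = GeneList(genes=list(expr.index), subpathway=labels)
            sub = subpathway_scores(expr, gl)
            diffs = {lab: (sub.loc[sep == 1, lab].mean()
                           - sub.loc[sep == 0, lab].mean())
                     for lab in sub.columns}
            hits += max(diffs, key=diffs.get) == "hot"
        assert hits >= 45


class TestPC1Score:
    def test_recovers_rank_one_signal(self, rng):
        signal = rng.normal(size=30)
        loadings = rng.uniform(0.5, 1.5, size=10)
        vals = np.outer(loadings, signal) + rng.normal(scale=1e-3,
                                                       size=(10, 30))
        expr = pd.DataFrame(vals, columns=[f"s{i}" for i in range(30)])
        score, ve = pc1_score(expr)
        assert abs(np.corrcoef(score, signal)[0, 1]) > 0.99
        assert ve > 0.99

    def test_sign_convention_deterministic(self, rng):
        expr = random_expression(rng, n_genes=6, n_samples=15)
        s1, _ = pc1_score(expr)
        s2, _ = pc1_score(expr * 1.0)
        pd.testing.assert_series_equal(s1, s2)

    def test_duplicating_dominant_block_raises_variance_explained(self, rng):
        expr = random_expression(rng, n_genes=6, n_samples=15)
        _, ve1 = pc1_score(expr)
        dup = pd.concat([expr, expr.iloc[[0]].rename(index={expr.index[0]: "dup"})])
        _, ve2 = pc1_score(dup)
        assert ve2 > ve1 * 0.8  # duplicated gene strengthens the top axis
        big = pd.concat([expr] + [expr.iloc[[0]].rename(
            index={expr.index[0]: f"dup{i}"}) for i in range(6)])
        _, ve3 = pc1_score(big)
        assert ve3 > ve1

    def test_affine_gene_maps_are_irrelevant(self, rng):
        expr = random_expression(rng, n_genes=6, n_samples=15)
        scaled = expr.mul(rng.uniform(0.5, 3, 6), axis=0).add(
            rng.normal(size=6), axis=0)
        s1, _ = pc1_score(expr)
        s2, _ = pc1_score(scaled)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_zero_variance_genes_dropped(self, rng):
        expr = random_expression(rng, n_genes=5, n_samples=12)
        expr.loc["flat"] = 1.0
        score, _ = pc1_score(expr)
        ref, _ = pc1_score(expr.drop(index="flat"))
        np.testing.assert_allclose(score, ref, atol=1e-10)


class TestRankScore:
    def test_hand_example_single_upregulated_gene(self):
        expr = pd.DataFrame([[5.0, 1.0, 3.0, 2.0]], index=["g"],
                            columns=list("abcd"))
        sep = pd.Series([1, 0, 0, 0], index=list("abcd"))
        np.testing.assert_array_equal(rank_score(expr, sep), [4, 1, 3, 2])

    def test_identical_sample_columns_share_one_score(self):
        # distinct genes, but every sample identical: all ranks tie and all
        # samples share the central rank
        base = np.random.default_rng(0).normal(size=3)
        expr = pd.DataFrame(np.tile(base[:, None], (1, 6)),
                            columns=list("abcdef"))
        sep = pd.Series([1, 1, 0, 0, 1, 0], index=list("abcdef"))
        out = rank_score(expr, sep)
        assert out.nunique() == 1
        assert out.iloc[0] == pytest.approx((6 + 1) / 2)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            expr = random_expression(rng, n_genes=10, n_samples=20)
            sep = pd.Series(rng.integers(0, 2, 20), index=expr.columns)
            if sep.nunique() < 2:
                continue
            got = rank_score(expr, sep)
            expected = brute_force_rank(expr, sep)
            np.testing.assert_allclose(got, expected)

    def test_sum_aggregate_option(self, rng):
        expr = random_expression(rng, n_genes=5, n_samples=12)
        sep = pd.Series(rng.integers(0, 2, 12), index=expr.columns)
        med = rank_score(expr, sep, aggregate="median")
        tot = rank_score(expr, sep, aggregate="sum")
        assert not np.allclose(med, tot)
        with pytest.raises(ValueError, match="aggregate"):
            rank_score(expr, sep, aggregate="mean")

    def test_correlates_with_quartile_score_under_shared_effect(self):
        cfg = CohortConfig(n_samples=200, n_genes=300, n_inflammatory=100,
                           probes_per_gene_mean=1.0, effect_delta=0.4,
                           batch_sd=(0, 0, 0), noise_sd=0.5,
                           cell_effect_sd=0.0, confounder_effects={},
                           sep_missing=(0, 0, 0), seed=31)
        c = generate_cohort(cfg)
        expr = collapse_probes(c.expression, c.probe_to_gene)
        panel, _ = select_inflammatory(expr, c.gene_list)
        qs = quartile_score(panel)
        rs = rank_score(panel, c.metadata["sep_early"])
        rho = stats.spearmanr(qs, rs).statistic
        assert rho > 0.4


class TestEffectiveTests:
    def test_duplicated_gene_structure(self, rng):
        """Two perfectly correlated genes + one independent gene: the
        standardized spectrum is (2/3, 1/3, 0), so 2 components reach 95%."""
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        expr = pd.DataFrame([a, 2 * a + 1, b], index=["g1", "g2", "g3"])
        k, alpha = effective_tests(expr, variance_target=0.95)
        assert k == 2
        assert alpha == pytest.approx(0.025)

    def test_full_rank_needs_all_components(self, rng):
        expr = random_expression(rng, n_genes=10, n_samples=30)
        k, _ = effective_tests(expr, variance_target=1.0)
        assert k == 10

    def test_alpha_is_bonferroni_over_k(self, rng):
        expr = random_expression(rng, n_genes=20, n_samples=40)
        k, alpha = effective_tests(expr, variance_target=0.9)
        assert alpha == pytest.approx(0.05 / k)
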