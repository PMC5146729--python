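"""Association models: descriptive tests, the score ladder, per-gene fits,
correlations, and simulated power."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflamscore import (CohortConfig, MODEL_LADDER, analysis_set,
                         collapse_probes, generate_cohort, life_course_ladder,
                         per_gene_association, power_by_simulation,
                         quartile_score, score_association,
                         score_correlations, select_inflammatory, table1)
from inflamscore.association import group_test_categorical


class TestCategoricalGroupTests:
    """Chi-squared conventions: continuity correction for 2x2 tables only."""

    @pytest.mark.parametrize("table, expected_p", [
        # recruitment centre x father's occupation (3x2, no correction)
        ([[4, 47, 31], [17, 59, 68]], 3.45e-2),
        # education x centre (3x2, no correction)
        ([[16, 58, 34], [16, 54, 67]], 2.24e-2),
        # gender x father's occupation (2x2, with correction)
        ([[62, 101], [20, 43]], 4.67e-1),
        # smoking x education (3x2, no correction)
        ([[42, 35, 31], [78, 30, 29]], 1.90e-2),
        # recruitment phase x household occupation (2x2, with correction)
        ([[119, 51], [32, 27]], 4.12e-2),
    ])
    def test_published_count_tables(self, table, expected_p):
        _, p = group_test_categorical(np.array(table))
        assert p == pytest.approx(expected_p, rel=5e-3)

    def test_identical_groups_give_chi2_zero(self):
        chi2, p = group_test_categorical(np.array([[30, 20], [30, 20]]))
        assert chi2 == 0.0
        assert p == 1.0


class TestTable1:
    def _meta_from_counts(self, counts: dict[str, tuple[int, int]],
                          group_sizes: tuple[int, int]) -> pd.DataFrame:
        rows = []
        for grp, size in zip((0.0, 1.0), group_sizes):
            n_done = 0
            for level, cnt in counts.items():
                c = cnt[0 if grp == 0 else 1]
                rows += [{"grp": grp, "gender": level}] * c
                n_done += c
            assert n_done == size
        return pd.DataFrame(rows)

    def test_reconstructed_gender_counts_match_published_p(self):
        meta = self._meta_from_counts(
            {"woman": (62, 101), "man": (20, 43)}, (82, 144))
        out = table1(meta, group="grp", continuous=(), categorical=("gender",))
        assert out["pvalue"].iloc[0] == pytest.approx(4.67e-1, rel=5e-3)
        assert out.loc[out["level"] == "woman", "group_0.0"].iloc[0] == "62 (75.6)"

    def test_continuous_uses_pooled_t_test(self, rng):
        meta = pd.DataFrame({
            "grp": np.repeat([0.0, 1.0], 40),
            "age": np.r_[rng.normal(50, 5, 40), rng.normal(53, 5, 40)],
        })
        out = table1(meta, group="grp", continuous=("age",), categorical=())
        a, b = meta.loc[meta.grp == 0, "age"], meta.loc[meta.grp == 1, "age"]
        _, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert out["pvalue"].iloc[0] == pytest.approx(p_ref)

    def test_non_binary_group_rejected(self, rng):
        meta = pd.DataFrame({"grp": [0, 1, 2] * 4, "age": rng.normal(size=12)})
        with pytest.raises(ValueError, match="binary"):
            table1(meta, group="grp")


class TestScoreAssociation:
    def test_matches_closed_form_least_squares(self, clean_cohort,
                                               clean_gene_expr):
        panel, _ = select_inflammatory(clean_gene_expr, clean_cohort.gene_list)
        score = quartile_score(panel)
        meta = clean_cohort.metadata
        res = score_association(score, meta, model="A")
        # reference: normal equations on the identical design
        from inflamscore.design import build_design
        sub = meta.loc[analysis_set(meta)]
        X = build_design(sub, MODEL_LADDER["A"], sep="sep_early").to_numpy(float)
        y = score.loc[sub.index].to_numpy(float)
        beta_ref = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert res.beta == pytest.approx(beta_ref, abs=1e-8)
        assert res.n == len(sub)

    def test_positive_coefficient_for_low_sep_upregulation(self, clean_cohort,
                                                           clean_gene_expr):
        panel, _ = select_inflammatory(clean_gene_expr, clean_cohort.gene_list)
        res = score_association(quartile_score(panel), clean_cohort.metadata,
                                model="A")
        assert res.beta > 0          # planted upward shift in the low group
        assert res.pvalue < 0.05

    def test_unknown_model_rejected(self, clean_cohort, clean_gene_expr):
        panel, _ = select_inflammatory(clean_gene_expr, clean_cohort.gene_list)
        with pytest.raises(ValueError, match="unknown model"):
            score_association(quartile_score(panel), clean_cohort.metadata,
                              model="Z")


class TestLifeCourseLadder:
    def test_adjustment_sets_strictly_nested(self):
        order = ["A", "B", "C", "D", "fully_adjusted"]
        for a, b in zip(order, order[1:]):
            assert set(MODEL_LADDER[a]) < set(MODEL_LADDER[b])

    def test_single_analysis_set_across_rungs(self):
        cfg = CohortConfig(n_samples=150, n_genes=120, n_inflammatory=40,
                           probes_per_gene_mean=1.0, batch_sd=(0, 0, 0),
                           noise_sd=0.5, seed=19)  # default missingness on
        c = generate_cohort(cfg)
        expr = collapse_probes(c.expression, c.probe_to_gene)
        panel, _ = select_inflammatory(expr, c.gene_list)
        ladder = life_course_ladder(quartile_score(panel), c.metadata,
                                    models=("A", "B", "C", "D"))
        assert ladder["n"].nunique() == 1
        assert ladder["n"].iloc[0] < cfg.n_samples       # missingness bites
        assert list(ladder.index) == ["A", "B", "C", "D"]


class TestPerGeneAssociation:
    def test_null_data_controls_familywise_error(self):
        """Null cohorts: at the PCA-corrected significance level at most a
        nominal share of families contain any flagged gene."""
        base = CohortConfig(n_samples=120, n_genes=30, n_inflammatory=10,
                            probes_per_gene_mean=1.0, effect_delta=0.0,
                            noise_sd=0.5, sep_missing=(0, 0, 0), seed=0)
        families_hit = 0
        for s in range(8):
            c = generate_cohort(dataclasses.replace(base, seed=400 + s))
            expr = collapse_probes(c.expression, c.probe_to_gene)
            res = per_gene_association(expr, c.metadata)
            families_hit += bool(res["significant"].any())
        assert families_hit <= 2

    def test_planted_strong_effects_rank_first(self):
        """10 genes with a 3-sigma shift are the 10 smallest p-values."""
        hits = 0
        for s in range(3):
            cfg = CohortConfig(n_samples=200, n_genes=60, n_inflammatory=10,
                               probes_per_gene_mean=1.0, effect_delta=1.5,
                               noise_sd=0.5, sep_missing=(0, 0, 0),
                               seed=70 + s)
            c = generate_cohort(cfg)
            expr = collapse_probes(c.expression, c.probe_to_gene)
            res = per_gene_association(expr, c.metadata)
            top = set(res.nsmallest(10, "pvalue").index)
            hits += top == set(c.gene_list.genes)
        assert hits >= 2


class TestScoreCorrelations:
    def test_self_correlation_and_antisymmetry(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20)})
        df["b"] = df["a"] * 2 + rng.normal(scale=0.1, size=20)
        df["neg"] = -df["a"]
        out = score_correlations(df)
        assert out.loc["a", "a"] == 1.0
        assert out.loc["a", "neg"] == pytest.approx(-out.loc["a", "a"])

    def test_constant_column_reported_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10)})
        out = score_correlations(df)
        assert np.isnan(out.loc["flat", "a"])
        assert np.isnan(out.loc["flat", "flat"])

    def test_subpathway_scores_all_positive_under_shared_signal(self):
        from inflamscore import subpathway_scores

        cfg = CohortConfig(n_samples=200, n_genes=1000, n_inflammatory=845,
                           probes_per_gene_mean=1.0, effect_delta=0.05,
                           batch_sd=(0, 0, 0), noise_sd=0.5,
                           cell_effect_sd=0.0,
                           confounder_effects={"age": 0.03},
                           sep_missing=(0, 0, 0), seed=2)
        c = generate_cohort(cfg)
        expr = collapse_probes(c.expression, c.probe_to_gene)
        sub = subpathway_scores(expr, c.gene_list)
        assert sub.shape[1] == 17
        corr = score_correlations(sub)
        assert (corr.to_numpy() > 0).all()


class TestPowerBySimulation:
    template = CohortConfig(n_samples=60, n_genes=60, n_inflammatory=20,
                            probes_per_gene_mean=1.0, batch_sd=(0, 0, 0),
                            noise_sd=0.5, cell_effect_sd=0.0,
                            confounder_effects={}, sep_missing=(0, 0, 0),
                            seed=0)

    def test_size_matches_level_under_null(self):
        power = power_by_simulation(self.template, effect=0.0, n_grid=[60],
                                    alpha=0.05, reps=200, seed=1)
        # binomial 99% envelope around 0.05 at 200 reps
        assert 0.01 <= power.loc[60] <= 0.10

    def test_monotone_in_n_and_effect(self):
        power_n = power_by_simulation(self.template, effect=0.5,
                                      n_grid=[40, 160], reps=100, seed=2)
        assert power_n.loc[160] >= power_n.loc[40] - 0.10
        small = power_by_simulation(self.template, effect=0.25, n_grid=[120],
                                    reps=100, seed=3)
        large = power_by_simulation(self.template, effect=0.5, n_grid=[120],
                                    reps=100, seed=3)
        assert large.loc[120] >= small.loc[120] - 0.10
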