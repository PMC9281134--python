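"""Normalization, NB GLM fitting, dispersion, tests, BH, Fisher, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthotx import de, simulate
from orthotx.de import (bh_adjust, call_significant, estimate_dispersion,
                        filter_low_expression, fisher_enrichment, fit_nb_glm,
                        nb_loglik, normalize_counts, pca_profile, run_de)
from orthotx.design import build_design_matrices
from orthotx.simulate import CountExperiment, make_sample_meta


def _experiment(counts: np.ndarray, lengths=None, kind="transcript"):
    meta = make_sample_meta()
    df = pd.DataFrame(counts, columns=meta.index,
                      index=[f"F{i}" for i in range(counts.shape[0])])
    if kind == "transcript":
        if lengths is None:
            lengths = np.full(counts.shape[0], 1000)
        lengths = pd.Series(lengths, index=df.index)
    else:
        lengths = None
    return CountExperiment(df, meta, lengths, kind)


class TestNormalization:
    def test_identical_columns_unit_size_factors(self):
        col = np.random.default_rng(0).poisson(100, size=50)
        exp = _experiment(np.tile(col[:, None], (1, 18)))
        norm = normalize_counts(exp)
        assert np.allclose(norm.size_factors, 1.0)

    def test_doubled_sample_size_factor_two(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(60, 18))
        counts[:, 0] *= 2
        exp = _experiment(counts)
        norm = normalize_counts(exp)
        rel = norm.size_factors / stats.gmean(norm.size_factors)
        assert rel.iloc[0] == pytest.approx(2.0, rel=0.05)

    def test_per_kilobase_arithmetic(self):
        counts = np.full((1, 18), 100)
        exp = _experiment(counts, lengths=[2000])
        norm = normalize_counts(exp)
        assert np.allclose(norm.normalized.to_numpy(), 50.0)

    def test_mirna_counts_skip_length_term(self):
        counts = np.full((3, 18), 40)
        exp = _experiment(counts, kind="mirna")
        norm = normalize_counts(exp)
        assert np.allclose(norm.normalized.to_numpy(), 40.0)

    def test_all_zero_sample_rejected(self):
        counts = np.random.default_rng(2).poisson(50, size=(20, 18))
        counts[:, 3] = 0
        with pytest.raises(ValueError, match="A_flower_1"):
            normalize_counts(_experiment(counts))


class TestLowExpressionFilter:
    def test_boundary_strictly_less_than(self):
        counts = np.zeros((2, 18), dtype=int)
        counts[0, 0] = 18   # sum 18 < 19 -> dropped
        counts[1, 0] = 19   # sum 19 -> kept
        exp = _experiment(counts, kind="mirna")
        kept = filter_low_expression(exp, threshold=19)
        assert list(kept.counts.index) == ["F1"]

    def test_transcripts_filtered_on_normalized_scale(self):
        counts = np.ones((2, 18), dtype=int) * 2
        exp = _experiment(counts, lengths=[4000, 500])
        # normalized sums: 2/(4) * 18 = 9 (dropped); 2/0.5*18 = 72 (kept)
        kept = filter_low_expression(exp, threshold=19)
        assert list(kept.counts.index) == ["F1"]

    def test_empty_matrix_passthrough(self):
        exp = _experiment(np.zeros((0, 18), dtype=int), kind="mirna")
        assert filter_low_expression(exp).counts.empty


class TestNBFit:
    def test_intercept_only_closed_form(self):
        meta = make_sample_meta()
        X = pd.DataFrame(np.ones((18, 1)), index=meta.index,
                         columns=["Intercept"])
        counts = pd.DataFrame(np.full((1, 18), 7.0), columns=meta.index)
        fit = fit_nb_glm(counts, X, np.zeros((1, 18)), 0.1)
        assert fit.beta[0, 0] == pytest.approx(np.log(7.0), abs=1e-6)

    def test_loglik_matches_grid_oracle_two_params(self):
        """Brute-force grid maximization of the NB log-likelihood agrees
        with IRLS to 1e-4 on two-condition toys."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"Intercept": np.ones(12),
                          "group": np.repeat([0.0, 1.0], 6)})
        for _ in range(10):
            mu0, lfc = rng.uniform(20, 200), rng.uniform(-1.5, 1.5)
            y = rng.negative_binomial(10, 10 / (10 + mu0 *
                                                np.exp(X["group"] * lfc)))
            counts = pd.DataFrame(y[None, :])
            alpha = 0.1
            fit = fit_nb_glm(counts, X, np.zeros((1, 12)), alpha)
            b0 = np.linspace(fit.beta[0, 0] - 0.3, fit.beta[0, 0] + 0.3, 81)
            b1 = np.linspace(fit.beta[0, 1] - 0.3, fit.beta[0, 1] + 0.3, 81)
            grid_best = -np.inf
            for g0 in b0:
                mu = np.exp(g0 + np.outer(b1, X["group"]))
                ll = nb_loglik(np.tile(y, (81, 1)), mu,
                               np.full(81, alpha))
                grid_best = max(grid_best, ll.max())
            assert fit.loglik[0] >= grid_best - 1e-4

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        exp, _ = simulate.generate_count_experiment(12, dispersion=0.1,
                                                    seed=3)
        norm = normalize_counts(exp)
        X, _ = build_design_matrices(exp.sample_meta)
        fit = fit_nb_glm(exp.counts, X, norm.offsets, 0.1)
        for i in range(12):
            ref = sm.GLM(exp.counts.iloc[i].to_numpy(), X.to_numpy(),
                         family=sm.families.NegativeBinomial(alpha=0.1),
                         offset=norm.offsets[i]).fit()
            assert np.allclose(ref.params, fit.beta[i], atol=1e-5)

    def test_constant_offset_shifts_intercept_only(self):
        exp, _ = simulate.generate_count_experiment(20, dispersion=0.1,
                                                    seed=4)
        X, _ = build_design_matrices(exp.sample_meta)
        off = normalize_counts(exp).offsets
        f1 = fit_nb_glm(exp.counts, X, off, 0.1)
        f2 = fit_nb_glm(exp.counts, X, off + np.log(2.0), 0.1)
        assert np.allclose(f1.beta[:, 1:], f2.beta[:, 1:], atol=1e-6)
        assert np.allclose(f1.beta[:, 0] - f2.beta[:, 0], np.log(2.0),
                           atol=1e-6)

    def test_size_factor_handles_library_depth(self):
        """A sample sequenced deeper (all counts scaled) gets a larger size
        factor and the fold-change estimates stay centred on the truth."""
        exp, truth = simulate.generate_count_experiment(
            400, dispersion=0.05, deg_fraction=0.2, effect_size_log2=2.0,
            baseline_mean_log2=(8.0, 11.0), seed=41)
        c2 = exp.counts.copy()
        c2.iloc[:, :3] = (c2.iloc[:, :3] * 2.5).round().astype(int)
        exp2 = CountExperiment(c2, exp.sample_meta, exp.feature_lengths,
                               "transcript")
        an = run_de(exp2)
        sf = an.size_factors
        assert (sf.iloc[:3] / sf.iloc[3:].mean()).mean() == pytest.approx(
            2.5, rel=0.1)
        eff = truth.effect_truth.loc[an.interaction.index]
        sp = eff.index[eff["beta_species"].abs() > 0]
        est = an.contrasts["species_B_vs_A.bud"].loc[sp, "log2fc"]
        assert np.abs(est - eff.loc[sp, "beta_species"]).median() < 0.5


class TestDispersion:
    def test_poisson_data_near_zero(self):
        exp, _ = simulate.generate_count_experiment(600, dispersion=0.0,
                                                    seed=9)
        X, _ = build_design_matrices(exp.sample_meta)
        d = estimate_dispersion(exp.counts, X,
                                normalize_counts(exp).offsets)
        assert d["alpha"].median() <= 0.01

    def test_nb_dispersion_recovered(self, null_experiment):
        exp, _ = null_experiment
        X, _ = build_design_matrices(exp.sample_meta)
        d = estimate_dispersion(exp.counts, X,
                                normalize_counts(exp).offsets)
        assert 0.05 <= d["alpha"].median() <= 0.2

    def test_constant_feature_at_lower_bound(self):
        counts = np.full((12, 18), 60)
        counts[1:] = np.random.default_rng(0).poisson(60, size=(11, 18))
        exp = _experiment(counts)
        X, _ = build_design_matrices(exp.sample_meta)
        d = estimate_dispersion(exp.counts, X,
                                normalize_counts(exp).offsets)
        assert d["alpha_mle"].iloc[0] <= 1e-6


class TestInteractionAndContrasts:
    def test_identical_models_give_null_statistic(self):
        exp, _ = simulate.generate_count_experiment(10, dispersion=0.1,
                                                    seed=2)
        X, _ = build_design_matrices(exp.sample_meta)
        off = normalize_counts(exp).offsets
        fit = fit_nb_glm(exp.counts, X, off, 0.1)
        tab = de.test_interaction(fit, fit)
        assert np.allclose(tab["stat"], 0.0)
        assert np.allclose(tab["pvalue"], 1.0)

    def test_null_pvalues_uniform(self, null_experiment):
        exp, _ = null_experiment
        an = run_de(exp)
        ks = stats.kstest(an.interaction["pvalue_lrt"].dropna(),
                          "uniform").statistic
        assert ks <= 0.05

    def test_species_effect_appears_in_all_structures(self):
        exp, truth = simulate.generate_count_experiment(
            400, dispersion=0.05, deg_fraction=0.3, ddeg_fraction=0.0,
            effect_size_log2=2.0, baseline_mean_log2=(8.0, 11.0), seed=19)
        an = run_de(exp)
        eff = truth.effect_truth.loc[an.interaction.index]
        sp = eff.index[(eff["beta_species"].abs() > 0)]
        for contrast in ("species_B_vs_A.bud", "species_B_vs_A.flower",
                         "species_B_vs_A.fruit"):
            est = an.contrasts[contrast].loc[sp, "log2fc"]
            planted = eff.loc[sp, "beta_species"]
            assert np.corrcoef(est, planted)[0, 1] > 0.95
            assert np.abs(est - planted).median() < 0.5

    def test_interaction_recovered_in_transition_contrasts(self):
        exp, truth = simulate.generate_count_experiment(
            300, dispersion=0.05, ddeg_fraction=0.2, effect_size_log2=2.0,
            baseline_mean_log2=(8.0, 11.0), seed=23)
        an = run_de(exp)
        eff = truth.effect_truth.loc[an.interaction.index]
        dd = eff.index[eff["is_ddeg"]]
        est = an.interaction.loc[dd, "log2fc_int_flower_vs_bud"]
        assert np.corrcoef(est, eff.loc[dd, "beta_int_flower"])[0, 1] > 0.95


class TestBH:
    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels_exactly(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(12)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_padj_never_below_p(self, null_experiment):
        exp, _ = null_experiment
        an = run_de(exp)
        tab = an.interaction.dropna(subset=["pvalue_lrt"])
        assert (tab["padj_lrt"] >= tab["pvalue_lrt"] - 1e-12).all()


class TestCalling:
    def _table(self, padj1, padj2, lfc):
        return pd.DataFrame({"padj_lrt": [padj1], "padj_ql": [padj2],
                             "log2fc": [lfc]}, index=["f"])

    def test_called_up(self):
        out = call_significant(self._table(5e-4, 5e-4, 1.2))
        assert bool(out["called"].iloc[0]) and out["direction"].iloc[0] == "up"

    def test_lfc_strictly_greater(self):
        out = call_significant(self._table(5e-4, 5e-4, 1.0))
        assert not out["called"].iloc[0]

    def test_engine_disagreement_blocks_call(self):
        out = call_significant(self._table(5e-4, 5e-3, 2.0))
        assert not out["called"].iloc[0]


class TestFisher:
    def test_fold_enrichment_arithmetic(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        called = {f"g{i}" for i in range(8)} | {"g50", "g51", "g52", "g53",
                                               "g54", "g55", "g56", "g57",
                                               "g58", "g59", "g60", "g61"}
        res = fisher_enrichment(called, universe, {"T": term})
        assert res.loc["T", "fold_enrichment"] == pytest.approx(4.0)

    def test_proportional_overlap_not_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        called = {"g0", "g1"} | {f"g{i}" for i in range(10, 28)}
        res = fisher_enrichment(called, universe, {"T": term})
        assert res.loc["T", "fold_enrichment"] == pytest.approx(1.0)
        assert res.loc["T", "pvalue"] > 0.5

    def test_pvalue_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric point masses
        no larger than the observed table's."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(10, 51))
            k_term = int(rng.integers(1, n))
            k_called = int(rng.integers(1, n))
            universe = [f"g{i}" for i in range(n)]
            term = set(rng.choice(universe, k_term, replace=False))
            called = set(rng.choice(universe, k_called, replace=False))
            res = fisher_enrichment(called, set(universe), {"T": term})
            x = len(term & called)
            pmf = [stats.hypergeom.pmf(i, n, k_term, k_called)
                   for i in range(k_called + 1)]
            obs = pmf[x]
            expected = sum(p for p in pmf if p <= obs * (1 + 1e-9))
            assert res.loc["T", "pvalue"] == pytest.approx(expected,
                                                           rel=1e-6)

    def test_called_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"x"}, {"y"}, {"T": {"y"}})


class TestPCA:
    def test_two_cluster_geometry(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(2, 8, size=(200, 1))
        mat = np.tile(base, (1, 18))
        mat[:, 9:] += 3.0
        norm = pd.DataFrame(2.0 ** mat - 1,
                            columns=make_sample_meta().index)
        coords, pct = pca_profile(norm)
        assert pct[0] > 99.0
        side = np.sign(coords["PC1"])
        assert abs(side.iloc[:9].sum()) == 9 and abs(side.iloc[9:].sum()) == 9

    def test_variance_percentages_monotone(self, effect_experiment):
        exp, _ = effect_experiment
        an = run_de(exp)
        _coords, pct = pca_profile(an.normalized)
        assert (pct >= -1e-9).all()
        assert (np.diff(pct) <= 1e-9).all()
        assert pct.sum() <= 100.0 + 1e-6

    def test_species_separate_on_leading_components(self):
        """With species divergence touching many features and weaker
        structure effects, species labels separate cleanly on PC1-PC2."""
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(31)
        meta = make_sample_meta()
        n = 600
        base = 2.0 ** rng.uniform(6, 10, n)
        sp_eff = np.zeros(n)
        sp_eff[:180] = rng.choice([-2.0, 2.0], 180)
        st_eff = np.zeros(n)
        st_eff[180:240] = rng.choice([-1.0, 1.0], 60)
        mu = np.empty((n, 18))
        for j, (_s, row) in enumerate(meta.iterrows()):
            m = base.copy()
            if row["species"] == "B":
                m = m * 2.0 ** sp_eff
            if row["structure"] == "flower":
                m = m * 2.0 ** st_eff
            if row["structure"] == "fruit":
                m = m * 2.0 ** (1.5 * st_eff)
            mu[:, j] = m
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu))
        exp = CountExperiment(
            pd.DataFrame(counts, columns=meta.index,
                         index=[f"F{i}" for i in range(n)]),
            meta, pd.Series(1000, index=[f"F{i}" for i in range(n)]),
            "transcript")
        coords, _pct = pca_profile(normalize_counts(exp).normalized)
        labels = (meta["species"] == "B").astype(int)
        assert silhouette_score(coords[["PC1", "PC2"]], labels) >= 0.5
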