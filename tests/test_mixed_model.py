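import numpy as np
import pandas as pd
import pytest

from larchgp.data import RelationshipMatrix
from larchgp.kinship import genomic_matrix, pedigree_additive
from larchgp.mixed_model import (
    ModelSpec,
    RandomTerm,
    _reml_loglik,
    build_model,
    compare_models,
    extract_blups,
    fit_reml,
    heritability,
    information_criteria,
    predict_genetic_values,
)


def residual_only_spec(y, X=None):
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    return ModelSpec(
        trait="t", y=y, X=X, fixed_labels=[f"b{i}" for i in range(X.shape[1])],
        terms=[], ids=np.array([f"i{k}" for k in range(len(y))], dtype=object),
    )


def one_way_spec(y, groups):
    y = np.asarray(y, dtype=float)
    levels = sorted(set(groups))
    Z = np.column_stack([(np.asarray(groups) == g).astype(float) for g in levels])
    term = RandomTerm("a", np.eye(len(levels)), Z, np.array(levels, dtype=object))
    return ModelSpec(
        trait="t", y=y, X=np.ones((len(y), 1)), fixed_labels=["mu"],
        terms=[term], ids=np.array([f"i{k}" for k in range(len(y))], dtype=object),
    )


class TestREMLClosedForms:
    def test_residual_only_equals_sample_variance(self, rng):
        y = rng.standard_normal(40) * 2.3 + 1.0
        fit = fit_reml(residual_only_spec(y))
        assert fit.variances["residual"] == pytest.approx(np.var(y, ddof=1), rel=1e-6)

    def test_balanced_one_way_anova(self, rng):
        # REML on a balanced one-way random-effects design equals the ANOVA
        # estimators (MSB - MSW)/k and MSW when MSB > MSW
        g, k = 12, 8
        groups = np.repeat(np.arange(g), k)
        y = rng.standard_normal(g * k) + np.repeat(2.0 * rng.standard_normal(g), k)
        ybar = y.reshape(g, k).mean(axis=1)
        msb = k * np.sum((ybar - y.mean()) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, k) - ybar[:, None]) ** 2) / (g * (k - 1))
        fit = fit_reml(one_way_spec(y, groups), tolerance=1e-10)
        assert fit.variances["a"] == pytest.approx((msb - msw) / k, rel=1e-6)
        assert fit.variances["residual"] == pytest.approx(msw, rel=1e-6)

    def test_grid_search_oracle_small_n(self, rng):
        # dense grid over the variance ratio matches the REML solution, n <= 12
        n = 12
        B = rng.standard_normal((n, n))
        K = B @ B.T / n
        K = K + 0.5 * np.eye(n)
        y = rng.standard_normal(n) + np.linalg.cholesky(K) @ rng.standard_normal(n)
        X = np.ones((n, 1))
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        spec = ModelSpec(trait="t", y=y, X=X, fixed_labels=["mu"],
                         terms=[RandomTerm("a", K, np.eye(n), ids)], ids=ids)

        def profile_logL(ratio):
            # V = sigma2 * (ratio*K + I); sigma2 profiles to y'P0y/(n-p)
            V0 = ratio * K + np.eye(n)
            _, P0 = _reml_loglik(y, X, V0)
            s2 = float(y @ P0 @ y) / (n - X.shape[1])
            logL, _ = _reml_loglik(y, X, s2 * V0)
            return logL

        grid = np.linspace(0.0, 8.0, 3201)
        values = [profile_logL(r) if r > 0 else profile_logL(1e-9) for r in grid]
        r_star = grid[int(np.argmax(values))]
        fit = fit_reml(spec, tolerance=1e-10)
        ratio_fit = fit.variances["a"] / fit.variances["residual"]
        assert ratio_fit == pytest.approx(r_star, abs=grid[1] - grid[0] + 1e-4)


class TestAlgorithms:
    @pytest.mark.parametrize("seed", range(5))
    def test_ai_and_em_reach_same_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        B = rng.standard_normal((n, n))
        K = B @ B.T / n + 0.5 * np.eye(n)
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        y = np.linalg.cholesky(K) @ rng.standard_normal(n) * 1.3 \
            + rng.standard_normal(n)
        spec = ModelSpec(trait="t", y=y, X=np.ones((n, 1)), fixed_labels=["mu"],
                         terms=[RandomTerm("a", K, np.eye(n), ids)], ids=ids)
        ai = fit_reml(spec, algorithm="AI", tolerance=1e-10, max_iter=300)
        em = fit_reml(spec, algorithm="EM", tolerance=1e-10, max_iter=20000)
        assert ai.logL == pytest.approx(em.logL, abs=1e-6)

    def test_em_never_decreases_loglik(self, rng):
        n = 30
        B = rng.standard_normal((n, n))
        K = B @ B.T / n + 0.3 * np.eye(n)
        ids = np.array([f"i{k}" for k in range(n)], dtype=object)
        y = np.linalg.cholesky(K + np.eye(n)) @ rng.standard_normal(n)
        spec = ModelSpec(trait="t", y=y, X=np.ones((n, 1)), fixed_labels=["mu"],
                         terms=[RandomTerm("a", K, np.eye(n), ids)], ids=ids)
        # manual EM iterations, tracking logL
        theta = np.array([np.var(y) / 2, np.var(y) / 2])
        Cs = [K, np.eye(n)]
        prev = -np.inf
        for _ in range(40):
            V = theta[0] * Cs[0] + theta[1] * Cs[1]
            logL, P = _reml_loglik(y, np.ones((n, 1)), V)
            assert logL >= prev - 1e-9
            prev = logL
            Py = P @ y
            for k, C in enumerate(Cs):
                theta[k] += theta[k] ** 2 * (
                    float(Py @ C @ Py) - float(np.trace(P @ C))
                ) / n

    def test_nesting_monotonicity(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        g_d = genomic_matrix(mid_sim.genotypes_complete, "D")
        mats = {"a": g_a, "d": g_d}
        small = fit_reml(build_model(mid_sim.phenotypes, "Y", mats, {"plot", "a"}),
                         tolerance=1e-8)
        big = fit_reml(build_model(mid_sim.phenotypes, "Y", mats, {"plot", "a", "d"}),
                       tolerance=1e-8)
        assert big.logL >= small.logL - 1e-6

    def test_ablup_gblup_equivalence(self, mid_sim):
        # feeding the pedigree A as the "genomic" matrix reproduces ABLUP
        ids = list(mid_sim.genotypes_complete.ids)
        A = pedigree_additive(mid_sim.pedigree_op).subset(ids)
        as_genomic = RelationshipMatrix("gen_A", A.values, A.ids)
        f1 = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": A}, {"plot", "a"}))
        f2 = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": as_genomic},
                                  {"plot", "a"}))
        for lab in f1.variances:
            assert f1.variances[lab] == pytest.approx(f2.variances[lab], abs=1e-8)
        assert f1.logL == pytest.approx(f2.logL, abs=1e-8)


class TestInformationCriteria:
    def test_aic_arithmetic(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a}, {"plot", "a"}))
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(-2 * fit.logL + 2 * fit.rho)
        assert bic == pytest.approx(-2 * fit.logL + np.log(fit.n) * fit.rho)
        assert fit.rho == 3  # plot, a, residual

    def test_bic_variants_worked_example(self):
        fake = type("F", (), {"logL": -100.0, "rho": 3, "n": 100})()
        aic, bic_std = information_criteria(fake)
        assert aic == pytest.approx(206.0)
        assert bic_std == pytest.approx(200 + 3 * np.log(100))          # 213.815...
        _, bic_paper = information_criteria(fake, bic_variant="paper")
        assert bic_paper == pytest.approx(200 + 6 * np.log(100))        # 227.631...

    def test_threshold_ranking(self):
        def fake(name, aic):
            f = type("F", (), {})()
            f.spec_name, f.trait, f.n = name, "t", 100
            f.logL, f.rho = -(aic - 4) / 2, 2
            f.aic, f.bic, f.converged = aic, aic + 5, True
            return f

        # published example: 380.15 vs 377.81 -> delta 2.34 > 2, not tied
        df = compare_models([fake("m1", 380.15), fake("m2", 377.81)])
        assert df.loc[0, "model"] == "m2"
        assert not df.loc[df["model"] == "m1", "tied_with_best"].iloc[0]
        df = compare_models([fake("x", 100.0), fake("y", 101.9), fake("z", 105.0)])
        assert df["tied_with_best"].tolist() == [True, True, False]
        df = compare_models([fake("p", 50.0), fake("q", 50.0)])
        assert df["tied_with_best"].all()

    def test_mixed_traits_rejected(self):
        a = type("F", (), {"spec_name": "a", "trait": "x", "n": 10,
                           "logL": -1.0, "rho": 1, "aic": 1.0, "bic": 1.0,
                           "converged": True})()
        b = type("F", (), {"spec_name": "b", "trait": "y", "n": 10,
                           "logL": -1.0, "rho": 1, "aic": 1.0, "bic": 1.0,
                           "converged": True})()
        with pytest.raises(ValueError):
            compare_models([a, b])


class TestHeritability:
    def _fake_fit(self, variances):
        labels = list(variances)
        return type("F", (), {
            "variances": dict(variances),
            "cov_variances": pd.DataFrame(np.eye(len(labels)) * 1e-4,
                                          index=labels, columns=labels),
            "genetic_labels": [l for l in labels if l in "adie"],
        })()

    def test_substitution_examples(self):
        est = heritability(self._fake_fit({"plot": 1.0, "a": 2.0, "residual": 7.0}))
        assert est.sigma_P2 == pytest.approx(10.0)
        assert est.h2 == pytest.approx(0.2)
        assert est.H2 == pytest.approx(0.2)
        est = heritability(self._fake_fit(
            {"plot": 0.0, "a": 1.0, "d": 1.0, "e": 2.0, "residual": 4.0}))
        assert est.h2 == pytest.approx(0.125)
        assert est.H2 == pytest.approx(0.5)

    def test_proportions_sum_to_one(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        g_d = genomic_matrix(mid_sim.genotypes_complete, "D")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a, "d": g_d},
                                   {"plot", "a", "d"}))
        est = heritability(fit)
        assert sum(est.proportions.values()) == pytest.approx(1.0, abs=1e-8)
        assert est.h2 <= est.H2 <= 1.0

    def test_h2_undefined_without_additive(self):
        est = heritability(self._fake_fit({"plot": 1.0, "d": 1.0, "residual": 2.0}))
        assert est.h2 is None and est.se_h2 is None

    def test_delta_method_se_against_numerical_jacobian(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a}, {"plot", "a"}))
        est = heritability(fit)
        labels = list(fit.variances)
        theta = np.array([fit.variances[l] for l in labels])
        cov = fit.cov_variances.loc[labels, labels].to_numpy()

        def h2_of(th):
            return th[labels.index("a")] / th.sum()

        eps = 1e-7
        grad = np.array([
            (h2_of(theta + eps * np.eye(len(theta))[k]) -
             h2_of(theta - eps * np.eye(len(theta))[k])) / (2 * eps)
            for k in range(len(theta))
        ])
        se_num = float(np.sqrt(grad @ cov @ grad))
        assert est.se_h2 == pytest.approx(se_num, abs=1e-6)


class TestBLUPsAndPrediction:
    def test_total_equals_additive_for_a_only(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a}, {"plot", "a"}))
        add = extract_blups(fit, "additive_only")
        tot = extract_blups(fit, "total_genetic")
        assert np.allclose(add, tot)

    def test_blups_correlate_with_truth(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a}, {"plot", "a"}))
        a_hat = extract_blups(fit, "additive_only")
        truth = pd.Series(mid_sim.truth.true_genetic_values["a"],
                          index=mid_sim.truth.individual_ids)
        r = np.corrcoef(a_hat, truth.loc[a_hat.index])[0, 1]
        rng = np.random.default_rng(0)
        r_null = max(
            abs(np.corrcoef(rng.permutation(a_hat), truth.loc[a_hat.index])[0, 1])
            for _ in range(5)
        )
        assert r > 0.3 and r > r_null + 0.1

    def test_prediction_matches_training_blup(self, mid_sim):
        # predicting individuals that were *in* training reproduces their BLUPs
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a}, {"plot", "a"}))
        some = list(fit.ids[:10])
        pred = predict_genetic_values(fit, {"a": g_a}, some, "additive_only")
        blup = extract_blups(fit, "additive_only").loc[some]
        assert np.allclose(pred, blup, atol=1e-8)

    def test_unknown_which_rejected(self, mid_sim):
        g_a = genomic_matrix(mid_sim.genotypes_complete, "A")
        fit = fit_reml(build_model(mid_sim.phenotypes, "Y", {"a": g_a}, {"plot", "a"}))
        with pytest.raises(ValueError):
            extract_blups(fit, "everything")


class TestBuildModel:
    def test_missing_matrix_rejected(self, tiny_sim):
        with pytest.raises(ValueError, match="no matching matrix"):
            build_model(tiny_sim.phenotypes, "Y", {}, {"plot", "a"})

    def test_single_block_rejected(self, tiny_sim):
        pheno = tiny_sim.phenotypes.copy()
        pheno["block"] = 1
        g_a = genomic_matrix(tiny_sim.genotypes_complete, "A")
        with pytest.raises(ValueError, match="2 blocks"):
            build_model(pheno, "Y", {"a": g_a}, {"plot", "a"})

    def test_missing_trait_individuals_dropped(self, tiny_sim):
        pheno = tiny_sim.phenotypes.copy()
        pheno.loc[pheno.index[:5], "Y"] = np.nan
        g_a = genomic_matrix(tiny_sim.genotypes_complete, "A")
        spec = build_model(pheno, "Y", {"a": g_a}, {"plot", "a"})
        assert spec.n == len(pheno) - 5

    def test_matrix_sequence_maps_by_kind(self, tiny_sim):
        g_a = genomic_matrix(tiny_sim.genotypes_complete, "A")
        g_d = genomic_matrix(tiny_sim.genotypes_complete, "D")
        spec = build_model(tiny_sim.phenotypes, "Y", [g_a, g_d], {"plot", "a", "d"})
        assert set(spec.labels) == {"plot", "a", "d"}
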