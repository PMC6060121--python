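"""Formula grammar, design matrices, fixed/mixed fits and term tests."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from aseimprint import models
from aseimprint.models import ModelSpec, RandomBatch, add_term, build_design, \
    fit_fixed, fit_mixed, heuristic_search, parse_model_spec, \
    predict_random_coefficients, residual_diagnostics


def simulate_lmm_frame(rng, n_genes=10, n_ind=50, gene_sd=0.5, resid_sd=0.3,
                       age_slope_sd=0.0, fixed_age=0.0, dx_sd=0.0):
    """Direct draw from y = b0_gene + age*(beta + b1_gene) + b_dx + eps."""
    genes = [f"g{k:02d}" for k in range(n_genes)]
    age = rng.normal(0, 1, n_ind)
    dx = rng.choice(["Control", "SCZ", "AFF"], n_ind, p=[0.5, 0.4, 0.1])
    b0 = rng.normal(0, gene_sd, n_genes)
    b1 = rng.normal(0, age_slope_sd, n_genes) if age_slope_sd else np.zeros(n_genes)
    bdx = {lev: rng.normal(0, dx_sd) if dx_sd else 0.0
           for lev in ("Control", "SCZ", "AFF")}
    rows = []
    for gi, g in enumerate(genes):
        eps = rng.normal(0, resid_sd, n_ind)
        y = b0[gi] + age * (fixed_age + b1[gi]) + \
            np.array([bdx[d] for d in dx]) + eps
        for j in range(n_ind):
            rows.append({"individual": f"i{j:03d}", "gene": g, "Gene": g,
                         "Age": age[j], "Dx": dx[j], "Q": y[j], "T": 30})
    frame = pd.DataFrame(rows)
    frame.attrs["true_age_slopes"] = dict(zip(genes, fixed_age + b1))
    frame.attrs["true_intercepts"] = dict(zip(genes, b0))
    return frame


class TestFormulaGrammar:
    def test_parse_best_model_formula(self):
        spec = parse_model_spec(
            "Q ~ RIN + (1|RNA_batch) + (1|Institution) + "
            "(1|Institution:Individual) + (1|Gene:Institution) + "
            "(1|Gender:Gene) + (Age + RIN + Ancestry.1 + Ancestry.3 | Gene)")
        assert spec.response == "Q"
        assert spec.fixed == ("RIN",)
        assert len(spec.batches) == 6
        assert spec.batches[2].factors == ("Institution", "Individual")
        assert spec.batches[-1] == RandomBatch(
            ("Gene",), ("Age", "RIN", "Ancestry.1", "Ancestry.3"))

    def test_round_trip(self):
        text = "Q ~ 1 + RIN + (1 | RNA_batch) + (1 + Age | Gene)"
        spec = parse_model_spec(text)
        assert parse_model_spec(models.format_model_spec(spec)) == spec

    @pytest.mark.parametrize("bad", ["Q + Age", "Q ~ (Age Gene)", "Q ~ (1|)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(models.ModelError):
            parse_model_spec(bad)

    def test_add_term_merges_into_existing_batch(self):
        base = parse_model_spec("Q ~ (1|Gene)")
        merged = add_term(base, "(Age|Gene)")
        assert merged.batches == (RandomBatch(("Gene",), ("Age",)),)
        assert add_term(merged, "(Age|Gene)") == merged   # idempotent
        assert add_term(merged, "(1|Gene)") == merged
        two = add_term(merged, "(1|Dx)")
        assert len(two.batches) == 2


class TestBuildDesign:
    def test_toy_model_column_counts(self):
        # 2 genes x 3 individuals, both Dx levels present
        rows = []
        for g in ("g1", "g2"):
            for j, dx in enumerate(["Control", "SCZ", "Control"]):
                rows.append({"individual": f"i{j}", "gene": g, "Gene": g,
                             "Age": float(j), "Ancestry.1": 0.1 * j, "Dx": dx,
                             "Q": 1.0})
        data = pd.DataFrame(rows)
        spec = parse_model_spec(
            "Q ~ Age + (1 + Age + Ancestry.1 | Gene) + (1 | Dx:Gene)")
        des = build_design(data, spec)
        assert des.X.shape == (6, 2)                  # intercept + Age
        assert des.batch_dims == [3, 1]
        # batch 1: 2 genes x (1 + 2 slopes) = 6; batch 2: 2x2 levels = 4
        assert des.Z.shape == (6, 6 + 4)
        assert list(des.z_index.batch.value_counts().sort_index()) == [6, 4]

    def test_unknown_covariate_and_empty_rejected(self):
        data = pd.DataFrame({"individual": ["i"], "gene": ["g"], "Gene": ["g"],
                             "Q": [np.nan], "Age": [1.0]})
        with pytest.raises(models.ModelError):
            build_design(data.assign(Q=1.0), parse_model_spec("Q ~ Height"))
        with pytest.raises(models.ModelError):
            build_design(data, parse_model_spec("Q ~ Age"))

    def test_intercept_only(self):
        data = pd.DataFrame({"individual": list("abc"), "gene": "g",
                             "Gene": "g", "Q": [1.0, 2.0, 3.0]})
        des = build_design(data, parse_model_spec("Q ~ 1"))
        assert des.X.shape == (3, 1) and des.Z.shape == (3, 0)


class TestFixedModels:
    def test_noiseless_recovery(self, rng):
        age = rng.normal(0, 1, 40)
        data = pd.DataFrame({"gene": "g", "Age": age, "Q": 1.0 + 2.0 * age,
                             "T": 20})
        fit = fit_fixed(data, "Q", ("Age",), "unlm")
        params = fit.per_gene["g"]["params"]
        assert params["(Intercept)"] == pytest.approx(1.0, abs=1e-10)
        assert params["Age"] == pytest.approx(2.0, abs=1e-10)

    def test_constant_weights_equal_unweighted(self, rng):
        age = rng.normal(0, 1, 30)
        data = pd.DataFrame({"gene": "g", "Age": age,
                             "Q": 1.0 + 0.5 * age + rng.normal(0, 0.2, 30),
                             "T": 7})
        un = fit_fixed(data, "Q", ("Age",), "unlm").per_gene["g"]["params"]
        wn = fit_fixed(data, "Q", ("Age",), "wnlm").per_gene["g"]["params"]
        assert np.allclose(un.to_numpy(), wn.to_numpy(), atol=1e-10)

    def test_ci_coverage_near_nominal(self, rng):
        """~95% of 1000 noisy replicates cover the true age slope."""
        n, beta, sigma = 500, 0.01, 0.2
        covered = 0
        for _ in range(1000):
            age = rng.normal(0, 1, n)
            data = pd.DataFrame({"gene": "g", "Age": age, "T": 20,
                                 "Q": 1.0 + beta * age + rng.normal(0, sigma, n)})
            res = fit_fixed(data, "Q", ("Age",), "unlm").per_gene["g"]
            lo, hi = res["conf_int"].loc["Age"]
            covered += lo <= beta <= hi
        assert 0.93 <= covered / 1000 <= 0.97

    def test_collinear_design_named(self, rng):
        data = pd.DataFrame({"gene": "g", "Age": 1.0, "Q": rng.normal(size=20),
                             "T": 5})
        with pytest.raises(models.ModelError, match="Age"):
            fit_fixed(data, "Q", ("Age",), "unlm")


class TestMixedFit:
    def test_no_random_terms_equals_ols(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=4, n_ind=30)
        des = build_design(frame, parse_model_spec("Q ~ Age"))
        fit = fit_mixed(des)
        X, y = des.X, des.y
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-10)
        assert fit.n_params == 3  # 2 coefficients + sigma^2

    def test_zero_variance_hits_boundary(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=6, n_ind=40, gene_sd=0.0)
        # remove even the chance between-gene variation so the ML estimate
        # of the gene variance component must sit on the zero boundary
        frame["Q"] = frame.Q - frame.groupby("gene").Q.transform("mean") \
            + frame.Q.mean()
        des = build_design(frame, parse_model_spec("Q ~ (1|Gene)"))
        fit = fit_mixed(des)
        assert fit.singular
        assert fit.omega_blocks[0][0, 0] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(predict_random_coefficients(fit).estimate, 0.0,
                           atol=1e-5)
        beta_ols = np.linalg.lstsq(des.X, des.y, rcond=None)[0]
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-4)

    def test_loglik_matches_mvn_density(self, rng):
        """Brute-force multivariate-normal evaluation, <= 200 observations."""
        frame = simulate_lmm_frame(rng, n_genes=5, n_ind=30, gene_sd=0.4,
                                   age_slope_sd=0.2, fixed_age=0.1)
        des = build_design(frame, parse_model_spec("Q ~ Age + (Age|Gene)"))
        fit = fit_mixed(des)
        q = des.Z.shape[1]
        Omega = np.zeros((q, q))
        pos = 0
        for blk, levels in zip(fit.omega_blocks, des.batch_levels):
            d = blk.shape[0]
            for _ in levels:
                Omega[pos:pos + d, pos:pos + d] = blk
                pos += d
        V = fit.sigma2 * np.eye(des.n_obs) + des.Z @ Omega @ des.Z.T
        ll = multivariate_normal.logpdf(des.y, des.X @ fit.beta.to_numpy(), V)
        assert fit.loglik == pytest.approx(ll, rel=1e-6)

    def test_agrees_with_lme4(self, rng, tmp_path):
        """Independent optimizer check: R/lme4 ML fit on the same data."""
        frame = simulate_lmm_frame(rng, n_genes=5, n_ind=25, gene_sd=0.5,
                                   age_slope_sd=0.3, fixed_age=0.2)
        des = build_design(frame, parse_model_spec("Q ~ Age + (Age|Gene)"))
        fit = fit_mixed(des)
        data_path = tmp_path / "d.tsv"
        frame.to_csv(data_path, sep="\t", index=False)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.delim('{data_path}')\n"
            "m <- lmer(Q ~ Age + (Age|Gene), data=d, REML=FALSE)\n"
            "cat(sprintf('%.10f %.10f', as.numeric(logLik(m)), AIC(m)))\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ll_r, aic_r = map(float, out.stdout.split())
        assert fit.loglik == pytest.approx(ll_r, abs=1e-4)
        assert fit.aic == pytest.approx(aic_r, abs=1e-3)

    def test_row_order_invariance(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=5, n_ind=20, gene_sd=0.4)
        spec = parse_model_spec("Q ~ Age + (1|Gene)")
        fit1 = fit_mixed(build_design(frame, spec))
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_mixed(build_design(shuffled, spec))
        assert fit1.loglik == pytest.approx(fit2.loglik, rel=1e-8)
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-6)

    def test_aic_identity(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=5, n_ind=20, gene_sd=0.4)
        fit = fit_mixed(build_design(frame, parse_model_spec("Q ~ (1|Gene)")))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_rank_deficient_named(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=4, n_ind=10)
        frame["Dup"] = frame.Age
        with pytest.raises(models.ModelError, match="Dup"):
            fit_mixed(build_design(frame,
                                   parse_model_spec("Q ~ Age + Dup + (1|Gene)")))


class TestTermTests:
    def test_delta_aic_chi2_consistency(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=8, n_ind=40, gene_sd=0.5)
        res = models.test_term(frame, parse_model_spec("Q ~ 1"), "(1|Gene)")
        assert res.delta_aic == pytest.approx(2 * res.df - res.chi2, abs=1e-6)
        assert res.delta_aic < 0  # strong gene effect must be detected
        assert res.p_value < 1e-6

    def test_constant_covariate_changes_nothing(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=6, n_ind=30, gene_sd=0.5)
        frame["Flat"] = 1.0
        res = models.test_term(frame, parse_model_spec("Q ~ (1|Gene)"), "(Flat|Gene)")
        assert res.chi2 == pytest.approx(0.0, abs=1e-4)
        assert res.p_value > 0.99
        assert res.delta_aic == pytest.approx(2 * res.df, abs=1e-4)

    def test_term_already_present_rejected(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=4, n_ind=10, gene_sd=0.5)
        with pytest.raises(models.ModelError):
            models.test_term(frame, parse_model_spec("Q ~ (1|Gene)"), "(1|Gene)")


class TestHeuristicSearch:
    def test_empty_candidates_identity(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=4, n_ind=20, gene_sd=0.5)
        start = parse_model_spec("Q ~ (1|Gene)")
        final, trail = heuristic_search(frame, start, [])
        assert final == start and trail.empty

    def test_duplicate_candidate_noop(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=6, n_ind=30, gene_sd=0.5)
        final, trail = heuristic_search(
            frame, parse_model_spec("Q ~ 1"), ["(1|Gene)", "(1|Gene)"])
        assert final == parse_model_spec("Q ~ (1|Gene)")
        assert trail.note.iloc[1] == "already in model"

    def test_recovers_generating_structure(self, rng):
        """Keeps (1|Gene), drops spurious (1|Dx) and (Age|Gene), >=80%."""
        hits = 0
        for _ in range(50):
            frame = simulate_lmm_frame(rng, n_genes=8, n_ind=40, gene_sd=0.5,
                                       resid_sd=0.3)
            final, _ = heuristic_search(
                frame, parse_model_spec("Q ~ 1"),
                ["(1|Gene)", "(1|Dx)", "(Age|Gene)"])
            ok = (final.batches == (RandomBatch(("Gene",)),))
            hits += ok
        assert hits >= 40


class TestRandomCoefficientPrediction:
    def test_shrinkage_vs_per_gene_ols(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=15, n_ind=25, gene_sd=0.3,
                                   resid_sd=0.5)
        fit = fit_mixed(build_design(frame, parse_model_spec("Q ~ (1|Gene)")))
        pred = predict_random_coefficients(fit)
        per_gene_means = frame.groupby("gene").Q.mean() - frame.Q.mean()
        assert pred.estimate.var() <= per_gene_means.var() + 1e-12

    def test_slope_recovery_correlation(self, rng):
        frame = simulate_lmm_frame(rng, n_genes=20, n_ind=500, gene_sd=0.3,
                                   age_slope_sd=0.15, resid_sd=0.3)
        fit = fit_mixed(build_design(frame,
                                     parse_model_spec("Q ~ Age + (Age|Gene)")))
        pred = predict_random_coefficients(fit)
        slopes = pred[pred.variable == "Age"].set_index("level").estimate
        truth = pd.Series(frame.attrs["true_age_slopes"])
        truth = truth - truth.mean()
        common = slopes.index
        r = np.corrcoef(slopes[common], truth[common])[0, 1]
        assert r >= 0.8


class TestDiagnostics:
    def test_normal_residuals_high_qq(self, rng):
        resid = rng.normal(0, 1, 2000)
        fitted = rng.normal(0, 1, 2000)
        diag = residual_diagnostics(resid, fitted)
        assert diag["qq_correlation"] > 0.99 and diag["normal_ok"]

    def test_heavy_tails_lower_qq(self, rng):
        n = 2000
        normal = residual_diagnostics(rng.normal(0, 1, n), np.zeros(n))
        heavy = residual_diagnostics(rng.standard_t(2, n), np.zeros(n))
        assert heavy["qq_correlation"] < normal["qq_correlation"] - 0.01

    def test_constant_residuals_flagged(self):
        diag = residual_diagnostics(np.ones(50), np.ones(50))
        assert diag["degenerate"]
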