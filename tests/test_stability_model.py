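"""GLMM fitting against quadrature and logistic-regression oracles; AICc; R²."""

import math

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize_scalar
from scipy.special import expit

from melostab.predictors import FEATURE_NAMES
from melostab.stability_model import (
    FittedGLMM,
    ModelError,
    aicc,
    all_subsets_selection,
    build_outcome_table,
    conditional_r2_from_components,
    estimate_correlations,
    fit_glmm,
    max_estimate_correlation,
    r2_nakagawa,
    standardize,
)
from melostab.synthetic import OutcomeGenConfig, generate_outcomes


def quadrature_loglik(table, beta, sigma, features=FEATURE_NAMES, nodes=61):
    """High-accuracy adaptive Gauss-Hermite marginal log-likelihood oracle."""
    X = np.column_stack(
        [np.ones(len(table))] + [table[f + "_z"].to_numpy(float) for f in features]
    )
    y = table["occurs"].to_numpy(float)
    codes, _ = pd.factorize(table["tune_family_id"])
    xs, ws = hermegauss(nodes)
    ll = 0.0
    for g in np.unique(codes):
        idx = codes == g
        xb = X[idx] @ beta
        yy = y[idx]

        def neg_joint(u):
            eta = xb + u
            return -(np.sum(yy * eta - np.logaddexp(0, eta)) - u * u / (2 * sigma**2))

        mode = minimize_scalar(neg_joint, bounds=(-10, 10), method="bounded",
                               options={"xatol": 1e-11}).x
        mu = expit(xb + mode)
        scale = 1.0 / math.sqrt(np.sum(mu * (1 - mu)) + 1.0 / sigma**2)
        u = mode + scale * xs
        eta = xb[None, :] + u[:, None]
        log_joint = (
            (yy[None, :] * eta - np.logaddexp(0, eta)).sum(axis=1)
            - u**2 / (2 * sigma**2)
            - 0.5 * math.log(2 * math.pi * sigma**2)
        )
        ll += math.log(np.sum(ws * np.exp(log_joint + xs**2 / 2)) * scale)
    return ll


class TestStandardize:
    def _frame(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({f: rng.normal(3, 2, size=n) for f in FEATURE_NAMES})

    def test_standardized_columns_have_mean0_sd1(self):
        out, stats = standardize(self._frame())
        for f in FEATURE_NAMES:
            z = out[f + "_z"]
            assert abs(z.mean()) < 1e-10
            assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_idempotent_on_already_standard_columns(self):
        out, _ = standardize(self._frame())
        renamed = out[[f + "_z" for f in FEATURE_NAMES]].rename(
            columns=lambda c: c[:-2]
        )
        twice, _ = standardize(renamed)
        for f in FEATURE_NAMES:
            assert np.allclose(twice[f + "_z"], renamed[f], atol=1e-10)

    def test_zero_sd_feature_named_in_error(self):
        frame = self._frame()
        frame["reversal"] = 1.5
        with pytest.raises(ModelError, match="reversal"):
            standardize(frame)


class TestOutcomeTable:
    def _inputs(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(
            {
                "melody_id": [f"m{i}" for i in range(10)],
                "phrase_index": [1] * 10,
                **{f: rng.normal(size=10) for f in FEATURE_NAMES},
            }
        )
        occ = pd.DataFrame(
            [
                {
                    "tune_family_id": "tf1",
                    "melody_id": f"m{i}",
                    "phrase_index": 1,
                    "target_melody_id": f"t{j}",
                    "occurs": int((i + j) % 2),
                }
                for i in range(10)
                for j in range(5)
            ]
        )
        return occ, feats

    def test_row_count_is_phrases_times_targets(self):
        occ, feats = self._inputs()
        table = build_outcome_table(occ, feats)
        assert len(table) == 50

    def test_undefined_feature_rows_dropped_and_logged(self):
        occ, feats = self._inputs()
        feats.loc[feats["melody_id"] == "m3", "surprisal"] = np.nan
        log = {}
        table = build_outcome_table(occ, feats, log)
        assert len(table) == 45
        assert log["phrases_dropped_undefined"] == 1

    def test_orphan_occurrence_rows_rejected(self):
        occ, feats = self._inputs()
        occ.loc[len(occ)] = ["tf1", "ghost", 1, "t0", 1]
        with pytest.raises(ModelError, match="ghost"):
            build_outcome_table(occ, feats)

    def test_row_multiset_invariant_under_input_order(self):
        occ, feats = self._inputs()
        a = build_outcome_table(occ, feats)
        b = build_outcome_table(
            occ.sample(frac=1, random_state=0), feats.sample(frac=1, random_state=1)
        )
        key = ["melody_id", "phrase_index", "target_melody_id"]
        a_sorted = a.sort_values(key).reset_index(drop=True)
        b_sorted = b.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a_sorted, b_sorted[a_sorted.columns])


class TestGlmmFit:
    def test_null_model_estimates_near_zero(self):
        cfg = OutcomeGenConfig(
            n_phrases=1000, n_families=50,
            intercept=0.0, beta={f: 0.0 for f in FEATURE_NAMES}, sigma_tf=0.0,
        )
        table = generate_outcomes(cfg, seed=10)
        fit = fit_glmm(table)
        assert fit.converged
        for est, se in zip(fit.beta, fit.se_beta):
            assert abs(est) < 3 * se + 1e-6

    def test_sigma_near_zero_when_no_group_effect(self):
        cfg = OutcomeGenConfig(
            n_phrases=800, n_families=40,
            intercept=0.3, beta={f: 0.0 for f in FEATURE_NAMES}, sigma_tf=0.0,
        )
        fit = fit_glmm(generate_outcomes(cfg, seed=11))
        assert fit.sigma_tf < 0.15

    def test_laplace_matches_quadrature_on_small_instances(self):
        for seed in (3, 4, 5):
            cfg = OutcomeGenConfig(n_phrases=40, n_families=10, variants_per_family=6)
            table = generate_outcomes(cfg, seed=seed)
            fit = fit_glmm(table)
            oracle = quadrature_loglik(table, fit.beta, fit.sigma_tf)
            assert abs(fit.loglik - oracle) < 0.1

    def test_reduces_to_plain_logistic_when_sigma_vanishes(self):
        import statsmodels.api as sm

        cfg = OutcomeGenConfig(
            n_phrases=600, n_families=30,
            beta={f: (0.4 if f == "length" else 0.0) for f in FEATURE_NAMES},
            sigma_tf=0.0,
        )
        table = generate_outcomes(cfg, seed=12)
        fit = fit_glmm(table, features=("length",))
        X = sm.add_constant(table["length_z"].to_numpy())
        ref = sm.Logit(table["occurs"], X).fit(disp=0)
        assert fit.sigma_tf < 0.05
        assert np.allclose(fit.beta, ref.params, atol=1e-3)

    def test_recovery_of_reference_parameters(self):
        cfg = OutcomeGenConfig(n_phrases=2000, n_families=150)
        table = generate_outcomes(cfg, seed=13)
        fit = fit_glmm(table)
        truth = np.array([cfg.intercept] + [cfg.beta[f] for f in FEATURE_NAMES])
        assert np.all(np.abs(fit.beta - truth) < 3 * fit.se_beta)
        assert abs(fit.sigma_tf - cfg.sigma_tf) < 3 * fit.se_sigma_tf

    def test_matches_lme4_reference_fit(self, tmp_path):
        """Cross-check the Laplace ML fit against R's lme4 glmer on one dataset."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        cfg = OutcomeGenConfig(n_phrases=200, n_families=25, variants_per_family=6)
        table = generate_outcomes(cfg, seed=14)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        cols = " + ".join(f"{f}_z" for f in FEATURE_NAMES)
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            f"m <- glmer(occurs ~ {cols} + (1|tune_family_id), data=d, family=binomial)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        ref_beta, ref_sigma, ref_ll = np.array(vals[:8]), vals[8], vals[9]
        fit = fit_glmm(table)
        assert np.allclose(fit.beta, ref_beta, atol=0.02)
        assert abs(fit.sigma_tf - ref_sigma) < 0.03
        assert abs(fit.loglik - ref_ll) < 0.5

    def test_single_class_outcome_rejected(self):
        cfg = OutcomeGenConfig(n_phrases=50, n_families=5)
        table = generate_outcomes(cfg, seed=15)
        table["occurs"] = 1
        with pytest.raises(ModelError, match="single class"):
            fit_glmm(table)


class TestAicc:
    def _fake_fit(self, loglik, k, n):
        return FittedGLMM(
            feature_names=tuple(), beta=np.zeros(k - 1), se_beta=np.zeros(k - 1),
            sigma_tf=0.0, se_sigma_tf=0.0, loglik=loglik, n_obs=n, n_groups=2,
            k_params=k, converged=True, vcov_beta=np.zeros((k - 1, k - 1)),
            var_fixed=0.0,
        )

    def test_closed_form(self):
        fit = self._fake_fit(loglik=-100.0, k=3, n=100)
        assert aicc(fit) == pytest.approx(206.0 + 24 / 96)

    def test_exceeds_plain_aic(self):
        fit = self._fake_fit(loglik=-50.0, k=4, n=200)
        assert aicc(fit) > -2 * fit.loglik + 2 * fit.k_params

    def test_too_few_observations_rejected(self):
        fit = self._fake_fit(loglik=-5.0, k=4, n=5)
        with pytest.raises(ModelError, match="n_obs"):
            aicc(fit)


class TestModelSelection:
    def _planted_table(self, seed):
        beta = {f: 0.0 for f in FEATURE_NAMES}
        beta["surprisal"] = -0.6
        cfg = OutcomeGenConfig(
            n_phrases=250, n_families=30, variants_per_family=6,
            intercept=0.0, beta=beta, sigma_tf=0.5,
        )
        return generate_outcomes(cfg, seed=seed)

    def test_planted_feature_selected(self):
        result = all_subsets_selection(self._planted_table(seed=21))
        assert "surprisal" in result.best_subset

    def test_all_subsets_present_and_ranked(self):
        table = self._planted_table(seed=22)
        result = all_subsets_selection(table, features=("length", "surprisal"))
        assert len(result.entries) + len(result.failed) == 4
        assert result.entries["aicc"].is_monotonic_increasing
        assert result.entries["delta_aicc"].iloc[0] == 0.0

    def test_ranking_invariant_to_feature_order(self):
        table = self._planted_table(seed=23)
        a = all_subsets_selection(table, features=("length", "surprisal", "position"))
        b = all_subsets_selection(table, features=("position", "length", "surprisal"))
        ra = [frozenset(s) for s in a.entries["subset"]]
        rb = [frozenset(s) for s in b.entries["subset"]]
        assert ra == rb


class TestEffectSize:
    def test_marginal_zero_when_no_fixed_effects(self):
        marginal, conditional = conditional_r2_from_components(0.0, 0.84)
        assert marginal == 0.0
        assert conditional > 0.0

    def test_equal_when_no_random_variance(self):
        marginal, conditional = conditional_r2_from_components(0.5, 0.0)
        assert marginal == conditional

    def test_reference_variance_components_give_conditional_022(self):
        # with sigma_tf = 0.84 and marginal R2 = 0.05, back out var_fixed and
        # confirm the conditional R2 the published analysis reports
        sigma_tf = 0.84
        resid = math.pi**2 / 3
        var_fixed = 0.05 / 0.95 * (sigma_tf**2 + resid)
        marginal, conditional = conditional_r2_from_components(var_fixed, sigma_tf)
        assert marginal == pytest.approx(0.05, abs=1e-12)
        assert round(conditional, 2) == 0.22

    def test_bounds_and_ordering_on_fitted_model(self):
        cfg = OutcomeGenConfig(n_phrases=400, n_families=30)
        fit = fit_glmm(generate_outcomes(cfg, seed=30))
        marginal, conditional = r2_nakagawa(fit)
        assert 0.0 <= marginal <= conditional <= 1.0


class TestEstimateCorrelations:
    def test_matrix_symmetric_unit_diagonal(self):
        cfg = OutcomeGenConfig(n_phrases=400, n_families=30)
        fit = fit_glmm(generate_outcomes(cfg, seed=31))
        corr = estimate_correlations(fit).to_numpy()
        assert np.allclose(corr, corr.T, atol=1e-10)
        assert np.allclose(np.diag(corr), 1.0, atol=1e-10)

    def test_independent_features_weakly_correlated(self):
        cfg = OutcomeGenConfig(n_phrases=1000, n_families=50)
        fit = fit_glmm(generate_outcomes(cfg, seed=32))
        corr = estimate_correlations(fit).to_numpy()
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.max(np.abs(off)) < 0.3

    def test_duplicated_feature_column_reported_as_collinear(self):
        cfg = OutcomeGenConfig(n_phrases=400, n_families=30)
        table = generate_outcomes(cfg, seed=33)
        table["reversal_z"] = table["length_z"]
        fit = fit_glmm(table, features=("length", "reversal"))
        assert max_estimate_correlation(fit) > 0.95
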