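"""Mixed-effects modelling of phrase occurrence probability.

The outcome table pairs every query phrase with every other variant of its
tune family (binary: the phrase occurs there or not) and carries the seven
standardized memorability predictors.  Occurrence probability is modelled
by a logistic GLMM with fixed slopes and a random intercept per tune
family, which absorbs the family-dependent error of the occurrence
detector:

    logit P(occurs) = beta0 + beta' F + u_family,   u ~ N(0, sigma_tf^2)

Estimation is maximum likelihood with a Laplace approximation to the
random-intercept integrals (one scalar mode per family, found by a
vectorized Newton iteration).  Model comparison uses the small-sample
Akaike criterion AICc over all subsets of the seven predictors, and effect
size is reported as Nakagawa–Schielzeth marginal/conditional R² with the
logit-link distribution-specific variance pi^2/3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .predictors import FEATURE_NAMES

LOGIT_RESIDUAL_VARIANCE = math.pi ** 2 / 3


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Outcome table assembly


def standardize(values: pd.DataFrame, columns=FEATURE_NAMES):
    """Z-score the given columns: (x - mean) / SD, with the stats returned.

    The statistics are computed over the rows given (one row per unique
    phrase); a zero-SD column is an error naming the column, since a
    constant predictor cannot be standardized.
    """
    out = values.copy()
    stats = {}
    for col in columns:
        x = values[col].to_numpy(dtype=float)
        mean = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ModelError(f"feature {col!r} has zero standard deviation")
        out[col + "_z"] = (x - mean) / sd
        stats[col] = (mean, sd)
    return out, stats


def build_outcome_table(
    occurrences,
    features: pd.DataFrame,
    drop_log: dict | None = None,
) -> pd.DataFrame:
    """Join occurrence records with per-phrase features into the model table.

    ``occurrences`` is an iterable of OccurrenceRecord (or a DataFrame with
    the same columns); ``features`` has one row per unique phrase with the
    seven raw predictors.  Standardization statistics are computed over the
    unique phrases and broadcast to the phrase x melody rows.  Phrases with
    undefined (NaN) features are dropped, with the count recorded in
    ``drop_log`` when given; occurrence rows without any feature row raise.
    """
    if isinstance(occurrences, pd.DataFrame):
        occ = occurrences.rename(columns={"source_melody_id": "melody_id"}).copy()
    else:
        occ = pd.DataFrame(
            {
                "tune_family_id": r.tune_family_id,
                "melody_id": r.source_melody_id,
                "phrase_index": r.phrase_index,
                "target_melody_id": r.target_melody_id,
                "cityblock": r.scores.cityblock,
                "alignment": r.scores.alignment,
                "siam": r.scores.siam,
                "occurs": int(r.occurs),
            }
            for r in occurrences
        )
    feats = features.copy()
    keys = ["melody_id", "phrase_index"]

    n_before = len(feats)
    defined = feats[list(FEATURE_NAMES)].notna().all(axis=1)
    feats = feats[defined]
    if drop_log is not None:
        drop_log["phrases_dropped_undefined"] = int(n_before - len(feats))

    feats, stats = standardize(feats)
    merged = occ.merge(feats, on=keys, how="left", validate="many_to_one")
    # rows whose phrase was dropped for undefined features are removed below;
    # rows that never had a feature row at all are an input error
    feature_index = set(map(tuple, features[keys].itertuples(index=False)))
    orphan_ids = [
        t for t in map(tuple, occ[keys].drop_duplicates().itertuples(index=False))
        if t not in feature_index
    ]
    if orphan_ids:
        raise ModelError(f"occurrence rows without features: {orphan_ids[:5]}")
    merged = merged.dropna(subset=[c + "_z" for c in FEATURE_NAMES])
    merged.attrs["feature_stats"] = stats
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Laplace ML fit of the random-intercept logistic model


@dataclass
class FittedGLMM:
    feature_names: tuple[str, ...]  # slopes, excluding intercept
    beta: np.ndarray                # intercept first
    se_beta: np.ndarray
    sigma_tf: float
    se_sigma_tf: float
    loglik: float
    n_obs: int
    n_groups: int
    k_params: int                   # intercept + slopes + variance
    converged: bool
    vcov_beta: np.ndarray
    var_fixed: float                # variance of X @ beta over rows
    random_intercepts: dict = field(default_factory=dict)

    @property
    def ci95(self) -> np.ndarray:
        return np.column_stack(
            [self.beta - 1.96 * self.se_beta, self.beta + 1.96 * self.se_beta]
        )

    def summary(self) -> pd.DataFrame:
        rows = [("intercept", *self._row(0))]
        rows += [
            (name, *self._row(i + 1)) for i, name in enumerate(self.feature_names)
        ]
        return pd.DataFrame(
            rows, columns=["parameter", "estimate", "se", "ci_low", "ci_high"]
        )

    def _row(self, i):
        return (
            float(self.beta[i]),
            float(self.se_beta[i]),
            float(self.beta[i] - 1.96 * self.se_beta[i]),
            float(self.beta[i] + 1.96 * self.se_beta[i]),
        )


def _laplace_loglik(beta, log_sigma, y, X, groups, n_groups, u0, inner_tol=1e-11,
                    max_inner=60):
    """Laplace log-likelihood; returns (loglik, u_hat, W_sums)."""
    sigma2 = math.exp(2.0 * log_sigma)
    fixed = X @ beta
    u = u0.copy()
    for _ in range(max_inner):
        eta = fixed + u[groups]
        mu = expit(eta)
        g = np.bincount(groups, weights=y - mu, minlength=n_groups) - u / sigma2
        w = np.bincount(groups, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / sigma2
        step = g / w
        u += step
        if np.max(np.abs(step)) < inner_tol:
            break
    eta = fixed + u[groups]
    # binomial log-likelihood, stable log(1+exp)
    bin_ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    W = np.bincount(groups, weights=expit(eta) * (1 - expit(eta)), minlength=n_groups)
    ll = bin_ll - float(np.sum(u * u)) / (2 * sigma2) - 0.5 * float(
        np.sum(np.log1p(sigma2 * W))
    )
    return ll, u, W


def _agq_loglik(beta, log_sigma, y, X, groups, n_groups, u0, n_quad):
    """Adaptive Gauss-Hermite refinement of the Laplace log-likelihood.

    Centers ``n_quad`` probabilists' Hermite nodes at each family's mode,
    scaled by the local curvature; ``n_quad=1`` reproduces the plain
    Laplace value.  Vectorized over families.
    """
    ll_lap, u, W = _laplace_loglik(beta, log_sigma, y, X, groups, n_groups, u0)
    if n_quad <= 1:
        return ll_lap, u
    sigma2 = math.exp(2.0 * log_sigma)
    scale = 1.0 / np.sqrt(W + 1.0 / sigma2)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    fixed = X @ beta
    log_terms = np.empty((n_quad, n_groups))
    for k, x in enumerate(nodes):
        uk = u + scale * x
        eta = fixed + uk[groups]
        per_row = y * eta - np.logaddexp(0.0, eta)
        log_terms[k] = (
            np.bincount(groups, weights=per_row, minlength=n_groups)
            - uk**2 / (2 * sigma2)
            - 0.5 * math.log(2 * math.pi * sigma2)
            + x * x / 2
        )
    m = log_terms.max(axis=0)
    integral = np.log(np.sum(weights[:, None] * np.exp(log_terms - m), axis=0))
    ll = float(np.sum(m + integral + np.log(scale)))
    return ll, u


def fit_glmm(
    table: pd.DataFrame,
    features=FEATURE_NAMES,
    outcome: str = "occurs",
    group: str = "tune_family_id",
    standardized: bool = True,
    tol: float = 1e-6,
    max_sigma: float = 25.0,
    n_quad: int = 20,
) -> FittedGLMM:
    """ML fit of the random-intercept logistic model on the outcome table.

    ``features`` names the slope columns (their ``_z`` counterparts are
    used when ``standardized``); an empty tuple fits the intercept-only
    model.  Optimization uses the Laplace approximation; the reported
    log-likelihood is refined at the optimum by ``n_quad``-node adaptive
    Gauss-Hermite quadrature (1 = pure Laplace).  Convergence is by
    projected-gradient norm below ``tol``; a non-convergent fit is
    returned flagged, never silently.
    """
    cols = [f + "_z" if standardized else f for f in features]
    y = table[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ModelError("outcome has a single class; cannot fit")
    codes, _ = pd.factorize(table[group])
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ModelError("need at least 2 tune families for a random intercept")
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in cols])

    p = X.shape[1]
    u_cache = np.zeros(n_groups)

    def negloglik(params):
        nonlocal u_cache
        ll, u_cache, _ = _laplace_loglik(
            params[:p], params[p], y, X, codes, n_groups, u_cache
        )
        return -ll

    x0 = np.zeros(p + 1)
    x0[0] = math.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    x0[p] = math.log(0.5)
    bounds = [(None, None)] * p + [(math.log(1e-4), math.log(max_sigma))]
    res = minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": tol},
    )
    params = res.x
    beta, log_sigma = params[:p], params[p]
    sigma = math.exp(log_sigma)
    ll, u_hat = _agq_loglik(beta, log_sigma, y, X, codes, n_groups, u_cache, n_quad)

    # observed information by central finite differences
    at_bound = log_sigma <= math.log(1e-4) + 1e-8
    H = _numeric_hessian(negloglik, params, fixed_last=at_bound)
    se = np.full(p + 1, np.nan)
    vcov_beta = np.full((p, p), np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        if np.all(d[: p] > 0):
            se[:p] = np.sqrt(d[:p])
            vcov_beta = cov[:p, :p]
        if not at_bound and d[p] > 0:
            se[p] = math.sqrt(d[p])
    except np.linalg.LinAlgError:
        pass

    group_names = pd.unique(table[group])
    return FittedGLMM(
        feature_names=tuple(features),
        beta=beta.copy(),
        se_beta=se[:p],
        sigma_tf=sigma,
        se_sigma_tf=float(sigma * se[p]) if np.isfinite(se[p]) else float("nan"),
        loglik=float(ll),
        n_obs=len(y),
        n_groups=n_groups,
        k_params=p + 1,
        converged=bool(res.success),
        vcov_beta=vcov_beta,
        var_fixed=float(np.var(X @ beta)),
        random_intercepts=dict(zip(group_names, u_hat)),
    )


def _numeric_hessian(f, x, step: float = 1e-4, fixed_last: bool = False) -> np.ndarray:
    n = len(x) - (1 if fixed_last else 0)
    H = np.zeros((len(x), len(x)))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            e_i = np.zeros(len(x)); e_i[i] = step
            e_j = np.zeros(len(x)); e_j[j] = step
            if i == j:
                H[i, i] = (f(x + e_i) - 2 * f0 + f(x - e_i)) / step ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + e_i + e_j) - f(x + e_i - e_j)
                    - f(x - e_i + e_j) + f(x - e_i - e_j)
                ) / (4 * step ** 2)
    if fixed_last:
        H[-1, -1] = 1.0  # variance pinned at the boundary; dummy block
    return H


# ---------------------------------------------------------------------------
# Information criteria, model selection, effect size


def aicc(fit: FittedGLMM) -> float:
    """Second-order Akaike information criterion of a converged fit."""
    if not fit.converged:
        raise ModelError("AICc requested for a non-converged fit")
    k, n = fit.k_params, fit.n_obs
    if n <= k + 1:
        raise ModelError(f"AICc undefined: n_obs={n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelSelectionResult:
    entries: pd.DataFrame        # subset, k, aicc, delta_aicc, sorted ascending
    fits: dict                   # frozenset(subset) -> FittedGLMM
    failed: list                 # subsets that did not converge

    @property
    def best_subset(self) -> tuple[str, ...]:
        return tuple(self.entries.iloc[0]["subset"])

    @property
    def best_fit(self) -> FittedGLMM:
        return self.fits[frozenset(self.best_subset)]

    def best_per_df(self) -> pd.DataFrame:
        """Table of the best model per parameter count (degrees of freedom)."""
        rows = []
        for k, grp in self.entries.groupby("k"):
            top = grp.iloc[0]
            fit = self.fits[frozenset(top["subset"])]
            coef = dict(zip(fit.feature_names, fit.beta[1:]))
            rows.append({"df": k, "aicc": top["aicc"], **coef})
        return pd.DataFrame(rows).sort_values("df").reset_index(drop=True)


def all_subsets_selection(
    table: pd.DataFrame,
    features=FEATURE_NAMES,
    **fit_kwargs,
) -> ModelSelectionResult:
    """Fit every subset of the candidate features and rank by AICc.

    The intercept-only model is included; non-convergent subsets are
    excluded from the ranking and listed in ``failed``.
    """
    entries = []
    fits: dict = {}
    failed = []
    for r in range(len(features) + 1):
        for subset in itertools.combinations(features, r):
            fit = fit_glmm(table, features=subset, **fit_kwargs)
            if not fit.converged:
                failed.append(subset)
                continue
            fits[frozenset(subset)] = fit
            entries.append({"subset": subset, "k": fit.k_params, "aicc": aicc(fit)})
    df = pd.DataFrame(entries).sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    return ModelSelectionResult(entries=df, fits=fits, failed=failed)


def r2_nakagawa(fit: FittedGLMM) -> tuple[float, float]:
    """Nakagawa-Schielzeth marginal and conditional R² for the logit GLMM.

    marginal = var(fixed) / (var(fixed) + sigma_tf² + pi²/3);
    conditional adds the random-intercept variance to the numerator.
    """
    var_f = fit.var_fixed
    var_tf = fit.sigma_tf ** 2
    denom = var_f + var_tf + LOGIT_RESIDUAL_VARIANCE
    return var_f / denom, (var_f + var_tf) / denom


def conditional_r2_from_components(var_fixed: float, sigma_tf: float) -> tuple[float, float]:
    """R² pair from explicit variance components (analytic convenience)."""
    denom = var_fixed + sigma_tf ** 2 + LOGIT_RESIDUAL_VARIANCE
    return var_fixed / denom, (var_fixed + sigma_tf ** 2) / denom


def estimate_correlations(fit: FittedGLMM) -> pd.DataFrame:
    """Pairwise correlations of the fixed-effect estimates (multicollinearity check)."""
    V = fit.vcov_beta
    if not np.all(np.isfinite(V)):
        raise ModelError("estimate covariance unavailable (singular information matrix)")
    d = np.sqrt(np.diag(V))
    corr = V / np.outer(d, d)
    names = ("intercept",) + tuple(fit.feature_names)
    return pd.DataFrame(corr, index=names, columns=names)


def max_estimate_correlation(fit: FittedGLMM) -> float:
    corr = estimate_correlations(fit).to_numpy()
    off = corr[~np.eye(len(corr), dtype=bool)]
    return float(np.max(np.abs(off))) if off.size else 0.0
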