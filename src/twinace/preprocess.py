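"""From raw ordinal item responses to analysis-ready scores.

Fixed pipeline order (logged in the preprocessing report):

    reverse-code -> EM-impute -> clip to [1,5] -> log10 -> moment screen
    -> residualize on covariates -> per-scale factor scores / composites

Imputation is expectation-maximization under a multivariate-normal model on
the individual-level item matrix; transformed items are treated as continuous
throughout (no polychoric machinery).  Each five-item scale gets a
maximum-likelihood single-factor fit and Bartlett factor scores; the
family-specific / family-unspecific composites are item-set means,
z-standardized over the analysis sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import FactorAnalysis

from .architecture import TRAIT_NAMES, MeasurementModel

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# EM imputation under a multivariate normal model


def _observed_loglik(X, miss, patterns, mu, Sigma):
    ll = 0.0
    for pat, idx in patterns:
        o = ~pat
        k = int(o.sum())
        if k == 0:
            continue
        Soo = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(Soo)
        D = X[np.ix_(idx, np.where(o)[0])] - mu[o]
        Si = np.linalg.inv(Soo)
        quad = np.einsum("ij,jk,ik->", D, Si, D)
        ll += -0.5 * (len(idx) * (k * _LOG2PI + logdet) + quad)
    return ll


def em_impute(
    X: np.ndarray, tol: float = 1e-6, max_iter: int = 200, ridge: float = 1e-8
) -> tuple[np.ndarray, dict]:
    """Impute missing entries by EM under a multivariate normal model.

    Rows are individuals, columns items.  Missing cells are replaced by their
    conditional expectations given the observed cells at the converged
    (mu, Sigma); observed cells are untouched.  The observed-data
    log-likelihood is tracked and is non-decreasing across iterations.

    Returns ``(completed, report)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    n_obs_per_col = (~miss).sum(axis=0)
    if np.any(n_obs_per_col < 2):
        bad = np.where(n_obs_per_col < 2)[0]
        raise ValueError(f"columns {bad.tolist()} have fewer than 2 observed values")
    frac = miss.mean()
    if frac >= 0.5:
        raise ValueError(f"missing fraction {frac:.2f} exceeds 50%")
    report = {
        "missing_fraction": float(frac),
        "n_iter": 0,
        "converged": True,
        "loglik": [],
    }
    if not miss.any():
        return X.copy(), report

    # group rows by missingness pattern for vectorized conditional expectations
    codes = np.packbits(miss, axis=1)
    _, inv = np.unique(codes, axis=0, return_inverse=True)
    patterns = []
    for u in np.unique(inv):
        idx = np.where(inv == u)[0]
        patterns.append((miss[idx[0]].copy(), idx))

    Xf = X.copy()
    col_means = np.nanmean(X, axis=0)
    for j in range(p):
        Xf[miss[:, j], j] = col_means[j]
    mu = Xf.mean(axis=0)
    Sigma = np.cov(Xf, rowvar=False, bias=True)

    prev_ll = -np.inf
    converged = False
    for it in range(max_iter):
        ll = _observed_loglik(X, miss, patterns, mu, Sigma)
        report["loglik"].append(float(ll))
        S_corr = np.zeros((p, p))
        for pat, idx in patterns:
            if not pat.any():
                continue
            o = np.where(~pat)[0]
            m = np.where(pat)[0]
            Soo = Sigma[np.ix_(o, o)]
            Som = Sigma[np.ix_(o, m)]
            try:
                B = np.linalg.solve(Soo, Som)
            except np.linalg.LinAlgError:
                warnings.warn(
                    "singular observed-block covariance during EM; "
                    f"ridge-regularized with {ridge:g}",
                    RuntimeWarning,
                )
                B = np.linalg.solve(Soo + ridge * np.eye(len(o)), Som)
            cond_cov = Sigma[np.ix_(m, m)] - Som.T @ B
            Xf[np.ix_(idx, m)] = mu[m] + (X[np.ix_(idx, o)] - mu[o]) @ B
            S_corr[np.ix_(m, m)] += len(idx) * cond_cov
        mu_new = Xf.mean(axis=0)
        D = Xf - mu_new
        Sigma_new = (D.T @ D + S_corr) / n
        delta = max(np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max())
        mu, Sigma = mu_new, Sigma_new
        report["n_iter"] = it + 1
        if it > 0 and abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0) and delta < 1e-4:
            converged = True
            break
        prev_ll = ll
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    report["converged"] = converged
    report["mu"] = mu
    report["Sigma"] = Sigma
    return Xf, report


# ---------------------------------------------------------------------------
# Elementwise transforms and screening


def clip_items(X: np.ndarray, lo: float = 1.0, hi: float = 5.0) -> np.ndarray:
    """Clip (imputed, continuous) responses back into the response scale."""
    return np.clip(np.asarray(X, dtype=float), lo, hi)


def log_transform(X: np.ndarray) -> np.ndarray:
    """Base-10 logarithm; requires every value >= 1 (clip first)."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 1.0):
        raise ValueError("log_transform requires all values >= 1; clip items first")
    return np.log10(X)


def moment_screen(
    X: np.ndarray, skew_limit: float = 3.0, kurt_limit: float = 10.0
) -> pd.DataFrame:
    """Flag columns with extreme skewness / excess kurtosis (report only).

    Degenerate (zero-variance) columns are flagged separately; no column is
    removed.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("moment screening needs at least 4 observations")
    var = X.var(axis=0, ddof=1)
    degenerate = var <= 0
    skew = np.full(X.shape[1], np.nan)
    kurt = np.full(X.shape[1], np.nan)
    ok = ~degenerate
    skew[ok] = sps.skew(X[:, ok], axis=0)
    kurt[ok] = sps.kurtosis(X[:, ok], axis=0)  # excess kurtosis
    return pd.DataFrame(
        {
            "skewness": skew,
            "kurtosis": kurt,
            "flag_skew": np.abs(skew) >= skew_limit,
            "flag_kurtosis": np.abs(kurt) >= kurt_limit,
            "degenerate": degenerate,
        }
    )


def residualize(Y: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of each column of Y on intercept + covariates."""
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(C).any():
        raise ValueError("covariates must be complete")
    Xd = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"covariate_{j}" for j in range(C.shape[1])]
        )
        raise ValueError(f"design matrix is rank deficient; collinear among {names}")
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    return Y - Xd @ beta


# ---------------------------------------------------------------------------
# Single-factor ML analysis, Bartlett scores, internal consistency


@dataclass
class FactorSolution:
    """One-factor maximum-likelihood solution for a single item scale."""

    loadings: np.ndarray
    uniqueness: np.ndarray
    mean: np.ndarray
    alpha: float | None = None
    score_coef: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.score_coef is None:
            psi_inv = 1.0 / self.uniqueness
            lam = self.loadings
            denom = float(lam @ (psi_inv * lam))
            if denom <= 0:
                raise ValueError("factor scores undefined: loadings are null")
            self.score_coef = (psi_inv * lam) / denom

    @property
    def communalities(self) -> np.ndarray:
        return self.loadings**2 / (self.loadings**2 + self.uniqueness)


def fit_single_factor(
    items: np.ndarray,
    uniqueness_floor: float = 0.005,
    max_iter: int = 5000,
    det_tol: float = 1e-10,
) -> FactorSolution:
    """Maximum-likelihood one-factor model for a scale's items.

    Heywood cases are bounded by flooring uniquenesses at
    ``uniqueness_floor``; the loading-sum sign convention is non-negative.
    Extreme collinearity is rejected via the correlation-matrix determinant.
    """
    X = np.asarray(items, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("single-factor fit requires at least 3 items")
    R = np.corrcoef(X, rowvar=False)
    if not np.isfinite(R).all() or abs(np.linalg.det(R)) < det_tol:
        raise ValueError(
            "item correlation matrix is singular (extreme collinearity); "
            "factor analysis rejected"
        )
    fa = FactorAnalysis(n_components=1, max_iter=max_iter, tol=1e-8)
    fa.fit(X)
    if fa.n_iter_ >= max_iter:
        grad = np.nan  # sklearn does not expose the gradient; report iterate count
        raise RuntimeError(
            f"factor analysis did not converge in {max_iter} iterations "
            f"(last gradient norm unavailable: {grad})"
        )
    lam = fa.components_[0].copy()
    if lam.sum() < 0:
        lam = -lam
    psi = np.maximum(fa.noise_variance_, uniqueness_floor)
    return FactorSolution(loadings=lam, uniqueness=psi, mean=fa.mean_.copy())


def bartlett_scores(items: np.ndarray, solution: FactorSolution) -> np.ndarray:
    """Conditionally unbiased factor scores:
    ``(L' Psi^-1 L)^-1 L' Psi^-1 (x - mean)``."""
    if np.any(solution.uniqueness <= 0):
        raise ValueError("scores undefined: non-positive uniqueness")
    X = np.asarray(items, dtype=float)
    if X.shape[1] != solution.loadings.size:
        raise ValueError("item count does not match the factor solution")
    return (X - solution.mean) @ solution.score_coef


def cronbach_alpha(items: np.ndarray) -> float:
    """Internal consistency: ``k/(k-1) * (1 - sum(var_i)/var_total)``."""
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("Cronbach alpha needs >= 2 items and >= 3 observations")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def cronbach_alpha_from_cov(C: np.ndarray) -> float:
    """Alpha from a population item covariance matrix (closed-form checks)."""
    C = np.asarray(C, dtype=float)
    k = C.shape[0]
    total = C.sum()
    if total <= 0:
        raise ValueError("zero total variance; alpha undefined")
    return k / (k - 1) * (1.0 - np.trace(C) / total)


def composite_scores(
    items: np.ndarray, family_specific: set[int] | frozenset
) -> tuple[np.ndarray, np.ndarray]:
    """Family-specific and family-unspecific mean scores, z-standardized.

    ``family_specific`` indexes the items referring to parents/family
    conditions; its complement is the family-unspecific set.  Standardization
    uses the n-1 SD convention.
    """
    X = np.asarray(items, dtype=float)
    k = X.shape[1]
    spec = sorted(int(i) for i in family_specific)
    unspec = sorted(set(range(k)) - set(spec))
    if not spec or not unspec:
        raise ValueError("family-specific and unspecific item sets must be non-empty")

    def z(v):
        sd = v.std(ddof=1)
        if sd <= 0:
            raise ValueError("composite has zero variance; z score undefined")
        return (v - v.mean()) / sd

    return z(X[:, spec].mean(axis=1)), z(X[:, unspec].mean(axis=1))


# ---------------------------------------------------------------------------
# Full pipeline

PIPELINE_ORDER = (
    "reverse_code",
    "em_impute",
    "clip",
    "log10",
    "moment_screen",
    "residualize",
    "factor_scores_and_composites",
)

COMPOSITE_NAMES = ("family_specific", "family_unspecific")


def preprocess_cohort(
    cohort,
    covariates: tuple[str, ...] = ("age", "sex"),
    mm: MeasurementModel | None = None,
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
) -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing pipeline on a :class:`TwinCohort`.

    For sex-difference analyses pass ``covariates=("age",)`` — items must not
    be adjusted for sex when sex differences are the question.

    Returns ``(scores, report)``: one row per individual with the five trait
    factor scores and the two composite z scores, plus a JSON-serializable
    report (imputation rate, screening flags, alpha and loadings per scale).
    """
    mm = mm if mm is not None else (cohort.mm or MeasurementModel.default())
    long = cohort.to_long()
    item_cols = [f"i{j + 1:02d}" for j in range(mm.n_items)]
    X = long[item_cols].to_numpy(dtype=float)

    # undo the emitted reversal so that higher always means more victimization
    for j in mm.reverse_coded:
        X[:, j] = 6.0 - X[:, j]

    X, em_report = em_impute(X, tol=em_tol, max_iter=em_max_iter)
    X = clip_items(X)
    X = log_transform(X)
    screen = moment_screen(X)

    cov_frames, used_covariates = [], []
    for c in covariates:
        if c == "age":
            v = long["age"].to_numpy(dtype=float)
        elif c == "sex":
            v = (long["sex"].to_numpy() == "M").astype(float)
        else:
            raise ValueError(f"unknown covariate {c!r}")
        if v.std() > 0:  # constant covariates (e.g. single-sex cohort) drop out
            cov_frames.append(v)
            used_covariates.append(c)
    if cov_frames:
        X = residualize(X, np.column_stack(cov_frames))
    covariates = tuple(used_covariates)

    scores = long[["family_id", "twin", "zygosity", "sex", "age"]].copy()
    trait_idx = mm.trait_of_item()
    report = {
        "pipeline_order": list(PIPELINE_ORDER),
        "covariates": list(covariates),
        "imputation": {
            "fraction": em_report["missing_fraction"],
            "n_iter": em_report["n_iter"],
            "converged": em_report["converged"],
        },
        "moment_screen": {
            "n_flag_skew": int(screen["flag_skew"].sum()),
            "n_flag_kurtosis": int(screen["flag_kurtosis"].sum()),
            "n_degenerate": int(screen["degenerate"].sum()),
        },
        "scales": {},
    }
    n_traits = mm.n_traits
    for t in range(n_traits):
        name = TRAIT_NAMES[t] if t < len(TRAIT_NAMES) else f"trait_{t + 1}"
        cols = np.where(trait_idx == t)[0]
        sol = fit_single_factor(X[:, cols])
        sol.alpha = cronbach_alpha(X[:, cols])
        scores[name] = bartlett_scores(X[:, cols], sol)
        item_sd = np.sqrt(sol.loadings**2 + sol.uniqueness)
        report["scales"][name] = {
            "alpha": float(sol.alpha),
            # correlation-metric loadings (raw ones live on the log10 scale)
            "loadings": (sol.loadings / item_sd).tolist(),
            "uniqueness": sol.uniqueness.tolist(),
        }
    fam_z, unfam_z = composite_scores(X, mm.family_specific)
    scores[COMPOSITE_NAMES[0]] = fam_z
    scores[COMPOSITE_NAMES[1]] = unfam_z
    return scores, report
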