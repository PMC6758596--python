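"""Multivariate twin models: bivariate correlated factors and common pathway.

Bivariate model (per trait pair X, Y): each twin pair contributes a 4-vector
(X1, Y1, X2, Y2).  Within-twin cross-trait covariance decomposes as

    cov(X, Y) = aX aY rG + cX cY rC + eX eY rE,

and cross-twin cross-trait covariance drops the E term and halves the
genetic term in DZ pairs.  The correlated-factors parameterization (paths
plus rG, rC, rE) is used because the correlations themselves are the
quantities of interest.

Common-pathway model (all 5 traits): one latent factor with unit variance
and its own ACE decomposition transmits shared etiology through loadings
lambda_i; trait-specific ACE residuals absorb the rest.  Pairs contribute
10-vectors (twin-1 traits, twin-2 traits).

All likelihoods are evaluated on per-group sufficient statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize

from ._rng import stage_rng
from .pairs import relatedness
from .univariate import ModelFitIndices, information_criteria, rmsea

_LOG2PI = math.log(2.0 * math.pi)


class MGroupStat(NamedTuple):
    n: int
    mean: np.ndarray
    cov: np.ndarray  # ML (1/n) convention


def multivariate_stats(pairs: dict[str, np.ndarray]) -> dict[str, MGroupStat]:
    out = {}
    for g, arr in pairs.items():
        arr = np.asarray(arr, dtype=float)
        n = arr.shape[0]
        m = arr.mean(axis=0)
        d = arr - m
        out[g] = MGroupStat(n=n, mean=m, cov=d.T @ d / n)
    return out


def _as_mstats(pairs_or_stats) -> dict[str, MGroupStat]:
    first = next(iter(pairs_or_stats.values()))
    if isinstance(first, MGroupStat):
        return pairs_or_stats
    return multivariate_stats(pairs_or_stats)


def gaussian_neg2ll(stats, sigma_of, mu_of) -> float:
    tot = 0.0
    for g, st in stats.items():
        S = sigma_of(g)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return math.inf
        Si = np.linalg.inv(S)
        d = st.mean - mu_of(g)
        p = S.shape[0]
        tot += st.n * (
            p * _LOG2PI + logdet + float((Si * st.cov).sum()) + float(d @ Si @ d)
        )
    return tot


def multivariate_saturated_neg2ll(stats) -> float:
    tot = 0.0
    for st in stats.values():
        sign, logdet = np.linalg.slogdet(st.cov)
        if sign <= 0:
            raise ValueError("degenerate group covariance in saturated model")
        p = st.cov.shape[0]
        tot += st.n * (p * _LOG2PI + logdet + p)
    return tot


# ---------------------------------------------------------------------------
# Bivariate correlated factors


def _sym_cross(stats, i, j):
    """Double-entry symmetrized moment across co-twins / within twin."""
    return {g: 0.5 * (st.cov[i, j] + st.cov[j, i]) for g, st in stats.items()}


def bivariate_moment_oracle(pairs_or_stats) -> dict:
    """Linear moment solve for the bivariate decomposition on exact moments.

    Solves the three cross-covariance equations for the component covariance
    products (G, C, E), then divides by the univariate Falconer paths:
    rG = G / (aX aY) and so on.  Exact on noise-free population moments;
    used as the ML oracle and as a starting point.
    """
    stats = _as_mstats(pairs_or_stats)
    mz = [g for g in stats if relatedness(g) == 1.0]
    dz = [g for g in stats if relatedness(g) == 0.5]

    def pooled(moment):
        num = {"MZ": 0.0, "DZ": 0.0}
        den = {"MZ": 0.0, "DZ": 0.0}
        for g, v in moment.items():
            k = "MZ" if g in mz else "DZ"
            num[k] += stats[g].n * v
            den[k] += stats[g].n
        return num["MZ"] / den["MZ"], num["DZ"] / den["DZ"]

    # variances: indices (X1, Y1, X2, Y2)
    vX = np.mean([0.5 * (st.cov[0, 0] + st.cov[2, 2]) for st in stats.values()])
    vY = np.mean([0.5 * (st.cov[1, 1] + st.cov[3, 3]) for st in stats.values()])
    ct_XX = pooled({g: 0.5 * (st.cov[0, 2] + st.cov[2, 0]) for g, st in stats.items()})
    ct_YY = pooled({g: 0.5 * (st.cov[1, 3] + st.cov[3, 1]) for g, st in stats.items()})
    ct_XY = pooled({g: 0.5 * (st.cov[0, 3] + st.cov[1, 2]) for g, st in stats.items()})
    wt_XY = np.mean(
        [0.5 * (st.cov[0, 1] + st.cov[2, 3]) for st in stats.values()]
    )

    def acev(cmz, cdz, v):
        return 2.0 * (cmz - cdz), 2.0 * cdz - cmz, v - cmz

    A_X, C_X, E_X = acev(*ct_XX, vX)
    A_Y, C_Y, E_Y = acev(*ct_YY, vY)
    G = 2.0 * (ct_XY[0] - ct_XY[1])
    C = 2.0 * ct_XY[1] - ct_XY[0]
    E = wt_XY - ct_XY[0]

    def safe_corr(prod, vx, vy):
        if vx <= 1e-10 or vy <= 1e-10:
            return math.nan
        return prod / math.sqrt(vx * vy)

    return {
        "paths_X": (math.sqrt(max(A_X, 0)), math.sqrt(max(C_X, 0)),
                    math.sqrt(max(E_X, 1e-6))),
        "paths_Y": (math.sqrt(max(A_Y, 0)), math.sqrt(max(C_Y, 0)),
                    math.sqrt(max(E_Y, 1e-6))),
        "rG": safe_corr(G, A_X, A_Y),
        "rC": safe_corr(C, C_X, C_Y),
        "rE": safe_corr(E, E_X, E_Y),
    }


@dataclass
class BivariateDecomposition:
    paths_X: dict
    paths_Y: dict
    rG: float
    rC: float
    rE: float
    mu: tuple
    minus2ll: float
    fit: ModelFitIndices
    flags: list = field(default_factory=list)
    cis: dict | None = None

    def implied_cross_trait_cov(self) -> float:
        terms = []
        for comp, r in (("a", self.rG), ("c", self.rC), ("e", self.rE)):
            if not math.isnan(r):
                terms.append(self.paths_X[comp] * self.paths_Y[comp] * r)
        return float(sum(terms))


def _bivariate_sigma(x, rel):
    muX, muY = x[0], x[1]
    aX, cX, eX, aY, cY, eY = x[2:8]
    rG, rC, rE = x[8:11]
    VX = aX * aX + cX * cX + eX * eX
    VY = aY * aY + cY * cY + eY * eY
    wXY = aX * aY * rG + cX * cY * rC + eX * eY * rE

    def sigma(g):
        rA = rel[g]
        ctX = rA * aX * aX + cX * cX
        ctY = rA * aY * aY + cY * cY
        ctXY = rA * aX * aY * rG + cX * cY * rC
        W = np.array([[VX, wXY], [wXY, VY]])
        B = np.array([[ctX, ctXY], [ctXY, ctY]])
        return np.block([[W, B], [B, W]])

    mu = np.array([muX, muY, muX, muY])
    return sigma, (lambda g: mu)


def fit_bivariate(
    pairs_or_stats, n_starts: int = 4, seed: int = 0, group_label: str = "full"
) -> BivariateDecomposition:
    """ML bivariate ACE decomposition of two traits' cross-covariance.

    Input groups map to ``(n, 4)`` arrays ordered (X1, Y1, X2, Y2).
    Components with near-zero variance in either trait get an undefined
    (NaN) correlation, flagged rather than reported as 0.
    """
    stats = _as_mstats(pairs_or_stats)
    rel = {g: relatedness(g) for g in stats}

    def objective(x):
        sigma, mu = _bivariate_sigma(x, rel)
        return gaussian_neg2ll(stats, sigma, mu)

    orc = bivariate_moment_oracle(stats)
    mu0 = np.mean([st.mean for st in stats.values()], axis=0)
    x0 = np.array(
        [0.5 * (mu0[0] + mu0[2]), 0.5 * (mu0[1] + mu0[3])]
        + list(orc["paths_X"]) + list(orc["paths_Y"])
        + [np.nan_to_num(orc[k], nan=0.0) for k in ("rG", "rC", "rE")]
    )
    x0[8:11] = np.clip(x0[8:11], -0.99, 0.99)
    rng = stage_rng(seed, "bivariate-starts")
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jit = x0.copy()
        jit[2:8] = np.abs(jit[2:8] * rng.uniform(0.5, 1.6, 6)) + 0.01
        jit[8:11] = np.clip(jit[8:11] + rng.uniform(-0.3, 0.3, 3), -0.95, 0.95)
        starts.append(jit)
    bounds = (
        [(None, None)] * 2
        + [(0.0, None), (0.0, None), (1e-4, None)] * 2
        + [(-0.9999, 0.9999)] * 3
    )
    best = None
    for s in starts:
        res = optimize.minimize(
            objective, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        objective, best.x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000,
                 "maxfev": 5000},
    )
    if res.fun <= best.fun:
        best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("bivariate optimization failed for every start")

    x = best.x
    aX, cX, eX, aY, cY, eY = x[2:8]
    rG, rC, rE = x[8:11]
    flags = []
    for comp, (pX, pY) in {"rG": (aX, aY), "rC": (cX, cY), "rE": (eX, eY)}.items():
        if pX * pX < 1e-3 or pY * pY < 1e-3:
            flags.append(
                f"{comp} undefined: near-zero component variance in one trait"
            )
            if comp == "rG":
                rG = math.nan
            elif comp == "rC":
                rC = math.nan
            else:
                rE = math.nan
    m2ll = float(best.fun)
    sat = multivariate_saturated_neg2ll(stats)
    k = 11
    n_moments = sum(4 + 10 for _ in stats)  # 4 means + 10 covariances per group
    df = n_moments - k
    n_pairs = sum(st.n for st in stats.values())
    chi2 = max(0.0, m2ll - sat)
    point, ci, label = rmsea(chi2, df, n_pairs)
    aic, bic = information_criteria(m2ll, k, n_pairs)
    fit = ModelFitIndices(m2ll, chi2, df, point, ci, label, aic, bic, n_pairs, k)
    return BivariateDecomposition(
        paths_X={"a": abs(aX), "c": abs(cX), "e": abs(eX)},
        paths_Y={"a": abs(aY), "c": abs(cY), "e": abs(eY)},
        rG=float(rG), rC=float(rC), rE=float(rE),
        mu=(float(x[0]), float(x[1])), minus2ll=m2ll, fit=fit, flags=flags,
    )


# ---------------------------------------------------------------------------
# Common pathway


@dataclass
class CommonPathwaySolution:
    """Latent-factor ACE decomposition with trait-specific residual ACE."""

    loadings: np.ndarray
    latent_a2: float
    latent_c2: float
    latent_e2: float
    specific_a2: np.ndarray
    specific_c2: np.ndarray
    specific_e2: np.ndarray
    mu: np.ndarray
    minus2ll: float
    fit: ModelFitIndices
    pruned: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def trait_variance(self) -> np.ndarray:
        return (
            self.loadings**2
            + self.specific_a2 + self.specific_c2 + self.specific_e2
        )

    @property
    def standardized_loadings(self) -> np.ndarray:
        return self.loadings / np.sqrt(self.trait_variance)

    def total_components(self) -> dict[str, np.ndarray]:
        """Per-trait total standardized a2/c2/e2 implied by the model."""
        V = self.trait_variance
        lam2 = self.loadings**2
        return {
            "a2": (lam2 * self.latent_a2 + self.specific_a2) / V,
            "c2": (lam2 * self.latent_c2 + self.specific_c2) / V,
            "e2": (lam2 * self.latent_e2 + self.specific_e2) / V,
        }


def _cp_unpack(x, t):
    mu = x[:t]
    lam = x[t:2 * t]
    u = x[2 * t:2 * t + 3]
    sa = x[2 * t + 3:3 * t + 3]
    sc = x[3 * t + 3:4 * t + 3]
    se = x[4 * t + 3:5 * t + 3]
    s2 = u @ u
    if s2 <= 1e-12:
        return None
    lat = u**2 / s2  # (aL2, cL2, eL2), sums to 1 by construction
    return mu, lam, lat, sa, sc, se


def _cp_sigma(lam, lat, sa, sc, se, rA):
    lamT = np.outer(lam, lam)
    W = lamT + np.diag(sa**2 + sc**2 + se**2)
    B = (rA * lat[0] + lat[1]) * lamT + np.diag(rA * sa**2 + sc**2)
    return np.block([[W, B], [B, W]])


def fit_common_pathway(
    pairs_or_stats,
    n_starts: int = 3,
    seed: int = 0,
    prune: bool = False,
    n_boot: int = 100,
    pairs_for_boot: dict | None = None,
) -> CommonPathwaySolution:
    """ML common-pathway fit for 5 traits measured on both twins.

    Input groups map to ``(n, 10)`` arrays ordered (twin-1 traits, twin-2
    traits).  Identification: latent variance fixed to 1, first loading
    non-negative.  With ``prune=True``, loadings and specific a/c paths whose
    95% bootstrap CI (B = ``n_boot`` family resamples, requires the raw
    ``pairs_for_boot`` arrays) covers 0 are set to 0 and the model refit once.
    """
    stats = _as_mstats(pairs_or_stats)
    rel = {g: relatedness(g) for g in stats}
    p = next(iter(stats.values())).cov.shape[0]
    t = p // 2

    def objective(x):
        un = _cp_unpack(x, t)
        if un is None:
            return math.inf
        mu, lam, lat, sa, sc, se = un
        mu2 = np.concatenate([mu, mu])
        return gaussian_neg2ll(
            stats,
            lambda g: _cp_sigma(lam, lat, sa, sc, se, rel[g]),
            lambda g: mu2,
        )

    # initialization: principal axis of the pooled within-twin covariance,
    # latent ACE from Falconer on the factor proxy, jittered extra starts
    Wp = np.mean(
        [0.5 * (st.cov[:t, :t] + st.cov[t:, t:]) for st in stats.values()], axis=0
    )
    w, V = np.linalg.eigh(Wp)
    v1 = V[:, -1] * (1 if V[:, -1].sum() >= 0 else -1)
    lam0 = np.sqrt(max(w[-1], 0.1)) * v1
    lam0 = np.clip(lam0, 0.05, None)

    def proxy_r(g_rel):
        num = den = 0.0
        for g, st in stats.items():
            if rel[g] != g_rel:
                continue
            ct = v1 @ st.cov[:t, t:] @ v1
            wt = 0.5 * (v1 @ st.cov[:t, :t] @ v1 + v1 @ st.cov[t:, t:] @ v1)
            num += st.n * (ct / wt if wt > 0 else 0)
            den += st.n
        return num / den if den else 0.0

    rmz, rdz = proxy_r(1.0), proxy_r(0.5)
    aL2 = min(max(2 * (rmz - rdz), 0.05), 0.9)
    cL2 = min(max(2 * rdz - rmz, 0.02), 0.9 - aL2 + 0.05)
    eL2 = max(1 - aL2 - cL2, 0.05)
    resid = np.clip(np.diag(Wp) - lam0**2, 0.05, None)
    mu0 = np.mean(
        [0.5 * (st.mean[:t] + st.mean[t:]) for st in stats.values()], axis=0
    )
    x0 = np.concatenate([
        mu0, lam0, np.sqrt([aL2, cL2, eL2]),
        np.sqrt(0.3 * resid), np.sqrt(0.1 * resid), np.sqrt(0.6 * resid),
    ])

    rng = stage_rng(seed, "cp-starts")
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jit = x0.copy()
        jit[t:] = np.abs(jit[t:] * rng.uniform(0.6, 1.5, size=len(x0) - t)) + 0.01
        starts.append(jit)

    lower = np.full(len(x0), -np.inf)
    upper = np.full(len(x0), np.inf)
    lower[t] = 0.0                      # sign convention: lambda_1 >= 0
    lower[2 * t:2 * t + 3] = 0.0        # latent square-roots
    upper[2 * t:2 * t + 3] = 10.0
    lower[2 * t + 3:4 * t + 3] = 0.0    # specific a, c paths
    lower[4 * t + 3:] = 1e-3            # specific e paths

    def run(starts_, lo, hi):
        bounds = list(zip(lo, hi))
        bounds = [
            (None if not np.isfinite(a) else a, None if not np.isfinite(b) else b)
            for a, b in bounds
        ]
        best = None
        for s in starts_:
            res = optimize.minimize(
                objective, s, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 3000},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    best = run(starts, lower, upper)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            "common-pathway optimization failed; best candidate: "
            f"{None if best is None else best.x}"
        )

    pruned: list[str] = []
    if prune:
        if pairs_for_boot is None:
            raise ValueError("prune=True requires pairs_for_boot (raw pair arrays)")
        pruned_idx = _cp_prune_indices(
            best.x, t, pairs_for_boot, objective_seed=seed, n_boot=n_boot,
            lower=lower, upper=upper, rel=rel,
        )
        if pruned_idx:
            lo2, hi2 = lower.copy(), upper.copy()
            names = _cp_path_names(t)
            for i in pruned_idx:
                lo2[i] = hi2[i] = 0.0
                pruned.append(names[i])
            x1 = best.x.copy()
            x1[list(pruned_idx)] = 0.0
            best2 = run([x1], lo2, hi2)
            if best2 is not None and np.isfinite(best2.fun):
                best = best2

    un = _cp_unpack(best.x, t)
    mu, lam, lat, sa, sc, se = un
    if lam.sum() < 0:
        lam = -lam
    m2ll = float(best.fun)
    sat = multivariate_saturated_neg2ll(stats)
    k = 5 * t + 2  # t means, t loadings, 3t specifics, 2 effective latent df
    n_moments = sum(p + p * (p + 1) // 2 for _ in stats)
    df = n_moments - k
    n_pairs = sum(st.n for st in stats.values())
    chi2 = max(0.0, m2ll - sat)
    point, ci, label = rmsea(chi2, df, n_pairs)
    aic, bic = information_criteria(m2ll, k, n_pairs)
    fit = ModelFitIndices(m2ll, chi2, df, point, ci, label, aic, bic, n_pairs, k)
    return CommonPathwaySolution(
        loadings=lam, latent_a2=float(lat[0]), latent_c2=float(lat[1]),
        latent_e2=float(lat[2]), specific_a2=sa**2, specific_c2=sc**2,
        specific_e2=se**2, mu=mu, minus2ll=m2ll, fit=fit, pruned=pruned,
    )


def _cp_path_names(t):
    names = [f"mu_{i}" for i in range(t)]
    names += [f"loading_{i}" for i in range(t)]
    names += ["latent_a", "latent_c", "latent_e"]
    names += [f"specific_a_{i}" for i in range(t)]
    names += [f"specific_c_{i}" for i in range(t)]
    names += [f"specific_e_{i}" for i in range(t)]
    return names


def _cp_prune_indices(x_hat, t, pairs, objective_seed, n_boot, lower, upper, rel):
    """Indices of loading / specific-a / specific-c paths whose 95% bootstrap
    CI covers 0 (normal-theory, warm-started single-start refits)."""
    from .univariate import bootstrap_ci  # stratified family bootstrap

    candidate = list(range(t, 2 * t)) + list(range(2 * t + 3, 4 * t + 3))
    bounds = [
        (None if not np.isfinite(a) else a, None if not np.isfinite(b) else b)
        for a, b in zip(lower, upper)
    ]

    def stat(resampled):
        stats_b = multivariate_stats(resampled)

        def obj(x):
            un = _cp_unpack(x, t)
            if un is None:
                return math.inf
            mu, lam, lat, sa, sc, se = un
            mu2 = np.concatenate([mu, mu])
            return gaussian_neg2ll(
                stats_b,
                lambda g: _cp_sigma(lam, lat, sa, sc, se, rel[g]),
                lambda g: mu2,
            )

        res = optimize.minimize(
            obj, x_hat, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 500},
        )
        return res.x[candidate]

    ci = bootstrap_ci(pairs, stat, B=max(100, n_boot), seed=objective_seed)
    covers0 = (ci.lower <= 0.0) & (ci.upper >= 0.0)
    return [candidate[i] for i in np.where(covers0)[0]]


def compare_cp_vs_univariate(cp: CommonPathwaySolution, uni: dict,
                             uni_cis: dict | None = None,
                             cp_cis: dict | None = None):
    """Per-trait differences between CP-implied total components and the
    univariate estimates, with CI-overlap significance when CIs are given.

    ``uni`` maps trait name -> VarianceComponents (trait order must match the
    CP fit's trait order).
    """
    import pandas as pd

    from .univariate import ci_overlap_compare

    tot = cp.total_components()
    rows = []
    for i, (trait, vc) in enumerate(uni.items()):
        for comp in ("a2", "c2", "e2"):
            cp_val = float(tot[comp][i])
            uni_val = float(getattr(vc, comp))
            row = dict(trait=trait, component=comp, cp=cp_val, univariate=uni_val,
                       difference=cp_val - uni_val, es=abs(cp_val - uni_val))
            if uni_cis and cp_cis and trait in uni_cis and trait in cp_cis:
                sig, es = ci_overlap_compare(
                    cp_val, cp_cis[trait][comp], uni_val, uni_cis[trait][comp]
                )
                row["significant"] = sig
            rows.append(row)
    return pd.DataFrame(rows)
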