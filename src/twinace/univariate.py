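"""Univariate ACE variance decomposition by maximum likelihood.

Each zygosity group contributes pairs (y1, y2) modelled as bivariate normal
with a single mean mu (equated across twin order and zygosity within an
analysis group), total variance V = a^2 + c^2 + e^2 and co-twin covariance

    MZ: a^2 + c^2        DZ: a^2/2 + c^2.

Parameters are path coefficients (a, c, e), squared in the covariance, so
signs are unidentified and results are reported as standardized squares.
The likelihood depends on the data only through per-group sufficient
statistics (n, mean vector, ML covariance), which keeps repeated fits —
multi-start, bootstrap, calibration simulations — cheap.

The saturated reference model frees 5 moments per group (2 means, 2
variances, 1 covariance), giving the df accounting used by the printed
tables: ACE df = 10 - 4 = 6, AE/CE df = 10 - 3 = 7 against a two-group
saturated model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy import optimize
from scipy import stats as sps

from ._rng import stage_rng, substream
from .pairs import relatedness

_LOG2PI = math.log(2.0 * math.pi)

MODELS = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}


class GroupStat(NamedTuple):
    """Sufficient statistics for one zygosity group of pairs."""

    n: int
    mean: tuple
    cov: tuple  # ((s11, s12), (s12, s22)), ML (1/n) convention


def pair_stats(pairs: dict[str, np.ndarray]) -> dict[str, GroupStat]:
    """Sufficient statistics per group from (n, 2) pair arrays."""
    out = {}
    for g, arr in pairs.items():
        arr = np.asarray(arr, dtype=float)
        n = arr.shape[0]
        m = arr.mean(axis=0)
        d = arr - m
        s11 = float(d[:, 0] @ d[:, 0] / n)
        s22 = float(d[:, 1] @ d[:, 1] / n)
        s12 = float(d[:, 0] @ d[:, 1] / n)
        out[g] = GroupStat(n=n, mean=(float(m[0]), float(m[1])),
                           cov=((s11, s12), (s12, s22)))
    return out


def stats_from_moments(
    rmz: float, rdz: float, V: float = 1.0, mu: float = 0.0, n: int = 100000
) -> dict[str, GroupStat]:
    """Noise-free population-moment 'data' for oracle checks."""
    return {
        "MZ": GroupStat(n, (mu, mu), ((V, rmz * V), (rmz * V, V))),
        "DZ": GroupStat(n, (mu, mu), ((V, rdz * V), (rdz * V, V))),
    }


def _as_stats(pairs_or_stats) -> dict[str, GroupStat]:
    if not pairs_or_stats:
        raise ValueError("no zygosity groups supplied")
    first = next(iter(pairs_or_stats.values()))
    if isinstance(first, GroupStat):
        return pairs_or_stats
    return pair_stats(pairs_or_stats)


def neg2ll_pairs(stats: dict[str, GroupStat], mu: float, V: float,
                 cov_of: Callable[[str], float]) -> float:
    """-2 log-likelihood of exchange-symmetric bivariate-normal pair models."""
    tot = 0.0
    for g, st in stats.items():
        w = cov_of(g)
        det = V * V - w * w
        if det <= 0.0 or V <= 0.0:
            return math.inf
        (s11, s12), (_, s22) = st.cov
        d1 = st.mean[0] - mu
        d2 = st.mean[1] - mu
        tr = (V * (s11 + s22) - 2.0 * w * s12) / det
        quad = (V * (d1 * d1 + d2 * d2) - 2.0 * w * d1 * d2) / det
        tot += st.n * (2.0 * _LOG2PI + math.log(det) + tr + quad)
    return tot


def saturated_neg2ll(stats: dict[str, GroupStat]) -> float:
    """Closed-form -2lnL of the per-group free-moment (saturated) model."""
    tot = 0.0
    for st in stats.values():
        (s11, s12), (_, s22) = st.cov
        det = s11 * s22 - s12 * s12
        if det <= 0:
            raise ValueError("degenerate group covariance in saturated model")
        tot += st.n * (2.0 * _LOG2PI + math.log(det) + 2.0)
    return tot


def falconer(stats: dict[str, GroupStat]) -> tuple[float, float, float, float]:
    """Moment estimates a2, c2, e2 (standardized) and total variance V.

    a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ, from pooled MZ-like
    and DZ-like groups; used as the ML starting point and as the exact-moment
    oracle.
    """
    def pooled_r_v(groups):
        ns = rs = vs = 0.0
        for g in groups:
            st = stats[g]
            (s11, s12), (_, s22) = st.cov
            v = 0.5 * (s11 + s22)
            rs += st.n * (s12 / v if v > 0 else 0.0)
            vs += st.n * v
            ns += st.n
        return rs / ns, vs / ns

    mz = [g for g in stats if relatedness(g) == 1.0]
    dz = [g for g in stats if relatedness(g) == 0.5]
    if not mz or not dz:
        raise ValueError("need at least one MZ-like and one DZ-like group")
    rmz, vmz = pooled_r_v(mz)
    rdz, vdz = pooled_r_v(dz)
    V = (vmz * sum(stats[g].n for g in mz) + vdz * sum(stats[g].n for g in dz)) / sum(
        st.n for st in stats.values()
    )
    return 2.0 * (rmz - rdz), 2.0 * rdz - rmz, 1.0 - rmz, V


@dataclass
class VarianceComponents:
    """Standardized ACE decomposition for one score in one analysis group."""

    model: str
    a2: float
    c2: float
    e2: float
    paths: dict
    total_variance: float
    mu: float
    group: str = "full"
    cis: dict | None = None
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"a2": self.a2, "c2": self.c2, "e2": self.e2}


@dataclass
class ModelFitIndices:
    minus2ll: float
    chi2: float
    df: int
    rmsea: float
    rmsea_ci: tuple
    rmsea_label: str
    aic: float
    bic: float
    n_pairs: int
    k_params: int


def information_criteria(minus2ll: float, k: int, n: int) -> tuple[float, float]:
    """AIC = -2lnL + 2k; BIC = -2lnL + k ln(n), n = number of pairs."""
    if n <= 0 or k < 0:
        raise ValueError("need n > 0 and k >= 0")
    return minus2ll + 2.0 * k, minus2ll + k * math.log(n)


def rmsea(chi2: float, df: int, n: int) -> tuple[float, tuple, str]:
    """RMSEA point estimate, 90% CI and the 0.06/0.08 fit label.

    Point = sqrt(max(0, (chi2 - df) / (df (n-1)))); CI bounds by inverting
    the noncentral chi-square at the 5% / 95% levels.
    """
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    if n <= 1:
        raise ValueError("RMSEA requires n > 1")
    denom = df * (n - 1)
    point = math.sqrt(max(0.0, (chi2 - df) / denom))

    def _bound(level):
        # find lambda with ncx2.cdf(chi2, df, lam) == level
        if sps.chi2.cdf(chi2, df) <= level:
            return 0.0
        lo, hi = 0.0, max(chi2, 1.0)
        while sps.ncx2.cdf(chi2, df, hi) > level:
            hi *= 2.0
            if hi > 1e8:
                break
        lam = optimize.brentq(
            lambda L: sps.ncx2.cdf(chi2, df, L) - level, lo, hi, xtol=1e-10
        )
        return math.sqrt(lam / denom)

    lo, hi = _bound(0.95), _bound(0.05)
    label = "excellent" if hi < 0.06 else ("mediocre" if hi < 0.08 else "poor")
    return point, (lo, hi), label


def _pack_cov_fn(model: str, x: np.ndarray):
    comps = MODELS[model]
    vals = dict(zip(comps, x[1:]))
    a = vals.get("a", 0.0)
    c = vals.get("c", 0.0)
    e = vals.get("e", 0.0)
    V = a * a + c * c + e * e
    return a, c, e, V


def fit_ace(
    pairs_or_stats,
    model: str = "ACE",
    n_starts: int = 5,
    seed: int = 0,
    polish: bool = True,
    warm_start: np.ndarray | None = None,
    group_label: str = "full",
) -> tuple[VarianceComponents, ModelFitIndices]:
    """ML fit of an ACE model (or AE/CE/E submodel) to twin-pair data.

    ``pairs_or_stats`` maps zygosity labels (MZ-like names imply genetic
    relatedness 1, anything else 0.5) to ``(n, 2)`` arrays or
    :class:`GroupStat`.  Multi-start: a Falconer-derived start plus jittered
    starts under a fixed sub-seed.  ``warm_start`` (paths vector) replaces
    the multi-start for cheap refits such as bootstrap resamples.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    stats = _as_stats(pairs_or_stats)
    if len(stats) < 2:
        raise ValueError("need at least two zygosity groups (MZ-like and DZ-like)")
    comps = MODELS[model]
    rel = {g: relatedness(g) for g in stats}

    def objective(x):
        a, c, e, V = _pack_cov_fn(model, x)
        return neg2ll_pairs(stats, x[0], V, lambda g: rel[g] * a * a + c * c)

    a2f, c2f, e2f, Vf = falconer(stats)
    mu0 = float(np.mean([st.mean for st in stats.values()]))
    start_map = {
        "a": math.sqrt(max(a2f, 0.01) * Vf),
        "c": math.sqrt(max(c2f, 0.01) * Vf),
        "e": math.sqrt(max(e2f, 0.05) * Vf),
    }
    base = np.array([mu0] + [start_map[c] for c in comps])
    if warm_start is not None:
        starts = [np.asarray(warm_start, dtype=float)]
    else:
        rng = stage_rng(seed, "ace-starts")
        starts = [base]
        for _ in range(max(0, n_starts - 1)):
            jit = base.copy()
            jit[1:] = np.abs(jit[1:] * rng.uniform(0.4, 1.8, size=len(comps)))
            jit[0] += rng.normal(0, 0.1 * math.sqrt(Vf))
            starts.append(jit)

    bounds = [(None, None)] + [
        (1e-4, None) if c == "e" else (0.0, None) for c in comps
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if polish:
        res = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
        )
        if res.fun <= best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("ACE optimization failed for every start")

    a, c, e, V = _pack_cov_fn(model, best.x)
    flags = []
    if model == "E":
        rmz = np.mean(
            [st.cov[0][1] / math.sqrt(st.cov[0][0] * st.cov[1][1])
             for g, st in stats.items() if rel[g] == 1.0]
        )
        if rmz > 0.1:
            flags.append(
                "boundary: familial resemblance present but E-only model fitted"
            )
    vc = VarianceComponents(
        model=model,
        a2=a * a / V, c2=c * c / V, e2=e * e / V,
        paths={"a": abs(a), "c": abs(c), "e": abs(e), **{
            k: 0.0 for k in ("a", "c", "e") if k not in comps}},
        total_variance=V, mu=float(best.x[0]), group=group_label, flags=flags,
    )
    for k in ("a", "c", "e"):
        if k not in comps:
            vc.paths[k] = 0.0
    m2ll = float(best.fun)
    sat = saturated_neg2ll(stats)
    k_params = 1 + len(comps)
    df = 5 * len(stats) - k_params
    chi2 = max(0.0, m2ll - sat)
    n_pairs = sum(st.n for st in stats.values())
    point, ci, label = rmsea(chi2, df, n_pairs)
    aic, bic = information_criteria(m2ll, k_params, n_pairs)
    fit = ModelFitIndices(
        minus2ll=m2ll, chi2=chi2, df=df, rmsea=point, rmsea_ci=ci,
        rmsea_label=label, aic=aic, bic=bic, n_pairs=n_pairs, k_params=k_params,
    )
    return vc, fit


def fit_saturated(pairs_or_stats) -> ModelFitIndices:
    """Fit indices of the per-group free-moment baseline (closed form)."""
    stats = _as_stats(pairs_or_stats)
    m2ll = saturated_neg2ll(stats)
    n_pairs = sum(st.n for st in stats.values())
    k = 5 * len(stats)
    aic, bic = information_criteria(m2ll, k, n_pairs)
    return ModelFitIndices(
        minus2ll=m2ll, chi2=0.0, df=0, rmsea=0.0, rmsea_ci=(0.0, 0.0),
        rmsea_label="saturated", aic=aic, bic=bic, n_pairs=n_pairs, k_params=k,
    )


@dataclass
class SubmodelSearch:
    fits: dict
    indices: dict
    lrt_p: dict
    candidates: list
    best: str

    @property
    def winner(self) -> VarianceComponents:
        return self.fits[self.best]


def submodel_search(pairs_or_stats, alpha: float = 0.05, seed: int = 0,
                    group_label: str = "full") -> SubmodelSearch:
    """Best-fitting univariate model: fit ACE, AE, CE, E; keep submodels not
    rejected against ACE by LRT at *alpha*; pick lowest AIC (ties -> fewer
    parameters).

    The LRT uses the naive chi-square reference (no boundary mixture),
    which is conservative for variance components at zero.
    """
    stats = _as_stats(pairs_or_stats)
    fits, indices, lrt_p = {}, {}, {}
    for m in ("ACE", "AE", "CE", "E"):
        vc, fi = fit_ace(stats, model=m, seed=seed, group_label=group_label)
        fits[m], indices[m] = vc, fi
    ace = indices["ACE"]
    candidates = ["ACE"]
    lrt_p["ACE"] = 1.0
    for m in ("AE", "CE", "E"):
        dchi = max(0.0, indices[m].minus2ll - ace.minus2ll)
        ddf = ace.k_params - indices[m].k_params
        p = float(sps.chi2.sf(dchi, ddf)) if ddf > 0 else 1.0
        lrt_p[m] = p
        if p >= alpha:
            candidates.append(m)
    best = min(
        candidates, key=lambda m: (round(indices[m].aic, 10), indices[m].k_params)
    )
    return SubmodelSearch(fits=fits, indices=indices, lrt_p=lrt_p,
                          candidates=candidates, best=best)


@dataclass
class BootstrapCI:
    estimate: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B_used: int
    n_failed: int
    method: str


def bootstrap_ci(
    pairs: dict[str, np.ndarray],
    statistic: Callable[[dict[str, np.ndarray]], np.ndarray],
    B: int = 1000,
    seed: int = 0,
    method: str = "normal",
) -> BootstrapCI:
    """Stratified family bootstrap for 95% CIs.

    Families are resampled with replacement within zygosity group; the
    statistic is recomputed per resample.  ``method='normal'`` gives
    estimate +/- 1.96 * bootstrap SD (CIs based on bootstrapped standard
    errors); ``method='percentile'`` gives the 2.5/97.5 percentiles.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if method not in ("normal", "percentile"):
        raise ValueError("method must be 'normal' or 'percentile'")
    arrays = {g: np.asarray(a, dtype=float) for g, a in pairs.items()}
    est = np.atleast_1d(np.asarray(statistic(arrays), dtype=float))
    rng = stage_rng(seed, "bootstrap")
    reps, n_failed = [], 0
    for b in range(B):
        resampled = {
            g: a[rng.integers(0, a.shape[0], a.shape[0])] for g, a in arrays.items()
        }
        try:
            reps.append(np.atleast_1d(np.asarray(statistic(resampled), dtype=float)))
        except Exception:
            n_failed += 1
    if n_failed > 0.10 * B:
        raise RuntimeError(
            f"statistic failed in {n_failed}/{B} bootstrap resamples"
        )
    R = np.vstack(reps)
    se = R.std(axis=0, ddof=1)
    if method == "normal":
        lo, hi = est - 1.96 * se, est + 1.96 * se
    else:
        lo = np.percentile(R, 2.5, axis=0)
        hi = np.percentile(R, 97.5, axis=0)
    return BootstrapCI(estimate=est, se=se, lower=lo, upper=hi,
                       B_used=B - n_failed, n_failed=n_failed, method=method)


def ci_overlap_compare(
    est1: float, ci1: tuple, est2: float, ci2: tuple
) -> tuple[bool, float]:
    """Significance by CI overlap: no overlap, or CIs just touching, counts
    as significant (p < 0.01 convention); effect size is the raw difference.
    """
    significant = min(ci1[1], ci2[1]) <= max(ci1[0], ci2[0])
    return bool(significant), float(abs(est1 - est2))


def ace_statistic(model: str = "ACE", component: str = "a2",
                  warm: bool = True) -> Callable:
    """Statistic factory for :func:`bootstrap_ci`: a standardized component
    from a (warm-started, unpolished) ACE refit of the resampled pairs."""
    cache = {}

    def stat(pairs):
        ws = cache.get("x")
        vc, _ = fit_ace(pairs, model=model, warm_start=ws, polish=False,
                        n_starts=1 if ws is not None else 3)
        comps = MODELS[model]
        cache["x"] = np.array([vc.mu] + [vc.paths[c] for c in comps])
        return getattr(vc, component)

    return stat
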