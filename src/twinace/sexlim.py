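"""Five-group sex-limitation models.

Do the same genes operate in women and men?  Same-sex groups (MZf, MZm, DZf,
DZm) identify per-sex ACE magnitudes but cannot separate a common additive
component from a sex-specific one: within a sex only the sum a^2 + a'^2
enters the expected covariances.  Opposite-sex DZ pairs (DZos, twin 1 =
female by convention) supply the separating moment — their cross-twin
covariance is

    1/2 * a_f * a_m + c_f * c_m,

to which the sex-specific additive component A' contributes nothing.  The
"general" model frees per-sex A, C, E and adds A' (configurable: in one sex
or, weakly identified, in both); the "common effects" model fixes A' to 0.
Nested models are compared by an ordinary (unscaled) ML likelihood-ratio
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from ._rng import stage_rng
from .univariate import GroupStat, _LOG2PI, pair_stats

SAME_SEX = {"MZf": ("f", 1.0), "MZm": ("m", 1.0), "DZf": ("f", 0.5),
            "DZm": ("m", 0.5)}


@dataclass
class SexLimSolution:
    """Per-sex standardized components from a five-group fit."""

    model: str  # "general" or "common_effects"
    ap_sexes: tuple
    components: dict  # sex -> {a2, ap2, c2, e2}
    ses: dict  # sex -> {a2, ap2, c2, e2} standard errors (may be NaN)
    paths: dict  # sex -> raw {a, ap, c, e}
    means: dict  # sex -> mu
    total_variance: dict  # sex -> V
    minus2ll: float
    k_params: int
    n_pairs: int
    flags: list = field(default_factory=list)


@dataclass
class LRTResult:
    dchi2: float
    ddf: int
    p: float
    label: str = "unscaled LRT"


def _sexlim_stats(pairs: dict[str, np.ndarray]) -> dict[str, GroupStat]:
    missing = [g for g in ("MZf", "MZm", "DZf", "DZm") if g not in pairs]
    if missing:
        raise ValueError(f"missing zygosity groups: {missing}")
    return pair_stats(pairs)


def _neg2ll_sexlim(stats, mu_f, mu_m, V, w_same, w_os):
    """Scalar five-group likelihood; V and w_same are dicts keyed by sex."""
    tot = 0.0
    for g, st in stats.items():
        if g == "DZos":
            V1, V2, w = V["f"], V["m"], w_os
            m1, m2 = mu_f, mu_m
        else:
            s, _ = SAME_SEX[g]
            V1 = V2 = V[s]
            w = w_same[g]
            m1 = m2 = mu_f if s == "f" else mu_m
        det = V1 * V2 - w * w
        if det <= 0 or V1 <= 0 or V2 <= 0:
            return math.inf
        (s11, s12), (_, s22) = st.cov
        d1 = st.mean[0] - m1
        d2 = st.mean[1] - m2
        tr = (V2 * s11 - 2.0 * w * s12 + V1 * s22) / det
        quad = (V2 * d1 * d1 - 2.0 * w * d1 * d2 + V1 * d2 * d2) / det
        tot += st.n * (2.0 * _LOG2PI + math.log(det) + tr + quad)
    return tot


def _unpack(x, ap_sexes):
    mu_f, mu_m, af, cf, ef, am, cm, em = x[:8]
    idx = 8
    apf = apm = 0.0
    if "f" in ap_sexes:
        apf = x[idx]
        idx += 1
    if "m" in ap_sexes:
        apm = x[idx]
    return mu_f, mu_m, {"f": (af, apf, cf, ef), "m": (am, apm, cm, em)}


def _expected(x, ap_sexes):
    mu_f, mu_m, paths = _unpack(x, ap_sexes)
    V, w_same = {}, {}
    for s, (a, ap, c, e) in paths.items():
        V[s] = a * a + ap * ap + c * c + e * e
    for g, (s, rA) in SAME_SEX.items():
        a, ap, c, e = paths[s]
        w_same[g] = rA * (a * a + ap * ap) + c * c
    af, _, cf, _ = paths["f"]
    am, _, cm, _ = paths["m"]
    w_os = 0.5 * af * am + cf * cm  # A' contributes nothing across DZos
    return mu_f, mu_m, V, w_same, w_os


def fit_sexlim(
    pairs: dict[str, np.ndarray],
    model: str = "general",
    ap_sexes: tuple = ("f", "m"),
    n_starts: int = 5,
    seed: int = 0,
    compute_ses: bool = True,
) -> SexLimSolution:
    """ML fit of a five-group sex-limitation model.

    ``model='general'`` estimates per-sex A, C, E plus A' in the sexes listed
    in ``ap_sexes`` (requires the DZos group); ``model='common_effects'``
    fixes A' to 0 in both sexes.  Estimating A' in both sexes at once is
    supported but weakly identified (only the single DZos cross-covariance
    separates the two) and is flagged as such.
    """
    if model not in ("general", "common_effects"):
        raise ValueError("model must be 'general' or 'common_effects'")
    ap_sexes = tuple(ap_sexes) if model == "general" else ()
    if model == "general" and "DZos" not in pairs:
        raise ValueError("the general sex-limitation model requires DZos pairs")
    stats = _sexlim_stats(pairs)

    def objective(x):
        mu_f, mu_m, V, w_same, w_os = _expected(x, ap_sexes)
        return _neg2ll_sexlim(stats, mu_f, mu_m, V, w_same, w_os)

    # starts from per-sex Falconer estimates
    def sex_start(s):
        mzg, dzg = ("MZf", "DZf") if s == "f" else ("MZm", "DZm")
        def r_v(g):
            (s11, s12), (_, s22) = stats[g].cov
            v = 0.5 * (s11 + s22)
            return (s12 / v if v > 0 else 0.0), v
        rmz, vmz = r_v(mzg)
        rdz, vdz = r_v(dzg)
        V = 0.5 * (vmz + vdz)
        a2 = max(2 * (rmz - rdz), 0.02)
        c2 = max(2 * rdz - rmz, 0.02)
        e2 = max(1 - rmz, 0.05)
        tot = a2 + c2 + e2
        return V * a2 / tot, V * c2 / tot, V * e2 / tot, V

    a2f, c2f, e2f, Vf = sex_start("f")
    a2m, c2m, e2m, Vm = sex_start("m")
    mu0_f = np.mean(stats["MZf"].mean + stats["DZf"].mean)
    mu0_m = np.mean(stats["MZm"].mean + stats["DZm"].mean)
    base = [mu0_f, mu0_m]
    half_f = 0.5 if "f" in ap_sexes else 1.0
    half_m = 0.5 if "m" in ap_sexes else 1.0
    base += [math.sqrt(a2f * half_f), math.sqrt(c2f), math.sqrt(e2f)]
    base += [math.sqrt(a2m * half_m), math.sqrt(c2m), math.sqrt(e2m)]
    if "f" in ap_sexes:
        base.append(math.sqrt(a2f * 0.5))
    if "m" in ap_sexes:
        base.append(math.sqrt(a2m * 0.5))
    base = np.array(base)

    rng = stage_rng(seed, "sexlim-starts")
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        jit = base.copy()
        jit[2:] = np.abs(jit[2:] * rng.uniform(0.4, 1.7, len(base) - 2)) + 0.01
        starts.append(jit)
    bounds = [(None, None)] * 2 + [
        (0.0, None), (0.0, None), (1e-4, None),
        (0.0, None), (0.0, None), (1e-4, None),
    ] + [(0.0, None)] * len(ap_sexes)

    best = None
    for s in starts:
        res = optimize.minimize(
            objective, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        objective, best.x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 10000, "maxfev": 10000},
    )
    if res.fun <= best.fun:
        best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("sex-limitation optimization failed for every start")

    mu_f, mu_m, paths = _unpack(best.x, ap_sexes)
    comps, path_out, V_out = {}, {}, {}
    for s, (a, ap, c, e) in paths.items():
        V = a * a + ap * ap + c * c + e * e
        comps[s] = {"a2": a * a / V, "ap2": ap * ap / V, "c2": c * c / V,
                    "e2": e * e / V}
        path_out[s] = {"a": abs(a), "ap": abs(ap), "c": abs(c), "e": abs(e)}
        V_out[s] = V
    flags = []
    if len(ap_sexes) == 2:
        flags.append(
            "weakly identified: A' estimated in both sexes; only the DZos "
            "cross-covariance separates a2 from ap2 within sex"
        )
    ses = {s: {k: math.nan for k in comps[s]} for s in comps}
    if compute_ses:
        ses = _standardized_ses(objective, best.x, ap_sexes, flags)
    return SexLimSolution(
        model=model, ap_sexes=ap_sexes, components=comps, ses=ses,
        paths=path_out, means={"f": float(mu_f), "m": float(mu_m)},
        total_variance=V_out, minus2ll=float(best.fun),
        k_params=len(best.x), n_pairs=sum(st.n for st in stats.values()),
        flags=flags,
    )


def _standardized_ses(objective, x_hat, ap_sexes, flags):
    """Delta-method SEs of the standardized components from the observed
    information (numerical Hessian of -2lnL / 2)."""
    k = len(x_hat)
    h = 1e-4 * np.maximum(np.abs(x_hat), 0.1)
    H = np.zeros((k, k))
    f0 = objective(x_hat)
    for i in range(k):
        for j in range(i, k):
            xi = x_hat.copy(); xi[i] += h[i]
            xj = x_hat.copy(); xj[j] += h[j]
            xij = x_hat.copy(); xij[i] += h[i]; xij[j] += h[j]
            H[i, j] = H[j, i] = (
                objective(xij) - objective(xi) - objective(xj) + f0
            ) / (h[i] * h[j])
    H *= 0.5  # Hessian of -lnL
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        flags.append("Hessian singular; SEs unavailable")
        return {s: {k_: math.nan for k_ in ("a2", "ap2", "c2", "e2")}
                for s in ("f", "m")}

    def std_components(x):
        _, _, paths = _unpack(x, ap_sexes)
        out = []
        for s in ("f", "m"):
            a, ap, c, e = paths[s]
            V = a * a + ap * ap + c * c + e * e
            out += [a * a / V, ap * ap / V, c * c / V, e * e / V]
        return np.array(out)

    g0 = std_components(x_hat)
    J = np.zeros((len(g0), k))
    for i in range(k):
        xp = x_hat.copy(); xp[i] += h[i]
        xm = x_hat.copy(); xm[i] -= h[i]
        J[:, i] = (std_components(xp) - std_components(xm)) / (2 * h[i])
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    se = np.sqrt(np.clip(var, 0.0, None))
    names = ("a2", "ap2", "c2", "e2")
    return {
        "f": dict(zip(names, se[:4])),
        "m": dict(zip(names, se[4:])),
    }


def lrt_general_vs_common(general: SexLimSolution,
                          common: SexLimSolution) -> LRTResult:
    """Unscaled likelihood-ratio test of the sex-specific genetic component."""
    dchi2 = common.minus2ll - general.minus2ll
    if dchi2 < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({dchi2:.3g}): optimizer failure in the "
            "general model"
        )
    dchi2 = max(0.0, dchi2)
    ddf = general.k_params - common.k_params
    p = float(sps.chi2.sf(dchi2, ddf)) if ddf > 0 else 1.0
    return LRTResult(dchi2=float(dchi2), ddf=int(ddf), p=p)


def sexlim_analysis(
    pairs: dict[str, np.ndarray],
    ap_sexes: tuple = ("f", "m"),
    seed: int = 0,
    compute_ses: bool = True,
) -> dict:
    """Fit general and common-effects models and compare them by LRT."""
    general = fit_sexlim(pairs, model="general", ap_sexes=ap_sexes, seed=seed,
                         compute_ses=compute_ses)
    common = fit_sexlim(pairs, model="common_effects", seed=seed,
                        compute_ses=compute_ses)
    return {
        "general": general,
        "common_effects": common,
        "lrt": lrt_general_vs_common(general, common),
    }
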