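"""Synthetic twin cohorts with known ACE architecture.

Liability model: each twin's trait vector is a weighted sum of additive
genetic (A), shared environmental (C) and unique environmental (E) factors,

    liability = a * A + a' * A' + c * C + e * E,

where per-trait weights are the square roots of the variance proportions and
each factor is multivariate standard normal across traits (correlation rG,
rC, rE respectively).  Co-twin correlations per factor follow the classical
twin design: A correlates 1 in MZ and 0.5 in DZ pairs, C correlates 1 within
any pair, E is independent.  The sex-specific A' correlates 1 (MZ) / 0.5
(same-sex DZ) and 0 across opposite-sex co-twins.  Marginal trait variance
is 1.

Liabilities are then discretized to 1-5 ordinal items through a
:class:`~twinace.architecture.MeasurementModel`, and responses are knocked
out completely at random at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .architecture import (
    TRAIT_NAMES,
    ZYGOSITY_GROUPS,
    MeasurementModel,
    TraitArchitecture,
    default_architecture,
)

#: Default cohort composition: 3,248 MZ and 6,314 DZ pairs, female-leaning,
#: with opposite-sex pairs making up half of the DZ group.
DEFAULT_N_PER_GROUP = {"MZf": 2098, "MZm": 1150, "DZf": 2040, "DZm": 1117, "DZos": 3157}

_GROUP_SEXES = {
    "MZf": ("F", "F"),
    "MZm": ("M", "M"),
    "DZf": ("F", "F"),
    "DZm": ("M", "M"),
    "DZos": ("F", "M"),  # twin 1 = female by convention
}


def _chol(R: np.ndarray, name: str) -> np.ndarray:
    """Cholesky factor with a PSD fallback via eigendecomposition."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        if w.min() < -1e-8:
            raise ValueError(f"{name} is not positive semi-definite") from None
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _paired_factor(rng, n: int, L: np.ndarray, r_cross: float):
    """Two factor draws per family, correlated r_cross across co-twins.

    Shared/unique decomposition: F_t = sqrt(r) * S + sqrt(1-r) * U_t with
    S, U_t ~ N(0, L L').
    """
    t = L.shape[0]
    shared = rng.standard_normal((n, t)) @ L.T
    u1 = rng.standard_normal((n, t)) @ L.T
    u2 = rng.standard_normal((n, t)) @ L.T
    s, u = np.sqrt(r_cross), np.sqrt(1.0 - r_cross)
    return s * shared + u * u1, s * shared + u * u2


def _simulate_group_plain(rng, arch: TraitArchitecture, zyg: str, n: int) -> np.ndarray:
    rA = 1.0 if zyg.startswith("MZ") else 0.5
    LG, LC, LE = (_chol(arch.rG, "rG"), _chol(arch.rC, "rC"), _chol(arch.rE, "rE"))
    A1, A2 = _paired_factor(rng, n, LG, rA)
    C1, C2 = _paired_factor(rng, n, LC, 1.0)
    E1, E2 = _paired_factor(rng, n, LE, 0.0)

    if arch.sexlim is None:
        a = np.sqrt(arch.a2)
        c = np.sqrt(arch.c2)
        e = np.sqrt(arch.e2)
        liab = np.empty((n, 2, arch.n_traits))
        liab[:, 0, :] = a * A1 + c * C1 + e * E1
        liab[:, 1, :] = a * A2 + c * C2 + e * E2
        return liab

    sl = arch.sexlim
    sexes = _GROUP_SEXES[zyg]
    # A' is uncorrelated across opposite-sex co-twins
    r_ap = 0.0 if zyg == "DZos" else rA
    P1, P2 = _paired_factor(rng, n, LG, r_ap)
    liab = np.empty((n, 2, arch.n_traits))
    for t, (F, P, C, E) in enumerate(((A1, P1, C1, E1), (A2, P2, C2, E2))):
        s = "f" if sexes[t] == "F" else "m"
        a = np.sqrt(getattr(sl, f"a2_{s}"))
        ap = np.sqrt(getattr(sl, f"ap2_{s}"))
        c = np.sqrt(getattr(sl, f"c2_{s}"))
        e = np.sqrt(getattr(sl, f"e2_{s}"))
        liab[:, t, :] = a * F + ap * P + c * C + e * E
    return liab


def _simulate_group_cp(rng, arch: TraitArchitecture, zyg: str, n: int) -> np.ndarray:
    """Common-pathway generative mode: latent ACE factor + specific ACE."""
    cp = arch.common_pathway
    rA = 1.0 if zyg.startswith("MZ") else 0.5
    one = np.ones((1, 1))
    t = cp.loadings.size

    LA1, LA2 = _paired_factor(rng, n, one, rA)
    LC1, LC2 = _paired_factor(rng, n, one, 1.0)
    LE1, LE2 = _paired_factor(rng, n, one, 0.0)
    lat1 = (
        np.sqrt(cp.latent_a2) * LA1 + np.sqrt(cp.latent_c2) * LC1
        + np.sqrt(cp.latent_e2) * LE1
    )
    lat2 = (
        np.sqrt(cp.latent_a2) * LA2 + np.sqrt(cp.latent_c2) * LC2
        + np.sqrt(cp.latent_e2) * LE2
    )

    eye = np.eye(t)
    SA1, SA2 = _paired_factor(rng, n, eye, rA)
    SC1, SC2 = _paired_factor(rng, n, eye, 1.0)
    SE1, SE2 = _paired_factor(rng, n, eye, 0.0)
    sa, sc, se = (np.sqrt(cp.specific_a2), np.sqrt(cp.specific_c2),
                  np.sqrt(cp.specific_e2))

    liab = np.empty((n, 2, t))
    liab[:, 0, :] = cp.loadings * lat1 + sa * SA1 + sc * SC1 + se * SE1
    liab[:, 1, :] = cp.loadings * lat2 + sa * SA2 + sc * SC2 + se * SE2
    return liab


def simulate_liabilities(
    arch: TraitArchitecture,
    n_per_group: dict[str, int],
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw continuous trait liabilities for every family.

    Returns ``(liabilities, meta)`` where ``liabilities`` has shape
    ``(n_families, 2, n_traits)`` and ``meta`` carries family_id, zygosity and
    per-twin sex, in fixed group order MZf, MZm, DZf, DZm, DZos.
    """
    for g in n_per_group:
        if g not in ZYGOSITY_GROUPS:
            raise ValueError(f"unknown zygosity group {g!r}")
        if n_per_group[g] < 0:
            raise ValueError("group sizes must be non-negative")
    rng = stage_rng(seed, "liabilities")
    blocks, rows = [], []
    fam = 0
    for zyg in ZYGOSITY_GROUPS:
        n = int(n_per_group.get(zyg, 0))
        if n == 0:
            continue
        if arch.common_pathway is not None:
            blocks.append(_simulate_group_cp(rng, arch, zyg, n))
        else:
            blocks.append(_simulate_group_plain(rng, arch, zyg, n))
        s1, s2 = _GROUP_SEXES[zyg]
        rows.append(
            pd.DataFrame(
                {
                    "family_id": np.arange(fam, fam + n),
                    "zygosity": zyg,
                    "sex1": s1,
                    "sex2": s2,
                }
            )
        )
        fam += n
    if not blocks:
        raise ValueError("no families requested")
    return np.concatenate(blocks, axis=0), pd.concat(rows, ignore_index=True)


def liabilities_to_items(
    liabilities: np.ndarray, mm: MeasurementModel, seed: int
) -> np.ndarray:
    """Discretize liabilities to ordinal 1-5 item responses.

    The pre-threshold item latent is ``loading * trait + sqrt(uniqueness) *
    noise``; its category is determined by the item's 4 ordered thresholds,
    and reverse-coded items are emitted as ``6 - category``.
    """
    liab = np.asarray(liabilities, dtype=float)
    if liab.ndim == 2:  # individuals x traits
        liab = liab[:, None, :]
        squeeze = True
    else:
        squeeze = False
    n, two, t = liab.shape
    if t != mm.n_traits:
        raise ValueError(
            f"liability trait count {t} does not match measurement model "
            f"({mm.n_traits} traits)"
        )
    rng = stage_rng(seed, "measurement")
    trait_idx = mm.trait_of_item()
    k = mm.n_items
    items = np.empty((n, two, k), dtype=float)
    noise_sd = np.sqrt(mm.uniqueness)
    for j in range(k):
        y = mm.loadings[j] * liab[:, :, trait_idx[j]]
        if noise_sd[j] > 0:
            y = y + noise_sd[j] * rng.standard_normal((n, two))
        cat = np.searchsorted(mm.thresholds[j], y) + 1
        if j in mm.reverse_coded:
            cat = 6 - cat
        items[:, :, j] = cat
    return items[:, 0, :] if squeeze else items


def inject_missingness(items: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Set each response missing (NaN) independently with probability *rate*."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missingness rate must be in [0, 1), got {rate}")
    out = np.asarray(items, dtype=float).copy()
    if rate == 0.0:
        return out
    rng = stage_rng(seed, "missingness")
    out[rng.random(out.shape) < rate] = np.nan
    return out


@dataclass
class TwinCohort:
    """A simulated (or loaded) twin cohort in wide, one-row-per-family form.

    ``wide`` columns: family_id, zygosity, sex1, sex2, age,
    i01_1..i25_1, i01_2..i25_2 (missing = NaN).  ``liabilities`` holds the
    generating continuous trait scores when the cohort was simulated, enabling
    measurement-free model-level tests.
    """

    wide: pd.DataFrame
    arch: TraitArchitecture | None = None
    mm: MeasurementModel | None = None
    seed: int | None = None
    liabilities: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_items(self) -> int:
        return sum(c.startswith("i") and c.endswith("_1") for c in self.wide.columns)

    def item_columns(self, twin: int) -> list[str]:
        k = self.n_items
        return [f"i{j + 1:02d}_{twin}" for j in range(k)]

    def to_long(self) -> pd.DataFrame:
        """One row per individual with item columns i01..i25."""
        k = self.n_items
        frames = []
        for t in (1, 2):
            cols = self.item_columns(t)
            df = self.wide[["family_id", "zygosity", f"sex{t}", "age"]].copy()
            df.columns = ["family_id", "zygosity", "sex", "age"]
            df["twin"] = t
            items = self.wide[cols].to_numpy(dtype=float)
            for j in range(k):
                df[f"i{j + 1:02d}"] = items[:, j]
            frames.append(df)
        long = pd.concat(frames, ignore_index=True)
        return long.sort_values(["family_id", "twin"], kind="stable").reset_index(
            drop=True
        )

    def liability_scores(self) -> pd.DataFrame | None:
        """Per-individual generating trait liabilities (simulated cohorts only)."""
        if self.liabilities is None:
            return None
        frames = []
        for t in (1, 2):
            df = self.wide[["family_id", "zygosity", f"sex{t}", "age"]].copy()
            df.columns = ["family_id", "zygosity", "sex", "age"]
            df["twin"] = t
            for j, name in enumerate(TRAIT_NAMES[: self.liabilities.shape[2]]):
                df[name] = self.liabilities[:, t - 1, j]
            frames.append(df)
        long = pd.concat(frames, ignore_index=True)
        return long.sort_values(["family_id", "twin"], kind="stable").reset_index(
            drop=True
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the wide table (missing = empty field) plus a JSON sidecar."""
        path = Path(path)
        self.wide.to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "architecture": self.arch.to_dict() if self.arch is not None else None,
            "measurement": self.mm.to_dict() if self.mm is not None else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TwinCohort":
        path = Path(path)
        wide = pd.read_csv(path)
        arch = mm = seed = None
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            seed = meta.get("seed")
            if meta.get("architecture"):
                arch = TraitArchitecture.from_dict(meta["architecture"])
            if meta.get("measurement"):
                mm = MeasurementModel.from_dict(meta["measurement"])
        return cls(wide=wide, arch=arch, mm=mm, seed=seed)


def simulate_cohort(
    seed: int,
    arch: TraitArchitecture | None = None,
    mm: MeasurementModel | None = None,
    n_per_group: dict[str, int] | None = None,
    missing_rate: float = 0.015,
    age_range: tuple[float, float] = (18.0, 49.0),
) -> TwinCohort:
    """Simulate a full twin cohort: liabilities, ordinal items, missingness.

    Ages are uniform over *age_range* and shared within a pair.  Defaults
    reproduce the reference composition (3,248 MZ + 6,314 DZ pairs, ~1.5%
    missing responses).
    """
    arch = arch if arch is not None else default_architecture()
    mm = mm if mm is not None else MeasurementModel.default(arch.n_traits)
    n_per_group = dict(n_per_group) if n_per_group is not None else dict(DEFAULT_N_PER_GROUP)

    liab, meta = simulate_liabilities(arch, n_per_group, seed)
    items = liabilities_to_items(liab, mm, seed)
    items = inject_missingness(items, missing_rate, seed)

    ages = stage_rng(seed, "ages").uniform(age_range[0], age_range[1], size=len(meta))
    wide = meta.copy()
    wide["age"] = np.round(ages, 1)
    k = mm.n_items
    for t in (1, 2):
        for j in range(k):
            wide[f"i{j + 1:02d}_{t}"] = items[:, t - 1, j]
    return TwinCohort(wide=wide, arch=arch, mm=mm, seed=seed, liabilities=liab)
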