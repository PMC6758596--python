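"""Generative truth for synthetic twin cohorts.

A :class:`TraitArchitecture` states, per trait, how much liability variance is
additive-genetic (A), shared-environmental (C) and unique-environmental (E),
and how those components correlate across traits (rG, rC, rE).  Two optional
extensions mirror the models fitted downstream: a common-pathway generative
mode (one latent ACE factor feeding all traits through loadings) and a
sex-limitation mode (per-sex ACE proportions plus a sex-specific additive
component A' that is uncorrelated across opposite-sex co-twins).

A :class:`MeasurementModel` maps continuous trait liabilities to 5-category
ordinal questionnaire items via item loadings, uniquenesses and ordered
thresholds, with a subset of items emitted reverse-coded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

ZYGOSITY_GROUPS = ("MZf", "MZm", "DZf", "DZm", "DZos")

#: Trait order used throughout: five maltreatment scales of a CTQ-style
#: questionnaire (abstract indices here, not the licensed item wording).
TRAIT_NAMES = (
    "emotional_abuse",
    "physical_abuse",
    "sexual_abuse",
    "emotional_neglect",
    "physical_neglect",
)

_SUM_TOL = 1e-12


def _as_vec(x, n: int, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.size == 1:
        v = np.full(n, float(v[0]))
    if v.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {v.shape}")
    return v


def check_correlation_matrix(R: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    """Validate symmetry, unit diagonal and positive semi-definiteness."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be square, got shape {R.shape}")
    if not np.allclose(R, R.T, atol=tol):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=tol):
        raise ValueError(f"{name} does not have a unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {w.min():.3e})"
        )
    return R


@dataclass
class CommonPathwayTruth:
    """One latent ACE factor transmitting shared etiology to every trait.

    The latent factor has unit variance (``a2 + c2 + e2 = 1``); each trait is
    ``loading * latent + specific``, with trait-specific ACE residuals sized so
    the marginal trait variance is 1.
    """

    loadings: np.ndarray
    latent_a2: float
    latent_c2: float
    latent_e2: float
    specific_a2: np.ndarray
    specific_c2: np.ndarray
    specific_e2: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        n = lam.size
        self.loadings = lam
        self.specific_a2 = _as_vec(self.specific_a2, n, "specific_a2")
        self.specific_c2 = _as_vec(self.specific_c2, n, "specific_c2")
        self.specific_e2 = _as_vec(self.specific_e2, n, "specific_e2")
        lat = self.latent_a2 + self.latent_c2 + self.latent_e2
        if abs(lat - 1.0) > _SUM_TOL:
            raise ValueError(f"latent a2+c2+e2 must equal 1, got {lat}")
        tot = lam**2 + self.specific_a2 + self.specific_c2 + self.specific_e2
        if np.any(np.abs(tot - 1.0) > 1e-9):
            raise ValueError(
                "per-trait loading^2 + specific a2+c2+e2 must equal 1; got "
                f"{tot}"
            )


@dataclass
class SexLimTruth:
    """Per-sex ACE proportions plus a sex-specific additive component A'.

    A' represents a set of genes operating in one sex only: it correlates 1
    across MZ co-twins, 0.5 across same-sex DZ co-twins and 0 across
    opposite-sex co-twins.  Per sex and trait, a2 + ap2 + c2 + e2 = 1.
    """

    a2_f: np.ndarray
    c2_f: np.ndarray
    e2_f: np.ndarray
    a2_m: np.ndarray
    c2_m: np.ndarray
    e2_m: np.ndarray
    ap2_f: np.ndarray = 0.0
    ap2_m: np.ndarray = 0.0

    def __post_init__(self) -> None:
        n = np.atleast_1d(np.asarray(self.a2_f, dtype=float)).size
        for name in ("a2_f", "c2_f", "e2_f", "ap2_f", "a2_m", "c2_m", "e2_m", "ap2_m"):
            setattr(self, name, _as_vec(getattr(self, name), n, name))
        for sex in ("f", "m"):
            tot = (
                getattr(self, f"a2_{sex}")
                + getattr(self, f"ap2_{sex}")
                + getattr(self, f"c2_{sex}")
                + getattr(self, f"e2_{sex}")
            )
            if np.any(np.abs(tot - 1.0) > 1e-9):
                raise ValueError(
                    f"a2 + ap2 + c2 + e2 must equal 1 per trait for sex '{sex}', got {tot}"
                )


@dataclass
class TraitArchitecture:
    """ACE variance proportions and cross-trait component correlations."""

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    rG: np.ndarray | None = None
    rC: np.ndarray | None = None
    rE: np.ndarray | None = None
    common_pathway: CommonPathwayTruth | None = None
    sexlim: SexLimTruth | None = None
    n_traits: int = field(init=False)

    def __post_init__(self) -> None:
        a2 = np.atleast_1d(np.asarray(self.a2, dtype=float))
        n = a2.size
        self.n_traits = n
        self.a2 = a2
        self.c2 = _as_vec(self.c2, n, "c2")
        self.e2 = _as_vec(self.e2, n, "e2")
        tot = self.a2 + self.c2 + self.e2
        if np.any(np.abs(tot - 1.0) > _SUM_TOL) and self.sexlim is None:
            raise ValueError(f"a2 + c2 + e2 must equal 1 per trait, got {tot}")
        for name in ("rG", "rC", "rE"):
            R = getattr(self, name)
            if R is None:
                R = np.eye(n)
            setattr(self, name, check_correlation_matrix(np.asarray(R, float), name))

    def to_dict(self) -> dict:
        d = {
            "a2": self.a2.tolist(),
            "c2": self.c2.tolist(),
            "e2": self.e2.tolist(),
            "rG": self.rG.tolist(),
            "rC": self.rC.tolist(),
            "rE": self.rE.tolist(),
        }
        if self.common_pathway is not None:
            cp = self.common_pathway
            d["common_pathway"] = {
                "loadings": cp.loadings.tolist(),
                "latent_a2": cp.latent_a2,
                "latent_c2": cp.latent_c2,
                "latent_e2": cp.latent_e2,
                "specific_a2": cp.specific_a2.tolist(),
                "specific_c2": cp.specific_c2.tolist(),
                "specific_e2": cp.specific_e2.tolist(),
            }
        if self.sexlim is not None:
            sl = self.sexlim
            d["sexlim"] = {
                k: getattr(sl, k).tolist()
                for k in ("a2_f", "c2_f", "e2_f", "ap2_f", "a2_m", "c2_m", "e2_m", "ap2_m")
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TraitArchitecture":
        cp = d.get("common_pathway")
        sl = d.get("sexlim")
        return cls(
            a2=np.asarray(d["a2"], float),
            c2=np.asarray(d["c2"], float),
            e2=np.asarray(d["e2"], float),
            rG=np.asarray(d["rG"], float) if d.get("rG") is not None else None,
            rC=np.asarray(d["rC"], float) if d.get("rC") is not None else None,
            rE=np.asarray(d["rE"], float) if d.get("rE") is not None else None,
            common_pathway=CommonPathwayTruth(**cp) if cp else None,
            sexlim=SexLimTruth(**sl) if sl else None,
        )


def _corr(n: int, off: float) -> np.ndarray:
    R = np.full((n, n), off)
    np.fill_diagonal(R, 1.0)
    return R


def default_architecture() -> TraitArchitecture:
    """Moderately heritable traits with correlated familial influences.

    a2/c2/e2 = 0.5/0.2/0.3 for every trait; cross-trait correlations set to
    the field-typical magnitudes recovered downstream (rG 0.43, rC 0.55,
    rE 0.13).
    """
    n = len(TRAIT_NAMES)
    return TraitArchitecture(
        a2=np.full(n, 0.5),
        c2=np.full(n, 0.2),
        e2=np.full(n, 0.3),
        rG=_corr(n, 0.43),
        rC=_corr(n, 0.55),
        rE=_corr(n, 0.13),
    )


@dataclass
class MeasurementModel:
    """Ordinal measurement of trait liabilities: 5 items per trait on 1-5.

    ``loadings[j]**2 + uniqueness[j] = 1`` so the pre-threshold item latent is
    standard normal; ``thresholds[j]`` are its 4 ordered cut points.  Items in
    ``reverse_coded`` are emitted as ``6 - category``.  ``family_specific``
    partitions items for the family-specific / family-unspecific composites.
    """

    loadings: np.ndarray
    thresholds: np.ndarray
    reverse_coded: frozenset
    family_specific: frozenset
    items_per_trait: int = 5

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        k = self.loadings.size
        if self.thresholds.shape != (k, 4):
            raise ValueError(
                f"thresholds must be ({k}, 4), got {self.thresholds.shape}"
            )
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            bad = np.where(np.any(np.diff(self.thresholds, axis=1) <= 0, axis=1))[0]
            raise ValueError(f"thresholds must be strictly increasing (items {bad})")
        if np.any((self.loadings <= 0) | (self.loadings > 1)):
            raise ValueError("item loadings must lie in (0, 1]")
        self.reverse_coded = frozenset(int(i) for i in self.reverse_coded)
        self.family_specific = frozenset(int(i) for i in self.family_specific)
        if not self.reverse_coded <= set(range(k)):
            raise ValueError("reverse_coded indices out of range")
        if not self.family_specific <= set(range(k)):
            raise ValueError("family_specific indices out of range")

    @property
    def n_items(self) -> int:
        return self.loadings.size

    @property
    def n_traits(self) -> int:
        return self.n_items // self.items_per_trait

    @property
    def uniqueness(self) -> np.ndarray:
        return 1.0 - self.loadings**2

    def trait_of_item(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_traits), self.items_per_trait)

    @classmethod
    def default(cls, n_traits: int = 5) -> "MeasurementModel":
        """5 items per trait; skewed categories typical of adversity scales.

        Default thresholds put ~60/20/10/5/5 % of mass on categories 1..5
        (maltreatment items are strongly right-skewed); item loadings average
        0.7.  For the canonical 5-trait layout, seven items are
        reverse-coded and the family-specific set is the emotional-abuse,
        emotional-neglect and physical-neglect scales (physical and sexual
        abuse, typically by unspecified persons, are family-unspecific).
        For other trait counts the reverse set is empty and the first
        scale's items are marked family-specific.
        """
        from scipy.stats import norm

        k = 5 * n_traits
        lam = np.tile([0.8, 0.75, 0.7, 0.65, 0.6], n_traits)
        thr = np.tile(norm.ppf([0.60, 0.80, 0.90, 0.95]), (k, 1))
        if n_traits == 5:
            reverse = frozenset({1, 6, 9, 12, 16, 19, 23})
            fam = frozenset(range(0, 5)) | frozenset(range(15, 25))
        else:
            reverse = frozenset()
            fam = frozenset(range(max(5, k // 2) if n_traits == 1 else 5))
            if n_traits == 1:
                fam = frozenset(range(3))
        return cls(loadings=lam, thresholds=thr, reverse_coded=reverse,
                   family_specific=fam)

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "thresholds": self.thresholds.tolist(),
            "reverse_coded": sorted(self.reverse_coded),
            "family_specific": sorted(self.family_specific),
            "items_per_trait": self.items_per_trait,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementModel":
        return cls(
            loadings=np.asarray(d["loadings"], float),
            thresholds=np.asarray(d["thresholds"], float),
            reverse_coded=frozenset(d["reverse_coded"]),
            family_specific=frozenset(d["family_specific"]),
            items_per_trait=int(d.get("items_per_trait", 5)),
        )


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config mirroring the architecture/measurement fields."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
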