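"""Reshape per-individual score tables into per-zygosity twin-pair arrays.

Twin models consume, per analysis group, an ``(n_pairs, 2*k)`` array laid out
as (twin-1 scores..., twin-2 scores...).  Grouping schemes mirror the
analysis designs: pooled MZ/DZ for the full sample, same-sex groups for the
single-sex analyses, and the five-group split (with female-first DZos
ordering) for sex-limitation models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Full-sample scheme: all DZ pairs pooled (DZos treated like same-sex DZ).
POOLED = {"MZ": ("MZf", "MZm"), "DZ": ("DZf", "DZm", "DZos")}
WOMEN = {"MZ": ("MZf",), "DZ": ("DZf",)}
MEN = {"MZ": ("MZm",), "DZ": ("DZm",)}
FIVE_GROUP = {g: (g,) for g in ("MZf", "MZm", "DZf", "DZm", "DZos")}


def pair_frame(scores: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """One row per family with ``<col>_1`` / ``<col>_2`` score columns.

    DZos pairs are reordered so twin 1 is the female co-twin.
    """
    t1 = scores[scores["twin"] == 1].set_index("family_id")
    t2 = scores[scores["twin"] == 2].set_index("family_id")
    common = t1.index.intersection(t2.index)
    t1, t2 = t1.loc[common], t2.loc[common]
    out = pd.DataFrame(index=common)
    out["zygosity"] = t1["zygosity"]
    swap = (t1["zygosity"] == "DZos") & (t1["sex"] == "M")
    for c in columns:
        a = t1[c].to_numpy().copy()
        b = t2[c].to_numpy().copy()
        s = swap.to_numpy()
        a[s], b[s] = b[s], a[s].copy()
        out[f"{c}_1"] = a
        out[f"{c}_2"] = b
    return out.reset_index()


def pairs_by_group(
    scores: pd.DataFrame,
    columns: str | list[str],
    scheme: dict[str, tuple[str, ...]] = POOLED,
) -> dict[str, np.ndarray]:
    """Per-group pair arrays shaped ``(n_pairs, 2*k)``, twin 1 block first."""
    if isinstance(columns, str):
        columns = [columns]
    pf = pair_frame(scores, columns)
    cols = [f"{c}_1" for c in columns] + [f"{c}_2" for c in columns]
    out = {}
    for label, zygs in scheme.items():
        sub = pf[pf["zygosity"].isin(zygs)]
        if len(sub):
            out[label] = sub[cols].to_numpy(dtype=float)
    return out


def relatedness(group: str) -> float:
    """Additive-genetic co-twin correlation implied by a group label."""
    return 1.0 if group.upper().startswith("MZ") else 0.5
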