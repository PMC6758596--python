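import numpy as np
import pytest

from twinace import TraitArchitecture, simulate_liabilities


def liability_pairs(arch, n_per_group, seed, trait=0, pooled=True):
    """Per-group (n, 2) liability pair arrays for one trait.

    With ``pooled=True``, groups are collapsed to MZ / DZ labels (DZos
    included with DZ); otherwise the five-group labels are kept.
    """
    liab, meta = simulate_liabilities(arch, n_per_group, seed)
    zyg = meta["zygosity"].to_numpy()
    out = {}
    for g in np.unique(zyg):
        label = (g[:2] if pooled else g)
        arr = liab[zyg == g][:, :, trait]
        out[label] = np.vstack([out[label], arr]) if label in out else arr
    return out


def liability_multipairs(arch, n_per_group, seed, traits=None, pooled=True):
    """Per-group (n, 2k) arrays (twin-1 traits then twin-2 traits)."""
    liab, meta = simulate_liabilities(arch, n_per_group, seed)
    traits = list(range(liab.shape[2])) if traits is None else list(traits)
    zyg = meta["zygosity"].to_numpy()
    out = {}
    for g in np.unique(zyg):
        label = (g[:2] if pooled else g)
        L = liab[zyg == g]
        arr = np.concatenate([L[:, 0, traits], L[:, 1, traits]], axis=1)
        out[label] = np.vstack([out[label], arr]) if label in out else arr
    return out


@pytest.fixture(scope="session")
def simple_arch():
    return TraitArchitecture(a2=[0.6], c2=[0.2], e2=[0.2])


@pytest.fixture(scope="session")
def ace_arch():
    return TraitArchitecture(a2=[0.5], c2=[0.2], e2=[0.3])
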