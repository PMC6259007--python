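import numpy as np
import pytest

import symnet as sn


@pytest.fixture(scope="session")
def clinical_5000():
    """Ordinal sample from the 17-node clinical preset, n=5000 (shared)."""
    spec = sn.preset_ptsd17("clinical", n=5000, seed=42)
    return spec, sn.sample_ordinal(spec)


@pytest.fixture()
def chain_network():
    """A - B - C chain with both weights 0.5."""
    w = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.0]])
    return sn.Network(labels=("A", "B", "C"), weights=w)


def random_network(p: int, seed: int, density: float = 0.6) -> sn.Network:
    """Random symmetric weighted network with some exact-zero edges."""
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    vals = rng.uniform(-0.6, 0.6, size=len(iu[0]))
    vals[rng.random(len(vals)) > density] = 0.0
    w[iu] = vals
    w = w + w.T
    return sn.Network(labels=tuple(f"N{i}" for i in range(p)), weights=w)
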