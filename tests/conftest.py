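"""Shared fixtures: exactly-weighted channel tables and junction data.

The "exact" tables realize a noisy-channel joint distribution with integer
cell counts, so plug-in estimates on them equal the analytic values computed
from the distribution itself — closed-form oracles for the information
quantities.
"""

from itertools import product

import numpy as np
import pytest

from vistla import DataTable, Feature, JunctionConfig, gen_junction


def channel_matrix(eps: float) -> np.ndarray:
    return np.array([[1 - eps, eps], [eps, 1 - eps]])


def exact_chain_table(depth: int, eps: float, n: int, names=None) -> DataTable:
    """Binary chain x0 -> x1 -> ... -> x_depth with symmetric flip ``eps``,
    materialized with cell counts exactly proportional to the joint
    probabilities (requires ``n * p`` integral for every cell)."""
    C = channel_matrix(eps)
    k = depth + 1
    rows = []
    for cell in product((0, 1), repeat=k):
        p = 0.5
        for a, b in zip(cell[:-1], cell[1:]):
            p *= C[a, b]
        cnt = p * n
        assert abs(cnt - round(cnt)) < 1e-9, "n does not give integral counts"
        rows.extend([cell] * round(cnt))
    arr = np.array(rows)
    names = names or [f"x{i}" for i in range(k)]
    feats = [Feature(nm, "binary", arr[:, i]) for i, nm in enumerate(names)]
    return DataTable(feats, anchor=names[0])


@pytest.fixture(scope="session")
def chain3_exact() -> DataTable:
    """a -> b -> c, eps=0.1, n=1000 (exact counts); anchor unused."""
    return exact_chain_table(2, 0.1, 1000, names=["a", "b", "c"])


@pytest.fixture(scope="session")
def chain4_exact() -> DataTable:
    """Y -> a -> b -> c, eps=0.1, n=2000 (exact counts), anchored at Y."""
    return exact_chain_table(3, 0.1, 2000, names=["Y", "a", "b", "c"])


@pytest.fixture(scope="session")
def junction() -> DataTable:
    return gen_junction(JunctionConfig(n=5000, seed=3))


@pytest.fixture(scope="session")
def independent_table() -> DataTable:
    """Anchor plus four mutually independent binary noise features."""
    rng = np.random.default_rng(42)
    feats = [Feature(nm, "binary", rng.integers(0, 2, 1000))
             for nm in ("Y", "N1", "N2", "N3", "N4")]
    return DataTable(feats, anchor="Y")
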