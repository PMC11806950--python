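"""Synthetic benchmarks: the junction network and anchored chains/DAGs.

Every generator is a seeded Bayesian-network sampler built from symmetric
binary channels: a child repeats its parent's bit, flipped independently
with probability ``eps``.  With a uniform root and ``0 < eps < 0.5`` the
mutual information with the anchor strictly decreases along every chain —
the data-processing-inequality structure the path search exploits — while
``eps = 0`` produces deterministic copies (MI ties, which the strict ι
gates refuse) and ``eps = 0.5`` severs all dependence.

The *junction* benchmark consists of two parallel chains
``Y→A1→A2→JA→A3`` and ``Y→B1→B2→JB→B3`` in which the intermediate
variables ``JA`` and ``JB`` are withheld and replaced by the single
4-category junction feature ``J`` pairing them, so ``J`` blends two
independent mechanisms into one measured column.  Pairwise statistics see
``J`` as a hub; the tri-variate search should instead resolve the two
chains and represent ``J`` as a relay on both, demonstrating how the
pair-level tree encodes multi-modality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataTable, Feature


@dataclass
class JunctionConfig:
    """Sampling configuration of the junction network.

    The default flip probability 0.2 is chosen so the *population* anchor-MI
    ordering is ``I(Y;A1) > I(Y;A2) > I(Y;J) > I(Y;A3)`` (verified by exact
    enumeration of the 512-cell joint): the 4-category junction feature pools
    two depth-3 variables, so at low noise it carries more anchor information
    than the depth-2 features and would legitimately precede them on every
    path, hiding the chain structure the benchmark exists to illustrate.
    """

    n: int = 5000
    eps: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps <= 0.5:
            raise ValueError("eps must lie in [0, 0.5]")
        if self.n < 1:
            raise ValueError("n must be positive")


@dataclass
class ChainConfig:
    """Configuration of ``branching`` independent noisy chains of length
    ``depth`` hanging off a shared binary anchor.

    With ``continuous=True`` the chain variables are real-valued: each child
    adds Gaussian noise of standard deviation ``noise_sd`` to its parent
    (anchor coded ±1), giving an ordinal benchmark for rank-based
    estimation; ``eps`` is ignored in that case.
    """

    depth: int = 3
    branching: int = 2
    n: int = 2000
    eps: float = 0.1
    seed: int = 0
    continuous: bool = False
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be at least 1")
        if not 0.0 <= self.eps <= 0.5:
            raise ValueError("eps must lie in [0, 0.5]")


def _flip(parent: np.ndarray, eps: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric binary channel: flip each bit with probability eps."""
    return parent ^ (rng.random(parent.size) < eps).astype(np.int64)


def gen_junction(cfg: JunctionConfig) -> DataTable:
    """Sample the junction network.

    Emits columns ``Y, A1, A2, A3, B1, B2, B3, J`` with ``J`` the
    4-category Cartesian pairing of the withheld ``JA`` and ``JB`` (the
    pairing, not an arithmetic product, so ``J`` retains the information of
    both).  The anchor is ``Y``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, eps = cfg.n, cfg.eps
    y = rng.integers(0, 2, n)
    a1 = _flip(y, eps, rng)
    a2 = _flip(a1, eps, rng)
    ja = _flip(a2, eps, rng)
    a3 = _flip(ja, eps, rng)
    b1 = _flip(y, eps, rng)
    b2 = _flip(b1, eps, rng)
    jb = _flip(b2, eps, rng)
    b3 = _flip(jb, eps, rng)
    j = 2 * ja + jb
    feats = [
        Feature("Y", "binary", y),
        Feature("A1", "binary", a1),
        Feature("A2", "binary", a2),
        Feature("A3", "binary", a3),
        Feature("B1", "binary", b1),
        Feature("B2", "binary", b2),
        Feature("B3", "binary", b3),
        Feature("J", "categorical", j),
    ]
    return DataTable(feats, anchor="Y")


def gen_chain(cfg: ChainConfig) -> tuple[DataTable, list[tuple[str, str]]]:
    """Sample independent anchored chains; returns the table and the
    ground-truth edge list for recovery scoring.

    Chain features are named ``C{branch}_{depth}`` (1-based).
    """
    rng = np.random.default_rng(cfg.seed)
    y = rng.integers(0, 2, cfg.n)
    feats = [Feature("Y", "binary", y)]
    edges: list[tuple[str, str]] = []
    for b in range(1, cfg.branching + 1):
        parent_name = "Y"
        parent = y.astype(float) * 2 - 1 if cfg.continuous else y
        for d in range(1, cfg.depth + 1):
            name = f"C{b}_{d}"
            if cfg.continuous:
                child = parent + rng.normal(0.0, cfg.noise_sd, cfg.n)
                feats.append(Feature(name, "ordinal", child))
            else:
                child = _flip(parent, cfg.eps, rng)
                feats.append(Feature(name, "binary", child))
            edges.append((parent_name, name))
            parent_name, parent = name, child
    return DataTable(feats, anchor="Y"), edges


@dataclass
class DagConfig:
    """Random anchored tree-shaped DAG: each feature's parent is drawn
    uniformly from the anchor and the features generated before it, and each
    edge gets its own flip probability drawn from ``eps_range``."""

    m: int = 5
    n: int = 500
    eps_range: tuple[float, float] = (0.05, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least two non-anchor features")


def gen_dag(cfg: DagConfig) -> tuple[DataTable, list[tuple[str, str]]]:
    """Sample a random anchored DAG of binary features (for stress tests)."""
    rng = np.random.default_rng(cfg.seed)
    y = rng.integers(0, 2, cfg.n)
    names = ["Y"]
    cols = [y]
    edges: list[tuple[str, str]] = []
    for i in range(1, cfg.m + 1):
        parent = int(rng.integers(0, len(cols)))
        eps = float(rng.uniform(*cfg.eps_range))
        child = _flip(cols[parent], eps, rng)
        names.append(f"X{i}")
        cols.append(child)
        edges.append((names[parent], names[i]))
    feats = [Feature(nm, "binary", col) for nm, col in zip(names, cols)]
    return DataTable(feats, anchor="Y"), edges
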