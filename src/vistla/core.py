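"""The influence-path search: ι edge weights and maxi-min Dijkstra.

The search works on a derived graph whose vertices are *ordered pairs* of
distinct non-anchor features.  An edge exists only between pairs of the form
``(X_a, X_b) -> (X_b, X_c)`` and carries the weight

    ι_Y((X_a,X_b),(X_b,X_c)) = max{I(X_a;X_b;X_c), 0}
                               × [I(X_a;X_b) > I(X_a;X_c)]
                               × [I(Y;X_b)  > I(Y;X_c)]

where ``[·]`` is the Iverson bracket.  The two strict-inequality gates
enforce the data processing inequality locally and with respect to the
anchor; the truncated interaction information rejects synergistic
(collider-like) triples.  A path's value is the **minimum** ι along it, and
the search finds, for every pair, the path from the anchor maximizing that
minimum — a widest-path (bottleneck) problem solved by a max-min variant of
Dijkstra's algorithm.

Initial scores seed the frontier: ``S[i,j] = ι_Y((Y,X_i),(X_i,X_j))``, i.e.
the anchor enters only through initialization and through the second gate.
Because every admissible edge strictly decreases ``I(Y;·)``, no feature can
repeat along a positively-scored path, which keeps reconstructed paths
simple at the feature level.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .data import DataTable
from .estimators import Estimator

#: predecessor sentinels
ANCHOR = -1
UNREACHABLE = -2


@dataclass
class SearchOptions:
    """Options of one search run.

    min_score
        Early-stop threshold in nats: the main loop halts once the best
        queued pair scores below it (0 disables the stop).
    targets
        Optional list of feature indices; the loop halts once every target
        has a visited pair ending at it.
    seed
        Seed of the PRNG used to break ties at queue extraction; part of the
        run configuration for reproducibility.
    """

    min_score: float = 0.0
    targets: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be non-negative")


@dataclass
class PairState:
    """Search state over ordered feature pairs.

    ``S[a, b]`` is the current (after the search: final) bottleneck score of
    the best known path from the anchor ending in ``(X_a, X_b)``;
    ``P[a, b]`` the predecessor feature of that path (``ANCHOR`` for initial
    pairs, ``UNREACHABLE`` while no positive path is known).  ``visit_log``
    records pairs in pop order together with their (then final) scores.
    """

    S: np.ndarray
    P: np.ndarray
    anchor: int
    feature_indices: list[int]
    visited: set[tuple[int, int]] = field(default_factory=set)
    visit_log: list[tuple[int, int, float]] = field(default_factory=list)
    visit_rank: dict[tuple[int, int], int] = field(default_factory=dict)
    n_iota: int = 0


def _iota(est: Estimator, y: int, a: int, b: int, c: int) -> float:
    """ι edge weight; gate checks first, interaction information last."""
    i_ab = est.mi(a, b)
    if not i_ab > est.mi(a, c):
        return 0.0
    if not est.mi(y, b) > est.mi(y, c):
        return 0.0
    ii = i_ab - est.cmi(a, b, c)
    return ii if ii > 0.0 else 0.0


def iota(est: Estimator, a: int, b: int, c: int) -> float:
    """Public ι_Y((X_a,X_b),(X_b,X_c)) for columns of ``est``'s table.

    ``a`` may be the anchor index (the initialization case); ``b`` and ``c``
    must be distinct non-anchor features different from ``a``.
    """
    y = est.table.anchor_index
    if len({a, b, c}) != 3:
        raise ValueError(f"feature indices must be pairwise distinct: {(a, b, c)}")
    if y in (b, c):
        raise ValueError("the anchor may only appear in first position")
    return _iota(est, y, a, b, c)


def init_scores(table: DataTable, est: Estimator) -> PairState:
    """Score every ordered pair of distinct non-anchor features against the
    anchor: ``S[i,j] = ι_Y((Y,X_i),(X_i,X_j))``.

    These m(m-1) evaluations are mutually independent.  Pairs with positive
    score get predecessor ``ANCHOR``; the rest are ``UNREACHABLE``.
    """
    y = table.anchor_index
    feats = table.non_anchor_indices
    if len(feats) < 2:
        raise ValueError("need at least two non-anchor features")
    M = table.m
    S = np.zeros((M, M))
    P = np.full((M, M), UNREACHABLE, dtype=np.int64)
    state = PairState(S=S, P=P, anchor=y, feature_indices=feats)
    for i in feats:
        for j in feats:
            if i == j:
                continue
            s = _iota(est, y, y, i, j)
            state.n_iota += 1
            if s > 0.0:
                S[i, j] = s
                P[i, j] = ANCHOR
    return state


def run_search(
    state: PairState,
    table: DataTable,
    est: Estimator,
    opts: SearchOptions | None = None,
) -> PairState:
    """Maxi-min Dijkstra over the ordered-pair graph (in place).

    Repeatedly pops the unvisited queued pair of maximal score (ties broken
    by a seeded PRNG), finalizes it, and relaxes every successor pair
    ``(b, c)`` with ``c ∉ {a, b}`` and ``(b, c)`` not yet visited via
    ``S[b,c] ← max(S[b,c], min(ι, S[a,b]))``.  Stale queue entries are
    skipped (lazy re-insertion).  Stops when the queue empties, the best
    queued score drops below ``opts.min_score``, or all targets have a
    visited terminal pair.
    """
    opts = opts or SearchOptions()
    y = state.anchor
    feats = state.feature_indices
    rng = np.random.default_rng(opts.seed)
    heap: list[tuple[float, float, int, int]] = []
    for i in feats:
        for j in feats:
            if i != j and state.S[i, j] > 0.0:
                heapq.heappush(heap, (-state.S[i, j], rng.random(), i, j))
    remaining = set(opts.targets) if opts.targets is not None else None
    if remaining is not None and not remaining:
        return state
    while heap:
        neg_s, _, a, b = heapq.heappop(heap)
        s = -neg_s
        if (a, b) in state.visited or s < state.S[a, b]:
            continue  # stale entry
        if opts.min_score > 0.0 and s < opts.min_score:
            break  # every remaining queued score is ≤ s
        state.visited.add((a, b))
        state.visit_rank[(a, b)] = len(state.visit_log)
        state.visit_log.append((a, b, s))
        if remaining is not None:
            remaining.discard(b)
            if not remaining:
                break
        for c in feats:
            if c == a or c == b or (b, c) in state.visited:
                continue
            w = _iota(est, y, a, b, c)
            state.n_iota += 1
            s2 = min(w, s)
            if s2 > state.S[b, c]:
                state.S[b, c] = s2
                state.P[b, c] = a
                heapq.heappush(heap, (-s2, rng.random(), b, c))
    return state


def search(
    table: DataTable,
    est: Estimator,
    opts: SearchOptions | None = None,
) -> PairState:
    """Convenience: ``init_scores`` followed by ``run_search``."""
    return run_search(init_scores(table, est), table, est, opts)


def exhaustive_pair_scores(table: DataTable, est: Estimator) -> np.ndarray:
    """Reference maxi-min pair scores by exhaustive path enumeration.

    Enumerates every sequence of distinct non-anchor features reachable from
    the anchor through positively-weighted ι edges and records, per terminal
    ordered pair, the maximum over sequences of the minimum edge weight.
    Exponential in m — intended as an independent oracle for small tables
    (m ≲ 7), not for analysis.  Restricting to distinct-feature sequences is
    exact: admissible edges strictly decrease I(Y;·), so a feature cannot
    recur on a positive path.
    """
    y = table.anchor_index
    feats = table.non_anchor_indices
    best = np.zeros((table.m, table.m))

    def extend(a: int, b: int, bottleneck: float, used: frozenset) -> None:
        for c in feats:
            if c in used:
                continue
            w = _iota(est, y, a, b, c)
            s = min(bottleneck, w)
            if s > 0.0:
                if s > best[b, c]:
                    best[b, c] = s
                extend(b, c, s, used | {c})

    for i in feats:
        for j in feats:
            if i == j:
                continue
            s0 = _iota(est, y, y, i, j)
            if s0 > 0.0:
                if s0 > best[i, j]:
                    best[i, j] = s0
                extend(i, j, s0, frozenset((i, j)))
    return best
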