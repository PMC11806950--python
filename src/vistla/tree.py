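"""Path reconstruction and the anchor-rooted influence tree.

After the search, each non-anchor feature ``X_t`` is reached through the
ordered pair ``(·, X_t)`` of highest final score; following the predecessor
map back to the anchor yields its influence path.  Merging the paths of all
reached features on shared pair-prefixes gives a tree rooted at the anchor.

Tree nodes are identified by **ordered pairs**, not by features: a feature
may legitimately occur as several distinct nodes when it participates in
separate mechanisms (multi-modality), e.g. a junction variable relaying two
independent branches.  Features that terminate their own path are *leaves*;
features interior to any path are *relays*.  A feature can relay in many
paths but leaf in at most one (only its single best path is reconstructed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ANCHOR, PairState, SearchOptions
from .data import DataTable


@dataclass(frozen=True)
class InfluencePath:
    """One influence path ``(Y, X_1, …, X_t)`` with its maxi-min score.

    ``features`` holds table column indices, anchor first; ``score`` is the
    minimum ι along the path in nats (> 0 by construction); ``terminal`` is
    the last feature.
    """

    features: tuple[int, ...]
    score: float

    @property
    def terminal(self) -> int:
        return self.features[-1]

    @property
    def length(self) -> int:
        """Number of non-anchor features on the path."""
        return len(self.features) - 1

    def pairs(self) -> list[tuple[int, int]]:
        """Consecutive ordered pairs along the path, anchor pair first."""
        return list(zip(self.features[:-1], self.features[1:]))


@dataclass
class TreeNode:
    """A pair-level tree vertex: feature ``feature`` reached from
    ``prev_feature`` (the anchor for depth-1 nodes)."""

    prev_feature: int
    feature: int
    depth: int
    score: float
    is_leaf: bool = False


@dataclass
class InfluenceTree:
    """Merged influence paths rooted at the anchor.

    ``nodes`` maps the ordered pair ``(prev_feature, feature)`` to its
    :class:`TreeNode`; ``roles`` maps each feature index to ``"leaf"``,
    ``"relay"`` or ``"both"`` (features never on a path are simply absent).
    """

    anchor: int
    paths: list[InfluencePath] = field(default_factory=list)
    nodes: dict[tuple[int, int], TreeNode] = field(default_factory=dict)
    roles: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_paths(cls, anchor: int, paths: list[InfluencePath]) -> "InfluenceTree":
        tree = cls(anchor=anchor, paths=sorted(paths, key=lambda p: p.terminal))
        for path in tree.paths:
            seq = path.features
            for depth in range(1, len(seq)):
                key = (seq[depth - 1], seq[depth])
                node = tree.nodes.get(key)
                if node is None:
                    node = TreeNode(key[0], key[1], depth, 0.0)
                    tree.nodes[key] = node
                if depth == path.length:
                    node.is_leaf = True
        # node score: bottleneck of the widest retained path through the node
        for path in tree.paths:
            seq = path.features
            for depth in range(1, len(seq)):
                node = tree.nodes[(seq[depth - 1], seq[depth])]
                node.score = max(node.score, path.score)
        for path in tree.paths:
            for feat in path.features[1:-1]:
                prior = tree.roles.get(feat)
                tree.roles[feat] = "both" if prior == "leaf" else prior or "relay"
            prior = tree.roles.get(path.terminal)
            tree.roles[path.terminal] = (
                "both" if prior in ("relay", "both") else "leaf"
            )
        return tree

    @property
    def is_empty(self) -> bool:
        return not self.paths

    def leaf_paths(self) -> list[InfluencePath]:
        return list(self.paths)

    def max_score(self) -> float:
        return max((p.score for p in self.paths), default=0.0)


def reconstruct_path(state: PairState, terminal: int) -> InfluencePath | None:
    """Best influence path ending at ``terminal``, or ``None`` if unreached.

    Selects the ordered pair ``(·, terminal)`` of maximal final score (ties
    resolved by the search's visit order, so the pair that won the seeded
    tie-break during the search is kept) and follows predecessors back to
    the anchor.
    """
    if terminal == state.anchor:
        raise ValueError("the anchor is the path root, not a terminal")
    feats = state.feature_indices
    candidates = [a for a in feats if a != terminal and state.S[a, terminal] > 0.0]
    if not candidates:
        return None
    best = max(state.S[a, terminal] for a in candidates)
    tied = [a for a in candidates if state.S[a, terminal] == best]
    first = min(
        tied,
        key=lambda a: (state.visit_rank.get((a, terminal), len(state.visit_rank)), a),
    )
    seq = [terminal, first]
    pair = (first, terminal)
    while True:
        prev = int(state.P[pair])
        if prev == ANCHOR:
            break
        seq.append(prev)
        pair = (prev, pair[0])
        if len(seq) > len(feats) + 1:  # defensive; cannot happen on valid states
            raise RuntimeError("predecessor cycle detected")
    seq.append(state.anchor)
    seq.reverse()
    if len(set(seq)) != len(seq):
        raise RuntimeError("reconstructed path revisits a feature")
    return InfluencePath(tuple(seq), float(best))


def build_tree(
    state: PairState,
    table: DataTable,
    opts: SearchOptions | None = None,
) -> InfluenceTree:
    """Reconstruct paths for all reachable terminals (or ``opts.targets``)
    and merge them into an anchor-rooted tree."""
    terminals = (
        opts.targets if opts is not None and opts.targets is not None
        else state.feature_indices
    )
    paths = []
    for t in terminals:
        p = reconstruct_path(state, t)
        if p is not None:
            paths.append(p)
    return InfluenceTree.from_paths(state.anchor, paths)


def prune(tree: InfluenceTree, min_score: float) -> InfluenceTree:
    """Drop every leaf path scoring below ``min_score`` (inclusive keep:
    a path scoring exactly the threshold survives); relays survive only on
    surviving paths.  Idempotent and monotone in the threshold."""
    if min_score < 0:
        raise ValueError("min_score must be non-negative")
    kept = [p for p in tree.paths if p.score >= min_score]
    return InfluenceTree.from_paths(tree.anchor, kept)
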