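"""Model/Results front-end over the influence-path machinery.

:class:`Vistla` is constructed from data plus a designated anchor and
estimation choices; :meth:`Vistla.fit` runs the pair-graph search and
returns a :class:`VistlaResults` carrying the influence tree, per-terminal
scores, diagnostics and serializers, with the permutation null available as
a method of the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .core import SearchOptions, init_scores, run_search
from .data import DataTable
from .estimators import Estimator
from .nullmodel import NullDistribution, null_distribution
from .tree import InfluenceTree, build_tree, prune


class Vistla:
    """Influence-path model anchored at one feature of a table.

    Parameters
    ----------
    data : DataTable or pandas.DataFrame
        Observations; a DataFrame is converted with kind inference.
    anchor : str
        Name of the anchor feature ``Y`` (required for DataFrames; for a
        DataTable it defaults to the table's own anchor).
    estimator : {"mle", "kt"}
        Information-estimation route: plug-in MLE on (discretized)
        categorical codes, or the rank-based Kendall transformation.
    bins : int
        Equal-frequency bin count for discretizing ordinal features under
        the MLE route.
    auto_split : bool
        Under the KT route, split >2-category unordered features into
        per-category indicators instead of rejecting them.
    """

    def __init__(
        self,
        data: DataTable | pd.DataFrame,
        anchor: str | None = None,
        estimator: str = "mle",
        bins: int = 10,
        auto_split: bool = False,
        kinds: dict[str, str] | None = None,
    ):
        if isinstance(data, DataTable):
            table = data
            if anchor is not None and anchor != table.anchor:
                table = DataTable(table.features, anchor)
        else:
            if anchor is None:
                raise ValueError("anchor is required when passing a DataFrame")
            table = DataTable.from_dataframe(data, anchor, kinds)
        if estimator == "kt" and auto_split:
            table = table.split_categoricals()
        self.table = table
        self.estimator_method = estimator
        self.bins = bins
        self.est = Estimator(table, method=estimator, bins=bins)

    @classmethod
    def from_csv(cls, path, anchor: str, delimiter: str = ",", **kwargs) -> "Vistla":
        return cls(
            _io.read_table(path, anchor, kwargs.pop("kinds", None), delimiter),
            **kwargs,
        )

    def fit(
        self,
        min_score: float = 0.0,
        targets: list[str] | None = None,
        seed: int = 0,
    ) -> "VistlaResults":
        """Run the maxi-min search and reconstruct the influence tree."""
        idx = [self.table.index(t) for t in targets] if targets else None
        opts = SearchOptions(min_score=min_score, targets=idx, seed=seed)
        state = run_search(init_scores(self.table, self.est), self.table, self.est, opts)
        tree = prune(build_tree(state, self.table, opts), min_score)
        return VistlaResults(self, state, tree, opts)


class VistlaResults:
    """Fitted influence paths: tree, scores, roles and diagnostics."""

    def __init__(self, model: Vistla, state, tree: InfluenceTree, opts: SearchOptions):
        self.model = model
        self.state = state
        self.tree = tree
        self.opts = opts

    # ------------------------------------------------------------- accessors
    @property
    def table(self) -> DataTable:
        return self.model.table

    @property
    def paths(self):
        return self.tree.paths

    @property
    def n_iota_evaluations(self) -> int:
        return self.state.n_iota

    @property
    def scores(self) -> pd.Series:
        """Maxi-min path score per reached terminal feature, in nats."""
        names = self.table.names
        return pd.Series(
            {names[p.terminal]: p.score for p in self.tree.paths},
            name="score_nats",
            dtype=float,
        ).sort_index()

    @property
    def roles(self) -> pd.Series:
        names = self.table.names
        return pd.Series(
            {names[f]: r for f, r in self.tree.roles.items()}, name="role"
        ).sort_index()

    def path_to(self, terminal: str) -> list[str] | None:
        """Feature-name sequence of the path reaching ``terminal``."""
        idx = self.table.index(terminal)
        names = self.table.names
        for p in self.tree.paths:
            if p.terminal == idx:
                return [names[i] for i in p.features]
        return None

    # ----------------------------------------------------------- derivations
    def prune(self, min_score: float) -> "VistlaResults":
        """New results with leaf paths below ``min_score`` nats removed."""
        return VistlaResults(
            self.model, self.state, prune(self.tree, min_score), self.opts
        )

    def null_distribution(
        self, replicates: int = 500, seed: int = 0
    ) -> NullDistribution:
        """Permutation null of path scores for this model's table/estimator."""
        return null_distribution(
            self.table,
            method=self.model.estimator_method,
            bins=self.model.bins,
            replicates=replicates,
            seed=seed,
            opts=SearchOptions(min_score=self.opts.min_score, seed=self.opts.seed),
        )

    # ---------------------------------------------------------- serializers
    def to_tsv(self) -> str:
        return _io.tree_to_tsv(self.tree, self.table)

    def to_dot(self) -> str:
        return _io.tree_to_dot(self.tree, self.table)

    def to_json(self) -> str:
        return _io.tree_to_json(self.tree, self.table)

    def summary(self) -> str:
        """Plain-text summary of the fitted influence paths."""
        names = self.table.names
        head = [
            "Vistla influence paths",
            "======================",
            f"anchor:     {names[self.tree.anchor]}",
            f"estimator:  {self.model.estimator_method}"
            + (f" (bins={self.model.bins})" if self.model.estimator_method == "mle" else ""),
            f"n obs:      {self.table.n}",
            f"features:   {self.table.m - 1} (+ anchor)",
            f"iota evals: {self.n_iota_evaluations}",
            f"paths:      {len(self.tree.paths)}",
            "",
        ]
        if self.tree.is_empty:
            head.append("no influence paths found")
            return "\n".join(head) + "\n"
        head.append(f"{'terminal':<12}{'len':>4}  {'score_nats':>10}  path")
        for p in sorted(self.tree.paths, key=lambda q: -q.score):
            chain = " -> ".join(names[i] for i in p.features)
            head.append(
                f"{names[p.terminal]:<12}{p.length:>4}  {_io.fmt(p.score):>10}  {chain}"
            )
        return "\n".join(head) + "\n"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<VistlaResults: {len(self.tree.paths)} paths, "
            f"max score {self.tree.max_score():.4g} nats>"
        )
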