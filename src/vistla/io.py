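"""Delimited-table input, tree/null serialization, and the full pipeline.

Scores are serialized at a fixed precision of 6 significant digits so
repeated runs diff cleanly; no timestamps enter any artifact, making runs
with identical configuration and seed byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import SearchOptions, init_scores, run_search
from .data import DataTable
from .estimators import Estimator
from .nullmodel import NullDistribution, null_distribution
from .tree import InfluenceTree, build_tree, prune

#: fixed serialization precision (significant digits)
PRECISION = 6


def fmt(x: float) -> str:
    return f"{x:.{PRECISION}g}"


def read_table(
    path,
    anchor: str,
    kinds: dict[str, str] | None = None,
    delimiter: str = ",",
) -> DataTable:
    """Read a delimited text table with a header row into a DataTable.

    Column kinds follow declared hints where given, otherwise inference:
    ≤2 distinct values → binary, numeric → ordinal, else categorical.
    Missing values are rejected with a message naming the offending columns.
    """
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty table")
    if anchor not in df.columns:
        raise ValueError(f"{path}: anchor {anchor!r} not among columns {list(df.columns)}")
    return DataTable.from_dataframe(df, anchor, kinds)


def write_table(table: DataTable, path, delimiter: str = ",") -> None:
    table.to_dataframe().to_csv(path, sep=delimiter, index=False)


# --------------------------------------------------------------------------
# tree serialization
# --------------------------------------------------------------------------

def _sorted_nodes(tree: InfluenceTree, table: DataTable):
    return sorted(
        tree.nodes.values(),
        key=lambda nd: (nd.depth, table.names[nd.feature], table.names[nd.prev_feature]),
    )


def tree_to_tsv(tree: InfluenceTree, table: DataTable) -> str:
    """TSV with one row per pair-node: depth, prev_feature, feature,
    score_nats, role (leaf for terminal nodes, relay otherwise)."""
    lines = ["depth\tprev_feature\tfeature\tscore_nats\trole"]
    for nd in _sorted_nodes(tree, table):
        role = "leaf" if nd.is_leaf else "relay"
        lines.append(
            f"{nd.depth}\t{table.names[nd.prev_feature]}\t"
            f"{table.names[nd.feature]}\t{fmt(nd.score)}\t{role}"
        )
    return "\n".join(lines) + "\n"


def tree_to_dot(tree: InfluenceTree, table: DataTable) -> str:
    """Graphviz DOT rendering: egg-shaped anchor, box-shaped leaves,
    ellipse-shaped relays.  Node identifiers are pair-based so a feature
    occurring on several branches stays expanded."""
    names = table.names
    out = ["digraph vistla {", "  rankdir=LR;"]
    anchor_id = "anchor"
    out.append(f'  {anchor_id} [label="{names[tree.anchor]}", shape=egg];')
    ids = {}
    for nd in _sorted_nodes(tree, table):
        nid = f"n_{names[nd.prev_feature]}_{names[nd.feature]}".replace("=", "_eq_")
        nid = nid.replace(" ", "_")
        ids[(nd.prev_feature, nd.feature)] = nid
        shape = "box" if nd.is_leaf else "ellipse"
        out.append(
            f'  "{nid}" [label="{names[nd.feature]}\\n{fmt(nd.score)}", shape={shape}];'
        )
    for path in tree.paths:
        seq = path.features
        prev_id = anchor_id
        for depth in range(1, len(seq)):
            nid = ids[(seq[depth - 1], seq[depth])]
            edge = f'  {json.dumps(prev_id)} -> "{nid}";' if prev_id == anchor_id \
                else f'  "{prev_id}" -> "{nid}";'
            if edge not in out:
                out.append(edge)
            prev_id = nid
    out.append("}")
    return "\n".join(out) + "\n"


def tree_to_json(tree: InfluenceTree, table: DataTable) -> str:
    """JSON document with the anchor, all paths (feature-name sequences plus
    scores) and all pair-nodes.  Schema::

        {"anchor": str,
         "paths": [{"features": [str, ...], "score_nats": float,
                    "terminal": str}, ...],
         "nodes": [{"depth": int, "prev_feature": str, "feature": str,
                    "score_nats": float, "role": "leaf"|"relay"}, ...],
         "roles": {feature: "leaf"|"relay"|"both"}}
    """
    names = table.names
    doc = {
        "anchor": names[tree.anchor],
        "paths": [
            {
                "features": [names[i] for i in p.features],
                "score_nats": float(fmt(p.score)),
                "terminal": names[p.terminal],
            }
            for p in tree.paths
        ],
        "nodes": [
            {
                "depth": nd.depth,
                "prev_feature": names[nd.prev_feature],
                "feature": names[nd.feature],
                "score_nats": float(fmt(nd.score)),
                "role": "leaf" if nd.is_leaf else "relay",
            }
            for nd in _sorted_nodes(tree, table)
        ],
        "roles": {names[f]: r for f, r in sorted(tree.roles.items())},
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


_WRITERS = {"tsv": tree_to_tsv, "dot": tree_to_dot, "json": tree_to_json}


def write_tree(tree: InfluenceTree, table: DataTable, path, format: str = "tsv") -> None:
    """Serialize a tree as ``dot``, ``json`` or ``tsv``."""
    writer = _WRITERS.get(format)
    if writer is None:
        raise ValueError(f"unknown tree format {format!r}; use one of {sorted(_WRITERS)}")
    Path(path).write_text(writer(tree, table))


def null_summary_tsv(null: NullDistribution) -> str:
    """Per-length TSV summary of the permutation null: sample counts and the
    50/95/99/100th percentiles, plus a pooled row."""
    lines = ["length\tn_paths\tp50\tp95\tp99\tmax"]
    rows = [(str(l), l) for l in null.lengths()] + [("pooled", None)]
    for label, length in rows:
        xs = null.scores(length)
        if xs.size == 0:
            continue
        lines.append(
            f"{label}\t{xs.size}\t"
            + "\t".join(fmt(null.percentile(q, length)) for q in (50, 95, 99, 100))
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one end-to-end run needs; see the CLI for the flag names."""

    input: str | Path
    anchor: str
    estimator: str = "mle"
    bins: int = 10
    min_score: float = 0.0
    targets: list[str] | None = None
    permutations: int = 0
    seed: int = 0
    out_prefix: str | Path = "vistla"
    formats: tuple[str, ...] = ("tsv", "dot", "json")
    delimiter: str = ","
    auto_split: bool = False
    kinds: dict[str, str] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Read → encode → search → tree → prune → optional null; write artifacts.

    Returns the mapping of artifact kind to written path.  The run log
    records the configuration, the number of ι evaluations and result
    counts, but no timestamps.
    """
    table = read_table(cfg.input, cfg.anchor, cfg.kinds or None, cfg.delimiter)
    if cfg.estimator == "kt" and cfg.auto_split:
        table = table.split_categoricals()
    est = Estimator(table, method=cfg.estimator, bins=cfg.bins)
    targets = [table.index(t) for t in cfg.targets] if cfg.targets else None
    opts = SearchOptions(min_score=cfg.min_score, targets=targets, seed=cfg.seed)
    state = run_search(init_scores(table, est), table, est, opts)
    tree = prune(build_tree(state, table, opts), cfg.min_score)

    prefix = Path(cfg.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    for f in cfg.formats:
        out = prefix.with_name(prefix.name + f".tree.{f}")
        write_tree(tree, table, out, format=f)
        artifacts[f"tree.{f}"] = out

    null = None
    if cfg.permutations > 0:
        null = null_distribution(
            table,
            method=cfg.estimator,
            bins=cfg.bins,
            replicates=cfg.permutations,
            seed=cfg.seed,
            opts=SearchOptions(min_score=cfg.min_score, seed=cfg.seed),
        )
        out = prefix.with_name(prefix.name + ".null.tsv")
        out.write_text(null_summary_tsv(null))
        artifacts["null.tsv"] = out

    log = {
        "anchor": cfg.anchor,
        "estimator": cfg.estimator,
        "bins": cfg.bins,
        "min_score": cfg.min_score,
        "targets": cfg.targets,
        "permutations": cfg.permutations,
        "seed": cfg.seed,
        "n_observations": table.n,
        "n_features": table.m,
        "n_iota_evaluations": state.n_iota,
        "n_pairs_visited": len(state.visited),
        "n_paths": len(tree.paths),
        "max_path_score_nats": float(fmt(tree.max_score())),
    }
    out = prefix.with_name(prefix.name + ".log.json")
    out.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["log.json"] = out
    return artifacts
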