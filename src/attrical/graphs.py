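"""Measurement on the who-follows-whom network.

A directed edge (A, B) means "A follows B". This module provides the
in-coreness centrality, followee-set extraction (all or single-way),
followee-averaged instrument construction, and Newman's assortativity
coefficient with a label-permutation null model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Hashable, Iterable, Mapping, Optional, Sequence, Set, Tuple

import igraph as ig
import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidConfigError

__all__ = [
    "FollowGraph",
    "InstrumentSet",
    "in_coreness",
    "followee_sets",
    "build_instruments",
    "newman_assortativity",
    "assortativity_null_z",
]

log = logging.getLogger(__name__)


class FollowGraph:
    """Simple directed follow graph: duplicate-free edges, no self-loops.

    Nodes may be any hashable ids; the node set is closed over the edges
    (an edge endpoint not listed in ``nodes`` raises).
    """

    def __init__(self, nodes: Iterable[Hashable], edges: Iterable[Tuple[Hashable, Hashable]]):
        self.nodes = list(dict.fromkeys(nodes))
        self._index = {u: i for i, u in enumerate(self.nodes)}
        seen: Set[Tuple[int, int]] = set()
        src, dst = [], []
        for a, b in edges:
            if a == b:
                raise InvalidConfigError(f"self-loop on node {a!r}")
            try:
                ia, ib = self._index[a], self._index[b]
            except KeyError as exc:
                raise InvalidConfigError(f"edge endpoint {exc.args[0]!r} not in node set")
            if (ia, ib) in seen:
                raise InvalidConfigError(f"duplicate edge ({a!r}, {b!r})")
            seen.add((ia, ib))
            src.append(ia)
            dst.append(ib)
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def edge_list(self) -> list[Tuple[Hashable, Hashable]]:
        return [(self.nodes[a], self.nodes[b]) for a, b in zip(self.src, self.dst)]

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, directed=True)
        g.add_edges(list(zip(self.src.tolist(), self.dst.tolist())))
        return g

    def out_degree(self) -> pd.Series:
        deg = np.bincount(self.src, minlength=self.n_nodes)
        return pd.Series(deg, index=pd.Index(self.nodes, name="user_id"), name="out_degree")

    def in_degree(self) -> pd.Series:
        deg = np.bincount(self.dst, minlength=self.n_nodes)
        return pd.Series(deg, index=pd.Index(self.nodes, name="user_id"), name="in_degree")

    # --- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write edges as two-column TSV (follower_id, followee_id)."""
        pd.DataFrame(
            {"follower_id": [self.nodes[i] for i in self.src],
             "followee_id": [self.nodes[i] for i in self.dst]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, nodes: Optional[Iterable[Hashable]] = None) -> "FollowGraph":
        df = pd.read_csv(path, sep="\t")
        edges = list(zip(df["follower_id"], df["followee_id"]))
        if nodes is None:
            nodes = sorted({u for e in edges for u in e})
        return cls(nodes, edges)


@dataclass
class InstrumentSet:
    """Followee-averaged attributes used as instruments.

    ``table`` is indexed by user_id with one column per aggregated
    attribute plus ``n_followees_used``; users with an empty followee set
    have NaN values and are flagged for exclusion from estimation.
    """

    table: pd.DataFrame
    mode: str  # "all" or "single_way"
    n_attribute_missing: int = 0

    @property
    def usable(self) -> pd.Index:
        return self.table.index[self.table["n_followees_used"] > 0]


def in_coreness(graph: FollowGraph) -> pd.Series:
    """In-coreness of every node.

    Node v's value is the largest k such that v belongs to a maximal
    subgraph in which every node has in-degree >= k within the subgraph
    (iterative peeling on in-degree). Empty graph -> empty result.
    """
    if graph.n_nodes == 0:
        return pd.Series(dtype=int, name="centrality")
    core = graph.to_igraph().coreness(mode="in")
    return pd.Series(
        np.asarray(core, dtype=int),
        index=pd.Index(graph.nodes, name="user_id"),
        name="centrality",
    )


def followee_sets(graph: FollowGraph, single_way: bool = False) -> Dict[Hashable, Set[Hashable]]:
    """Per-user followee sets.

    With ``single_way`` the set keeps only followees that do not follow the
    user back (reciprocated ties removed).
    """
    out: Dict[Hashable, Set[Hashable]] = {u: set() for u in graph.nodes}
    if single_way:
        pairs = set(zip(graph.src.tolist(), graph.dst.tolist()))
        for a, b in pairs:
            if (b, a) not in pairs:
                out[graph.nodes[a]].add(graph.nodes[b])
    else:
        for a, b in zip(graph.src, graph.dst):
            out[graph.nodes[a]].add(graph.nodes[b])
    return out


def build_instruments(
    graph: FollowGraph,
    attributes: pd.DataFrame | Mapping[Hashable, float],
    single_way: bool = False,
) -> InstrumentSet:
    """Unweighted followee means of per-user attributes.

    ``attributes`` is a DataFrame indexed by user_id (one column per
    attribute) or a mapping user_id -> value (a single attribute named
    "attribute"). Followees with a missing (NaN or absent) attribute are
    omitted from the mean and counted in a logged exclusion tally. Users
    whose (possibly single-way) followee set is empty get NaN means and
    ``n_followees_used`` = 0.
    """
    if not isinstance(attributes, pd.DataFrame):
        attributes = pd.DataFrame({"attribute": pd.Series(dict(attributes))})
    sets = followee_sets(graph, single_way=single_way)
    cols = list(attributes.columns)
    rows = {}
    n_missing = 0
    for user, fset in sets.items():
        if not fset:
            rows[user] = [np.nan] * len(cols) + [0]
            continue
        sub = attributes.reindex(list(fset))
        ok = sub.notna().all(axis=1)
        n_missing += int((~ok).sum())
        used = sub.loc[ok]
        if used.empty:
            rows[user] = [np.nan] * len(cols) + [0]
        else:
            rows[user] = list(used.mean(axis=0).values) + [len(used)]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"followee_mean_{c}" for c in cols] + ["n_followees_used"]
    )
    table.index.name = "user_id"
    table["n_followees_used"] = table["n_followees_used"].astype(int)
    if n_missing:
        log.info("build_instruments: %d followee attribute values missing, omitted", n_missing)
    return InstrumentSet(
        table=table.loc[graph.nodes],
        mode="single_way" if single_way else "all",
        n_attribute_missing=n_missing,
    )


def _mixing_r(src_labels: np.ndarray, dst_labels: np.ndarray, n_labels: int) -> float:
    """Newman's r from integer edge-endpoint labels (directed, each edge once)."""
    m = len(src_labels)
    within = float(np.mean(src_labels == dst_labels))
    a = np.bincount(src_labels, minlength=n_labels) / m
    b = np.bincount(dst_labels, minlength=n_labels) / m
    ab = float(a @ b)
    denom = 1.0 - ab
    if denom == 0.0:
        raise DegenerateInputError("assortativity undefined: a single label carries all edges")
    return (within - ab) / denom


def newman_assortativity(graph: FollowGraph, labels: Mapping[Hashable, Hashable]) -> float:
    """Newman's assortativity coefficient r for a categorical node attribute.

    Computed on the directed mixing matrix e (each directed edge counted
    once): r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) with
    a, b the row and column sums. r = 1 iff every edge joins same-label
    nodes. Raises DegenerateInputError when only one label is present on
    edge endpoints (denominator zero).
    """
    if graph.n_edges == 0:
        raise DegenerateInputError("assortativity requires at least one edge")
    cats = sorted({labels[u] for u in graph.nodes}, key=repr)
    cat_index = {c: i for i, c in enumerate(cats)}
    node_lab = np.array([cat_index[labels[u]] for u in graph.nodes], dtype=np.int64)
    return _mixing_r(node_lab[graph.src], node_lab[graph.dst], len(cats))


def assortativity_null_z(
    graph: FollowGraph,
    labels: Mapping[Hashable, Hashable],
    n_perm: int = 1000,
    seed: int | None = None,
) -> Tuple[float, float]:
    """Permutation z-score and two-sided p-value for assortativity.

    The null holds the graph fixed and permutes node labels (preserving
    label counts); z = (r_obs - mean_null) / sd_null, with the 0/0 -> 0
    convention when the null distribution is degenerate. The p-value uses
    add-one smoothing: (1 + #{|r_null - mean| >= |r_obs - mean|}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation z", stacklevel=2)
    cats = sorted({labels[u] for u in graph.nodes}, key=repr)
    cat_index = {c: i for i, c in enumerate(cats)}
    node_lab = np.array([cat_index[labels[u]] for u in graph.nodes], dtype=np.int64)
    n_labels = len(cats)
    r_obs = _mixing_r(node_lab[graph.src], node_lab[graph.dst], n_labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = node_lab[rng.permutation(graph.n_nodes)]
        null[i] = _mixing_r(perm[graph.src], perm[graph.dst], n_labels)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0.0:
        z = 0.0  # degenerate null: r_obs equal to every draw
    else:
        z = (r_obs - mean) / sd
    p = (1.0 + int(np.sum(np.abs(null - mean) >= abs(r_obs - mean)))) / (n_perm + 1.0)
    return float(z), float(p)
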