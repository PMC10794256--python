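"""Similarity clustering of BDAs and candidate status assignment.

BGCs are greedily grouped into clusters in which at least one member has
BDA similarity >= 0.8 (by default) to another member — equivalently, the
connected components of the graph whose edges are similarities at or
above the threshold (single linkage).  Candidates are then classified:

hit       — direct similarity >= threshold to at least one reference;
clustered — no such reference edge, but >= threshold to another candidate;
orphan    — similar to nothing.

The threshold is inclusive: similarity exactly 0.8 qualifies.  A
candidate that reaches a reference only transitively (through other
candidates, with no direct edge) is "clustered" and additionally flagged
``in_reference_cluster``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .bgc_io import BDA

__all__ = [
    "ClusterConfig",
    "ClusterAssignment",
    "cluster_greedy",
    "assign_status",
    "collapse_identical",
]


@dataclass(frozen=True)
class ClusterConfig:
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class ClusterAssignment:
    """Cluster memberships plus per-candidate status."""

    clusters: list[frozenset[str]]
    status: dict[str, str]  # candidate_id -> hit | clustered | orphan
    hit_pairs: list[tuple[str, str, float]]  # (candidate, reference, similarity)
    best_reference: dict[str, tuple[str, float]] = field(default_factory=dict)
    in_reference_cluster: set[str] = field(default_factory=set)


def _threshold_graph(
    table: pd.DataFrame, threshold: float, ids: Iterable[str]
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(ids)
    hits = table[(table["similarity"] >= threshold) & (table["id_a"] != table["id_b"])]
    g.add_edges_from(zip(hits["id_a"], hits["id_b"]))
    return g


def cluster_greedy(
    table: pd.DataFrame,
    config: ClusterConfig = ClusterConfig(),
    ids: Sequence[str] = (),
) -> list[frozenset[str]]:
    """Greedy single-linkage clusters at the similarity threshold.

    Equals the connected components of the >=-threshold similarity
    graph; order-independent (components are returned sorted by their
    smallest member).  ``ids`` extends the node universe so isolated
    BGCs appear as singletons even without table rows.
    """
    universe = set(table["id_a"]) | set(table["id_b"]) | set(ids)
    g = _threshold_graph(table, config.threshold, universe)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: min(c))


def assign_status(
    table: pd.DataFrame,
    clusters: Sequence[frozenset[str]],
    reference_ids: Iterable[str],
    config: ClusterConfig = ClusterConfig(),
) -> ClusterAssignment:
    """Classify candidates as hit / clustered / orphan.

    Hit requires a direct >=-threshold similarity edge to a reference
    (boundary inclusive); clustered requires a direct edge to another
    candidate; everything else is orphan.
    """
    refs = set(reference_ids)
    universe = set(table["id_a"]) | set(table["id_b"])
    for c in clusters:
        universe |= c
    candidates = sorted(universe - refs)
    edges = table[table["similarity"] >= config.threshold]

    ref_partner: dict[str, list[tuple[str, float]]] = {c: [] for c in candidates}
    cand_partner: dict[str, bool] = {c: False for c in candidates}
    best_ref: dict[str, tuple[str, float]] = {}
    for row in table.itertuples(index=False):
        pairs = ((row.id_a, row.id_b), (row.id_b, row.id_a))
        for cand, other in pairs:
            if cand in refs or cand not in ref_partner:
                continue
            if other in refs:
                cur = best_ref.get(cand)
                if cur is None or row.similarity > cur[1] or (
                    row.similarity == cur[1] and other < cur[0]
                ):
                    best_ref[cand] = (other, float(row.similarity))
    for row in edges.itertuples(index=False):
        for cand, other in ((row.id_a, row.id_b), (row.id_b, row.id_a)):
            if cand in refs:
                continue
            if other in refs:
                ref_partner[cand].append((other, float(row.similarity)))
            else:
                cand_partner[cand] = True

    member_cluster = {m: c for c in clusters for m in c}
    status: dict[str, str] = {}
    hit_pairs: list[tuple[str, str, float]] = []
    in_ref_cluster: set[str] = set()
    for cand in candidates:
        if ref_partner[cand]:
            status[cand] = "hit"
            hit_pairs.extend((cand, r, s) for r, s in sorted(ref_partner[cand]))
        elif cand_partner[cand]:
            status[cand] = "clustered"
            cluster = member_cluster.get(cand, frozenset())
            if cluster & refs:
                in_ref_cluster.add(cand)
        else:
            status[cand] = "orphan"
    return ClusterAssignment(
        clusters=list(clusters),
        status=status,
        hit_pairs=hit_pairs,
        best_reference=best_ref,
        in_reference_cluster=in_ref_cluster,
    )


def collapse_identical(bdas: Sequence[BDA]) -> tuple[dict[tuple[str, ...], list[str]], int]:
    """Group BGC ids sharing token-identical BDAs.

    Returns (groups keyed by token sequence, number of ids belonging to
    groups of size >= 2); grouping is input-order independent.
    """
    groups: dict[tuple[str, ...], list[str]] = {}
    for b in bdas:
        groups.setdefault(b.tokens, []).append(b.bgc_id)
    for ids in groups.values():
        ids.sort()
    shared = sum(len(ids) for ids in groups.values() if len(ids) >= 2)
    return groups, shared
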