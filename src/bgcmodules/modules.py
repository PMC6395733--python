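"""Module detection: significance networks, maximal cliques, threshold ladder.

At a significance threshold t, orthogroups form the nodes of an undirected
graph with an edge wherever a pair's best (adjacency or colocalization)
FDR-adjusted p-value is <= t.  Every maximal clique of at least three nodes
is a putative module.  All distinct adjusted p-values up to a cap (default
0.1) are tried as thresholds; a clique emitted at several thresholds is one
module whose *strictest threshold* is the smallest of them.  Modules whose
members never co-occur in at least two clusters are discarded as spurious.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import networkx as nx
import pandas as pd

from .data import UNASSIGNED, Dataset, ValidationError
from .significance import InteractionResult


@dataclass
class Module:
    """A set of >= 3 orthogroups forming a maximal clique of significant
    pairwise interactions."""

    module_id: str
    smcogs: frozenset[str]
    strictest_threshold: float
    supporting_clusters: frozenset[str]
    metrics: object | None = field(default=None, compare=False)
    mib_score: float | None = field(default=None, compare=False)


def pair_pvalues(results: Sequence[InteractionResult]) -> dict[tuple[str, str], float]:
    """Best adjusted p per unordered pair (min over interaction kinds)."""
    best: dict[tuple[str, str], float] = {}
    for r in results:
        if r.p_adjusted is None:
            raise ValidationError("results lack adjusted p-values")
        key = tuple(sorted((r.cog_a, r.cog_b)))
        best[key] = min(best.get(key, 1.0), r.p_adjusted)
    return best


def build_network(results: Sequence[InteractionResult], threshold: float) -> nx.Graph:
    """Graph with an edge wherever either kind's adjusted p <= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside (0, 1]")
    graph = nx.Graph(threshold=threshold)
    for (a, b), p in sorted(pair_pvalues(results).items()):
        graph.add_node(a)
        graph.add_node(b)
        if p <= threshold:
            graph.add_edge(a, b, p_adjusted=p)
    return graph


def maximal_cliques(graph: nx.Graph, min_size: int = 3) -> list[frozenset[str]]:
    """All maximal cliques with at least ``min_size`` nodes, sorted."""
    cliques = [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= min_size]
    return sorted(cliques, key=lambda c: (len(c), tuple(sorted(c))))


def threshold_ladder(
    results: Sequence[InteractionResult],
    cap: float = 0.1,
    max_steps: int | None = None,
) -> list[float]:
    """Distinct adjusted p-values <= cap, ascending.

    With ``max_steps`` set, an evenly rank-spaced subsample that always keeps
    the smallest and largest value.
    """
    values = sorted({p for p in pair_pvalues(results).values() if p <= cap})
    if max_steps is not None and 0 < max_steps < len(values):
        if max_steps == 1:
            return [values[-1]]
        idx = [round(i * (len(values) - 1) / (max_steps - 1)) for i in range(max_steps)]
        return [values[i] for i in sorted(set(idx))]
    return values


def supporting_clusters(dataset: Dataset, smcogs: frozenset[str]) -> frozenset[str]:
    """Clusters containing every member orthogroup (at any positions)."""
    support = None
    membership: dict[str, set[str]] = {}
    for cluster in dataset.clusters:
        for cog in {g.smcog_id for g in cluster.genes if g.smcog_id != UNASSIGNED}:
            membership.setdefault(cog, set()).add(cluster.cluster_id)
    for cog in smcogs:
        clusters = membership.get(cog, set())
        support = clusters if support is None else support & clusters
    return frozenset(support or set())


def detect_modules(
    results: Sequence[InteractionResult],
    dataset: Dataset,
    cap: float = 0.1,
    min_size: int = 3,
    min_support: int = 2,
    max_steps: int | None = None,
) -> list[Module]:
    """Collect maximal cliques over the full threshold ladder.

    A clique (identified by its orthogroup set) seen at several thresholds is
    one module with the smallest emitting threshold; modules supported by
    fewer than ``min_support`` clusters are removed.
    """
    membership: dict[str, set[str]] = {}
    for cluster in dataset.clusters:
        for cog in {g.smcog_id for g in cluster.genes if g.smcog_id != UNASSIGNED}:
            membership.setdefault(cog, set()).add(cluster.cluster_id)

    strictest: dict[frozenset[str], float] = {}
    for threshold in threshold_ladder(results, cap, max_steps):
        graph = build_network(results, threshold)
        for clique in maximal_cliques(graph, min_size):
            if clique not in strictest:  # ladder ascends, first hit is strictest
                strictest[clique] = threshold

    modules = []
    for smcogs in sorted(strictest, key=lambda c: tuple(sorted(c))):
        support = frozenset(
            set.intersection(*(membership.get(cog, set()) for cog in smcogs))
            if smcogs
            else set()
        )
        if len(support) < min_support:
            continue
        modules.append(
            Module(
                module_id="+".join(sorted(smcogs)),
                smcogs=smcogs,
                strictest_threshold=strictest[smcogs],
                supporting_clusters=support,
            )
        )
    return modules


def edge_list(results: Sequence[InteractionResult], threshold: float) -> pd.DataFrame:
    """Edge table (cog_a, cog_b, p_adjusted) for one threshold."""
    graph = build_network(results, threshold)
    rows = [
        {"cog_a": a, "cog_b": b, "p_adjusted": d["p_adjusted"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["cog_a", "cog_b", "p_adjusted"])


def candidate_module_count(
    n_smcogs: int, min_size: int = 3, max_size: int = 10
) -> int:
    """Exact count of possible modules of bounded size: sum of C(n, k)."""
    return sum(comb(n_smcogs, k) for k in range(min_size, max_size + 1))
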