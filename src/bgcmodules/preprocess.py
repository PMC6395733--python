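"""Data conditioning: cluster trimming, orthogroup filtering, redundancy
removal and orthogroup category annotation.

These stages turn a raw cluster collection into the non-redundant, annotated
dataset the interaction statistics operate on:

1. *Trimming* removes low-confidence genes from the extremes of each cluster
   (cluster predictors pad boundaries greedily; genes whose probability of
   carrying a biosynthesis-relevant domain is below a threshold are peeled
   off from each end inward).
2. *smCOG filtering* discards orthogroups with fewer than three member genes;
   their genes stay in place as UNASSIGNED placeholders so that gene
   positions are preserved.
3. *Deduplication* keeps, within every group of clusters sharing the same
   smCOG composition (as a multiset), only the shortest cluster.
4. *Category annotation* assigns each orthogroup a functional category from
   the categories of its member genes via majority-share rules.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

from .data import (
    GENE_CATEGORIES,
    UNASSIGNED,
    Cluster,
    Dataset,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Fixed priority used to break exact ties between equally common categories.
_CATEGORY_PRIORITY = ("core", "tailoring", "transport", "regulator", "other")


@dataclass
class PreprocessReport:
    """Bookkeeping for the conditioning stages."""

    genes_trimmed: int = 0
    smcogs_removed: int = 0
    genes_unassigned_after_filter: int = 0
    clusters_dropped_empty: int = 0
    clusters_dropped_redundant: int = 0

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            genes_trimmed=self.genes_trimmed + other.genes_trimmed,
            smcogs_removed=self.smcogs_removed + other.smcogs_removed,
            genes_unassigned_after_filter=self.genes_unassigned_after_filter
            + other.genes_unassigned_after_filter,
            clusters_dropped_empty=self.clusters_dropped_empty
            + other.clusters_dropped_empty,
            clusters_dropped_redundant=self.clusters_dropped_redundant
            + other.clusters_dropped_redundant,
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def trim_cluster(cluster: Cluster, threshold: float = 0.1) -> Cluster | None:
    """Peel genes off both cluster ends while their domain probability is
    below ``threshold``.

    Scanning proceeds strictly end-inward and stops at the first gene meeting
    the threshold, so interior low-probability genes survive.  Returns None
    when every gene is trimmed.  Clusters where any gene lacks a probability
    are returned unchanged (trimming needs complete annotation).
    """
    if any(g.domain_prob is None for g in cluster.genes):
        log.debug("cluster %s: domain_prob missing, trimming skipped", cluster.cluster_id)
        return cluster
    lo, hi = 0, len(cluster.genes)
    while lo < hi and cluster.genes[lo].domain_prob < threshold:
        lo += 1
    while hi > lo and cluster.genes[hi - 1].domain_prob < threshold:
        hi -= 1
    if lo == hi:
        return None
    if lo == 0 and hi == len(cluster.genes):
        return cluster
    return cluster.with_genes(cluster.genes[lo:hi])


def trim_dataset(
    dataset: Dataset, threshold: float = 0.1
) -> tuple[Dataset, PreprocessReport]:
    report = PreprocessReport()
    kept = []
    for cluster in dataset.clusters:
        trimmed = trim_cluster(cluster, threshold)
        if trimmed is None:
            report.clusters_dropped_empty += 1
            report.genes_trimmed += len(cluster)
            continue
        report.genes_trimmed += len(cluster) - len(trimmed)
        kept.append(trimmed)
    return Dataset.from_clusters(kept, dataset.provenance), report


def filter_smcogs(
    dataset: Dataset, min_members: int = 3
) -> tuple[Dataset, PreprocessReport]:
    """Drop orthogroups with fewer than ``min_members`` genes.

    Genes of dropped orthogroups are relabelled UNASSIGNED but keep their
    positions; clusters left with no assigned gene at all are dropped.
    """
    report = PreprocessReport()
    sizes = Counter()
    for gene in dataset.genes():
        if gene.smcog_id != UNASSIGNED:
            sizes[gene.smcog_id] += 1
    removed = {cog for cog, n in sizes.items() if n < min_members}
    report.smcogs_removed = len(removed)

    kept_clusters = []
    for cluster in dataset.clusters:
        genes = []
        n_assigned = 0
        for gene in cluster.genes:
            if gene.smcog_id in removed:
                genes.append(replace(gene, smcog_id=UNASSIGNED))
                report.genes_unassigned_after_filter += 1
            else:
                if gene.smcog_id != UNASSIGNED:
                    n_assigned += 1
                genes.append(gene)
        if n_assigned == 0:
            report.clusters_dropped_empty += 1
            continue
        kept_clusters.append(cluster.with_genes(genes))
    return Dataset.from_clusters(kept_clusters, dataset.provenance), report


def composition_key(cluster: Cluster) -> tuple[tuple[str, int], ...]:
    """Order-independent multiset of a cluster's smCOG labels (copy numbers
    matter; UNASSIGNED excluded)."""
    counts = Counter(g.smcog_id for g in cluster.genes if g.smcog_id != UNASSIGNED)
    return tuple(sorted(counts.items()))


def dedupe_clusters(dataset: Dataset) -> tuple[Dataset, PreprocessReport]:
    """Within each group of clusters with identical smCOG composition, keep
    only the one with fewest genes (ties: lexicographically smallest id)."""
    report = PreprocessReport()
    best: dict[tuple, Cluster] = {}
    for cluster in dataset.clusters:
        key = composition_key(cluster)
        incumbent = best.get(key)
        if incumbent is None or (len(cluster), cluster.cluster_id) < (
            len(incumbent),
            incumbent.cluster_id,
        ):
            best[key] = cluster
    kept_ids = {c.cluster_id for c in best.values()}
    kept = [c for c in dataset.clusters if c.cluster_id in kept_ids]
    report.clusters_dropped_redundant = len(dataset.clusters) - len(kept)
    return Dataset.from_clusters(kept, dataset.provenance), report


def annotate_smcog_category(member_categories: Sequence[str]) -> str:
    """Derive an orthogroup category from its member genes' categories.

    Rules, applied in order on the category frequency shares:

    1. if the most common category is "other" but the second most common
       holds > 40% of genes, use the second;
    2. else if the most common category holds > 60%, use it;
    3. else if top + second together hold > 75%, use the double category
       "top/second";
    4. otherwise "mixed".

    Exact ties in frequency are broken by the fixed priority
    core > tailoring > transport > regulator > other.
    """
    if not member_categories:
        raise ValidationError("empty category list")
    for cat in member_categories:
        if cat not in GENE_CATEGORIES:
            raise ValidationError(f"unknown gene category {cat!r}")
    counts = Counter(member_categories)
    total = sum(counts.values())
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], _CATEGORY_PRIORITY.index(kv[0]))
    )
    top, top_n = ranked[0]
    second, second_n = ranked[1] if len(ranked) > 1 else (None, 0)
    top_share = top_n / total
    second_share = second_n / total
    if top == "other" and second is not None and second_share > 0.40:
        return second
    if top_share > 0.60:
        return top
    if top_share < 0.60 and second is not None and top_share + second_share > 0.75:
        return f"{top}/{second}"
    return "mixed"


def annotate_dataset(dataset: Dataset) -> Dataset:
    """Fill in every SmCOG record's category from its member genes (in place)."""
    members: dict[str, list[str]] = {cog: [] for cog in dataset.smcogs}
    for gene in dataset.genes():
        if gene.smcog_id != UNASSIGNED:
            members[gene.smcog_id].append(gene.category)
    for cog_id, cats in members.items():
        dataset.smcogs[cog_id].category = annotate_smcog_category(cats)
    return dataset


def preprocess(
    dataset: Dataset, trim_threshold: float = 0.1, min_members: int = 3
) -> tuple[Dataset, PreprocessReport]:
    """Run all conditioning stages in order: trim, filter, dedupe, annotate."""
    dataset, r1 = trim_dataset(dataset, trim_threshold)
    dataset, r2 = filter_smcogs(dataset, min_members)
    dataset, r3 = dedupe_clusters(dataset)
    dataset = annotate_dataset(dataset)
    return dataset, r1.merge(r2).merge(r3)
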