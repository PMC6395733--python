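"""Interaction counting between orthogroup pairs.

Two kinds of pairwise interaction are counted within clusters:

* **adjacency** — two orthogroups occupying immediately neighbouring gene
  positions (linear topology, no wraparound; cluster-boundary genes have a
  single neighbour);
* **colocalization** — two orthogroups occurring anywhere within the same
  cluster.

For a fixed orthogroup A, every position not occupied by an A gene is
*available* and falls into a position class: for adjacency, by its number of
A neighbours (0, 1 or 2); for colocalization, by whether its cluster contains
an A gene at all.  The resulting class capacities and the observed class
occupancies of the moving orthogroup B form the :class:`PairProfile` the
significance tests consume.

Colocalization counting first applies a duplicate-collapse transform to each
cluster: all occurrences of any orthogroup appearing more than once are
replaced in place by empty (unassigned) positions, and the displaced genes
are re-attached at the cluster end behind one empty separator position.  The
empty positions remain available, which is what makes the resulting p-values
conservative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterator

from .data import UNASSIGNED, Cluster, Dataset, Gene, ValidationError

ADJACENCY = "adjacency"
COLOCALIZATION = "colocalization"


@dataclass(frozen=True)
class PairProfile:
    """Position-class capacities and occupancies for one ordered smCOG pair.

    ``capacities[k]`` is the number of available positions in class k and
    ``occupancies[k]`` the number of moving-COG genes observed there.  For
    adjacency the classes are (a, b, c) = 0/1/2 fixed-COG neighbours; for
    colocalization they are (a, b) = cluster without/with the fixed COG.
    """

    fixed_cog: str
    moving_cog: str
    kind: str
    capacities: tuple[int, ...]
    occupancies: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.capacities) != len(self.occupancies):
            raise ValidationError("capacities/occupancies length mismatch")
        if any(b > n for n, b in zip(self.capacities, self.occupancies)):
            raise ValidationError(
                f"occupancy exceeds capacity: {self.occupancies} vs {self.capacities}"
            )
        if any(n < 0 for n in self.capacities) or any(b < 0 for b in self.occupancies):
            raise ValidationError("negative count in profile")

    @property
    def n_tot(self) -> int:
        return sum(self.capacities)

    @property
    def b_tot(self) -> int:
        return sum(self.occupancies)

    @property
    def i_orig(self) -> int:
        """Observed interaction count: sum of class-weighted occupancies
        (class weights 0, 1, 2, ... = number of interactions per gene)."""
        return sum(k * b for k, b in enumerate(self.occupancies))


# ---------------------------------------------------------------------------
# Duplicate collapse (colocalization only)


def _terminal_collapsed_blocks(seq: list[str]) -> int:
    """Return the start index of the already-collapsed tail of ``seq``.

    A collapsed tail is a run of suffix blocks, each of the form
    [UNASSIGNED, X, X, ..., X] with the same orthogroup X repeated >= 2
    times.  Recognising these makes the transform idempotent.
    """
    end = len(seq)
    while True:
        i = end
        while i > 0 and seq[i - 1] != UNASSIGNED and (i == end or seq[i - 1] == seq[i]):
            i -= 1
        run = end - i
        if run >= 2 and i > 0 and seq[i - 1] == UNASSIGNED:
            end = i - 1
        else:
            return end


def collapse_duplicates(cluster: Cluster) -> Cluster:
    """Move duplicated orthogroups to the cluster end.

    For each orthogroup occurring k >= 2 times (first-occurrence order), the
    k genes are replaced in place by empty positions and appended at the end
    behind one empty separator.  Unassigned genes are never collapsed.
    Already-collapsed terminal blocks are left alone, so the transform is
    idempotent.
    """
    seq = cluster.smcog_sequence()
    head_end = _terminal_collapsed_blocks(seq)
    counts = Counter(s for s in seq[:head_end] if s != UNASSIGNED)
    dup_order = []
    for s in seq[:head_end]:
        if s != UNASSIGNED and counts[s] >= 2 and s not in dup_order:
            dup_order.append(s)
    if not dup_order:
        return cluster

    def placeholder(n: int) -> Gene:
        return Gene(
            gene_id=f"{cluster.cluster_id}__empty{n}",
            cluster_id=cluster.cluster_id,
            position=0,
            smcog_id=UNASSIGNED,
            category="other",
        )

    n_empty = 0
    body: list[Gene] = []
    moved: dict[str, list[Gene]] = {cog: [] for cog in dup_order}
    for gene in cluster.genes[:head_end]:
        if gene.smcog_id in moved:
            moved[gene.smcog_id].append(gene)
            body.append(placeholder(n_empty))
            n_empty += 1
        else:
            body.append(gene)
    tail = list(cluster.genes[head_end:])  # previously collapsed blocks stay put
    for cog in dup_order:
        tail.append(placeholder(n_empty))
        n_empty += 1
        tail.extend(moved[cog])
    return cluster.with_genes(body + tail)


def collapse_dataset(dataset: Dataset) -> Dataset:
    return Dataset.from_clusters(
        [collapse_duplicates(c) for c in dataset.clusters], dataset.provenance
    )


# ---------------------------------------------------------------------------
# Counting


def _check_pair(dataset: Dataset, cog_a: str, cog_b: str) -> None:
    if cog_a == cog_b:
        raise ValidationError("self-pairs are not supported")
    for cog in (cog_a, cog_b):
        if cog == UNASSIGNED or cog not in dataset.smcogs:
            raise ValidationError(f"smCOG {cog!r} not present in dataset")


def count_adjacency(dataset: Dataset, cog_a: str, cog_b: str) -> PairProfile:
    """Profile the pair (fixed=cog_a, moving=cog_b) for adjacency.

    Positions holding A genes are fixed and unavailable; every other
    position (unassigned ones included) is classified by its number of
    immediate A neighbours within the cluster.
    """
    _check_pair(dataset, cog_a, cog_b)
    n_total_positions = dataset.n_genes
    n_a_genes = 0
    n_class = [0, 0, 0]  # capacities for 0/1/2 A-neighbours
    b_class = [0, 0, 0]
    for cluster in dataset.clusters:
        seq = cluster.smcog_sequence()
        length = len(seq)
        a_pos = [i for i, s in enumerate(seq) if s == cog_a]
        n_a_genes += len(a_pos)
        a_set = set(a_pos)
        # only neighbours of A positions can be in class b or c
        affected = {p for i in a_pos for p in (i - 1, i + 1) if 0 <= p < length} - a_set
        for p in affected:
            k = (p - 1 in a_set) + (p + 1 in a_set)
            n_class[k] += 1
        for i, s in enumerate(seq):
            if s == cog_b:
                b_class[(i - 1 in a_set) + (i + 1 in a_set)] += 1
    n_class[0] = n_total_positions - n_a_genes - n_class[1] - n_class[2]
    return PairProfile(
        fixed_cog=cog_a,
        moving_cog=cog_b,
        kind=ADJACENCY,
        capacities=tuple(n_class),
        occupancies=tuple(b_class),
    )


def count_colocalization(dataset: Dataset, cog_a: str, cog_b: str) -> PairProfile:
    """Profile the pair (fixed=cog_a, moving=cog_b) for colocalization.

    Must be called on a duplicate-collapsed dataset.  Available positions in
    clusters containing an A gene form class b, those in A-free clusters
    class a; the observed interaction count is the number of B genes
    co-resident with A.
    """
    _check_pair(dataset, cog_a, cog_b)
    n_a = n_b = b_a = b_b = 0
    for cluster in dataset.clusters:
        seq = cluster.smcog_sequence()
        a_count = sum(1 for s in seq if s == cog_a)
        b_count = sum(1 for s in seq if s == cog_b)
        avail = len(seq) - a_count
        if a_count:
            n_b += avail
            b_b += b_count
        else:
            n_a += avail
            b_a += b_count
    return PairProfile(
        fixed_cog=cog_a,
        moving_cog=cog_b,
        kind=COLOCALIZATION,
        capacities=(n_a, n_b),
        occupancies=(b_a, b_b),
    )


def enumerate_candidate_pairs(dataset: Dataset) -> list[tuple[str, str]]:
    """Unordered smCOG pairs with at least one observed interaction.

    Any two orthogroups sharing a cluster colocalize at least once, and
    adjacency implies colocalization, so co-residence is the candidate
    criterion; all other pairs are never tested.
    """
    pairs: set[tuple[str, str]] = set()
    for cluster in dataset.clusters:
        present = sorted({g.smcog_id for g in cluster.genes if g.smcog_id != UNASSIGNED})
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                pairs.add((a, b))
    return sorted(pairs)


def iter_profiles(dataset: Dataset) -> Iterator[PairProfile]:
    """Diagnostic iterator: both kinds, both orientations, all candidates."""
    collapsed = collapse_dataset(dataset)
    for a, b in enumerate_candidate_pairs(dataset):
        yield count_adjacency(dataset, a, b)
        yield count_adjacency(dataset, b, a)
        yield count_colocalization(collapsed, a, b)
        yield count_colocalization(collapsed, b, a)
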