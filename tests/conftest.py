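from __future__ import annotations

import numpy as np
import pytest

from bgcmodules.data import Cluster, Dataset, Gene, UNASSIGNED


def make_cluster(cluster_id, smcog_seq, categories=None, probs=None, **kwargs) -> Cluster:
    """Build a cluster from a sequence of smCOG labels ('x' -> UNASSIGNED)."""
    genes = []
    for i, label in enumerate(smcog_seq):
        smcog = UNASSIGNED if label in ("x", UNASSIGNED) else label
        genes.append(
            Gene(
                gene_id=f"{cluster_id}_g{i}",
                cluster_id=cluster_id,
                position=i,
                smcog_id=smcog,
                category=categories[i] if categories else "other",
                domain_prob=probs[i] if probs else None,
            )
        )
    return Cluster(cluster_id=cluster_id, genes=tuple(genes), **kwargs)


def make_dataset(*clusters) -> Dataset:
    return Dataset.from_clusters(clusters)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_dataset() -> Dataset:
    """Six clusters where the triangle A-B-C recurs together and D, E are noise."""
    return make_dataset(
        make_cluster("c1", ["A", "B", "C", "x", "D"], compound_class="nrps"),
        make_cluster("c2", ["B", "A", "C", "E"], compound_class="pks"),
        make_cluster("c3", ["C", "A", "B", "x"], compound_class="nrps", curated=True),
        make_cluster("c4", ["A", "C", "B", "D"], compound_class="terpene"),
        make_cluster("c5", ["D", "x", "E", "x", "A", "B", "C"], compound_class="pks"),
        make_cluster("c6", ["E", "x", "D", "x", "x"], compound_class="other"),
    )


def random_dataset(rng, n_clusters=5, n_cogs=4, length_range=(4, 8), assign_rate=0.8):
    """Small random dataset for oracle comparisons."""
    cogs = [chr(ord("A") + i) for i in range(n_cogs)]
    clusters = []
    for ci in range(n_clusters):
        length = int(rng.integers(*length_range))
        seq = [
            cogs[int(rng.integers(n_cogs))] if rng.random() < assign_rate else "x"
            for _ in range(length)
        ]
        clusters.append(
            make_cluster(
                f"r{ci}", seq, compound_class=f"cls{int(rng.integers(3))}"
            )
        )
    return make_dataset(*clusters)
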