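"""Synthetic cluster collections with planted modules.

The generator emulates the structure of a real cluster collection at desk
scale: clusters of varying length, a background of orthogroups placed
uniformly at random (with replacement, so duplicated orthogroups occur and
exercise the duplicate-collapse transform), and optional *planted modules* —
fixed sets of 3–6 orthogroups inserted together (contiguously or scattered)
into a controlled fraction of clusters.  Gene categories follow a fixed
frequency profile and each cluster draws a compound-class label; classes may
optionally be correlated with planting to mimic lineage-driven co-occurrence.

Everything is driven by one integer seed: the same spec always yields a
byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import UNASSIGNED, Cluster, Dataset, Gene, ValidationError
from .modules import Module

_CATEGORY_NAMES = ("core", "regulator", "tailoring", "transport", "other")
_CATEGORY_PROBS = (0.25, 0.10, 0.30, 0.15, 0.20)


@dataclass(frozen=True)
class PlantedModule:
    """A fixed orthogroup set inserted together into a fraction of clusters."""

    smcogs: tuple[str, ...]
    fraction: float
    contiguous: bool = True

    def __post_init__(self) -> None:
        if not 3 <= len(self.smcogs) <= 6:
            raise ValidationError("planted module size must be in 3..6")
        if len(set(self.smcogs)) != len(self.smcogs):
            raise ValidationError("planted module smCOGs must be distinct")
        if not 0.0 < self.fraction <= 1.0:
            raise ValidationError("insertion fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic collection.

    Defaults model a desk-scale corpus: 100 clusters of 5–15 genes, 30
    background orthogroups filling ~70% of positions, five compound classes.
    """

    n_clusters: int = 100
    cluster_length_range: tuple[int, int] = (5, 15)
    n_background_cogs: int = 30
    background_rate: float = 0.7
    planted_modules: tuple[PlantedModule, ...] = ()
    n_classes: int = 5
    curated_fraction: float = 0.1
    correlate_classes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cluster_length_range
        if lo < 3 or hi < lo:
            raise ValidationError("cluster lengths must satisfy 3 <= min <= max")
        if not 0.0 < self.background_rate <= 1.0:
            raise ValidationError("background rate must lie in (0, 1]")
        for pm in self.planted_modules:
            if len(pm.smcogs) > lo:
                raise ValidationError(
                    f"planted module of size {len(pm.smcogs)} exceeds the minimum "
                    f"cluster length {lo}"
                )


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw one cluster collection from the spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.cluster_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_clusters)
    background = [f"BG{i:04d}" for i in range(spec.n_background_cogs)]
    class_labels = [f"class{i + 1:02d}" for i in range(spec.n_classes)]

    # which clusters receive which planted module
    targets: list[set[int]] = []
    for pm in spec.planted_modules:
        count = int(round(pm.fraction * spec.n_clusters))
        targets.append(
            {int(i) for i in rng.choice(spec.n_clusters, size=count, replace=False)}
        )

    clusters = []
    for ci in range(spec.n_clusters):
        length = int(lengths[ci])
        slots: list[str | None] = [None] * length
        planted_here = False
        for pm, chosen in zip(spec.planted_modules, targets):
            if ci not in chosen:
                continue
            planted_here = True
            size = len(pm.smcogs)
            order = [pm.smcogs[j] for j in rng.permutation(size)]
            free = [i for i, s in enumerate(slots) if s is None]
            placed = False
            if pm.contiguous:
                starts = [
                    s
                    for s in range(length - size + 1)
                    if all(slots[s + j] is None for j in range(size))
                ]
                if starts:
                    start = int(rng.choice(starts))
                    for j, cog in enumerate(order):
                        slots[start + j] = cog
                    placed = True
            if not placed:
                if len(free) < size:
                    continue  # no room left (only possible with many overlapping plants)
                pos = rng.choice(len(free), size=size, replace=False)
                for p, cog in zip(pos, order):
                    slots[int(free[int(p)])] = cog
        for i in range(length):
            if slots[i] is None:
                if rng.random() < spec.background_rate:
                    slots[i] = background[int(rng.integers(spec.n_background_cogs))]
                else:
                    slots[i] = UNASSIGNED
        cluster_id = f"SYN{ci:04d}"
        genes = tuple(
            Gene(
                gene_id=f"{cluster_id}_g{i:03d}",
                cluster_id=cluster_id,
                position=i,
                smcog_id=slots[i],
                category=_CATEGORY_NAMES[
                    int(rng.choice(len(_CATEGORY_NAMES), p=_CATEGORY_PROBS))
                ],
            )
            for i in range(length)
        )
        if spec.correlate_classes and planted_here:
            compound_class = class_labels[0]
        else:
            compound_class = class_labels[int(rng.integers(spec.n_classes))]
        clusters.append(
            Cluster(
                cluster_id=cluster_id,
                genes=genes,
                compound_class=compound_class,
                curated=bool(rng.random() < spec.curated_fraction),
            )
        )
    return Dataset.from_clusters(
        clusters, provenance={"synthetic": True, "seed": spec.seed}
    )


@dataclass
class RecoveryReport:
    """How each planted module fared against the detected module list."""

    outcomes: dict[tuple[str, ...], str] = field(default_factory=dict)
    n_spurious: int = 0

    @property
    def n_recovered(self) -> int:
        """Planted modules recovered exactly or as a superset."""
        return sum(1 for v in self.outcomes.values() if v in ("exact", "superset"))


def score_recovery(
    detected: Sequence[Module], spec: SyntheticSpec
) -> RecoveryReport:
    """Classify each planted module as exact / superset / subset / missed and
    count detected modules overlapping no planted set at all."""
    detected_sets = [set(m.smcogs) for m in detected]
    report = RecoveryReport()
    planted_union: set[str] = set()
    for pm in spec.planted_modules:
        planted = set(pm.smcogs)
        planted_union |= planted
        if any(d == planted for d in detected_sets):
            outcome = "exact"
        elif any(d > planted for d in detected_sets):
            outcome = "superset"
        elif any(d < planted for d in detected_sets):
            outcome = "subset"
        else:
            outcome = "missed"
        report.outcomes[tuple(sorted(planted))] = outcome
    report.n_spurious = sum(1 for d in detected_sets if not d & planted_union)
    return report
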