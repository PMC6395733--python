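"""Module prioritisation: per-module metrics, Shannon entropy of compound
classes, and the MIB (Module Interest Benchmarking) weighted-rank score.

Each detected module is described by its size, the number of supporting
clusters (and how many of those carry a curated-database flag), its
strictest detection threshold, the diversity of compound classes produced by
its supporting clusters (Shannon entropy, natural log), and the functional
category make-up of its member orthogroups.  The MIB score ranks modules on
each metric separately (better = higher rank, average ranks on ties), takes
a weighted sum of the ranks, and rescales linearly to [1, 100].

Default weights: module size 2, Shannon entropy 15, number of supporting
clusters 10, strictest threshold 5 (stricter is better), tailoring
percentage 10, everything else 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, rankdata

from .data import Dataset, ValidationError
from .modules import Module


@dataclass(frozen=True)
class ModuleMetrics:
    size: int
    n_bgc: int
    n_curated: int
    strictest_threshold: float
    n_classes: int
    shannon_entropy: float
    category_percent: Mapping[str, float]

    @property
    def tailoring_percent(self) -> float:
        return self.category_percent.get("tailoring", 0.0)


@dataclass(frozen=True)
class MibWeights:
    """Non-negative weight per ranking metric."""

    size: float = 2.0
    entropy: float = 15.0
    n_bgc: float = 10.0
    threshold: float = 5.0
    tailoring_percent: float = 10.0
    n_curated: float = 0.0
    n_classes: float = 0.0
    #: extra category-percentage metrics (e.g. {"core": 1.0}); default none
    category_percent: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [
            self.size,
            self.entropy,
            self.n_bgc,
            self.threshold,
            self.tailoring_percent,
            self.n_curated,
            self.n_classes,
            *self.category_percent.values(),
        ]
        if any(w < 0 for w in values):
            raise ValidationError("MIB weights must be non-negative")


def shannon_entropy(class_counts: Mapping[str, int]) -> float:
    """SE = -sum f_i ln f_i over compound classes with positive counts."""
    total = sum(class_counts.values())
    if total <= 0 or any(c < 0 for c in class_counts.values()):
        raise ValidationError("class counts must be non-negative with a positive sum")
    return -sum(
        (c / total) * math.log(c / total) for c in class_counts.values() if c > 0
    )


def _split_category(category: str) -> dict[str, float]:
    """A double category like 'tailoring/core' contributes 0.5 to each part."""
    parts = category.split("/")
    return {p: 1.0 / len(parts) for p in parts}


def compute_metrics(module: Module, dataset: Dataset) -> ModuleMetrics:
    """Populate all per-module metrics from the supporting clusters and the
    member orthogroups' annotated categories."""
    clusters = {c.cluster_id: c for c in dataset.clusters}
    support = [clusters[cid] for cid in module.supporting_clusters]
    class_counts = Counter(c.compound_class for c in support)
    weights: Counter = Counter()
    for cog in module.smcogs:
        record = dataset.smcogs.get(cog)
        if record is None or record.category is None:
            raise ValidationError(f"member smCOG {cog!r} lacks a category annotation")
        for cat, w in _split_category(record.category).items():
            weights[cat] += w
    size = len(module.smcogs)
    return ModuleMetrics(
        size=size,
        n_bgc=len(support),
        n_curated=sum(1 for c in support if c.curated),
        strictest_threshold=module.strictest_threshold,
        n_classes=len(class_counts),
        shannon_entropy=shannon_entropy(class_counts),
        category_percent={cat: 100.0 * w / size for cat, w in sorted(weights.items())},
    )


def mib_score(
    metrics: Sequence[ModuleMetrics], weights: MibWeights | None = None
) -> np.ndarray:
    """Weighted-rank score per module, rescaled to [1, 100].

    Per metric, modules are ranked with the better value receiving the
    higher rank (larger is better everywhere except the strictest
    threshold, where smaller is better); exact ties get average ranks.
    When every module scores identically the degenerate rescale maps all
    to 100.
    """
    if not metrics:
        raise ValidationError("need at least one module")
    weights = weights or MibWeights()
    columns: list[tuple[float, np.ndarray]] = [
        (weights.size, np.array([m.size for m in metrics], dtype=float)),
        (weights.entropy, np.array([m.shannon_entropy for m in metrics])),
        (weights.n_bgc, np.array([m.n_bgc for m in metrics], dtype=float)),
        (weights.threshold, -np.array([m.strictest_threshold for m in metrics])),
        (weights.tailoring_percent, np.array([m.tailoring_percent for m in metrics])),
        (weights.n_curated, np.array([m.n_curated for m in metrics], dtype=float)),
        (weights.n_classes, np.array([m.n_classes for m in metrics], dtype=float)),
    ]
    for cat, w in sorted(weights.category_percent.items()):
        columns.append(
            (w, np.array([m.category_percent.get(cat, 0.0) for m in metrics]))
        )
    raw = np.zeros(len(metrics))
    for w, values in columns:
        if w > 0:
            raw += w * rankdata(values)  # ties -> average ranks
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full(len(metrics), 100.0)
    return 1.0 + 99.0 * (raw - lo) / (hi - lo)


def prioritize_modules(
    modules: Sequence[Module], dataset: Dataset, weights: MibWeights | None = None
) -> list[Module]:
    """Attach metrics and MIB scores to every module (in place); returns the
    modules sorted by descending score, then id."""
    if not modules:
        return []
    for m in modules:
        m.metrics = compute_metrics(m, dataset)
    scores = mib_score([m.metrics for m in modules], weights)
    for m, s in zip(modules, scores):
        m.mib_score = float(s)
    return sorted(modules, key=lambda m: (-m.mib_score, m.module_id))


def quartile_enrichment(
    selected_scores: Sequence[float],
    all_scores: Sequence[float],
    quantile: float = 0.25,
) -> float:
    """One-sided Fisher exact test: is the selection over-represented in the
    top ``quantile`` fraction of all scores?

    The top set is the highest floor(quantile * n) scores; tied boundary
    scores are all included.
    """
    if len(selected_scores) == 0:
        raise ValidationError("empty selection")
    if not 0.0 < quantile < 1.0:
        raise ValidationError("quantile must lie in (0, 1)")
    all_scores = sorted(all_scores, reverse=True)
    n = len(all_scores)
    k = max(1, int(math.floor(quantile * n)))
    cutoff = all_scores[k - 1]
    top_total = sum(1 for s in all_scores if s >= cutoff)
    x = sum(1 for s in selected_scores if s >= cutoff)
    table = [
        [x, len(selected_scores) - x],
        [top_total - x, (n - top_total) - (len(selected_scores) - x)],
    ]
    return float(fisher_exact(table, alternative="greater")[1])
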