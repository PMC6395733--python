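"""Model/Results interface over the full detection pipeline.

:class:`SubclusterModel` holds a cluster collection plus the analysis
settings; :meth:`SubclusterModel.fit` runs conditioning, interaction
counting, significance testing, clique-based module detection and MIB
prioritisation, and returns a :class:`SubclusterResults` carrying the
interaction table, the module list and a text summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import modules as module_detect
from .data import (
    Dataset,
    modules_to_frame,
    read_cluster_table,
    read_genbank_clusters,
    write_modules,
)
from .preprocess import PreprocessReport, preprocess
from .prioritize import MibWeights, prioritize_modules
from .significance import InteractionResult, results_to_frame, test_all_pairs


@dataclass
class SubclusterModel:
    """Co-occurrence module detection over a cluster collection.

    Parameters mirror the method's published defaults: genes with a
    biosynthetic-domain probability below ``trim_threshold`` are trimmed
    from cluster extremes, orthogroups need ``min_members`` genes, the
    threshold ladder is capped at ``cap``, modules need ``min_size``
    orthogroups and ``min_support`` supporting clusters.
    """

    dataset: Dataset
    trim_threshold: float = 0.1
    min_members: int = 3
    cap: float = 0.1
    min_size: int = 3
    min_support: int = 2
    ladder_steps: int | None = None
    weights: MibWeights = field(default_factory=MibWeights)

    @classmethod
    def from_table(cls, path: str | Path, format: str = "tsv", **kwargs) -> "SubclusterModel":
        return cls(read_cluster_table(path, format), **kwargs)

    @classmethod
    def from_genbank(
        cls, path: str | Path, smcog_map=None, **kwargs
    ) -> "SubclusterModel":
        return cls(read_genbank_clusters(path, smcog_map), **kwargs)

    def fit(self) -> "SubclusterResults":
        data, report = preprocess(
            self.dataset, self.trim_threshold, self.min_members
        )
        results = test_all_pairs(data)
        detected = module_detect.detect_modules(
            results,
            data,
            cap=self.cap,
            min_size=self.min_size,
            min_support=self.min_support,
            max_steps=self.ladder_steps,
        )
        detected = prioritize_modules(detected, data, self.weights)
        return SubclusterResults(
            model=self,
            dataset=data,
            report=report,
            interactions=results,
            modules=detected,
        )


@dataclass
class SubclusterResults:
    """Fitted pipeline output: interaction significance and ranked modules."""

    model: SubclusterModel
    dataset: Dataset
    report: PreprocessReport
    interactions: list[InteractionResult]
    modules: list

    @property
    def interaction_table(self) -> pd.DataFrame:
        return results_to_frame(self.interactions)

    @property
    def module_table(self) -> pd.DataFrame:
        return modules_to_frame(self.modules)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Subcluster detection results",
            "============================",
            f"clusters analysed:        {len(self.dataset.clusters)}",
            f"orthogroups (smCOGs):     {len(self.dataset.smcogs)}",
            f"interaction tests:        {len(self.interactions)}",
            f"modules detected:         {len(self.modules)}",
            f"genes trimmed:            {self.report.genes_trimmed}",
            f"smCOGs below size cutoff: {self.report.smcogs_removed}",
            f"redundant clusters:       {self.report.clusters_dropped_redundant}",
            "",
        ]
        if self.modules:
            lines.append(f"top modules by MIB score (of {len(self.modules)}):")
            frame = self.module_table.head(top)
            lines.append(
                frame[
                    ["module_id", "size", "n_bgc", "strictest_threshold", "mib_score"]
                ].to_string(index=False)
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write the interaction table, module table (+ JSON sidecar),
        per-threshold edge lists, and the preprocessing report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.interaction_table.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        write_modules(self.modules, outdir / "modules.tsv")
        ladder = module_detect.threshold_ladder(
            self.interactions, self.model.cap, self.model.ladder_steps
        )
        edges = []
        for t in ladder:
            frame = module_detect.edge_list(self.interactions, t)
            frame.insert(0, "threshold", t)
            edges.append(frame)
        combined = (
            pd.concat(edges, ignore_index=True)
            if edges
            else pd.DataFrame(columns=["threshold", "cog_a", "cog_b", "p_adjusted"])
        )
        combined.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(
                {
                    "preprocess": self.report.to_dict(),
                    "parameters": {
                        "trim_threshold": self.model.trim_threshold,
                        "min_members": self.model.min_members,
                        "cap": self.model.cap,
                        "min_size": self.model.min_size,
                        "min_support": self.model.min_support,
                        "ladder_steps": self.model.ladder_steps,
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
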