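"""Domain types and I/O for gene cluster collections.

The unit of analysis is a *cluster*: an ordered list of genes extracted from
a genomic region (e.g. an antiSMASH-predicted biosynthetic gene cluster).
Each gene carries an orthogroup label (an smCOG id, or the ``UNASSIGNED``
sentinel for genes that belong to no retained orthogroup), a functional
category, and optionally a probability of carrying a biosynthesis-relevant
domain.  Only gene *order* matters to the downstream statistics; genomic
coordinates and strand are deliberately not retained.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Reserved sentinel for genes without an orthogroup label; never a valid smCOG id.
UNASSIGNED = "UNASSIGNED"

#: Gene-level functional categories.
GENE_CATEGORIES = ("core", "regulator", "tailoring", "transport", "other")


class FormatError(ValueError):
    """A file does not conform to the expected tabular/JSON layout."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


@dataclass(frozen=True)
class Gene:
    """One gene position within a cluster."""

    gene_id: str
    cluster_id: str
    position: int
    smcog_id: str = UNASSIGNED
    category: str = "other"
    domain_prob: float | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"gene {self.gene_id}: negative position")
        if self.category not in GENE_CATEGORIES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown category {self.category!r}"
            )
        if self.domain_prob is not None and not 0.0 <= self.domain_prob <= 1.0:
            raise ValidationError(
                f"gene {self.gene_id}: domain_prob {self.domain_prob} outside [0, 1]"
            )

    @property
    def assigned(self) -> bool:
        return self.smcog_id != UNASSIGNED


@dataclass(frozen=True)
class Cluster:
    """An ordered gene cluster; the unit within which interactions are counted."""

    cluster_id: str
    genes: tuple[Gene, ...]
    compound_class: str = "unknown"
    curated: bool = False
    organism: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"cluster {self.cluster_id}: empty gene list")
        positions = [g.position for g in self.genes]
        if positions != list(range(len(self.genes))):
            raise ValidationError(
                f"cluster {self.cluster_id}: positions not dense 0..{len(self.genes) - 1}: "
                f"{positions}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def smcog_sequence(self) -> list[str]:
        return [g.smcog_id for g in self.genes]

    def with_genes(self, genes: Sequence[Gene]) -> "Cluster":
        """Rebuild this cluster with a new gene list, re-indexing positions densely."""
        reindexed = tuple(
            replace(g, position=i, cluster_id=self.cluster_id)
            for i, g in enumerate(genes)
        )
        return replace(self, genes=reindexed)


@dataclass
class SmCOG:
    """An orthogroup of genes drawn from across the cluster collection."""

    smcog_id: str
    member_gene_ids: set[str] = field(default_factory=set)
    category: str | None = None  # e.g. "tailoring", "tailoring/core", "mixed"


@dataclass
class Dataset:
    """A validated collection of clusters plus the orthogroup records they reference."""

    clusters: list[Cluster]
    smcogs: dict[str, SmCOG]
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_clusters(
        cls, clusters: Iterable[Cluster], provenance: dict | None = None
    ) -> "Dataset":
        """Build a Dataset, deriving orthogroup membership from gene labels."""
        clusters = list(clusters)
        smcogs: dict[str, SmCOG] = {}
        for cluster in clusters:
            for gene in cluster.genes:
                if gene.smcog_id == UNASSIGNED:
                    continue
                smcogs.setdefault(gene.smcog_id, SmCOG(gene.smcog_id))
                smcogs[gene.smcog_id].member_gene_ids.add(gene.gene_id)
        ds = cls(clusters=clusters, smcogs=smcogs, provenance=provenance or {})
        ds.validate()
        return ds

    def validate(self) -> None:
        seen = set()
        for cluster in self.clusters:
            if cluster.cluster_id in seen:
                raise ValidationError(f"duplicate cluster_id {cluster.cluster_id!r}")
            seen.add(cluster.cluster_id)
            for gene in cluster.genes:
                if gene.smcog_id != UNASSIGNED and gene.smcog_id not in self.smcogs:
                    raise ValidationError(
                        f"gene {gene.gene_id}: smCOG {gene.smcog_id!r} has no record"
                    )

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.clusters)

    def genes(self) -> Iterable[Gene]:
        for cluster in self.clusters:
            yield from cluster.genes

    def smcog_positions(self) -> dict[str, list[tuple[str, int]]]:
        """Map each smCOG id to its (cluster_id, position) occurrences, in order."""
        out: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for cluster in self.clusters:
            for gene in cluster.genes:
                if gene.smcog_id != UNASSIGNED:
                    out[gene.smcog_id].append((cluster.cluster_id, gene.position))
        return dict(out)


# ---------------------------------------------------------------------------
# Tabular I/O

_REQUIRED_COLUMNS = ("cluster_id", "gene_id", "position", "smcog_id", "category")
_OPTIONAL_COLUMNS = ("domain_prob", "compound_class", "curated_flag", "organism")


def _clusters_from_frame(frame: pd.DataFrame) -> list[Cluster]:
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"missing required column {column!r}")
    dup = frame.duplicated(subset=["cluster_id", "position"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise ValidationError(
            f"duplicate (cluster_id, position) = ({row['cluster_id']}, {row['position']})"
        )
    clusters = []
    # groupby(sort=True) gives a deterministic cluster order by id
    for cluster_id, group in frame.groupby("cluster_id", sort=True):
        group = group.sort_values("position")
        genes = []
        for _, row in group.iterrows():
            prob = row.get("domain_prob")
            if prob is not None and pd.isna(prob):
                prob = None
            genes.append(
                Gene(
                    gene_id=str(row["gene_id"]),
                    cluster_id=str(cluster_id),
                    position=int(row["position"]),
                    smcog_id=str(row["smcog_id"]),
                    category=str(row["category"]),
                    domain_prob=None if prob is None else float(prob),
                )
            )
        first = group.iloc[0]
        organism = first.get("organism")
        if organism is not None and pd.isna(organism):
            organism = None
        cluster = Cluster(
            cluster_id=str(cluster_id),
            genes=tuple(genes),
            compound_class=str(first.get("compound_class", "unknown")),
            curated=bool(first.get("curated_flag", False)),
            organism=None if organism is None else str(organism),
        )
        clusters.append(cluster)
    return clusters


def read_cluster_table(path: str | Path, format: str = "tsv") -> Dataset:
    """Read a cluster table (TSV with one row per gene, or the JSON dump).

    Required columns: cluster_id, gene_id, position, smcog_id, category.
    Per-cluster fields (compound_class, curated_flag, organism) are repeated
    on each gene row; the first row of a cluster wins.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"smcog_id": str})
        clusters = _clusters_from_frame(frame)
    elif format == "json":
        payload = json.loads(path.read_text())
        clusters = [_cluster_from_dict(c) for c in payload["clusters"]]
    else:
        raise FormatError(f"unknown format {format!r}")
    return Dataset.from_clusters(clusters, provenance={"source": str(path)})


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for cluster in dataset.clusters:
        for gene in cluster.genes:
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "gene_id": gene.gene_id,
                    "position": gene.position,
                    "smcog_id": gene.smcog_id,
                    "category": gene.category,
                    "domain_prob": gene.domain_prob,
                    "compound_class": cluster.compound_class,
                    "curated_flag": cluster.curated,
                    "organism": cluster.organism,
                }
            )
    return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))


def write_cluster_table(dataset: Dataset, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        dataset_to_frame(dataset).to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {"clusters": [_cluster_to_dict(c) for c in dataset.clusters]}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise FormatError(f"unknown format {format!r}")


def _cluster_to_dict(cluster: Cluster) -> dict:
    return {
        "cluster_id": cluster.cluster_id,
        "compound_class": cluster.compound_class,
        "curated_flag": cluster.curated,
        "organism": cluster.organism,
        "genes": [
            {
                "gene_id": g.gene_id,
                "position": g.position,
                "smcog_id": g.smcog_id,
                "category": g.category,
                "domain_prob": g.domain_prob,
            }
            for g in cluster.genes
        ],
    }


def _cluster_from_dict(payload: Mapping) -> Cluster:
    cluster_id = str(payload["cluster_id"])
    genes = tuple(
        Gene(
            gene_id=str(g["gene_id"]),
            cluster_id=cluster_id,
            position=int(g["position"]),
            smcog_id=str(g.get("smcog_id", UNASSIGNED)),
            category=str(g.get("category", "other")),
            domain_prob=g.get("domain_prob"),
        )
        for g in sorted(payload["genes"], key=lambda g: int(g["position"]))
    )
    return Cluster(
        cluster_id=cluster_id,
        genes=genes,
        compound_class=str(payload.get("compound_class", "unknown")),
        curated=bool(payload.get("curated_flag", False)),
        organism=payload.get("organism"),
    )


# ---------------------------------------------------------------------------
# GenBank convenience reader

def read_genbank_clusters(
    path: str | Path, smcog_map: Mapping[str, str] | str | Path | None = None
) -> Dataset:
    """Extract one cluster per GenBank record from its CDS features.

    Genes are ordered by start coordinate regardless of strand.  Orthogroup
    labels come from an ``smcog`` feature qualifier or from ``smcog_map``
    (a mapping, or a path to a 2-column gene_id<TAB>smcog_id file); genes
    lacking a label become UNASSIGNED.
    """
    from Bio import SeqIO

    if smcog_map is not None and not isinstance(smcog_map, Mapping):
        smcog_map = read_smcog_map(smcog_map)
    mapping: Mapping[str, str] = smcog_map or {}

    path = Path(path)
    clusters = []
    for record in SeqIO.parse(str(path), "genbank"):
        try:
            cds = [f for f in record.features if f.type == "CDS"]
            if not cds:
                raise ValidationError(f"record {record.id}: no CDS features")
            cds.sort(key=lambda f: int(f.location.start))
            genes = []
            for i, feat in enumerate(cds):
                quals = feat.qualifiers
                gene_id = (
                    quals.get("locus_tag", quals.get("protein_id", quals.get("gene", [None])))
                )[0] or f"{record.id}_cds{i}"
                smcog = quals.get("smcog", [None])[0] or mapping.get(gene_id, UNASSIGNED)
                category = quals.get("category", ["other"])[0]
                prob = quals.get("domain_prob", [None])[0]
                genes.append(
                    Gene(
                        gene_id=gene_id,
                        cluster_id=record.id,
                        position=i,
                        smcog_id=smcog,
                        category=category,
                        domain_prob=None if prob is None else float(prob),
                    )
                )
            clusters.append(
                Cluster(
                    cluster_id=record.id,
                    genes=tuple(genes),
                    compound_class=record.annotations.get("compound_class", "unknown"),
                    organism=record.annotations.get("organism"),
                )
            )
        except ValidationError:
            raise
        except Exception as exc:  # malformed record: skip, keep going
            log.warning("skipping unparsable record in %s: %s", path, exc)
    if not clusters:
        raise FormatError(f"{path}: no GenBank records with CDS features")
    return Dataset.from_clusters(clusters, provenance={"source": str(path)})


def read_smcog_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column gene_id -> smcog_id TSV sidecar mapping."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"smcog map line needs 2 columns: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# Module table output

_MODULE_COLUMNS = (
    "module_id",
    "smcogs",
    "size",
    "n_bgc",
    "n_curated",
    "strictest_threshold",
    "shannon_entropy",
    "category_percent",
    "mib_score",
)


def modules_to_frame(modules: Sequence) -> pd.DataFrame:
    """Flatten detected modules into one row per module (stable, diffable)."""
    rows = []
    for m in modules:
        metrics = m.metrics
        rows.append(
            {
                "module_id": m.module_id,
                "smcogs": ",".join(sorted(m.smcogs)),
                "size": len(m.smcogs),
                "n_bgc": len(m.supporting_clusters),
                "n_curated": None if metrics is None else metrics.n_curated,
                "strictest_threshold": m.strictest_threshold,
                "shannon_entropy": None if metrics is None else metrics.shannon_entropy,
                "category_percent": None
                if metrics is None
                else json.dumps(metrics.category_percent, sort_keys=True),
                "mib_score": m.mib_score,
            }
        )
    return pd.DataFrame(rows, columns=_MODULE_COLUMNS)


def write_modules(modules: Sequence, path: str | Path) -> None:
    """Write the module TSV plus a JSON sidecar with supporting cluster ids."""
    path = Path(path)
    modules_to_frame(modules).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    payload = {
        m.module_id: {
            "smcogs": sorted(m.smcogs),
            "strictest_threshold": m.strictest_threshold,
            "supporting_clusters": sorted(m.supporting_clusters),
        }
        for m in modules
    }
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
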