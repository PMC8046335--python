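"""Domain types: gene records, per-genome gene orders, and the operon-cluster model.

The operon-cluster model describes the reference arrangement of a conserved
run of operons (e.g. the secE-rpoBC-str-S10-spc-alpha cluster of the
transcription/translation machinery) as an ordered list of operons, each an
ordered list of gene labels.  Highly variable genes (classically the four
tRNAs of the tufB operon) can be excluded from event calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "GeneRecord",
    "GeneOrderTable",
    "Operon",
    "OperonClusterModel",
    "default_cluster_model",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 1-based inclusive coordinates on a replicon."""

    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    gene_label: str
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) for {self.gene_label!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_label:
            raise ValueError("gene_label must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneOrderTable:
    """All gene records of one genome, canonically sorted by (replicon, start).

    ``circular_replicons`` lists replicons whose first and last genes are
    adjacent; by default replicons are treated as linearized.
    """

    genome_id: str
    records: list[GeneRecord] = field(default_factory=list)
    circular_replicons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.replicon_id, r.start, r.gene_label)
        )
        seen = set()
        for r in self.records:
            key = (r.replicon_id, r.start, r.gene_label)
            if key in seen:
                raise ValueError(f"duplicate record {key} in genome {self.genome_id}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_label(self, label: str) -> list[GeneRecord]:
        """All copies of a gene, in chromosomal order."""
        return [r for r in self.records if r.gene_label == label]

    def replicon(self, replicon_id: str) -> list[GeneRecord]:
        return [r for r in self.records if r.replicon_id == replicon_id]

    @property
    def labels(self) -> list[str]:
        return [r.gene_label for r in self.records]


@dataclass
class Operon:
    name: str
    genes: list[str]


@dataclass
class OperonClusterModel:
    """Ordered operons, each an ordered gene list, defining the reference cluster."""

    operons: list[Operon]
    excluded_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.operons:
            raise ValueError("cluster model needs at least one operon")
        labels = self.all_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"gene labels duplicated in cluster model: {dupes}")

    @property
    def all_labels(self) -> list[str]:
        """Every model gene label in cluster order (including excluded ones)."""
        return [g for op in self.operons for g in op.genes]

    @property
    def active_labels(self) -> list[str]:
        """Cluster-order labels with the excluded (hyper-variable) genes removed."""
        return [g for g in self.all_labels if g not in self.excluded_labels]

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self.all_labels)

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Consecutive gene pairs in cluster order, over the active labels."""
        labels = self.active_labels
        return list(zip(labels, labels[1:]))

    def operon_of(self, label: str) -> str | None:
        for op in self.operons:
            if label in op.genes:
                return op.name
        return None

    def junction_name(self, gene_a: str, gene_b: str) -> str:
        """Operon-pair tag for a junction: 'str-S10' across operons, 'S10' within."""
        op_a, op_b = self.operon_of(gene_a), self.operon_of(gene_b)
        if op_a == op_b:
            return op_a or "?"
        return f"{op_a}-{op_b}"

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "operons": [{"name": op.name, "genes": list(op.genes)} for op in self.operons],
            "excluded_labels": sorted(self.excluded_labels),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "OperonClusterModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        operons = [Operon(name=o["name"], genes=list(o["genes"])) for o in data["operons"]]
        return cls(operons=operons, excluded_labels=frozenset(data.get("excluded_labels", [])))


def default_cluster_model() -> OperonClusterModel:
    """The E. coli-style reference cluster: tufB tail plus the six core operons.

    The four tufB-operon tRNAs are excluded from event calling because their
    presence/absence is hyper-variable across genomes.
    """
    operons = [
        Operon("tufB", ["tRNA-Thr1", "tRNA-Tyr", "tRNA-Gly", "tRNA-Thr2", "tufB"]),
        Operon("secE", ["secE", "nusG"]),
        Operon("rpoBC", ["rplK", "rplA", "rplJ", "rplL", "rpoB", "rpoC"]),
        Operon("str", ["rpsL", "rpsG", "fusA", "tufA"]),
        Operon(
            "S10",
            ["rpsJ", "rplC", "rplD", "rplW", "rplB", "rpsS", "rplV", "rpsC",
             "rplP", "rpmC", "rpsQ"],
        ),
        Operon(
            "spc",
            ["rplN", "rplX", "rplE", "rpsN", "rpsH", "rplF", "rplR", "rpsE",
             "rpmD", "rplO", "secY", "rpmJ"],
        ),
        Operon("alpha", ["rpsM", "rpsK", "rpsD", "rpoA", "rplQ"]),
    ]
    return OperonClusterModel(
        operons=operons,
        excluded_labels=frozenset({"tRNA-Thr1", "tRNA-Tyr", "tRNA-Gly", "tRNA-Thr2"}),
    )
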