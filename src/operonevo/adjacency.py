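"""Three-state adjacency characters for cluster gene pairs.

Every adjacent gene pair of the cluster model is scored in every genome as
CONNECTED (same replicon, intergenic gap below a distance threshold,
default 10 kb), DISCONNECTED (different replicons or gap at/above the
threshold) or DELETED (either gene absent from the genome).  No distinction
is made between different separation distances of disconnected pairs.

"Connected" deliberately ignores intervening genes: a small insertion that
breaks operon concatenation but leaves the pair within the threshold is
still CONNECTED, with the insertion recorded separately via
``intervening_count`` for downstream event classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .model import GeneOrderTable, GeneRecord, OperonClusterModel

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyState",
    "PairStateMatrix",
    "SyntenyNeighborhood",
    "DISTANCE_THRESHOLD_BP",
    "cluster_blocks",
    "cluster_region",
    "resolve_copy",
    "pair_state",
    "build_state_matrix",
    "extract_neighborhood",
    "count_gene_copies",
]

DISTANCE_THRESHOLD_BP = 10_000  # pairs closer than this are "connected"


class AdjacencyState(str, Enum):
    CONNECTED = "CONNECTED"
    DISCONNECTED = "DISCONNECTED"
    DELETED = "DELETED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _intergenic_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Intergenic bp between two genes on one replicon (0 if they overlap)."""
    left, right = (a, b) if a.start <= b.start else (b, a)
    return max(0, right.start - left.end - 1)


def cluster_blocks(
    table: GeneOrderTable,
    model: OperonClusterModel,
    threshold: int = DISTANCE_THRESHOLD_BP,
) -> list[list[int]]:
    """Runs of model-gene occurrences (indices into ``table.records``).

    Consecutive occurrences on the same replicon separated by less than
    ``threshold`` bp stay in one block; each block is one cluster fragment.
    """
    model_labels = model.label_set
    hits = [i for i, r in enumerate(table.records) if r.gene_label in model_labels]
    if not hits:
        return []
    blocks: list[list[int]] = [[hits[0]]]
    for prev, cur in zip(hits, hits[1:]):
        a, b = table.records[prev], table.records[cur]
        if a.replicon_id == b.replicon_id and _intergenic_gap(a, b) < threshold:
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    return blocks


def cluster_region(
    table: GeneOrderTable,
    model: OperonClusterModel,
    threshold: int = DISTANCE_THRESHOLD_BP,
) -> list[int]:
    """Indices of the genome's main cluster run.

    The block carrying the most distinct model genes wins; a gene with
    several copies is represented by the copy inside it.
    """
    blocks = cluster_blocks(table, model, threshold)
    if not blocks:
        return []
    # most distinct model genes wins; ties broken by block size then position
    return max(
        blocks,
        key=lambda blk: (
            len({table.records[i].gene_label for i in blk}),
            len(blk),
            -blk[0],
        ),
    )


def resolve_copy(
    table: GeneOrderTable,
    label: str,
    region: list[int] | None = None,
) -> GeneRecord | None:
    """The genome's representative copy of a gene: in-cluster copy if any."""
    copies = [(i, r) for i, r in enumerate(table.records) if r.gene_label == label]
    if not copies:
        return None
    if region:
        region_set = set(region)
        for i, r in copies:
            if i in region_set:
                return r
    return copies[0][1]


def pair_state(
    pair: tuple[str, str],
    table: GeneOrderTable,
    distance_threshold: int = DISTANCE_THRESHOLD_BP,
    model: OperonClusterModel | None = None,
    region: list[int] | None = None,
) -> tuple[AdjacencyState, int | None, int | None]:
    """Score one cluster gene pair in one genome.

    Returns ``(state, gap_bp, intervening_count)``; the two auxiliaries are
    None for DELETED pairs (and gap/count are meaningless across replicons,
    where they are also None).  Symmetric in the order of the pair.
    """
    if len(table) == 0:
        raise ValueError(f"genome {table.genome_id}: empty gene-order table")
    if region is None and model is not None:
        region = cluster_region(table, model, distance_threshold)
    a = resolve_copy(table, pair[0], region)
    b = resolve_copy(table, pair[1], region)
    if a is None or b is None:
        return AdjacencyState.DELETED, None, None
    if a.replicon_id != b.replicon_id:
        return AdjacencyState.DISCONNECTED, None, None
    gap = _intergenic_gap(a, b)
    left, right = (a, b) if a.start <= b.start else (b, a)
    intervening = sum(
        1
        for r in table.records
        if r.replicon_id == a.replicon_id and r.start > left.end and r.end < right.start
    )
    if gap >= distance_threshold:
        return AdjacencyState.DISCONNECTED, gap, intervening
    return AdjacencyState.CONNECTED, gap, intervening


@dataclass
class PairStateMatrix:
    """(adjacent gene pair x genome) -> adjacency state, plus gap/count."""

    pairs: list[tuple[str, str]]
    genomes: list[str]
    states: dict[tuple[tuple[str, str], str], AdjacencyState] = field(default_factory=dict)
    gap_bp: dict[tuple[tuple[str, str], str], int] = field(default_factory=dict)
    intervening: dict[tuple[tuple[str, str], str], int] = field(default_factory=dict)

    def state(self, pair: tuple[str, str], genome: str) -> AdjacencyState:
        return self.states[(pair, genome)]

    def leaf_states(self, pair: tuple[str, str]) -> dict[str, AdjacencyState]:
        return {g: self.states[(pair, g)] for g in self.genomes}

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            g: [self.states[(p, g)].value for p in self.pairs] for g in self.genomes
        }
        index = [f"{a}--{b}" for a, b in self.pairs]
        return pd.DataFrame(data, index=index)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="pair")


def build_state_matrix(
    tables: list[GeneOrderTable],
    model: OperonClusterModel,
    threshold: int = DISTANCE_THRESHOLD_BP,
) -> PairStateMatrix:
    """Complete pair-state matrix over all genomes, pairs in model order."""
    genome_ids = [t.genome_id for t in tables]
    if len(genome_ids) != len(set(genome_ids)):
        raise ValueError("genome_ids must be unique across tables")
    pairs = model.adjacent_pairs()
    matrix = PairStateMatrix(pairs=pairs, genomes=genome_ids)
    for table in tables:
        region = cluster_region(table, model, threshold)
        if not region:
            logger.warning(
                "genome %s has no cluster genes; scoring all pairs DELETED",
                table.genome_id,
            )
        for pair in pairs:
            if not region:
                state, gap, inter = AdjacencyState.DELETED, None, None
            else:
                state, gap, inter = pair_state(
                    pair, table, threshold, model=model, region=region
                )
            key = (pair, table.genome_id)
            matrix.states[key] = state
            if gap is not None:
                matrix.gap_bp[key] = gap
            if inter is not None:
                matrix.intervening[key] = inter
    return matrix


@dataclass
class SyntenyNeighborhood:
    """Up to ``window`` genes flanking a focal gene on each side."""

    genome_id: str
    focal: str
    upstream: list[str]  # chromosomal order, nearest last
    downstream: list[str]  # nearest first


def extract_neighborhood(
    table: GeneOrderTable,
    focal: str,
    window: int = 5,
    model: OperonClusterModel | None = None,
) -> SyntenyNeighborhood:
    """Local synteny context of a gene, truncated at replicon ends."""
    region = cluster_region(table, model) if model is not None else None
    rec = resolve_copy(table, focal, region)
    if rec is None:
        raise ValueError(f"gene {focal!r} absent from genome {table.genome_id}")
    replicon = table.replicon(rec.replicon_id)
    idx = next(i for i, r in enumerate(replicon) if r is rec)
    upstream = [r.gene_label for r in replicon[max(0, idx - window): idx]]
    downstream = [r.gene_label for r in replicon[idx + 1: idx + 1 + window]]
    return SyntenyNeighborhood(
        genome_id=table.genome_id, focal=focal, upstream=upstream, downstream=downstream
    )


def count_gene_copies(
    tables: list[GeneOrderTable],
    label: str,
    model: OperonClusterModel,
) -> dict[str, dict[str, int]]:
    """Per-genome copy counts of a gene, split by cluster membership.

    Cluster membership means lying inside the genome's main run of cluster
    genes; this is the classification used to type duplicate ribosomal genes
    (e.g. an in-operon rpmJ1 vs. a distal rpmJ2 copy).
    """
    if not label:
        raise ValueError("label must be non-empty")
    out: dict[str, dict[str, int]] = {}
    for table in tables:
        region = set(cluster_region(table, model))
        n_in = sum(
            1
            for i, r in enumerate(table.records)
            if r.gene_label == label and i in region
        )
        n_total = sum(1 for r in table.records if r.gene_label == label)
        out[table.genome_id] = {
            "n_total": n_total,
            "n_in_cluster": n_in,
            "n_outside": n_total - n_in,
        }
    return out
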