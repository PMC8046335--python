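"""Readers and writers for on-disk artifacts.

Gene orders come in as tab-separated tables (one row per gene) or GFF3;
trees as Newick with integer internal-node supports.  All coordinates are
1-based inclusive (the GFF3 convention), so the intergenic gap between
consecutive genes is ``start(next) - end(prev) - 1``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from .model import GeneOrderTable, GeneRecord
from .trees import SupportTree

if TYPE_CHECKING:  # pragma: no cover
    from .events import AlterationEvent

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_label",
    "read_gene_order_table",
    "write_gene_order_table",
    "read_support_tree",
    "write_event_table",
]

TSV_COLUMNS = ["genome_id", "replicon", "start", "end", "strand", "gene_label", "product"]

# gene symbols are canonically lowercase-initial (rpoB, not RpoB); labels with
# an internal dash (tRNA-Thr) are structured names and left alone
def normalize_label(label: str) -> str:
    label = label.strip()
    if not label or "-" in label:
        return label
    return label[0].lower() + label[1:]


def _parse_tsv(path: Path) -> list[GeneRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"genome_id", "replicon", "start", "end", "strand", "gene_label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: gene-order TSV must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    GeneRecord(
                        genome_id=row["genome_id"],
                        replicon_id=row["replicon"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=row["strand"],
                        gene_label=normalize_label(row["gene_label"]),
                        product=row.get("product") or None,
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return records


GFF3_LABEL_KEYS = ("gene", "Name", "locus_tag")  # attribute precedence
GFF3_FEATURE_TYPES = {"gene", "tRNA"}


def _parse_gff3(path: Path, genome_id: str) -> list[GeneRecord]:
    from gffutils.iterators import DataIterator

    records = []
    for feature in DataIterator(str(path)):
        if feature.featuretype not in GFF3_FEATURE_TYPES:
            continue
        label = None
        for key in GFF3_LABEL_KEYS:
            if key in feature.attributes and feature.attributes[key]:
                label = feature.attributes[key][0]
                break
        if label is None:
            continue
        if feature.featuretype == "tRNA" and not label.startswith("tRNA"):
            label = f"tRNA-{label}"
        product = feature.attributes["product"][0] if "product" in feature.attributes else None
        try:
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=feature.seqid,
                    start=int(feature.start),
                    end=int(feature.end),
                    strand=feature.strand if feature.strand in ("+", "-") else "+",
                    gene_label=normalize_label(label),
                    product=product,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: feature {label!r}: {exc}") from exc
    return records


def read_gene_order_table(
    path, dialect: str = "tsv", genome_id: str | None = None
) -> list[GeneOrderTable]:
    """Read one or more per-genome gene-order tables from a TSV or GFF3 file.

    A TSV file may hold several genomes (one table per distinct genome_id);
    a GFF3 file holds one genome, named ``genome_id`` (default: file stem).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        records = _parse_tsv(path)
    elif dialect == "gff3":
        records = _parse_gff3(path, genome_id or path.stem)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'gff3'")
    by_genome: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    return [GeneOrderTable(genome_id=g, records=rs) for g, rs in sorted(by_genome.items())]


def write_gene_order_table(tables: Iterable[GeneOrderTable], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for table in tables:
            for r in table.records:
                writer.writerow(
                    [r.genome_id, r.replicon_id, r.start, r.end, r.strand,
                     r.gene_label, r.product or ""]
                )


def read_support_tree(path) -> SupportTree:
    """Read a rooted Newick tree with integer internal-node supports."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return SupportTree.from_newick(str(path), is_path=True)


EVENT_COLUMNS = ["event_id", "branch_id", "type", "subtype", "genes", "operon_pair", "notes"]


def write_event_table(
    events: "Iterable[AlterationEvent]", path, tree: SupportTree | None = None
) -> None:
    """Write placed events as TSV, ordered by branch preorder then event_id."""
    events = list(events)
    for ev in events:
        if not ev.branch_id:
            raise ValueError(f"event {ev.event_id} has no branch assignment")
    if tree is not None:
        order = {bid: i for i, bid in enumerate(tree.preorder_branch_ids())}
        events.sort(key=lambda e: (order.get(e.branch_id, len(order)), e.event_id))
    else:
        events.sort(key=lambda e: (e.branch_id, e.event_id))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            writer.writerow(
                [ev.event_id, ev.branch_id, ev.type, ev.subtype,
                 ",".join(ev.genes), ev.operon_pair, ev.notes or ""]
            )
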