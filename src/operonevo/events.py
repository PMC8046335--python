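"""Alteration events: diff extant genomes against the ancestor and place events.

Alterations fall into the two-class taxonomy used throughout:

* **deletions** remove a gene from an operon but leave the operon-operon
  concatenation intact — subtype ``gene_loss`` (no copy left anywhere) or
  ``gene_translocation`` (a homologous copy exists elsewhere in the genome);
* **rearrangements** change operon structure or concatenation — subtypes
  ``insertion`` (novel genes between cluster genes, still < 10 kb),
  ``transposon_integration`` (an insertion whose payload looks like a
  transposable element), ``full_disconnection`` (>= 10 kb separation or a
  replicon split) and ``inversion`` (a cluster segment on the minority
  strand).

Shared alterations are merged into *novel-neighborhood characters* and
placed on the tree under a single-origin (Dollo/dominant) assumption: each
character arises exactly once on the branch subtending the MRCA of the
genomes carrying it; carriers' descendants that lack it are explained by
secondary losses, which are recorded but kept out of headline totals.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import dendropy

from .adjacency import (
    AdjacencyState,
    DISTANCE_THRESHOLD_BP,
    cluster_blocks,
    cluster_region,
    extract_neighborhood,
    pair_state,
    resolve_copy,
)
from .model import GeneOrderTable, OperonClusterModel
from .reconstruct import AncestralCluster
from .trees import SupportTree, branch_id, clade_leaves

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationEvent",
    "RawAlteration",
    "NovelNeighborhoodCharacter",
    "TRANSPOSASE_KEYWORDS",
    "looks_like_transposase",
    "diff_to_ancestor",
    "collect_neighborhood_characters",
    "place_events",
    "select_best_tree",
    "summarize_events",
]

DELETION_SUBTYPES = {"gene_loss", "gene_translocation"}
REARRANGEMENT_SUBTYPES = {
    "insertion",
    "transposon_integration",
    "full_disconnection",
    "inversion",
}

TRANSPOSASE_KEYWORDS = ("transposase", "insertion sequence", "tnp", "is")


def looks_like_transposase(
    label: str, product: str | None = None, keywords=TRANSPOSASE_KEYWORDS
) -> bool:
    """Keyword test for transposable-element genes (tnpA, IS26, 'transposase ...')."""
    lab = label.lower()
    for kw in keywords:
        if kw in ("is", "tnp"):
            if lab.startswith(kw) and (len(lab) == len(kw) or not lab[len(kw)].isalpha()
                                       or kw == "tnp"):
                return True
        elif kw in lab:
            return True
    if product:
        prod = product.lower()
        for kw in keywords:
            if len(kw) > 3 and kw in prod:
                return True
    return False


@dataclass
class RawAlteration:
    """One deviation of one genome from the ancestral arrangement."""

    genome_id: str
    subtype: str
    junction: tuple[str, ...]  # flanking ancestral gene(s) or host operon genes
    payload: tuple[str, ...]  # deleted genes or minimal inserted segment
    operon_pair: str
    context: tuple[str, ...] = ()  # novel flanking labels (disconnections)

    def character_key(self) -> tuple:
        """Identity for merging across genomes; orientation-insensitive payload."""
        pay = min(self.payload, tuple(reversed(self.payload)))
        ctx = min(self.context, tuple(reversed(self.context)))
        return (self.subtype, self.junction, pay, ctx)


@dataclass
class NovelNeighborhoodCharacter:
    """A derived arrangement shared by >= 1 genome, merged across the data set."""

    subtype: str
    junction: tuple[str, ...]
    payload: tuple[str, ...]
    operon_pair: str
    present: set[str] = field(default_factory=set)
    context: tuple[str, ...] = ()


@dataclass
class AlterationEvent:
    """A typed, branch-placed alteration event."""

    event_id: str
    type: str  # deletion | rearrangement | secondary_loss
    subtype: str
    operon_pair: str
    genes: tuple[str, ...]
    branch_id: str = ""
    supporting_taxa: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.subtype in DELETION_SUBTYPES and self.type != "deletion":
            raise ValueError(f"subtype {self.subtype} requires type=deletion")
        if self.subtype in REARRANGEMENT_SUBTYPES and self.type != "rearrangement":
            raise ValueError(f"subtype {self.subtype} requires type=rearrangement")


def _event_type(subtype: str) -> str:
    if subtype in DELETION_SUBTYPES:
        return "deletion"
    if subtype in REARRANGEMENT_SUBTYPES:
        return "rearrangement"
    return "secondary_loss"


def diff_to_ancestor(
    table: GeneOrderTable,
    ancestral: AncestralCluster,
    model: OperonClusterModel,
    threshold: int = DISTANCE_THRESHOLD_BP,
    window: int = 5,
    transposase_keywords=TRANSPOSASE_KEYWORDS,
) -> list[RawAlteration]:
    """Raw alterations of one genome relative to the ancestral cluster.

    Consecutive absent genes merge into a single deletion alteration (the
    classic two-gene rplJL deletion is one event).  Classification
    precedence at a junction: full_disconnection > insertion > inversion.
    """
    if not ancestral.genes:
        raise ValueError("ancestral cluster is empty")
    alterations: list[RawAlteration] = []
    region = cluster_region(table, model, threshold)
    genes = [g for g in ancestral.genes if g not in model.excluded_labels]

    # Which blocks of model genes still count as cluster fragments?  The
    # main block always does.  A distal block of >= 2 model genes is a
    # disconnection fragment (still "in the cluster") unless the main block
    # bridges directly over its gene run — then the run was excised from an
    # intact concatenation and the block is a translocated outside copy
    # (the rplJL pattern).  Solitary distal copies are outside homologs.
    main_idx = set(region)
    main_labels = {table.records[i].gene_label for i in region}
    order = model.all_labels  # full cluster order, excluded genes included
    pos_full = {g: i for i, g in enumerate(order)}
    cluster_idx = set(main_idx)
    for blk in cluster_blocks(table, model, threshold):
        if set(blk) <= main_idx:
            continue
        blk_genes = {table.records[i].gene_label for i in blk} & set(pos_full)
        if len(blk_genes) < 2:
            continue
        pos = sorted(pos_full[g] for g in blk_genes)
        contiguous = pos == list(range(pos[0], pos[-1] + 1))
        excised = False
        if contiguous and 0 < pos[0] and pos[-1] < len(order) - 1:
            # nearest informative (non-excluded) flanks of the excised run
            left = next(
                (order[i] for i in range(pos[0] - 1, -1, -1)
                 if order[i] not in model.excluded_labels), None,
            )
            right = next(
                (order[i] for i in range(pos[-1] + 1, len(order))
                 if order[i] not in model.excluded_labels), None,
            )
            if left in main_labels and right in main_labels:
                bridged, _, _ = pair_state(
                    (left, right), table, threshold, region=region
                )
                excised = bridged == AdjacencyState.CONNECTED
        if not excised:
            cluster_idx |= set(blk)

    def in_cluster(label: str) -> bool:
        return any(
            i in cluster_idx
            for i, r in enumerate(table.records)
            if r.gene_label == label
        )

    def outside_copies(label: str) -> int:
        return sum(
            1
            for i, r in enumerate(table.records)
            if r.gene_label == label and i not in cluster_idx
        )

    # --- deletions: runs of consecutive ancestral genes absent from the cluster
    absent = [g for g in genes if not in_cluster(g)]
    absent_set = set(absent)
    run: list[str] = []
    runs: list[list[str]] = []
    for g in genes:
        if g in absent_set:
            run.append(g)
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)
    for run in runs:
        if len(run) == len(genes):
            continue  # whole cluster missing: scored as DELETED states upstream
        has_copy = any(outside_copies(g) > 0 for g in run)
        subtype = "gene_translocation" if has_copy else "gene_loss"
        host = model.operon_of(run[0]) or "?"
        alterations.append(
            RawAlteration(
                genome_id=table.genome_id,
                subtype=subtype,
                junction=(host,),
                payload=tuple(run),
                operon_pair=host,
            )
        )

    # --- junction alterations between consecutive *present* ancestral genes
    present = [g for g in genes if g not in absent_set]
    for a, b in zip(present, present[1:]):
        state, gap, intervening = pair_state(
            (a, b), table, threshold, model=model, region=region
        )
        opair = model.junction_name(a, b)
        if state == AdjacencyState.DISCONNECTED:
            ctx: list[str] = []
            for focal in (a, b):
                try:
                    nb = extract_neighborhood(table, focal, window, model=model)
                    ctx.extend(
                        l for l in nb.upstream + nb.downstream
                        if l not in model.label_set
                    )
                except ValueError:
                    pass
            alterations.append(
                RawAlteration(
                    genome_id=table.genome_id,
                    subtype="full_disconnection",
                    junction=(a, b),
                    payload=(),
                    operon_pair=opair,
                    context=tuple(ctx[: 2 * window]),
                )
            )
        elif state == AdjacencyState.CONNECTED and intervening:
            rec_a = resolve_copy(table, a, region)
            rec_b = resolve_copy(table, b, region)
            left_rec, right_rec = (
                (rec_a, rec_b) if rec_a.start <= rec_b.start else (rec_b, rec_a)
            )
            inserted = [
                r
                for r in table.records
                if r.replicon_id == rec_a.replicon_id
                and r.start > left_rec.end
                and r.end < right_rec.start
                and r.gene_label not in model.label_set
            ]
            if not inserted:
                continue
            payload = tuple(r.gene_label for r in inserted)
            is_tnp = any(
                looks_like_transposase(r.gene_label, r.product, transposase_keywords)
                for r in inserted
            )
            alterations.append(
                RawAlteration(
                    genome_id=table.genome_id,
                    subtype="transposon_integration" if is_tnp else "insertion",
                    junction=(a, b),
                    payload=payload,
                    operon_pair=opair,
                )
            )

    # --- inversions: maximal minority-strand runs of cluster genes
    region_records = [table.records[i] for i in region]
    model_in_region = [r for r in region_records if r.gene_label in set(genes)]
    if model_in_region:
        strands = Counter(r.strand for r in model_in_region)
        consensus = strands.most_common(1)[0][0]
        if len(strands) > 1:
            inv_run: list[str] = []
            for r in model_in_region + [None]:  # sentinel flushes the last run
                if r is not None and r.strand != consensus:
                    inv_run.append(r.gene_label)
                elif inv_run:
                    host = model.operon_of(inv_run[0]) or "?"
                    alterations.append(
                        RawAlteration(
                            genome_id=table.genome_id,
                            subtype="inversion",
                            junction=(host,),
                            payload=tuple(inv_run),
                            operon_pair=host,
                        )
                    )
                    inv_run = []
    return alterations


def collect_neighborhood_characters(
    raw: list[RawAlteration], window: int = 5
) -> list[NovelNeighborhoodCharacter]:
    """Merge identical alterations across genomes into presence-mapped characters.

    Identity = (subtype, junction, payload, novel context), with payload and
    context compared orientation-insensitively; the same inserted segment at
    a different junction is a different character.
    """
    by_key: dict[tuple, NovelNeighborhoodCharacter] = {}
    for alt in raw:
        key = alt.character_key()
        if key not in by_key:
            by_key[key] = NovelNeighborhoodCharacter(
                subtype=alt.subtype,
                junction=alt.junction,
                payload=alt.payload,
                operon_pair=alt.operon_pair,
                context=alt.context,
            )
        by_key[key].present.add(alt.genome_id)
    return [by_key[k] for k in sorted(by_key, key=repr)]


def _absent_subtrees(node: dendropy.Node, present: set[str]) -> list[dendropy.Node]:
    """Maximal subtrees under ``node`` containing no presence leaf."""
    out: list[dendropy.Node] = []
    for child in node.child_nodes():
        if clade_leaves(child) & present:
            out.extend(_absent_subtrees(child, present))
        else:
            out.append(child)
    return out


def place_events(
    tree: SupportTree,
    characters: list[NovelNeighborhoodCharacter],
    dominance: bool = True,
) -> tuple[list[AlterationEvent], list[AlterationEvent], list[NovelNeighborhoodCharacter]]:
    """Dollo placement: one gain per character at the MRCA stem, plus losses.

    Returns ``(events, secondary_losses, conflicts)``.  With
    ``dominance=False``, characters whose carriers are not a complete clade
    are returned as conflicts instead of being placed.
    """
    leaves = set(tree.leaf_names)
    events: list[AlterationEvent] = []
    losses: list[AlterationEvent] = []
    conflicts: list[NovelNeighborhoodCharacter] = []
    n_ev = n_loss = 0
    for char in characters:
        present = char.present & leaves
        if not present:
            raise ValueError(
                f"character {char.subtype}@{char.junction} present in zero tree leaves"
            )
        mrca = tree.mrca(present) if len(present) > 1 else next(
            lf for lf in tree.tree.leaf_node_iter() if lf.taxon.label in present
        )
        clade = clade_leaves(mrca)
        if not dominance and clade != present:
            conflicts.append(char)
            continue
        n_ev += 1
        events.append(
            AlterationEvent(
                event_id=f"EV{n_ev:03d}",
                type=_event_type(char.subtype),
                subtype=char.subtype,
                operon_pair=char.operon_pair,
                genes=char.payload or char.junction,
                branch_id=branch_id(mrca),
                supporting_taxa=frozenset(present),
            )
        )
        for sub in _absent_subtrees(mrca, present):
            n_loss += 1
            losses.append(
                AlterationEvent(
                    event_id=f"LS{n_loss:03d}",
                    type="secondary_loss",
                    subtype="secondary_loss",
                    operon_pair=char.operon_pair,
                    genes=char.payload or char.junction,
                    branch_id=branch_id(sub),
                    supporting_taxa=frozenset(),
                    notes=f"loss of EV{n_ev:03d}",
                )
            )
    return events, losses, conflicts


def select_best_tree(
    candidate_trees: list[SupportTree],
    characters: list[NovelNeighborhoodCharacter],
) -> tuple[SupportTree, list[dict]]:
    """Pick the tree explaining the characters with the fewest alterations.

    Trees are ranked by total alterations (gains + implied secondary losses)
    ascending, then mean internal bootstrap support descending.  The full
    ranking is returned alongside the winner.
    """
    if not candidate_trees:
        raise ValueError("need at least one candidate tree")
    leafsets = {frozenset(t.leaf_names) for t in candidate_trees}
    if len(leafsets) > 1:
        raise ValueError("candidate trees have different leaf sets")
    ranking = []
    for i, tree in enumerate(candidate_trees):
        events, losses, _ = place_events(tree, characters, dominance=True)
        ranking.append(
            {
                "tree_index": i,
                "n_events": len(events),
                "n_losses": len(losses),
                "total_alterations": len(events) + len(losses),
                "mean_support": tree.mean_internal_support(),
            }
        )
    ranking.sort(key=lambda r: (r["total_alterations"], -r["mean_support"]))
    for r in ranking:
        logger.info(
            "tree %d: %d alterations, mean support %.1f",
            r["tree_index"], r["total_alterations"], r["mean_support"],
        )
    return candidate_trees[ranking[0]["tree_index"]], ranking


def summarize_events(
    events: list[AlterationEvent],
    losses: list[AlterationEvent] | None = None,
    count_losses: bool = False,
) -> dict:
    """Deterministic event summary: headline totals count primary events only."""
    primary = [e for e in events if e.type in ("deletion", "rearrangement")]
    if count_losses and losses:
        primary = primary + list(losses)
    n_del = sum(1 for e in primary if e.type == "deletion")
    n_rea = sum(1 for e in primary if e.type == "rearrangement")
    by_subtype = Counter(e.subtype for e in primary)
    per_branch: dict[str, int] = defaultdict(int)
    for e in primary:
        per_branch[e.branch_id] += 1
    breaking = ("insertion", "transposon_integration", "full_disconnection")
    per_pair: dict[str, int] = defaultdict(int)
    for e in primary:
        if e.subtype in breaking and "-" in e.operon_pair:
            per_pair[e.operon_pair] += 1
    n_insertion_like = by_subtype["insertion"] + by_subtype["transposon_integration"]
    return {
        "n_total": len(primary),
        "n_deletions": n_del,
        "n_rearrangements": n_rea,
        "by_subtype": dict(sorted(by_subtype.items())),
        "per_branch": dict(sorted(per_branch.items())),
        "concatenation_breaking_per_operon_pair": dict(sorted(per_pair.items())),
        "fraction_insertion_rearrangements": (
            n_insertion_like / n_rea if n_rea else 0.0
        ),
        "n_secondary_losses": len(losses or []),
    }
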