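"""Synthetic gene-order evolution along a phylogeny, with a ground-truth log.

A cluster of ordered operons evolves along a Yule tree under independent
per-branch Poisson processes of: gene deletion (optionally leaving a
homologous copy at a distant locus), small gene insertions at inter-operon
junctions, full disconnection of two operons (preferentially at junctions
already invaded by an insertion — the invasion-separation pattern),
segment inversion, and transposon integration.  Leaves are emitted as
coordinate-bearing gene-order tables; the TruthLog records every applied
event with enough detail that replaying it reproduces the leaf tables
byte-identically.

Random streams are per-branch (derived from the seed and the branch id), so
adding taxa does not reshuffle the events of unrelated branches.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .model import GeneOrderTable, GeneRecord, OperonClusterModel, default_cluster_model
from .trees import SupportTree, branch_id

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthLog",
    "simulate_tree",
    "evolve_cluster",
    "replay_log",
    "perturb_gene_tree",
    "score_recovery",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator (rates are events per unit branch length)."""

    n_taxa: int = 24
    seed: int = 0
    tree_model: str = "yule"
    branch_scale: float = 0.05  # mean branch length, substitutions/site
    r_insertion: float = 1.0
    r_deletion: float = 1.0
    r_disconnection: float = 0.5
    r_inversion: float = 0.25
    r_transposon: float = 0.25
    p_homolog_copy: float = 0.5
    invasion_bias: float = 5.0  # weight multiplier at previously invaded junctions
    insert_size_geom_p: float = 0.5
    gene_len_mean: float = 900.0
    gene_len_sd: float = 200.0
    intergenic_gap_mean: float = 100.0
    far_locus_offset: int = 50_000  # bp between loci; must exceed 10 kb

    def __post_init__(self) -> None:
        rates = (self.r_insertion, self.r_deletion, self.r_disconnection,
                 self.r_inversion, self.r_transposon)
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be >= 0")
        if not 0 <= self.p_homolog_copy <= 1:
            raise ValueError("p_homolog_copy must be in [0, 1]")
        if not 0 < self.insert_size_geom_p <= 1:
            raise ValueError("insert_size_geom_p must be in (0, 1]")
        if self.far_locus_offset <= 10_000:
            raise ValueError("far_locus_offset must exceed 10,000 bp")


@dataclass(frozen=True)
class TruthEvent:
    branch_id: str
    subtype: str
    payload: tuple[str, ...]
    junction: tuple[str, ...]
    # replay parameters: structural coordinates of the edit
    locus: int = 0
    position: int = 0
    strands: tuple[str, ...] = ()
    homolog_copy: bool = False
    span: int = 0  # inverted-segment length in genes (inversions only)


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)
    ancestral_labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.events)

    def primary_events(self) -> list[TruthEvent]:
        return list(self.events)


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(n_taxa: int, seed: int, branch_scale: float = 0.05) -> SupportTree:
    """Yule (pure-birth) tree, rescaled to a given mean branch length.

    Leaves are named g01..gNN in preorder; all supports are set to 100 so
    support-collapsing is a no-op unless the caller lowers them.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    tree.is_rooted = True
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length]
    scale = branch_scale / (sum(lengths) / len(lengths)) if lengths else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scale
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            i += 1
            node.taxon.label = f"g{i:02d}"
        elif node.parent_node is not None:
            node.label = "100"
    return SupportTree(tree)


# ---------------------------------------------------------------------------
# cluster evolution

_EVENT_KINDS = ("insertion", "deletion", "disconnection", "inversion", "transposon")


@dataclass
class _Gene:
    label: str
    strand: str


Arrangement = list  # list[list[_Gene]]: ordered loci, each an ordered gene list


def _branch_rng(seed: int, bid: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(bid.encode())])


def _main_locus(loci: Arrangement, model_labels: frozenset[str]) -> int:
    """Index of the locus carrying the most model genes (the cluster)."""
    best, best_n = 0, -1
    for i, locus in enumerate(loci):
        n = sum(1 for g in locus if g.label in model_labels)
        if n > best_n:
            best, best_n = i, n
    return best


def _interoperon_junctions(
    locus: list[_Gene], model: OperonClusterModel
) -> list[tuple[int, bool]]:
    """(position, invaded) pairs; position i = the junction after gene i.

    A junction joins the last model gene of one operon to the first model
    gene of a different operon; intervening non-model genes mark it invaded.
    """
    model_positions = [
        (i, model.operon_of(g.label)) for i, g in enumerate(locus)
        if g.label in model.label_set
    ]
    out = []
    for (i, op_a), (j, op_b) in zip(model_positions, model_positions[1:]):
        if op_a != op_b:
            out.append((i, j - i > 1))
    return out


def _apply_insertion(
    loci: Arrangement, ev: TruthEvent
) -> None:
    locus = loci[ev.locus]
    genes = [_Gene(l, s) for l, s in zip(ev.payload, ev.strands)]
    loci[ev.locus] = locus[: ev.position + 1] + genes + locus[ev.position + 1:]


def _apply_deletion(loci: Arrangement, ev: TruthEvent) -> None:
    locus = loci[ev.locus]
    assert locus[ev.position].label == ev.payload[0]
    del locus[ev.position]
    if ev.homolog_copy:
        loci.append([_Gene(ev.payload[0], "+")])


def _apply_disconnection(loci: Arrangement, ev: TruthEvent) -> None:
    locus = loci[ev.locus]
    loci[ev.locus] = locus[: ev.position + 1]
    loci.append(locus[ev.position + 1:])


def _apply_inversion(loci: Arrangement, ev: TruthEvent) -> None:
    locus = loci[ev.locus]
    i, k = ev.position, ev.span or len(ev.payload)
    segment = locus[i: i + k][::-1]
    for g in segment:
        g.strand = "+" if g.strand == "-" else "-"
    loci[ev.locus] = locus[:i] + segment + locus[i + k:]


_APPLY = {
    "insertion": _apply_insertion,
    "transposon_integration": _apply_insertion,
    "gene_loss": _apply_deletion,
    "gene_translocation": _apply_deletion,
    "full_disconnection": _apply_disconnection,
    "inversion": _apply_inversion,
}


def _draw_branch_events(
    loci: Arrangement,
    model: OperonClusterModel,
    config: SimulationConfig,
    bid: str,
    branch_length: float,
) -> list[TruthEvent]:
    """Draw and apply this branch's events; returns the log entries."""
    rng = _branch_rng(config.seed, bid)
    tag = zlib.crc32(bid.encode()) % 99991  # stable novel-label namespace
    rates = {
        "insertion": config.r_insertion,
        "deletion": config.r_deletion,
        "disconnection": config.r_disconnection,
        "inversion": config.r_inversion,
        "transposon": config.r_transposon,
    }
    queue: list[str] = []
    for kind in _EVENT_KINDS:
        queue.extend([kind] * rng.poisson(rates[kind] * branch_length))
    queue = [queue[i] for i in rng.permutation(len(queue))]
    log: list[TruthEvent] = []
    counters = {"ins": 0, "tnp": 0}
    for kind in queue:
        main = _main_locus(loci, model.label_set)
        locus = loci[main]
        if kind in ("insertion", "transposon"):
            junctions = _interoperon_junctions(locus, model)
            if not junctions:
                continue
            pos, _ = junctions[rng.integers(len(junctions))]
            if kind == "insertion":
                k = int(rng.geometric(config.insert_size_geom_p))
                labels = tuple(
                    f"ins{tag}x{counters['ins'] + j}" for j in range(k)
                )
                counters["ins"] += k
                subtype = "insertion"
            else:
                labels = (f"tnpA{tag}x{counters['tnp']}",)
                counters["tnp"] += 1
                subtype = "transposon_integration"
            strands = tuple(str(rng.choice(["+", "-"])) for _ in labels)
            a, b = locus[pos].label, next(
                g.label for g in locus[pos + 1:] if g.label in model.label_set
            )
            ev = TruthEvent(bid, subtype, labels, (a, b), main, pos, strands)
        elif kind == "deletion":
            candidates = [
                i for i, g in enumerate(locus) if g.label in model.label_set
            ]
            if len(candidates) < 2:
                continue
            pos = int(candidates[rng.integers(len(candidates))])
            label = locus[pos].label
            has_copy = bool(rng.random() < config.p_homolog_copy)
            subtype = "gene_translocation" if has_copy else "gene_loss"
            ev = TruthEvent(
                bid, subtype, (label,), (model.operon_of(label) or "?",),
                main, pos, homolog_copy=has_copy,
            )
        elif kind == "disconnection":
            junctions = _interoperon_junctions(locus, model)
            if not junctions:
                continue
            weights = np.array(
                [config.invasion_bias if invaded else 1.0 for _, invaded in junctions]
            )
            pos_idx = int(rng.choice(len(junctions), p=weights / weights.sum()))
            pos, _ = junctions[pos_idx]
            a = locus[pos].label
            b = next(g.label for g in locus[pos + 1:] if g.label in model.label_set)
            ev = TruthEvent(bid, "full_disconnection", (), (a, b), main, pos)
        else:  # inversion
            candidates = [
                i for i, g in enumerate(locus) if g.label in model.label_set
            ]
            if not candidates:
                continue
            start_idx = int(rng.integers(len(candidates)))
            n_genes = min(int(rng.geometric(0.5)), 3, len(candidates) - start_idx)
            pos = candidates[start_idx]
            last = candidates[start_idx + n_genes - 1]
            span = last - pos + 1  # embedded non-model genes invert along
            payload = tuple(
                g.label for g in locus[pos: pos + span] if g.label in model.label_set
            )
            if not payload:
                continue
            host = model.operon_of(payload[0]) or "?"
            ev = TruthEvent(bid, "inversion", payload, (host,), main, pos, span=span)
        _APPLY[ev.subtype](loci, ev)
        log.append(ev)
    return log


def _emit_leaf_table(
    leaf: str, loci: Arrangement, config: SimulationConfig
) -> GeneOrderTable:
    rng = _branch_rng(config.seed ^ 0x5EED, f"coords:{leaf}")
    records = []
    cursor = 1000
    for locus in loci:
        for gene in locus:
            length = max(150, int(rng.normal(config.gene_len_mean, config.gene_len_sd)))
            start = cursor
            end = start + length - 1
            records.append(
                GeneRecord(
                    genome_id=leaf,
                    replicon_id="chr",
                    start=start,
                    end=end,
                    strand=gene.strand,
                    gene_label=gene.label,
                )
            )
            cursor = end + 1 + max(1, int(rng.exponential(config.intergenic_gap_mean)))
        cursor += config.far_locus_offset
    return GeneOrderTable(genome_id=leaf, records=records)


def _copy_arrangement(loci: Arrangement) -> Arrangement:
    return [[replace(g) for g in locus] for locus in loci]


def evolve_cluster(
    tree: SupportTree,
    model: OperonClusterModel | None = None,
    config: SimulationConfig | None = None,
) -> tuple[list[GeneOrderTable], TruthLog]:
    """Evolve the cluster down the tree; emit leaf tables and the truth log."""
    model = model or default_cluster_model()
    config = config or SimulationConfig()
    if len(model.operons) < 2:
        raise ValueError("cluster model needs at least two operons")
    ancestral: Arrangement = [[_Gene(l, "+") for l in model.all_labels]]
    log = TruthLog(ancestral_labels=tuple(model.all_labels))
    tables: list[GeneOrderTable] = []

    def descend(node: dendropy.Node, loci: Arrangement) -> None:
        if node.parent_node is not None:
            bid = branch_id(node)
            log.events.extend(
                _draw_branch_events(
                    loci, model, config, bid, tree.branch_length(node),
                )
            )
        if node.is_leaf():
            tables.append(_emit_leaf_table(node.taxon.label, loci, config))
        else:
            for child in node.child_nodes():
                descend(child, _copy_arrangement(loci))

    descend(tree.root, ancestral)
    tables.sort(key=lambda t: t.genome_id)
    return tables, log


def replay_log(
    tree: SupportTree,
    model: OperonClusterModel,
    log: TruthLog,
    config: SimulationConfig,
) -> list[GeneOrderTable]:
    """Re-derive the leaf tables by applying the logged events along the tree.

    Uses no event randomness; coordinates come from the same per-leaf
    streams as the original emission, so output is byte-identical.
    """
    by_branch: dict[str, list[TruthEvent]] = {}
    for ev in log.events:
        by_branch.setdefault(ev.branch_id, []).append(ev)
    tables: list[GeneOrderTable] = []

    def descend(node: dendropy.Node, loci: Arrangement) -> None:
        if node.parent_node is not None:
            for ev in by_branch.get(branch_id(node), []):
                _APPLY[ev.subtype](loci, ev)
        if node.is_leaf():
            tables.append(_emit_leaf_table(node.taxon.label, loci, config))
        else:
            for child in node.child_nodes():
                descend(child, _copy_arrangement(loci))

    descend(tree.root, [[_Gene(l, "+") for l in log.ancestral_labels]])
    tables.sort(key=lambda t: t.genome_id)
    return tables


# ---------------------------------------------------------------------------
# gene-tree perturbation (fixture for the HGT test)


def perturb_gene_tree(
    species_tree: SupportTree, n_spr: int, seed: int
) -> SupportTree:
    """Apply n_spr random subtree-prune-regraft moves; supports set to 100.

    With n_spr = 0 the topology is returned unchanged (as a copy).  Each
    applied move is required to change the unrooted topology, so one move on
    a tree with >= 5 leaves always yields a positive RF distance to the
    original.
    """
    if n_spr < 0:
        raise ValueError("n_spr must be >= 0")
    from .hgt import rf_distance

    rng = random.Random(seed)
    out = species_tree.clone()
    for node in out.internal_nodes():
        node.label = "100"
    for _ in range(n_spr):
        for _attempt in range(50):
            trial = out.clone()
            if _one_spr(trial, rng) and rf_distance(trial, out) > 0:
                out = trial
                break
    return out


def _one_spr(tree: SupportTree, rng: random.Random) -> bool:
    nodes = [
        n
        for n in tree.tree.preorder_node_iter()
        if n.parent_node is not None and n.parent_node.parent_node is not None
    ]
    if not nodes:
        return False
    prune = rng.choice(nodes)
    parent = prune.parent_node
    grand = parent.parent_node
    parent.remove_child(prune)
    sibs = parent.child_nodes()
    if len(sibs) == 1:  # suppress the unifurcation left behind
        sib = sibs[0]
        sib.edge.length = (sib.edge.length or 0.0) + (parent.edge.length or 0.0)
        grand.remove_child(parent)
        grand.add_child(sib)
    subtree_nodes = set(id(n) for n in prune.preorder_iter())
    targets = [
        n
        for n in tree.tree.preorder_node_iter()
        if n.parent_node is not None and id(n) not in subtree_nodes
    ]
    if not targets:
        return False
    target = rng.choice(targets)
    tparent = target.parent_node
    joint = dendropy.Node(label="100")
    tlen = target.edge.length or 0.0
    tparent.remove_child(target)
    tparent.add_child(joint)
    joint.edge.length = tlen / 2
    joint.add_child(target)
    target.edge.length = tlen / 2
    joint.add_child(prune)
    return True


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    truth: TruthLog,
    inferred,
    tree: SupportTree,
    excluded: frozenset[str] = frozenset(),
) -> dict:
    """Precision/recall of inferred events vs. the truth log, greedy 1-to-1.

    Events match on subtype plus payload (junction for disconnections);
    ``branch_exact_frac`` is the fraction of matched events on truth
    branches with >= 2 descendant leaves whose placement is identical.
    Truth events acting only on ``excluded`` labels (genes the analysis
    disregards, e.g. the hyper-variable tufB tRNAs) are not scored.
    """
    clade_size = {}
    for node in tree.tree.preorder_node_iter():
        clade_size[branch_id(node)] = sum(1 for _ in node.leaf_iter())

    def key(subtype, payload, junction):
        if subtype == "full_disconnection":
            return (subtype, tuple(sorted(junction)))
        return (subtype, tuple(sorted(payload)))

    truth_items = [
        (key(ev.subtype, ev.payload, ev.junction), ev.branch_id)
        for ev in truth.primary_events()
        if not (ev.payload and set(ev.payload) <= excluded)
    ]
    inferred_items = [
        (key(ev.subtype, ev.genes, ev.genes), ev.branch_id) for ev in inferred
    ]
    unmatched = list(inferred_items)
    tp = 0
    branch_checked = branch_exact = 0
    for tkey, tbranch in truth_items:
        hit = next((item for item in unmatched if item[0] == tkey), None)
        if hit is None:
            continue
        unmatched.remove(hit)
        tp += 1
        if clade_size.get(tbranch, 0) >= 2:
            branch_checked += 1
            if hit[1] == tbranch:
                branch_exact += 1
    n_truth, n_inferred = len(truth_items), len(inferred_items)
    return {
        "n_truth": n_truth,
        "n_inferred": n_inferred,
        "true_positives": tp,
        "precision": tp / n_inferred if n_inferred else 1.0,
        "recall": tp / n_truth if n_truth else 1.0,
        "branch_exact_frac": branch_exact / branch_checked if branch_checked else 1.0,
    }
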