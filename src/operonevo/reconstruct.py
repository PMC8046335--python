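"""Ancestral connectivity of cluster gene pairs by two-hypothesis parsimony.

For each adjacent gene pair the minimum number of state changes on the
ingroup tree is computed twice: once with the root fixed to CONNECTED
(N_connected) and once fixed to DISCONNECTED (N_disconnected).  The pair is
called ancestrally connected iff N_connected <= N_disconnected AND the
outgroup genomes agree with the connection.  Ties therefore go to the
connected hypothesis.

``min_changes`` is a Sankoff-style dynamic program over the rooted tree
(unit transition costs by default, polytomies handled natively);
``brute_force_min_changes`` enumerates every internal labeling and exists
to validate the DP on small trees.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy

from .adjacency import AdjacencyState, PairStateMatrix
from .model import OperonClusterModel, Operon
from .trees import SupportTree

logger = logging.getLogger(__name__)

__all__ = [
    "PairDecision",
    "AncestralCluster",
    "min_changes",
    "brute_force_min_changes",
    "decide_pair",
    "reconstruct_cluster",
]

STATES = (AdjacencyState.CONNECTED, AdjacencyState.DISCONNECTED, AdjacencyState.DELETED)
_INF = float("inf")


def _unit_cost(a: AdjacencyState, b: AdjacencyState) -> int:
    return 0 if a == b else 1


def min_changes(
    tree: SupportTree,
    leaf_states: dict[str, AdjacencyState],
    root_state: AdjacencyState,
    cost=_unit_cost,
) -> int:
    """Minimum number of state changes on the tree with the root state fixed.

    Dynamic program in postorder: for each node and state, the cheapest cost
    of its subtree given the node takes that state; child contributions are
    ``min over child state (child_cost + transition cost)``, summed over
    children (so multifurcations contribute independently).
    """
    missing = set(tree.leaf_names) - set(leaf_states)
    if missing:
        raise ValueError(f"missing leaf states for: {sorted(missing)}")
    costs: dict[dendropy.Node, dict[AdjacencyState, float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            observed = leaf_states[node.taxon.label]
            costs[node] = {s: (0 if s == observed else _INF) for s in STATES}
        else:
            table = {}
            for s in STATES:
                total = 0.0
                for child in node.child_nodes():
                    total += min(costs[child][t] + cost(s, t) for t in STATES)
                table[s] = total
            costs[node] = table
    result = costs[tree.root][root_state]
    if result == _INF:  # cannot happen with finite cost matrix
        raise ValueError("no labeling consistent with the fixed root state")
    return int(result)


def brute_force_min_changes(
    tree: SupportTree,
    leaf_states: dict[str, AdjacencyState],
    root_state: AdjacencyState,
) -> int:
    """Exhaustive oracle: enumerate all internal labelings with the root fixed."""
    internal = tree.internal_nodes()
    if len(internal) > 12:
        raise ValueError(f"{len(internal)} internal nodes; oracle limited to 12")
    missing = set(tree.leaf_names) - set(leaf_states)
    if missing:
        raise ValueError(f"missing leaf states for: {sorted(missing)}")
    free = [n for n in internal if n is not tree.root]
    best = None
    for labeling in itertools.product(STATES, repeat=len(free)):
        assignment = dict(zip((id(n) for n in free), labeling))
        assignment[id(tree.root)] = root_state

        def state_of(node: dendropy.Node) -> AdjacencyState:
            if node.is_leaf():
                return leaf_states[node.taxon.label]
            return assignment[id(node)]

        changes = sum(
            1
            for node in tree.tree.preorder_node_iter()
            if node.parent_node is not None
            and state_of(node) != state_of(node.parent_node)
        )
        best = changes if best is None else min(best, changes)
    return int(best)


@dataclass
class PairDecision:
    """Verdict on one gene pair's ancestral connectivity."""

    pair: tuple[str, str]
    n_connected: int
    n_disconnected: int
    outgroup_agrees: bool
    verdict: str  # "ancestrally_connected" | "not_connected"

    def __post_init__(self) -> None:
        expected = (
            "ancestrally_connected"
            if self.n_connected <= self.n_disconnected and self.outgroup_agrees
            else "not_connected"
        )
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with decision rule")


def decide_pair(
    tree: SupportTree,
    matrix: PairStateMatrix,
    pair: tuple[str, str],
    outgroup: set[str],
    outgroup_rule: str = "majority",
) -> PairDecision:
    """Apply the two-hypothesis rule with outgroup agreement to one pair.

    The N values are computed on the ingroup subtree only; the outgroup is
    consulted solely for rule 2.  ``outgroup_rule`` is "majority" (CONNECTED
    in at least half of the informative outgroup genomes) or "any" (at least
    one).  With no informative outgroup genome, agreement is False.
    """
    if pair not in matrix.pairs:
        raise ValueError(f"pair {pair} not in state matrix")
    leaves = set(tree.leaf_names)
    outgroup = set(outgroup)
    if not outgroup <= leaves:
        raise ValueError(f"outgroup taxa not in tree: {sorted(outgroup - leaves)}")
    ingroup = sorted(leaves - outgroup)
    if not ingroup:
        raise ValueError("outgroup covers the whole tree; no ingroup left")
    subtree = tree.extract_subtree(ingroup)
    states = {g: matrix.state(pair, g) for g in ingroup}
    n_conn = min_changes(subtree, states, AdjacencyState.CONNECTED)
    n_disc = min_changes(subtree, states, AdjacencyState.DISCONNECTED)

    informative = [
        g
        for g in sorted(outgroup)
        if g in matrix.genomes and matrix.state(pair, g) != AdjacencyState.DELETED
    ]
    n_og_connected = sum(
        1 for g in informative if matrix.state(pair, g) == AdjacencyState.CONNECTED
    )
    if not informative:
        logger.warning("pair %s: no informative outgroup genome; rule 2 fails", pair)
        agrees = False
    elif outgroup_rule == "any":
        agrees = n_og_connected >= 1
    elif outgroup_rule == "majority":
        agrees = n_og_connected * 2 >= len(informative)
    else:
        raise ValueError(f"unknown outgroup_rule {outgroup_rule!r}")

    verdict = (
        "ancestrally_connected" if n_conn <= n_disc and agrees else "not_connected"
    )
    return PairDecision(pair, n_conn, n_disc, agrees, verdict)


@dataclass
class AncestralCluster:
    """The reconstructed ancestral arrangement: retained genes and connected pairs."""

    model: OperonClusterModel
    genes: list[str]  # cluster order, genes inferred present in the ancestor
    connected_pairs: set[tuple[str, str]]

    def adjacencies(self) -> list[tuple[str, str]]:
        """Consecutive retained-gene pairs in ancestral order."""
        return list(zip(self.genes, self.genes[1:]))

    def to_yaml(self, path) -> None:
        retained = set(self.genes)
        ops = [
            Operon(op.name, [g for g in op.genes if g in retained])
            for op in self.model.operons
        ]
        OperonClusterModel(
            operons=[op for op in ops if op.genes],
            excluded_labels=self.model.excluded_labels & retained,
        ).to_yaml(path)


def reconstruct_cluster(
    tree: SupportTree,
    matrix: PairStateMatrix,
    model: OperonClusterModel,
    outgroup: set[str],
    outgroup_rule: str = "majority",
) -> tuple[AncestralCluster, list[PairDecision]]:
    """Decide every model pair and assemble the ancestral cluster.

    A gene is dropped from the ancestral model when both its flanking pairs
    are not_connected AND the gene is DELETED in a majority of ingroup
    genomes (i.e. the data give no evidence it was ancestrally present).
    """
    decisions = [
        decide_pair(tree, matrix, pair, outgroup, outgroup_rule)
        for pair in matrix.pairs
    ]
    by_pair = {d.pair: d for d in decisions}
    labels = model.active_labels
    ingroup = [g for g in matrix.genomes if g in set(tree.leaf_names) - set(outgroup)]

    def majority_deleted(label: str) -> bool:
        flanking = [p for p in matrix.pairs if label in p]
        if not flanking:
            return False
        n_del = sum(
            1
            for g in ingroup
            if all(matrix.state(p, g) == AdjacencyState.DELETED for p in flanking)
        )
        return n_del * 2 > len(ingroup)

    retained = []
    for i, label in enumerate(labels):
        flanking = []
        if i > 0:
            flanking.append((labels[i - 1], label))
        if i < len(labels) - 1:
            flanking.append((label, labels[i + 1]))
        all_disconnected = all(
            by_pair[p].verdict == "not_connected" for p in flanking if p in by_pair
        )
        if flanking and all_disconnected and majority_deleted(label):
            continue
        retained.append(label)

    connected = {
        d.pair for d in decisions if d.verdict == "ancestrally_connected"
    }
    cluster = AncestralCluster(model=model, genes=retained, connected_pairs=connected)
    return cluster, decisions
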