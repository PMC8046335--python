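"""Vertical-descent test: support-collapsed Robinson-Foulds comparison.

A gene tree is compared with its species tree after contracting every
internal edge whose child node has bootstrap support below a threshold
(default 80; the boundary is strict, so exactly 80 is retained).  The
Robinson-Foulds distance is then the size of the symmetric difference of
the two unrooted topologies' non-trivial bipartition sets.  RF = 0 is read
as consistent with vertical descent; any RF > 0 is a conflict, with the
discordant bipartitions listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .trees import SupportTree, node_support

logger = logging.getLogger(__name__)

__all__ = ["RFReport", "collapse_low_support", "rf_distance", "hgt_report"]

BOOTSTRAP_THRESHOLD = 80


@dataclass
class RFReport:
    rf: int
    max_rf: int
    threshold: int
    n_collapsed_gene_tree: int
    n_collapsed_species_tree: int
    verdict: str  # consistent_vertical | conflict
    discordant_bipartitions: list[frozenset[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rf": self.rf,
            "max_rf": self.max_rf,
            "threshold": self.threshold,
            "n_collapsed_gene_tree": self.n_collapsed_gene_tree,
            "n_collapsed_species_tree": self.n_collapsed_species_tree,
            "verdict": self.verdict,
            "discordant_bipartitions": [
                sorted(b) for b in sorted(self.discordant_bipartitions, key=sorted)
            ],
        }


def collapse_low_support(
    tree: SupportTree, threshold: int = BOOTSTRAP_THRESHOLD
) -> tuple[SupportTree, int]:
    """Contract internal edges whose child support is below the threshold.

    Absent (or non-numeric) supports count as below threshold, with a
    warning.  Leaves are never touched; contracted branch lengths are
    discarded — downstream comparisons are topology-only.  Returns the
    collapsed copy and the number of contracted edges.
    """
    out = tree.clone()
    to_collapse = []
    for node in out.internal_nodes(exclude_root=True):
        support = node_support(node)
        if support is None:
            logger.warning(
                "internal node without support treated as below threshold %d",
                threshold,
            )
            to_collapse.append(node)
        elif support < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out, len(to_collapse)


def rf_distance(t1: SupportTree, t2: SupportTree) -> int:
    """Robinson-Foulds distance between two trees on identical leaf sets."""
    l1, l2 = set(t1.leaf_names), set(t2.leaf_names)
    if l1 != l2:
        raise ValueError(
            f"leaf-set mismatch: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    b1 = t1.nontrivial_bipartitions()
    b2 = t2.nontrivial_bipartitions()
    return len(b1 ^ b2)


def hgt_report(
    gene_tree: SupportTree,
    species_tree: SupportTree,
    threshold: int = BOOTSTRAP_THRESHOLD,
    collapse: str = "both",
) -> RFReport:
    """Collapse both trees at the threshold, compute RF, and give the verdict.

    ``collapse`` may restrict collapsing to one side ("gene", "species") or
    disable it ("none"); the default treats both trees symmetrically.
    """
    if collapse not in ("both", "gene", "species", "none"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    n_cg = n_cs = 0
    g, s = gene_tree, species_tree
    if collapse in ("both", "gene"):
        g, n_cg = collapse_low_support(gene_tree, threshold)
    if collapse in ("both", "species"):
        s, n_cs = collapse_low_support(species_tree, threshold)
    bg = g.nontrivial_bipartitions()
    bs = s.nontrivial_bipartitions()
    if set(g.leaf_names) != set(s.leaf_names):
        raise ValueError(
            "leaf-set mismatch between gene tree and species tree: "
            f"{sorted(set(g.leaf_names) ^ set(s.leaf_names))}"
        )
    rf = len(bg ^ bs)
    if not bg and not bs:
        logger.warning(
            "both trees are stars after collapsing; RF=0 is uninformative"
        )
    return RFReport(
        rf=rf,
        max_rf=len(bg) + len(bs),
        threshold=threshold,
        n_collapsed_gene_tree=n_cg,
        n_collapsed_species_tree=n_cs,
        verdict="consistent_vertical" if rf == 0 else "conflict",
        discordant_bipartitions=sorted(bg ^ bs, key=sorted),
    )
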