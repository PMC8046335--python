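"""Rooted support trees: a thin wrapper over dendropy.

Internal-node Newick labels are interpreted as integer bootstrap supports
(0-100).  Branch-comment support dialects (``[&support=...]``) are rejected:
one dialect keeps parsing bit-exact.  Trees are kept rooted as written;
re-rooting is never performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

logger = logging.getLogger(__name__)

__all__ = ["SupportTree", "branch_id", "node_support", "clade_leaves"]


def node_support(node: dendropy.Node) -> int | None:
    """Bootstrap support of an internal node, or None when absent/non-numeric."""
    label = node.label
    if label is None:
        return None
    try:
        value = int(str(label))
    except ValueError:
        return None
    if not 0 <= value <= 100:
        return None
    return value


def clade_leaves(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def branch_id(node: dendropy.Node) -> str:
    """Stable identifier of the branch above ``node``: its sorted clade leaf set."""
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(clade_leaves(node)))


@dataclass
class SupportTree:
    """A rooted tree with branch lengths (subs/site) and 0-100 node supports."""

    tree: dendropy.Tree

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = True) -> "SupportTree":
        if "[&" in (open(source).read() if is_path else source):
            raise ValueError(
                "branch-comment support dialects ([&support=...]) are not "
                "accepted; encode supports as integer internal-node labels"
            )
        kwargs = dict(
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        try:
            if is_path:
                tree = dendropy.Tree.get(path=source, **kwargs)
            else:
                tree = dendropy.Tree.get(data=source, **kwargs)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf names in tree: {exc}") from exc
        self = cls(tree)
        labels = self.leaf_names
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf names in tree: {dupes}")
        for node in tree.preorder_internal_node_iter():
            if node.label is not None and node_support(node) is None:
                logger.warning(
                    "non-numeric internal node label %r treated as absent support",
                    node.label,
                )
        return self

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def clone(self) -> "SupportTree":
        return SupportTree(self.tree.clone(depth=1))

    # -- queries -----------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def internal_nodes(self, exclude_root: bool = False) -> list[dendropy.Node]:
        nodes = [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]
        if exclude_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def preorder_branch_ids(self) -> list[str]:
        return [branch_id(n) for n in self.tree.preorder_node_iter()]

    def mrca(self, leaf_names) -> dendropy.Node:
        leaf_names = set(leaf_names)
        node = self.tree.mrca(taxon_labels=sorted(leaf_names))
        if node is None:
            raise ValueError(f"no MRCA found for {sorted(leaf_names)}")
        return node

    def branch_length(self, node: dendropy.Node) -> float:
        return node.edge.length if node.edge.length is not None else 0.0

    def mean_internal_support(self) -> float:
        vals = [
            node_support(n)
            for n in self.internal_nodes(exclude_root=True)
            if node_support(n) is not None
        ]
        return sum(vals) / len(vals) if vals else 0.0

    # -- manipulation ------------------------------------------------------

    def extract_subtree(self, leaf_names) -> "SupportTree":
        """Restrict to the given leaves (copy); unifurcations suppressed."""
        keep = set(leaf_names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(labels=keep)
        sub.is_rooted = True
        return SupportTree(sub)

    # -- bipartitions (unrooted view) --------------------------------------

    def nontrivial_bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions of the unrooted topology.

        Each is canonicalized as the side NOT containing the lexicographically
        smallest leaf, so sets from different trees on the same leaves compare
        directly.
        """
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        biparts: set[frozenset[str]] = set()
        for node in self.tree.preorder_internal_node_iter():
            if node is self.root:
                continue
            clade = clade_leaves(node)
            side = clade if ref not in clade else all_leaves - clade
            if 1 < len(side) < len(all_leaves) - 1:
                biparts.add(side)
        return biparts
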