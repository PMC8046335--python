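"""Event classification, character merging, Dollo placement and summaries."""

from __future__ import annotations

import pytest

import operonevo as oe
from operonevo.events import (
    NovelNeighborhoodCharacter,
    RawAlteration,
    collect_neighborhood_characters,
    diff_to_ancestor,
    looks_like_transposase,
    place_events,
    select_best_tree,
    summarize_events,
)
from operonevo.reconstruct import AncestralCluster
from operonevo.trees import branch_id, clade_leaves

from conftest import make_table


@pytest.fixture(scope="module")
def ancestral(model):
    return AncestralCluster(
        model=model,
        genes=model.active_labels,
        connected_pairs=set(model.adjacent_pairs()),
    )


def tree_of(newick: str) -> oe.SupportTree:
    return oe.SupportTree.from_newick(newick, is_path=False)


class TestDiffToAncestor:
    def test_ancestral_genome_yields_no_alterations(self, model, ancestral):
        table = make_table("G1", model.all_labels)
        assert diff_to_ancestor(table, ancestral, model) == []

    def test_small_insertion_payload_is_minimal_segment(self, model, ancestral):
        genes = list(model.all_labels)
        at = genes.index("rpsL")  # between the rpoBC and str operons
        genes[at:at] = ["tusD", "tusC", "tusB"]
        alts = diff_to_ancestor(make_table("G1", genes), ancestral, model)
        assert len(alts) == 1
        (alt,) = alts
        assert alt.subtype == "insertion"
        assert alt.payload == ("tusD", "tusC", "tusB")
        assert alt.junction == ("rpoC", "rpsL")
        assert alt.operon_pair == "rpoBC-str"

    def test_translocated_pair_is_one_deletion_with_copy(self, model, ancestral):
        # rplJ-rplL removed from the cluster but present at a distant locus
        genes = [l for l in model.all_labels if l not in ("rplJ", "rplL")]
        genes += [("rplJ", "+", 500_000), "rplL"]
        alts = diff_to_ancestor(make_table("G1", genes), ancestral, model)
        assert len(alts) == 1
        (alt,) = alts
        assert alt.subtype == "gene_translocation"
        assert alt.payload == ("rplJ", "rplL")
        assert alt.operon_pair == "rpoBC"

    def test_lost_gene_without_copy_is_gene_loss(self, model, ancestral):
        genes = [l for l in model.all_labels if l != "rpmJ"]
        alts = diff_to_ancestor(make_table("G1", genes), ancestral, model)
        assert [a.subtype for a in alts] == ["gene_loss"]
        assert alts[0].payload == ("rpmJ",)

    def test_large_separation_is_full_disconnection(self, model, ancestral):
        genes = list(model.all_labels)
        at = genes.index("rpsJ")  # split between the str and S10 operons
        genes[at] = ("rpsJ", "+", 150_000)
        alts = diff_to_ancestor(make_table("G1", genes), ancestral, model)
        assert [a.subtype for a in alts] == ["full_disconnection"]
        assert alts[0].junction == ("tufA", "rpsJ")
        assert alts[0].operon_pair == "str-S10"

    def test_transposase_payload_flags_transposon(self, model, ancestral):
        genes = list(model.all_labels)
        at = genes.index("rpsL")
        genes[at:at] = ["tnpA"]
        alts = diff_to_ancestor(make_table("G1", genes), ancestral, model)
        assert [a.subtype for a in alts] == ["transposon_integration"]

    def test_minority_strand_run_is_inversion(self, model, ancestral):
        genes = []
        for label in model.all_labels:
            if label in ("rplN", "rplX", "rplE"):
                genes.append((label, "-"))
            else:
                genes.append(label)
        # the flipped genes keep their position, only orientation changes
        alts = diff_to_ancestor(make_table("G1", genes), ancestral, model)
        assert [a.subtype for a in alts] == ["inversion"]
        assert alts[0].payload == ("rplN", "rplX", "rplE")

    def test_excluded_genes_are_ignored(self, model, ancestral):
        genes = [l for l in model.all_labels if l != "tRNA-Tyr"]
        assert diff_to_ancestor(make_table("G1", genes), ancestral, model) == []


class TestCharacterCollection:
    def _alt(self, genome, payload=("tusD", "tusC", "tusB"),
             junction=("rpoC", "rpsL")):
        return RawAlteration(
            genome_id=genome, subtype="insertion", junction=junction,
            payload=payload, operon_pair="rpoBC-str",
        )

    def test_identical_alterations_merge(self):
        chars = collect_neighborhood_characters(
            [self._alt(f"G{i}") for i in range(40)]
        )
        assert len(chars) == 1
        assert len(chars[0].present) == 40

    def test_reverse_orientation_merges(self):
        chars = collect_neighborhood_characters(
            [self._alt("G1"), self._alt("G2", payload=("tusB", "tusC", "tusD"))]
        )
        assert len(chars) == 1

    def test_different_payload_same_junction_distinct(self):
        chars = collect_neighborhood_characters(
            [self._alt("G1"), self._alt("G2", payload=("bfd", "bfr"))]
        )
        assert len(chars) == 2

    def test_same_payload_different_junction_distinct(self):
        chars = collect_neighborhood_characters(
            [self._alt("G1"), self._alt("G2", junction=("tufA", "rpsJ"))]
        )
        assert len(chars) == 2


def _char(present, subtype="insertion", payload=("insX",)):
    return NovelNeighborhoodCharacter(
        subtype=subtype, junction=("rpoC", "rpsL"), payload=payload,
        operon_pair="rpoBC-str", present=set(present),
    )


def brute_force_dollo_cost(tree: oe.SupportTree, present: set[str]) -> int:
    """Minimum gains+losses over all single-gain placements (oracle)."""
    best = None
    for node in tree.tree.preorder_node_iter():
        clade = clade_leaves(node)
        if not present <= clade:
            continue

        def losses(n):
            below = clade_leaves(n)
            if not below & present:
                return 1
            if n.is_leaf():
                return 0
            return sum(losses(c) for c in n.child_nodes())

        total = 1 + (0 if node.is_leaf() else sum(losses(c) for c in node.child_nodes()))
        best = total if best is None else min(best, total)
    return best


class TestDolloPlacement:
    TREE = "(((A,B),(C,D)),((E,F),(G,H)));"

    def test_full_clade_gain_no_losses(self):
        tree = tree_of(self.TREE)
        events, losses, _ = place_events(tree, [_char({"A", "B", "C", "D"})])
        assert len(events) == 1 and not losses
        assert events[0].branch_id == "A|B|C|D"

    def test_near_complete_clade_gain_plus_loss(self):
        tree = tree_of(self.TREE)
        events, losses, _ = place_events(tree, [_char({"A", "B", "C"})])
        assert events[0].branch_id == "A|B|C|D"
        assert [l.branch_id for l in losses] == ["D"]

    def test_scattered_presence_counts_absent_subtrees(self):
        tree = tree_of(self.TREE)
        events, losses, _ = place_events(tree, [_char({"A", "H"})])
        assert len(events) == 1
        # gain at the root clade; losses = maximal absent subtrees
        assert len(losses) == brute_force_dollo_cost(tree, {"A", "H"}) - 1

    def test_dollo_is_single_origin_minimal(self):
        """Gain at the carriers' MRCA minimizes gains+losses (<= 10 leaves)."""
        import random

        rng = random.Random(5)
        for rep in range(30):
            tree = oe.simulate_tree(rng.randint(4, 10), rng.randrange(9999))
            leaves = tree.leaf_names
            k = rng.randint(1, len(leaves))
            present = set(rng.sample(leaves, k))
            events, losses, _ = place_events(tree, [_char(present)])
            assert len(events) == 1
            assert 1 + len(losses) == brute_force_dollo_cost(tree, present)

    def test_non_monophyletic_conflict_without_dominance(self):
        tree = tree_of(self.TREE)
        events, losses, conflicts = place_events(
            tree, [_char({"A", "H"})], dominance=False
        )
        assert not events and not losses and len(conflicts) == 1

    def test_character_absent_everywhere_rejected(self):
        tree = tree_of(self.TREE)
        with pytest.raises(ValueError, match="zero"):
            place_events(tree, [_char(set())])


class TestTreeSelection:
    def test_fewest_alterations_wins(self):
        # carriers {A,B} are a clade in t1 (1 gain) but split in t2 (gain+loss)
        t1 = tree_of("(((A:1,B:1)100:1,C:1)100:1,D:1);")
        t2 = tree_of("(((A:1,C:1)100:1,B:1)100:1,D:1);")
        best, ranking = select_best_tree([t1, t2], [_char({"A", "B"})])
        assert best is t1
        assert ranking[0]["total_alterations"] < ranking[1]["total_alterations"]

    def test_support_breaks_ties(self):
        t1 = tree_of("(((A:1,B:1)90:1,C:1)90:1,D:1);")
        t2 = tree_of("(((A:1,B:1)99:1,C:1)99:1,D:1);")
        best, _ = select_best_tree([t1, t2], [_char({"A", "B"})])
        assert best is t2

    def test_single_candidate_returned(self):
        t1 = tree_of("((A,B),C);")
        best, ranking = select_best_tree([t1], [_char({"A"})])
        assert best is t1 and len(ranking) == 1

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf"):
            select_best_tree([tree_of("((A,B),C);"), tree_of("((A,B),D);")], [])


class TestSummaries:
    def test_totals_additive_and_order_invariant(self, sim_bundle):
        events = sim_bundle["events"]
        summary = summarize_events(events, sim_bundle["losses"])
        assert summary["n_total"] == summary["n_deletions"] + summary["n_rearrangements"]
        reversed_summary = summarize_events(list(reversed(events)), sim_bundle["losses"])
        assert summary == reversed_summary

    def test_simulation_truth_composition(self, model):
        """Inferred summary classes mirror a deletion+insertion-only truth."""
        tree = oe.simulate_tree(12, 21)
        config = oe.SimulationConfig(
            n_taxa=12, seed=21, r_insertion=1.2, r_deletion=0.8,
            r_disconnection=0, r_inversion=0, r_transposon=0,
        )
        tables, log = oe.evolve_cluster(tree, model, config)
        truth_del = sum(e.subtype in ("gene_loss", "gene_translocation")
                        for e in log.events)
        truth_ins = sum(e.subtype == "insertion" for e in log.events)
        assert truth_del + truth_ins == len(log.events)

        ancestral = AncestralCluster(
            model=model, genes=model.active_labels,
            connected_pairs=set(model.adjacent_pairs()),
        )
        raw = []
        for t in tables:
            raw.extend(diff_to_ancestor(t, ancestral, model))
        events, losses, _ = place_events(
            tree, collect_neighborhood_characters(raw)
        )
        summary = summarize_events(events, losses)
        assert summary["n_total"] == summary["n_deletions"] + summary["n_rearrangements"]
        assert summary["by_subtype"].get("full_disconnection", 0) == 0
        assert summary["by_subtype"].get("inversion", 0) == 0

    def test_empty_event_list_all_zero(self):
        summary = summarize_events([])
        assert summary["n_total"] == 0
        assert summary["n_deletions"] == 0
        assert summary["n_rearrangements"] == 0
        assert summary["by_subtype"] == {}

    def test_concatenation_breaking_counts_inter_operon_only(self):
        from operonevo.events import AlterationEvent

        events = [
            AlterationEvent("EV001", "rearrangement", "insertion",
                            "rpoBC-str", ("x",), branch_id="b1"),
            AlterationEvent("EV002", "rearrangement", "inversion",
                            "spc", ("rplN",), branch_id="b1"),
            AlterationEvent("EV003", "deletion", "gene_loss",
                            "spc", ("rpmJ",), branch_id="b2"),
        ]
        summary = summarize_events(events)
        assert summary["concatenation_breaking_per_operon_pair"] == {"rpoBC-str": 1}
        assert summary["fraction_insertion_rearrangements"] == 0.5


def test_transposase_keyword_detection():
    assert looks_like_transposase("tnpA")
    assert looks_like_transposase("is26")
    assert looks_like_transposase("yfgX", "putative transposase")
    assert not looks_like_transposase("insB" if False else "rpoB")
    assert not looks_like_transposase("istidine")  # 'is' prefix needs a digit
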