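"""Simulator contracts: determinism, replay identity, rate calibration."""

from __future__ import annotations

import numpy as np
import pytest

import operonevo as oe
from operonevo.io import write_gene_order_table
from operonevo.simulate import SimulationConfig, replay_log
from operonevo.trees import branch_id, clade_leaves


class TestSimulateTree:
    def test_two_taxa_is_a_cherry(self):
        tree = oe.simulate_tree(2, 1)
        assert len(tree.leaf_names) == 2
        assert len(tree.internal_nodes()) == 1

    def test_same_seed_identical_newick(self):
        assert oe.simulate_tree(10, 42).to_newick() == \
            oe.simulate_tree(10, 42).to_newick()

    def test_different_seed_differs(self):
        assert oe.simulate_tree(10, 1).to_newick() != \
            oe.simulate_tree(10, 2).to_newick()

    def test_rooted_binary_internal_node_count(self):
        tree = oe.simulate_tree(24, 0)
        assert len(tree.internal_nodes()) == 23

    def test_mean_branch_length_rescaled(self):
        tree = oe.simulate_tree(16, 5, branch_scale=0.07)
        lengths = [
            tree.branch_length(n)
            for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
        ]
        assert np.mean([l for l in lengths if l > 0]) == pytest.approx(0.07, rel=0.05)

    def test_fewer_than_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            oe.simulate_tree(1, 0)


class TestEvolveCluster:
    def test_zero_rates_reproduce_ancestor_everywhere(self, model):
        tree = oe.simulate_tree(6, 9)
        config = SimulationConfig(
            n_taxa=6, seed=9, r_insertion=0, r_deletion=0,
            r_disconnection=0, r_inversion=0, r_transposon=0,
        )
        tables, log = oe.evolve_cluster(tree, model, config)
        assert len(log) == 0
        for table in tables:
            assert table.labels == model.all_labels

    def test_deletion_only_rates_only_remove_genes(self, model):
        tree = oe.simulate_tree(8, 15)
        config = SimulationConfig(
            n_taxa=8, seed=15, r_insertion=0, r_deletion=3.0,
            r_disconnection=0, r_inversion=0, r_transposon=0,
            p_homolog_copy=0.0,
        )
        tables, log = oe.evolve_cluster(tree, model, config)
        assert all(ev.subtype == "gene_loss" for ev in log.events)
        for table in tables:
            assert set(table.labels) <= set(model.all_labels)

    def test_determinism_per_seed(self, model):
        config = SimulationConfig(n_taxa=8, seed=33)
        tree = oe.simulate_tree(8, 33)
        t1, l1 = oe.evolve_cluster(tree, model, config)
        t2, l2 = oe.evolve_cluster(tree, model, config)
        assert l1.events == l2.events
        assert [t.records for t in t1] == [t.records for t in t2]

    def test_replay_reproduces_leaf_tables_byte_identically(
        self, model, tmp_path
    ):
        tree = oe.simulate_tree(12, 5)
        config = SimulationConfig(n_taxa=12, seed=5)
        tables, log = oe.evolve_cluster(tree, model, config)
        replayed = replay_log(tree, model, log, config)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_gene_order_table(tables, p1)
        write_gene_order_table(replayed, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_event_counts_match_poisson_expectation(self, model):
        """Mean events per replicate tracks sum(rates) x total branch length."""
        n_rep = 100
        totals = []
        tree = oe.simulate_tree(10, 77)
        total_len = sum(
            tree.branch_length(n)
            for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
        )
        rate_sum = 2.0 + 1.0  # defaults below
        for rep in range(n_rep):
            config = SimulationConfig(
                n_taxa=10, seed=1000 + rep, r_insertion=1.0, r_deletion=1.0,
                r_disconnection=1.0, r_inversion=0, r_transposon=0,
            )
            _, log = oe.evolve_cluster(tree, model, config)
            totals.append(len(log))
        expected = rate_sum * total_len
        se = np.sqrt(expected / n_rep)
        assert abs(np.mean(totals) - expected) <= 3 * se + 0.1 * expected

    @staticmethod
    def _invaded_fraction(model, bias: float, n_rep: int = 60) -> tuple[int, int]:
        """(disconnections at previously invaded junctions, total)."""
        hits = total = 0
        for rep in range(n_rep):
            config = SimulationConfig(
                n_taxa=6, seed=5000 + rep, branch_scale=0.3,
                r_insertion=2.0, r_deletion=0, r_disconnection=1.0,
                r_inversion=0, r_transposon=0, invasion_bias=bias,
            )
            tree_scaled = oe.simulate_tree(6, 5000 + rep, branch_scale=0.3)
            _, log = oe.evolve_cluster(tree_scaled, model, config)
            insertions = [
                (set(ev.branch_id.split("|")), ev.junction)
                for ev in log.events
                if ev.subtype in ("insertion", "transposon_integration")
            ]
            for ev in log.events:
                if ev.subtype != "full_disconnection":
                    continue
                total += 1
                below = set(ev.branch_id.split("|"))
                # invaded earlier on this lineage: insertion at the same
                # junction on the same branch or any ancestral branch
                if any(
                    junction == ev.junction and below <= anc
                    for anc, junction in insertions
                ):
                    hits += 1
        return hits, total

    def test_invasion_bias_prefers_invaded_junctions(self, model):
        """With a strong bias, disconnections concentrate at junctions that
        an insertion already invaded, relative to an unbiased control."""
        hits_biased, total_biased = self._invaded_fraction(model, bias=50.0)
        hits_ctrl, total_ctrl = self._invaded_fraction(model, bias=1.0)
        assert total_biased > 20 and total_ctrl > 20
        assert hits_biased / total_biased > hits_ctrl / total_ctrl

    def test_too_few_operons_rejected(self):
        from operonevo.model import Operon, OperonClusterModel

        single = OperonClusterModel(operons=[Operon("only", ["rpoB", "rpoC"])])
        with pytest.raises(ValueError, match="two operons"):
            oe.evolve_cluster(oe.simulate_tree(4, 1), single, SimulationConfig())


class TestPerBranchStreams:
    def test_shared_branches_keep_their_events_when_taxa_added(self, model):
        """Branch RNG is keyed by the branch's clade, so grafting an extra
        clade elsewhere does not reshuffle events on unchanged branches."""
        small = oe.SupportTree.from_newick(
            "(((A:0.3,B:0.3):0.3,C:0.5):0.2,D:0.6);", is_path=False
        )
        big = oe.SupportTree.from_newick(
            "(((A:0.3,B:0.3):0.3,C:0.5):0.2,(D:0.6,(E:0.2,F:0.2):0.3):0.1);",
            is_path=False,
        )
        config = SimulationConfig(n_taxa=4, seed=21, r_insertion=3.0,
                                  r_deletion=3.0, r_disconnection=0,
                                  r_inversion=0, r_transposon=0)
        _, log_small = oe.evolve_cluster(small, model, config)
        _, log_big = oe.evolve_cluster(big, model, config)

        def events_on(log, bid):
            return [(e.subtype, e.junction, e.payload) for e in log.events
                    if e.branch_id == bid]

        for bid in ["A", "B", "C", "A|B", "A|B|C"]:
            assert events_on(log_small, bid) == events_on(log_big, bid)


class TestPerturbGeneTree:
    def test_zero_moves_identity(self):
        base = oe.simulate_tree(8, 3)
        assert oe.rf_distance(oe.perturb_gene_tree(base, 0, 1), base) == 0

    def test_one_move_changes_topology(self):
        base = oe.simulate_tree(8, 3)
        perturbed = oe.perturb_gene_tree(base, 1, 4)
        assert sorted(perturbed.leaf_names) == sorted(base.leaf_names)
        assert oe.rf_distance(perturbed, base) > 0

    def test_deterministic_per_seed(self):
        base = oe.simulate_tree(8, 3)
        assert oe.perturb_gene_tree(base, 2, 7).to_newick() == \
            oe.perturb_gene_tree(base, 2, 7).to_newick()


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(r_deletion=-1)

    def test_far_offset_must_exceed_threshold(self):
        with pytest.raises(ValueError):
            SimulationConfig(far_locus_offset=5_000)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_homolog_copy=1.5)
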