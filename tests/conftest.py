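"""Shared fixtures: compact genome builders and a seeded simulation bundle."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import operonevo as oe
from operonevo.model import GeneOrderTable, GeneRecord
from operonevo.trees import clade_leaves

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_table(
    genome_id: str,
    genes,
    gap: int = 100,
    start: int = 1000,
    replicon: str = "chr",
    gene_len: int = 900,
) -> GeneOrderTable:
    """Build a gene-order table from a compact description.

    ``genes`` is a list of entries: a label (gene on '+', default gap), or a
    tuple ``(label, strand)`` or ``(label, strand, gap_before)``.
    """
    records = []
    cursor = start
    for entry in genes:
        if isinstance(entry, str):
            label, strand, gap_before = entry, "+", gap
        elif len(entry) == 2:
            (label, strand), gap_before = entry, gap
        else:
            label, strand, gap_before = entry
        cursor += gap_before
        records.append(
            GeneRecord(
                genome_id=genome_id,
                replicon_id=replicon,
                start=cursor,
                end=cursor + gene_len - 1,
                strand=strand,
                gene_label=label,
            )
        )
        cursor += gene_len
    return GeneOrderTable(genome_id=genome_id, records=records)


@pytest.fixture(scope="session")
def model():
    return oe.default_cluster_model()


# rates sized so the summed per-pair event rate is about 0.05 per unit
# branch length over the model's ~40 adjacent pairs
LOW_RATES = dict(
    r_insertion=0.7,
    r_deletion=0.7,
    r_disconnection=0.3,
    r_inversion=0.15,
    r_transposon=0.15,
)


@pytest.fixture(scope="session")
def sim_bundle(model):
    """Seeded 24-taxon simulation with the full downstream analysis."""
    seed = 7
    tree = oe.simulate_tree(24, seed)
    config = oe.SimulationConfig(n_taxa=24, seed=seed, **LOW_RATES)
    tables, log = oe.evolve_cluster(tree, model, config)
    kids = sorted(tree.root.child_nodes(), key=lambda n: len(clade_leaves(n)))
    outgroup = set(clade_leaves(kids[0]))
    ingroup = sorted(set(tree.leaf_names) - outgroup)
    matrix = oe.build_state_matrix(tables, model)
    ancestral, decisions = oe.reconstruct_cluster(tree, matrix, model, outgroup)
    ingroup_tree = tree.extract_subtree(ingroup)
    raw = []
    for t in tables:
        if t.genome_id in set(ingroup):
            raw.extend(oe.diff_to_ancestor(t, ancestral, model))
    characters = oe.collect_neighborhood_characters(raw)
    events, losses, conflicts = oe.place_events(ingroup_tree, characters)
    return dict(
        seed=seed,
        tree=tree,
        config=config,
        tables=tables,
        log=log,
        outgroup=outgroup,
        ingroup=ingroup,
        ingroup_tree=ingroup_tree,
        matrix=matrix,
        ancestral=ancestral,
        decisions=decisions,
        characters=characters,
        events=events,
        losses=losses,
        conflicts=conflicts,
    )
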