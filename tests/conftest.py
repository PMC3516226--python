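"""Shared fixtures: desk-scale simulated data sets and pipeline helpers."""

from __future__ import annotations

import pytest

from paleokaryo import scenario as sc
from paleokaryo.formats import group_hsps
from paleokaryo.homology import call_homologs, summarize_pair
from paleokaryo.simulate import SimConfig, noise_free, simulate
from paleokaryo.synteny import SyntenyParams, detect_blocks


def run_homology(result):
    """Pool a simulation's HSPs and call homolog pairs."""
    alignments = [
        summarize_pair(q, s, grp, result.gene_index[q].cds_length)
        for (q, s), grp in group_hsps(result.hsps).items()
        if q in result.gene_index and s in result.gene_index
    ]
    genome_map = {g: rec.genome_id for g, rec in result.gene_index.items()}
    return call_homologs(alignments, genome_map, result.divergence_classes)


def run_synteny(result, pairs, seed=1, keep_invalid=False):
    return detect_blocks(
        pairs,
        result.gene_index,
        SyntenyParams(seed=seed, n_shuffles=300),
        keep_invalid=keep_invalid,
    )


def anchor_f1(blocks, truth_pairs, genome_a, genome_b):
    """Anchor-level F1 of ortholog blocks against a true pair set."""
    predicted = set()
    for b in blocks:
        if b.kind != "orthologous":
            continue
        if {b.genome_a, b.genome_b} != {genome_a, genome_b}:
            continue
        for a in b.anchors:
            predicted.add(frozenset((a.gene_a, a.gene_b)))
    if not predicted or not truth_pairs:
        return 0.0
    tp = len(predicted & truth_pairs)
    precision = tp / len(predicted)
    recall = tp / len(truth_pairs)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@pytest.fixture(scope="session")
def wgd_sim():
    """Noise-free 3-genome data set descending from a shared (pre-speciation) WGD."""
    cfg = noise_free(
        SimConfig(
            n_protogenes=1200,
            seed=3,
            shared_events=[sc.Event("WGD")],
            lineage_events={
                "g1": [sc.Event("Cfus_TCF", {"chrom_a": 0, "chrom_b": 5})],
                "g2": [sc.Event("Cfis", {"chrom": 0, "pos": 2})],
                "g3": [],
            },
        )
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def flat_sim():
    """Noise-free 3-genome data set with no WGD and 4 scripted events."""
    cfg = noise_free(
        SimConfig(
            n_protogenes=1200,
            seed=5,
            lineage_events={
                "g1": [
                    sc.Event("Cfus_TCF", {"chrom_a": 0, "chrom_b": 3}),
                    sc.Event("Cfis", {"chrom": 1, "pos": 4}),
                ],
                "g2": [sc.Event("inversion", {"chrom": 2, "start": 1, "end": 4})],
                "g3": [sc.Event("Cfis", {"chrom": 4, "pos": 3})],
            },
        )
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def wgd_pairs_blocks(wgd_sim):
    pairs = run_homology(wgd_sim)
    blocks = run_synteny(wgd_sim, pairs)
    return pairs, blocks


@pytest.fixture(scope="session")
def flat_pairs_blocks(flat_sim):
    pairs = run_homology(flat_sim)
    blocks = run_synteny(flat_sim, pairs)
    return pairs, blocks
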