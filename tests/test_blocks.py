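"""Breakpoint clustering, block segmentation, projection and karyotype assembly."""

import pytest

from wgtkit.blocks import (
    AncestralKaryotype,
    GBAssociation,
    GenomicBlock,
    assemble_ancestral_karyotype,
    block_labels,
    detect_breakpoints,
    find_gb_associations,
    project_blocks,
    segment_blocks,
)
from wgtkit.synteny import SyntenicFragment, SyntenicPair

from conftest import make_genome


def frag(fid, q_chrom, ref, ref_chrom, lo, hi, orientation="forward", copy_id=0,
         q_start=0):
    ranks = range(lo, hi + 1)
    if orientation == "inverted":
        ranks = reversed(list(ranks))
    pairs = [
        SyntenicPair(f"{q_chrom}_p{fid}_{r}", ref.gene_at(ref_chrom, r).gene_id, 2)
        for r in ranks
    ]
    span = (hi - lo + 1) * 2000
    return SyntenicFragment(
        fid, pairs, q_chrom, q_start, q_start + span, ref_chrom,
        ref.gene_at(ref_chrom, lo).start, ref.gene_at(ref_chrom, hi).end,
        orientation, (0, 0), (lo, hi), copy_id,
    )


@pytest.fixture
def ref():
    return make_genome("ref", {"r1": 200, "r2": 120})


def test_shared_cut_becomes_breakpoint(ref):
    copies = {
        c: [frag(c, f"q{c}", ref, "r1", 0, 99, copy_id=c),
            frag(10 + c, f"q{c}x", ref, "r1", 100, 199, copy_id=c)]
        for c in range(3)
    }
    bps = detect_breakpoints(copies, ref)
    assert len(bps) == 1
    assert bps[0].boundary == 100 and len(bps[0].supporting_copies) == 3


def test_single_copy_cut_is_not_a_breakpoint(ref):
    copies = {
        0: [frag(0, "q0", ref, "r1", 0, 99), frag(1, "q0b", ref, "r1", 100, 199)],
        1: [frag(2, "q1", ref, "r1", 0, 199)],
        2: [frag(3, "q2", ref, "r1", 0, 199)],
    }
    assert detect_breakpoints(copies, ref) == []


def test_near_terminal_cuts_ignored(ref):
    copies = {
        c: [frag(c, f"q{c}", ref, "r1", 5, 195, copy_id=c)] for c in range(3)
    }
    assert detect_breakpoints(copies, ref) == []


def test_planted_cuts_recovered_from_simulation(quiet_sim, quiet_run):
    planted = set(quiet_sim.truth.planted_breakpoints)
    detected = {(b.ref_chrom, b.boundary) for b in quiet_run.breakpoints}
    assert len(detected) == len(planted)
    for chrom, b in planted:
        assert any(c == chrom and abs(d - b) <= 10 for c, d in detected)


def test_segmentation_counts_and_tiling(ref):
    bps = detect_breakpoints(
        {
            c: [frag(3 * c, f"q{c}", ref, "r1", 0, 59, copy_id=c),
                frag(3 * c + 1, f"q{c}b", ref, "r1", 60, 139, copy_id=c),
                frag(3 * c + 2, f"q{c}c", ref, "r1", 140, 199, copy_id=c)]
            for c in range(2)
        },
        ref,
    )
    blocks = segment_blocks(ref, bps)
    # r1 cut twice -> 3 blocks; r2 uncut -> 1 block
    assert [b.ref_chrom for b in blocks] == ["r1", "r1", "r1", "r2"]
    assert [b.label for b in blocks] == ["A", "B", "C", "D"]
    for chrom in ("r1", "r2"):
        spans = sorted(
            (b.rank_start, b.rank_end) for b in blocks if b.ref_chrom == chrom
        )
        assert spans[0][0] == 0 and spans[-1][1] == ref.n_genes(chrom)
        for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
            assert e1 == s2  # contiguous, disjoint


def test_no_breakpoints_one_block_per_chromosome(ref):
    blocks = segment_blocks(ref, [])
    assert [(b.label, b.ref_chrom) for b in blocks] == [("A", "r1"), ("B", "r2")]


def test_block_label_sequence_extends_beyond_z():
    labs = block_labels(30)
    assert labs[:3] == ["A", "B", "C"]
    assert labs[25] == "Z" and labs[26] == "AA" and labs[27] == "AB"


def test_projection_forward_and_inverted_labels(ref):
    blocks = segment_blocks(ref, [])
    fwd = frag(0, "qa", ref, "r1", 0, 199, q_start=0)
    inv = frag(1, "qb", ref, "r2", 0, 119, orientation="inverted", q_start=0)
    anns = {a.query_chrom: a for a in project_blocks(blocks, [fwd, inv])}
    assert anns["qa"].labels() == ["A"]
    assert anns["qb"].labels() == ["B'"]


def test_association_candidate_rule(ref):
    blocks = segment_blocks(ref, [])  # A = r1, B = r2
    anns = project_blocks(
        blocks,
        [
            frag(0, "q1", ref, "r1", 0, 199, copy_id=0, q_start=0),
            frag(1, "q1", ref, "r2", 0, 119, copy_id=0, q_start=500_000),
            frag(2, "q2", ref, "r1", 0, 199, copy_id=1, q_start=0),
            frag(3, "q2", ref, "r2", 0, 119, copy_id=1, q_start=500_000),
            frag(4, "q3", ref, "r1", 0, 199, copy_id=2, q_start=0),
        ],
    )
    assocs = find_gb_associations(anns, blocks, ref)
    (a,) = [x for x in assocs if not x.present_in_reference]
    assert a.junction == frozenset({("A", "R"), ("B", "L")})
    assert a.support == 2 and a.is_ancestral_candidate


def test_reference_adjacency_never_a_candidate(ref):
    bps = detect_breakpoints(
        {
            c: [frag(2 * c, f"q{c}", ref, "r1", 0, 99, copy_id=c),
                frag(2 * c + 1, f"q{c}", ref, "r1", 100, 199, copy_id=c,
                     q_start=500_000)]
            for c in range(3)
        },
        ref,
    )
    blocks = segment_blocks(ref, bps)
    frags = [
        frag(2 * c, f"q{c}", ref, "r1", 0, 99, copy_id=c, q_start=0)
        for c in range(3)
    ] + [
        frag(2 * c + 1, f"q{c}", ref, "r1", 100, 199, copy_id=c, q_start=500_000)
        for c in range(3)
    ]
    assocs = find_gb_associations(project_blocks(blocks, frags), blocks, ref)
    for a in assocs:
        if a.junction == frozenset({("A", "R"), ("B", "L")}):
            assert a.present_in_reference and not a.is_ancestral_candidate


def _assoc(j, support, in_ref=False):
    return GBAssociation(frozenset(j), support, in_ref, frozenset())


def test_assembly_identity_without_candidates(ref):
    blocks = segment_blocks(ref, [])
    karyo = assemble_ancestral_karyotype(blocks, [])
    assert karyo.as_strings() == ["A", "B"]


def test_assembly_higher_support_wins():
    blocks = [
        GenomicBlock("A", "r1", 0, 100),
        GenomicBlock("B", "r2", 0, 100),
        GenomicBlock("C", "r3", 0, 100),
    ]
    karyo = assemble_ancestral_karyotype(
        blocks,
        [
            _assoc([("A", "R"), ("B", "L")], 3),
            _assoc([("A", "R"), ("C", "L")], 2),
        ],
    )
    assert karyo.as_strings() == ["A B", "C"]


def test_assembly_cycle_is_error():
    blocks = [GenomicBlock("A", "r1", 0, 100), GenomicBlock("B", "r2", 0, 100)]
    with pytest.raises(ValueError, match="cycle"):
        assemble_ancestral_karyotype(
            blocks,
            [
                _assoc([("A", "R"), ("B", "L")], 3),
                _assoc([("A", "L"), ("B", "R")], 2),
            ],
        )


def test_each_block_appears_once_in_karyotype(default_run):
    labs = [l for chrom in default_run.karyotype.chromosomes for l, _ in chrom]
    assert sorted(labs) == sorted(b.label for b in default_run.blocks)


def test_planted_associations_recovered_exactly_without_noise(quiet_sim, quiet_run):
    cands = {a.junction for a in quiet_run.associations if a.is_ancestral_candidate}
    assert cands == quiet_sim.truth.planted_associations


def test_karyotype_matches_truth_without_noise(quiet_sim, quiet_run):
    assert (
        quiet_run.karyotype.canonical()
        == quiet_sim.truth.ancestor_karyotype.canonical()
    )
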