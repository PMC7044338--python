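"""End-to-end orchestration: synthetic (or real) inputs -> syntenic pairs ->
fragments -> shared breakpoints -> genomic blocks -> ancestral karyotype ->
sub-genome assignment -> retention/dominance statistics, plus recovery
metrics against a simulation's truth tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .blocks import (
    AncestralKaryotype,
    BlockAnnotation,
    Breakpoint,
    GBAssociation,
    GenomicBlock,
    assemble_ancestral_karyotype,
    detect_breakpoints,
    find_gb_associations,
    project_blocks,
    segment_blocks,
)
from .core_io import Genome
from .dominance import ParalogDoublet
from .simulate import SimResult, TruthTables
from .subgenomes import (
    RetentionCounts,
    SubgenomeAssignment,
    assign_fragment_copies,
    assign_subgenomes,
    retention_counts,
)
from .synteny import (
    SyntenicFragment,
    SyntenicPair,
    SyntenyConfig,
    assemble_fragments,
    filter_fragments,
    find_syntenic_pairs,
)

__all__ = ["PipelineResult", "run_pipeline", "paralog_doublets", "validate_against_truth"]


@dataclass
class PipelineResult:
    pairs: list[SyntenicPair]
    fragments: list[SyntenicFragment]
    breakpoints: list[Breakpoint]
    blocks: list[GenomicBlock]
    annotations: list[BlockAnnotation]
    associations: list[GBAssociation]
    karyotype: AncestralKaryotype
    assignment: SubgenomeAssignment
    counts: RetentionCounts


def run_pipeline(
    query: Genome,
    ref: Genome,
    hits,
    cfg: SyntenyConfig = SyntenyConfig(),
    breakpoint_tolerance: int = 10,
    window: int = 1001,
) -> PipelineResult:
    """Run the full comparative pipeline from homology hits to sub-genomes."""
    pairs = find_syntenic_pairs(query, ref, hits, cfg)
    all_fragments = assemble_fragments(pairs, query, ref, cfg)
    copies = assign_fragment_copies(all_fragments, ref)
    # the span filter governs breakpoint detection (structural cuts), where
    # small-fragment ends are mostly noise; block projection and sub-genome
    # accounting keep every credible fragment so that real synteny broken
    # into sub-threshold pieces still contributes junction evidence
    fragments = filter_fragments(all_fragments, cfg)
    kept = {f.fragment_id for f in fragments}
    breakpoints = detect_breakpoints(
        {k: [f for f in v if f.fragment_id in kept] for k, v in copies.items()},
        ref,
        tolerance=breakpoint_tolerance,
    )
    blocks = segment_blocks(ref, breakpoints)
    credible = [f for f in all_fragments if f.n_pairs >= 5]
    annotations = project_blocks(blocks, credible)
    associations = find_gb_associations(annotations, blocks, ref)
    karyotype = assemble_ancestral_karyotype(blocks, associations)
    assignment = assign_subgenomes(karyotype, blocks, all_fragments, ref, window=window)
    counts = retention_counts(assignment, pairs, n_ref_genes=ref.n_genes())
    return PipelineResult(
        pairs, fragments, breakpoints, blocks, annotations, associations,
        karyotype, assignment, counts,
    )


def paralog_doublets(
    pairs: Sequence[SyntenicPair],
    assignment: SubgenomeAssignment,
) -> dict[tuple[str, str], list[ParalogDoublet]]:
    """Sub-genome paralog doublets keyed by pair, from shared ref orthologs.

    Two polyploid genes syntenic to the same reference gene but assigned to
    different sub-genomes form a doublet; gene_a is the member from the
    higher-priority sub-genome (LF > MF1 > MF2).
    """
    order = {"LF": 0, "MF1": 1, "MF2": 2}
    per_ref: dict[str, list[tuple[str, str]]] = {}
    for p in pairs:
        lab = assignment.gene_labels.get(p.query_gene)
        if lab is not None:
            per_ref.setdefault(p.ref_gene, []).append((p.query_gene, lab))
    out: dict[tuple[str, str], list[ParalogDoublet]] = {}
    for ref_gene in sorted(per_ref):
        members = sorted(per_ref[ref_gene], key=lambda t: order[t[1]])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (ga, la), (gb, lb) = members[i], members[j]
                if la == lb:
                    continue
                out.setdefault((la, lb), []).append(ParalogDoublet(ga, gb, (la, lb)))
    return out


def validate_against_truth(
    result: PipelineResult, truth: TruthTables, tolerance: int = 10
) -> dict[str, float]:
    """Stage-by-stage recovery metrics of a pipeline run against truth."""
    # breakpoints
    planted = truth.planted_breakpoints
    detected = [(bp.ref_chrom, bp.boundary) for bp in result.breakpoints]
    tp = sum(
        1
        for (c, b) in planted
        if any(dc == c and abs(db - b) <= tolerance for dc, db in detected)
    )
    bp_recall = tp / len(planted) if planted else 1.0
    used = sum(
        1
        for (dc, db) in detected
        if any(c == dc and abs(b - db) <= tolerance for c, b in planted)
    )
    bp_precision = used / len(detected) if detected else 1.0

    # associations (label-comparable when breakpoints were recovered exactly)
    candidates = {a.junction for a in result.associations if a.is_ancestral_candidate}
    assoc_recall = (
        len(candidates & truth.planted_associations) / len(truth.planted_associations)
        if truth.planted_associations
        else 1.0
    )
    assoc_fp = len(candidates - truth.planted_associations)

    # karyotype
    n_chrom = result.karyotype.n_chromosomes
    karyotype_match = float(
        result.karyotype.canonical() == truth.ancestor_karyotype.canonical()
    )

    # sub-genome labels
    unit_total = unit_correct = 0
    gene_total = gene_correct = 0
    for unit in result.assignment.units:
        for color, label in unit.labels.items():
            truth_labs = [
                truth.subgenome_of_gene[p.query_gene]
                for f in unit.copy_fragments[color]
                for p in f.pairs
                if p.query_gene in truth.subgenome_of_gene
            ]
            if not truth_labs:
                continue
            majority = max(set(truth_labs), key=truth_labs.count)
            unit_total += 1
            unit_correct += majority == label
            gene_total += len(truth_labs)
            gene_correct += sum(t == label for t in truth_labs)
    return {
        "breakpoint_recall": bp_recall,
        "breakpoint_precision": bp_precision,
        "association_recall": assoc_recall,
        "association_false_positives": float(assoc_fp),
        "n_ancestor_chromosomes": float(n_chrom),
        "karyotype_exact_match": karyotype_match,
        "unit_label_accuracy": unit_correct / unit_total if unit_total else 0.0,
        "gene_label_accuracy": gene_correct / gene_total if gene_total else 0.0,
    }


def run_on_simulation(sim: SimResult, **kwargs) -> PipelineResult:
    return run_pipeline(sim.polyploid, sim.reference, sim.hits, **kwargs)
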