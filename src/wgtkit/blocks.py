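"""Genomic blocks, shared breakpoints, and ancestral-karyotype assembly.

The diploid reference genome is segmented into labelled *genomic blocks*
(A, B, C, ... in gene-rank coordinates) at breakpoints supported by more than
one sub-genome copy of the polyploid.  Blocks are then projected onto the
polyploid chromosomes; block adjacencies ("GB associations") that appear in
two or more sub-genome copies but not in the reference evidence junctions of
the pre-polyploidy diploid ancestor, and are stitched into an ancestral
karyotype by end-matching.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import Genome
from .synteny import SyntenicFragment

__all__ = [
    "Breakpoint",
    "GenomicBlock",
    "BlockAnnotation",
    "GBAssociation",
    "AncestralKaryotype",
    "detect_breakpoints",
    "segment_blocks",
    "project_blocks",
    "find_gb_associations",
    "assemble_ancestral_karyotype",
    "block_labels",
]


@dataclass(frozen=True)
class Breakpoint:
    """A cut between two consecutive reference gene ranks, shared by >= 2 copies.

    ``boundary`` is the rank index b of the cut between genes b-1 and b.
    """

    ref_chrom: str
    boundary: int
    supporting_copies: frozenset


@dataclass(frozen=True)
class GenomicBlock:
    label: str
    ref_chrom: str
    rank_start: int  # inclusive
    rank_end: int    # exclusive

    @property
    def n_genes(self) -> int:
        return self.rank_end - self.rank_start


@dataclass
class BlockAnnotation:
    """Ordered, oriented block labels along one polyploid chromosome."""

    query_chrom: str
    entries: list[tuple[str, str, SyntenicFragment]]  # (label, orientation, fragment)

    def labels(self) -> list[str]:
        return [lab + ("" if ori == "forward" else "'") for lab, ori, _ in self.entries]


@dataclass
class GBAssociation:
    """An adjacency of two blocks, keyed by which block *ends* meet."""

    junction: frozenset  # {(label, 'L'|'R'), (label, 'L'|'R')}
    support: int
    present_in_reference: bool
    copy_contexts: frozenset

    @property
    def is_ancestral_candidate(self) -> bool:
        return self.support >= 2 and not self.present_in_reference


@dataclass
class AncestralKaryotype:
    """Chromosomes as ordered, oriented block label lists."""

    chromosomes: list[list[tuple[str, str]]]  # [(label, orientation), ...]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def as_strings(self) -> list[str]:
        out = []
        for chrom in self.chromosomes:
            out.append(" ".join(l + ("" if o == "forward" else "'") for l, o in chrom))
        return out

    def canonical(self) -> frozenset:
        """Orientation-of-reading-invariant form for karyotype comparison."""
        chroms = []
        for chrom in self.chromosomes:
            fwd = tuple((l, o) for l, o in chrom)
            rev = tuple(
                (l, "inverted" if o == "forward" else "forward")
                for l, o in reversed(chrom)
            )
            chroms.append(min(fwd, rev))
        return frozenset(chroms)


def block_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — enough labels for n blocks."""
    labels = []
    for i in range(n):
        s = ""
        k = i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


def detect_breakpoints(
    fragments_by_copy: Mapping[object, Sequence[SyntenicFragment]],
    ref: Genome,
    tolerance: int = 10,
) -> list[Breakpoint]:
    """Cluster interior fragment-end cuts across copies into shared breakpoints.

    Every fragment contributes candidate cuts at both of its reference
    rank-span boundaries; cuts within ``tolerance`` ranks of a chromosome end
    never count (fractionation trims fragment ends, so near-terminal cuts are
    edge jitter, not rearrangement).  Candidates within ``tolerance`` ranks
    are clustered (single linkage); a cluster supported by at least two
    distinct copies becomes a breakpoint at its median boundary.
    """
    candidates: dict[str, list[tuple[int, object]]] = {}
    for copy_id, frags in fragments_by_copy.items():
        for f in frags:
            n = ref.n_genes(f.ref_chrom)
            lo, hi = f.ref_rank_span
            for b in (lo, hi + 1):
                if tolerance < b < n - tolerance:
                    candidates.setdefault(f.ref_chrom, []).append((b, copy_id))

    breakpoints: list[Breakpoint] = []
    for chrom in sorted(candidates):
        cands = sorted(candidates[chrom])
        cluster: list[tuple[int, object]] = []
        for b, cid in cands + [(None, None)]:
            if cluster and (b is None or b - cluster[-1][0] > tolerance):
                copies = frozenset(c for _, c in cluster)
                if len(copies) >= 2:
                    boundary = int(statistics.median_low([x for x, _ in cluster]))
                    breakpoints.append(Breakpoint(chrom, boundary, copies))
                cluster = []
            if b is not None:
                cluster.append((b, cid))
    return breakpoints


def segment_blocks(ref: Genome, breakpoints: Iterable[Breakpoint]) -> list[GenomicBlock]:
    """Cut each reference chromosome at its breakpoints; label blocks
    alphabetically in chromosome order then position order.

    The output tiles every chromosome: disjoint, contiguous, exhaustive over
    gene ranks.
    """
    cuts: dict[str, set[int]] = {}
    for bp in breakpoints:
        cuts.setdefault(bp.ref_chrom, set()).add(bp.boundary)
    spans: list[tuple[str, int, int]] = []
    for chrom in ref.chromosomes:
        n = ref.n_genes(chrom)
        if n == 0:
            continue
        bounds = [0] + sorted(b for b in cuts.get(chrom, ()) if 0 < b < n) + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            spans.append((chrom, a, b))
    labels = block_labels(len(spans))
    return [GenomicBlock(lab, c, a, b) for lab, (c, a, b) in zip(labels, spans)]


def project_blocks(
    blocks: Sequence[GenomicBlock],
    fragments: Sequence[SyntenicFragment],
    min_block_overlap: float = 0.5,
    min_end_genes: int = 25,
    end_tolerance: int = 10,
) -> list[BlockAnnotation]:
    """Relabel fragments by the blocks they cover on the reference.

    Coverage is assessed per *chain* — the fragments of one sub-genome copy
    (same query chromosome, reference chromosome and copy) pooled together —
    so that a block whose coverage is split across fragments (for example by
    a small filtered-out inversion in its middle) still reaches the
    ``min_block_overlap`` threshold.  A qualifying chain emits the block's
    label through each member fragment that touches the block; inverted
    fragments emit their labels in descending reference order (rendered
    primed).  Chains covering no block sufficiently are skipped.
    """
    by_chrom: dict[str, list[GenomicBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    for v in by_chrom.values():
        v.sort(key=lambda b: b.rank_start)

    # copy-level covered span per block: all fragments of one sub-genome copy
    # (same reference chromosome and copy id) pool their coverage, even when
    # a fission has scattered them over several polyploid chromosomes
    chain_cover: dict[tuple, dict[str, list[tuple[int, int]]]] = {}
    for f in fragments:
        key = (f.ref_chrom, f.copy_id)
        lo, hi = f.ref_rank_span
        for b in by_chrom.get(f.ref_chrom, []):
            s, e = max(lo, b.rank_start), min(hi + 1, b.rank_end)
            if e > s:
                chain_cover.setdefault(key, {}).setdefault(b.label, []).append((s, e))
    chain_ok: dict[tuple, set[str]] = {}
    block_by_label = {b.label: b for b in blocks}
    for key, per_block in chain_cover.items():
        ok = set()
        for lab, ivs in per_block.items():
            merged = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            covered = sum(e - s for s, e in merged)
            if covered >= min_block_overlap * block_by_label[lab].n_genes:
                ok.add(lab)
        chain_ok[key] = ok

    per_query: dict[str, list[tuple[tuple, str, str, SyntenicFragment]]] = {}
    for f in fragments:
        key = (f.ref_chrom, f.copy_id)
        lo, hi = f.ref_rank_span
        labs: list[tuple[int, str]] = []
        for b in by_chrom.get(f.ref_chrom, []):
            ov = min(hi + 1, b.rank_end) - max(lo, b.rank_start)
            if ov <= 0:
                continue
            # a sizeable fragment that reaches a block boundary is junction
            # evidence even when a rearrangement took a bite out of the rest
            # of this copy's block
            touches_boundary = (
                abs(lo - b.rank_start) <= end_tolerance
                or abs(hi + 1 - b.rank_end) <= end_tolerance
            )
            if b.label in chain_ok.get(key, ()) or (
                ov >= min_end_genes and touches_boundary
            ):
                labs.append((b.rank_start, b.label))
        if not labs:
            continue
        labs.sort(reverse=(f.orientation == "inverted"))
        for i, (_, lab) in enumerate(labs):
            # order labels within the fragment by query position
            per_query.setdefault(f.query_chrom, []).append(
                ((f.query_start, i), lab, f.orientation, f)
            )
    annotations = []
    for chrom in sorted(per_query):
        entries = []
        for _, lab, ori, frag in sorted(per_query[chrom], key=lambda t: t[0]):
            if entries and entries[-1][0] == lab and entries[-1][1] == ori:
                continue  # same block continued across chained fragments
            entries.append((lab, ori, frag))
        annotations.append(BlockAnnotation(chrom, entries))
    return annotations


def _entry_end(entry, block: GenomicBlock, ref: Genome, leading: bool) -> str:
    """Which end of the block faces the junction.

    Determined from the reference rank of the fragment's boundary pair
    (leading or trailing in query order) within the block — nearer the block
    start means 'L', nearer the end means 'R'.  This stays correct even when
    a small local inversion flips the boundary fragment's own orientation.
    """
    _, ori, frag = entry
    in_block = [
        p for p in frag.pairs
        if block.rank_start <= ref[p.ref_gene].rank < block.rank_end
    ]
    if in_block:
        r = ref[in_block[0 if leading else -1].ref_gene].rank
        left_d = r - block.rank_start
        right_d = block.rank_end - 1 - r
        return "L" if left_d < right_d else "R"
    # no pair inside the block (label emitted via pooled chain coverage):
    # fall back to the fragment's own orientation
    if leading:
        return "L" if ori == "forward" else "R"
    return "R" if ori == "forward" else "L"


def _junction(entry_a, entry_b, block_by_label, ref: Genome) -> frozenset:
    """End-signature of the junction between two consecutive oriented blocks."""
    lab_a, _, _ = entry_a
    lab_b, _, _ = entry_b
    end_a = (lab_a, _entry_end(entry_a, block_by_label[lab_a], ref, leading=False))
    end_b = (lab_b, _entry_end(entry_b, block_by_label[lab_b], ref, leading=True))
    return frozenset([end_a, end_b])


def reference_junctions(blocks: Sequence[GenomicBlock]) -> set[frozenset]:
    """Junction signatures of block adjacencies along the reference."""
    by_chrom: dict[str, list[GenomicBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    juncs: set[frozenset] = set()
    for chrom, bl in by_chrom.items():
        bl.sort(key=lambda b: b.rank_start)
        for a, b in zip(bl[:-1], bl[1:]):
            juncs.add(frozenset([(a.label, "R"), (b.label, "L")]))
    return juncs


def find_gb_associations(
    annotations: Sequence[BlockAnnotation],
    blocks: Sequence[GenomicBlock],
    ref: Genome,
) -> list[GBAssociation]:
    """Mine every adjacent block pair in the polyploid annotations.

    Support counts distinct copy contexts, proxied by the polyploid
    chromosome carrying the junction: each sub-genome copy shows an ancestral
    junction on its own chromosome, whereas a lineage-specific fusion joint
    occurs on a single chromosome and so cannot reach the support >= 2
    ancestral threshold on its own.
    """
    ref_juncs = reference_junctions(blocks)
    block_by_label = {b.label: b for b in blocks}
    contexts: dict[frozenset, set] = {}
    for ann in annotations:
        for ea, eb in zip(ann.entries[:-1], ann.entries[1:]):
            if ea[0] == eb[0]:
                continue  # same block split over two fragments: not a junction
            j = _junction(ea, eb, block_by_label, ref)
            # copy context = the polyploid chromosome: each sub-genome copy
            # carries the junction on its own chromosome, while a cross-copy
            # fusion joint occurs on a single chromosome and counts once
            contexts.setdefault(j, set()).add(ann.query_chrom)
    out = []
    for j, ctxs in contexts.items():
        out.append(
            GBAssociation(
                junction=j,
                support=len(ctxs),
                present_in_reference=j in ref_juncs,
                copy_contexts=frozenset(ctxs),
            )
        )
    out.sort(key=lambda a: sorted(a.junction))
    return out


def assemble_ancestral_karyotype(
    blocks: Sequence[GenomicBlock],
    associations: Sequence[GBAssociation],
) -> AncestralKaryotype:
    """Stitch blocks into ancestral chromosomes by end-matching.

    Edges, in priority order (support desc, reference adjacency preferred on
    ties, then lexicographic): ancestral candidate junctions (support >= 2,
    absent from the reference), then reference adjacencies still observed in
    at least two sub-genome copies — the latter heal spurious breakpoints
    without re-joining true ancestral chromosome ends, which are essentially
    never observed as junctions in multiple copies.  Each block end carries at most
    one edge; maximal simple paths are the ancestral chromosomes.  A cycle is
    an error (circular chromosomes are out of model).
    """
    edges = []
    for a in associations:
        if a.is_ancestral_candidate:
            edges.append((-a.support, 1, sorted(a.junction), a.junction))
        elif a.present_in_reference and a.support >= 2:
            edges.append((-a.support, 0, sorted(a.junction), a.junction))
    edges.sort()

    label_set = {b.label for b in blocks}
    taken: dict[tuple[str, str], tuple[str, str]] = {}
    comp: dict[str, str] = {lab: lab for lab in label_set}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for _, _, _, junction in edges:
        (la, ea), (lb, eb) = sorted(junction)
        if la not in label_set or lb not in label_set:
            continue
        if (la, ea) in taken or (lb, eb) in taken:
            continue
        if la == lb:
            raise ValueError(f"cycle formed by self-junction on block {la}")
        ra, rb = find(la), find(lb)
        if ra == rb:
            cycle = sorted(l for l in label_set if find(l) == ra)
            raise ValueError(f"cycle formed among blocks: {', '.join(cycle)}")
        taken[(la, ea)] = (lb, eb)
        taken[(lb, eb)] = (la, ea)
        comp[rb] = ra

    # walk maximal paths
    chromosomes: list[list[tuple[str, str]]] = []
    visited: set[str] = set()
    for lab in sorted(label_set):
        if lab in visited:
            continue
        start = lab
        # walk left to a free end
        end = "L"
        seen = {lab}
        while (start, end) in taken:
            nxt_lab, nxt_end = taken[(start, end)]
            if nxt_lab in seen:
                break
            seen.add(nxt_lab)
            start = nxt_lab
            end = "L" if nxt_end == "R" else "R"
        # traverse rightward from the free end
        chrom: list[tuple[str, str]] = []
        cur, entry_end = start, end
        while True:
            visited.add(cur)
            orientation = "forward" if entry_end == "L" else "inverted"
            chrom.append((cur, orientation))
            out_end = "R" if entry_end == "L" else "L"
            if (cur, out_end) not in taken:
                break
            nxt_lab, nxt_end = taken[(cur, out_end)]
            cur, entry_end = nxt_lab, nxt_end
        chromosomes.append(chrom)
    return AncestralKaryotype(chromosomes)
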