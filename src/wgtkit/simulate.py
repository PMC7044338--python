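"""Synthetic paleohexaploid genomes with known truth.

The generator emulates the statistical structure of a triplicated legume
genome analysed against a diploid relative: a diploid ancestor (default nine
chromosomes) gives rise on one side to the *reference* genome through a few
fissions/fusions/inversions (default eleven chromosomes), and on the other to
a paleohexaploid that carries three fractionating copies of the ancestor with
biased retention (default 0.8/0.6/0.5), lineage-specific rearrangements, a
TE landscape whose density is lowest in the least-fractionated sub-genome,
and expression in which a gene's level is damped by its promoter TE load
(multiplier ``exp(-beta * te_fraction)``), so that sub-genome expression
dominance is a causal consequence of TE bias rather than an assumption of
the analysis code.

CDS sequences are built from fourfold-degenerate codon families only, so that
every third position is a synonymous site; synonymous divergence is planted
as a Jukes–Cantor process along the species tree with branch lengths chosen
to put the polyploid/reference Ks peak at 0.51 and the homoeolog (WGT) peak
at 0.28.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import AncestralKaryotype, GenomicBlock, block_labels
from .core_io import (
    ExpressionTable,
    GeneModel,
    Genome,
    HomologyHit,
    TEFeature,
    merged_coverage,
    write_gff3,
    write_go_tsv,
    write_hits_tsv,
    write_te_bed,
)

__all__ = ["SimConfig", "TruthTables", "SimResult", "simulate"]

# fourfold-degenerate families whose first/second-position changes are never
# synonymous, so each codon carries exactly one synonymous site (the third
# position) and planted third-position divergence maps one-to-one onto Ks
_FOURFOLD_PREFIX_LIST = ["TC", "CC", "AC", "GT", "GC", "GG"]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic paleohexaploid."""

    seed: int = 0
    n_ancestor_chromosomes: int = 9
    genes_per_chromosome: int = 300
    retention_rates: tuple[float, float, float] = (0.8, 0.6, 0.5)
    n_rearrangements: int = 20          # polyploid-lineage events
    ref_n_chromosomes: int = 11
    ref_fusions: int = 1
    ref_inversions: int = 2
    min_segment: int = 100              # genes between structural boundaries
    te_rates: tuple[float, float, float] = (0.15, 0.30, 0.35)  # insertions/kb
    te_mean_length: int = 500
    expr_log_mu: float = 2.0
    expr_log_sigma: float = 1.0
    dominance_beta: float = 2.0
    tissue_sigma: float = 0.3
    tissues: tuple[str, ...] = ("leaf", "stem", "root")
    ks_wgt: float = 0.28
    ks_ref: float = 0.51
    codons_per_gene: int = 120
    n_tandem: int = 40
    n_dispersed: int = 40
    noise_hit_rate: float = 0.02
    n_go_terms: int = 30
    ref_variant: int = 0  # alternative reference rearrangement history

    def __post_init__(self):
        if not all(0 < r <= 1 for r in self.retention_rates):
            raise ValueError("retention rates must lie in (0, 1]")
        if self.ref_n_chromosomes - self.n_ancestor_chromosomes + self.ref_fusions < 0:
            raise ValueError("reference chromosome count infeasible")
        for name in ("n_ancestor_chromosomes", "genes_per_chromosome",
                     "codons_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rearrangements < 0:
            raise ValueError("n_rearrangements must be >= 0")


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic files."""

    locus_of_gene: dict[str, int]
    copy_of_gene: dict[str, int]
    subgenome_of_gene: dict[str, str]
    duplicate_mode: dict[str, str]           # planted tandem/dispersed genes
    retained: np.ndarray                     # (3, n_loci) bool
    ref_gene_of_locus: dict[int, str]
    planted_breakpoints: list[tuple[str, int]]
    planted_associations: set[frozenset]
    truth_blocks: list[GenomicBlock]
    ancestor_karyotype: AncestralKaryotype
    promoter_te_fraction: dict[str, float]
    expression_baseline: dict[str, float]

    @property
    def n_loci(self) -> int:
        return self.retained.shape[1]


@dataclass
class SimResult:
    config: SimConfig
    reference: Genome
    polyploid: Genome
    ref_cds: dict[str, str]
    query_cds: dict[str, str]
    tes: list[TEFeature]
    hits: list[HomologyHit]
    within_homologs: list[tuple[str, str]]
    expression: ExpressionTable
    go_query: dict[str, set[str]]
    go_ref: dict[str, set[str]]
    truth: TruthTables

    def write(self, outdir: str) -> None:
        """Emit the pipeline-ready file set (plus a truth directory)."""
        os.makedirs(outdir, exist_ok=True)
        write_gff3(self.reference, os.path.join(outdir, "reference.gff3"))
        write_gff3(self.polyploid, os.path.join(outdir, "polyploid.gff3"))
        _write_fasta(self.ref_cds, os.path.join(outdir, "reference_cds.fasta"))
        _write_fasta(self.query_cds, os.path.join(outdir, "polyploid_cds.fasta"))
        write_te_bed(self.tes, os.path.join(outdir, "polyploid_tes.bed"))
        write_hits_tsv(self.hits, os.path.join(outdir, "hits.tsv"))
        pd.DataFrame(self.within_homologs, columns=["gene_a", "gene_b"]).to_csv(
            os.path.join(outdir, "within_homologs.tsv"), sep="\t", index=False
        )
        expr = self.expression.values.copy()
        expr.insert(0, "length", [self.expression.gene_length[g] for g in expr.index])
        expr.to_csv(os.path.join(outdir, "expression_counts.tsv"), sep="\t")
        write_go_tsv(self.go_query, os.path.join(outdir, "go_query.tsv"))
        write_go_tsv(self.go_ref, os.path.join(outdir, "go_reference.tsv"))
        tdir = os.path.join(outdir, "truth")
        os.makedirs(tdir, exist_ok=True)
        t = self.truth
        with open(os.path.join(tdir, "truth.json"), "w") as fh:
            json.dump(
                {
                    "subgenome_of_gene": t.subgenome_of_gene,
                    "copy_of_gene": t.copy_of_gene,
                    "locus_of_gene": t.locus_of_gene,
                    "duplicate_mode": t.duplicate_mode,
                    "planted_breakpoints": [list(b) for b in t.planted_breakpoints],
                    "planted_associations": [sorted(map(list, a)) for a in
                                             sorted(t.planted_associations,
                                                    key=lambda s: sorted(s))],
                    "ancestor_karyotype": t.ancestor_karyotype.as_strings(),
                    "promoter_te_fraction": t.promoter_te_fraction,
                    "expression_baseline": t.expression_baseline,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _write_fasta(seqs: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for gid in seqs:
            fh.write(f">{gid}\n")
            s = seqs[gid]
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# structure algebra: a chromosome is a list of (locus, orient) with orient ±1
# ---------------------------------------------------------------------------

def _invert(seg):
    return [(l, -o) for l, o in reversed(seg)]


def _anc_adjacent(a, b, anc_next) -> bool:
    """True if oriented loci a, b are consecutive in the ancestor."""
    (la, oa), (lb, ob) = a, b
    if oa == 1 and ob == 1:
        return anc_next.get(la) == lb
    if oa == -1 and ob == -1:
        return anc_next.get(lb) == la
    return False


def _discontinuities(chrom, anc_next) -> list[int]:
    return [
        i
        for i in range(1, len(chrom))
        if not _anc_adjacent(chrom[i - 1], chrom[i], anc_next)
    ]


def _sample_ref_structure(cfg: SimConfig, rng, ancestor):
    """Derive the reference from the ancestor: fissions to raise the
    chromosome number, optional fusions, and inversions, all keeping every
    structural boundary at least ``min_segment`` genes from any other."""
    anc_next = {}
    for chrom in ancestor:
        for (la, _), (lb, _) in zip(chrom[:-1], chrom[1:]):
            anc_next[la] = lb
    chroms = [list(c) for c in ancestor]
    n_fissions = cfg.ref_n_chromosomes - cfg.n_ancestor_chromosomes + cfg.ref_fusions
    m = cfg.min_segment

    for _ in range(n_fissions):
        for _try in range(200):
            ci = int(rng.integers(len(chroms)))
            c = chroms[ci]
            if len(c) < 2 * m:
                continue
            pos = int(rng.integers(m, len(c) - m + 1))
            if all(abs(pos - d) >= m for d in _discontinuities(c, anc_next)):
                chroms[ci:ci + 1] = [c[:pos], c[pos:]]
                break
        else:
            raise RuntimeError("could not place a reference fission")
    for _ in range(cfg.ref_fusions):
        i, j = rng.choice(len(chroms), size=2, replace=False)
        a, b = chroms[int(i)], chroms[int(j)]
        if rng.random() < 0.5:
            b = _invert(b)
        merged = a + b
        chroms = [c for k, c in enumerate(chroms) if k not in (int(i), int(j))]
        chroms.append(merged)
    for _ in range(cfg.ref_inversions):
        for _try in range(200):
            ci = int(rng.integers(len(chroms)))
            c = chroms[ci]
            if len(c) < 3 * m:
                continue
            i = int(rng.integers(m, len(c) - 2 * m + 1))
            j = i + int(rng.integers(m, min(2 * m, len(c) - m - i) + 1))
            bounds = _discontinuities(c, anc_next) + [0, len(c)]
            if all(abs(i - d) >= m and abs(j - d) >= m for d in bounds if d not in (i, j)):
                chroms[ci] = c[:i] + _invert(c[i:j]) + c[j:]
                break
        else:
            raise RuntimeError("could not place a reference inversion")
    # canonical order: by smallest locus contained
    chroms.sort(key=lambda c: min(l for l, _ in c))
    return chroms, anc_next


def _truth_blocks_and_karyotype(cfg, ancestor, ref_chroms, ref_names, anc_next):
    """Planted breakpoints, blocks, ancestral karyotype and associations,
    derived by comparing ancestor continuity along reference coordinates."""
    breakpoints: list[tuple[str, int]] = []
    spans: list[tuple[str, int, int]] = []
    for name, chrom in zip(ref_names, ref_chroms):
        cuts = _discontinuities(chrom, anc_next)
        breakpoints.extend((name, c) for c in cuts)
        bounds = [0] + cuts + [len(chrom)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            spans.append((name, a, b))
    labels = block_labels(len(spans))
    blocks = [GenomicBlock(lab, c, a, b) for lab, (c, a, b) in zip(labels, spans)]

    # locus -> (block index, offset, ref orientation of the locus)
    ref_pos: dict[int, tuple[int, int, int]] = {}
    for bi, b in enumerate(blocks):
        chrom = ref_chroms[ref_names.index(b.ref_chrom)]
        for off, (locus, orient) in enumerate(chrom[b.rank_start:b.rank_end]):
            ref_pos[locus] = (bi, off, orient)

    karyo: list[list[tuple[str, str]]] = []
    for chrom in ancestor:
        row: list[tuple[str, str]] = []
        i = 0
        while i < len(chrom):
            locus, orient = chrom[i]
            bi, off, rorient = ref_pos[locus]
            # direction of traversal through the block in ref offsets
            j = i + 1
            direction = 0
            while j < len(chrom) and ref_pos[chrom[j][0]][0] == bi:
                step = ref_pos[chrom[j][0]][1] - ref_pos[chrom[j - 1][0]][1]
                direction = 1 if step > 0 else -1
                j += 1
            if direction == 0:
                direction = 1 if orient == rorient else -1
            row.append((blocks[bi].label, "forward" if direction > 0 else "inverted"))
            i = j
        karyo.append(row)
    karyotype = AncestralKaryotype(karyo)

    ref_juncs = set()
    for name, chrom in zip(ref_names, ref_chroms):
        bl = sorted((b for b in blocks if b.ref_chrom == name), key=lambda b: b.rank_start)
        for a, b in zip(bl[:-1], bl[1:]):
            ref_juncs.add(frozenset([(a.label, "R"), (b.label, "L")]))
    associations: set[frozenset] = set()
    for row in karyo:
        for (la, oa), (lb, ob) in zip(row[:-1], row[1:]):
            j = frozenset([
                (la, "R" if oa == "forward" else "L"),
                (lb, "L" if ob == "forward" else "R"),
            ])
            if j not in ref_juncs:
                associations.add(j)
    return breakpoints, blocks, karyotype, associations


def _sample_polyploid_structure(cfg, rng, ancestor, retained, block_of_locus):
    """Three fractionated ancestor copies plus lineage-specific fissions,
    fusions and inversions (inversions confined to one genomic block)."""
    chroms: list[list] = []
    copy_of_chrom: list[int] = []
    for k in range(3):
        for chrom in ancestor:
            kept = [(l, o) for l, o in chrom if retained[k, l]]
            if kept:
                chroms.append([(l, o, k) for l, o in kept])
                copy_of_chrom.append(k)

    n = cfg.n_rearrangements
    if n > 0:
        if n >= 6:
            fusions, fissions = 3, 1
        elif n >= 2:
            fusions, fissions = 2, 0
        else:
            fusions, fissions = 0, 0
        inversions = n - fusions - fissions
        for _ in range(fissions):
            for _try in range(100):
                ci = int(rng.integers(len(chroms)))
                if len(chroms[ci]) < 60:
                    continue
                pos = int(rng.integers(30, len(chroms[ci]) - 30 + 1))
                c = chroms[ci]
                chroms[ci:ci + 1] = [c[:pos], c[pos:]]
                break
        for _ in range(fusions):
            if len(chroms) < 2:
                break
            i, j = rng.choice(len(chroms), size=2, replace=False)
            a, b = chroms[int(i)], chroms[int(j)]
            if rng.random() < 0.5:
                b = [(l, -o, k) for l, o, k in reversed(b)]
            merged = a + b
            chroms = [c for k2, c in enumerate(chroms) if k2 not in (int(i), int(j))]
            chroms.append(merged)
        for _ in range(inversions):
            for _try in range(100):
                ci = int(rng.integers(len(chroms)))
                c = chroms[ci]
                if len(c) < 56:
                    continue
                i = int(rng.integers(5, len(c) - 45))
                j = i + int(rng.integers(10, 41))
                seg = c[i:j]
                if len({block_of_locus[l] for l, _, _ in seg}) == 1:
                    chroms[ci] = c[:i] + [(l, -o, k) for l, o, k in reversed(seg)] + c[j:]
                    break
    chroms.sort(key=lambda c: min(l for l, _, _ in c))
    return chroms


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _jc_evolve(third: np.ndarray, t: float, rng) -> np.ndarray:
    """One Jukes–Cantor step of expected length t substitutions/site."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = third.copy()
    hit = rng.random(third.shape) < p_change
    shift = rng.integers(1, 4, size=third.shape)
    out[hit] = (out[hit] + shift[hit]) % 4
    return out


def _cds_strings(prefixes: np.ndarray, thirds: np.ndarray) -> list[str]:
    """Assemble CDS strings from per-codon prefix indices and third bases."""
    out = []
    for pi, ti in zip(prefixes, thirds):
        codons = [_FOURFOLD_PREFIX_LIST[p] + _BASES[t] for p, t in zip(pi, ti)]
        out.append("".join(codons))
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig = SimConfig()) -> SimResult:
    rng = np.random.default_rng(cfg.seed)
    # the reference lineage draws from its own stream so that two variants of
    # the reference history can be generated against an identical polyploid
    # (the reference-choice robustness check)
    rng_ref = np.random.default_rng([cfg.seed, 104729 + cfg.ref_variant])
    n_chr, gpc = cfg.n_ancestor_chromosomes, cfg.genes_per_chromosome
    n_loci = n_chr * gpc

    # orientation in the structure algebra is the segment orientation (+1
    # everywhere in the ancestor); transcriptional strand is an independent
    # per-locus attribute that inversions flip at layout time
    anc_strand = rng.choice([1, -1], size=n_loci)
    ancestor = [
        [(c * gpc + i, 1) for i in range(gpc)]
        for c in range(n_chr)
    ]

    ref_chroms, anc_next = _sample_ref_structure(cfg, rng_ref, ancestor)
    ref_names = [f"rchr{i + 1:02d}" for i in range(len(ref_chroms))]
    (planted_bps, truth_blocks, truth_karyotype,
     planted_assoc) = _truth_blocks_and_karyotype(cfg, ancestor, ref_chroms,
                                                  ref_names, anc_next)
    block_of_locus = {}
    for b in truth_blocks:
        chrom = ref_chroms[ref_names.index(b.ref_chrom)]
        for locus, _ in chrom[b.rank_start:b.rank_end]:
            block_of_locus[locus] = b.label

    retained = np.vstack(
        [rng.random(n_loci) < r for r in cfg.retention_rates]
    )
    poly_chroms = _sample_polyploid_structure(cfg, rng, ancestor, retained,
                                              block_of_locus)

    # --- planted tandem / dispersed duplicates --------------------------
    # entries become (locus, orient, copy, mode); mode "" = WGT-derived
    poly_entries: list[list[tuple[int, int, int, str]]] = [
        [(l, o, k, "") for l, o, k in c] for c in poly_chroms
    ]
    flat = [
        (ci, gi)
        for ci, c in enumerate(poly_entries)
        for gi in range(len(c))
    ]
    dup_parents: list[tuple[int, int, str]] = []
    if cfg.n_tandem + cfg.n_dispersed > 0 and flat:
        picks = rng.choice(len(flat), size=min(cfg.n_tandem + cfg.n_dispersed,
                                               len(flat)), replace=False)
        for idx, pick in enumerate(sorted(int(p) for p in picks)):
            mode = "tandem" if idx < cfg.n_tandem else "dispersed"
            dup_parents.append((*flat[pick], mode))
    # insert from the end so indices stay valid
    for ci, gi, mode in sorted(dup_parents, reverse=True):
        locus, orient, k, _ = poly_entries[ci][gi]
        if mode == "tandem":
            poly_entries[ci].insert(gi + 1, (locus, orient, k, "tandem"))
        else:
            tci = int(rng.integers(len(poly_entries)))
            tgi = int(rng.integers(len(poly_entries[tci]) + 1))
            poly_entries[tci].insert(tgi, (locus, orient, k, "dispersed"))

    # --- coordinate layout + TEs ---------------------------------------
    subg_names = ("LF", "MF1", "MF2")
    ref_gene_of_locus = {l: f"R{l:05d}" for l in range(n_loci)}
    ref_genes = []
    ref_lengths = {}
    for name, chrom in zip(ref_names, ref_chroms):
        pos = 0
        for locus, orient in chrom:
            pos += int(rng_ref.integers(1000, 4001))
            glen = int(rng_ref.integers(1000, 4001))
            ref_genes.append(
                GeneModel(ref_gene_of_locus[locus], name, pos, pos + glen,
                          "+" if orient * anc_strand[locus] > 0 else "-")
            )
            pos += glen
        ref_lengths[name] = pos + 2000
    reference = Genome("reference", ref_genes, ref_lengths)

    poly_names = [f"qchr{i + 1:02d}" for i in range(len(poly_entries))]
    poly_genes: list[GeneModel] = []
    poly_lengths: dict[str, int] = {}
    tes: list[TEFeature] = []
    locus_of_gene: dict[str, int] = {}
    copy_of_gene: dict[str, int] = {}
    subgenome_of_gene: dict[str, str] = {}
    duplicate_mode: dict[str, str] = {}
    serial = 0
    for name, chrom in zip(poly_names, poly_entries):
        pos = 0
        for locus, orient, k, mode in chrom:
            gap = int(rng.integers(1000, 4001))
            lam = cfg.te_rates[k] * gap / 1000.0
            n_te = int(rng.poisson(lam))
            cursor = pos
            for _ in range(n_te):
                tlen = int(rng.geometric(1.0 / cfg.te_mean_length))
                start = cursor + int(rng.integers(0, max(1, gap // max(1, n_te))))
                end = min(start + tlen, pos + gap)
                if end > start:
                    tes.append(TEFeature(name, start, end, f"fam{int(rng.integers(5))}"))
                    cursor = end
            pos += gap
            glen = int(rng.integers(1000, 4001))
            gid = f"Q{serial:05d}"
            serial += 1
            poly_genes.append(
                GeneModel(gid, name, pos, pos + glen,
                          "+" if orient * anc_strand[locus] > 0 else "-")
            )
            locus_of_gene[gid] = locus
            copy_of_gene[gid] = k
            if mode:
                duplicate_mode[gid] = mode
            else:
                subgenome_of_gene[gid] = subg_names[k]
            pos += glen
        poly_lengths[name] = pos + 2000
    polyploid = Genome("polyploid", poly_genes, poly_lengths)

    # --- promoter TE fractions (truth) ---------------------------------
    cov = {}
    for t in tes:
        cov.setdefault(t.chromosome, []).append((t.start, t.end))
    cov = {c: merged_coverage(iv) for c, iv in cov.items()}
    promoter_te: dict[str, float] = {}
    for g in polyploid.genes:
        if g.strand == "+":
            s, e = max(0, g.start - 2000), g.start
        else:
            s, e = g.end, min(poly_lengths[g.chromosome], g.end + 2000)
        c = cov.get(g.chromosome)
        promoter_te[g.gene_id] = (c.covered(s, e) / (e - s)) if (c and e > s) else 0.0

    # --- expression ------------------------------------------------------
    gene_ids = [g.gene_id for g in polyploid.genes]
    base = np.exp(
        rng.normal(cfg.expr_log_mu, cfg.expr_log_sigma, size=len(gene_ids))
        - cfg.dominance_beta * np.array([promoter_te[g] for g in gene_ids])
    )
    lengths = {g.gene_id: g.end - g.start for g in polyploid.genes}
    cols = {}
    for tissue in cfg.tissues:
        level = base * np.exp(rng.normal(0.0, cfg.tissue_sigma, size=len(gene_ids)))
        lam = level * np.array([lengths[g] for g in gene_ids]) / 1000.0
        cols[tissue] = rng.poisson(lam)
    expression = ExpressionTable(
        pd.DataFrame(cols, index=gene_ids).astype(float),
        unit="raw_count",
        gene_length=lengths,
    )

    # --- GO --------------------------------------------------------------
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    go_of_locus = {
        l: set(rng.choice(terms, size=int(rng.integers(1, 5)), replace=False))
        for l in range(n_loci)
    }
    go_query = {g: set(go_of_locus[locus_of_gene[g]]) for g in gene_ids}
    go_ref = {ref_gene_of_locus[l]: set(go_of_locus[l]) for l in range(n_loci)}

    # --- CDS with planted synonymous divergence -------------------------
    nc = cfg.codons_per_gene
    prefixes = rng.integers(0, len(_FOURFOLD_PREFIX_LIST), size=(n_loci, nc))
    anc3 = rng.integers(0, 4, size=(n_loci, nc))
    half = cfg.ks_ref / 2.0
    stem = max(0.0, half - cfg.ks_wgt / 2.0)
    ref3 = _jc_evolve(anc3, half, rng)
    stem3 = _jc_evolve(anc3, stem, rng)
    copy3 = [_jc_evolve(stem3, cfg.ks_wgt / 2.0, rng) for _ in range(3)]
    ref_cds_by_locus = _cds_strings(prefixes, ref3)
    copy_cds_by_locus = [_cds_strings(prefixes, c3) for c3 in copy3]
    ref_cds = {ref_gene_of_locus[l]: ref_cds_by_locus[l] for l in range(n_loci)}
    query_cds = {
        g: copy_cds_by_locus[copy_of_gene[g]][locus_of_gene[g]] for g in gene_ids
    }

    # --- homology hits ---------------------------------------------------
    hits: list[HomologyHit] = []
    for g in gene_ids:
        if g in duplicate_mode:
            continue
        ident = float(np.clip(rng.normal(75, 5), 50, 95))
        hits.append(
            HomologyHit(
                g,
                ref_gene_of_locus[locus_of_gene[g]],
                float(10.0 ** -rng.uniform(50, 180)),
                ident,
                float(np.clip(rng.normal(95, 3), 70, 100)),
                float(ident * 8 + rng.normal(0, 10)),
            )
        )
    n_noise = int(cfg.noise_hit_rate * len(gene_ids))
    ref_ids = list(ref_gene_of_locus.values())
    for _ in range(n_noise):
        q = gene_ids[int(rng.integers(len(gene_ids)))]
        r = ref_ids[int(rng.integers(len(ref_ids)))]
        hits.append(
            HomologyHit(q, r, float(10.0 ** -rng.uniform(5, 30)),
                        float(np.clip(rng.normal(45, 5), 20, 60)),
                        float(np.clip(rng.normal(60, 10), 20, 100)),
                        float(rng.normal(80, 15))),
        )

    genes_by_locus: dict[int, list[str]] = {}
    for g in gene_ids:
        genes_by_locus.setdefault(locus_of_gene[g], []).append(g)
    within: list[tuple[str, str]] = []
    for locus in sorted(genes_by_locus):
        members = sorted(genes_by_locus[locus])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                within.append((members[i], members[j]))

    truth = TruthTables(
        locus_of_gene=locus_of_gene,
        copy_of_gene=copy_of_gene,
        subgenome_of_gene=subgenome_of_gene,
        duplicate_mode=duplicate_mode,
        retained=retained,
        ref_gene_of_locus=ref_gene_of_locus,
        planted_breakpoints=planted_bps,
        planted_associations=planted_assoc,
        truth_blocks=truth_blocks,
        ancestor_karyotype=truth_karyotype,
        promoter_te_fraction=promoter_te,
        expression_baseline={g: float(b) for g, b in zip(gene_ids, base)},
    )
    return SimResult(
        config=cfg,
        reference=reference,
        polyploid=polyploid,
        ref_cds=ref_cds,
        query_cds=query_cds,
        tes=tes,
        hits=hits,
        within_homologs=within,
        expression=expression,
        go_query=go_query,
        go_ref=go_ref,
        truth=truth,
    )
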