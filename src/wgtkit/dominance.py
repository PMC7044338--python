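"""Homoeolog expression dominance and TE density profiling.

Dominance between a sub-genome paralog doublet is called per tissue at a fold
threshold f: the doublet is evaluable when at least one member has TPM > 5
(genes in the bottom 1% of the tissue's expression ranking are treated as not
expressed, i.e. 0); the a-member dominates when TPM_a >= f * TPM_b, and
symmetrically.  Directional bias across doublets is tested with an exact
two-sided binomial test at p = 1/2.  TE load is profiled in 100-bp windows
stepping 10 bp across the gene flanks, and in the 2-kb promoter upstream of
the transcription start site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binomtest, mannwhitneyu

from .core_io import ExpressionTable, GeneModel, Genome, TEFeature, merged_coverage

__all__ = [
    "ParalogDoublet",
    "DominanceCall",
    "BinomialResult",
    "call_dominance",
    "dominance_binomial_test",
    "te_profile",
    "promoter_te_density",
    "compare_te_by_dominance",
    "not_expressed_set",
]

FOLD_THRESHOLDS = (1, 1.5, 2, 3, 4, 6, 10)


@dataclass(frozen=True)
class ParalogDoublet:
    gene_a: str
    gene_b: str
    subgenome_pair: tuple[str, str] = ("LF", "MF1")


@dataclass(frozen=True)
class DominanceCall:
    doublet: ParalogDoublet
    tissue: str
    fold: float
    call: str  # a_dominant | b_dominant | neutral | not_evaluable


def not_expressed_set(expr: ExpressionTable, tissue: str, quantile: float = 0.01) -> set[str]:
    """Bottom-``quantile`` of the tissue's expression ranking (high to low):
    floor(quantile * n) lowest-expressed genes, flagged as not expressed."""
    if tissue not in expr.values.columns:
        raise ValueError(f"unknown tissue: {tissue!r}")
    col = expr.values[tissue]
    k = int(math.floor(quantile * len(col)))
    if k <= 0:
        return set()
    return set(col.sort_values(ascending=True).index[:k])


def call_dominance(
    doublets: Sequence[ParalogDoublet],
    expr: ExpressionTable,
    tissue: str,
    fold: float,
    min_expression: float = 5.0,
) -> list[DominanceCall]:
    """Call expression dominance for each doublet at fold threshold ``fold``."""
    if expr.unit != "TPM":
        raise ValueError("expression must be in TPM (convert with to_tpm)")
    if tissue not in expr.values.columns:
        raise ValueError(f"unknown tissue: {tissue!r}")
    flagged = not_expressed_set(expr, tissue)
    col = expr.values[tissue]
    calls = []
    for d in doublets:
        a = 0.0 if d.gene_a in flagged else float(col.get(d.gene_a, 0.0))
        b = 0.0 if d.gene_b in flagged else float(col.get(d.gene_b, 0.0))
        if max(a, b) <= min_expression:
            call = "not_evaluable"
        else:
            a_dom = a >= fold * b
            b_dom = b >= fold * a
            if a_dom and b_dom:
                call = "neutral"  # only possible at fold <= 1 with a == b
            elif a_dom:
                call = "a_dominant"
            elif b_dom:
                call = "b_dominant"
            else:
                call = "neutral"
        calls.append(DominanceCall(d, tissue, fold, call))
    return calls


@dataclass(frozen=True)
class BinomialResult:
    n_a: int
    n_b: int
    p_value: float          # sum of outcomes no more likely than observed
    p_two_tail: float       # 2 x min tail, capped at 1

    def __float__(self):
        return self.p_value


def dominance_binomial_test(n_a: int, n_b: int) -> BinomialResult:
    """Exact two-sided binomial test of n_a successes in n_a+n_b at p = 1/2.

    The primary p-value sums the probabilities of all outcomes at most as
    likely as the observed count; 2 x min-tail (capped) is reported alongside.
    """
    if n_a < 0 or n_b < 0 or n_a + n_b < 1:
        raise ValueError("need non-negative counts with n_a + n_b >= 1")
    n = n_a + n_b
    p = float(binomtest(n_a, n, 0.5).pvalue)
    from scipy.stats import binom

    tail = min(binom.cdf(n_a, n, 0.5), binom.sf(n_a - 1, n, 0.5))
    return BinomialResult(n_a, n_b, p, min(1.0, 2.0 * float(tail)))


# ---------------------------------------------------------------------------
# TE density
# ---------------------------------------------------------------------------

def _te_coverage_by_chrom(tes: Iterable[TEFeature]) -> dict[str, merged_coverage]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in tes:
        by_chrom.setdefault(t.chromosome, []).append((t.start, t.end))
    return {c: merged_coverage(iv) for c, iv in by_chrom.items()}


def te_profile(
    genes: Sequence[GeneModel],
    tes: Iterable[TEFeature],
    chromosome_lengths: Mapping[str, int],
    flank_bp: int = 3000,
    window: int = 100,
    step: int = 10,
) -> dict[str, np.ndarray]:
    """Mean TE nucleotide fraction in sliding windows across the gene flanks.

    Windows run across the 5' and 3' flanking regions (strand-aware, offsets
    relative to the gene boundary); TEs are merged before counting; windows
    extending past a chromosome end are dropped from that gene's contribution.
    Returns {"five_prime": ..., "three_prime": ...}, each of length
    (flank_bp - window) // step + 1 ordered from the gene boundary outward.
    """
    cov = _te_coverage_by_chrom(tes)
    nbins = (flank_bp - window) // step + 1
    sums = {side: np.zeros(nbins) for side in ("five_prime", "three_prime")}
    counts = {side: np.zeros(nbins) for side in ("five_prime", "three_prime")}
    for g in genes:
        c = cov.get(g.chromosome)
        L = chromosome_lengths.get(g.chromosome)
        if L is None:
            raise ValueError(f"no chromosome length for {g.chromosome}")
        for side in ("five_prime", "three_prime"):
            upstream = (side == "five_prime") == (g.strand == "+")
            for i in range(nbins):
                off = i * step
                if upstream:
                    s = g.start - off - window
                    e = g.start - off
                else:
                    s = g.end + off
                    e = g.end + off + window
                if s < 0 or e > L:
                    continue
                frac = (c.covered(s, e) / window) if c is not None else 0.0
                sums[side][i] += frac
                counts[side][i] += 1
    out = {}
    for side in ("five_prime", "three_prime"):
        with np.errstate(invalid="ignore"):
            out[side] = np.where(counts[side] > 0, sums[side] / counts[side], np.nan)
    return out


def promoter_te_density(
    gene: GeneModel,
    tes: Iterable[TEFeature] | merged_coverage | dict,
    chromosome_length: int,
    upstream: int = 2000,
) -> float:
    """Merged-TE covered fraction of the promoter (2 kb upstream of the TSS).

    The promoter is truncated at the chromosome boundary; for a minus-strand
    gene it extends rightward of the gene end.
    """
    if isinstance(tes, dict):
        cov = tes.get(gene.chromosome)
    elif isinstance(tes, merged_coverage):
        cov = tes
    else:
        cov = _te_coverage_by_chrom(t for t in tes if t.chromosome == gene.chromosome).get(
            gene.chromosome
        )
    if gene.strand == "+":
        s, e = max(0, gene.start - upstream), gene.start
    else:
        s, e = gene.end, min(chromosome_length, gene.end + upstream)
    if e <= s:
        return 0.0
    covered = cov.covered(s, e) if cov is not None else 0
    return covered / (e - s)


@dataclass
class TEDominanceSummary:
    n_doublets: int
    mean_density_dominant: float
    mean_density_suppressed: float
    p_value: float


def compare_te_by_dominance(
    calls: Sequence[DominanceCall],
    promoter_density: Mapping[str, float],
) -> TEDominanceSummary:
    """Promoter TE load of dominant vs suppressed doublet members.

    Uses doublets with a directional call at the calls' single fold level and
    reports group means plus a two-sided Wilcoxon rank-sum p-value.
    """
    dom, sup = [], []
    for c in calls:
        if c.call == "a_dominant":
            d, s = c.doublet.gene_a, c.doublet.gene_b
        elif c.call == "b_dominant":
            d, s = c.doublet.gene_b, c.doublet.gene_a
        else:
            continue
        if d in promoter_density and s in promoter_density:
            dom.append(promoter_density[d])
            sup.append(promoter_density[s])
    if len(dom) < 2:
        raise ValueError("fewer than 2 evaluable directional doublets")
    if np.ptp(dom + sup) == 0:
        p = 1.0
    else:
        p = float(mannwhitneyu(dom, sup, alternative="two-sided").pvalue)
    return TEDominanceSummary(len(dom), float(np.mean(dom)), float(np.mean(sup)), p)
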