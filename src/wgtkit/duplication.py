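"""Duplication-mode classification, GO over-retention enrichment, and
homology-threshold ortholog filtering.

Duplicated genes are classified with priority WGT > tandem > dispersed: a
gene with a syntenic ortholog in any reference species is a polyploidy (WGT)
duplicate; otherwise a homolog on the same chromosome within a few
intervening genes makes it tandem; any remaining homolog-bearing gene is a
dispersed duplicate, and genes without homologs are singletons.  GO
over-retention is tested per term with one-sided (greater) Fisher's exact
tests, Benjamini–Hochberg corrected across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import false_discovery_control, hypergeom

from .core_io import Genome, HomologyHit

__all__ = [
    "OrthologFilter",
    "EnrichmentResult",
    "classify_duplications",
    "fisher_enrichment",
    "ortholog_filter",
    "copy_number_table",
]


def classify_duplications(
    genome: Genome,
    synteny_flags: Mapping[str, bool] | set,
    homology_pairs: Iterable[tuple[str, str]],
    tandem_max_intervening: int = 5,
) -> dict[str, str]:
    """gene_id -> {WGT, tandem, dispersed, singleton}.

    ``synteny_flags`` marks genes with a syntenic ortholog in at least one
    reference species; ``homology_pairs`` are within-genome homolog pairs.
    """
    if not isinstance(synteny_flags, (set, frozenset)):
        synteny_flags = {g for g, v in synteny_flags.items() if v}
    partners: dict[str, set[str]] = {g.gene_id: set() for g in genome.genes}
    for a, b in homology_pairs:
        if a == b or a not in partners or b not in partners:
            continue
        partners[a].add(b)
        partners[b].add(a)
    out: dict[str, str] = {}
    for g in genome.genes:
        gid = g.gene_id
        if gid in synteny_flags:
            out[gid] = "WGT"
        elif not partners[gid]:
            out[gid] = "singleton"
        elif any(
            genome[h].chromosome == g.chromosome
            and abs(genome[h].rank - g.rank) - 1 <= tandem_max_intervening
            for h in partners[gid]
        ):
            out[gid] = "tandem"
        else:
            out[gid] = "dispersed"
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    a: int  # study & annotated
    b: int  # study & not annotated
    c: int  # non-study & annotated
    d: int  # non-study & not annotated
    odds_ratio: float
    p_value: float
    q_value: float


def fisher_enrichment(
    go: Mapping[str, set[str]],
    study_set: set[str],
    universe: set[str],
) -> list[EnrichmentResult]:
    """One-sided (greater) Fisher's exact test per GO term, BH-corrected.

    Tests every term with at least one study-set member; the one-sided p is
    the hypergeometric upper tail P(X >= a).  Results are sorted by q then p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not study_set <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in go.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    M, N = len(universe), len(study_set)
    rows = []
    for term in sorted(term_genes):
        annotated = term_genes[term]
        a = len(annotated & study_set)
        if a == 0:
            continue
        n = len(annotated)
        b = N - a
        c = n - a
        d = M - N - c
        p = float(hypergeom.sf(a - 1, M, n, N))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((term, a, b, c, d, odds, p))
    if not rows:
        return []
    qs = false_discovery_control([r[6] for r in rows], method="bh")
    results = [
        EnrichmentResult(term, a, b, c, d, odds, p, float(q))
        for (term, a, b, c, d, odds, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results


@dataclass(frozen=True)
class OrthologFilter:
    """Alignment-hit thresholds for ortholog identification."""

    max_e: float = 1e-20
    min_coverage: float = 50.0
    min_identity: float = 35.0


def ortholog_filter(
    hits: Iterable[HomologyHit], f: OrthologFilter = OrthologFilter()
) -> set[str]:
    """Distinct query genes with a hit passing all thresholds:
    e-value <= max_e AND coverage > min_coverage AND identity > min_identity."""
    kept = set()
    for h in hits:
        if (
            h.e_value <= f.max_e
            and h.coverage_pct > f.min_coverage
            and h.identity_pct > f.min_identity
        ):
            kept.add(h.query_id)
    return kept


def copy_number_table(ref_to_copies: Mapping[str, Sequence[str]]) -> dict[int, int]:
    """Histogram of reference genes by number of retained polyploid copies.

    Multiplicities above 3 violate the triplication model and raise.
    """
    hist = {0: 0, 1: 0, 2: 0, 3: 0}
    for ref_gene, copies in ref_to_copies.items():
        m = len(set(copies))
        if m > 3:
            raise ValueError(
                f"reference gene {ref_gene} maps to {m} copies (> 3)"
            )
        hist[m] += 1
    return hist
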