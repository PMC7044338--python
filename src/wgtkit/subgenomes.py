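"""Sub-genome partitioning of a triplicated genome and retention statistics.

After a whole-genome triplication, each ancestral region is present in up to
three copies that fractionate (lose genes) at different rates.  This module
groups syntenic fragments into the three copies, ranks the copies of each
ancestral chromosome by retained-gene density in a sliding window of 1001
ancestor loci (500 each side), and names them LF (least fractionated), MF1
and MF2 (more fractionated 1 and 2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import chi2_contingency

from .blocks import AncestralKaryotype, GenomicBlock
from .core_io import Genome
from .synteny import SyntenicFragment, SyntenicPair

__all__ = [
    "SUBGENOME_LABELS",
    "RetentionCounts",
    "SubgenomeAssignment",
    "assign_fragment_copies",
    "retention_profile",
    "assign_subgenomes",
    "reconstruct_subgenome_chromosomes",
    "retention_counts",
    "retention_uniformity_test",
]

SUBGENOME_LABELS = ("LF", "MF1", "MF2")

_ENUMERATION_CAP = 8  # chains per conflict component before greedy fallback


_MIN_SHARED = 5  # covered ranks two chains must share to be called conflicting


def _color_chains(
    covered: list[set[int]],
    gap_tolerance: int = 10,
) -> list[int]:
    """Proper <=3-coloring of chains under shared-coverage conflicts.

    Two chains conflict (descend from different copies) when they cover at
    least ``_MIN_SHARED`` of the same ancestor ranks — span overlap alone is
    not enough, because a single spurious pair can inflate a fragment's span.
    Colorings are enumerated exhaustively per conflict component (capped;
    greedy first-fit beyond the cap, with a warning), choosing the one with
    the fewest implied rearrangement joins: a same-color chain pair costs
    nothing only when the gap between their spans is within ``gap_tolerance``
    ranks (a clean fission cut).  Ties break lexicographically, making the
    result deterministic.
    """
    k = len(covered)
    spans = [(min(c), max(c)) if c else (0, -1) for c in covered]
    conflict = [[False] * k for _ in range(k)]
    adj = [[0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if len(covered[i] & covered[j]) >= _MIN_SHARED:
                conflict[i][j] = conflict[j][i] = True
            else:
                gap = max(spans[i][0], spans[j][0]) - min(spans[i][1], spans[j][1])
                adj[i][j] = adj[j][i] = 0 if gap <= gap_tolerance else 1

    # connected components of the conflict graph (plus singletons)
    comp = list(range(k))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if conflict[i][j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    comp[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)

    colors = [0] * k
    for members in groups.values():
        if len(members) == 1:
            colors[members[0]] = 0
            continue
        if len(members) <= _ENUMERATION_CAP:
            best = None
            for assign in itertools.product(range(3), repeat=len(members)):
                ok = True
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        if assign[a] == assign[b] and conflict[members[a]][members[b]]:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                cost = sum(
                    adj[members[a]][members[b]]
                    for a in range(len(members))
                    for b in range(a + 1, len(members))
                    if assign[a] == assign[b]
                )
                # prefer packing complementary (fission-split) chains into one
                # copy over leaving them in separate colors
                cand = (cost, len(set(assign)), assign)
                if best is None or cand < best:
                    best = cand
            if best is None:
                raise ValueError(
                    "more than three mutually overlapping copies: violates the "
                    "triplication model"
                )
            for m, c in zip(members, best[2]):
                colors[m] = c
        else:
            warnings.warn(
                "conflict component larger than the enumeration cap; using "
                "greedy first-fit coloring",
                stacklevel=2,
            )
            order = sorted(members, key=lambda m: spans[m])
            for m in order:
                used = {
                    colors[o] for o in order[: order.index(m)] if conflict[m][o]
                }
                free = [c for c in range(3) if c not in used]
                if not free:
                    raise ValueError(
                        "more than three mutually overlapping copies: violates "
                        "the triplication model"
                    )
                colors[m] = free[0]
    return colors


def assign_fragment_copies(
    fragments: Sequence[SyntenicFragment], ref: Genome
) -> dict[tuple[str, int], list[SyntenicFragment]]:
    """Group fragments into <=3 sub-genome copies per reference chromosome.

    Fragments on the same query chromosome with disjoint reference spans are
    pre-chained (they descend from one copy); chains are then 3-colored under
    the rule that copies may not overlap the same reference interval.  Sets
    ``copy_id`` on each fragment and returns {(ref_chrom, copy): fragments}.
    """
    by_ref: dict[str, list[SyntenicFragment]] = {}
    for f in fragments:
        by_ref.setdefault(f.ref_chrom, []).append(f)

    out: dict[tuple[str, int], list[SyntenicFragment]] = {}
    for chrom in sorted(by_ref):
        frags = sorted(by_ref[chrom], key=lambda f: (f.query_chrom, f.query_start))

        def frag_cov(f):
            return {ref[p.ref_gene].rank for p in f.pairs}

        chains: list[list[SyntenicFragment]] = []
        chain_cov: list[set[int]] = []
        for f in frags:
            fc = frag_cov(f)
            if (
                chains
                and chains[-1][-1].query_chrom == f.query_chrom
                and len(chain_cov[-1] & fc) < _MIN_SHARED
            ):
                chains[-1].append(f)
                chain_cov[-1] |= fc
            else:
                chains.append([f])
                chain_cov.append(set(fc))
        colors = _color_chains(chain_cov)
        for chain, color in zip(chains, colors):
            for f in chain:
                f.copy_id = color
            out.setdefault((chrom, color), []).extend(chain)
    return out


def retention_profile(
    n_loci: int,
    retained_masks: Mapping[object, np.ndarray],
    window: int = 1001,
) -> dict[object, np.ndarray]:
    """Percent retained homologs per copy in a centred window of ancestor loci.

    ``retained_masks`` maps copy -> boolean array over the ancestor gene
    order.  The window (default 1001 = 500 each side) is truncated at the
    ends and never crosses the unit it is called on.
    """
    if window < 3:
        raise ValueError("window must be at least 3")
    half = window // 2
    idx = np.arange(n_loci)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n_loci, idx + half + 1)
    out = {}
    for copy, mask in retained_masks.items():
        mask = np.asarray(mask, dtype=float)
        if mask.shape[0] != n_loci:
            raise ValueError("mask length does not match locus count")
        csum = np.concatenate([[0.0], np.cumsum(mask)])
        out[copy] = 100.0 * (csum[hi] - csum[lo]) / (hi - lo)
    return out


@dataclass
class SubgenomeUnit:
    """One ancestral chromosome: its blocks, copies, and retention densities."""

    unit_id: int
    blocks: list[GenomicBlock]
    locus_ids: list[str]                       # ancestor (reference) gene ids, in order
    copy_fragments: dict[int, list[SyntenicFragment]]
    copy_retained: dict[int, np.ndarray]
    copy_density: dict[int, float]
    labels: dict[int, str]                     # copy -> LF/MF1/MF2


@dataclass
class SubgenomeAssignment:
    units: list[SubgenomeUnit]
    gene_labels: dict[str, str]                # query gene -> LF/MF1/MF2
    fragment_labels: dict[int, str]            # fragment_id -> label

    def label_of(self, query_gene: str) -> str | None:
        return self.gene_labels.get(query_gene)


def assign_subgenomes(
    karyotype: AncestralKaryotype,
    blocks: Sequence[GenomicBlock],
    fragments: Sequence[SyntenicFragment],
    ref: Genome,
    window: int = 1001,
) -> SubgenomeAssignment:
    """Rank the copies of each ancestral chromosome by retention density.

    The unit of assignment is the ancestral chromosome (its ordered blocks);
    per unit, copies are grouped from fragments (same rules as
    :func:`assign_fragment_copies`, in ancestral-locus coordinates), their
    1001-gene retention profiles averaged, and the densest copy named LF,
    then MF1, then MF2.  Ties break by total retained genes, then by the
    smallest query chromosome name.
    """
    block_by_label = {b.label: b for b in blocks}
    units: list[SubgenomeUnit] = []
    gene_labels: dict[str, str] = {}
    fragment_labels: dict[int, str] = {}
    for uid, chrom_blocks in enumerate(karyotype.chromosomes):
        blocks_in_unit = [block_by_label[lab] for lab, _ in chrom_blocks]
        # ancestor locus order: concatenated block gene ranks
        locus_ids: list[str] = []
        locus_index: dict[str, int] = {}
        for (lab, ori), b in zip(chrom_blocks, blocks_in_unit):
            ranks = range(b.rank_start, b.rank_end)
            if ori == "inverted":
                ranks = reversed(list(ranks))
            for r in ranks:
                gid = ref.gene_at(b.ref_chrom, r).gene_id
                locus_index[gid] = len(locus_ids)
                locus_ids.append(gid)

        # membership by covered loci (a fission-split fragment covering less
        # than half a block still belongs to the unit for retention purposes)
        unit_frags = [
            f
            for f in fragments
            if sum(p.ref_gene in locus_index for p in f.pairs) >= _MIN_SHARED
        ]
        if not unit_frags:
            continue

        # one node per (reference chromosome, copy): the per-reference-
        # chromosome 3-coloring already guarantees at most three copies each;
        # copy identities are then aligned across the unit's reference
        # chromosomes by maximizing query-chromosome co-occurrence (a copy's
        # material travels together unless a rearrangement separated it)
        nodes: dict[tuple, list[SyntenicFragment]] = {}
        for f in sorted(unit_frags, key=lambda f: (f.query_chrom, f.query_start)):
            nodes.setdefault((f.ref_chrom, f.copy_id), []).append(f)
        ref_chroms = sorted({rc for rc, _ in nodes})
        qcounts: dict[tuple, dict[str, int]] = {}
        for key, frs in nodes.items():
            cnt: dict[str, int] = {}
            for f in frs:
                n_in = sum(p.ref_gene in locus_index for p in f.pairs)
                cnt[f.query_chrom] = cnt.get(f.query_chrom, 0) + n_in
            qcounts[key] = cnt

        def cooccurrence(u, v):
            cu, cv = qcounts[u], qcounts[v]
            return sum(min(cu[q], cv[q]) for q in cu.keys() & cv.keys())

        colors_per_chrom = {
            rc: sorted(c for rc2, c in nodes if rc2 == rc) for rc in ref_chroms
        }
        if any(len(v) > 3 for v in colors_per_chrom.values()):
            raise ValueError(
                "more than three copies on a reference chromosome: violates "
                "the triplication model"
            )
        if len(ref_chroms) <= 6:
            best = None
            group_maps = [
                list(itertools.permutations(range(3), len(colors_per_chrom[rc])))
                for rc in ref_chroms
            ]
            for combo in itertools.product(*group_maps):
                grouping = {}
                for rc, perm in zip(ref_chroms, combo):
                    for color, g in zip(colors_per_chrom[rc], perm):
                        grouping[(rc, color)] = g
                score = sum(
                    cooccurrence(u, v)
                    for u, v in itertools.combinations(sorted(grouping), 2)
                    if grouping[u] == grouping[v]
                )
                cand = (-score, tuple(sorted(grouping.items())))
                if best is None or cand < best[0]:
                    best = (cand, grouping)
            grouping = best[1]
        else:  # very large units: align each chromosome greedily in turn
            grouping = {}
            for rc in ref_chroms:
                best_perm = None
                for perm in itertools.permutations(range(3), len(colors_per_chrom[rc])):
                    trial = dict(
                        zip(((rc, c) for c in colors_per_chrom[rc]), perm)
                    )
                    score = sum(
                        cooccurrence(u, v)
                        for u in trial
                        for v in grouping
                        if trial[u] == grouping[v]
                    )
                    cand = (-score, perm)
                    if best_perm is None or cand < best_perm:
                        best_perm = cand
                for color, g in zip(colors_per_chrom[rc], best_perm[1]):
                    grouping[(rc, color)] = g

        copy_fragments: dict[int, list[SyntenicFragment]] = {}
        copy_retained: dict[int, np.ndarray] = {}
        for key, frs in nodes.items():
            copy_fragments.setdefault(grouping[key], []).extend(frs)
        for color, frs in copy_fragments.items():
            mask = np.zeros(len(locus_ids), dtype=bool)
            for f in frs:
                for p in f.pairs:
                    i = locus_index.get(p.ref_gene)
                    if i is not None:
                        mask[i] = True
            copy_retained[color] = mask
        profiles = retention_profile(len(locus_ids), copy_retained, window=window)
        density = {c: float(np.mean(v)) for c, v in profiles.items()}

        ranked = sorted(
            density,
            key=lambda c: (
                -density[c],
                -int(copy_retained[c].sum()),
                min(f.query_chrom for f in copy_fragments[c]),
            ),
        )
        labels = {c: SUBGENOME_LABELS[i] for i, c in enumerate(ranked[:3])}
        units.append(
            SubgenomeUnit(
                uid, blocks_in_unit, locus_ids, copy_fragments, copy_retained,
                density, labels,
            )
        )
        for color, frs in copy_fragments.items():
            lab = labels.get(color)
            if lab is None:
                continue
            for f in frs:
                fragment_labels[f.fragment_id] = lab
                for p in f.pairs:
                    gene_labels[p.query_gene] = lab
    return SubgenomeAssignment(units, gene_labels, fragment_labels)


def reconstruct_subgenome_chromosomes(
    assignment: SubgenomeAssignment,
) -> dict[str, list[list[str]]]:
    """Per sub-genome block painting of each ancestral chromosome.

    Returns {label: [ordered oriented block labels per unit, ...]}, asserting
    the hard rule that one painting never holds two fragments covering the
    same ancestral interval.
    """
    paintings: dict[str, list[list[str]]] = {lab: [] for lab in SUBGENOME_LABELS}
    for unit in assignment.units:
        for color, frags in unit.copy_fragments.items():
            lab = unit.labels.get(color)
            if lab is None:
                continue
            # rule 1: no two fragments of one painting may cover the same
            # ancestral loci (shared covered loci, not just touching spans —
            # a single spurious pair can inflate a fragment's span)
            seen: dict[str, set] = {}
            for f in frags:
                fset = {p.ref_gene for p in f.pairs}
                prev = seen.setdefault(f.ref_chrom, set())
                if len(prev & fset) >= _MIN_SHARED:
                    raise AssertionError(
                        f"painting invariant violated: fragment {f.fragment_id} "
                        f"re-covers ancestral loci already painted in {lab}"
                    )
                prev |= fset
            ordered = sorted(
                frags, key=lambda f: (f.query_chrom, f.query_start)
            )
            row = []
            for f in ordered:
                for b in unit.blocks:
                    lo, hi = f.ref_rank_span
                    if b.ref_chrom == f.ref_chrom:
                        ov = min(hi + 1, b.rank_end) - max(lo, b.rank_start)
                        if ov >= 0.5 * b.n_genes:
                            row.append(
                                b.label + ("" if f.orientation == "forward" else "'")
                            )
            paintings[lab].append(row)
    return paintings


@dataclass
class RetentionCounts:
    per_subgenome: dict[str, int]
    multiplicity: dict[int, int]        # ref genes with 0/1/2/3 retained copies
    chi2_gof: float
    p_gof: float
    chi2_homogeneity: float | None
    p_homogeneity: float | None


def retention_uniformity_test(
    observed: Sequence[int], n_opportunities: int | None = None
) -> tuple[float, float, float | None, float | None]:
    """Chi-square tests of equal retention across sub-genome copies.

    Returns (chi2_gof, p_gof, chi2_homogeneity, p_homogeneity).  The
    goodness-of-fit statistic tests the retained counts against their mean
    (df = k-1).  When ``n_opportunities`` (ancestral loci per copy) is given,
    a retained/lost homogeneity chi-square is also computed; under the
    independent per-copy gene-loss model this construction, unlike the
    goodness-of-fit one, has a uniformly distributed null p-value.
    """
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    if total <= 0:
        return 0.0, 1.0, None, None
    expected = total / len(obs)
    chi2_gof = float(((obs - expected) ** 2 / expected).sum())
    p_gof = float(_chi2.sf(chi2_gof, df=len(obs) - 1))
    chi2_h = p_h = None
    if n_opportunities is not None:
        lost = np.maximum(n_opportunities - obs, 0)
        table = np.vstack([obs, lost])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            res = chi2_contingency(table, correction=False)
            chi2_h, p_h = float(res.statistic), float(res.pvalue)
    return chi2_gof, p_gof, chi2_h, p_h


def retention_counts(
    assignment: SubgenomeAssignment,
    pairs: Sequence[SyntenicPair],
    n_ref_genes: int | None = None,
) -> RetentionCounts:
    """Retained-gene counts per sub-genome with uniformity chi-square tests.

    The goodness-of-fit chi-square tests the three retained counts against
    equal retention (df = 2).  When ``n_ref_genes`` is given, a 2x3
    retained/lost homogeneity chi-square is also computed; under independent
    per-copy gene loss this construction, unlike the goodness-of-fit one, has
    a calibrated null p-value.
    """
    counts = {lab: 0 for lab in SUBGENOME_LABELS}
    for gene, lab in assignment.gene_labels.items():
        counts[lab] += 1

    per_ref: dict[str, set[str]] = {}
    for p in pairs:
        if p.query_gene in assignment.gene_labels:
            per_ref.setdefault(p.ref_gene, set()).add(
                assignment.gene_labels[p.query_gene]
            )
    multiplicity = {0: 0, 1: 0, 2: 0, 3: 0}
    for ref_gene, labs in per_ref.items():
        m = len(labs)
        if m > 3:
            raise ValueError(f"reference gene {ref_gene} has {m} retained copies")
        multiplicity[m] += 1
    if n_ref_genes is not None:
        multiplicity[0] = n_ref_genes - sum(
            v for k, v in multiplicity.items() if k > 0
        )

    observed = [counts[lab] for lab in SUBGENOME_LABELS]
    chi2_gof, p_gof, chi2_h, p_h = retention_uniformity_test(observed, n_ref_genes)
    return RetentionCounts(counts, multiplicity, chi2_gof, p_gof, chi2_h, p_h)
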