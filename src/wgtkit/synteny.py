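"""Syntenic gene-pair detection and fragment assembly.

A homology hit (q, r) between the polyploid query and the diploid reference is
promoted to a *syntenic pair* when the genes flanking q corroborate it: among
the ``flank_window`` genes on each side of q, at least ``min_support`` must
themselves hit a gene within ``flank_window`` ranks of r.  Pairs are then
chained into *syntenic fragments* — maximal runs of collinear pairs treated as
intact inherited ancestral segments — under the interruption rule: two pairs
are chainable iff, in each genome separately, fewer than ``max_intervening``
genes lie between them OR they are less than ``max_gap`` bp apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import Genome, HomologyHit

__all__ = [
    "SyntenyConfig",
    "SyntenicPair",
    "SyntenicFragment",
    "find_syntenic_pairs",
    "assemble_fragments",
    "filter_fragments",
    "dotplot_table",
]


@dataclass(frozen=True)
class SyntenyConfig:
    flank_window: int = 20
    min_support: int = 2
    max_intervening: int = 50       # exclusive: "< 50 genes"
    max_gap: int = 200_000          # exclusive: "< 200 kb"
    min_fragment_span: int = 200_000  # strict: "longer than 200 kb"
    max_pairings_per_ref: int = 3   # triplicated genome: <= 3 query copies

    def __post_init__(self):
        for name in ("flank_window", "min_support", "max_intervening",
                     "max_gap", "min_fragment_span", "max_pairings_per_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SyntenicPair:
    query_gene: str
    ref_gene: str
    support: int
    bitscore: float = 0.0


@dataclass
class SyntenicFragment:
    """A maximal monotone run of syntenic pairs on one (query, ref) chromosome lane."""

    fragment_id: int
    pairs: list[SyntenicPair]
    query_chrom: str
    query_start: int
    query_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    orientation: str  # "forward" | "inverted"
    query_rank_span: tuple[int, int] = (0, 0)
    ref_rank_span: tuple[int, int] = (0, 0)
    copy_id: int | None = None

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def find_syntenic_pairs(
    query: Genome,
    ref: Genome,
    hits: Iterable[HomologyHit],
    cfg: SyntenyConfig = SyntenyConfig(),
) -> list[SyntenicPair]:
    """Accept hits corroborated by flanking homologous pairs.

    At most ``cfg.max_pairings_per_ref`` query genes are retained per
    reference gene, ranked by support, then bitscore, then gene id.
    """
    hits = [h for h in hits if h.query_id in query and h.subject_id in ref]
    # query gene -> {(ref chrom, ref rank), ...}
    targets: dict[str, set[tuple[str, int]]] = {}
    best_bits: dict[tuple[str, str], float] = {}
    for h in hits:
        rg = ref[h.subject_id]
        targets.setdefault(h.query_id, set()).add((rg.chromosome, rg.rank))
        key = (h.query_id, h.subject_id)
        if h.bitscore > best_bits.get(key, -1.0):
            best_bits[key] = h.bitscore

    W = cfg.flank_window
    accepted: list[SyntenicPair] = []
    for (qid, rid) in sorted(best_bits):
        qg, rg = query[qid], ref[rid]
        chrom_genes = query.genes_on(qg.chromosome)
        lo = max(0, qg.rank - W)
        hi = min(len(chrom_genes), qg.rank + W + 1)
        support = 0
        for nb in chrom_genes[lo:hi]:
            if nb.gene_id == qid:
                continue
            for (tchrom, trank) in targets.get(nb.gene_id, ()):
                if tchrom == rg.chromosome and abs(trank - rg.rank) <= W:
                    support += 1
                    break
        if support >= cfg.min_support:
            accepted.append(
                SyntenicPair(qid, rid, support, best_bits[(qid, rid)])
            )

    # cap pairings per reference gene
    by_ref: dict[str, list[SyntenicPair]] = {}
    for p in accepted:
        by_ref.setdefault(p.ref_gene, []).append(p)
    kept: list[SyntenicPair] = []
    for rid, plist in by_ref.items():
        plist.sort(key=lambda p: (-p.support, -p.bitscore, p.query_gene))
        kept.extend(plist[: cfg.max_pairings_per_ref])
    kept.sort(key=lambda p: (p.query_gene, p.ref_gene))
    return kept


def _chainable(p1, p2, query: Genome, ref: Genome, cfg: SyntenyConfig) -> bool:
    """Proximity test in each genome: (< max_intervening genes) OR (< max_gap bp)."""
    for genome, a_id, b_id in ((query, p1.query_gene, p2.query_gene),
                               (ref, p1.ref_gene, p2.ref_gene)):
        a, b = genome[a_id], genome[b_id]
        intervening = abs(a.rank - b.rank) - 1
        gap = max(0, max(a.start, b.start) - min(a.end, b.end))
        if not (intervening < cfg.max_intervening or gap < cfg.max_gap):
            return False
    return True


def assemble_fragments(
    pairs: Sequence[SyntenicPair],
    query: Genome,
    ref: Genome,
    cfg: SyntenyConfig = SyntenyConfig(),
) -> list[SyntenicFragment]:
    """Partition pairs into fragments: connected components of the
    chainability relation, split into maximal monotone ref-rank runs.

    The result is invariant to input order (pairs are sorted internally) and
    partitions the input: every pair lands in exactly one fragment.
    """
    lanes: dict[tuple[str, str], list[SyntenicPair]] = {}
    for p in pairs:
        lane = (query[p.query_gene].chromosome, ref[p.ref_gene].chromosome)
        lanes.setdefault(lane, []).append(p)

    fragments: list[SyntenicFragment] = []
    fid = 0
    for lane in sorted(lanes):
        lane_pairs = sorted(
            lanes[lane],
            key=lambda p: (query[p.query_gene].rank, ref[p.ref_gene].rank, p.query_gene),
        )
        n = len(lane_pairs)
        # union-find over chainability
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            qi = query[lane_pairs[i].query_gene]
            for j in range(i + 1, n):
                qj = query[lane_pairs[j].query_gene]
                # sorted by query rank: once the query-side test fails it
                # fails for every later j too, so the scan can stop early
                if (qj.rank - qi.rank - 1 >= cfg.max_intervening
                        and max(0, qj.start - qi.end) >= cfg.max_gap):
                    break
                if _chainable(lane_pairs[i], lane_pairs[j], query, ref, cfg):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comps: dict[int, list[SyntenicPair]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(lane_pairs[i])
        for root in sorted(comps, key=lambda r: query[comps[r][0].query_gene].rank):
            for run in _monotone_runs(comps[root], ref):
                fragments.append(_make_fragment(fid, run, query, ref))
                fid += 1
    return fragments


def _monotone_runs(
    comp: list[SyntenicPair], ref: Genome
) -> list[list[SyntenicPair]]:
    """Split a query-rank-ordered component into maximal runs of strictly
    monotone reference rank (direction fixed by the first step)."""
    runs: list[list[SyntenicPair]] = []
    cur = [comp[0]]
    direction = 0
    for p in comp[1:]:
        prev_rank = ref[cur[-1].ref_gene].rank
        rank = ref[p.ref_gene].rank
        step = 1 if rank > prev_rank else (-1 if rank < prev_rank else 0)
        if step == 0 or (direction and step != direction):
            runs.append(cur)
            cur = [p]
            direction = 0
        else:
            if not direction:
                direction = step
            cur.append(p)
    runs.append(cur)

    # Repair boundary artifacts of the greedy split.  A single spurious pair
    # (an accepted off-diagonal hit) or the first pair of an inverted segment
    # lands at the tail of the preceding run and severs an otherwise clean
    # run; isolate such outliers into singleton runs and re-join, or hand
    # boundary strays to the run they are rank-adjacent to.
    def _rank(p):
        return ref[p.ref_gene].rank

    def _is_monotone(run):
        rs = [_rank(p) for p in run]
        steps = {(a < b) - (a > b) for a, b in zip(rs[:-1], rs[1:])}
        return 0 not in steps and len(steps) <= 1

    guard = 2 * len(comp) + 10
    changed = True
    while changed and guard > 0:
        guard -= 1
        changed = False
        for k in range(len(runs) - 1):
            r1, r2 = runs[k], runs[k + 1]
            if len(r1) >= 2:
                jump_in = abs(_rank(r1[-1]) - _rank(r1[-2]))
                bridge = abs(_rank(r2[0]) - _rank(r1[-2]))
                jump_next = abs(_rank(r2[0]) - _rank(r1[-1]))
                if bridge < jump_in and _is_monotone(r1[:-1] + r2):
                    outlier = r1[-1]
                    runs[k: k + 2] = [r1[:-1] + r2, [outlier]]
                    changed = True
                    break
                if jump_next < jump_in and _is_monotone([r1[-1]] + r2):
                    r2.insert(0, r1.pop())
                    changed = True
                    break
    return [r for r in runs if r]


def _make_fragment(fid, run, query, ref) -> SyntenicFragment:
    qg = [query[p.query_gene] for p in run]
    rg = [ref[p.ref_gene] for p in run]
    ref_ranks = [g.rank for g in rg]
    orientation = "inverted" if len(run) > 1 and ref_ranks[-1] < ref_ranks[0] else "forward"
    return SyntenicFragment(
        fragment_id=fid,
        pairs=list(run),
        query_chrom=qg[0].chromosome,
        query_start=min(g.start for g in qg),
        query_end=max(g.end for g in qg),
        ref_chrom=rg[0].chromosome,
        ref_start=min(g.start for g in rg),
        ref_end=max(g.end for g in rg),
        orientation=orientation,
        query_rank_span=(min(g.rank for g in qg), max(g.rank for g in qg)),
        ref_rank_span=(min(ref_ranks), max(ref_ranks)),
    )


def filter_fragments(
    fragments: Iterable[SyntenicFragment], cfg: SyntenyConfig = SyntenyConfig()
) -> list[SyntenicFragment]:
    """Keep fragments whose query span is strictly longer than the minimum."""
    return [f for f in fragments if f.query_span > cfg.min_fragment_span]


def dotplot_table(fragments: Iterable[SyntenicFragment]) -> pd.DataFrame:
    """Lossless per-pair export for dot plotting (one row per syntenic pair)."""
    rows = []
    for f in fragments:
        for p in f.pairs:
            rows.append(
                (p.query_gene, f.query_chrom, p.ref_gene, f.ref_chrom,
                 f.fragment_id, f.orientation)
            )
    return pd.DataFrame(
        rows,
        columns=["query_gene", "query_chrom", "ref_gene", "ref_chrom",
                 "fragment_id", "orientation"],
    )
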