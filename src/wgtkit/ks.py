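"""Codon-level Ks/Ka estimation and Ks-based dating of polyploidy events.

The estimator is the Nei–Gojobori (1986) method: per-codon synonymous-site
fractions, observed synonymous/nonsynonymous differences averaged over all
minimal substitution pathways (pathways through stop codons excluded), and a
Jukes–Cantor multiple-hit correction

    K = -(3/4) * ln(1 - 4p/3)

applied separately to the synonymous (ps) and nonsynonymous (pn) proportions.
Divergence times follow the molecular-clock conversion t = Ks / (2 mu), with
the legume neutral rate mu = 6.38e-9 substitutions per site per year as the
default; the factor 2 splits the substitutions across the two diverging
lineages.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.stats import gaussian_kde
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "DatingConfig",
    "back_translate",
    "nei_gojobori",
    "ks_for_cds_pair",
    "align_proteins",
    "ks_peak",
    "divergence_time",
    "extract_synonymous_supermatrix",
    "p_distance",
    "jc_distance",
    "nj_tree",
    "FOURFOLD_PREFIXES",
]

_BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: codon prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = frozenset(
    {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}
)


def _codon_table() -> dict[str, str]:
    table = {}
    for c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
        table[c] = str(Seq(c).translate())
    return table


CODON_TO_AA = _codon_table()


def _syn_fraction(codon: str) -> float:
    """NG86 synonymous-site count of one codon (sum of per-position fractions).

    Mutations creating stop codons count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in CODON_TO_AA if c not in STOP_CODONS}


@functools.lru_cache(maxsize=4096)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal substitution pathways that avoid stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways blocked by stops: fall back to unrestricted
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if CODON_TO_AA.get(nxt, "*") == CODON_TO_AA.get(cur, "*"):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class CodonAlignment:
    """Gap-aligned CDS sequences (pairwise or multi-species).

    Sequences must be equal length, divisible by 3.  Codon columns containing
    gaps or ambiguity codes are masked; unmasked columns may not contain
    internal stop codons.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        lens = {len(s) for s in self.seqs}
        if len(lens) != 1:
            raise ValueError("aligned sequences must have equal length")
        (L,) = lens
        if L % 3:
            raise ValueError("alignment length must be divisible by 3")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codon_column(self, i: int) -> list[str]:
        return [s[3 * i: 3 * i + 3] for s in self.seqs]

    def column_mask(self) -> list[bool]:
        """True for codon columns that are complete (no gaps/ambiguity) in
        every sequence and contain no stop codon."""
        mask = []
        for i in range(self.n_codons):
            col = self.codon_column(i)
            ok = all(
                all(b in _BASES for b in codon) and codon not in STOP_CODONS
                for codon in col
            )
            mask.append(ok)
        return mask


@dataclass
class KsEstimate:
    """Nei–Gojobori site counts, proportions and JC-corrected rates."""

    S: float
    N: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None

    @property
    def defined(self) -> bool:
        return self.ks is not None and self.ka is not None


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(aln: CodonAlignment) -> KsEstimate:
    """NG86 Ks/Ka for a pairwise codon alignment.

    Synonymous sites S are the per-codon synonymous fractions summed over
    unmasked columns and averaged between the two sequences; observed
    differences are averaged over minimal substitution pathways.
    """
    if len(aln.seqs) != 2:
        raise ValueError("nei_gojobori expects a pairwise alignment")
    mask = aln.column_mask()
    if not any(mask):
        raise ValueError("no complete codon columns to compare")
    S1 = S2 = 0.0
    sd = nd = 0.0
    ncols = 0
    for i, ok in enumerate(mask):
        if not ok:
            continue
        c1, c2 = aln.codon_column(i)
        S1 += _SYN_SITES[c1]
        S2 += _SYN_SITES[c2]
        ds, dn = _pathway_counts(c1, c2)
        sd += ds
        nd += dn
        ncols += 1
    S = (S1 + S2) / 2.0
    N = 3.0 * ncols - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    return KsEstimate(S, N, sd, nd, ps, pn, _jc_correct(ps), _jc_correct(pn))


def back_translate(
    protein_aln: Mapping[str, str], cds_by_gene: Mapping[str, str]
) -> CodonAlignment:
    """Replace each aligned residue by its codon; gaps become triple gaps.

    Each protein must equal the standard-code translation of its CDS; a
    mismatch is an error naming the gene and residue position.
    """
    ids, seqs = [], []
    for gid, prot in protein_aln.items():
        cds = cds_by_gene[gid].upper()
        residues = prot.replace("-", "")
        if len(cds) < 3 * len(residues):
            raise ValueError(f"{gid}: CDS shorter than aligned protein")
        out = []
        k = 0
        for pos, aa in enumerate(prot):
            if aa == "-":
                out.append("---")
                continue
            codon = cds[3 * k: 3 * k + 3]
            trans = CODON_TO_AA.get(codon, "X")
            if trans != aa.upper() and not (aa == "*" and codon in STOP_CODONS):
                raise ValueError(
                    f"{gid}: residue {pos} is {aa!r} but codon {codon!r} translates to {trans!r}"
                )
            out.append(codon)
            k += 1
        ids.append(gid)
        seqs.append("".join(out))
    return CodonAlignment(ids, seqs)


def align_proteins(seq1: str, seq2: str) -> tuple[str, str]:
    """Global pairwise protein alignment (BLOSUM62, affine gap 10/0.5).

    A built-in aligner so the Ks pipeline runs with no external binary.
    """
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    best = aligner.align(seq1, seq2)[0]
    a, b = str(best[0]), str(best[1])
    return a, b


def ks_for_cds_pair(id1: str, cds1: str, id2: str, cds2: str) -> KsEstimate:
    """Translate, align the proteins, back-translate, and run NG86."""
    p1 = str(Seq(cds1).translate()).rstrip("*")
    p2 = str(Seq(cds2).translate()).rstrip("*")
    a1, a2 = align_proteins(p1, p2)
    aln = back_translate({id1: a1, id2: a2}, {id1: cds1, id2: cds2})
    return nei_gojobori(aln)


@dataclass(frozen=True)
class DatingConfig:
    """Molecular-clock settings: neutral rate in substitutions/site/year."""

    neutral_rate: float = 6.38e-9

    def __post_init__(self):
        if self.neutral_rate <= 0:
            raise ValueError("neutral_rate must be positive")


def divergence_time(ks: float, cfg: DatingConfig = DatingConfig()) -> float:
    """Years since divergence: t = Ks / (2 mu)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * cfg.neutral_rate)


def ks_peak(
    values: Sequence[float],
    bandwidth: float | str = "silverman",
    max_ks: float = 3.0,
    grid_size: int = 512,
) -> list[float]:
    """Modes of the Ks distribution from a Gaussian kernel-density estimate.

    Values above ``max_ks`` (saturated estimates) are excluded first; peaks
    are local maxima of the KDE evaluated on a uniform grid, sorted ascending.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        raise ValueError("empty Ks distribution")
    vals = vals[vals <= max_ks]
    if vals.size == 0:
        raise ValueError("no Ks values at or below the saturation cutoff")
    if np.ptp(vals) == 0:
        return [float(vals[0])]
    kde = gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    floor = 0.1 * dens.max()  # ignore low shoulder wiggles in the tail
    peaks = [
        float(grid[i + 1])
        for i in np.nonzero(interior)[0]
        if dens[i + 1] >= floor
    ]
    if not peaks:
        peaks = [float(grid[int(np.argmax(dens))])]
    return sorted(peaks)


# ---------------------------------------------------------------------------
# Synonymous supermatrix + NJ tree
# ---------------------------------------------------------------------------

def extract_synonymous_supermatrix(
    alignments: Iterable[CodonAlignment],
) -> dict[str, str]:
    """Concatenate fourfold-degenerate third-position sites across alignments.

    A site qualifies iff its column is gap-free and the codon of *every*
    species has a fourfold-degenerate third position.  Returns one
    concatenated sequence per species; the species set must be identical
    across alignments.
    """
    species: list[str] | None = None
    parts: dict[str, list[str]] = {}
    for aln in alignments:
        if species is None:
            species = list(aln.ids)
            parts = {s: [] for s in species}
        elif set(aln.ids) != set(species):
            raise ValueError("species set mismatch across alignments")
        order = [aln.ids.index(s) for s in species]
        mask = aln.column_mask()
        for i, ok in enumerate(mask):
            if not ok:
                continue
            col = aln.codon_column(i)
            if all(c[:2] in FOURFOLD_PREFIXES for c in col):
                for s, j in zip(species, order):
                    parts[s].append(col[j][2])
    if species is None:
        raise ValueError("no alignments given")
    return {s: "".join(parts[s]) for s in species}


def p_distance(seq1: str, seq2: str) -> float:
    if len(seq1) != len(seq2) or not seq1:
        raise ValueError("sequences must be non-empty and equal length")
    diffs = sum(a != b for a, b in zip(seq1, seq2))
    return diffs / len(seq1)


def jc_distance(seq1: str, seq2: str) -> float:
    p = p_distance(seq1, seq2)
    d = _jc_correct(p)
    if d is None:
        raise ValueError("p-distance >= 0.75: JC distance undefined")
    return float(d)


def nj_tree(distance_matrix: np.ndarray, taxa: Sequence[str]) -> str:
    """Neighbor-joining tree (Saitou–Nei Q criterion) as a Newick string.

    Requires a symmetric, non-negative matrix with a zero diagonal and at
    least three taxa.  Branch lengths are reported as computed (they may be
    negative on non-additive input).
    """
    m = np.asarray(distance_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(taxa):
        raise ValueError("distance matrix shape does not match taxa")
    if m.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
        raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")
    tree = _skbio_nj(DistanceMatrix(m, list(taxa)))
    return str(tree).strip()


def supermatrix_nj_tree(supermatrix: Mapping[str, str], correction: str = "jc") -> str:
    """NJ tree from a synonymous-site supermatrix via (JC-corrected) p-distances."""
    taxa = sorted(supermatrix)
    dist = jc_distance if correction == "jc" else p_distance
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist(supermatrix[taxa[i]], supermatrix[taxa[j]])
    return nj_tree(m, taxa)
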