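"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate contract: all in-memory intervals are 0-based half-open
(``[start, end)``); conversions from 1-based closed formats (GFF3) happen at
the I/O boundary only.  Gene *rank* is the 0-based ordinal position of a gene
among the genes of its chromosome sorted by start coordinate (ties broken by
gene id), and is the coordinate system most downstream operations work in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "Genome",
    "TEFeature",
    "HomologyHit",
    "ExpressionTable",
    "read_gff3",
    "write_gff3",
    "read_te_bed",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_expression_tsv",
    "read_go_tsv",
    "to_tpm",
    "merge_intervals",
    "merged_coverage",
]

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: chromosome, 0-based half-open interval, strand, rank."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


class Genome:
    """An annotated genome: a named, rank-indexed collection of gene loci.

    Ranks are recomputed on construction; per chromosome they form a gap-free
    permutation of ``0..n-1`` ordered by start coordinate (ties by gene id).
    """

    def __init__(
        self,
        name: str,
        genes: Iterable[GeneModel],
        chromosome_lengths: Mapping[str, int] | None = None,
    ):
        self.name = name
        by_chrom: dict[str, list[GeneModel]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id: {g.gene_id}")
            seen.add(g.gene_id)
            by_chrom.setdefault(g.chromosome, []).append(g)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._by_id: dict[str, GeneModel] = {}
        for chrom in sorted(by_chrom):
            ranked = []
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(ordered):
                rg = GeneModel(g.gene_id, g.chromosome, g.start, g.end, g.strand, i)
                ranked.append(rg)
                self._by_id[rg.gene_id] = rg
            self._by_chrom[chrom] = ranked
        if chromosome_lengths is None:
            chromosome_lengths = {
                c: (gl[-1].end if gl else 0)
                for c, gl in ((c, sorted(v, key=lambda g: g.end)) for c, v in self._by_chrom.items())
            }
        self.chromosome_lengths = dict(chromosome_lengths)
        for g in self._by_id.values():
            L = self.chromosome_lengths.get(g.chromosome)
            if L is not None and g.end > L:
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of {g.chromosome} ({g.end} > {L})"
                )

    @property
    def genes(self) -> list[GeneModel]:
        return [g for c in sorted(self._by_chrom) for g in self._by_chrom[c]]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return list(self._by_chrom.get(chromosome, []))

    def n_genes(self, chromosome: str | None = None) -> int:
        if chromosome is None:
            return len(self._by_id)
        return len(self._by_chrom.get(chromosome, []))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def gene_at(self, chromosome: str, rank: int) -> GeneModel:
        return self._by_chrom[chromosome][rank]


@dataclass(frozen=True)
class TEFeature:
    """A transposable-element annotation interval (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    family: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid TE interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class HomologyHit:
    """One row of a pairwise protein/CDS homology search table."""

    query_id: str
    subject_id: str
    e_value: float
    identity_pct: float
    coverage_pct: float
    bitscore: float = 0.0

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        for v, name in ((self.identity_pct, "identity"), (self.coverage_pct, "coverage")):
            if not 0 <= v <= 100:
                raise ValueError(f"{name} percentage out of [0, 100]: {v}")


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix, tagged raw_count or TPM.

    ``gene_length`` (effective length in bp) is required for TPM conversion of
    raw counts.
    """

    values: pd.DataFrame
    unit: str = "raw_count"
    gene_length: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.unit not in ("raw_count", "TPM"):
            raise ValueError("unit must be 'raw_count' or 'TPM'")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def to_tpm(table: ExpressionTable) -> ExpressionTable:
    """Convert raw counts to TPM: 1e6 * (c_g/L_g) / sum_h(c_h/L_h) per sample.

    Idempotent on tables already in TPM.  Raises on an all-zero sample column
    (the normalisation is undefined).
    """
    if table.unit == "TPM":
        return table
    if table.gene_length is None:
        raise ValueError("gene_length is required to convert raw counts to TPM")
    lengths = pd.Series(
        {g: float(table.gene_length[g]) for g in table.values.index}, dtype=float
    )
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = table.values.div(lengths, axis=0)
    denom = rpk.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {', '.join(map(str, zero.index))}")
    tpm = rpk.div(denom, axis=1) * 1e6
    return ExpressionTable(tpm, unit="TPM", gene_length=table.gene_length)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def read_gff3(path: str, name: str | None = None) -> Genome:
    """Read gene loci from a GFF3 file into a rank-annotated :class:`Genome`.

    ``gene`` features are used directly; when a file carries only mRNA/CDS
    rows, gene spans are derived from them grouped by ID/Parent.  Duplicate
    gene IDs are a hard error.  Input need not be sorted.
    """
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            sort_attribute_values=False,
        )
    except gffutils.exceptions.EmptyInputError:
        return Genome(name or path, [])
    genes: list[GeneModel] = []
    gene_feats = list(db.features_of_type("gene"))
    if gene_feats:
        for f in gene_feats:
            genes.append(_gene_from_feature(f))
    else:
        spans: dict[str, list] = {}
        for f in db.all_features():
            if f.featuretype not in ("mRNA", "CDS", "exon"):
                continue
            parents = f.attributes.get("Parent", [f.id])
            for pid in parents:
                rec = spans.setdefault(pid, [f.seqid, f.start, f.end, f.strand])
                rec[1] = min(rec[1], f.start)
                rec[2] = max(rec[2], f.end)
        for gid, (seqid, start, end, strand) in spans.items():
            genes.append(GeneModel(gid, seqid, start - 1, end, strand))
    return Genome(name or path, genes)


def _gene_from_feature(f) -> GeneModel:
    if f.end < f.start:
        raise ValueError(f"gene {f.id}: end < start in GFF3 input")
    return GeneModel(f.id, f.seqid, f.start - 1, f.end, f.strand if f.strand in "+-" else "+")


def write_gff3(genome: Genome, path: str) -> None:
    """Write gene rows back out as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            L = genome.chromosome_lengths.get(chrom)
            if L:
                fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for g in genome.genes:
            fh.write(
                f"{g.chromosome}\twgtkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_te_bed(path: str, dialect: str) -> list[TEFeature]:
    """Read TE annotations from BED3+ (0-based half-open) or GFF3 (1-based closed).

    ``dialect`` must be ``"bed"`` or ``"gff3"``; coordinates are normalised to
    the internal 0-based half-open convention.  Overlapping features are kept
    as-is (merged on demand downstream).
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError("dialect must be 'bed' or 'gff3'")
    feats: list[TEFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "bed":
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                family = parts[3] if len(parts) > 3 else "."
            else:
                chrom, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
                family = parts[2]
            if start < 0:
                raise ValueError(f"negative coordinate on {chrom}: {start}")
            feats.append(TEFeature(chrom, start, end, family))
    return feats


def write_te_bed(features: Iterable[TEFeature], path: str) -> None:
    with open(path, "w") as fh:
        for t in features:
            fh.write(f"{t.chromosome}\t{t.start}\t{t.end}\t{t.family}\n")


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def read_hits_tsv(path: str) -> list[HomologyHit]:
    """Read a homology hit table (TSV with header: query, subject, e_value,
    identity_pct, coverage_pct[, bitscore])."""
    df = pd.read_csv(path, sep="\t")
    required = {"query", "subject", "e_value", "identity_pct", "coverage_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    bits = df["bitscore"] if "bitscore" in df.columns else pd.Series(0.0, index=df.index)
    return [
        HomologyHit(str(q), str(s), float(e), float(i), float(c), float(b))
        for q, s, e, i, c, b in zip(
            df["query"], df["subject"], df["e_value"], df["identity_pct"],
            df["coverage_pct"], bits,
        )
    ]


def write_hits_tsv(hits: Iterable[HomologyHit], path: str) -> None:
    pd.DataFrame(
        [
            (h.query_id, h.subject_id, h.e_value, h.identity_pct, h.coverage_pct, h.bitscore)
            for h in hits
        ],
        columns=["query", "subject", "e_value", "identity_pct", "coverage_pct", "bitscore"],
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(
    path: str, unit: str = "raw_count", gene_length: Mapping[str, float] | None = None
) -> ExpressionTable:
    """Read a gene x sample expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df.astype(float), unit=unit, gene_length=gene_length)


def read_go_tsv(path: str) -> dict[str, set[str]]:
    """Read gene -> GO term annotations from a two-column TSV.

    The second column may hold a single term or a comma-separated list; term
    ids must look like ``GO:0000000``.
    """
    out: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=0)
    gene_col, term_col = df.columns[:2]
    for gene, terms in zip(df[gene_col], df[term_col]):
        if pd.isna(terms):
            continue
        for term in str(terms).split(","):
            term = term.strip()
            if not term:
                continue
            if not _GO_RE.match(term):
                raise ValueError(f"malformed GO term id: {term!r}")
            out.setdefault(str(gene), set()).add(term)
    return out


def write_go_tsv(go: Mapping[str, set[str]], path: str) -> None:
    pd.DataFrame(
        [(g, ",".join(sorted(ts))) for g, ts in sorted(go.items())],
        columns=["gene", "go_terms"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval utilities shared by the TE statistics
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse overlapping/adjacent half-open intervals into a disjoint set."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class merged_coverage:
    """Fast covered-base queries against a merged interval set.

    Precomputes prefix sums so that the number of covered bases inside any
    window [a, b) is answered in O(log n).
    """

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        merged = merge_intervals(intervals)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)
        lens = self.ends - self.starts
        self.prefix = np.concatenate([[0], np.cumsum(lens)])

    def covered(self, a: int, b: int) -> int:
        """Covered bases within [a, b)."""
        if b <= a or len(self.starts) == 0:
            return 0
        i = int(np.searchsorted(self.ends, a, side="right"))
        j = int(np.searchsorted(self.starts, b, side="left"))
        if i >= j:
            return 0
        total = int(self.prefix[j] - self.prefix[i])
        total -= max(0, a - int(self.starts[i]))
        total -= max(0, int(self.ends[j - 1]) - b)
        return total
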