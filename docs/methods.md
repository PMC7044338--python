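# Methods

`wgtkit` analyses a paleopolyploid genome against a related diploid
reference: it detects syntenic gene pairs and chains them into inherited
fragments, segments the reference into genomic blocks at breakpoints shared
across sub-genome copies, deduces the pre-polyploidy diploid ancestral
karyotype from block adjacencies, partitions the triplicated gene space into
LF/MF1/MF2 sub-genomes by retention density, dates the polyploidy with
Nei–Gojobori Ks, and quantifies homoeolog expression dominance and its
association with promoter TE load. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
experiments do and do not establish.

## Synteny model

A homology hit (q, r) between a polyploid gene and a reference gene is
promoted to a syntenic pair only with *flanking support*: among the
`flank_window` (default 20) genes on each side of q, at least `min_support`
(default 2) must themselves hit a gene within `flank_window` ranks of r.
Rank means the 0-based ordinal of a gene along its chromosome ordered by
start coordinate (ties by gene id); all internal coordinates are 0-based
half-open. Because the genome is a triplication, one reference gene may pair
with at most three polyploid genes (`max_pairings_per_ref = 3`; surplus
candidates are dropped by support, then bitscore, then gene id).

Pairs are chained into fragments under the interruption rule: two pairs are
chainable iff, **in each genome separately**, fewer than 50 genes lie between
them *or* they are less than 200 kb apart. The operator binding is a
deliberate reading — both clauses are per-genome proximity tests, and "in
both genomes" scopes the whole disjunction. Fragments are the connected
components of chainability split into maximal runs of strictly monotone
reference rank, so each fragment has a well-defined orientation and
micro-inversions become separate fragments. Two boundary repairs keep the
runs faithful: the first pair of an inverted segment (which momentarily
continues the previous run's trend) is handed back to the run it is
rank-adjacent to, and a single interior outlier pair — typically an accepted
off-diagonal hit — is isolated into its own singleton run so it cannot sever
its host run. Both repairs only move pairs between runs of the same
component, so the partition of pairs is preserved.

Fragments with a query span strictly greater than 200 kb (`>`; the length
rule is "longer than") feed the structural analysis below. Sub-genome gene
accounting, however, keeps every fragment: the span filter exists to clean
the breakpoint signal, and discarding sub-threshold fragments from the
retention census would systematically undercount the more fractionated
copies wherever a small inversion has fragmented their synteny.

## Blocks, breakpoints and the ancestral karyotype

Fragment ends in reference rank coordinates are candidate cuts. Cuts within
`tolerance` (10) ranks of a chromosome end are discarded — fractionation
trims fragment ends, so near-terminal cuts are edge jitter, not
rearrangement. The remaining cuts are clustered per chromosome by single
linkage at the same tolerance; clusters supported by at least two distinct
copies (copies come from a per-reference-chromosome 3-colouring of fragment
chains under the rule that one copy never covers the same interval twice)
become breakpoints at the cluster's median. Breakpoints tile each reference
chromosome into labelled blocks (A, B, C, …, AA, …; chromosome order, then
position).

Blocks are projected back onto the polyploid. Coverage is assessed per copy
(all fragments of one copy of one reference chromosome pooled, even when
scattered over several polyploid chromosomes by a fission), and a block's
label is emitted when the copy covers at least 50% of the block's genes, or
when a fragment of at least 25 genes reaches within 10 ranks of a block
boundary — a fragment abutting a block end is junction evidence even if a
rearrangement took a bite out of the rest of that copy's block. Junction
end-signatures (which block ends meet) are computed from the reference rank
of the boundary pair nearest the junction, not from the fragment's own
orientation, which keeps the signature correct when a small local inversion
flips the boundary fragment. Junction support counts distinct polyploid
chromosomes: each sub-genome copy carries an ancestral junction on its own
chromosome, while a lineage-specific fusion joint occurs on a single
chromosome and cannot reach the ancestral threshold on its own.

The ancestral karyotype is assembled by end-matching. Edges in priority
order (support, reference-adjacency preference, label): candidate junctions
(support ≥ 2 and absent from the reference), then reference adjacencies that
are still *observed* in at least two copies. The second class heals spurious
breakpoints — two copies coincidentally cut near the same rank — because the
flanking blocks are still seen adjacent in the uncut copies, whereas a true
ancestral chromosome boundary is essentially never observed as a junction.
Each block end carries at most one edge; maximal simple paths are the
ancestral chromosomes; a cycle is an error (circular chromosomes are out of
model). Known limitation: if two sub-genome copies independently fuse the
same pair of block ends, the method must infer an ancestral association —
the shared-by-two-copies criterion is an identifiability assumption, not a
theorem, and the scaled-down simulations make such coincidences relatively
more likely than they would be at real genome size.

## Sub-genome assignment

The unit of assignment is the ancestral chromosome. Within a unit,
fragments are grouped per (reference chromosome, copy) — at most three per
chromosome by construction — and copy identities are aligned across the
unit's reference chromosomes by maximizing query-chromosome co-occurrence
(a copy's material travels together unless a rearrangement separated it);
the alignment is exhaustive for up to six reference chromosomes per unit and
greedy beyond. Per aligned copy, retained ancestral loci are smoothed in a
centred window of 1001 loci (500 each side, truncated at unit ends), and
copies are ranked by mean density: LF (least fractionated), MF1, MF2. Ties
break by total retained genes, then by smallest query chromosome name.

Retained-gene counts per sub-genome are tested against equal retention two
ways. The 3-category goodness-of-fit chi-square (df = 2) matches the shape
of the published test, but under the model actually generating the data —
independent per-copy Bernoulli gene loss — the three retained counts are
independent binomials, and conditioning them on their total is *not*
multinomial sampling: the statistic is under-dispersed and its null p-value
is not uniform. The package therefore also reports a 2×3 retained/lost
homogeneity chi-square, which is the calibrated construction under
independent loss; calibration claims are made on the homogeneity p-value
only. A second caveat: because LF/MF1/MF2 are assigned by *ranking*
densities, the labelled counts are order statistics, and even at equal rates
the ranked counts spread; calibration is therefore checked on unranked
(truth-labelled) counts.

## Ks estimation and dating

Ks/Ka follow Nei–Gojobori (1986): per-codon synonymous-site fractions
(mutations to stop codons count as nonsynonymous), observed differences
averaged over all minimal substitution pathways with stop-containing
pathways excluded (all pathways used if every one is blocked), sites
averaged between the two sequences, and a Jukes–Cantor correction
K = −(3/4)·ln(1 − 4p/3) applied to both proportions; p ≥ 3/4 flags the
estimate undefined. Codons containing gaps or ambiguity codes are masked
pairwise. Protein alignment for CDS pairs uses a built-in global aligner
(BLOSUM62, affine gaps 10/0.5) so the pipeline needs no external binary;
back-translation verifies that each protein equals the translation of its
CDS and turns alignment gaps into triple gaps.

Ks distribution modes come from a Gaussian KDE (Silverman bandwidth by
default, 512-point grid, values above Ks = 3 excluded as saturated); local
maxima below 10% of the global density maximum are ignored as tail
shoulders. Note that the KDE mode of a right-skewed Ks distribution sits
slightly below the planted mean divergence (by roughly 0.01–0.02 at the
simulated sample sizes); the reported peak is the statistic, not the mean.
Divergence times use the molecular clock t = Ks/(2μ) with the legume neutral
rate μ = 6.38×10⁻⁹ substitutions·site⁻¹·year⁻¹ — the factor 2 splits the
substitutions across the two diverging lineages, and this convention
reproduces all five published Ks→age pairs (0.12→9.40 My, 0.51→39.97,
0.52→40.75, 0.28→21.94, 0.11→8.62).

The phylogenetic track extracts synonymous sites as third positions of
fourfold-degenerate codons in *every* species at a gap-free column,
concatenates them per species, and builds a neighbor-joining tree
(Saitou–Nei Q criterion; JC-corrected p-distances by default; branch
lengths reported as computed, negative values included). On additive
matrices NJ reproduces the generating tree exactly.

## Dominance and TE statistics

Expression is TPM (counts converted per sample as 1e6·(c/L)/Σ(c/L); columns
sum to 10⁶). Per tissue, the bottom 1% of the expression ranking
(floor(0.01·n) genes) is flagged not expressed and treated as 0. A doublet
is evaluable when at least one member exceeds TPM 5; at fold threshold f the
a-member dominates iff TPM_a ≥ f·TPM_b (symmetrically for b; both only at
f = 1 with equality, which is neutral). Directional bias across doublets is
tested with the exact two-sided binomial at p = ½ ("sum of outcomes no more
likely than observed" as the primary definition; 2×min-tail reported
alongside). TE density uses 100-bp windows stepping 10 bp across the
strand-aware 5′/3′ flanks (default 3 kb; windows past a chromosome end are
dropped from that gene's mean; TEs merged before counting), and promoter
load is the merged-TE covered fraction of the 2 kb upstream of the TSS
(rightward of the gene end on the minus strand, truncated at chromosome
boundaries). Dominant-vs-suppressed promoter load is compared with a
two-sided Wilcoxon rank-sum test — a deliberate choice, as no specific test
is canonical for this contrast.

## Duplication classes, enrichment, ortholog filtering

Duplication modes are exclusive with priority WGT > tandem > dispersed: a
syntenic ortholog in any reference species means WGT; otherwise a homolog on
the same chromosome within ≤ 5 intervening genes (configurable; no canonical
value exists) means tandem; remaining homolog-bearing genes are dispersed;
genes without homologs are singletons. GO over-retention uses one-sided
(greater) Fisher exact tests per term with Benjamini–Hochberg correction
across tested terms; both raw p and q are reported. The ortholog filter
keeps hits with E ≤ 10⁻²⁰, coverage > 50% and identity > 35%; the E-value
inequality is deliberately "at most" — an "at least 10⁻²⁰" reading would
admit arbitrarily poor alignments and contradict the filter's purpose.

## The synthetic paleohexaploid generator

The generator builds a diploid ancestor (9 chromosomes × 300 genes by
default), derives the *reference* genome from it by 3 fissions, 1 fusion and
2 inversions (11 chromosomes; every structural boundary at least
`min_segment` = 100 genes from any other, so blocks are ≥ 100 genes ≈ 500 kb
— small but proportionate stand-ins for real legume blocks), and derives the
polyploid as three ancestor copies fractionated at rates 0.8/0.6/0.5 with 20
lineage-specific rearrangements (16 inversions of 10–40 genes confined to
one block, 1 fission, 3 fusions; net −2 chromosomes, giving ~25). Fewer
random fusions than fissions+inversions is the realistic mix at this scale:
coincident fusion pairs — the known identifiability limit above — scale
quadratically with the fusion count, and at real genome size their
probability is negligible.

Gene layout draws gene lengths and intergenic gaps uniformly from 1–4 kb
(~5 kb per gene, so the 50-gene and 200-kb interruption thresholds are
commensurate, as they are in real legumes). TEs are inserted in intergenic
space at per-sub-genome rates (0.15/0.30/0.35 insertions per kb for
LF/MF1/MF2; geometric lengths, mean 500 bp), so TE density is lowest in LF
by construction. Expression is log-normal (μ = 2, σ = 1 on the log scale)
multiplied by exp(−β·promoter TE fraction) with β = 2, then emitted as
Poisson counts per tissue — dominance is thereby a *causal consequence* of
TE bias, and the analysis has to recover it rather than assume it.

CDS sequences use only fourfold-degenerate codon families whose first and
second positions admit no synonymous change (TCN, CCN, ACN, GTN, GCN, GGN),
so each codon carries exactly one synonymous site and planted third-position
divergence maps one-to-one onto Ks. Divergence is a Jukes–Cantor process
along the species tree with branch lengths placing the homoeolog peak at
Ks = 0.28 and the polyploid–reference peak at 0.51. Homology hits carry
realistic identity/coverage/bitscore noise plus 2% spurious off-diagonal
hits; 40 tandem and 40 dispersed duplicate genes are planted without
reference hits. The reference lineage draws from its own random stream, so
two reference histories (`ref_variant`) can be generated against an
identical polyploid — the reference-choice robustness check.

What the simulations do not emulate: sequence-level TE structure, gene
length/expression covariation, real intron/exon architecture, segmental
duplications, assembly error, or lineage rate variation in Ks. Passing the
recovery experiments shows the algorithms are correct under the stated
generative model at desk scale; it does not certify performance on real
assemblies, whose genome-scale counts (gene numbers, fragment counts, block
counts) are deliberately out of scope.

## Problem sizes and determinism

Default experiments use 2 700 ancestral loci (~5 200 polyploid genes), 50
seeded replicates for structure recovery, 500 gene pairs for Ks peaks, and
200 null replicates for calibration — sizes chosen so the full suite runs
comfortably on a single CPU while keeping the binomial error of the reported
percentages small. All randomness flows from `numpy.random.default_rng`
seeded from a single integer; generator outputs are byte-identical across
runs with the same seed.
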