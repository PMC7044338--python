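"""Nei-Gojobori estimation, Ks peaks, dating, supermatrix and NJ trees."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from wgtkit.ks import (
    CodonAlignment,
    DatingConfig,
    back_translate,
    divergence_time,
    extract_synonymous_supermatrix,
    jc_distance,
    ks_for_cds_pair,
    ks_peak,
    nei_gojobori,
    nj_tree,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE = [
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOPS
]


# ---------------------------------------------------------------------------
# independent NG86 oracle: explicit site counting + recursive pathway walk
# ---------------------------------------------------------------------------

def oracle_syn_sites(codon):
    aa = str(Seq(codon).translate())
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOPS and str(Seq(alt).translate()) == aa:
                syn += 1
        total += syn / 3
    return total


def oracle_pathways(c1, c2, allow_stops=False):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []

    def walk(cur, remaining, sd, nd):
        if not remaining:
            results.append((sd, nd))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS and not allow_stops:
                continue
            syn = str(Seq(nxt).translate()) == str(Seq(cur).translate())
            walk(nxt, [p for p in remaining if p != pos], sd + syn, nd + (not syn))

    walk(c1, diff, 0, 0)
    if not results and not allow_stops:
        return oracle_pathways(c1, c2, allow_stops=True)
    return results


def oracle_ng86(seq1, seq2):
    n = len(seq1) // 3
    S = sd = nd = 0.0
    for i in range(n):
        a, b = seq1[3 * i: 3 * i + 3], seq2[3 * i: 3 * i + 3]
        S += (oracle_syn_sites(a) + oracle_syn_sites(b)) / 2
        paths = oracle_pathways(a, b)
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    N = 3 * n - S
    ps, pn = (sd / S if S else 0.0), (nd / N if N else 0.0)
    ks = None if ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    ka = None if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
    return S, N, sd, nd, ks, ka


def test_identical_sequences_have_zero_rates():
    est = nei_gojobori(CodonAlignment(["a", "b"], ["ATGGCT", "ATGGCT"]))
    assert est.ks == 0 and est.ka == 0


def test_fourfold_synonymous_difference_hand_value():
    # GGT vs GGC: one synonymous third-position change; S = 2 over two codons
    est = nei_gojobori(CodonAlignment(["a", "b"], ["GGTGGA", "GGCGGA"]))
    assert est.sd == 1 and est.S == pytest.approx(2.0)
    assert est.ps == pytest.approx(0.5)
    assert est.ks == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-4)  # 0.8239
    assert est.ka == 0


def test_nonsynonymous_difference_hand_value():
    # ATG (Met) vs ATA (Ile): S = (0 + 2/3)/2 = 1/3, one nonsynonymous hit
    est = nei_gojobori(CodonAlignment(["a", "b"], ["ATG", "ATA"]))
    assert est.S == pytest.approx(1 / 3)
    assert est.N == pytest.approx(8 / 3)
    assert est.nd == 1 and est.sd == 0
    assert est.ka == pytest.approx(-0.75 * math.log(0.5), abs=1e-4)  # 0.5199
    assert est.ks == 0


def test_ng86_matches_pathway_oracle_on_random_short_pairs(rng):
    """Exhaustive minimal-pathway enumeration on <=3-codon pairs (500 draws)."""
    for _ in range(500):
        n = int(rng.integers(1, 4))
        s1 = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n))
        s2 = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n))
        est = nei_gojobori(CodonAlignment(["a", "b"], [s1, s2]))
        S, N, sd, nd, ks, ka = oracle_ng86(s1, s2)
        assert est.S == pytest.approx(S)
        assert est.N == pytest.approx(N)
        assert est.sd == pytest.approx(sd)
        assert est.nd == pytest.approx(nd)
        for got, want, p in ((est.ks, ks, est.ps), (est.ka, ka, est.pn)):
            if (got is None) != (want is None):
                assert abs(p - 0.75) < 1e-9  # saturation boundary rounding
            elif want is not None:
                assert got == pytest.approx(want)


def test_ng86_is_symmetric(rng):
    for _ in range(50):
        s1 = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 5))
        s2 = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 5))
        a = nei_gojobori(CodonAlignment(["x", "y"], [s1, s2]))
        b = nei_gojobori(CodonAlignment(["y", "x"], [s2, s1]))
        assert a.ks == b.ks and a.ka == b.ka and a.S == b.S


def test_gapped_codons_are_masked():
    est = nei_gojobori(CodonAlignment(["a", "b"], ["ATG---GGT", "ATGAAAGGC"]))
    assert est.S == pytest.approx((0 + 1 + 1) / 2 + 0 / 2)  # only ATG + GGT/GGC columns


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

def test_back_translate_gap_becomes_triple_gap():
    aln = back_translate({"g": "M-K"}, {"g": "ATGAAA"})
    assert aln.seqs[0] == "ATG---AAA"


def test_back_translate_mismatch_is_error():
    with pytest.raises(ValueError, match="g:"):
        back_translate({"g": "MK"}, {"g": "ATGCCC"})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(SENSE), min_size=1, max_size=20), st.randoms())
def test_back_translate_round_trip(codons, r):
    cds = "".join(codons)
    protein = str(Seq(cds).translate())
    aligned = ""
    for aa in protein:  # sprinkle alignment gaps
        if r.random() < 0.3:
            aligned += "-"
        aligned += aa
    aln = back_translate({"g": aligned}, {"g": cds})
    recovered = str(Seq(aln.seqs[0].replace("---", "")).translate())
    assert recovered == protein


def test_ks_for_cds_pair_runs_built_in_aligner():
    cds1 = "ATGGCTGGTACTCCA"
    cds2 = "ATGGCCGGAACTCCA"
    est = ks_for_cds_pair("a", cds1, "b", cds2)
    assert est.ka == 0 and est.ks > 0


# ---------------------------------------------------------------------------
# peaks and dating
# ---------------------------------------------------------------------------

def test_single_peak_recovered_from_truncated_normal(rng):
    vals = np.abs(rng.normal(0.28, 0.05, 1000))
    peaks = ks_peak(vals)
    assert len(peaks) >= 1
    assert min(peaks, key=lambda p: abs(p - 0.28)) == pytest.approx(0.28, abs=0.02)


def test_bimodal_mixture_recovers_both_modes(rng):
    vals = np.concatenate(
        [np.abs(rng.normal(0.12, 0.03, 1000)), np.abs(rng.normal(0.51, 0.05, 1000))]
    )
    peaks = ks_peak(vals)
    assert len(peaks) == 2
    assert peaks[0] == pytest.approx(0.12, abs=0.03)
    assert peaks[1] == pytest.approx(0.51, abs=0.03)


def test_constant_data_yields_its_value_and_empty_is_error():
    assert ks_peak([0.2] * 50) == [0.2]
    with pytest.raises(ValueError):
        ks_peak([])


def test_saturated_values_excluded():
    vals = [0.2] * 50 + [5.0] * 10
    assert ks_peak(vals) == [0.2]


@pytest.mark.parametrize(
    "ks,my",
    [(0.12, 9.40), (0.51, 39.97), (0.52, 40.75), (0.28, 21.94), (0.11, 8.62)],
)
def test_divergence_times_at_legume_neutral_rate(ks, my):
    assert divergence_time(ks) / 1e6 == pytest.approx(my, abs=0.005)


def test_divergence_time_is_linear_and_rejects_negative():
    assert divergence_time(0.2) == pytest.approx(2 * divergence_time(0.1))
    assert divergence_time(0.0) == 0.0
    with pytest.raises(ValueError):
        divergence_time(-0.1)


# ---------------------------------------------------------------------------
# synonymous supermatrix
# ---------------------------------------------------------------------------

def test_glycine_box_gives_one_synonymous_site():
    aln = CodonAlignment(["s1", "s2", "s3"], ["GGT", "GGC", "GGG"])
    sm = extract_synonymous_supermatrix([aln])
    assert sm == {"s1": "T", "s2": "C", "s3": "G"}


def test_gapped_column_excluded():
    aln = CodonAlignment(["s1", "s2"], ["GGT---", "GGC---"])
    sm = extract_synonymous_supermatrix([aln])
    assert sm == {"s1": "T", "s2": "C"}


def test_species_mismatch_is_error():
    a = CodonAlignment(["s1", "s2"], ["GGT", "GGC"])
    b = CodonAlignment(["s1", "s3"], ["GGT", "GGC"])
    with pytest.raises(ValueError):
        extract_synonymous_supermatrix([a, b])


def test_supermatrix_matches_independent_column_scan(rng):
    fourfold = {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}
    alns = []
    for _ in range(5):
        cols = [[SENSE[i] for i in rng.integers(0, len(SENSE), 3)] for _ in range(30)]
        alns.append(
            CodonAlignment(
                ["s1", "s2", "s3"],
                ["".join(c[k] for c in cols) for k in range(3)],
            )
        )
    sm = extract_synonymous_supermatrix(alns)
    expected = 0
    for aln in alns:
        for i in range(aln.n_codons):
            col = aln.codon_column(i)
            if all(c[:2] in fourfold for c in col):
                expected += 1
    assert {len(v) for v in sm.values()} == {expected}


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _patristic(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


def test_three_taxon_closed_form():
    m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    nwk = nj_tree(m, ["A", "B", "C"])
    d = _patristic(nwk)
    assert d[("A", "B")] == pytest.approx(2)
    assert d[("A", "C")] == pytest.approx(4)
    assert d[("B", "C")] == pytest.approx(4)


def test_additive_matrix_recovered_exactly():
    # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
    taxa = list("ABCD")
    d = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
         ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
    m = np.zeros((4, 4))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                m[i, j] = d[tuple(sorted((a, b)))]
    got = _patristic(nj_tree(m, taxa))
    for (a, b), v in d.items():
        assert got[(a, b)] == pytest.approx(v)


def test_zero_distance_cherry_and_input_validation():
    m = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], float)
    d = _patristic(nj_tree(m, ["A", "B", "C"]))
    assert d[("A", "B")] == pytest.approx(0)
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["A", "B"])


def test_jc_distance_inverts_p_distance():
    p = 0.2
    assert jc_distance("A" * 80 + "C" * 20, "A" * 100) == pytest.approx(
        -0.75 * math.log(1 - 4 * p / 3)
    )
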