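"""Syntenic-pair detection and fragment chaining against literal-rule oracles."""

import numpy as np
import pytest

from wgtkit.core_io import HomologyHit
from wgtkit.synteny import (
    SyntenyConfig,
    assemble_fragments,
    dotplot_table,
    filter_fragments,
    find_syntenic_pairs,
)

from conftest import make_genome


def hit(q, r, bits=100.0):
    return HomologyHit(q, r, 1e-50, 80.0, 95.0, bits)


def test_perfect_collinearity_accepts_all():
    q = make_genome("q", {"q1": 10})
    r = make_genome("r", {"r1": 10})
    hits = [hit(f"q1_g{i}", f"r1_g{i}") for i in range(10)]
    pairs = find_syntenic_pairs(q, r, hits)
    assert len(pairs) == 10
    assert all(p.support >= 2 for p in pairs)


def test_lone_hit_without_flank_support_rejected():
    q = make_genome("q", {"q1": 41})
    r = make_genome("r", {"r1": 41})
    pairs = find_syntenic_pairs(q, r, [hit("q1_g20", "r1_g20")])
    assert pairs == []


def brute_force_pairs(query, ref, hits, cfg):
    """Literal re-statement of the acceptance rule, coded independently."""
    hitset = {}
    for h in hits:
        hitset.setdefault(h.query_id, set()).add(h.subject_id)
    best_bits = {}
    for h in hits:
        best_bits[(h.query_id, h.subject_id)] = max(
            best_bits.get((h.query_id, h.subject_id), -1), h.bitscore
        )
    accepted = []
    for (qid, rid) in best_bits:
        qg, rg = query[qid], ref[rid]
        support = 0
        for nb in query.genes_on(qg.chromosome):
            if nb.gene_id == qid or abs(nb.rank - qg.rank) > cfg.flank_window:
                continue
            ok = False
            for sid in hitset.get(nb.gene_id, ()):
                sg = ref[sid]
                if sg.chromosome == rg.chromosome and abs(sg.rank - rg.rank) <= cfg.flank_window:
                    ok = True
            support += ok
        if support >= cfg.min_support:
            accepted.append((qid, rid, support))
    by_ref = {}
    for qid, rid, s in accepted:
        by_ref.setdefault(rid, []).append((qid, s))
    kept = set()
    for rid, lst in by_ref.items():
        lst.sort(key=lambda t: (-t[1], -best_bits[(t[0], rid)], t[0]))
        for qid, _ in lst[: cfg.max_pairings_per_ref]:
            kept.add((qid, rid))
    return kept


def test_pair_detection_matches_brute_force(rng):
    q = make_genome("q", {"q1": 50})
    r = make_genome("r", {"r1": 50})
    hits = []
    for i in range(50):
        if rng.random() < 0.8:
            hits.append(hit(f"q1_g{i}", f"r1_g{i}", float(rng.integers(50, 300))))
    for _ in range(15):  # off-diagonal noise
        i, j = rng.integers(0, 50, 2)
        hits.append(hit(f"q1_g{i}", f"r1_g{j}", float(rng.integers(50, 300))))
    cfg = SyntenyConfig()
    got = {(p.query_gene, p.ref_gene) for p in find_syntenic_pairs(q, r, hits, cfg)}
    assert got == brute_force_pairs(q, r, hits, cfg)


def _pairs_for(q, r, idx_pairs):
    hits = [hit(f"q1_g{i}", f"r1_g{j}") for i, j in idx_pairs]
    # bypass flank filtering: feed pairs straight into assembly
    from wgtkit.synteny import SyntenicPair

    return [SyntenicPair(f"q1_g{i}", f"r1_g{j}", 2) for i, j in idx_pairs]


def test_adjacent_pairs_chain_into_one_fragment():
    q = make_genome("q", {"q1": 10})
    r = make_genome("r", {"r1": 10})
    frags = assemble_fragments(_pairs_for(q, r, [(0, 0), (1, 1)]), q, r)
    assert len(frags) == 1
    assert frags[0].orientation == "forward"


def test_distant_pairs_split_when_both_criteria_exceeded():
    # 60 intervening genes and > 200 kb apart in the query (2 kb per gene)
    q = make_genome("q", {"q1": 70}, gene_len=2000, gap=2000)
    r = make_genome("r", {"r1": 70}, gene_len=2000, gap=2000)
    frags = assemble_fragments(_pairs_for(q, r, [(0, 0), (61, 61)]), q, r)
    assert len(frags) == 2


def test_close_in_bp_chains_despite_many_intervening_genes():
    # 60 intervening genes but only ~6 kb apart: the bp rule keeps them together
    q = make_genome("q", {"q1": 70}, gene_len=50, gap=50)
    r = make_genome("r", {"r1": 70}, gene_len=50, gap=50)
    frags = assemble_fragments(_pairs_for(q, r, [(0, 0), (61, 61)]), q, r)
    assert len(frags) == 1


def brute_force_closure(pairs, q, r, cfg):
    """Transitive closure of the chainability relation, coded independently."""
    def chainable(p1, p2):
        for g, a, b in ((q, p1.query_gene, p2.query_gene), (r, p1.ref_gene, p2.ref_gene)):
            ga, gb = g[a], g[b]
            genes = abs(ga.rank - gb.rank) - 1
            bp = max(0, max(ga.start, gb.start) - min(ga.end, gb.end))
            if not (genes < cfg.max_intervening or bp < cfg.max_gap):
                return False
        return True

    classes = [{i} for i in range(len(pairs))]
    changed = True
    while changed:
        changed = False
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                if classes[i] and classes[j] and any(
                    chainable(pairs[a], pairs[b])
                    for a in classes[i]
                    for b in classes[j]
                ):
                    classes[i] |= classes[j]
                    classes[j] = set()
                    changed = True
    return {
        frozenset((pairs[i].query_gene, pairs[i].ref_gene) for i in c)
        for c in classes
        if c
    }


def test_assembly_partitions_pairs_and_respects_closure(rng):
    q = make_genome("q", {"q1": 120}, gene_len=2000, gap=2000)
    r = make_genome("r", {"r1": 120}, gene_len=2000, gap=2000)
    idx = sorted(rng.choice(120, size=30, replace=False))
    jitter = [int(i + rng.integers(-1, 2)) % 120 for i in idx]
    pairs = _pairs_for(q, r, list(zip(idx, jitter)))
    cfg = SyntenyConfig()
    frags = assemble_fragments(pairs, q, r, cfg)

    # partition: every pair in exactly one fragment
    seen = [(p.query_gene, p.ref_gene) for f in frags for p in f.pairs]
    assert sorted(seen) == sorted((p.query_gene, p.ref_gene) for p in pairs)

    # each fragment lies within one closure class, and the classes are
    # exactly unions of fragments
    classes = brute_force_closure(pairs, q, r, cfg)
    for f in frags:
        fset = {(p.query_gene, p.ref_gene) for p in f.pairs}
        assert any(fset <= c for c in classes)
    rebuilt = {}
    for f in frags:
        fset = frozenset((p.query_gene, p.ref_gene) for p in f.pairs)
        owner = next(c for c in classes if fset <= c)
        rebuilt.setdefault(owner, set()).update(fset)
    assert all(rebuilt[c] == set(c) for c in rebuilt)


def test_assembly_is_order_invariant(rng):
    q = make_genome("q", {"q1": 100}, gene_len=2000, gap=2000)
    r = make_genome("r", {"r1": 100}, gene_len=2000, gap=2000)
    idx = sorted(rng.choice(100, size=30, replace=False))
    pairs = _pairs_for(q, r, [(i, i) for i in idx])
    ref_out = assemble_fragments(pairs, q, r)
    for _ in range(3):
        perm = list(rng.permutation(len(pairs)))
        out = assemble_fragments([pairs[i] for i in perm], q, r)
        assert [
            [(p.query_gene, p.ref_gene) for p in f.pairs] for f in out
        ] == [[(p.query_gene, p.ref_gene) for p in f.pairs] for f in ref_out]


def test_fragments_are_monotone_in_ref_rank(default_run, default_sim):
    ref = default_sim.reference
    for f in default_run.fragments:
        ranks = [ref[p.ref_gene].rank for p in f.pairs]
        if len(ranks) > 1:
            steps = {np.sign(b - a) for a, b in zip(ranks[:-1], ranks[1:])}
            assert steps <= {1} or steps <= {-1}


def test_span_filter_and_dotplot_rows():
    q = make_genome("q", {"q1": 200}, gene_len=2000, gap=2000)
    r = make_genome("r", {"r1": 200}, gene_len=2000, gap=2000)
    pairs = _pairs_for(q, r, [(i, i) for i in range(100)] + [(150, 150), (151, 151)])
    frags = assemble_fragments(pairs, q, r)
    kept = filter_fragments(frags)
    assert len(frags) == 2 and len(kept) == 1  # 8 kb fragment dropped
    table = dotplot_table(frags)
    assert len(table) == sum(f.n_pairs for f in frags)
    assert dotplot_table([]).empty
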