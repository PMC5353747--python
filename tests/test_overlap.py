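"""The rank-based overlap engine: tails, running scan, direction decomposition."""

import numpy as np
import pytest

from sigoverlap import (
    UniverseSpec,
    bonferroni_threshold,
    classify_correlation,
    directional_decomposition,
    hypergeometric_tail,
    running_fisher,
)
from sigoverlap.overlap import cutoff_pairs

from conftest import hypergeom_tail_oracle, make_signature, random_signature


@pytest.mark.parametrize(
    "k, n1, n2, N, expected",
    [
        (1, 1, 1, 2, 0.5),
        (5, 5, 5, 10, 1 / 252),  # exhaustive: 1 favourable of C(10,5) draws
        (2, 3, 3, 6, 0.5),  # (C(3,2)C(3,1)+C(3,3))/C(6,3) = 10/20
        (0, 3, 3, 10, 1.0),
    ],
)
def test_hypergeometric_tail_exact_values(k, n1, n2, N, expected):
    assert hypergeometric_tail(k, n1, n2, N) == pytest.approx(expected, rel=1e-12)


def test_hypergeometric_tail_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeometric_tail(4, 3, 5, 10)  # k > min(n1, n2)
    with pytest.raises(ValueError):
        hypergeometric_tail(1, 11, 5, 10)  # set larger than universe
    with pytest.raises(ValueError):
        hypergeometric_tail(-1, 3, 5, 10)


def test_hypergeometric_tail_matches_enumeration_small_universes():
    for N in range(1, 11):
        for n1 in range(N + 1):
            for n2 in range(N + 1):
                for k in range(min(n1, n2) + 1):
                    expected = float(hypergeom_tail_oracle(k, n1, n2, N))
                    assert hypergeometric_tail(k, n1, n2, N) == pytest.approx(
                        expected, rel=1e-10
                    ), (k, n1, n2, N)


def test_hypergeometric_tail_monotone_in_k():
    last = 1.0
    for k in range(0, 8):
        p = hypergeometric_tail(k, 8, 9, 25)
        assert p <= last + 1e-15
        last = p
    assert hypergeometric_tail(max(0, 8 + 9 - 25), 8, 9, 25) == 1.0
    assert hypergeometric_tail(4, 12, 12, 20) == 1.0  # k at the forced-overlap floor


def test_cutoff_pairs_schemes():
    assert cutoff_pairs(10, 10) == [(j, j) for j in range(1, 11)]
    assert cutoff_pairs(3, 7) == [(1, 3), (2, 5), (3, 7)]  # every rank when short
    assert cutoff_pairs(100, 20) == [(10 * j, 2 * j) for j in range(1, 11)]
    assert cutoff_pairs(0, 5) == []
    per_rank = cutoff_pairs(20, 20, "per-rank")
    assert len(per_rank) == 20 and per_rank[0] == (1, 1)
    with pytest.raises(ValueError):
        cutoff_pairs(5, 5, "nope")


def test_disjoint_signatures_give_p_one(universe200):
    genes, uni = universe200
    q = make_signature([(g, "up") for g in genes[:10]])
    r = make_signature([(g, "down") for g in genes[10:20]])
    res = running_fisher(q, r, uni)
    assert res.p_final == 1.0 and res.n_overlap == 0


def test_identical_signatures_matched_prefixes():
    genes = [f"U{i:03d}" for i in range(100)]
    uni = UniverseSpec(genes)
    sig = make_signature([(g, "up") for g in genes[:10]])
    res = running_fisher(sig, sig, uni)
    # best cutoff is the full-length prefix; corrected by the 10 scanned
    expected_best = float(hypergeom_tail_oracle(10, 10, 10, 100))
    assert res.p_raw_best == pytest.approx(expected_best, rel=1e-10)
    assert res.n_cutoffs_scanned == 10
    assert res.p_final == pytest.approx(expected_best * 10, rel=1e-10)
    assert res.n_overlap == 10


def test_single_shared_gene_smallest_universe():
    uni = UniverseSpec(["A", "B"])
    sig = make_signature([("A", "up")])
    res = running_fisher(sig, sig, uni)
    assert res.p_raw_best == pytest.approx(0.5)
    assert res.n_cutoffs_scanned == 1
    assert res.p_final == pytest.approx(0.5)


def test_empty_signature_is_degenerate_not_error(universe200):
    genes, uni = universe200
    empty = make_signature([])
    other = make_signature([(genes[0], "up")])
    res = running_fisher(empty, other, uni)
    assert res.p_final == 1.0 and res.n_overlap == 0


def test_gene_outside_universe_raises(universe200):
    _, uni = universe200
    stray = make_signature([("NOT_THERE", "up")])
    with pytest.raises(ValueError, match="outside"):
        running_fisher(stray, stray, uni)


def test_overlap_count_symmetric_under_swap(universe200, rng):
    genes, uni = universe200
    q = random_signature(rng, genes, 30, "q")
    r = random_signature(rng, genes, 40, "r")
    res_qr = running_fisher(q, r, uni)
    res_rq = running_fisher(r, q, uni)
    assert res_qr.n_overlap == res_rq.n_overlap
    assert res_qr.overlap_gene_ids == res_rq.overlap_gene_ids


def test_directional_decomposition_simple_cases():
    uni = UniverseSpec([f"U{i}" for i in range(10)] + ["G1", "G2"])
    q = make_signature([("G1", "up"), ("G2", "down")])
    r = make_signature([("G1", "up"), ("G2", "up")])
    dd = directional_decomposition(q, r, uni)
    assert dd.sub_results[("up", "up")].overlap_gene_ids == ("G1",)
    assert dd.sub_results[("down", "up")].overlap_gene_ids == ("G2",)
    assert dd.count(("down", "down")) == 0 and dd.count(("up", "down")) == 0
    assert dd.threshold == pytest.approx(0.0125)

    all_up = make_signature([(f"U{i}", "up") for i in range(5)])
    dd = directional_decomposition(all_up, all_up, uni)
    assert dd.count(("up", "up")) == 5
    for pair in (("down", "down"), ("up", "down"), ("down", "up")):
        assert dd.count(pair) == 0
        assert dd.sub_results[pair].p_final == 1.0


def test_directional_counts_partition_total_overlap(rng):
    genes = [f"U{i:03d}" for i in range(500)]
    uni = UniverseSpec(genes)
    for _ in range(20):
        q = random_signature(rng, genes, 50, "q")
        r = random_signature(rng, genes, 50, "r")
        dd = directional_decomposition(q, r, uni)
        # oracle: plain set arithmetic per direction pair
        qd, rd = q.directions(), r.directions()
        shared = set(qd) & set(rd)
        for dq in ("up", "down"):
            for dr in ("up", "down"):
                expected = {g for g in shared if qd[g] == dq and rd[g] == dr}
                assert set(dd.sub_results[(dq, dr)].overlap_gene_ids) == expected
        assert sum(dd.counts.values()) == dd.overall.n_overlap
        sets = [set(sub.overlap_gene_ids) for sub in dd.sub_results.values()]
        assert sum(len(s) for s in sets) == len(set().union(*sets))


@pytest.mark.parametrize(
    "alpha, m, expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.05, 12, 0.05 / 12)]
)
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_bonferroni_threshold_rejects_zero_comparisons():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((64, 77, 14, 27), "positive"),  # 141 concordant vs 41 discordant
        ((0, 0, 0, 0), "mixed"),
        ((3, 0, 1, 1), "positive"),
        ((3, 0, 2, 1), "mixed"),  # 3 concordant vs 3 discordant is a tie
        ((1, 1, 3, 2), "negative"),
        ((1, 1, 2, 0), "mixed"),
    ],
)
def test_classify_correlation(counts, expected, universe200):
    genes, uni = universe200
    n_uu, n_dd, n_ud, n_du = counts
    # build signatures realizing exactly these directional counts
    it = iter(genes)
    q_entries, r_entries = [], []
    for n, (dq, dr) in zip(counts, (("up", "up"), ("down", "down"), ("up", "down"), ("down", "up"))):
        for _ in range(n):
            g = next(it)
            q_entries.append((g, dq))
            r_entries.append((g, dr))
    if not q_entries:
        g = next(it)
        q_entries, r_entries = [(g, "up")], [(next(it), "up")]
    dd = directional_decomposition(make_signature(q_entries), make_signature(r_entries), uni)
    assert classify_correlation(dd) == expected
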