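"""Bridge formation, clustering, the exceedance test, and the three filters."""

import itertools
from fractions import Fraction

import pytest

from readstitch.bridges import (
    Bridge, BridgeCluster, cluster_bridges, exceedance_filter, exceedance_pvalue,
    filter_bridges, filter_min_count, form_bridges, probability_filter,
)
from readstitch.coverage import BinFit, CoverageModel
from readstitch.paf import AlignmentRecord
import numpy as np


def aln(name, rl, rs, re, strand, t, tl, ts, te, mq=60):
    return AlignmentRecord(name, rl, rs, re, strand, t, tl, ts, te, re - rs, re - rs, mq)


def bridge(fe, te, dist, rem_from=5000, rem_to=5000, mq=(60, 60), read="r"):
    return Bridge(fe, te, dist, min(mq), max(mq), rem_from, rem_to, 100, 100, read)


def cluster(fe, te, dists, rem_from=None, rem_to=None, mqs=None):
    n = len(dists)
    rem_from = rem_from or [5000] * n
    rem_to = rem_to or [5000] * n
    mqs = mqs or [(60, 60)] * n
    members = [
        bridge(fe, te, d, rf, rt, mq, f"r{i}")
        for i, (d, rf, rt, mq) in enumerate(zip(dists, rem_from, rem_to, mqs))
    ]
    return BridgeCluster(fe, te, members)


# --- formation -------------------------------------------------------------


def test_bridge_from_adjacent_mappings():
    a = aln("r", 2000, 0, 800, "+", "A", 5000, 4200, 5000)
    b = aln("r", 2000, 1100, 2000, "+", "B", 5000, 0, 900)
    (br,) = form_bridges([a, b])
    assert br.from_end == ("A", "r") and br.to_end == ("B", "l")
    assert br.distance == 300
    assert br.remaining_len_from == 800 and br.remaining_len_to == 900


def test_three_mappings_form_two_bridges():
    a = aln("r", 3000, 0, 900, "+", "A", 5000, 4100, 5000)
    b = aln("r", 3000, 1000, 1900, "+", "B", 900, 0, 900)
    c = aln("r", 3000, 2000, 3000, "+", "C", 5000, 0, 1000)
    brs = form_bridges([a, b, c])
    assert len(brs) == 2
    keys = {(x.from_end, x.to_end) for x in brs}
    assert (("A", "r"), ("B", "l")) in keys and (("B", "r"), ("C", "l")) in keys


def test_overlapping_anchors_give_negative_distance():
    a = aln("r", 2000, 0, 1000, "+", "A", 5000, 4000, 5000)
    b = aln("r", 2000, 950, 2000, "+", "B", 5000, 0, 1050)
    (br,) = form_bridges([a, b])
    assert br.distance == -50


def test_same_end_self_bridge_requires_long_distance():
    # palindromic artifact: out and back onto the same end with a short gap
    a = aln("r", 3000, 0, 900, "+", "A", 5000, 4100, 5000)
    b = aln("r", 3000, 1000, 1900, "-", "A", 5000, 4100, 5000)
    assert form_bridges([a, b], min_self_distance=1000) == []
    b2 = aln("r", 6000, 4000, 4900, "-", "A", 5000, 4100, 5000)
    assert len(form_bridges([a, b2], min_self_distance=1000)) == 1


# --- clustering ------------------------------------------------------------


def test_cluster_by_relative_distance():
    brs = [bridge(("A", "r"), ("B", "l"), d, read=f"r{d}") for d in (100, 110, 1000)]
    cs = cluster_bridges(brs, rel_tol=0.2, abs_floor=100)
    assert sorted(c.count for c in cs) == [1, 2]
    big = next(c for c in cs if c.count == 2)
    assert {b.distance for b in big.members} == {100, 110}


def test_single_bridge_single_cluster():
    cs = cluster_bridges([bridge(("A", "r"), ("B", "l"), 500)])
    assert len(cs) == 1 and cs[0].count == 1


def test_far_apart_gap_lengths_make_two_clusters():
    brs = [bridge(("A", "r"), ("B", "l"), d) for d in (200, 210, 5000, 5100)]
    cs = cluster_bridges(brs)
    assert sorted(c.count for c in cs) == [2, 2]


# --- minimum count ---------------------------------------------------------


def test_min_count_filter():
    c1 = cluster(("A", "r"), ("B", "l"), [100])
    c3 = cluster(("A", "r"), ("C", "l"), [100, 100, 100])
    assert filter_min_count([c1, c3], 3) == [c3]
    mixed = [c1, c3, cluster(("D", "r"), ("E", "l"), [1, 2])]
    assert filter_min_count(mixed, 3) == [c3]
    with pytest.raises(ValueError):
        filter_min_count([c1], 0)


# --- exceedance test -------------------------------------------------------


def enumeration_pvalue(n_control, n_test, r):
    """Oracle: exhaustively place distinct ranks into control/test groups."""
    n = n_control + n_test
    favorable = 0
    total = 0
    for controls in itertools.combinations(range(n), n_control):
        cs = set(controls)
        tests = [v for v in range(n) if v not in cs]
        test_max = max(tests) if tests else -1
        exceed = sum(1 for v in cs if v > test_max)
        favorable += exceed >= r
        total += 1
    return Fraction(favorable, total)


def test_exceedance_examples():
    assert exceedance_pvalue(5, 5, 0) == 1.0
    assert exceedance_pvalue(3, 2, 2) == pytest.approx(0.3)
    assert exceedance_pvalue(5, 1, 5) == pytest.approx(1 / 6)


def test_exceedance_matches_enumeration_exactly():
    """Exact rational agreement with permutation enumeration, all small cases."""
    for nc in range(1, 7):
        for nt in range(1, 5):
            for r in range(0, nc + 1):
                assert exceedance_pvalue(nc, nt, r, exact=True) == enumeration_pvalue(nc, nt, r)


def test_exceedance_filter_lone_cluster_never_removed():
    c = cluster(("A", "r"), ("B", "l"), [100, 100, 100])
    assert exceedance_filter([c], 0.01) == [c]


def test_exceedance_filter_removes_truncated_side():
    # control cluster: long remaining lengths; test cluster: all shorter
    good = cluster(("A", "r"), ("B", "l"), [100] * 5,
                   rem_to=[9000, 9500, 9700, 9900, 10000])
    bad = cluster(("A", "r"), ("C", "l"), [100] * 5,
                  rem_to=[1000, 1100, 1200, 1300, 1400])
    out = exceedance_filter([good, bad], 0.01)
    # r = 5, p = C(5,5)/C(10,5) ~= 0.00397 < 0.01
    assert exceedance_pvalue(5, 5, 5) == pytest.approx(1 / 252)
    assert out == [good]


def test_exceedance_filter_restores_bridge_between_bare_ends():
    good = cluster(("A", "r"), ("B", "l"), [100] * 5,
                   rem_to=[9000, 9500, 9700, 9900, 10000])
    bad = cluster(("A", "r"), ("C", "l"), [100] * 5,
                  rem_to=[1000, 1100, 1200, 1300, 1400])
    lonely = cluster(("C", "l"), ("D", "r"), [100] * 4,
                     rem_from=[900, 950, 980, 990], rem_to=[8000] * 4)
    out = exceedance_filter([good, bad, lonely], 0.01)
    assert good in out


# --- probability filter ----------------------------------------------------


def nb_model(mean=25.0, dispersion=10.0, bin_size=1000):
    counts = np.arange(100)
    return CoverageModel([BinFit(bin_size, mean, dispersion, counts)])


def test_probability_filter_removes_rare_competitor():
    strong = cluster(("A", "r"), ("B", "l"), [100] * 20)
    weak = cluster(("A", "r"), ("C", "l"), [100] * 2)
    out = probability_filter([strong, weak], nb_model(), prob_factor=10.0)
    assert out == [strong]


def test_probability_filter_keeps_symmetric_clusters():
    a = cluster(("A", "r"), ("B", "l"), [100] * 10)
    b = cluster(("A", "r"), ("C", "l"), [100] * 10)
    assert probability_filter([a, b], nb_model(), 10.0) == [a, b]


def test_probability_filter_exempts_distances_beyond_bins():
    strong = cluster(("A", "r"), ("B", "l"), [100] * 20)
    weak = cluster(("A", "r"), ("C", "l"), [5000] * 2)  # beyond the 1000 bp bin
    out = probability_filter([strong, weak], nb_model(), 10.0)
    assert weak in out


def test_quality_levels_resolve_before_counts():
    # same totals, but one cluster's members have low mapping quality
    hi = cluster(("A", "r"), ("B", "l"), [100] * 12)
    lo = cluster(("A", "r"), ("C", "l"), [100] * 12, mqs=[(20, 20)] * 12)
    out = probability_filter([hi, lo], nb_model(), prob_factor=10.0)
    assert hi in out and lo not in out


# --- chain properties ------------------------------------------------------


def test_filter_chain_idempotent():
    model = nb_model()
    clusters = [
        cluster(("A", "r"), ("B", "l"), [100] * 20),
        cluster(("A", "r"), ("C", "l"), [100] * 2),
        cluster(("D", "r"), ("E", "l"), [300] * 8),
        cluster(("D", "r"), ("F", "l"), [310] * 8,
                rem_to=[500, 600, 700, 800, 900, 950, 980, 990]),
    ]
    once = filter_bridges(clusters, model)
    twice = filter_bridges(once, model)
    assert twice == once
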