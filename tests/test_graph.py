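"""Unconflicted scaffolding, long-range extraction, and the scaffold graph."""

import random

from graphfix import (
    entries_from_steps, entry_set, make_conn, make_pair_cluster,
    oracle_build_graph, random_layout_world, reverse_steps,
)
from readstitch.bridges import Bridge, BridgeCluster
from readstitch.graph import (
    build_graph, extract_long_range, filter_long_range, remove_duplicates_from_graph,
    scaffold_unconflicted,
)


def cluster(fe, te, dist=100, count=5):
    members = [
        Bridge(fe, te, dist, 60, 60, 5000, 5000, 100, 100, f"r{i}")
        for i in range(count)
    ]
    return BridgeCluster(fe, te, members)


# --- unconflicted scaffolding ---------------------------------------------


def test_linear_chain_merges_to_one_scaffold():
    clusters = [
        cluster(("A", "r"), ("B", "l")),
        cluster(("B", "r"), ("C", "l")),
    ]
    scaffolds, contig_map, remaining = scaffold_unconflicted(clusters, "ABC")
    assert len(scaffolds) == 1 and remaining == []
    assert [n for n, _ in scaffolds[0].parts] == ["A", "B", "C"]
    assert [s for _, s in scaffolds[0].parts] == ["+", "+", "+"]


def test_conflicting_end_is_not_merged():
    clusters = [
        cluster(("A", "r"), ("B", "l")),
        cluster(("A", "r"), ("C", "l")),
    ]
    scaffolds, contig_map, remaining = scaffold_unconflicted(clusters, "ABC")
    assert len(scaffolds) == 3
    assert len(remaining) == 2


def test_merge_equals_union_find_oracle():
    rng = random.Random(0)
    for trial in range(10):
        n = rng.randint(4, 10)
        names = [f"c{i}" for i in range(n)]
        order = names[:]
        rng.shuffle(order)
        clusters = [cluster((a, "r"), (b, "l")) for a, b in zip(order, order[1:])]
        # union-find oracle over unconflicted edges
        parent = {x: x for x in names}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for c in clusters:
            ra, rb = find(c.from_end[0]), find(c.to_end[0])
            parent[ra] = rb
        scaffolds, contig_map, _ = scaffold_unconflicted(clusters, names)
        groups = {}
        for name in names:
            groups.setdefault(find(name), set()).add(name)
        got = {frozenset(s.contig_names) for s in scaffolds}
        assert got == {frozenset(g) for g in groups.values()}


# --- long-range extraction -------------------------------------------------


def _aln(name, rl, rs, re, strand, t, tl, ts, te, mq=60):
    from readstitch.paf import AlignmentRecord

    return AlignmentRecord(name, rl, rs, re, strand, t, tl, ts, te, re - rs, re - rs, mq)


def _world_for_extraction():
    """Three single-contig scaffolds X, Y, Z and accepted clusters X-Y, Y-Z."""
    clusters = []
    scaffolds, contig_map, _ = scaffold_unconflicted([], "XYZ")
    sid = {s.parts[0][0]: s.scaffold_id for s in scaffolds}
    lifted = [
        make_pair_cluster(sid["X"], "r", sid["Y"], "l", 100),
        make_pair_cluster(sid["Y"], "r", sid["Z"], "l", 100),
    ]
    return scaffolds, contig_map, lifted, sid


def test_read_over_three_scaffolds_yields_connection():
    scaffolds, contig_map, lifted, sid = _world_for_extraction()
    alns = [
        _aln("r", 6000, 0, 1900, "+", "X", 2000, 100, 2000),
        _aln("r", 6000, 2000, 3900, "+", "Y", 2000, 0, 1900),
        _aln("r", 6000, 4000, 5900, "+", "Z", 2000, 0, 1900),
    ]
    conns = extract_long_range(alns, contig_map, scaffolds, lifted)
    assert len(conns) == 1
    assert [v.scaffold_id for v in conns[0].visits] == [sid["X"], sid["Y"], sid["Z"]]


def test_read_over_two_scaffolds_yields_none():
    scaffolds, contig_map, lifted, sid = _world_for_extraction()
    alns = [
        _aln("r", 4000, 0, 1900, "+", "X", 2000, 100, 2000),
        _aln("r", 4000, 2000, 3900, "+", "Y", 2000, 0, 1900),
    ]
    assert extract_long_range(alns, contig_map, scaffolds, lifted) == []


def test_unaccepted_hop_splits_traversal():
    scaffolds, contig_map, lifted, sid = _world_for_extraction()
    lifted = lifted[:1]  # Y-Z hop is not an accepted bridge
    alns = [
        _aln("r", 6000, 0, 1900, "+", "X", 2000, 100, 2000),
        _aln("r", 6000, 2000, 3900, "+", "Y", 2000, 0, 1900),
        _aln("r", 6000, 4000, 5900, "+", "Z", 2000, 0, 1900),
    ]
    assert extract_long_range(alns, contig_map, scaffolds, lifted) == []


# --- graph construction ----------------------------------------------------


def test_build_graph_single_connection_entries():
    steps = [(0, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    entries = entries_from_steps([steps], [])
    by_start = {}
    for e in entries:
        by_start.setdefault(e.start, []).append(e.path)
    assert by_start[(0, "r")] == [((1, "+", 100.0), (2, "+", 200.0))]
    assert ((2, "-", 200.0), (0, "-", 100.0)) in by_start[(1, "r")] or by_start[(1, "l")]
    # entries exist from every scaffold toward both ends
    assert (1, "l") in by_start and (1, "r") in by_start
    assert by_start[(2, "l")] == [((1, "-", 200.0), (0, "-", 100.0))]


def test_contained_path_removed():
    long_steps = [(0, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    entries = entries_from_steps(
        [long_steps], [make_pair_cluster(0, "r", 1, "l", 100.0)]
    )
    from_x = [e for e in entries if e.start == (0, "r")]
    assert len(from_x) == 1  # the single-step path {1} is a prefix of {1,2}
    assert len(from_x[0].path) == 2
    assert from_x[0].support >= 6  # read support plus cluster count


def test_build_graph_matches_oracle_on_random_fixtures():
    for seed in range(100):
        layout, dists, steps_full, conns, clusters = random_layout_world(seed)
        got = build_graph([make_conn(s, f"r{i}") for i, s in enumerate(conns)], clusters)
        want = oracle_build_graph(conns, clusters)
        assert entry_set(got) == entry_set(want), f"seed {seed}"


def test_bidirectionality_before_pruning():
    steps = [(0, "+", 0.0), (1, "-", 150.0), (2, "+", 300.0)]
    entries = entries_from_steps([steps], [])
    # the forward entry from 0 has a mirrored entry from 2
    fwd = next(e for e in entries if e.start == (0, "r"))
    rev = next(e for e in entries if e.start == (2, "l"))
    assert [s for s, _, _ in rev.path] == [1, 0]
    assert [st for _, st, _ in rev.path] == ["+", "-"]


# --- long-range filtering --------------------------------------------------


def test_unique_long_range_bridge_kept():
    steps = [(0, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    conns = [make_conn(steps, f"r{i}") for i in range(4)]
    assert len(filter_long_range(conns)) == 4


def test_both_sides_failing_splits_connection():
    # the doubtful traversal (5, 1, 2) has better-supported competitors that
    # share its remaining two scaffolds on each side; both outer anchors of
    # its own reads are truncated
    good_left = [(0, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    good_right = [(5, "+", 0.0), (1, "+", 100.0), (7, "+", 200.0)]
    bad = [(5, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    conns = [make_conn(good_left, f"g{i}") for i in range(8)]
    conns += [make_conn(good_right, f"h{i}") for i in range(8)]
    for i in range(2):
        c = make_conn(bad, f"b{i}")
        c.visits[0].remaining_left = 400
        c.visits[-1].remaining_right = 400
        conns.append(c)
    out = filter_long_range(conns, pval_threshold=0.05)
    keys = {tuple(v.scaffold_id for v in c.visits) for c in out}
    assert (5, 1, 2) not in keys
    assert (0, 1, 2) in keys and (5, 1, 7) in keys


def test_one_side_failing_keeps_connection():
    good_left = [(0, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    half_bad = [(5, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0)]
    conns = [make_conn(good_left, f"g{i}") for i in range(8)]
    for i in range(2):
        c = make_conn(half_bad, f"b{i}")
        c.visits[0].remaining_left = 400  # truncated on the left outer only
        conns.append(c)
    out = filter_long_range(conns, pval_threshold=0.05)
    keys = {tuple(v.scaffold_id for v in c.visits) for c in out}
    assert (5, 1, 2) in keys


# --- duplicate removal -----------------------------------------------------


def test_duplicate_with_lower_support_removed_from_shared_paths():
    via_a = [(0, "+", 0.0), (1, "+", 100.0), (3, "+", 100.0)]
    via_dup = [(0, "+", 0.0), (2, "+", 100.0), (3, "+", 100.0)]
    conns = [make_conn(via_a, f"a{i}") for i in range(12)]
    conns += [make_conn(via_dup, f"d{i}") for i in range(3)]
    entries = build_graph(conns, [])
    out = remove_duplicates_from_graph(entries, [(2, 1, "+")])
    assert all(all(sid != 2 for sid, _, _ in e.path) for e in out)


def test_duplicate_with_disjoint_neighborhood_untouched():
    via_a = [(0, "+", 0.0), (1, "+", 100.0), (3, "+", 100.0)]
    elsewhere = [(5, "+", 0.0), (2, "+", 100.0), (6, "+", 100.0)]
    conns = [make_conn(via_a, f"a{i}") for i in range(5)]
    conns += [make_conn(elsewhere, f"e{i}") for i in range(5)]
    entries = build_graph(conns, [])
    out = remove_duplicates_from_graph(entries, [(2, 1, "+")])
    assert entry_set(out) == entry_set(entries)


def test_equal_counts_tie_break_deterministic():
    via_a = [(0, "+", 0.0), (1, "+", 100.0), (3, "+", 100.0)]
    via_dup = [(0, "+", 0.0), (2, "+", 100.0), (3, "+", 100.0)]
    conns = [make_conn(via_a, f"a{i}") for i in range(4)]
    conns += [make_conn(via_dup, f"d{i}") for i in range(4)]
    entries = build_graph(conns, [])
    out1 = remove_duplicates_from_graph(entries, [(2, 1, "+")])
    out2 = remove_duplicates_from_graph(list(reversed(entries)), [(2, 1, "+")])
    # the larger id (2) loses on a full tie, regardless of input order
    assert all(all(sid != 2 for sid, _, _ in e.path) for e in out1)
    assert entry_set(out1) == entry_set(out2)
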