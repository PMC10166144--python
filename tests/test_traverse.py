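"""Graph traversal: initial paths, loops, combination tests, merging, finishing."""

import itertools

import pytest

from graphfix import adjacent_pair_clusters, make_conn
from readstitch.graph import build_graph
from readstitch.pairs import build_pairs, enforce_consistency, filter_pairs
from readstitch.traverse import (
    LoopStructure, ScaffoldPath, _attach, build_loop_units, can_combine,
    combine_paths, find_loops, handle_inverted_repeats, initial_unique_paths,
    insert_placeable_paths, merge_paths, remove_contained, reverse_path,
    finish_paths, path_sids, traverse_graph, traverse_loop,
)


def chain_steps(layout, dists):
    return [
        (sid, strand, 0.0 if k == 0 else dists[k - 1])
        for k, (sid, strand) in enumerate(layout)
    ]


def windows_of(steps, min_n=3):
    out = []
    for n in range(min_n, len(steps) + 1):
        for i in range(len(steps) - n + 1):
            w = [list(s) for s in steps[i: i + n]]
            w[0][2] = 0.0
            out.append([tuple(x) for x in w])
    return out


def world(windows, clusters=()):
    entries = build_graph([make_conn(w, f"r{i}") for i, w in enumerate(windows)],
                          list(clusters))
    pairs = enforce_consistency(filter_pairs(build_pairs(entries), entries), entries)
    return entries, pairs


# --- initial unique paths --------------------------------------------------


def test_unbranched_chain_yields_single_path():
    layout = [(i, "+") for i in range(5)]
    dists = [100.0 * (k + 1) for k in range(4)]
    entries, pairs = world(windows_of(chain_steps(layout, dists)))
    paths = initial_unique_paths(pairs)
    assert len(paths) == 1
    assert sorted(path_sids(paths[0])) == [0, 1, 2, 3, 4]


def test_biallelic_branch_splits_paths():
    dists = [100.0, 200.0, 300.0, 400.0]
    hap1 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")], dists)
    hap2 = chain_steps([(0, "+"), (1, "+"), (5, "+"), (3, "+"), (4, "+")], dists)
    entries, pairs = world(windows_of(hap1) + windows_of(hap2))
    paths = initial_unique_paths(pairs)
    # no single path runs through the branch scaffold alternatives
    for p in paths:
        sids = set(path_sids(p))
        assert not ({2, 5} <= sids)


def test_no_pairs_no_paths():
    assert initial_unique_paths([]) == []


# --- loops -----------------------------------------------------------------


LOOP_DISTS = (100.0, 200.0, 300.0, 400.0)


def loop_world():
    """True walk X R A R Y: the repeat scaffold R is traversed twice."""
    d1, d2, d3, d4 = LOOP_DISTS
    windows = [
        [(0, "+", 0.0), (1, "+", d1), (2, "+", d2)],
        [(1, "+", 0.0), (2, "+", d2), (1, "+", d3)],
        [(2, "+", 0.0), (1, "+", d3), (3, "+", d4)],
    ]
    return world(windows)


def test_find_loops_members_and_exits():
    entries, pairs = loop_world()
    (loop,) = find_loops(entries)
    assert loop.members == {1, 2}
    assert loop.exits == {0, 3}


def test_loops_sharing_scaffold_merge():
    windows = [
        [(0, "+", 0.0), (1, "+", 100.0), (2, "+", 200.0), (1, "+", 300.0)],
        [(1, "+", 0.0), (3, "+", 100.0), (1, "+", 500.0)],
    ]
    entries, _ = world(windows)
    loops = find_loops(entries)
    assert len(loops) == 1
    assert loops[0].members == {1, 2, 3}


def test_loop_closure_equals_fixed_point():
    windows = [
        [(0, "+", 0.0), (1, "+", 100.0), (5, "+", 150.0), (2, "+", 200.0), (1, "+", 300.0)],
    ]
    entries, _ = world(windows)
    (loop,) = find_loops(entries)
    # brute-force fixed point: scaffolds between two members in any entry path
    fulls = []
    for e in entries:
        start_strand = "+" if e.start[1] == "r" else "-"
        fulls.append([e.start[0]] + [s for s, _, _ in e.path])
    members = {1}
    changed = True
    while changed:
        changed = False
        for seq in fulls:
            inside = [i for i, sid in enumerate(seq) if sid in members]
            if len(inside) >= 2:
                add = set(seq[inside[0]: inside[-1] + 1]) - members
                if add:
                    members |= add
                    changed = True
    assert loop.members == members


def test_build_loop_units_simple_cycle():
    entries, _ = loop_world()
    (loop,) = find_loops(entries)
    units = build_loop_units(loop, entries)
    assert len(units) == 1
    assert path_sids(units[0]) == (1, 2, 1)


def test_traverse_loop_resolves_double_traversal():
    entries, pairs = loop_world()
    (loop,) = find_loops(entries)
    units = build_loop_units(loop, entries)
    paths = traverse_loop(loop, units, entries, pairs)
    assert len(paths) == 1
    assert path_sids(paths[0]) == (0, 1, 2, 1, 3)


def oracle_loop_search(loop, units, entries, pairs, max_units=6):
    """Exhaustive enumeration over unit sequences (independent of the search)."""
    bridged_exits = set()
    for p in loop.exit_paths:
        if any(sid in loop.exits for sid, _, _ in p[1:]):
            bridged_exits.add(p[0][0])
    unbridged = sorted(loop.exits - bridged_exits)
    if len(unbridged) != 2:
        return None
    a_sid, b_sid = unbridged
    starts = [p for p in loop.exit_paths if p[0][0] == a_sid]
    targets = [reverse_path(p) for p in loop.exit_paths if p[0][0] == b_sid]
    best = None
    for n in range(0, max_units + 1):
        for seq in itertools.product(units, repeat=n):
            for s in starts:
                path = s
                penalty = 0
                dead = False
                for u in seq:
                    ext = _attach(path, u)
                    if ext is None or not can_combine(path, ext, entries, pairs,
                                                      require_both=False):
                        dead = True
                        break
                    path = path + ext
                if dead:
                    continue
                for t in targets:
                    ext = _attach(path, t)
                    if ext is None or not can_combine(path, ext, entries, pairs,
                                                      require_both=False):
                        continue
                    cand = path + ext
                    key = (penalty, len(cand), cand)
                    if best is None or key < best:
                        best = key
    return best[2] if best else None


def test_traverse_loop_matches_exhaustive_search():
    entries, pairs = loop_world()
    (loop,) = find_loops(entries)
    units = build_loop_units(loop, entries)
    got = traverse_loop(loop, units, entries, pairs)
    want = oracle_loop_search(loop, units, entries, pairs)
    assert want is not None and got and got[-1] == want


def test_bridged_loop_takes_read_path_verbatim():
    d1, d2, d3, d4 = LOOP_DISTS
    spanning = [(0, "+", 0.0), (1, "+", d1), (2, "+", d2), (1, "+", d3), (3, "+", d4)]
    windows = windows_of(spanning)
    entries, pairs = world(windows)
    (loop,) = find_loops(entries)
    units = build_loop_units(loop, entries)
    paths = traverse_loop(loop, units, entries, pairs)
    assert any(path_sids(p) == (0, 1, 2, 1, 3) for p in paths)


def test_loop_with_many_exits_left_unresolved():
    d = 100.0
    windows = [
        [(0, "+", 0.0), (1, "+", d), (2, "+", d)],
        [(1, "+", 0.0), (2, "+", d), (1, "+", d)],
        [(2, "+", 0.0), (1, "+", d), (3, "+", d)],
        [(2, "+", 0.0), (1, "+", d), (4, "+", 2 * d)],
        [(5, "+", 0.0), (2, "+", d), (1, "+", d)],
    ]
    entries, pairs = world(windows)
    (loop,) = find_loops(entries)
    assert len(loop.exits) > 2
    units = build_loop_units(loop, entries)
    assert traverse_loop(loop, units, entries, pairs) == []


# --- inverted repeats ------------------------------------------------------


def test_bridged_inverted_repeat_included():
    steps = [(0, "+", 0.0), (1, "+", 100.0), (1, "-", 200.0), (2, "+", 300.0)]
    entries, _ = world([steps])
    paths = handle_inverted_repeats(entries)
    assert any(path_sids(p) == (0, 1, 1, 2) for p in paths)


def test_unbridged_two_exit_inverted_repeat_resolved():
    windows = [
        [(0, "+", 0.0), (1, "+", 100.0), (1, "-", 200.0)],
        [(2, "+", 0.0), (1, "+", 300.0), (1, "-", 200.0)],
    ]
    entries, _ = world(windows)
    paths = handle_inverted_repeats(entries)
    assert paths, "two-exit palindrome should be resolved"
    (p,) = paths
    assert set(path_sids(p)) == {0, 1, 2}or set(path_sids(p)) == {0, 1, 1, 2}


# --- combination test ------------------------------------------------------


def test_two_halves_of_supported_chain_combine():
    layout = [(i, "+") for i in range(6)]
    dists = [100.0] * 5
    steps = chain_steps(layout, dists)
    entries, pairs = world(windows_of(steps))
    a, b = tuple(steps[:3]), tuple(steps[3:])
    assert can_combine(a, b, entries, pairs)


def test_first_scaffold_mismatch_invalid():
    layout = [(i, "+") for i in range(6)]
    dists = [100.0] * 5
    steps = chain_steps(layout, dists)
    entries, pairs = world(windows_of(steps))
    a = tuple(steps[:3])
    wrong = ((9, "+", 100.0), (4, "+", 100.0))
    assert not can_combine(a, wrong, entries, pairs)


def test_haplotype_crossing_combination_rejected():
    dists = [100.0] * 4
    hap1 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")], dists)
    hap2 = chain_steps([(5, "+"), (1, "+"), (2, "+"), (3, "+"), (6, "+")], dists)
    entries, pairs = world(windows_of(hap1) + windows_of(hap2))
    a = tuple(hap1[:3])  # 0 1 2
    good = tuple(hap1[3:])  # 3 4
    cross = (hap2[3], hap2[4])  # 3 6
    assert can_combine(a, good, entries, pairs)
    assert not can_combine(a, cross, entries, pairs)


# --- merging ---------------------------------------------------------------


def sp(steps, support=5):
    return ScaffoldPath.from_steps(tuple(steps), support)


def test_identical_paths_merge_to_one():
    steps = chain_steps([(0, "+"), (1, "+"), (2, "+")], [100.0, 200.0])
    out = merge_paths([sp(steps), sp(steps)], ploidy=2)
    assert len(out) == 1 and out[0].n_haps == 1


def test_haplotype_variants_merge_to_two_hap_path():
    dists = [100.0] * 4
    hap1 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")], dists)
    hap2 = chain_steps([(0, "+"), (1, "+"), (5, "+"), (3, "+"), (4, "+")], dists)
    out = merge_paths([sp(hap1, 9), sp(hap2, 4)], ploidy=2)
    assert len(out) == 1
    merged = out[0]
    assert merged.n_haps == 2
    assert path_sids(merged.hap(0)) == (0, 1, 2, 3, 4)  # higher support first
    assert path_sids(merged.hap(1)) == (0, 1, 5, 3, 4)


def test_over_ploidy_alternatives_stay_separate():
    dists = [100.0] * 2
    alts = [
        chain_steps([(0, "+"), (x, "+"), (3, "+")], dists) for x in (1, 2, 4)
    ]
    out = merge_paths([sp(a) for a in alts], ploidy=2)
    assert len(out) == 3
    assert all(p.n_haps == 1 for p in out)


def test_distance_only_variants_reduce():
    a = chain_steps([(0, "+"), (1, "+"), (2, "+")], [100.0, 200.0])
    b = chain_steps([(0, "+"), (1, "+"), (2, "+")], [130.0, 200.0])
    c = chain_steps([(0, "+"), (5, "+"), (2, "+")], [100.0, 200.0])
    out = merge_paths([sp(a, 9), sp(b, 2), sp(c, 5)], ploidy=2)
    assert len(out) == 1 and out[0].n_haps == 2


def test_deletion_only_path_removed_when_over_ploidy():
    dists = [100.0] * 3
    full1 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+")], dists)
    full2 = chain_steps([(0, "+"), (5, "+"), (2, "+"), (3, "+")], dists)
    deleted = chain_steps([(0, "+"), (2, "+"), (3, "+")], [200.0, 100.0])
    out = merge_paths([sp(full1, 9), sp(full2, 5), sp(deleted, 2)], ploidy=2)
    assert len(out) == 1 and out[0].n_haps == 2


# --- combining -------------------------------------------------------------


def test_unique_overlap_combines():
    layout = [(i, "+") for i in range(6)]
    dists = [100.0] * 5
    steps = chain_steps(layout, dists)
    entries, pairs = world(windows_of(steps))
    a = sp(steps[:4])
    b = sp(steps[3:])
    out = combine_paths([a, b], entries, pairs)
    assert len(out) == 1
    assert path_sids(out[0].primary) in ((0, 1, 2, 3, 4, 5), (5, 4, 3, 2, 1, 0))


def test_two_equal_partners_prevent_combination():
    dists = [100.0] * 3
    hap1 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+")], dists)
    hap2 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (4, "+")], dists)
    entries, pairs = world(windows_of(hap1) + windows_of(hap2))
    a = sp(hap1[:3])
    b = sp(hap1[2:])
    c = sp(hap2[2:])
    out = combine_paths([a, b, c], entries, pairs)
    assert len(out) == 3  # ambiguous: no combination


def test_chain_of_three_combines_iteratively():
    layout = [(i, "+") for i in range(7)]
    dists = [100.0] * 6
    steps = chain_steps(layout, dists)
    entries, pairs = world(windows_of(steps))
    parts = [sp(steps[:3]), sp(steps[2:5]), sp(steps[4:])]
    out = combine_paths(parts, entries, pairs)
    assert len(out) == 1
    assert len(out[0].primary) == 7


# --- insertion and finishing ----------------------------------------------


def test_insert_unambiguous_haplotype_fragment():
    dists = [100.0] * 4
    base = sp(chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")], dists), 9)
    frag = sp(chain_steps([(1, "+"), (5, "+"), (3, "+")], [100.0, 100.0]), 3)
    out = insert_placeable_paths([base, frag], ploidy=2)
    assert len(out) == 1
    assert out[0].n_haps == 2


def test_ambiguous_insertion_rejected():
    dists = [100.0] * 4
    base1 = sp(chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")], dists), 9)
    base2 = sp(chain_steps([(9, "+"), (1, "+"), (8, "+"), (3, "+"), (7, "+")], dists), 9)
    frag = sp(chain_steps([(1, "+"), (5, "+"), (3, "+")], [100.0, 100.0]), 3)
    out = insert_placeable_paths([base1, base2, frag], ploidy=2)
    assert len(out) == 3  # two valid positions: not inserted


def test_remove_contained_paths():
    steps = chain_steps([(i, "+") for i in range(5)], [100.0] * 4)
    big = sp(steps)
    small = sp(steps[1:4])
    out = remove_contained([big, small])
    assert out == [big]


def test_circular_path_linearized():
    steps = chain_steps(
        [(0, "+"), (1, "+"), (2, "+"), (0, "+")], [100.0, 100.0, 100.0]
    )
    out = finish_paths([sp(steps)], [], [])
    assert path_sids(out[0].primary) == (0, 1, 2)


def test_clean_linear_path_unchanged_by_finish():
    steps = chain_steps([(i, "+") for i in range(4)], [100.0] * 3)
    out = finish_paths([sp(steps)], [], [])
    assert len(out) == 1 and out[0].primary == tuple(steps)


# --- full traversal --------------------------------------------------------


def test_full_reconstruction_on_unbranched_graph():
    layout = [(i, "+") for i in range(6)]
    dists = [100.0 * (k + 1) for k in range(5)]
    steps = chain_steps(layout, dists)
    clusters = adjacent_pair_clusters(layout, dists)
    entries = build_graph([make_conn(w, f"r{i}") for i, w in enumerate(windows_of(steps))],
                          clusters)
    pairs = enforce_consistency(filter_pairs(build_pairs(entries), entries), entries)
    final = traverse_graph(entries, pairs, range(6))
    assert len(final) == 1
    p = final[0].primary
    assert path_sids(p) in ((0, 1, 2, 3, 4, 5), (5, 4, 3, 2, 1, 0))


def test_traversal_covers_every_scaffold_once():
    dists = [100.0] * 4
    hap1 = chain_steps([(0, "+"), (1, "+"), (2, "+"), (3, "+"), (4, "+")], dists)
    entries, pairs = world(windows_of(hap1))
    final = traverse_graph(entries, pairs, range(7))
    seen = []
    for f in final:
        seen.extend(path_sids(f.primary))
    assert sorted(seen) == [0, 1, 2, 3, 4, 5, 6]  # 5, 6 as singletons
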