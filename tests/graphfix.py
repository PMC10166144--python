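"""Graph-level fixture helpers: synthetic connections, clusters, and oracles.

These build scaffold-graph inputs directly (no sequences), so structural
operations can be checked against independent brute-force constructions.
"""

from __future__ import annotations

import random

from readstitch.graph import (
    LongRangeConnection, ScafCluster, ScaffoldGraphEntry, Visit, _flip,
    build_graph,
)


class FakeCluster:
    """Minimal stand-in exposing the count/mean_distance surface (synthetic)."""

    def __init__(self, count: int, mean_distance: float):
        self.count = count
        self.mean_distance = mean_distance


def make_conn(steps, read="r") -> LongRangeConnection:
    """steps: [(sid, strand, dist_from_prev)] with the first dist ignored."""
    visits = []
    pos = 0
    for k, (sid, strand, dist) in enumerate(steps):
        d = 0.0 if k == 0 else float(dist)
        visits.append(
            Visit(sid, strand, d, read_enter=pos, read_exit=pos + 1000,
                  mapq=60, remaining_left=pos + 1000, remaining_right=99_000 - pos)
        )
        pos += 1100
    return LongRangeConnection(read, visits)


def make_pair_cluster(sid_a, side_a, sid_b, side_b, dist, count=5) -> ScafCluster:
    return ScafCluster((sid_a, side_a), (sid_b, side_b), FakeCluster(count, float(dist)))


def exit_side(strand):
    return "r" if strand == "+" else "l"


def entry_side(strand):
    return "l" if strand == "+" else "r"


def reverse_steps(steps):
    out = []
    for i in range(len(steps) - 1, -1, -1):
        d = steps[i + 1][2] if i + 1 < len(steps) else 0.0
        out.append((steps[i][0], _flip(steps[i][1]), d))
    return out


def adjacent_pair_clusters(layout, dists, count=5):
    """One accepted cluster per adjacent pair of an oriented layout."""
    out = []
    for k, ((a, sa), (b, sb)) in enumerate(zip(layout, layout[1:])):
        out.append(
            make_pair_cluster(a, exit_side(sa), b, entry_side(sb), dists[k], count)
        )
    return out


def oracle_build_graph(conn_step_lists, pair_clusters):
    """Independent construction: oriented copies, suffix enumeration, quadratic pruning."""
    raw: dict = {}

    def add(start, path, w):
        raw.setdefault(start, {})
        raw[start][path] = raw[start].get(path, 0) + w

    for steps in conn_step_lists:
        for oriented in (list(steps), reverse_steps(steps)):
            for i in range(len(oriented) - 1):
                sid, strand, _ = oriented[i]
                start = (sid, exit_side(strand))
                path = tuple((s, st, float(d)) for s, st, d in oriented[i + 1:])
                add(start, path, 1)
    for c in pair_clusters:
        (fa, fs), (ta, ts) = c.from_end, c.to_end
        add((fa, fs), ((ta, "+" if ts == "l" else "-", float(c.mean_distance)),), c.count)
        add((ta, ts), ((fa, "+" if fs == "l" else "-", float(c.mean_distance)),), c.count)
    entries = []
    for start, paths in raw.items():
        for p in paths:
            contained = any(q != p and q[: len(p)] == p for q in paths)
            if contained:
                continue
            support = sum(w for q, w in paths.items() if q[: len(p)] == p or p[: len(q)] == q)
            entries.append(ScaffoldGraphEntry(start, p, support))
    return entries


def entry_set(entries):
    return {(e.start, tuple((s, st, round(d)) for s, st, d in e.path), e.support)
            for e in entries}


def random_layout_world(seed, n_min=4, n_max=8, n_reads=8):
    """A random oriented chain plus read windows over it (both orientations)."""
    rng = random.Random(seed)
    n = rng.randint(n_min, n_max)
    layout = [(i, rng.choice("+-")) for i in range(n)]
    dists = [100.0 * (k + 1) for k in range(n - 1)]
    steps_full = [
        (sid, strand, 0.0 if k == 0 else dists[k - 1])
        for k, (sid, strand) in enumerate(layout)
    ]
    conns = []
    for _ in range(n_reads):
        i = rng.randrange(0, n - 2)
        j = rng.randrange(i + 2, n)  # window of >= 3 scaffolds
        window = [
            (sid, strand, 0.0 if k == i else dists[k - 1])
            for k, (sid, strand) in enumerate(layout)
        ][i: j + 1]
        if rng.random() < 0.5:
            window = reverse_steps(window)
        conns.append(window)
    clusters = adjacent_pair_clusters(layout, dists, count=rng.randint(3, 9))
    return layout, dists, steps_full, conns, clusters


def entries_from_steps(conn_step_lists, pair_clusters):
    return build_graph([make_conn(s) for s in conn_step_lists], pair_clusters)
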