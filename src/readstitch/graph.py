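"""Unconflicted scaffolding, long-range connections, and the scaffold graph.

Contig ends whose surviving bridge is mutually exclusive are merged into
scaffolds right away.  Reads that traverse at least three scaffolds provide
long-range connections; after filtering these against each other, every
directional sub-path of every connection becomes a scaffold-graph entry: the
graph lists, for each scaffold side, all read-supported outgoing paths with
orientations and distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .bridges import BridgeCluster, End, exceedance_pvalue
from .paf import AlignmentRecord

Step = tuple[int, str, float]  # (scaffold_id, strand, distance from previous)
ScafEnd = tuple[int, str]  # (scaffold_id, side 'l' or 'r')


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass
class Scaffold:
    scaffold_id: int
    parts: list[tuple[str, str]]  # (contig name, strand)
    joins: list[BridgeCluster] = field(default_factory=list)  # len(parts) - 1

    @property
    def contig_names(self) -> list[str]:
        return [name for name, _ in self.parts]


def scaffold_unconflicted(
    clusters: Sequence[BridgeCluster], contig_names: Iterable[str]
) -> tuple[list[Scaffold], dict[str, tuple[int, int, str]], list[BridgeCluster]]:
    """Merge contigs joined by mutually exclusive bridges into scaffolds.

    An end is unconflicted iff exactly one surviving cluster touches it and
    the partner end is likewise exclusive (reciprocal-best semantics).
    Returns the scaffolds, a contig -> (scaffold_id, position, strand) map,
    and the clusters not consumed by merging.
    """
    per_end: dict[End, list[BridgeCluster]] = {}
    for c in clusters:
        per_end.setdefault(c.from_end, []).append(c)
        if c.to_end != c.from_end:
            per_end.setdefault(c.to_end, []).append(c)
    used: set[int] = set()
    edge_at: dict[End, BridgeCluster] = {}
    for i, c in enumerate(clusters):
        if c.from_end[0] == c.to_end[0]:
            continue  # self-bridges feed the loop machinery, not direct merging
        if len(per_end[c.from_end]) == 1 and len(per_end[c.to_end]) == 1:
            edge_at[c.from_end] = c
            edge_at[c.to_end] = c
            used.add(i)

    scaffolds: list[Scaffold] = []
    contig_map: dict[str, tuple[int, int, str]] = {}
    visited: set[str] = set()

    def other(side: str) -> str:
        return "l" if side == "r" else "r"

    names = sorted(set(contig_names))
    # chain starts: contigs with a free end; then any remaining (cycles)
    order = [n for n in names if (n, "l") not in edge_at or (n, "r") not in edge_at]
    order += [n for n in names if n not in order]
    for name in order:
        if name in visited:
            continue
        # choose entry side: a side without an edge if possible
        entry = "l" if (name, "l") not in edge_at else "r"
        parts: list[tuple[str, str]] = []
        joins: list[BridgeCluster] = []
        cur, side = name, entry
        while True:
            visited.add(cur)
            orient = "+" if side == "l" else "-"
            parts.append((cur, orient))
            exit_end = (cur, other(side))
            c = edge_at.get(exit_end)
            if c is None:
                break
            nxt_end = c.to_end if c.from_end == exit_end else c.from_end
            if nxt_end[0] in visited:  # cycle: stop deterministically
                break
            joins.append(c)
            cur, side = nxt_end
        sid = len(scaffolds)
        scaffolds.append(Scaffold(sid, parts, joins))
        for pos, (cname, orient) in enumerate(parts):
            contig_map[cname] = (sid, pos, orient)
    remaining = [c for i, c in enumerate(clusters) if i not in used]
    return scaffolds, contig_map, remaining


def contig_end_to_scaffold_end(
    end: End, contig_map: dict[str, tuple[int, int, str]], scaffolds: list[Scaffold]
) -> ScafEnd | None:
    """Map a contig end to the scaffold end it is exposed at (None if interior)."""
    name, side = end
    sid, pos, orient = contig_map[name]
    outward_left = (side == "l") == (orient == "+")
    if outward_left and pos == 0:
        return (sid, "l")
    if not outward_left and pos == len(scaffolds[sid].parts) - 1:
        return (sid, "r")
    return None


@dataclass
class ScafCluster:
    """A bridge cluster re-expressed between scaffold ends."""

    from_end: ScafEnd
    to_end: ScafEnd
    base: BridgeCluster

    @property
    def count(self) -> int:
        return self.base.count

    @property
    def mean_distance(self) -> float:
        return self.base.mean_distance


def lift_clusters(
    clusters: Sequence[BridgeCluster],
    contig_map: dict[str, tuple[int, int, str]],
    scaffolds: list[Scaffold],
) -> list[ScafCluster]:
    out = []
    for c in clusters:
        fe = contig_end_to_scaffold_end(c.from_end, contig_map, scaffolds)
        te = contig_end_to_scaffold_end(c.to_end, contig_map, scaffolds)
        if fe is not None and te is not None:
            out.append(ScafCluster(fe, te, c))
    return out


@dataclass
class Visit:
    scaffold_id: int
    strand: str
    dist_from_prev: float  # cluster-mean distance; 0.0 for the first visit
    read_enter: int  # read coordinate entering this scaffold
    read_exit: int
    mapq: int
    remaining_left: int  # aligned read span from the read's first mapping
    remaining_right: int


@dataclass
class LongRangeConnection:
    read_name: str
    visits: list[Visit]

    def __len__(self) -> int:
        return len(self.visits)


def _entry_side_scaffold(strand: str) -> str:
    return "l" if strand == "+" else "r"


def _exit_side_scaffold(strand: str) -> str:
    return "r" if strand == "+" else "l"


def extract_long_range(
    alns: Sequence[AlignmentRecord],
    contig_map: dict[str, tuple[int, int, str]],
    scaffolds: list[Scaffold],
    accepted: Sequence[ScafCluster],
) -> list[LongRangeConnection]:
    """Per read, the ordered scaffold traversal where every hop is an accepted bridge.

    Consecutive mappings within one scaffold collapse into a single visit;
    hops between scaffolds must match an accepted cluster (ends and distance
    within that cluster's spread), otherwise the traversal is split.  Only
    traversals of >= 3 scaffolds are returned.
    """
    acc: dict[tuple[ScafEnd, ScafEnd], list[ScafCluster]] = {}
    for c in accepted:
        acc.setdefault((c.from_end, c.to_end), []).append(c)
        acc.setdefault((c.to_end, c.from_end), []).append(c)

    def hop_cluster(fe: ScafEnd, te: ScafEnd, dist: float) -> ScafCluster | None:
        best = None
        for c in acc.get((fe, te), ()):  # nearest accepted distance cluster
            tol = max(0.2 * abs(c.mean_distance), 100)
            if abs(dist - c.mean_distance) <= tol:
                if best is None or abs(dist - c.mean_distance) < abs(dist - best.mean_distance):
                    best = c
        return best

    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alns:
        by_read.setdefault(a.read_name, []).append(a)
    connections: list[LongRangeConnection] = []
    for name in sorted(by_read):
        maps = sorted(by_read[name], key=lambda a: (a.read_start, a.read_end))
        first_start = maps[0].read_start
        last_end = maps[-1].read_end
        visits: list[Visit] = []
        prev = None
        for a in maps:
            if a.target_name not in contig_map:
                prev = None
                if len(visits) >= 3:
                    connections.append(LongRangeConnection(name, visits))
                visits = []
                continue
            sid, pos, orient = contig_map[a.target_name]
            strand = "+" if a.strand == orient else "-"
            if (
                visits
                and visits[-1].scaffold_id == sid
                and visits[-1].strand == strand
                and prev is not None
                and prev[0] == sid
                and pos == prev[1] + (1 if strand == "+" else -1)
            ):
                v = visits[-1]
                v.read_exit = a.read_end
                v.remaining_left = a.read_end - first_start
                v.mapq = min(v.mapq, a.mapq)
                prev = (sid, pos)
                continue
            dist = 0.0
            if visits:
                pv = visits[-1]
                fe = (pv.scaffold_id, _exit_side_scaffold(pv.strand))
                te = (sid, _entry_side_scaffold(strand))
                raw = a.read_start - pv.read_exit
                c = hop_cluster(fe, te, raw)
                if c is None:
                    if len(visits) >= 3:
                        connections.append(LongRangeConnection(name, visits))
                    visits = []
                else:
                    dist = c.mean_distance
            visits.append(
                Visit(
                    scaffold_id=sid,
                    strand=strand,
                    dist_from_prev=dist,
                    read_enter=a.read_start,
                    read_exit=a.read_end,
                    mapq=a.mapq,
                    remaining_left=a.read_end - first_start,
                    remaining_right=last_end - a.read_start,
                )
            )
            prev = (sid, pos)
        if len(visits) >= 3:
            connections.append(LongRangeConnection(name, visits))
    return connections


def _window_key(visits: Sequence[Visit]) -> tuple:
    """Orientation-normalized identity of a window of visits.

    The first element carries no incoming distance (it belongs outside the
    window); both traversal directions map to the same key.
    """
    fwd = ((visits[0].scaffold_id, visits[0].strand),) + tuple(
        (v.scaffold_id, v.strand, round(v.dist_from_prev)) for v in visits[1:]
    )
    rev = ((visits[-1].scaffold_id, _flip(visits[-1].strand)),) + tuple(
        (visits[i].scaffold_id, _flip(visits[i].strand), round(visits[i + 1].dist_from_prev))
        for i in range(len(visits) - 2, -1, -1)
    )
    return min(fwd, rev)


def filter_long_range(
    connections: list[LongRangeConnection],
    pval_threshold: float = 0.01,
) -> list[LongRangeConnection]:
    """Filter long-range bridges against alternatives sharing n-1 scaffolds.

    For every window length n (from 3 up), windows sharing all scaffolds but
    one outer one compete.  The minimum-count requirement is lifted; the
    exceedance test runs on the outer-anchor remaining read lengths and a
    window is removed only when it fails on *both* sides.  Connections are
    split at the outer scaffolds of removed windows before n increases.
    Count-expectation comparisons do not apply here: a window of three or
    more scaffolds spans more than any coverage bin, which exempts it.
    """
    n = 3
    while True:
        max_len = max((len(c) for c in connections), default=0)
        if n > max_len:
            break
        # collect windows of length n: (connection idx, start)
        windows: dict[tuple, list[tuple[int, int]]] = {}
        for ci, conn in enumerate(connections):
            for s in range(0, len(conn) - n + 1):
                windows.setdefault(_window_key(conn.visits[s:s + n]), []).append((ci, s))

        def inner_key(key_and_occ, drop_left: bool):
            ci, s = key_and_occ
            vis = connections[ci].visits[s:s + n]
            part = vis[1:] if drop_left else vis[:-1]
            return _window_key(part)

        # group windows by shared inner n-1 scaffolds on each side
        fails: dict[tuple, list[bool]] = {k: [False, False] for k in windows}
        for side_i, drop_left in enumerate((True, False)):
            groups: dict[tuple, list[tuple]] = {}
            for k, occs in windows.items():
                groups.setdefault(inner_key(occs[0], drop_left), []).append(k)
            for gkey in groups:
                members = groups[gkey]
                if len(members) < 2:
                    continue
                # remaining lengths of the outer anchor for each member window
                samples = {}
                for k in members:
                    vals = []
                    for ci, s in windows[k]:
                        vis = connections[ci].visits[s:s + n]
                        outer = vis[0] if drop_left else vis[-1]
                        # a truncated outer mapping has little read aligned on
                        # its own side of the connection
                        vals.append(outer.remaining_left if drop_left else outer.remaining_right)
                    samples[k] = vals
                control = max(members, key=lambda k: max(samples[k]))
                for k in members:
                    if k == control:
                        continue
                    r = sum(1 for v in samples[control] if v > max(samples[k]))
                    p = exceedance_pvalue(len(samples[control]), len(samples[k]), r)
                    if p < pval_threshold:
                        fails[k][side_i] = True
        removed = {k for k, f in fails.items() if f[0] and f[1]}
        if removed:
            new_conns: list[LongRangeConnection] = []
            for ci, conn in enumerate(connections):
                cut_after: set[int] = set()
                for s in range(0, len(conn) - n + 1):
                    if _window_key(conn.visits[s:s + n]) in removed:
                        # split at the outer scaffolds of the removed window
                        cut_after.add(s)          # after left outer
                        cut_after.add(s + n - 2)  # before right outer
                start = 0
                for cut in sorted(cut_after):
                    piece = conn.visits[start:cut + 1]
                    if len(piece) >= 3:
                        new_conns.append(LongRangeConnection(conn.read_name, _rebase(piece)))
                    start = cut + 1
                piece = conn.visits[start:]
                if len(piece) >= 3:
                    new_conns.append(LongRangeConnection(conn.read_name, _rebase(piece)))
            connections = new_conns
        n += 1
    return connections


def _rebase(visits: list[Visit]) -> list[Visit]:
    out = [Visit(**vars(v)) for v in visits]
    if out:
        out[0].dist_from_prev = 0.0
    return out


@dataclass(frozen=True)
class ScaffoldGraphEntry:
    start: ScafEnd
    path: tuple[Step, ...]
    support: int


def build_graph(
    connections: Sequence[LongRangeConnection], pair_clusters: Sequence[ScafCluster]
) -> list[ScaffoldGraphEntry]:
    """All supported directional sub-paths per scaffold side, deduplicated.

    Every scaffold of every connection contributes the paths to both ends of
    the connection; every pairwise cluster contributes length-1 entries in
    both directions.  Paths completely contained within (a prefix of) longer
    paths from the same start are removed; entry support counts the reads
    whose path extends the entry's path.
    """
    raw: dict[ScafEnd, dict[tuple[Step, ...], int]] = {}

    def add(start: ScafEnd, path: tuple[Step, ...], weight: int = 1) -> None:
        raw.setdefault(start, {})
        raw[start][path] = raw[start].get(path, 0) + weight

    for conn in connections:
        vs = conn.visits
        for i, v in enumerate(vs):
            fwd = tuple(
                (w.scaffold_id, w.strand, w.dist_from_prev) for w in vs[i + 1:]
            )
            if fwd:
                add((v.scaffold_id, _exit_side_scaffold(v.strand)), fwd)
            bwd_steps = []
            for j in range(i - 1, -1, -1):
                bwd_steps.append((vs[j].scaffold_id, _flip(vs[j].strand), vs[j + 1].dist_from_prev))
            if bwd_steps:
                add((v.scaffold_id, _entry_side_scaffold(v.strand)), tuple(bwd_steps))
    for c in pair_clusters:
        fs, fside = c.from_end
        ts, tside = c.to_end
        # leaving from_end we enter to_end: strand of target is '+' if entered on 'l'
        add((fs, fside), (((ts, "+" if tside == "l" else "-", c.mean_distance)),) , weight=c.count)
        add((ts, tside), (((fs, "+" if fside == "l" else "-", c.mean_distance)),) , weight=c.count)

    entries: list[ScaffoldGraphEntry] = []
    for start in sorted(raw):
        paths = raw[start]

        def is_prefix(p: tuple, q: tuple) -> bool:
            return len(p) < len(q) and q[: len(p)] == p

        keep = [p for p in paths if not any(is_prefix(p, q) for q in paths)]
        for p in sorted(keep):
            support = sum(w for q, w in paths.items() if q[: len(p)] == p or p[: len(q)] == q)
            entries.append(ScaffoldGraphEntry(start, p, support))
    return entries


def graph_to_gfa(
    entries: Sequence[ScaffoldGraphEntry], scaffold_lengths: dict[int, int]
) -> str:
    """GFA 1 export of the reduced graph: scaffolds as segments, first-step
    adjacencies as links (inspection aid only)."""
    lines = ["H\tVN:Z:1.0"]
    for sid in sorted(scaffold_lengths):
        lines.append(f"S\ts{sid}\t*\tLN:i:{scaffold_lengths[sid]}")
    seen = set()
    for e in entries:
        if not e.path:
            continue
        sid, side = e.start
        nxt, strand, _ = e.path[0]
        a = (f"s{sid}", "+" if side == "r" else "-")
        b = (f"s{nxt}", strand)
        key = min((a, b), ((b[0], _flip(b[1])), (a[0], _flip(a[1]))))
        if key in seen:
            continue
        seen.add(key)
        lines.append(f"L\t{key[0][0]}\t{key[0][1]}\t{key[1][0]}\t{key[1][1]}\t0M")
    return "\n".join(lines) + "\n"


def remove_duplicates_from_graph(
    entries: list[ScaffoldGraphEntry],
    dup_pairs: Sequence[tuple[int, int, str]],
    scaffold_len: dict[int, int] | None = None,
) -> list[ScaffoldGraphEntry]:
    """Remove the weaker member of a duplicated scaffold pair from shared paths.

    ``dup_pairs`` holds (dup_scaffold, template_scaffold, relative strand).
    Where entries through the duplicate mirror entries through the template
    (same start, same path shape after substitution), the member whose
    entries have the lower support is removed from those shared paths.  Ties
    break toward removing the shorter scaffold, then the larger id.
    """
    by_start: dict[ScafEnd, dict[tuple[Step, ...], ScaffoldGraphEntry]] = {}
    for e in entries:
        by_start.setdefault(e.start, {})[e.path] = e
    doomed: set[ScaffoldGraphEntry] = set()
    for dup, template, strand in dup_pairs:
        def subst(path: tuple[Step, ...], a: int, b: int) -> tuple[Step, ...]:
            return tuple(
                (b, s if strand == "+" else _flip(s), d) if sid == a else (sid, s, d)
                for sid, s, d in path
            )

        for e in entries:
            if e in doomed or all(sid != dup for sid, _, _ in e.path):
                continue
            twin_path = subst(e.path, dup, template)
            twin = by_start.get(e.start, {}).get(twin_path)
            if twin is None or twin in doomed:
                continue
            if e.support != twin.support:
                doomed.add(e if e.support < twin.support else twin)
            else:
                if scaffold_len and scaffold_len.get(dup, 0) != scaffold_len.get(template, 0):
                    loser = dup if scaffold_len[dup] < scaffold_len[template] else template
                else:
                    loser = max(dup, template)
                doomed.add(e if loser == dup else twin)
    return [e for e in entries if e not in doomed]
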