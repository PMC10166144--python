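"""Origin-extension pairs: conditioning a scaffold's continuation on its other side.

The scaffold graph lists all supported paths leaving each scaffold side.  An
origin-extension pair selects which continuation (extension) is allowed given
the path observed on the opposite side (origin).  Pairs are filtered at the
branch points where origins diverge: from each branch point, every graph path
consistent with the origin is followed back to the centre, and only
extensions matching the remainder of such a path survive.  Sides with a
single origin are never filtered, which limits the damage of missing
long-range connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .graph import ScaffoldGraphEntry, ScafEnd, Step, _flip

REL_TOL = 0.2
ABS_FLOOR = 100.0


def dist_close(a: float, b: float) -> bool:
    return abs(a - b) <= max(REL_TOL * max(abs(a), abs(b)), ABS_FLOOR)


def steps_match(a: Step, b: Step, check_dist: bool = True) -> bool:
    if a[0] != b[0] or a[1] != b[1]:
        return False
    return dist_close(a[2], b[2]) if check_dist else True


def paths_compatible(p: Sequence[Step], q: Sequence[Step]) -> bool:
    """True if the two paths agree along their common prefix."""
    return all(steps_match(a, b) for a, b in zip(p, q))


@dataclass(frozen=True)
class OriginExtensionPair:
    center: int
    origin: ScaffoldGraphEntry
    extension: ScaffoldGraphEntry

    def __post_init__(self) -> None:
        assert self.origin.start[0] == self.center == self.extension.start[0]
        assert self.origin.start[1] != self.extension.start[1]


def build_pairs(entries: Sequence[ScaffoldGraphEntry]) -> list[OriginExtensionPair]:
    """All ordered pairs of opposite-side entries per centre scaffold."""
    by_side: dict[ScafEnd, list[ScaffoldGraphEntry]] = {}
    for e in entries:
        by_side.setdefault(e.start, []).append(e)
    pairs: list[OriginExtensionPair] = []
    centers = sorted({s for s, _ in by_side})
    for c in centers:
        left = by_side.get((c, "l"), [])
        right = by_side.get((c, "r"), [])
        for o in left:
            for e in right:
                pairs.append(OriginExtensionPair(c, o, e))
                pairs.append(OriginExtensionPair(c, e, o))
    return pairs


def _entry_index(entries: Sequence[ScaffoldGraphEntry]) -> dict[ScafEnd, list[ScaffoldGraphEntry]]:
    idx: dict[ScafEnd, list[ScaffoldGraphEntry]] = {}
    for e in entries:
        idx.setdefault(e.start, []).append(e)
    return idx


def _toward_center_start(step: Step) -> ScafEnd:
    """The side of a traversed scaffold that faces back where we came from."""
    sid, strand, _ = step
    return (sid, "l" if strand == "+" else "r")


def consistent_remainders(
    origin: ScaffoldGraphEntry,
    depth: int,
    entries_idx: dict[ScafEnd, list[ScaffoldGraphEntry]],
) -> list[tuple[Step, ...]]:
    """Follow graph paths from the origin's scaffold at ``depth`` back past the centre.

    Returns the path remainders beyond the centre (possibly empty tuples when
    a consistent path stops at the centre).
    """
    o = origin.path
    start = _toward_center_start(o[depth])
    # the expected back-path: scaffolds depth-1 .. 0, then the centre
    expected: list[tuple[int, str]] = []
    for j in range(depth - 1, -1, -1):
        expected.append((o[j][0], _flip(o[j][1])))
    # walking back into the centre, the centre is traversed opposite to the
    # direction in which the origin left it
    expected.append((origin.start[0], "-" if origin.start[1] == "r" else "+"))
    # distances along the back-path mirror the forward distances
    back_dists = [o[j + 1][2] for j in range(depth - 1, -1, -1)] + [o[0][2]]
    remainders: list[tuple[Step, ...]] = []
    for e in entries_idx.get(start, ()):  # graph paths from the branch point
        ok = True
        for k, (sid, strand) in enumerate(expected):
            if k >= len(e.path):
                ok = False  # stops before reaching the centre
                break
            sid_e, strand_e, dist_e = e.path[k]
            if sid_e != sid or strand_e != strand or not dist_close(dist_e, back_dists[k]):
                ok = False
                break
        if ok:
            remainders.append(e.path[len(expected):])
    return remainders


def _extension_matches(extension: tuple[Step, ...], remainders: list[tuple[Step, ...]]) -> bool:
    return any(paths_compatible(extension, r) for r in remainders)


def filter_pairs(
    pairs: Sequence[OriginExtensionPair], entries: Sequence[ScaffoldGraphEntry]
) -> list[OriginExtensionPair]:
    """Keep pairs whose extension matches a graph path consistent with the origin.

    Branch points are the first diverging positions between origins of the
    same centre side; sides with one origin are never filtered.  A pair
    removed directly but valid with origin and extension swapped is kept.
    """
    idx = _entry_index(entries)
    by_center_side: dict[ScafEnd, list[ScaffoldGraphEntry]] = {}
    for p in pairs:
        group = by_center_side.setdefault(p.origin.start, [])
        if p.origin not in group:
            group.append(p.origin)

    def directly_valid(p: OriginExtensionPair) -> bool:
        origins = by_center_side[p.origin.start]
        if len(origins) == 1:
            return True
        depths: set[int] = set()
        for other in origins:
            if other is p.origin:
                continue
            d = 0
            limit = min(len(p.origin.path), len(other.path))
            while d < limit and steps_match(p.origin.path[d], other.path[d]):
                d += 1
            if d < len(p.origin.path):
                depths.add(d)
        if not depths:
            return True  # origin never diverges from the others within its length
        remainders: list[tuple[Step, ...]] = []
        for d in sorted(depths, reverse=True):  # furthest from the centre first
            remainders.extend(consistent_remainders(p.origin, d, idx))
        if not remainders:
            return True  # no graph path reaches the centre: keep (conservative)
        return _extension_matches(p.extension.path, remainders)

    direct = {p: directly_valid(p) for p in pairs}
    swapped = {(p.center, p.origin, p.extension): p for p in pairs}
    out = []
    for p in pairs:
        if direct[p]:
            out.append(p)
            continue
        rev = swapped.get((p.center, p.extension, p.origin))
        if rev is not None and direct[rev]:
            out.append(p)
    return out


def enforce_consistency(
    pairs: Sequence[OriginExtensionPair], entries: Sequence[ScaffoldGraphEntry]
) -> list[OriginExtensionPair]:
    """Close the pair set: following an extension by one scaffold, the extended
    scaffold's origins through the centre must pair with the remaining
    extension; missing pairs are added (monotone, idempotent)."""
    idx = _entry_index(entries)
    out = list(pairs)
    have = {(p.center, p.origin, p.extension) for p in pairs}
    for p in pairs:
        e1_sid, e1_strand, e1_dist = p.extension.path[0]
        back_start = (e1_sid, "l" if e1_strand == "+" else "r")
        fwd_start = (e1_sid, "r" if e1_strand == "+" else "l")
        center_strand_back = "-" if p.extension.start[1] == "r" else "+"
        for origin2 in idx.get(back_start, ()):  # origins of e1 through the centre
            s0 = origin2.path[0]
            if s0[0] != p.center or s0[1] != center_strand_back or not dist_close(s0[2], e1_dist):
                continue
            rest = p.extension.path[1:]
            if not rest:
                continue
            for ext2 in idx.get(fwd_start, ()):
                if not paths_compatible(ext2.path, rest):
                    continue
                key = (e1_sid, origin2, ext2)
                if key not in have:
                    have.add(key)
                    out.append(OriginExtensionPair(e1_sid, origin2, ext2))
    return out
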