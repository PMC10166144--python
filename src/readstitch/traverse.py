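"""Scaffold-graph traversal: build, merge and combine scaffold paths.

Initial paths follow unique origin-extension pairs; loops (scaffolds repeated
within one read) and inverted repeats get specialised constructors.  The main
loop then alternates merging (stacking alternative haplotypes that share both
ends, up to the ploidy) and combining (joining paths over unique best
overlaps) until convergence, removes contained paths, inserts unambiguously
placeable paths, and finishes with unique extensions and duplicate/circular
trimming.

A single-haplotype path is a tuple of steps ``(scaffold_id, strand,
distance_from_previous)`` with the first distance 0; merged paths align
haplotypes position by position, using ``None`` for a deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .graph import ScaffoldGraphEntry, ScafEnd, Step, _flip
from .pairs import OriginExtensionPair, dist_close, paths_compatible, steps_match

Path = tuple[Step, ...]

MAIN_LOOP_CAP = 20


def reverse_path(p: Path) -> Path:
    out = []
    for i in range(len(p) - 1, -1, -1):
        d = p[i + 1][2] if i + 1 < len(p) else 0.0
        out.append((p[i][0], _flip(p[i][1]), d))
    return tuple(out)


def canonical_path(p: Path) -> Path:
    r = reverse_path(p)
    return min(p, r, key=lambda q: tuple((s, st, round(d)) for s, st, d in q))


def path_sids(p: Path) -> tuple[int, ...]:
    return tuple(s for s, _, _ in p)


@dataclass
class ScaffoldPath:
    """Aligned haplotype alternatives over a shared position axis."""

    positions: list[list[Step | None]]  # inner length == haplotype count
    supports: list[int] = field(default_factory=list)  # per-haplotype order key

    @classmethod
    def from_steps(cls, steps: Path, support: int = 0) -> "ScaffoldPath":
        return cls([[s] for s in steps], [support])

    @property
    def n_haps(self) -> int:
        return len(self.positions[0]) if self.positions else 0

    def hap(self, h: int) -> Path:
        return tuple(s for pos in self.positions for s in (pos[h],) if s is not None)

    @property
    def primary(self) -> Path:
        return self.hap(0)

    def all_sids(self) -> set[int]:
        return {s[0] for pos in self.positions for s in pos if s is not None}

    def __len__(self) -> int:
        return len(self.positions)


SupportFn = Callable[[Path], int]


def _entry_index(entries: Sequence[ScaffoldGraphEntry]) -> dict[ScafEnd, list[ScaffoldGraphEntry]]:
    idx: dict[ScafEnd, list[ScaffoldGraphEntry]] = {}
    for e in entries:
        idx.setdefault(e.start, []).append(e)
    return idx


def _pair_index(
    pairs: Sequence[OriginExtensionPair],
) -> dict[tuple[int, str], list[OriginExtensionPair]]:
    """Pairs indexed by (center, extension side)."""
    idx: dict[tuple[int, str], list[OriginExtensionPair]] = {}
    for p in pairs:
        idx.setdefault((p.center, p.extension.start[1]), []).append(p)
    return idx


# --- initial paths ---------------------------------------------------------


def unique_extension_step(
    center: int, side: str, pair_idx
) -> Step | None:
    """The single first-extension step of a centre side, if all pairs agree."""
    steps = set()
    for p in pair_idx.get((center, side), ()):
        steps.add(p.extension.path[0])
    exact = {(s, st, round(d)) for s, st, d in steps}
    if len(exact) == 1:
        return next(iter(steps))
    return None


def initial_unique_paths(pairs: Sequence[OriginExtensionPair]) -> list[Path]:
    """Chain scaffolds along reciprocally unique origin-extension first steps."""
    pair_idx = _pair_index(pairs)
    centers = sorted({p.center for p in pairs})

    def next_of(center: int, strand: str) -> Step | None:
        # moving "forward" through center with the given strand, the extension
        # leaves via 'r' for '+' and 'l' for '-'
        side = "r" if strand == "+" else "l"
        step = unique_extension_step(center, side, pair_idx)
        if step is None:
            return None
        if strand == "-":
            return step  # steps are already oriented along the traversal
        return step

    def reciprocal(center: int, strand: str, step: Step) -> bool:
        nxt, nst, nd = step
        back_side = "l" if nst == "+" else "r"
        if not pair_idx.get((nxt, back_side)):
            return True  # terminal scaffold: nothing to contradict the link
        back = unique_extension_step(nxt, back_side, pair_idx)
        if back is None:
            return False
        return back[0] == center and back[1] == _flip(strand) and dist_close(back[2], nd)

    links: dict[tuple[int, str], Step] = {}
    for c in centers:
        for strand in ("+", "-"):
            step = next_of(c, strand)
            if step is not None and reciprocal(c, strand, step):
                links[(c, strand)] = step
    # terminal scaffolds have no pairs of their own; mirror the unique link
    # of their neighbour so chains reach the ends
    mirrors: dict[tuple[int, str], set] = {}
    for (c, strand), (nxt, nst, nd) in links.items():
        mirrors.setdefault((nxt, _flip(nst)), set()).add((c, _flip(strand), nd))
    for key, cands in mirrors.items():
        if key not in links and len(cands) == 1:
            links[key] = next(iter(cands))

    paths: list[Path] = []
    seen: set[int] = set()
    for c in centers:
        if c in seen:
            continue
        # walk backward to the chain start
        cur, strand = c, "+"
        visited = {c}
        while True:
            back = links.get((cur, _flip(strand)))
            if back is None or back[0] in visited:
                break
            cur, strand = back[0], _flip(back[1])
            visited.add(cur)
        # walk forward collecting steps
        steps: list[Step] = [(cur, strand, 0.0)]
        visited = {cur}
        while True:
            nxt = links.get((cur, strand))
            if nxt is None or nxt[0] in visited:
                break
            steps.append(nxt)
            cur, strand = nxt[0], nxt[1]
            visited.add(cur)
        if len(steps) > 1:
            paths.append(tuple(steps))
            seen.update(s for s, _, _ in steps)
    return paths


# --- loops -----------------------------------------------------------------


@dataclass
class LoopStructure:
    members: set[int]
    exits: set[int]
    exit_paths: list[Path]  # oriented exit -> into the loop, starting at the exit


def _entry_full(e: ScaffoldGraphEntry) -> Path:
    start_strand = "+" if e.start[1] == "r" else "-"
    return ((e.start[0], start_strand, 0.0),) + e.path


def find_loops(entries: Sequence[ScaffoldGraphEntry]) -> list[LoopStructure]:
    """Loops: scaffolds repeated within one graph path, closed over in-betweens."""
    fulls = [path_sids(_entry_full(e)) for e in entries]
    loops: list[set[int]] = []
    for seq in fulls:
        first: dict[int, int] = {}
        for i, sid in enumerate(seq):
            if sid in first:
                loops.append(set(seq[first[sid]: i + 1]))
            else:
                first[sid] = i
    if not loops:
        return []
    # merge loops sharing a scaffold, then close over in-between scaffolds
    changed = True
    while changed:
        changed = False
        merged: list[set[int]] = []
        for l in loops:
            for m in merged:
                if m & l:
                    m |= l
                    changed = True
                    break
            else:
                merged.append(set(l))
        loops = merged
        for l in loops:
            for seq in fulls:
                inside = [i for i, sid in enumerate(seq) if sid in l]
                if len(inside) >= 2:
                    between = set(seq[inside[0]: inside[-1] + 1])
                    if not between <= l:
                        l |= between
                        changed = True
    out = []
    for members in loops:
        exits: set[int] = set()
        exit_paths: list[Path] = []
        for e in entries:
            if e.start[0] in members:
                for sid, _, _ in e.path:
                    if sid not in members:
                        exits.add(sid)
                        break
        for e in entries:
            if e.start[0] in exits and e.path and e.path[0][0] in members:
                exit_paths.append(_entry_full(e))
        out.append(LoopStructure(members, exits, exit_paths))
    return out


def build_loop_units(
    loop: LoopStructure, entries: Sequence[ScaffoldGraphEntry], max_len: int | None = None
) -> list[Path]:
    """Greedy bidirectional extension of cycles through the loop.

    From every inside scaffold the path is stepped one scaffold at a time,
    following the graph entries anchored deepest in the existing path (the
    greedy choice); on ties all consistent extensions are followed.  A unit is
    accepted only if its reverse is also found when walking the other way.
    """
    idx = _entry_index(entries)
    cap = max_len if max_len is not None else 3 * len(loop.members) + 2

    def walk(start_sid: int, start_strand: str) -> set[Path]:
        done: set[Path] = set()
        stack: list[Path] = [((start_sid, start_strand, 0.0),)]
        while stack:
            p = stack.pop()
            if len(p) > cap:
                continue
            # candidate next steps: entries anchored at the earliest position
            # whose path matches the rest of p and extends beyond it
            best_anchor = None
            nexts: list[Step] = []
            for i in range(len(p)):
                sid, strand, _ = p[i]
                start = (sid, "r" if strand == "+" else "l")
                tail = p[i + 1:]
                for e in idx.get(start, ()):
                    if len(e.path) <= len(tail):
                        continue
                    if not all(steps_match(a, b) for a, b in zip(e.path, tail)):
                        continue
                    if best_anchor is None or i < best_anchor:
                        best_anchor = i
                        nexts = []
                    if i == best_anchor:
                        nexts.append(e.path[len(tail)])
                if best_anchor is not None:
                    break  # earliest anchor found; greedy decision made
            uniq = {(s, st, round(d)): (s, st, d) for s, st, d in nexts}
            for step in uniq.values():
                sid = step[0]
                if sid == start_sid:
                    done.add(p + (step,))
                elif sid in loop.members:
                    stack.append(p + (step,))
                # else: leaves the loop -> discard
        return done

    units: list[Path] = []
    seen: set[Path] = set()
    for sid in sorted(loop.members):
        fwd = walk(sid, "+")
        bwd = walk(sid, "-")
        bwd_keys = {canonical_path(u) for u in bwd}
        for u in sorted(fwd):
            if canonical_path(u) in bwd_keys and canonical_path(u) not in seen:
                seen.add(canonical_path(u))
                units.append(u)
    return units


def _attach(path: Path, piece: Path) -> Path | None:
    """Extension of ``path`` by ``piece`` over their largest end overlap.

    The overlap must match in scaffold, strand and (interior) distances;
    returns the appended steps, or None if the piece does not attach.
    """
    for k in range(min(len(path), len(piece)), 0, -1):
        if any(path[-k + i][0] != piece[i][0] or path[-k + i][1] != piece[i][1]
               for i in range(k)):
            continue
        if all(dist_close(path[len(path) - k + i][2], piece[i][2]) for i in range(1, k)):
            ext = piece[k:]
            if ext:
                return ext
    return None


def traverse_loop(
    loop: LoopStructure,
    units: Sequence[Path],
    entries: Sequence[ScaffoldGraphEntry],
    pairs: Sequence[OriginExtensionPair],
    max_units: int = 6,
) -> list[Path]:
    """Resolve a loop into exit-to-exit paths.

    Bridged loops (an exit path reaching another exit) contribute the read
    path verbatim.  Otherwise, with exactly two unbridged exits, units are
    appended one at a time along connections validated by the combination
    test; connections not selected as best incur a penalty, and the
    minimum-penalty (then shortest) path wins.  Loops with more than two
    unbridged exits stay unresolved (empty result).
    """
    bridged: list[Path] = []
    bridged_exits: set[int] = set()
    for p in loop.exit_paths:
        inner = [i for i, (sid, _, _) in enumerate(p) if sid in loop.exits and i > 0]
        if inner:
            j = inner[0]
            bridged.append(p[: j + 1])
            bridged_exits.add(p[0][0])
            bridged_exits.add(p[j][0])
    unbridged = sorted(loop.exits - bridged_exits)
    if len(unbridged) != 2:
        return bridged
    a_sid, b_sid = unbridged
    starts = [p for p in loop.exit_paths if p[0][0] == a_sid]
    targets = [reverse_path(p) for p in loop.exit_paths if p[0][0] == b_sid]
    if not starts or not targets:
        return bridged
    best: tuple[int, int, Path] | None = None  # (penalty, length, path)
    stack: list[tuple[Path, int, int]] = [(s, 0, 0) for s in sorted(starts)]
    while stack:
        path, penalty, n_units = stack.pop()
        # termination: does a target (reversed exit path of B) attach?
        for t in targets:
            ext = _attach(path, t)
            if ext is not None and can_combine(path, ext, entries, pairs, require_both=False):
                cand = path + ext
                key = (penalty, len(cand), cand)
                if best is None or key < (best[0], best[1], best[2]):
                    best = key
        if n_units >= max_units:
            continue
        exts = []
        for u in units:
            ext = _attach(path, u)
            if ext is not None and can_combine(path, ext, entries, pairs, require_both=False):
                exts.append(ext)
        bests = select_best_connections(path, exts, entries, pairs)
        for ext in exts:
            extra = 0 if ext in bests else 1
            stack.append((path + ext, penalty + extra, n_units + 1))
    out = list(bridged)
    if best is not None:
        out.append(best[2])
    return out


def select_best_connections(
    path: Path,
    extensions: Sequence[Path],
    entries: Sequence[ScaffoldGraphEntry],
    pairs: Sequence[OriginExtensionPair],
) -> list[Path]:
    """Best connections: extensions that also validate in the reverse direction."""
    if len(extensions) <= 1:
        return list(extensions)
    best = [
        e for e in extensions
        if can_combine(path, e, entries, pairs, require_both=True)
    ]
    return best if best else list(extensions)


# --- inverted repeats ------------------------------------------------------


def handle_inverted_repeats(
    entries: Sequence[ScaffoldGraphEntry],
) -> list[Path]:
    """Initial paths through inverted repeats.

    Bridged inverted repeats (a read path covering the scaffold, its reverse
    copy and flanks) are included verbatim.  Unbridged mirror-symmetric
    regions are resolved only when the graph allows exactly two exits and the
    exit of one side does not reappear in the path leaving the other side
    (which would admit a two-haplotype interpretation instead).
    """
    paths: list[Path] = []
    mirrored: set[int] = set()
    for e in entries:
        full = _entry_full(e)
        occ: dict[int, list[int]] = {}
        for i, (sid, strand, _) in enumerate(full):
            occ.setdefault(sid, []).append(i)
        for sid, positions in occ.items():
            if len(positions) < 2:
                continue
            i, j = positions[0], positions[-1]
            if full[i][1] == full[j][1]:
                continue  # same-strand repeat: loop machinery handles it
            mirrored.add(sid)
            if i > 0 and j < len(full) - 1:
                paths.append(full)  # bridged: flanks on both sides
    if not mirrored:
        return []
    # unbridged: find the two exits around the mirrored core
    core = mirrored
    exits: dict[int, Path] = {}
    for e in entries:
        full = _entry_full(e)
        if full[0][0] not in core and len(full) > 1 and full[1][0] in core:
            exits[full[0][0]] = full
    if len(exits) == 2 and not paths:
        (xa, pa), (xb, pb) = sorted(exits.items())
        # filter: exit scaffold of one side present in the path leaving the other
        if xa not in path_sids(pb)[1:] and xb not in path_sids(pa)[1:]:
            rb = reverse_path(pb)
            if pa[-1][0] == rb[0][0]:
                combined = pa + rb[1:]
                paths.append(combined)
    # deduplicate
    uniq: list[Path] = []
    seen = set()
    for p in paths:
        k = canonical_path(p)
        if k not in seen:
            seen.add(k)
            uniq.append(p)
    return uniq


# --- combination test ------------------------------------------------------


def _matching_origins(
    path: Path, entries_idx: dict[ScafEnd, list[ScaffoldGraphEntry]]
) -> list[ScaffoldGraphEntry]:
    """Origins of the path's last scaffold, looking back into the path.

    Origins fully matching the path are preferred; otherwise the ones with
    the longest continuous match from the combining end.
    """
    last = path[-1]
    start = (last[0], "l" if last[1] == "+" else "r")
    back = reverse_path(path)[1:]  # the path seen from its end, excluding the last scaffold
    candidates = entries_idx.get(start, ())
    scored: list[tuple[int, ScaffoldGraphEntry]] = []
    for e in candidates:
        m = 0
        for a, b in zip(e.path, back):
            if steps_match(a, b):
                m += 1
            else:
                break
        full = m == min(len(e.path), len(back))
        scored.append((len(back) + 1 if full and m == len(back) else m, e))
    if not scored:
        return []
    top = max(s for s, _ in scored)
    return [e for s, e in scored if s == top]


def can_combine(
    path_a: Path,
    path_b: Path,
    entries: Sequence[ScaffoldGraphEntry] | dict,
    pairs: Sequence[OriginExtensionPair] | dict,
    require_both: bool = True,
    _depth: int = 0,
) -> bool:
    """Test whether appending ``path_b`` after ``path_a`` violates the graph.

    ``path_b``'s first step must carry the junction distance.  For every
    origin matching ``path_a`` from its combining end, the valid extensions
    are searched for a full-length match with ``path_b``; a first-scaffold
    mismatch in all of them is a rejection, and an undecided prefix match
    recurses one scaffold deeper.  By default both directions must validate.
    """
    if not path_b:
        return True
    entries_idx = entries if isinstance(entries, dict) else _entry_index(entries)
    pair_idx = pairs if isinstance(pairs, dict) else _pair_index(pairs)

    def one_direction(a: Path, b: Path, depth: int) -> bool:
        if not b or depth > len(b) + 2:
            return True
        center = a[-1][0]
        side = "r" if a[-1][1] == "+" else "l"
        origins = _matching_origins(a, entries_idx)
        cpairs = pair_idx.get((center, side), [])
        exts: list[Path] = []
        if origins:
            keys = {(o.start, o.path) for o in origins}
            exts = [
                p.extension.path for p in cpairs
                if (p.origin.start, p.origin.path) in keys
            ]
        if not exts:
            exts = [p.extension.path for p in cpairs]
        if not exts:
            # no information at this junction: fall back to raw graph entries
            exts = [e.path for e in entries_idx.get((center, side), ())]
        if not exts:
            return False
        undecided = False
        for x in exts:
            if not steps_match(x[0], b[0]):
                continue
            if paths_compatible(x, b):
                if len(x) >= len(b):
                    return True
                undecided = True
        if undecided:
            return one_direction(a + b[:1], b[1:], depth + 1)
        return False

    fwd = one_direction(path_a, path_b, 0)
    if not fwd:
        return False
    if not require_both:
        return True
    # reverse direction: B (reversed) extended by A (reversed), junction distance on A's head
    ra = reverse_path(path_a)
    rb = reverse_path(path_b)
    junction = path_b[0][2]
    head = (ra[0][0], ra[0][1], junction)
    return one_direction(rb, (head,) + ra[1:], 0)


# --- merging ---------------------------------------------------------------


def _tokens(p: Path) -> tuple[tuple[int, str], ...]:
    return tuple((s, st) for s, st, _ in p)


def _align_columns(ref: Path, alt: Path) -> list[tuple[int | None, int | None]] | None:
    """Global alignment of two paths on (scaffold, strand) tokens.

    Returns columns of (ref index | None, alt index | None); both end tokens
    must align to each other (paths in one merge group share their ends).
    Mismatched interior tokens align as substitution columns (alternative
    haplotypes); the cost order prefers substitutions, then fewer deletions.
    """
    rt, at = _tokens(ref), _tokens(alt)
    if rt[0] != at[0] or rt[-1] != at[-1]:
        return None
    n, m = len(rt), len(at)
    MATCH, SUB, GAP = 0, 2, 3  # lexicographic cost per column
    INF = 10**9
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    D[n][m] = 0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i < n and j < m:
                step = MATCH if rt[i] == at[j] else SUB
                D[i][j] = min(D[i][j], step + D[i + 1][j + 1])
            if i < n:
                D[i][j] = min(D[i][j], GAP + D[i + 1][j])
            if j < m:
                D[i][j] = min(D[i][j], GAP + D[i][j + 1])
    cols: list[tuple[int | None, int | None]] = []
    i = j = 0
    while i < n or j < m:
        if i < n and j < m and D[i][j] == (MATCH if rt[i] == at[j] else SUB) + D[i + 1][j + 1]:
            cols.append((i, j))
            i += 1
            j += 1
        elif i < n and D[i][j] == GAP + D[i + 1][j]:
            cols.append((i, None))
            i += 1
        else:
            cols.append((None, j))
            j += 1
    if cols[0] != (0, 0) or cols[-1] != (n - 1, m - 1):
        return None
    return cols


def _align_paths(ref: Path, alt: Path) -> list[int | None] | None:
    """Map each position of ``alt`` to a position of ``ref`` (insertions fail)."""
    cols = _align_columns(ref, alt)
    if cols is None:
        return None
    mapping: list[int | None] = [None] * len(alt)
    for ri, aj in cols:
        if aj is not None:
            if ri is None:
                return None  # alt has a scaffold with no ref position
            mapping[aj] = ri
    return mapping


def merge_paths(
    paths: list[ScaffoldPath], ploidy: int = 2, support_fn: SupportFn | None = None
) -> list[ScaffoldPath]:
    """Stack paths sharing both end scaffolds as haplotypes (up to ploidy).

    Reduction order inside a group: exact duplicates, then distance-only
    differences, then pure-deletion paths; groups still above ploidy stay
    separate.  Haplotypes are ordered by the lowest junction support, with
    successive minima as tie-breaks.
    """
    support_fn = support_fn or (lambda p: 0)

    def group_key(sp: ScaffoldPath):
        p = sp.primary
        ends = ((p[0][0], p[0][1]), (p[-1][0], p[-1][1]))
        rends = ((p[-1][0], _flip(p[-1][1])), (p[0][0], _flip(p[0][1])))
        return min(ends, rends)

    def oriented(sp: ScaffoldPath) -> Path:
        p = sp.primary
        ends = ((p[0][0], p[0][1]), (p[-1][0], p[-1][1]))
        rends = ((p[-1][0], _flip(p[-1][1])), (p[0][0], _flip(p[0][1])))
        return p if ends <= rends else reverse_path(p)

    singles = [sp for sp in paths if len(sp.primary) <= 1 or sp.n_haps > 1]
    multi = [sp for sp in paths if len(sp.primary) > 1 and sp.n_haps == 1]
    groups: dict[tuple, list[Path]] = {}
    for sp in multi:
        groups.setdefault(group_key(sp), []).append(oriented(sp))
    out: list[ScaffoldPath] = list(singles)
    for key in sorted(groups):
        alts = groups[key]
        # 1. exact duplicates
        uniq: dict[tuple, Path] = {}
        for p in alts:
            k = tuple((s, st, round(d)) for s, st, d in p)
            uniq.setdefault(k, p)
        alts = list(uniq.values())
        # 2. distance-only differences
        if len(alts) > ploidy:
            bytok: dict[tuple, Path] = {}
            for p in sorted(alts, key=lambda q: -support_fn(q)):
                bytok.setdefault(_tokens(p), p)
            alts = list(bytok.values())
        # 3. pure-deletion paths (token subsequence of another)
        if len(alts) > ploidy:
            def is_subseq(short, long):
                it = iter(long)
                return all(tok in it for tok in short)
            alts = [
                p for p in alts
                if not any(
                    q is not p and len(_tokens(q)) > len(_tokens(p))
                    and is_subseq(_tokens(p), _tokens(q))
                    for q in alts
                )
            ]
        if len(alts) == 1:
            out.append(ScaffoldPath.from_steps(alts[0], support_fn(alts[0])))
            continue
        if len(alts) > ploidy:
            for p in alts:
                out.append(ScaffoldPath.from_steps(p, support_fn(p)))
            continue
        # merge into one multi-haplotype path, aligned pairwise to the best alt
        order = sorted(alts, key=lambda p: (-support_fn(p), -len(p)))
        ref = order[0]
        rows: list[list[Step | None]] = [[s for s in ref]]
        axis: list[int | None] = list(range(len(ref)))  # ref index per column
        ok = True
        for p in order[1:]:
            if any(ri is None for ri in axis):
                ok = False  # stacked insertions from several haplotypes
                break
            cols = _align_columns(ref, p)
            if cols is None:
                ok = False
                break
            # remap existing rows onto the new column axis
            colmap = {ri: k for k, (ri, _) in enumerate(cols) if ri is not None}
            new_rows: list[list[Step | None]] = []
            for row in rows:
                new_row: list[Step | None] = [None] * len(cols)
                for old_k, ri in enumerate(axis):
                    if ri is not None:
                        new_row[colmap[ri]] = row[old_k]
                new_rows.append(new_row)
            prow: list[Step | None] = [None] * len(cols)
            for k, (ri, aj) in enumerate(cols):
                if aj is not None:
                    prow[k] = p[aj]
            new_rows.append(prow)
            rows = new_rows
            axis = [ri for ri, _ in cols]
        if not ok:
            for p in alts:
                out.append(ScaffoldPath.from_steps(p, support_fn(p)))
            continue
        positions = [[row[k] for row in rows] for k in range(len(rows[0]))]
        out.append(ScaffoldPath(positions, [support_fn(p) for p in order]))
    return out


# --- combining -------------------------------------------------------------


def _overlap_len(a: Path, b: Path) -> int:
    """Longest suffix of a equal (tokens + close distances) to a prefix of b."""
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        sa = a[len(a) - k:]
        sb = b[:k]
        if _tokens(sa) != _tokens(sb):
            continue
        if all(dist_close(x[2], y[2]) for x, y in zip(sa[1:], sb[1:])):
            best = k
    return best


def combine_paths(
    paths: list[ScaffoldPath],
    entries: Sequence[ScaffoldGraphEntry],
    pairs: Sequence[OriginExtensionPair],
) -> list[ScaffoldPath]:
    """Join paths over unique best end overlaps, re-validating each join."""
    entries_idx = _entry_index(entries)
    pair_idx = _pair_index(pairs)
    changed = True
    while changed:
        changed = False
        n = len(paths)
        done = False
        for i in range(n):
            if done:
                break
            for j in range(n):
                if i == j or paths[i].n_haps > 1 or paths[j].n_haps > 1:
                    continue
                a, b = paths[i].primary, paths[j].primary
                for bb in (b, reverse_path(b)):
                    k = _overlap_len(a, bb)
                    if k == 0 or k >= len(a) or k >= len(bb):
                        continue
                    tail = bb[k:]
                    if not can_combine(a, tail, entries_idx, pair_idx):
                        continue
                    # uniqueness: no other partner overlaps this end as well
                    rivals = 0
                    for j2 in range(n):
                        if j2 in (i, j) or paths[j2].n_haps > 1:
                            continue
                        c = paths[j2].primary
                        for cc in (c, reverse_path(c)):
                            k2 = _overlap_len(a, cc)
                            if 0 < k2 < len(a) and k2 < len(cc) and can_combine(
                                a, cc[k2:], entries_idx, pair_idx
                            ):
                                rivals += 1
                    if rivals:
                        continue
                    combined = a + tail
                    sup = min(paths[i].supports[0], paths[j].supports[0])
                    new = [p for t, p in enumerate(paths) if t not in (i, j)]
                    new.append(ScaffoldPath.from_steps(combined, sup))
                    paths = new
                    changed = True
                    done = True
                    break
                if done:
                    break
    return paths


def remove_contained(paths: list[ScaffoldPath]) -> list[ScaffoldPath]:
    """Remove paths fully represented (as a contiguous stretch) in another path."""
    def contains(big: Path, small: Path) -> bool:
        bt, st = _tokens(big), _tokens(small)
        if len(st) > len(bt):
            return False
        for off in range(len(bt) - len(st) + 1):
            if bt[off: off + len(st)] == st:
                return True
        return False

    out: list[ScaffoldPath] = []
    for i, sp in enumerate(paths):
        p = sp.primary
        contained = any(
            j != i
            and (contains(q.primary, p) or contains(q.primary, reverse_path(p)))
            and (len(q.primary) > len(p) or (len(q.primary) == len(p) and j < i))
            for j, q in enumerate(paths)
        )
        if not contained:
            out.append(sp)
    return out


def insert_placeable_paths(
    paths: list[ScaffoldPath], ploidy: int = 2
) -> list[ScaffoldPath]:
    """Insert a path as an extra haplotype where its two end scaffolds occur
    in exactly one base path region with a free haplotype."""
    result = list(paths)
    for sp in paths:
        if sp.n_haps > 1 or len(sp.primary) < 2:
            continue
        p = sp.primary
        placements: list[tuple[int, int, int, Path]] = []
        for bi, base in enumerate(result):
            if base is sp or base.n_haps >= ploidy:
                continue
            bp = base.primary
            for cand in (p, reverse_path(p)):
                first, last = cand[0], cand[-1]
                for i in range(len(bp)):
                    if bp[i][0] != first[0] or bp[i][1] != first[1]:
                        continue
                    for j in range(i + 1, len(bp)):
                        if bp[j][0] == last[0] and bp[j][1] == last[1]:
                            if _align_paths(bp[i: j + 1], cand) is not None:
                                placements.append((bi, i, j, cand))
        if len(placements) != 1:
            continue
        bi, i, j, cand = placements[0]
        base = result[bi]
        bp = base.primary
        mapping = _align_paths(bp[i: j + 1], cand)
        positions: list[list[Step | None]] = [list(pos) for pos in base.positions]
        col: list[Step | None] = [None] * len(bp)
        for cj, ci in enumerate(mapping):
            if ci is not None:
                col[i + ci] = cand[cj]
        for t in range(len(bp)):
            positions[t].append(col[t])
        result[bi] = ScaffoldPath(positions, base.supports + sp.supports)
        result.remove(sp)
    return result


def finish_paths(
    paths: list[ScaffoldPath],
    entries: Sequence[ScaffoldGraphEntry],
    pairs: Sequence[OriginExtensionPair],
    duplicated: set[int] | None = None,
) -> list[ScaffoldPath]:
    """Final cleanup: duplicated ends, circular paths, unconnected duplicates."""
    duplicated = duplicated or set()

    # trim duplicated path ends
    def longest_dup_suffix(p: Path, others: list[Path]) -> int:
        st = _tokens(p)
        best = 0
        for q in others:
            for qq in (q, reverse_path(q)):
                qt = _tokens(qq)
                for k in range(1, len(st)):
                    if len(qt) < k:
                        break
                    for off in range(len(qt) - k + 1):
                        if qt[off: off + k] == st[len(st) - k:]:
                            # continuation on the same side (not an overlap)?
                            if off + k < len(qt):
                                best = max(best, k)
        return best

    kept: list[ScaffoldPath] = []
    for i, sp in enumerate(paths):
        if sp.n_haps > 1:
            kept.append(sp)
            continue
        p = sp.primary
        others = [q.primary for j, q in enumerate(paths) if j != i]
        k_right = longest_dup_suffix(p, others)
        k_left = longest_dup_suffix(reverse_path(p), others)
        if k_right + k_left >= len(p) and (k_right or k_left):
            for s in p:  # duplicated ends overlap: disassemble
                kept.append(ScaffoldPath.from_steps(((s[0], s[1], 0.0),), sp.supports[0]))
            continue
        if k_right and k_right < len(p):
            p = p[: len(p) - k_right]
        if k_left and k_left < len(p):
            p = p[k_left:]
            p = ((p[0][0], p[0][1], 0.0),) + p[1:]
        # circular: suffix equal to the path's own prefix
        for k in range(min(len(p) - 1, len(p) // 2), 0, -1):
            if _tokens(p[:k]) == _tokens(p[len(p) - k:]):
                p = p[: len(p) - k]
                break
        kept.append(ScaffoldPath.from_steps(p, sp.supports[0]) if p != sp.primary else sp)
    kept = remove_contained(kept)
    # drop unconnected contigs marked as duplicates
    final = [
        sp for sp in kept
        if not (len(sp.primary) == 1 and sp.primary[0][0] in duplicated)
    ]
    return final


# --- driver ----------------------------------------------------------------


def traverse_graph(
    entries: Sequence[ScaffoldGraphEntry],
    pairs: Sequence[OriginExtensionPair],
    all_scaffolds: Iterable[int],
    ploidy: int = 2,
    support_fn: SupportFn | None = None,
    duplicated: set[int] | None = None,
) -> list[ScaffoldPath]:
    """Full traversal: initial paths, merge/combine to convergence, finish."""
    support_fn = support_fn or (lambda p: 0)
    initial = initial_unique_paths(pairs)
    loops = find_loops(entries)
    loop_paths: list[Path] = []
    loop_members: set[int] = set()
    for loop in loops:
        units = build_loop_units(loop, entries)
        loop_paths.extend(traverse_loop(loop, units, entries, pairs))
        loop_members |= loop.members
    inv_paths = handle_inverted_repeats(entries)
    paths: list[Path] = []
    covered: set[int] = set()
    for p in loop_paths + inv_paths:
        paths.append(p)
        covered |= set(path_sids(p))
    for p in initial:
        if not (set(path_sids(p)) & loop_members):
            paths.append(p)
            covered |= set(path_sids(p))

    def included(two: Path) -> bool:
        toks = _tokens(two)
        rtoks = _tokens(reverse_path(two))
        for q in paths:
            qt = _tokens(q)
            for t in (toks, rtoks):
                for off in range(len(qt) - 1):
                    if qt[off: off + 2] == t:
                        return True
        return False

    # nonunique origin-extension pairs as two-scaffold paths
    for pr in pairs:
        c = pr.center
        strand = "+" if pr.extension.start[1] == "r" else "-"
        step = pr.extension.path[0]
        two = ((c, strand, 0.0), step)
        if not included(two):
            paths.append(two)
            covered |= {c, step[0]}
    for sid in sorted(set(all_scaffolds) - covered):
        paths.append(((sid, "+", 0.0),))

    sps = [ScaffoldPath.from_steps(p, support_fn(p)) for p in paths]

    def main_loop(sps: list[ScaffoldPath]) -> list[ScaffoldPath]:
        for _ in range(MAIN_LOOP_CAP):
            before = sorted(
                tuple((s, st, round(d)) for s, st, d in sp.primary) for sp in sps
            )
            sps = merge_paths(sps, ploidy, support_fn)
            sps = combine_paths(sps, entries, pairs)
            after = sorted(
                tuple((s, st, round(d)) for s, st, d in sp.primary) for sp in sps
            )
            if before == after:
                return sps
        return sps  # iteration cap reached (termination guard)

    sps = main_loop(sps)
    sps = remove_contained(sps)
    sps = main_loop(sps)
    sps = insert_placeable_paths(sps, ploidy)
    sps = main_loop(sps)
    sps = finish_paths(sps, entries, pairs, duplicated)
    return sps
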