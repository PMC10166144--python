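"""Gap filling: align reads to scaffold paths and pick the best read per gap.

A read aligns to a path when its ordered contig mappings follow the path
contig by contig (order, strand, consistent distances) until the read or the
path ends.  Multi-mapping placements are resolved by duplication counts, and
for every junction the spanning read with the best anchor qualities (then the
gap length closest to the cluster mean, then the most matching bases) donates
its sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .paf import AlignmentRecord
from .pairs import dist_close

ContigStep = tuple[str, str]  # (contig name, strand along the path)


@dataclass
class ContigPath:
    """A final scaffold path expanded to contig level."""

    name: str
    steps: list[ContigStep]
    gap_means: list[float]  # len(steps) - 1, mean cluster distance per junction
    original_gaps: list[int | None] | None = None  # N-run length when the
    # junction is an untouched original connection, else None


@dataclass
class JunctionAnchor:
    mapq_low: int
    mapq_high: int
    matches_low: int
    matches_high: int
    read_gap: tuple[int, int]  # read interval spanning the junction
    strand: str  # orientation of the read relative to the path


@dataclass
class PathReadAlignment:
    read_name: str
    path_index: int
    start_pos: int  # first path position covered
    n_pos: int
    orientation: str  # '+' read follows the path forward
    anchors: dict[int, JunctionAnchor]  # junction index -> anchor
    duplication_count: int = 1


def _mappings_follow(
    maps: Sequence[AlignmentRecord], path: ContigPath, start_pos: int, orientation: str
) -> dict[int, JunctionAnchor] | None:
    """Check that the read's mappings walk the path from start_pos; collect anchors."""
    anchors: dict[int, JunctionAnchor] = {}
    step = 1 if orientation == "+" else -1
    pos = start_pos
    for k, a in enumerate(maps):
        if pos < 0 or pos >= len(path.steps):
            return None  # read continues past the path end: allowed, stop
        cname, cstrand = path.steps[pos]
        if a.target_name != cname:
            return None
        rel = "+" if a.strand == cstrand else "-"
        if (rel == "+") != (orientation == "+"):
            return None
        if k + 1 < len(maps):
            b = maps[k + 1]
            gap = b.read_start - a.read_end
            j = pos if orientation == "+" else pos - 1
            if 0 <= j < len(path.gap_means) and dist_close(gap, path.gap_means[j]):
                anchors[j] = JunctionAnchor(
                    mapq_low=min(a.mapq, b.mapq),
                    mapq_high=max(a.mapq, b.mapq),
                    matches_low=min(a.matches, b.matches),
                    matches_high=max(a.matches, b.matches),
                    read_gap=(a.read_end, b.read_start),
                    strand=orientation,
                )
            else:
                return None
        pos += step
    return anchors


def align_reads_to_paths(
    alns: Sequence[AlignmentRecord], paths: Sequence[ContigPath]
) -> list[PathReadAlignment]:
    """Reads whose contig-mapping sequence is consistent with a path.

    The read must map to every contig of the path from where it enters until
    the read or the path ends; reads skipping a contig yield no alignment.
    """
    pos_of: dict[str, list[tuple[int, int]]] = {}
    for pi, p in enumerate(paths):
        for k, (cname, _) in enumerate(p.steps):
            pos_of.setdefault(cname, []).append((pi, k))
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alns:
        by_read.setdefault(a.read_name, []).append(a)
    out: list[PathReadAlignment] = []
    for name in sorted(by_read):
        maps = sorted(by_read[name], key=lambda a: (a.read_start, a.read_end))
        placements: list[PathReadAlignment] = []
        first = maps[0]
        for pi, k in pos_of.get(first.target_name, ()):
            path = paths[pi]
            for orientation in ("+", "-"):
                anchors = _mappings_follow(maps, path, k, orientation)
                if anchors is None:
                    continue
                lo = min(k, k + (len(maps) - 1) * (1 if orientation == "+" else -1))
                placements.append(
                    PathReadAlignment(name, pi, lo, len(maps), orientation, anchors)
                )
        # deduplicate identical placements found via both orientations of a
        # single mapping
        seen = set()
        for pl in placements:
            key = (pl.path_index, pl.start_pos, pl.n_pos)
            if key not in seen:
                seen.add(key)
                out.append(pl)
    return out


def resolve_multimapping(
    alignments: list[PathReadAlignment], paths: Sequence[ContigPath]
) -> list[PathReadAlignment]:
    """Remove multi-mapped placements unless a junction would lose all coverage.

    Per read, a contig's duplication count is how often it occurs among the
    read's valid placements; a placement's count is the lowest over its
    contigs (a count of one means uniquely placed, e.g. via a unique flank
    contig).  Placements with a higher count are removed, except where that
    would leave a junction uncovered, in which case the lowest-count
    placements are kept trimmed to that junction.
    """

    def contigs_of(al: PathReadAlignment) -> list[str]:
        steps = paths[al.path_index].steps
        return [c for c, _ in steps[al.start_pos: al.start_pos + al.n_pos]]

    by_read: dict[str, list[PathReadAlignment]] = {}
    for al in alignments:
        by_read.setdefault(al.read_name, []).append(al)
    kept: list[PathReadAlignment] = []
    removed: list[PathReadAlignment] = []
    for name, als in by_read.items():
        contig_count: dict[str, int] = {}
        for al in als:
            for c in contigs_of(al):
                contig_count[c] = contig_count.get(c, 0) + 1
        for al in als:
            al.duplication_count = min(contig_count[c] for c in contigs_of(al))
        for al in als:
            (kept if al.duplication_count == 1 else removed).append(al)
    # junction coverage check: restore removed placements (trimmed) for
    # junctions no kept placement covers
    covered: set[tuple[int, int]] = set()
    for al in kept:
        covered.update((al.path_index, j) for j in al.anchors)
    removed.sort(key=lambda al: (al.duplication_count, al.read_name))
    for al in removed:
        need = {j for j in al.anchors if (al.path_index, j) not in covered}
        if need:
            al.anchors = {j: al.anchors[j] for j in need}
            covered.update((al.path_index, j) for j in need)
            kept.append(al)
    return kept


@dataclass
class GapFillChoice:
    path_index: int
    junction: int
    read_name: str | None  # None: no spanning read, emit an N gap
    read_gap: tuple[int, int] = (0, 0)
    strand: str = "+"
    gap_length: int = 0


def select_gap_reads(
    alignments: Sequence[PathReadAlignment], paths: Sequence[ContigPath]
) -> list[GapFillChoice]:
    """Per junction, rank spanning reads and pick the best one.

    Ranking: higher low-side mapping quality, then higher high-side quality,
    then gap length closest to the junction mean, then more matching bases
    (low side first).  Full ties resolve to the lexicographically smallest
    read name for reproducibility.
    """
    cands: dict[tuple[int, int], list[tuple]] = {}
    for al in alignments:
        for j, anc in al.anchors.items():
            gap_len = anc.read_gap[1] - anc.read_gap[0]
            mean = paths[al.path_index].gap_means[j]
            key = (
                -anc.mapq_low,
                -anc.mapq_high,
                abs(gap_len - mean),
                -anc.matches_low,
                -anc.matches_high,
                al.read_name,
            )
            cands.setdefault((al.path_index, j), []).append((key, al, anc, gap_len))
    choices: list[GapFillChoice] = []
    for pi, path in enumerate(paths):
        for j in range(len(path.steps) - 1):
            if path.original_gaps and path.original_gaps[j] is not None:
                # untouched original connection: keep the original N gap
                choices.append(
                    GapFillChoice(pi, j, None, gap_length=max(1, path.original_gaps[j]))
                )
                continue
            pool = cands.get((pi, j))
            if not pool:
                choices.append(
                    GapFillChoice(pi, j, None, gap_length=max(1, round(path.gap_means[j])))
                )
                continue
            key, al, anc, gap_len = min(pool)
            choices.append(
                GapFillChoice(pi, j, al.read_name, anc.read_gap, anc.strand, gap_len)
            )
    return choices


def split_uncovered(
    paths: list[ContigPath], alignments: Sequence[PathReadAlignment]
) -> list[ContigPath]:
    """Split paths at junctions no read covers (single-haplotype salvage)."""
    covered: set[tuple[int, int]] = set()
    for al in alignments:
        covered.update((al.path_index, j) for j in al.anchors)
    out: list[ContigPath] = []
    for pi, p in enumerate(paths):
        cut = [
            j for j in range(len(p.steps) - 1)
            if (pi, j) not in covered
            and not (p.original_gaps and p.original_gaps[j] is not None)
        ]
        if not cut:
            out.append(p)
            continue
        start = 0
        piece = 0
        for j in cut + [len(p.steps) - 1]:
            steps = p.steps[start: j + 1]
            if steps:
                out.append(
                    ContigPath(
                        f"{p.name}.{piece}",
                        steps,
                        p.gap_means[start: j],
                        p.original_gaps[start: j] if p.original_gaps else None,
                    )
                )
                piece += 1
            start = j + 1
    return out
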