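"""Detect contigs duplicated by other contigs from the assembly self-alignment.

Near-identical contigs (haplotype duplicates, collapsed repeats emitted
twice) let reads map to either copy, which undermines phasing and blows up
the path combinatorics downstream.  A contig is marked duplicated when an
alignment (or an order/orientation-consistent chain of alignments) from
another contig covers it almost entirely and ends close to both of its ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .paf import AlignmentRecord


@dataclass
class DuplicationMark:
    dup_contig: str
    template_contig: str
    strand: str
    covered_fraction: float
    end_clearance_left: int
    end_clearance_right: int


def _is_self_diagonal(a: AlignmentRecord, tol: int = 10) -> bool:
    return (
        a.read_name == a.target_name
        and abs(a.read_start - a.target_start) <= tol
        and abs(a.read_end - a.target_end) <= tol
        and a.strand == "+"
    )


def detect_duplications(
    self_alns: Sequence[AlignmentRecord],
    min_cov_frac: float = 0.95,
    max_end_dist: int = 2000,
) -> list[DuplicationMark]:
    """Mark contigs covered >= ``min_cov_frac`` by another contig's alignment.

    In the self-alignment PAF the query is the candidate duplicate and the
    target the template.  Multiple partial alignments from one template are
    combined when their order and orientation match (collinear chain).
    """
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for a in self_alns:
        if a.read_name == a.target_name and _is_self_diagonal(a):
            continue
        if a.read_name == a.target_name:
            continue  # a contig is never its own template
        groups.setdefault((a.read_name, a.target_name, a.strand), []).append(a)
    marks: list[DuplicationMark] = []
    for (dup, template, strand) in sorted(groups):
        alns = sorted(groups[(dup, template, strand)], key=lambda a: a.read_start)
        # keep only a collinear chain: target coordinates must advance in the
        # direction implied by the strand as query coordinates advance
        chain: list[AlignmentRecord] = []
        for a in alns:
            if not chain:
                chain.append(a)
                continue
            prev = chain[-1]
            if strand == "+" and a.target_start >= prev.target_start:
                chain.append(a)
            elif strand == "-" and a.target_start <= prev.target_start:
                chain.append(a)
        qlen = chain[0].read_len
        covered = 0
        last_end = 0
        for a in chain:
            s, e = max(a.read_start, last_end), a.read_end
            if e > s:
                covered += e - s
                last_end = e
        frac = covered / qlen
        left = chain[0].read_start
        right = qlen - chain[-1].read_end
        if frac >= min_cov_frac and left <= max_end_dist and right <= max_end_dist:
            marks.append(DuplicationMark(dup, template, strand, frac, left, right))
    return marks
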