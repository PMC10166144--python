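"""Misassembly correction: break contigs where reads consistently diverge.

An alignment that stops inside a contig while both the read and the contig
continue marks a potential break.  Divergences in close vicinity support each
other; alignments mapping continuously over the region veto the break.  The
support-versus-veto decision reuses the bridge-selection machinery (minimum
count plus coverage-probability comparison), accepted positions in a vicinity
are merged, and contigs are broken at the centre of the merged cluster.
Afterwards contig ends without alignments are trimmed and contigs barely
longer than the minimum alignment length are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .coverage import CoverageModel
from .fasta import ContigRecord
from .paf import AlignmentRecord


@dataclass
class BreakCandidate:
    contig: str
    position: int
    support: int
    vetoes: int


@dataclass
class TrimResult:
    contig: str
    new_start: int  # relative to the contig
    new_end: int
    dropped: bool


def _divergence_positions(
    a: AlignmentRecord, min_clearance: int
) -> list[int]:
    """Contig positions where this alignment stops while read and contig continue."""
    out = []
    # clearance on the read side beyond the mapped interval, oriented to the contig
    right_read = (a.read_len - a.read_end) if a.strand == "+" else a.read_start
    left_read = a.read_start if a.strand == "+" else (a.read_len - a.read_end)
    if a.target_end <= a.target_len - min_clearance and right_read >= min_clearance:
        out.append(a.target_end)
    if a.target_start >= min_clearance and left_read >= min_clearance:
        out.append(a.target_start)
    return out


def collect_break_candidates(
    alns: Sequence[AlignmentRecord],
    vicinity: int = 100,
    min_clearance: int = 200,
) -> list[BreakCandidate]:
    """One candidate per diverging alignment, with windowed support and vetoes.

    Support counts all divergences (including the candidate itself) within
    +/- ``vicinity``; vetoes count alignments spanning the whole window.
    """
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for a in alns:
        by_contig.setdefault(a.target_name, []).append(a)
    cands: list[BreakCandidate] = []
    for contig in sorted(by_contig):
        group = by_contig[contig]
        positions: list[int] = []
        for a in group:
            positions.extend(_divergence_positions(a, min_clearance))
        positions.sort()
        for p in positions:
            support = sum(1 for q in positions if abs(q - p) <= vicinity)
            vetoes = sum(
                1 for a in group if a.target_start <= p - vicinity and a.target_end >= p + vicinity
            )
            cands.append(BreakCandidate(contig, p, support, vetoes))
    return cands


def decide_breaks(
    cands: Sequence[BreakCandidate],
    model: CoverageModel | None,
    min_count: int = 3,
    prob_factor: float = 10.0,
    vicinity: int = 100,
) -> dict[str, list[int]]:
    """Accept breaks per the bridge rules; merge nearby accepts to their centre.

    A candidate passes when its support reaches the minimum count and the
    vetoes do not have a many-times-higher coverage probability.  Both counts
    are judged with the smallest-bin coverage fit (break regions are points,
    not gaps).  Without a model, vetoes are compared to support directly.
    """
    accepted: dict[str, list[int]] = {}
    for c in cands:
        if c.support < min_count:
            continue
        if c.vetoes > 0:
            if model is not None and model.fits:
                f = model.fits[0]
                if f.cdf(c.vetoes) >= prob_factor * f.cdf(c.support):
                    continue
            elif c.vetoes >= prob_factor * c.support:
                continue
        accepted.setdefault(c.contig, []).append(c.position)
    breaks: dict[str, list[int]] = {}
    for contig, positions in accepted.items():
        positions.sort()
        merged: list[int] = []
        run = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] <= vicinity:
                run.append(p)
            else:
                merged.append((run[0] + run[-1]) // 2)
                run = [p]
        merged.append((run[0] + run[-1]) // 2)
        breaks[contig] = merged
    return breaks


def remove_unaccepted_divergent(
    alns: Sequence[AlignmentRecord],
    breaks: dict[str, list[int]],
    vicinity: int = 100,
    min_clearance: int = 200,
) -> list[AlignmentRecord]:
    """Drop alignments that diverge inside a contig at an unaccepted position.

    Divergent mappings whose break was vetoed most likely stem from a
    different repeat copy or a chimeric read; keeping them would create false
    bridges.
    """
    out: list[AlignmentRecord] = []
    for a in alns:
        bad = False
        for p in _divergence_positions(a, min_clearance):
            if not any(abs(p - q) <= vicinity for q in breaks.get(a.target_name, ())):
                bad = True
                break
        if not bad:
            out.append(a)
    return out


def apply_breaks(
    contigs: Sequence[ContigRecord], breaks: dict[str, list[int]]
) -> list[ContigRecord]:
    """Split contigs at accepted positions; broken joins carry no original gap."""
    out: list[ContigRecord] = []
    cid = 0
    for c in contigs:
        positions = sorted(breaks.get(c.name, []))
        positions = [p for p in positions if 0 < p < c.length]
        if not positions:
            out.append(replace(c, contig_id=cid))
            cid += 1
            continue
        bounds = [0] + positions + [c.length]
        for k, (s, e) in enumerate(zip(bounds, bounds[1:])):
            last = k == len(bounds) - 2
            out.append(
                ContigRecord(
                    contig_id=cid,
                    name=f"{c.name}.{k}",
                    scaffold_name=c.scaffold_name,
                    start=c.start + s,
                    end=c.start + e,
                    # a broken join is a detected misassembly: no gap is kept
                    gap_after_len=c.gap_after_len if last else None,
                    leading_gap_len=c.leading_gap_len if k == 0 else 0,
                )
            )
            cid += 1
    return out


def trim_and_drop(
    contigs: Sequence[ContigRecord],
    alns: Sequence[AlignmentRecord],
    min_aln_len: int = 500,
    drop_slack: float = 1.2,
) -> list[TrimResult]:
    """Trim unaligned contig ends; drop contigs barely longer than min_aln_len.

    Contigs with no alignments at all are dropped.  The retention threshold
    ``drop_slack * min_aln_len`` avoids the on/off boundary where a handful of
    bases decides whether a read can have an accepted alignment.
    """
    cover: dict[str, tuple[int, int]] = {}
    for a in alns:
        lo, hi = cover.get(a.target_name, (a.target_start, a.target_end))
        cover[a.target_name] = (min(lo, a.target_start), max(hi, a.target_end))
    results: list[TrimResult] = []
    for c in contigs:
        if c.name not in cover:
            results.append(TrimResult(c.name, 0, 0, dropped=True))
            continue
        lo, hi = cover[c.name]
        lo, hi = max(0, lo), min(c.length, hi)
        dropped = (hi - lo) <= drop_slack * min_aln_len
        results.append(TrimResult(c.name, lo, hi, dropped))
    return results
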