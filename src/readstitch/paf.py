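"""PAF alignment parsing and mapping-level prefilters.

All coordinates are 0-based half-open, PAF convention.  Secondary alignments
(``tp:A:S``) are excluded at parse time; supplementary (split) alignments are
kept as separate records because end-spanning split mappings are the
scaffolding signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass
class AlignmentRecord:
    """One read-to-contig (or contig-to-contig) mapping in PAF semantics."""

    read_name: str
    read_len: int
    read_start: int
    read_end: int
    strand: str  # '+' or '-'
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise ValueError(f"bad read interval for {self.read_name}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(f"bad target interval for {self.read_name} on {self.target_name}")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


def parse_paf_line(line: str, lineno: int = 0) -> AlignmentRecord | None:
    """Parse one PAF line; returns None for excluded secondary alignments."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"PAF line {lineno}: expected >= 12 columns, got {len(fields)}")
    for tag in fields[12:]:
        if tag == "tp:A:S":
            return None
    try:
        return AlignmentRecord(
            read_name=fields[0],
            read_len=int(fields[1]),
            read_start=int(fields[2]),
            read_end=int(fields[3]),
            strand=fields[4],
            target_name=fields[5],
            target_len=int(fields[6]),
            target_start=int(fields[7]),
            target_end=int(fields[8]),
            matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
        )
    except ValueError as exc:
        raise ValueError(f"PAF line {lineno}: {exc}") from exc


def load_paf(path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = parse_paf_line(line, lineno)
            if rec is not None:
                records.append(rec)
    return records


def write_paf(path, records: Iterable[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_name, r.read_len, r.read_start, r.read_end, r.strand,
                        r.target_name, r.target_len, r.target_start, r.target_end,
                        r.matches, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


def prefilter_alignments(
    alns: Sequence[AlignmentRecord], min_mapq: int = 20, min_aln_len: int = 500
) -> list[AlignmentRecord]:
    """Keep records with mapq >= min_mapq and read span >= min_aln_len (order preserved)."""
    if min_mapq < 0 or min_aln_len < 0:
        raise ValueError("thresholds must be >= 0")
    return [a for a in alns if a.mapq >= min_mapq and a.read_span >= min_aln_len]


def _zmw_key(name: str) -> str | None:
    parts = name.split("/")
    if len(parts) >= 2 and parts[1]:
        return "/".join(parts[:2])
    return None


def dedup_subreads(alns: Sequence[AlignmentRecord], read_type: str = "CLR") -> list[AlignmentRecord]:
    """For PacBio CLR, keep the alignments of only one subread per ZMW.

    A DNA fragment sequenced repeatedly yields several subreads named
    ``movie/zmw/start_end``; keeping them all would give the fragment undue
    weight.  The representative is the subread with the greatest total aligned
    bases (ties broken by lexicographic name).  CCS and Nanopore reads pass
    through unchanged.
    """
    if read_type != "CLR":
        return list(alns)
    total: dict[str, int] = {}
    zmw_of: dict[str, str] = {}
    warned = False
    for a in alns:
        key = _zmw_key(a.read_name)
        if key is None:
            if not warned:
                warnings.warn("CLR read name without ZMW field; treating whole name as key")
                warned = True
            key = a.read_name
        zmw_of[a.read_name] = key
        total[a.read_name] = total.get(a.read_name, 0) + a.read_span
    best: dict[str, str] = {}
    for name in sorted(total):
        key = zmw_of[name]
        if key not in best or total[name] > total[best[key]]:
            best[key] = name
    keep = set(best.values())
    return [a for a in alns if a.read_name in keep]
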