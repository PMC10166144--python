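"""Assembly input/output: FASTA handling, scaffold splitting, change application.

A draft assembly arrives as scaffolds whose gaps are encoded as runs of ``N``.
The first pipeline stage splits every scaffold into gap-free contigs while
remembering where it came from; the last stage applies an ordered list of
changes (kept contig segments, read-derived gap fills, explicit gaps, drops)
to emit the improved assembly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered name → sequence dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class ContigRecord:
    """A gap-free piece of a scaffold, with provenance in its parent.

    ``gap_after_len`` is the length of the N-run following this contig in the
    parent scaffold (``None`` when nothing follows).  ``leading_gap_len`` is
    only set on the first contig of a scaffold that begins with an N-run, so
    the identity change list can reproduce the input byte-identically.
    """

    contig_id: int
    name: str
    scaffold_name: str
    start: int
    end: int
    gap_after_len: int | None = None
    leading_gap_len: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, assembly: Mapping[str, str]) -> str:
        return assembly[self.scaffold_name][self.start:self.end]


_N_RUN = re.compile(r"[Nn]+")


def split_assembly(assembly: Mapping[str, str], min_n_run: int = 1) -> list[ContigRecord]:
    """Split every scaffold into contigs at N-runs of length >= ``min_n_run``.

    Shorter N-runs are retained inside contigs.  Scaffolds that are all N
    yield no contigs.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    contigs: list[ContigRecord] = []
    cid = 0
    for name, seq in assembly.items():
        if not seq:
            raise ValueError(f"scaffold {name!r} has empty sequence")
        cuts = [m.span() for m in _N_RUN.finditer(seq) if m.end() - m.start() >= min_n_run]
        pos = 0
        pieces: list[tuple[int, int, int | None]] = []  # start, end, gap_after
        for gs, ge in cuts:
            if gs > pos:
                pieces.append((pos, gs, ge - gs))
            pos = ge
        if pos < len(seq):
            pieces.append((pos, len(seq), None))
        if not pieces:
            continue  # scaffold is all N
        # a leading N-run is recorded on the first contig; a trailing run ends
        # up as the gap_after_len of the last contig via the loop above
        leading = pieces[0][0]
        k = 0
        for start, end, gap_after in pieces:
            contigs.append(
                ContigRecord(
                    contig_id=cid,
                    name=f"{name}_chunk{k}",
                    scaffold_name=name,
                    start=start,
                    end=end,
                    gap_after_len=gap_after,
                    leading_gap_len=leading if k == 0 else 0,
                )
            )
            cid += 1
            k += 1
    return contigs


# --- change list -----------------------------------------------------------


@dataclass
class Keep:
    contig_id: int
    strand: str = "+"
    trim_left: int = 0
    trim_right: int = 0


@dataclass
class Fill:
    read_name: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class Gap:
    length: int


@dataclass
class Break:
    contig_id: int
    position: int


@dataclass
class Drop:
    contig_id: int


ChangeRecord = Keep | Fill | Gap


@dataclass
class ChangeList:
    """Ordered output-scaffold groups plus break/drop bookkeeping records."""

    scaffolds: list[tuple[str, list[ChangeRecord]]] = field(default_factory=list)
    breaks: list[Break] = field(default_factory=list)
    drops: list[Drop] = field(default_factory=list)

    def add_scaffold(self, name: str, records: list[ChangeRecord]) -> None:
        self.scaffolds.append((name, records))


def identity_changes(contigs: Iterable[ContigRecord]) -> ChangeList:
    """A ChangeList reproducing the original assembly verbatim."""
    changes = ChangeList()
    by_scaffold: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        by_scaffold.setdefault(c.scaffold_name, []).append(c)
    for name, cs in by_scaffold.items():
        records: list[ChangeRecord] = []
        cs = sorted(cs, key=lambda c: c.start)
        if cs[0].leading_gap_len:
            records.append(Gap(cs[0].leading_gap_len))
        for c in cs:
            records.append(Keep(c.contig_id))
            if c.gap_after_len is not None:
                records.append(Gap(c.gap_after_len))
        changes.add_scaffold(name, records)
    return changes


ReadAccessor = Mapping[str, str] | Callable[[str], str]


def _get_read(reads: ReadAccessor, name: str) -> str:
    if callable(reads):
        return reads(name)
    try:
        return reads[name]
    except KeyError:
        raise KeyError(name)


def apply_changes(
    assembly: Mapping[str, str],
    contigs: Iterable[ContigRecord],
    changes: ChangeList,
    reads: ReadAccessor | None = None,
) -> dict[str, str]:
    """Apply a ChangeList, producing the improved assembly.

    KEEP segments pass through byte-identical (case preserved, optionally
    reverse-complemented and trimmed); FILL sequences come from the read
    accessor and are emitted upper-case; GAP records become N-runs.
    """
    by_id = {c.contig_id: c for c in contigs}
    out: dict[str, str] = {}
    for name, records in changes.scaffolds:
        parts: list[str] = []
        for rec in records:
            if isinstance(rec, Keep):
                c = by_id[rec.contig_id]
                if rec.trim_left < 0 or rec.trim_right < 0 or rec.trim_left + rec.trim_right > c.length:
                    raise ValueError(f"trims out of bounds for contig {c.name}")
                seg = c.sequence(assembly)
                seg = seg[rec.trim_left: c.length - rec.trim_right]
                if rec.strand == "-":
                    seg = reverse_complement(seg)
                parts.append(seg)
            elif isinstance(rec, Fill):
                if reads is None:
                    raise ValueError(f"FILL from read {rec.read_name!r} but no read accessor given")
                try:
                    seq = _get_read(reads, rec.read_name)
                except KeyError:
                    raise ValueError(
                        f"gap fill in scaffold {name!r}: read {rec.read_name!r} not resolvable"
                    )
                seg = seq[rec.start: rec.end]
                if rec.strand == "-":
                    seg = reverse_complement(seg)
                parts.append(seg.upper())
            elif isinstance(rec, Gap):
                parts.append("N" * rec.length)
            else:  # pragma: no cover - defensive
                raise TypeError(f"unknown change record {rec!r}")
        out[name] = "".join(parts)
    return out


# --- serialization ---------------------------------------------------------


def changes_to_tsv(changes: ChangeList, contigs: Iterable[ContigRecord]) -> str:
    """One record per line: out_scaffold, record_type, contig_or_read, strand, start, end, extra."""
    by_id = {c.contig_id: c for c in contigs}
    lines = ["#out_scaffold\trecord_type\tcontig_or_read\tstrand\tstart\tend\textra"]
    for name, records in changes.scaffolds:
        for rec in records:
            if isinstance(rec, Keep):
                c = by_id[rec.contig_id]
                lines.append(
                    f"{name}\tKEEP\t{c.name}\t{rec.strand}\t{rec.trim_left}\t{rec.trim_right}\t"
                )
            elif isinstance(rec, Fill):
                lines.append(f"{name}\tFILL\t{rec.read_name}\t{rec.strand}\t{rec.start}\t{rec.end}\t")
            elif isinstance(rec, Gap):
                lines.append(f"{name}\tGAP\t-\t+\t0\t{rec.length}\t")
    for b in changes.breaks:
        c = by_id.get(b.contig_id)
        cname = c.name if c else str(b.contig_id)
        lines.append(f"-\tBREAK\t{cname}\t+\t{b.position}\t{b.position}\t")
    for d in changes.drops:
        c = by_id.get(d.contig_id)
        cname = c.name if c else str(d.contig_id)
        lines.append(f"-\tDROP\t{cname}\t+\t0\t0\t")
    return "\n".join(lines) + "\n"


def changes_from_tsv(text: str, contigs: Iterable[ContigRecord]) -> ChangeList:
    """Parse the TSV produced by :func:`changes_to_tsv` back into a ChangeList."""
    by_name = {c.name: c for c in contigs}
    changes = ChangeList()
    groups: dict[str, list[ChangeRecord]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"changes TSV line {lineno}: expected >= 6 columns")
        scaf, typ, ref, strand, a, b = fields[:6]
        if typ == "KEEP":
            if ref not in by_name:
                raise ValueError(f"changes TSV line {lineno}: unknown contig {ref!r}")
            rec: ChangeRecord = Keep(by_name[ref].contig_id, strand, int(a), int(b))
        elif typ == "FILL":
            rec = Fill(ref, int(a), int(b), strand)
        elif typ == "GAP":
            rec = Gap(int(b))
        elif typ == "BREAK":
            changes.breaks.append(Break(by_name[ref].contig_id if ref in by_name else -1, int(a)))
            continue
        elif typ == "DROP":
            changes.drops.append(Drop(by_name[ref].contig_id if ref in by_name else -1))
            continue
        else:
            raise ValueError(f"changes TSV line {lineno}: unknown record type {typ!r}")
        if scaf not in groups:
            groups[scaf] = []
            order.append(scaf)
        groups[scaf].append(rec)
    for scaf in order:
        changes.add_scaffold(scaf, groups[scaf])
    return changes


def changes_to_agp(changes: ChangeList, contigs: Iterable[ContigRecord]) -> str:
    """AGP 2.1 export for KEEP/GAP-only output scaffolds (FILL paths are skipped)."""
    by_id = {c.contig_id: c for c in contigs}
    lines = ["##agp-version 2.1"]
    for name, records in changes.scaffolds:
        if any(isinstance(r, Fill) for r in records):
            continue
        pos = 0
        part = 1
        for rec in records:
            if isinstance(rec, Keep):
                c = by_id[rec.contig_id]
                ln = c.length - rec.trim_left - rec.trim_right
                lines.append(
                    "\t".join(
                        [name, str(pos + 1), str(pos + ln), str(part), "W", c.name,
                         str(rec.trim_left + 1), str(c.length - rec.trim_right), rec.strand]
                    )
                )
                pos += ln
            elif isinstance(rec, Gap):
                if rec.length == 0:
                    continue
                lines.append(
                    "\t".join(
                        [name, str(pos + 1), str(pos + rec.length), str(part), "N",
                         str(rec.length), "scaffold", "yes", "align_genus"]
                    )
                )
                pos += rec.length
            part += 1
    return "\n".join(lines) + "\n"
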