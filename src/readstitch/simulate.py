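"""Synthetic test worlds: genome, defective draft, reads, and exact PAF.

The generator emulates the pipeline's inputs end to end: a toy (optionally
diploid) genome, a fragmented draft whose gaps are N-runs of deliberately
inaccurate length, injected misassemblies (chimeric joins), collapsed and
diverged repeats, duplicated haplotype contigs, and long reads with known
placements.  PAF records are computed exactly from those placements - never
by running a mapper - so every downstream stage can be tested against the
recorded truth.

The error model is i.i.d. substitutions: read coordinates stay exact while
matching-base counts drop, which is what the count- and length-based filters
consume.  A diverged repeat embedded at the start of two contigs optionally
mis-assigns a fraction of the reads that end inside the repeat to the other
copy; their alignments are truncated at the read end inside the repeat,
which is the wrong-repeat-copy signal the exceedance filter exists for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fasta import ContigRecord, reverse_complement, split_assembly
from .paf import AlignmentRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class RepeatSpec:
    copies: int = 2
    length: int = 6000
    divergence: float = 0.01
    wrong_map_rate: float = 0.25  # fraction of repeat-ending reads mis-assigned
    flank: int = 6000  # unique sequence following the repeat within its contig


@dataclass
class FixtureSpec:
    seed: int = 42
    genome_length: int = 200_000
    ploidy: int = 1
    heterozygosity: float = 0.0
    repeat: RepeatSpec | None = None
    collapsed_repeat: bool = False  # one contig, two genome loci (loop preset)
    inverted_repeat: bool = False  # second locus on the reverse strand
    n_gaps: int = 10
    gap_len_range: tuple[int, int] = (100, 800)
    n_scaffold_splits: int = 2
    n_misassemblies: int = 0
    n_duplicated_contigs: int = 0
    read_median: int = 12_000
    read_sigma: float = 0.4
    read_min: int = 1_000
    coverage: float = 30.0
    error_rate: float = 0.0
    chimeric_read_rate: float = 0.0
    min_emit: int = 300  # smallest read/contig overlap that yields a PAF record

    def validate(self) -> None:
        for name in ("heterozygosity", "error_rate", "chimeric_read_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.repeat is not None:
            need = self.repeat.copies * (self.repeat.length + self.repeat.flank)
            if need > self.genome_length // 2:
                raise ValueError("repeat specification does not fit the genome")
        if self.n_gaps * self.gap_len_range[1] > self.genome_length // 2:
            raise ValueError("gaps do not fit the genome")


@dataclass
class TrueContig:
    name: str  # split-assembly contig name
    length: int
    loci: list[tuple[int, str]]  # (genome start, strand); 2 loci = collapsed repeat
    segments: list[tuple[int, int]] | None = None  # chimera: ordered genome intervals
    repeat_group: int | None = None  # diverged-copy group; repeat sits at contig start
    repeat_len: int = 0
    dup_of: str | None = None


@dataclass
class TruthSet:
    contigs: list[TrueContig]
    junctions: list[tuple[str, str, str, str, int]]  # (nameA, sideA, nameB, sideB, dist)
    gap_junctions: list[int]  # junction indices that were N-gaps in the draft
    break_positions: list[tuple[str, int]]  # (contig name, position in contig)
    read_placements: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    chimeric_reads: set[str] = field(default_factory=set)


@dataclass
class World:
    spec: FixtureSpec
    genome: dict[str, str]
    assembly: dict[str, str]  # the draft, with N gaps
    contigs: list[ContigRecord]
    reads: dict[str, str]
    paf: list[AlignmentRecord]
    self_paf: list[AlignmentRecord]
    truth: TruthSet


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, np.ndarray]:
    """Substitute bases i.i.d. at ``rate``; returns new sequence and positions."""
    if rate <= 0:
        return seq, np.empty(0, dtype=int)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = rng.binomial(len(seq), rate)
    pos = np.sort(rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False))
    for p in pos:
        arr[p] = rng.choice(BASES[BASES != arr[p]])
    return arr.tobytes().decode(), pos


def generate_world(spec: FixtureSpec) -> World:
    """Build a deterministic world from the fixture specification."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_junctions = spec.n_gaps + spec.n_scaffold_splits
    n_contigs = n_junctions + 1
    gap_lens = rng.integers(spec.gap_len_range[0], spec.gap_len_range[1] + 1, n_junctions)
    budget = spec.genome_length - int(gap_lens.sum())
    min_contig = max(4000, budget // (4 * n_contigs))
    weights = rng.dirichlet(np.full(n_contigs, 3.0))
    contig_lens = np.maximum((weights * budget).astype(int), min_contig)

    repeat_members: list[int] = []
    if spec.repeat is not None:
        idxs = np.linspace(1, n_contigs - 2, spec.repeat.copies).astype(int)
        repeat_members = sorted(dict.fromkeys(int(i) for i in idxs))
        for i in repeat_members:
            contig_lens[i] = spec.repeat.length + spec.repeat.flank

    collapsed_idx = collapsed_second = None
    if spec.collapsed_repeat:
        collapsed_idx = max(1, n_contigs // 3)
        collapsed_second = min(n_contigs - 2, 2 * n_contigs // 3)
        if collapsed_second <= collapsed_idx + 1:
            collapsed_second = collapsed_idx + 2
        contig_lens[collapsed_second] = contig_lens[collapsed_idx]

    # genome, left to right
    repeat_seq: str | None = None
    collapsed_seq: str | None = None
    parts: list[str] = []
    starts: list[int] = []
    pos = 0
    for i in range(n_contigs):
        ln = int(contig_lens[i])
        if i in repeat_members:
            if repeat_seq is None:
                repeat_seq = _random_seq(rng, spec.repeat.length)
                core = repeat_seq
            else:
                core, _ = _mutate(rng, repeat_seq, spec.repeat.divergence)
            seq = core + _random_seq(rng, ln - len(core))
        elif i == collapsed_idx:
            collapsed_seq = _random_seq(rng, ln)
            seq = collapsed_seq
        elif i == collapsed_second:
            seq = reverse_complement(collapsed_seq) if spec.inverted_repeat else collapsed_seq
        else:
            seq = _random_seq(rng, ln)
        starts.append(pos)
        parts.append(seq)
        pos += ln
        if i < n_junctions:
            parts.append(_random_seq(rng, int(gap_lens[i])))
            pos += int(gap_lens[i])
    genome0 = "".join(parts)
    genome: dict[str, str] = {"hap0": genome0}
    if spec.ploidy == 2 and spec.heterozygosity > 0:
        genome["hap1"] = _mutate(rng, genome0, spec.heterozygosity)[0]

    split_at = set(
        rng.choice(n_junctions, size=min(spec.n_scaffold_splits, n_junctions), replace=False).tolist()
    ) if spec.n_scaffold_splits else set()
    if collapsed_second is not None:
        # the draft collapses the second repeat locus; split the scaffold
        # around it instead of fabricating a false N-join
        split_at |= {collapsed_second - 1, collapsed_second}
    # draw draft N-run lengths for every junction up front so downstream
    # structure edits (chimeras, removed contigs) cannot shift the rng stream
    noisy_gap = [
        max(1, int(round(int(gap_lens[i]) * rng.uniform(0.6, 1.4))))
        for i in range(n_junctions)
    ]

    # contig bookkeeping, pre-chimera
    raw: list[dict] = []
    for i in range(n_contigs):
        if i == collapsed_second:
            continue  # same contig as collapsed_idx
        loci = [(starts[i], "+")]
        if i == collapsed_idx:
            loci.append((starts[collapsed_second], "-" if spec.inverted_repeat else "+"))
        raw.append(
            dict(
                index=i, length=int(contig_lens[i]), loci=loci,
                segments=[(starts[i], starts[i] + int(contig_lens[i]))],
                repeat_group=0 if i in repeat_members else None,
            )
        )

    # misassemblies: cross-join the halves of two distant contigs
    break_at: dict[int, int] = {}  # original contig index -> break position
    eligible = [
        k for k, c in enumerate(raw)
        if c["repeat_group"] is None and len(c["loci"]) == 1 and c["length"] >= 10_000
    ]
    displaced_pieces: list[dict] = []
    for _ in range(spec.n_misassemblies):
        if len(eligible) < 2:
            break
        ka, kb = eligible.pop(0), eligible.pop()
        a, b = raw[ka], raw[kb]
        cut_a, cut_b = a["length"] // 2, b["length"] // 2
        (sa0, sa1), (sb0, sb1) = a["segments"][0], b["segments"][0]
        raw[ka] = dict(
            index=a["index"], length=cut_a + (sb1 - sb0 - cut_b), loci=None,
            segments=[(sa0, sa0 + cut_a), (sb0 + cut_b, sb1)], repeat_group=None,
        )
        break_at[a["index"]] = cut_a
        raw[kb] = dict(index=b["index"], removed=True)
        for s0, s1 in ((sa0 + cut_a, sa1), (sb0, sb0 + cut_b)):
            displaced_pieces.append(
                dict(index=None, length=s1 - s0, loci=[(s0, "+")],
                     segments=[(s0, s1)], repeat_group=None)
            )

    # draft scaffolds in genome order; displaced pieces become own scaffolds
    scaffolds: list[list[dict]] = [[]]
    n_lens: list[list[int]] = [[]]
    for c in raw:
        if c.get("removed"):
            continue
        scaffolds[-1].append(c)
        i = c["index"]
        if i is not None and i < n_junctions and i != collapsed_second:
            if i in split_at:
                scaffolds.append([])
                n_lens.append([])
            else:
                n_lens[-1].append(noisy_gap[i])
    for c in displaced_pieces:
        scaffolds.append([c])
        n_lens.append([])

    # duplicated contigs: near-identical copies appended as their own scaffolds
    dup_sources = [c for c in raw if c.get("loci") and c["repeat_group"] is None]
    for d in range(spec.n_duplicated_contigs):
        src = dup_sources[(d + 1) % len(dup_sources)]
        scaffolds.append([
            dict(index=None, length=src["length"], loci=list(src["loci"]),
                 segments=list(src["segments"]), repeat_group=None,
                 dup_of=src["index"])
        ])
        n_lens.append([])

    def contig_seq(c: dict) -> str:
        return "".join(genome0[s0:s1] for s0, s1 in c["segments"])

    assembly: dict[str, str] = {}
    placed: list[dict] = []
    for group, gaps in zip(scaffolds, n_lens):
        if not group:
            continue
        name = f"scaffold{len(assembly)}"
        pieces = []
        for k, c in enumerate(group):
            seq = contig_seq(c)
            if c.get("dup_of") is not None and spec.heterozygosity > 0:
                seq = _mutate(rng, seq, spec.heterozygosity)[0]
            pieces.append(seq)
            if k < len(gaps):
                pieces.append("N" * gaps[k])
            placed.append(dict(c, scaffold=name, chunk=k))
        assembly[name] = "".join(pieces)

    contigs = split_assembly(assembly, min_n_run=1)
    rec_by_key = {(r.scaffold_name, int(r.name.rsplit("chunk", 1)[1])): r for r in contigs}
    true_contigs: list[TrueContig] = []
    index_to_name: dict[int, str] = {}
    break_positions: list[tuple[str, int]] = []
    for c in placed:
        rec = rec_by_key[(c["scaffold"], c["chunk"])]
        tc = TrueContig(
            name=rec.name, length=rec.length, loci=c.get("loci") or [],
            segments=c.get("segments"),
            repeat_group=c.get("repeat_group"),
            repeat_len=spec.repeat.length if c.get("repeat_group") is not None else 0,
        )
        if c.get("dup_of") is not None:
            tc.dup_of = index_to_name.get(c["dup_of"], str(c["dup_of"]))
        elif c.get("index") is not None:
            index_to_name[c["index"]] = rec.name
        if c.get("index") in break_at:
            break_positions.append((rec.name, break_at[c["index"]]))
        true_contigs.append(tc)

    # truth junctions: genome adjacency of contig anchor intervals
    anchors: list[tuple[int, int, str, str]] = []
    for tc in true_contigs:
        if tc.dup_of is not None:
            continue
        if len(tc.loci) > 1:
            for s0, strand in tc.loci:
                anchors.append((s0, s0 + tc.length, tc.name, strand))
        elif tc.segments is not None and len(tc.segments) == 1:
            s0, s1 = tc.segments[0]
            anchors.append((s0, s1, tc.name, "+"))
    anchors.sort()
    junctions: list[tuple[str, str, str, str, int]] = []
    jmap: dict[tuple[int, int], int] = {}
    for (a0, a1, an, astr), (b0, b1, bn, bstr) in zip(anchors, anchors[1:]):
        dist = b0 - a1
        if dist < 0 or dist > spec.gap_len_range[1] * 2:
            continue
        jmap[(a1, b0)] = len(junctions)
        junctions.append(
            (an, "r" if astr == "+" else "l", bn, "l" if bstr == "+" else "r", dist)
        )
    gap_j: list[int] = []
    for i in range(n_junctions):
        if i in split_at or i == collapsed_second:
            continue
        a1 = starts[i] + int(contig_lens[i])
        b0 = a1 + int(gap_lens[i])
        if (a1, b0) in jmap:
            gap_j.append(jmap[(a1, b0)])

    truth = TruthSet(true_contigs, junctions, sorted(gap_j), break_positions)
    reads, paf = _simulate_reads(spec, rng, genome, true_contigs, truth)
    self_paf = _self_alignments(spec, true_contigs)
    return World(spec, genome, assembly, contigs, reads, paf, self_paf, truth)


def _simulate_reads(
    spec: FixtureSpec,
    rng: np.random.Generator,
    genome: dict[str, str],
    true_contigs: list[TrueContig],
    truth: TruthSet,
) -> tuple[dict[str, str], list[AlignmentRecord]]:
    G = len(genome["hap0"])
    mu = np.log(spec.read_median)
    total_target = spec.coverage * G
    reads: dict[str, str] = {}
    paf: list[AlignmentRecord] = []

    repeat_copies = [tc for tc in true_contigs if tc.repeat_group is not None]
    # (genome interval, strand, contig offset, contig)
    intervals: list[tuple[int, int, str, int, TrueContig]] = []
    for tc in true_contigs:
        if tc.dup_of is not None:
            continue
        if len(tc.loci) > 1:
            for s0, strand in tc.loci:
                intervals.append((s0, s0 + tc.length, strand, 0, tc))
        else:
            off = 0
            for s0, s1 in tc.segments or []:
                intervals.append((s0, s1, "+", off, tc))
                off += s1 - s0
    intervals.sort(key=lambda t: t[0])

    emitted = 0
    i = 0
    haps = sorted(genome)
    while emitted < total_target:
        hap = haps[i % len(haps)]
        ln = int(np.clip(rng.lognormal(mu, spec.read_sigma), spec.read_min, G - 1))
        start = int(rng.integers(0, G - ln))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"read{i:05d}"
        i += 1
        emitted += ln

        if rng.random() < spec.chimeric_read_rate:
            ln2 = ln // 2
            start2 = int(rng.integers(0, G - ln2))
            fwd = genome[hap][start: start + ln - ln2] + genome[hap][start2: start2 + ln2]
            placements = [(start, start + ln - ln2, 0), (start2, start2 + ln2, ln - ln2)]
            truth.chimeric_reads.add(name)
        else:
            fwd = genome[hap][start: start + ln]
            placements = [(start, start + ln, 0)]
        fwd, subs = _mutate(rng, fwd, spec.error_rate)
        reads[name] = reverse_complement(fwd) if strand == "-" else fwd
        truth.read_placements[name] = (start, start + ln, strand)

        wrong = spec.repeat is not None and rng.random() < spec.repeat.wrong_map_rate
        for p0, p1, read_off in placements:
            for g0, g1, cstrand, off, tc in intervals:
                if g1 <= p0 or g0 >= p1:
                    continue
                lo, hi = max(p0, g0), min(p1, g1)
                if hi - lo < spec.min_emit:
                    continue
                target = tc
                mapq = 60
                if tc.repeat_group is not None:
                    rend = g0 + tc.repeat_len  # repeat occupies the contig start
                    if p0 >= g0 and p1 <= rend:
                        mapq = 3  # fully inside the repeat: ambiguous placement
                    elif wrong and p0 < g0 and g0 < p1 <= rend and len(repeat_copies) > 1:
                        # read enters the repeat and ends inside it: the mapper
                        # can pick the wrong copy; the alignment is truncated
                        # at the read end and carries the divergence penalty
                        others = [c for c in repeat_copies if c is not tc]
                        target = others[0]
                        mapq = 30
                # contig coordinates of the overlap
                if cstrand == "+":
                    t0 = off + (lo - g0)
                else:
                    t0 = off + (g1 - hi)
                # read coordinates (forward placement first)
                fr0 = read_off + (lo - p0)
                fr1 = read_off + (hi - p0)
                n_sub = int(np.searchsorted(subs, fr1) - np.searchsorted(subs, fr0))
                if strand == "-":
                    r0, r1 = ln - fr1, ln - fr0
                else:
                    r0, r1 = fr0, fr1
                aln_strand = strand if cstrand == "+" else ("-" if strand == "+" else "+")
                matches = (hi - lo) - n_sub
                if target is not tc:
                    matches = int(matches * (1 - spec.repeat.divergence))
                paf.append(
                    AlignmentRecord(
                        read_name=name, read_len=ln, read_start=r0, read_end=r1,
                        strand=aln_strand, target_name=target.name,
                        target_len=target.length,
                        target_start=t0, target_end=t0 + (hi - lo),
                        matches=max(1, matches), block_len=hi - lo, mapq=mapq,
                    )
                )
    return reads, paf


def _self_alignments(spec: FixtureSpec, true_contigs: list[TrueContig]) -> list[AlignmentRecord]:
    """Contig-to-contig records: diverged repeat copies and duplicated contigs."""
    out: list[AlignmentRecord] = []

    def rec(q: TrueContig, t: TrueContig, strand: str, identity: float,
            span: int | None = None) -> AlignmentRecord:
        ln = span if span is not None else min(q.length, t.length)
        return AlignmentRecord(
            read_name=q.name, read_len=q.length, read_start=0, read_end=ln,
            strand=strand, target_name=t.name, target_len=t.length,
            target_start=0, target_end=ln,
            matches=max(1, int(ln * identity)), block_len=ln, mapq=60,
        )

    copies = [tc for tc in true_contigs if tc.repeat_group is not None]
    for a in copies:
        for b in copies:
            if a is not b:  # only the repeat core aligns, not the unique flank
                out.append(rec(a, b, "+", 1 - spec.repeat.divergence, span=a.repeat_len))
    by_name = {tc.name: tc for tc in true_contigs}
    for tc in true_contigs:
        if tc.dup_of is not None and tc.dup_of in by_name:
            src = by_name[tc.dup_of]
            ident = 1 - spec.heterozygosity
            out.append(rec(tc, src, "+", ident))
            out.append(rec(src, tc, "+", ident))
    return out


# --- presets ---------------------------------------------------------------

PRESETS: dict[str, FixtureSpec] = {
    "clean-haploid": FixtureSpec(),
    "diploid-het": FixtureSpec(
        ploidy=2, heterozygosity=0.01, n_duplicated_contigs=1, genome_length=150_000,
        n_gaps=6, n_scaffold_splits=1,
    ),
    "two-copy-repeat": FixtureSpec(
        repeat=RepeatSpec(), error_rate=0.02, genome_length=150_000,
        n_gaps=8, n_scaffold_splits=0,
    ),
    "chimera": FixtureSpec(n_misassemblies=2, n_gaps=6, n_scaffold_splits=0),
    "loop": FixtureSpec(
        collapsed_repeat=True, genome_length=60_000, n_gaps=8, n_scaffold_splits=0,
        read_median=6000, read_sigma=0.25,
    ),
    "inverted-repeat": FixtureSpec(
        collapsed_repeat=True, inverted_repeat=True, genome_length=60_000, n_gaps=8,
        n_scaffold_splits=0, read_median=6000, read_sigma=0.25,
    ),
}


def preset(name: str, seed: int | None = None) -> FixtureSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = replace(PRESETS[name])
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec
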