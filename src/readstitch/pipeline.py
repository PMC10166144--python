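"""End-to-end orchestration: split, correct, bridge, traverse, fill, finish.

The scaffold pass consumes a split assembly, read-to-assembly alignments and
assembly self-alignments, and produces a change list plus the improved
assembly: prefilter and deduplicate mappings, fit the coverage model, break
misassembled contigs, trim unsupported ends, filter bridges, scaffold, build
and traverse the scaffold graph, and fill every resulting gap with the best
spanning read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import breaks as brk
from . import bridges as br
from . import fill as gf
from . import graph as gr
from . import pairs as px
from . import traverse as tv
from .coverage import CoverageModel, fit_coverage_model
from .duplications import detect_duplications
from .fasta import (
    Break, ChangeList, ContigRecord, Drop, Fill, Gap, Keep, apply_changes,
)
from .paf import AlignmentRecord, dedup_subreads, prefilter_alignments


@dataclass
class PipelineConfig:
    read_type: str = "Nanopore"  # CLR, CCS or Nanopore
    min_mapq: int = 20
    min_aln_len: int = 500
    min_count: int = 3
    pval_threshold: float = 0.01
    prob_factor: float = 10.0
    ploidy: int = 2
    vicinity: int = 100
    min_break_clearance: int = 200
    drop_slack: float = 1.2
    n_bin_sizes: int = 10
    cluster_rel_tol: float = 0.2
    cluster_abs_floor: int = 100


@dataclass
class PipelineResult:
    assembly: dict[str, str]
    changes: ChangeList
    contigs: list[ContigRecord]
    report: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)  # surviving bridge clusters


def _retarget_alignments(
    alns: Sequence[AlignmentRecord],
    old_contigs: Sequence[ContigRecord],
    new_contigs: Sequence[ContigRecord],
    min_aln_len: int,
) -> list[AlignmentRecord]:
    """Re-express alignments on post-break sub-contigs (clip at break points)."""
    pieces: dict[str, list[ContigRecord]] = {}
    old_by_name = {c.name: c for c in old_contigs}
    for c in new_contigs:
        base = c.name.rsplit(".", 1)[0] if "." in c.name else c.name
        pieces.setdefault(base if base in old_by_name else c.name, []).append(c)
    out: list[AlignmentRecord] = []
    for a in alns:
        subs = pieces.get(a.target_name)
        if subs is None:
            continue
        if len(subs) == 1 and subs[0].name == a.target_name:
            out.append(a)
            continue
        old = old_by_name[a.target_name]
        best, best_ov = None, 0
        for c in subs:
            s, e = c.start - old.start, c.end - old.start  # bounds within old contig
            ov = min(a.target_end, e) - max(a.target_start, s)
            if ov > best_ov:
                best, best_ov, bounds = c, ov, (s, e)
        if best is None or best_ov < min_aln_len:
            continue
        s, e = bounds
        lo, hi = max(a.target_start, s), min(a.target_end, e)
        cut_l, cut_r = lo - a.target_start, a.target_end - hi
        if a.strand == "+":
            r0, r1 = a.read_start + cut_l, a.read_end - cut_r
        else:
            r0, r1 = a.read_start + cut_r, a.read_end - cut_l
        out.append(
            AlignmentRecord(
                read_name=a.read_name, read_len=a.read_len, read_start=r0, read_end=r1,
                strand=a.strand, target_name=best.name, target_len=best.length,
                target_start=lo - s, target_end=hi - s,
                matches=min(a.matches, hi - lo), block_len=hi - lo, mapq=a.mapq,
            )
        )
    return out


def _expand_paths(
    final_paths: list[tv.ScaffoldPath],
    scaffolds: list[gr.Scaffold],
) -> list[gf.ContigPath]:
    """Expand scaffold-level paths to contig level (primary haplotype)."""
    out: list[gf.ContigPath] = []
    for k, sp in enumerate(final_paths):
        steps: list[gf.ContigStep] = []
        gap_means: list[float] = []
        originals: list[int | None] = []
        for sid, strand, dist in sp.primary:
            sc = scaffolds[sid]
            parts = sc.parts if strand == "+" else [
                (n, ("-" if s == "+" else "+")) for n, s in reversed(sc.parts)
            ]
            joins = sc.joins if strand == "+" else list(reversed(sc.joins))
            if steps:
                gap_means.append(dist)
                originals.append(None)
            for t, (cname, cstrand) in enumerate(parts):
                steps.append((cname, cstrand))
                if t < len(joins):
                    gap_means.append(joins[t].mean_distance)
                    originals.append(None)
        out.append(gf.ContigPath(f"path{k}", steps, gap_means, originals))
    return out


def _rejoin_original(
    paths: list[gf.ContigPath], contigs: Sequence[ContigRecord]
) -> list[gf.ContigPath]:
    """Keep original scaffold connections between untouched contigs as gapped joins."""
    by_scaffold: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        by_scaffold.setdefault(c.scaffold_name, []).append(c)
    adjacency: dict[str, tuple[str, int]] = {}  # left contig -> (right contig, N len)
    for cs in by_scaffold.values():
        cs = sorted(cs, key=lambda c: c.start)
        for a, b in zip(cs, cs[1:]):
            if a.gap_after_len is not None:
                adjacency[a.name] = (b.name, a.gap_after_len)
    changed = True
    while changed:
        changed = False
        right_end: dict[str, int] = {}
        left_start: dict[str, int] = {}
        for i, p in enumerate(paths):
            if p.steps[-1][1] == "+":
                right_end[p.steps[-1][0]] = i
            if p.steps[0][1] == "+":
                left_start[p.steps[0][0]] = i
        for left, (right, nlen) in sorted(adjacency.items()):
            i = right_end.get(left)
            j = left_start.get(right)
            if i is None or j is None or i == j:
                continue
            a, b = paths[i], paths[j]
            merged = gf.ContigPath(
                a.name,
                a.steps + b.steps,
                a.gap_means + [float(nlen)] + b.gap_means,
                (a.original_gaps or [None] * len(a.gap_means))
                + [nlen]
                + (b.original_gaps or [None] * len(b.gap_means)),
            )
            paths = [p for t, p in enumerate(paths) if t not in (i, j)] + [merged]
            changed = True
            break
    return paths


def scaffold_pass(
    assembly: Mapping[str, str],
    contigs: list[ContigRecord],
    alns: Sequence[AlignmentRecord],
    self_alns: Sequence[AlignmentRecord],
    reads: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    report: dict = {}
    changes = ChangeList()

    acc = prefilter_alignments(alns, cfg.min_mapq, cfg.min_aln_len)
    acc = dedup_subreads(acc, cfg.read_type)
    report["alignments_in"] = len(alns)
    report["alignments_accepted"] = len(acc)

    read_lengths = sorted({a.read_name: a.read_len for a in acc}.values())
    contig_lengths = {c.name: c.length for c in contigs}
    try:
        model: CoverageModel | None = fit_coverage_model(
            acc, contig_lengths, read_lengths, cfg.n_bin_sizes
        )
    except ValueError:
        model = None

    # --- breaking ---
    cands = brk.collect_break_candidates(acc, cfg.vicinity, cfg.min_break_clearance)
    accepted = brk.decide_breaks(cands, model, cfg.min_count, cfg.prob_factor, cfg.vicinity)
    acc = brk.remove_unaccepted_divergent(acc, accepted, cfg.vicinity, cfg.min_break_clearance)
    new_contigs = brk.apply_breaks(contigs, accepted)
    acc = _retarget_alignments(acc, contigs, new_contigs, cfg.min_aln_len)
    name_to_id = {c.name: c.contig_id for c in contigs}
    report["break_details"] = []
    for cname, positions in sorted(accepted.items()):
        for p in positions:
            changes.breaks.append(Break(name_to_id[cname], p))
            report["break_details"].append((cname, p))
    report["breaks"] = sum(len(v) for v in accepted.values())

    trims = brk.trim_and_drop(new_contigs, acc, cfg.min_aln_len, cfg.drop_slack)
    trim_by_name = {t.contig: t for t in trims}
    dropped = {t.contig for t in trims if t.dropped}
    live_contigs = [c for c in new_contigs if c.name not in dropped]
    acc = [a for a in acc if a.target_name not in dropped]
    new_by_name = {c.name: c for c in new_contigs}
    for cname in sorted(dropped):
        changes.drops.append(Drop(new_by_name[cname].contig_id))
    report["dropped_contigs"] = len(dropped)

    # --- bridging ---
    bridges = br.form_bridges(acc, min_self_distance=2 * cfg.min_aln_len)
    clusters = br.cluster_bridges(bridges, cfg.cluster_rel_tol, cfg.cluster_abs_floor)
    surviving = br.filter_bridges(
        clusters, model, cfg.min_count, cfg.pval_threshold, cfg.prob_factor
    )
    report["bridge_clusters"] = len(clusters)
    report["bridge_clusters_kept"] = len(surviving)

    # --- scaffold graph ---
    scaffolds, contig_map, remaining = gr.scaffold_unconflicted(
        surviving, [c.name for c in live_contigs]
    )
    lifted = gr.lift_clusters(remaining, contig_map, scaffolds)
    conns = gr.extract_long_range(acc, contig_map, scaffolds, lifted)
    conns = gr.filter_long_range(conns, cfg.pval_threshold)
    entries = gr.build_graph(conns, lifted)
    report["scaffolds_unconflicted"] = len(scaffolds)
    report["long_range_connections"] = len(conns)

    marks = detect_duplications(self_alns)
    single = {
        sc.parts[0][0]: sc.scaffold_id for sc in scaffolds if len(sc.parts) == 1
    }
    dup_pairs = [
        (single[m.dup_contig], single[m.template_contig], m.strand)
        for m in marks
        if m.dup_contig in single and m.template_contig in single
    ]
    entries = gr.remove_duplicates_from_graph(
        entries, dup_pairs, {sc.scaffold_id: sum(1 for _ in sc.parts) for sc in scaffolds}
    )
    duplicated = {d for d, _, _ in dup_pairs}

    prs = px.build_pairs(entries)
    prs = px.filter_pairs(prs, entries)
    prs = px.enforce_consistency(prs, entries)

    support: dict[tuple, int] = {}
    for c in lifted:
        for key in ((c.from_end, c.to_end), (c.to_end, c.from_end)):
            support[key] = max(support.get(key, 0), c.count)

    def support_fn(path: tv.Path) -> int:
        best = 10**9
        prev = None
        for sid, strand, _ in path:
            end = (sid, "r" if strand == "+" else "l")
            if prev is not None:
                key = (prev, (sid, "l" if strand == "+" else "r"))
                best = min(best, support.get(key, 0))
            prev = end
        return best if best < 10**9 else 0

    final = tv.traverse_graph(
        entries, prs, [sc.scaffold_id for sc in scaffolds],
        cfg.ploidy, support_fn, duplicated,
    )
    report["final_paths"] = len(final)

    # --- gap filling ---
    cpaths = _expand_paths(final, scaffolds)
    cpaths = _rejoin_original(cpaths, live_contigs)
    pals = gf.align_reads_to_paths(acc, cpaths)
    cpaths = gf.split_uncovered(cpaths, pals)
    pals = gf.align_reads_to_paths(acc, cpaths)
    pals = gf.resolve_multimapping(pals, cpaths)
    choices = gf.select_gap_reads(pals, cpaths)
    report["junctions"] = len(choices)
    report["junctions_filled"] = sum(1 for c in choices if c.read_name is not None)

    # --- change list + output ---
    live_by_name = {c.name: c for c in live_contigs}
    choice_by_junction = {(c.path_index, c.junction): c for c in choices}
    for pi, path in enumerate(cpaths):
        records: list = []
        pending_trim = 0
        for k, (cname, cstrand) in enumerate(path.steps):
            c = live_by_name[cname]
            t = trim_by_name.get(cname)
            tl = t.new_start if t else 0
            tr = c.length - t.new_end if t else 0
            if cstrand == "+":
                tl += pending_trim
            else:
                tr += pending_trim
            pending_trim = 0
            records.append(Keep(c.contig_id, cstrand, tl, tr))
            if k >= len(path.steps) - 1:
                continue
            ch = choice_by_junction.get((pi, k))
            if ch is None:
                records.append(Gap(max(1, round(path.gap_means[k]))))
            elif ch.read_name is None:
                records.append(Gap(ch.gap_length))
            else:
                g0, g1 = ch.read_gap
                if g1 > g0:
                    records.append(Fill(ch.read_name, g0, g1, ch.strand))
                elif g1 < g0:
                    pending_trim = g0 - g1  # overlapping flanks: trim downstream
        changes.add_scaffold(path.name, records)

    out = apply_changes(assembly, live_contigs, changes, reads)
    return PipelineResult(out, changes, live_contigs, report, surviving)


def run(
    assembly: Mapping[str, str],
    alns: Sequence[AlignmentRecord],
    self_alns: Sequence[AlignmentRecord],
    reads: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Split the assembly and run one full scaffold pass.

    Further iterations need fresh alignments against the improved assembly,
    which an external mapper must provide; each call performs one pass.
    """
    from .fasta import split_assembly

    contigs = split_assembly(assembly)
    return scaffold_pass(assembly, contigs, alns, self_alns, reads, cfg)
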