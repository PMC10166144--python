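"""Filter performance against synthetic truth: FDR and Fraction Possibilities Kept.

A surviving bridge cluster is a true positive when it connects the right
contig ends in the right orientation and its mean distance lies within 0.5
to 1.5 of the true junction distance.  The false discovery rate is the
fraction of surviving clusters that are false; the Fraction Possibilities
Kept is the fraction of true joins present before filtering that a surviving
cluster still realizes.  The sweep evaluates each filter stage cumulatively,
with earlier stages fixed at their selected values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .bridges import (
    BridgeCluster, cluster_bridges, exceedance_filter, filter_min_count,
    form_bridges, probability_filter,
)
from .coverage import CoverageModel
from .simulate import TruthSet, World


def _truth_index(truth: TruthSet) -> dict[tuple, int]:
    idx: dict[tuple, int] = {}
    for an, aside, bn, bside, dist in truth.junctions:
        ea, eb = (an, aside), (bn, bside)
        if eb < ea:
            ea, eb = eb, ea
        idx[(ea, eb)] = dist
    return idx


def is_true_cluster(cluster: BridgeCluster, truth_idx: dict[tuple, int]) -> bool:
    key = (cluster.from_end, cluster.to_end)
    if key not in truth_idx:
        return False
    true_dist = truth_idx[key]
    d = cluster.mean_distance
    if true_dist <= 0:
        return abs(d) <= 150  # zero-length joins: allow the clustering floor
    return 0.5 * true_dist <= d <= 1.5 * true_dist


@dataclass
class FilterMetrics:
    stage: str
    n_kept: int
    n_true: int
    fdr: float
    fraction_kept: float


def score_clusters(
    before: Sequence[BridgeCluster],
    after: Sequence[BridgeCluster],
    truth: TruthSet,
    stage: str = "all",
) -> FilterMetrics:
    idx = _truth_index(truth)
    true_before = {c.key for c in before if is_true_cluster(c, idx)}
    n_true = sum(1 for c in after if is_true_cluster(c, idx))
    n_kept = len(after)
    true_after = {c.key for c in after if is_true_cluster(c, idx)}
    fdr = (n_kept - n_true) / n_kept if n_kept else 0.0
    frac = len(true_after & true_before) / len(true_before) if true_before else 1.0
    return FilterMetrics(stage, n_kept, n_true, fdr, frac)


def filter_sweep(
    world: World,
    clusters: Sequence[BridgeCluster],
    model: CoverageModel | None,
    min_counts: Sequence[int] = (1, 2, 3, 5),
    pvals: Sequence[float] = (0.05, 0.01, 0.001),
    prob_factors: Sequence[float] = (3.0, 10.0, 30.0),
    selected: tuple[int, float, float] = (3, 0.01, 10.0),
) -> list[dict]:
    """Grid-search each filter stage cumulatively; returns rows of metrics.

    For each stage, prior stages run with their selected values and the
    stage's own parameter is swept; metrics describe the bridges remaining
    after all filters up to that stage.
    """
    sel_count, sel_pval, sel_factor = selected
    rows: list[dict] = []
    for mc in min_counts:
        after = filter_min_count(clusters, mc)
        m = score_clusters(clusters, after, world.truth, "min_count")
        rows.append(dict(stage="min_count", param=mc, fdr=m.fdr, fraction_kept=m.fraction_kept))
    base = filter_min_count(clusters, sel_count)
    for pv in pvals:
        after = exceedance_filter(base, pv)
        m = score_clusters(clusters, after, world.truth, "exceedance")
        rows.append(dict(stage="exceedance", param=pv, fdr=m.fdr, fraction_kept=m.fraction_kept))
    base2 = exceedance_filter(base, sel_pval)
    if model is not None:
        for pf in prob_factors:
            after = probability_filter(base2, model, pf)
            m = score_clusters(clusters, after, world.truth, "probability")
            rows.append(dict(stage="probability", param=pf, fdr=m.fdr, fraction_kept=m.fraction_kept))
    return rows


def clusters_from_world(world: World, cfg=None):
    """Convenience: accepted-alignment clusters for a world (prefilter + cluster)."""
    from .paf import dedup_subreads, prefilter_alignments
    from .pipeline import PipelineConfig

    cfg = cfg or PipelineConfig()
    acc = prefilter_alignments(world.paf, cfg.min_mapq, cfg.min_aln_len)
    acc = dedup_subreads(acc, cfg.read_type)
    bridges = form_bridges(acc, min_self_distance=2 * cfg.min_aln_len)
    return cluster_bridges(bridges, cfg.cluster_rel_tol, cfg.cluster_abs_floor)


def assembly_identity(output: dict[str, str], genome: dict[str, str]) -> float:
    """Mean per-base identity of output scaffolds against the closest haplotype.

    Exact-substring containment counts as identity 1; otherwise the edit
    distance (edlib when available, else a banded fallback) is normalized by
    scaffold length.
    """
    from .fasta import reverse_complement

    if not output:
        return 0.0
    total, weight = 0.0, 0
    for seq in output.values():
        s = seq.upper().replace("N", "")
        best = 0.0
        for hap in genome.values():
            for cand in (s, reverse_complement(s)):
                if cand in hap:
                    best = 1.0
                    break
            if best == 1.0:
                break
        if best < 1.0:
            best = max(best, _edlib_identity(s, genome))
        total += best * len(s)
        weight += len(s)
    return total / weight if weight else 0.0


def _edlib_identity(s: str, genome: dict[str, str]) -> float:
    try:
        import edlib
    except ImportError:  # pragma: no cover
        return 0.0
    best = 0.0
    for hap in genome.values():
        res = edlib.align(s, hap, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = max(best, 1.0 - res["editDistance"] / len(s))
    return best


def score_world(world: World, result) -> dict:
    """End-to-end report: gaps closed, breaks found, identity, junction joins."""
    truth = world.truth
    joined: set[tuple] = set()
    by_id = {c.contig_id: c.name for c in result.contigs}
    for name, records in result.changes.scaffolds:
        prev_keep: str | None = None
        gap_since = False
        for r in records:
            typ = type(r).__name__
            if typ == "Keep":
                cname = by_id[r.contig_id]
                if prev_keep is not None and not gap_since:
                    joined.add((prev_keep, cname))
                    joined.add((cname, prev_keep))
                prev_keep, gap_since = cname, False
            elif typ == "Gap":
                gap_since = True  # an N gap between keeps: junction not closed
    gaps_closed = 0
    for j in truth.gap_junctions:
        an, _, bn, _, _ = truth.junctions[j]
        if (an, bn) in joined:
            gaps_closed += 1
    found, spurious = 0, 0
    matched = set()
    details = result.report.get("break_details", [])
    for cname, position in details:
        hit = False
        for k, (tn, tp) in enumerate(truth.break_positions):
            if tn == cname and abs(tp - position) <= 1000 and k not in matched:
                matched.add(k)
                hit = True
                break
        found += hit
        spurious += not hit
    identity = assembly_identity(result.assembly, world.genome)
    return dict(
        n_gap_junctions=len(truth.gap_junctions),
        gaps_closed=gaps_closed,
        breaks_true=len(truth.break_positions),
        breaks_found=found,
        breaks_spurious=spurious,
        identity=identity,
        n_output_scaffolds=len(result.assembly),
    )
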