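"""Bridges between contig ends and the three bridge filters.

A bridge is read-derived evidence joining two oriented contig ends with a
signed distance (negative = the anchor mappings overlap on the read).
Bridges joining the same ends are clustered by relative distance difference,
then filtered three ways:

1. a minimum cluster count, removing chimeric-read connections;
2. a one-sided exceedance test on remaining read lengths, removing bridges
   whose anchor mappings are truncated because they stem from a different
   repeat copy;
3. a comparison of the cluster count against the genome-wide expectation
   (negative-binomial coverage model), removing rare connections that a
   competing bridge at the same end explains many times better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

from .coverage import CoverageModel
from .paf import AlignmentRecord

End = tuple[str, str]  # (contig name, side 'l' or 'r')


@dataclass
class Bridge:
    from_end: End
    to_end: End
    distance: int
    mapq_low: int
    mapq_high: int
    remaining_len_from: int
    remaining_len_to: int
    matches_from: int
    matches_to: int
    read_name: str
    # read interval between the two anchor mappings, and its strand relative
    # to the from->to traversal; used later to cut the gap-filling sequence
    read_gap: tuple[int, int] = (0, 0)
    gap_strand: str = "+"

    @property
    def key(self) -> tuple[End, End]:
        return (self.from_end, self.to_end)


def _exit_side(strand: str) -> str:
    return "r" if strand == "+" else "l"


def _entry_side(strand: str) -> str:
    return "l" if strand == "+" else "r"


def canonical(from_end: End, to_end: End) -> bool:
    """True if (from, to) is already the canonical orientation of the connection."""
    return from_end <= to_end


def flip_bridge(b: Bridge) -> Bridge:
    return Bridge(
        from_end=b.to_end,
        to_end=b.from_end,
        distance=b.distance,
        mapq_low=b.mapq_low,
        mapq_high=b.mapq_high,
        remaining_len_from=b.remaining_len_to,
        remaining_len_to=b.remaining_len_from,
        matches_from=b.matches_to,
        matches_to=b.matches_from,
        read_name=b.read_name,
        read_gap=b.read_gap,
        gap_strand="-" if b.gap_strand == "+" else "+",
    )


def form_bridges(
    alns: Sequence[AlignmentRecord], min_self_distance: int = 1000
) -> list[Bridge]:
    """One bridge per adjacent pair of accepted mappings of a read.

    Mappings are taken in read-coordinate order; the bridge distance is the
    read gap between the anchors.  Same-end self-bridges are kept only when
    the distance exceeds ``min_self_distance`` (hairpin/palindrome mapping
    artifacts produce short same-end self-links).  Bridges are stored in
    canonical end order so each physical connection has one key.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alns:
        by_read.setdefault(a.read_name, []).append(a)
    bridges: list[Bridge] = []
    for name in by_read:
        maps = sorted(by_read[name], key=lambda a: (a.read_start, a.read_end))
        if len(maps) < 2:
            continue
        first_start = maps[0].read_start
        last_end = maps[-1].read_end
        for a, b in zip(maps, maps[1:]):
            from_end = (a.target_name, _exit_side(a.strand))
            to_end = (b.target_name, _entry_side(b.strand))
            if from_end == to_end and b.read_start - a.read_end <= min_self_distance:
                continue
            br = Bridge(
                from_end=from_end,
                to_end=to_end,
                distance=b.read_start - a.read_end,
                mapq_low=min(a.mapq, b.mapq),
                mapq_high=max(a.mapq, b.mapq),
                remaining_len_from=a.read_end - first_start,
                remaining_len_to=last_end - b.read_start,
                matches_from=a.matches,
                matches_to=b.matches,
                read_name=name,
                read_gap=(a.read_end, b.read_start),
                gap_strand="+",
            )
            if not canonical(from_end, to_end):
                br = flip_bridge(br)
            bridges.append(br)
    return bridges


@dataclass
class BridgeCluster:
    """Bridges joining the same ends with mutually consistent distances."""

    from_end: End
    to_end: End
    members: list[Bridge] = field(default_factory=list)

    @property
    def key(self) -> tuple[End, End]:
        return (self.from_end, self.to_end)

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def mean_distance(self) -> float:
        return sum(b.distance for b in self.members) / len(self.members)

    def quality_levels(self) -> list[tuple[int, int]]:
        """Distinct (mapq_low, mapq_high) pairs, highest combined quality first."""
        return sorted({(b.mapq_low, b.mapq_high) for b in self.members}, reverse=True)

    def cumulative_count(self, level: tuple[int, int]) -> int:
        """Members at the given combined quality or higher."""
        return sum(1 for b in self.members if (b.mapq_low, b.mapq_high) >= level)

    def remaining(self, side: str) -> list[int]:
        """Member remaining read lengths on one side ('from' or 'to')."""
        if side == "from":
            return [b.remaining_len_from for b in self.members]
        return [b.remaining_len_to for b in self.members]

    def end(self, side: str) -> End:
        return self.from_end if side == "from" else self.to_end


def cluster_bridges(
    bridges: Iterable[Bridge], rel_tol: float = 0.2, abs_floor: int = 100
) -> list[BridgeCluster]:
    """Greedy distance clustering of bridges sharing an endpoint key.

    Bridges are taken in ascending distance; one joins the current cluster iff
    its distance is within ``max(rel_tol * |mean|, abs_floor)`` of the running
    cluster mean.  Clusters joining the same ends at different distances are
    downstream treated like bridges joining different ends.
    """
    by_key: dict[tuple[End, End], list[Bridge]] = {}
    for b in bridges:
        by_key.setdefault(b.key, []).append(b)
    clusters: list[BridgeCluster] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda b: b.distance)
        current: list[Bridge] = []
        mean = 0.0
        for b in group:
            if current and abs(b.distance - mean) > max(rel_tol * abs(mean), abs_floor):
                clusters.append(BridgeCluster(key[0], key[1], current))
                current = []
            current.append(b)
            mean = sum(x.distance for x in current) / len(current)
        if current:
            clusters.append(BridgeCluster(key[0], key[1], current))
    return clusters


def filter_min_count(clusters: Sequence[BridgeCluster], min_count: int = 3) -> list[BridgeCluster]:
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [c for c in clusters if c.count >= min_count]


def exceedance_pvalue(n_control: int, n_test: int, r: int, exact: bool = False):
    """One-sided exceedance probability: C(n_control, r) / C(n_control + n_test, r).

    Under exchangeability of the pooled samples this is the probability that
    the ``r`` largest of all ``n_control + n_test`` values are all controls,
    i.e. that at least ``r`` control values exceed the test maximum.
    """
    if not (0 <= r <= n_control):
        raise ValueError("require 0 <= r <= n_control")
    p = Fraction(comb(n_control, r), comb(n_control + n_test, r))
    return p if exact else float(p)


def _end_index(clusters: Sequence[BridgeCluster]) -> dict[End, list[int]]:
    idx: dict[End, list[int]] = {}
    for i, c in enumerate(clusters):
        idx.setdefault(c.from_end, []).append(i)
        if c.to_end != c.from_end:
            idx.setdefault(c.to_end, []).append(i)
    return idx


def _sides_at(cluster: BridgeCluster, end: End) -> list[str]:
    sides = []
    if cluster.from_end == end:
        sides.append("from")
    if cluster.to_end == end:
        sides.append("to")
    return sides


def cluster_test_pvalues(clusters: Sequence[BridgeCluster]) -> list[list[float]]:
    """The four exceedance p-values per cluster.

    For each of a cluster's two sides, its remaining read lengths are compared
    within the group of clusters sharing that side's contig end and within the
    group sharing the other side's end.  Per group the cluster with the
    longest remaining length is the control; every other cluster is tested
    against it, adjusting the test maximum by the positive distance
    difference.  A cluster acting as control (or without competitors) gets
    p = 1 for that test.
    """
    end_idx = _end_index(clusters)
    pvals: list[list[float]] = [[] for _ in clusters]

    for shared_end, indices in end_idx.items():
        if len(indices) < 2:
            for i in indices:
                pvals[i].extend([1.0, 1.0])
            continue
        # For the group sharing `shared_end`, two comparisons are run: on the
        # remaining lengths at the shared end itself, and on the remaining
        # lengths at each cluster's far end.
        for measured in ("near", "far"):
            samples: list[tuple[int, list[int], float]] = []
            for i in indices:
                c = clusters[i]
                for s in _sides_at(c, shared_end):
                    side = s if measured == "near" else ("to" if s == "from" else "from")
                    samples.append((i, c.remaining(side), c.mean_distance))
            control = max(samples, key=lambda t: max(t[1]))
            c_idx, c_vals, c_dist = control
            for i, vals, dist in samples:
                if (i, vals, dist) is control:
                    pvals[i].append(1.0)
                    continue
                adj = max(0.0, dist - c_dist)
                test_max = max(vals) + adj
                r = sum(1 for v in c_vals if v > test_max)
                pvals[i].append(exceedance_pvalue(len(c_vals), len(vals), r))
    return pvals


def exceedance_filter(
    clusters: Sequence[BridgeCluster], pval_threshold: float = 0.01
) -> list[BridgeCluster]:
    """Remove clusters failing any of their four exceedance tests, then restore.

    Restoration: if a contig end is left with no bridges, removed bridges
    joining two such bridge-less ends are brought back, choosing the one with
    the largest minimum p-value (ties: higher count, then lexicographic key).
    """
    pvals = cluster_test_pvalues(clusters)
    kept = [c for c, ps in zip(clusters, pvals) if not ps or min(ps) >= pval_threshold]
    removed = [(c, ps) for c, ps in zip(clusters, pvals) if ps and min(ps) < pval_threshold]
    if not removed:
        return kept
    covered = set()
    for c in kept:
        covered.add(c.from_end)
        covered.add(c.to_end)
    restorable = [(c, ps) for c, ps in removed if c.from_end not in covered and c.to_end not in covered]
    # group by the pair of bare ends; restore the best bridge per pair
    by_pair: dict[tuple[End, End], list[tuple[BridgeCluster, list[float]]]] = {}
    for c, ps in restorable:
        by_pair.setdefault(c.key, []).append((c, ps))
    for key in sorted(by_pair):
        cands = by_pair[key]
        best = max(cands, key=lambda t: (min(t[1]), t[0].count, t[0].key))
        kept.append(best[0])
    return kept


def probability_filter(
    clusters: Sequence[BridgeCluster], model: CoverageModel, prob_factor: float = 10.0
) -> list[BridgeCluster]:
    """Remove clusters that a competitor at the same end explains many times better.

    Each cluster's probability is the fitted NB CDF at its count, using the
    lowest bin size still >= its mean bridge distance.  Competing clusters at
    a shared contig end are compared on cumulative counts from high to low
    combined mapping quality; the highest quality level that resolves the
    conflict (probability ratio >= ``prob_factor``) decides.  Clusters whose
    mean distance exceeds every bin size are exempt.
    """
    end_idx = _end_index(clusters)
    remove: set[int] = set()
    for _end, indices in sorted(end_idx.items()):
        if len(indices) < 2:
            continue
        for ai in indices:
            for bi in indices:
                if ai >= bi:
                    continue
                a, b = clusters[ai], clusters[bi]
                fa = model.fit_for_distance(a.mean_distance)
                fb = model.fit_for_distance(b.mean_distance)
                if fa is None or fb is None:
                    continue
                levels = sorted(set(a.quality_levels()) | set(b.quality_levels()), reverse=True)
                for level in levels:
                    pa = fa.cdf(a.cumulative_count(level))
                    pb = fb.cdf(b.cumulative_count(level))
                    if pa >= prob_factor * pb and pa > 0:
                        remove.add(bi)
                        break
                    if pb >= prob_factor * pa and pb > 0:
                        remove.add(ai)
                        break
    return [c for i, c in enumerate(clusters) if i not in remove]


def clusters_to_tsv(clusters: Sequence[BridgeCluster]) -> str:
    """Diagnostic dump: one cluster per line (endpoints, count, mean distance)."""
    lines = ["#from_contig\tfrom_side\tto_contig\tto_side\tcount\tmean_distance"]
    for c in clusters:
        lines.append(
            f"{c.from_end[0]}\t{c.from_end[1]}\t{c.to_end[0]}\t{c.to_end[1]}"
            f"\t{c.count}\t{c.mean_distance:.1f}"
        )
    return "\n".join(lines) + "\n"


def filter_bridges(
    clusters: Sequence[BridgeCluster],
    model: CoverageModel | None,
    min_count: int = 3,
    pval_threshold: float = 0.01,
    prob_factor: float = 10.0,
) -> list[BridgeCluster]:
    """The full filter chain: minimum count, exceedance test, coverage probability."""
    out = filter_min_count(clusters, min_count)
    out = exceedance_filter(out, pval_threshold)
    if model is not None:
        out = probability_filter(out, model, prob_factor)
    return out
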