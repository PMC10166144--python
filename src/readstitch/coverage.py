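"""Expected-coverage model: negative-binomial fits to read counts in bins.

To judge whether a bridge is supported by an unusually small number of reads,
the genome-wide distribution of read counts is estimated from consecutive,
non-overlapping bins laid over the original (unbroken) contigs.  One fit is
made per bin size, with bin sizes placed at read-length quantiles so each
bridge distance can be matched to a comparable bin.  Only the lower half of
the cumulative count distribution is fitted, which keeps collapsed repeats
(inflated counts) out of the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats


def _nb_cdf(k, mean: float, dispersion: float):
    # dispersion = NB size parameter r; p = r / (r + mean)
    p = dispersion / (dispersion + mean)
    return stats.nbinom.cdf(k, dispersion, p)


@dataclass
class BinFit:
    bin_size: int
    mean: float
    dispersion: float
    counts: np.ndarray  # sorted per-bin counts (empirical distribution)
    degenerate: bool = False  # all counts identical: CDF is a step

    def cdf(self, k: int) -> float:
        if self.degenerate:
            return float(np.mean(self.counts <= k))
        return float(_nb_cdf(k, self.mean, self.dispersion))


@dataclass
class CoverageModel:
    fits: list[BinFit] = field(default_factory=list)

    @property
    def bin_sizes(self) -> list[int]:
        return [f.bin_size for f in self.fits]

    def fit_for_distance(self, distance: float) -> BinFit | None:
        """The fit with the lowest bin size still >= the (mean bridge) distance."""
        for f in self.fits:  # fits kept sorted ascending by bin size
            if f.bin_size >= distance:
                return f
        return None

    def probability(self, count: int, distance: float) -> float | None:
        """P(observed count or less) under the matched bin-size fit; None if exempt."""
        f = self.fit_for_distance(distance)
        if f is None:
            return None
        return f.cdf(count)


def fit_nb_to_counts(counts: Sequence[int]) -> tuple[float, float, bool]:
    """Least-squares fit of an NB CDF to the lower half of an empirical CDF.

    Returns (mean, dispersion, degenerate).  Initialization comes from
    lower-half sample moments; bounded least squares keeps both parameters
    positive.
    """
    counts = np.sort(np.asarray(counts, dtype=float))
    n = len(counts)
    if n == 0:
        raise ValueError("no bins to fit")
    if counts[0] == counts[-1]:
        return float(counts[0]), 1e6, True
    # empirical CDF at each distinct count value
    values, idx = np.unique(counts, return_index=True)
    ecdf = (idx + np.diff(np.append(idx, n)) ) / n  # P(X <= v)
    lower = ecdf <= 0.5
    if lower.sum() < 2:
        lower = np.zeros_like(lower, dtype=bool)
        lower[: max(2, len(values) // 2)] = True
    v, e = values[lower], ecdf[lower]
    half = counts[: max(2, n // 2)]
    m0 = max(float(np.mean(half)), 0.5)
    var0 = max(float(np.var(half)), m0 + 0.1)
    r0 = m0 * m0 / max(var0 - m0, 1e-3)
    r0 = float(np.clip(r0, 0.1, 1e4))

    def resid(theta):
        mean, disp = theta
        return _nb_cdf(v, mean, disp) - e

    res = optimize.least_squares(
        resid, x0=[m0, r0], bounds=([1e-3, 1e-3], [1e6, 1e6]), xtol=1e-10, ftol=1e-10
    )
    mean, disp = res.x
    return float(mean), float(disp), False


def quantile_bin_sizes(read_lengths: Sequence[int], n_bin_sizes: int = 10) -> list[int]:
    """Bin sizes at read-length quantiles with equal numbers of reads between them."""
    lengths = np.asarray(read_lengths, dtype=float)
    qs = (np.arange(n_bin_sizes) + 0.5) / n_bin_sizes
    sizes = sorted({int(round(s)) for s in np.quantile(lengths, qs)})
    return [s for s in sizes if s > 0]


def fit_coverage_model(
    alns,
    contig_lengths: dict[str, int],
    read_lengths: Sequence[int],
    n_bin_sizes: int = 10,
) -> CoverageModel:
    """Fit one NB per bin size from reads fully covering shifted full-length bins.

    ``contig_lengths`` should describe the original, unbroken contigs.  Bins in
    a contig are shifted so all are full length, leaving an equal number of
    bases uncovered at each contig end.  A bin size no contig can host, or one
    that no read fully covers, is dropped with a warning.
    """
    sizes = quantile_bin_sizes(read_lengths, n_bin_sizes)
    by_target: dict[str, list] = {}
    for a in alns:
        by_target.setdefault(a.target_name, []).append(a)
    fits: list[BinFit] = []
    for size in sizes:
        counts: list[int] = []
        for name, length in contig_lengths.items():
            nbins = length // size
            if nbins == 0:
                continue
            offset = (length - nbins * size) // 2
            starts = offset + size * np.arange(nbins)
            bin_counts = np.zeros(nbins, dtype=int)
            for a in by_target.get(name, ()):  # count reads covering the full bin
                lo = int(np.ceil((a.target_start - offset) / size))
                hi = (a.target_end - offset) // size
                lo = max(lo, 0)
                hi = min(hi, nbins)
                if hi > lo:
                    bin_counts[lo:hi] += 1
            counts.extend(bin_counts.tolist())
        if not counts:
            warnings.warn(f"no contig long enough for bin size {size}; dropped")
            continue
        if max(counts) == 0:
            warnings.warn(f"no read fully covers any bin of size {size}; dropped")
            continue
        mean, disp, degenerate = fit_nb_to_counts(counts)
        fits.append(BinFit(size, mean, disp, np.sort(np.asarray(counts)), degenerate))
    if not fits:
        raise ValueError("no bin size could be fitted: all contigs too short or uncovered")
    fits.sort(key=lambda f: f.bin_size)
    return CoverageModel(fits)
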