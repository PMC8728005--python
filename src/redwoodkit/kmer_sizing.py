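"""Genome size estimation from a k-mer multiplicity histogram.

For a haploid sequencing library, the histogram of 31-mer multiplicities
shows an error component at low coverage, a main peak at the per-copy
coverage depth c, and — in a hexaploid — secondary peaks near 2c and 3c
from k-mers identical across two or three subgenomes. The genome size is
G = T / c where T is the total k-mer instance count (sum of coverage x
count) above the error cutoff. Summing all coverage >= cutoff (including
the 2c/3c peaks) counts subgenome-shared sequence once per copy, which is
what dividing by the 1-copy depth requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import KmerHistogram

logger = logging.getLogger("redwoodkit")


@dataclass
class SizeEstimate:
    error_cutoff: int
    main_peak: int
    total_instances: int
    genome_size: float
    subgenome_peaks: list[int] = field(default_factory=list)
    refined_peak: float | None = None  # centroid-refined depth, if used

    @property
    def genome_size_gbp(self) -> float:
        """Genome size rounded to one decimal in Gbp (report convenience)."""
        return round(self.genome_size / 1e9, 1)


def _smooth(counts: np.ndarray) -> np.ndarray:
    """Median-of-3 smoothing; endpoints copied through unchanged."""
    if len(counts) < 3:
        return counts.astype(float)
    out = counts.astype(float).copy()
    stacked = np.stack([counts[:-2], counts[1:-1], counts[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def find_error_cutoff(hist: KmerHistogram) -> int:
    """Coverage of the first local minimum above coverage 1.

    Scans the median-of-3 smoothed counts upward from the lowest coverage;
    a local minimum is a bin strictly below its left neighbor and not above
    its right neighbor. The valley must separate error mass from signal, so
    it only qualifies if some later bin rises above it (a peak exists to its
    right). If no such valley exists (monotone decreasing histogram) the
    cutoff is 1 with a warning.
    """
    if len(hist.coverages) == 0:
        raise ValueError("empty histogram")
    if len(hist.coverages) < 3:
        raise ValueError("histogram needs at least 3 bins")
    s = _smooth(hist.counts)
    for i in range(1, len(s) - 1):
        if s[i] < s[i - 1] and s[i] <= s[i + 1] and np.max(s[i + 1 :]) > s[i]:
            return int(hist.coverages[i])
    logger.warning("no error valley found below the mode; cutoff set to 1")
    return 1


def find_main_peak(hist: KmerHistogram, cutoff: int) -> int:
    """Coverage with the maximal smoothed count at coverage >= cutoff.

    Ties break toward the smaller coverage.
    """
    s = _smooth(hist.counts)
    mask = hist.coverages >= cutoff
    if not np.any(mask) or np.all(hist.counts[mask] == 0):
        raise ValueError("no k-mer mass above the error cutoff")
    sel = np.where(mask)[0]
    best = sel[int(np.argmax(s[sel]))]  # argmax returns the first maximum
    return int(hist.coverages[best])


def refine_peak(hist: KmerHistogram, cutoff: int, c: int, span: int = 3) -> float:
    """Sub-unit refinement of the main-peak depth from local count ratios.

    Under the standard model of k-mer coverage (each genomic position
    sequenced to Poisson depth mu), counts near the peak obey
    count(x+1)/count(x) = mu/(x+1), so each adjacent bin pair yields the
    depth estimate (x+1) * count(x+1)/count(x). The integer argmax of a
    discretized peak can be off by one (Poisson mass at mu-1 equals the
    mass at mu exactly); the median of these ratio estimates over bins
    within ``span`` of the argmax recovers mu without that grid bias.
    Falls back to the argmax when the ratios are unusable.
    """
    covs = hist.coverages
    counts = hist.counts.astype(float)
    pos = {int(x): i for i, x in enumerate(covs)}
    estimates = []
    for x in range(c - span, c + span):
        i, j = pos.get(x), pos.get(x + 1)
        if i is None or j is None or counts[i] <= 0 or counts[j] <= 0:
            continue
        estimates.append((x + 1) * counts[j] / counts[i])
    if not estimates:
        return float(c)
    mu = float(np.median(estimates))
    if not (0.75 * c <= mu <= 1.25 * c) or mu <= cutoff:
        return float(c)
    return mu


def estimate_genome_size(hist: KmerHistogram, cutoff: int, c: float) -> SizeEstimate:
    """G = T / c with T the instance mass at coverage >= cutoff."""
    if cutoff >= c:
        raise ValueError("error cutoff must lie below the main peak")
    mask = hist.coverages >= cutoff
    t = int(np.sum(hist.coverages[mask] * hist.counts[mask]))
    if t == 0:
        raise ValueError("zero k-mer instances above cutoff")
    c_int = int(round(c))
    return SizeEstimate(
        error_cutoff=cutoff,
        main_peak=c_int,
        total_instances=t,
        genome_size=t / c,
        subgenome_peaks=find_subgenome_peaks(hist, cutoff, c_int),
        refined_peak=None if c == c_int else float(c),
    )


def estimate_from_histogram(hist: KmerHistogram) -> SizeEstimate:
    """Full pipeline: error cutoff, main peak, centroid refinement, G = T/c."""
    cutoff = find_error_cutoff(hist)
    peak = find_main_peak(hist, cutoff)
    refined = refine_peak(hist, cutoff, peak)
    return estimate_genome_size(hist, cutoff, refined)


def find_subgenome_peaks(hist: KmerHistogram, cutoff: int, c: int) -> list[int]:
    """Local maxima near 2c and 3c (within +/- 0.25 c), if present.

    Absent peaks are simply not reported. A window's maximum counts as a
    peak only if it is an interior local maximum of the smoothed series
    (not a monotone shoulder of the main peak).
    """
    s = _smooth(hist.counts)
    covs = hist.coverages
    peaks: list[int] = []
    for m in (2, 3):
        lo, hi = m * c - 0.25 * c, m * c + 0.25 * c
        sel = np.where((covs >= max(lo, cutoff)) & (covs <= hi))[0]
        if len(sel) == 0:
            continue
        best = sel[int(np.argmax(s[sel]))]
        if 0 < best < len(s) - 1 and s[best] >= s[best - 1] and s[best] >= s[best + 1]:
            # require a genuine bump: strictly above at least one neighbor
            if s[best] > s[best - 1] or s[best] > s[best + 1]:
                peaks.append(int(covs[best]))
    return peaks


def fold_coverage(read_count: float, mean_read_length: float, genome_size: float) -> float:
    """Sequencing depth: reads x mean length / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if read_count < 0 or mean_read_length <= 0:
        raise ValueError("read count and length must be nonnegative/positive")
    return read_count * mean_read_length / genome_size


def size_report(est: SizeEstimate) -> str:
    """TSV report of the estimate (cutoff, c, T, G exact and rounded)."""
    lines = [
        "metric\tvalue",
        f"error_cutoff\t{est.error_cutoff}",
        f"main_peak_coverage\t{est.main_peak}",
        f"total_kmer_instances\t{est.total_instances}",
        f"genome_size_bp\t{est.genome_size:.0f}",
        f"genome_size_gbp_1dp\t{est.genome_size_gbp}",
        f"subgenome_peaks\t{','.join(map(str, est.subgenome_peaks)) or 'none'}",
    ]
    return "\n".join(lines) + "\n"
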