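"""Phasograms: distance histograms that reveal nucleosome phasing.

A read phasogram is the histogram of genomic distances between read
start positions mapped to the same strand; when cleavage is guided by
nucleosomes the phasogram shows a comb of peaks at multiples of the
nucleosome repeat length (~193 bp).  N-pile filtering keeps only start
positions observed at least N times — recurrent apoptotic cut sites —
which sharpens the comb considerably.

The dominant spacing is estimated by regressing detected peak positions
on their rank, mirroring the peak-position-vs-index insets used to read
the repeat length off a phasogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import linregress

from .histograms import DistanceHistogram

DEFAULT_MAX_DISTANCE = 2500
DEFAULT_PILE_ORDER = 3


def read_starts_from_fragments(frags: pd.DataFrame) -> pd.DataFrame:
    """Derive strand-assigned read starts from a fragment table.

    Each fragment contributes a plus-strand read start at its leftmost
    base and a minus-strand read start at its rightmost base
    (``end − 1``).
    """
    plus = pd.DataFrame({
        "chrom": frags["chrom"],
        "pos": frags["start"],
        "strand": "+",
    })
    minus = pd.DataFrame({
        "chrom": frags["chrom"],
        "pos": frags["end"] - 1,
        "strand": "-",
    })
    return pd.concat([plus, minus], ignore_index=True)


def _pair_distance_counts(positions: np.ndarray, max_distance: int,
                          counts: np.ndarray) -> None:
    """Accumulate pairwise distances of sorted unique positions <= max."""
    positions = np.sort(positions)
    n = positions.size
    for lag in range(1, n):
        d = positions[lag:] - positions[:-lag]
        d = d[d <= max_distance]
        if d.size == 0:
            break
        np.add.at(counts, d, 1)


def compute_phasogram(starts: pd.DataFrame, pile_order: int = DEFAULT_PILE_ORDER,
                      max_distance: int = DEFAULT_MAX_DISTANCE) -> DistanceHistogram:
    """N-pile read phasogram.

    Within each (chromosome, strand) group, positions with multiplicity
    >= ``pile_order`` are retained (each counted once thereafter) and
    every ordered pair of retained positions at distance 1..max_distance
    increments the histogram.
    """
    if pile_order < 1:
        raise ValueError("pile_order must be >= 1")
    counts = np.zeros(max_distance + 1, dtype=np.int64)
    for _, group in starts.groupby(["chrom", "strand"], sort=True):
        pos, mult = np.unique(group["pos"].to_numpy(np.int64), return_counts=True)
        retained = pos[mult >= pile_order]
        _pair_distance_counts(retained, max_distance, counts)
    return DistanceHistogram(counts, pile_order=pile_order)


@dataclass
class SpacingEstimate:
    """Dominant spacing from a distance histogram.

    ``spacing`` is the slope of peak position regressed on peak index;
    ``r`` the correlation coefficient of that fit.
    """

    spacing: float
    peak_positions: np.ndarray
    r: float

    def __post_init__(self) -> None:
        self.peak_positions = np.asarray(self.peak_positions, dtype=np.int64)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def estimate_spacing(hist: DistanceHistogram, smooth_sd: float = 10.0,
                     min_separation: int = 100, min_lag: int = 100,
                     prominence_frac: float = 0.05) -> SpacingEstimate:
    """Estimate the dominant spacing of a phasogram comb.

    The histogram is smoothed with a Gaussian (sd ``smooth_sd``), local
    maxima at least ``min_separation`` apart are detected (ignoring
    distances below ``min_lag``, where co-located-cluster mass lives),
    and the spacing is the regression slope of peak position on index.
    """
    smooth = gaussian_filter1d(hist.counts.astype(float), smooth_sd)
    search = smooth[min_lag:]
    prominence = prominence_frac * (search.max() - search.min())
    peaks, _ = find_peaks(search, distance=min_separation, prominence=prominence)
    peaks = peaks + min_lag
    if peaks.size < 2:
        raise ValueError(
            f"need >= 2 detectable peaks to estimate spacing, found {peaks.size}"
        )
    fit = linregress(np.arange(peaks.size), peaks)
    return SpacingEstimate(float(fit.slope), peaks, float(fit.rvalue))


def peak_distance_histogram(dyads, max_distance: int = DEFAULT_MAX_DISTANCE,
                            smooth_sd: float = 10.0
                            ) -> tuple[DistanceHistogram, SpacingEstimate]:
    """Histogram of distances between called nucleosome peak dyads.

    ``dyads`` may be an array of dyad coordinates or a list of objects
    with a ``dyad`` attribute.  All peak pairs within ``max_distance``
    are counted; the spacing estimate runs on the resulting histogram.
    """
    arr = np.asarray(
        [p.dyad if hasattr(p, "dyad") else p for p in dyads], dtype=np.int64
    )
    if arr.size < 2:
        raise ValueError("need at least two peaks")
    counts = np.zeros(max_distance + 1, dtype=np.int64)
    _pair_distance_counts(arr, max_distance, counts)
    hist = DistanceHistogram(counts, pile_order=1)
    return hist, estimate_spacing(hist, smooth_sd=smooth_sd)


@dataclass
class PeriodicityResult:
    """Sub-peak periodicity below the major length mode.

    ``found`` is False when fewer than three sub-peaks were detected, in
    which case ``period`` is NaN.
    """

    period: float
    peak_positions: np.ndarray
    found: bool


def subpeak_periodicity(length_hist: DistanceHistogram, low: int = 90,
                        high: int | None = None, detrend_sd: float = 15.0
                        ) -> PeriodicityResult:
    """Period of the minor length modes below the major fragment peak.

    The length histogram is restricted to ``low .. high`` (default: up
    to 5 bp below the histogram mode), detrended by subtracting a heavy
    Gaussian smooth (sd ``detrend_sd``), and local maxima at least 5 bp
    apart with prominence above the Poisson noise scale are detected.
    The period is the mean difference of consecutive maxima; fewer than
    three maxima yield an undefined-flagged result.
    """
    counts = length_hist.counts.astype(float)
    if high is None:
        high = int(np.argmax(counts)) - 5
    if high - low < 10 or counts.size <= low:
        return PeriodicityResult(float("nan"), np.array([], dtype=np.int64), False)
    segment = counts[low:high + 1]
    detrended = segment - gaussian_filter1d(segment, detrend_sd)
    prominence = 4.0 * np.sqrt(segment.mean() + 1.0)
    peaks, _ = find_peaks(detrended, distance=5, prominence=prominence)
    positions = peaks + low
    if positions.size < 3:
        return PeriodicityResult(float("nan"), positions, False)
    period = float(np.mean(np.diff(positions)))
    return PeriodicityResult(period, positions, True)
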