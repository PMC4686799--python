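"""Nucleosome peak calling from trimmed-fragment dyad density.

Dyads of trimmed fragments are counted per base, smoothed with a
Gaussian kernel, and local maxima above a multiple of the regional mean
density are accepted greedily (highest density first) subject to a
147 bp minimum dyad separation, so that the ±73 bp footprints of
accepted peaks never overlap.  A peak's stringency is its smoothed
density relative to the regional mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import ttest_ind

from .regions import Region, intersect_length

logger = logging.getLogger(__name__)

FOOTPRINT_HALF = 73          # footprint = dyad ± 73, 147 bases inclusive
FOOTPRINT_SIZE = 2 * FOOTPRINT_HALF + 1
MIN_SEPARATION = FOOTPRINT_SIZE
DEFAULT_BANDWIDTH = 30.0


@dataclass
class NucleosomePeak:
    """A called nucleosome dyad with its 147 bp footprint."""

    chrom: str
    dyad: int
    stringency: float

    @property
    def start(self) -> int:
        """Footprint start (half-open: [dyad-73, dyad+74))."""
        return self.dyad - FOOTPRINT_HALF

    @property
    def end(self) -> int:
        return self.dyad + FOOTPRINT_HALF + 1


def _dyad_array(trimmed) -> tuple[np.ndarray, str | None]:
    """Accept a trimmed-fragment DataFrame, TrimmedFragment list or array."""
    if isinstance(trimmed, pd.DataFrame):
        chrom = trimmed["chrom"].iloc[0] if len(trimmed) else None
        return trimmed["dyad"].to_numpy(np.int64), chrom
    if len(trimmed) and hasattr(trimmed[0], "dyad"):
        return (np.asarray([t.dyad for t in trimmed], dtype=np.int64),
                trimmed[0].chrom)
    return np.asarray(trimmed, dtype=np.int64), None


def call_peaks(trimmed, region: Region, bandwidth: float = DEFAULT_BANDWIDTH,
               threshold: float = 1.0) -> list[NucleosomePeak]:
    """Call nucleosome peaks within one region.

    Parameters
    ----------
    trimmed
        Trimmed fragments (DataFrame with a ``dyad`` column, list of
        :class:`~cfdnafrag.fragmentio.TrimmedFragment`, or dyad array).
    region
        The calling region; dyads outside it are ignored.
    bandwidth
        Gaussian kernel sd (bases) for smoothing the dyad-count signal.
    threshold
        Candidate maxima must reach ``threshold ×`` the regional mean
        smoothed density.

    Returns peaks sorted by dyad, with successive dyads >= 147 bp apart.
    """
    dyads, chrom = _dyad_array(trimmed)
    chrom = chrom if chrom is not None else region.chrom
    dyads = dyads[(dyads >= region.start) & (dyads < region.end)]
    if dyads.size == 0:
        return []
    signal = np.bincount(dyads - region.start, minlength=region.length).astype(float)
    smooth = gaussian_filter1d(signal, bandwidth, mode="constant")
    mean_density = smooth.mean()
    if mean_density <= 0:
        raise ValueError("regional mean density is zero")

    candidates, _ = find_peaks(smooth, height=threshold * mean_density)
    order = np.argsort(smooth[candidates], kind="stable")[::-1]
    accepted: list[int] = []
    accepted_sorted: list[int] = []
    for idx in candidates[order]:
        pos = int(idx)
        i = np.searchsorted(accepted_sorted, pos)
        if i > 0 and pos - accepted_sorted[i - 1] < MIN_SEPARATION:
            continue
        if i < len(accepted_sorted) and accepted_sorted[i] - pos < MIN_SEPARATION:
            continue
        accepted_sorted.insert(i, pos)
        accepted.append(pos)

    return [
        NucleosomePeak(chrom, region.start + pos, float(smooth[pos] / mean_density))
        for pos in sorted(accepted)
    ]


def peaks_to_bed(peaks: list[NucleosomePeak]) -> pd.DataFrame:
    """BED6 representation: score = stringency × 100, clamped to 0..1000."""
    return pd.DataFrame({
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "name": [f"peak_{i}" for i in range(len(peaks))],
        "score": [int(min(max(p.stringency * 100, 0), 1000)) for p in peaks],
        "strand": ".",
    })


def occupancy_fraction(peaks: list[NucleosomePeak], regions: pd.DataFrame) -> float:
    """Fraction of the regions' bases covered by peak footprints.

    Overlapping footprints are merged before summing, so the result is
    always in [0, 1].
    """
    if len(regions) == 0:
        raise ValueError("no regions")
    total = int((regions["end"] - regions["start"]).sum())
    if total <= 0:
        raise ValueError("regions have zero total length")
    covered = 0
    peak_df = pd.DataFrame({
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
    })
    for chrom, reg in regions.groupby("chrom"):
        sel = peak_df.loc[peak_df["chrom"] == chrom]
        if len(sel) == 0:
            continue
        covered += intersect_length(
            sel["start"].to_numpy(), sel["end"].to_numpy(),
            reg["start"].to_numpy(), reg["end"].to_numpy(),
        )
    return covered / total


@dataclass
class GcProfile:
    """Positional GC content across peak footprints.

    ``per_offset`` holds the mean GC fraction at each footprint offset
    −73..+73 across all usable peaks; ``per_peak`` the mean GC of each
    peak's footprint; ``mean``/``sd`` summarise ``per_peak``.
    """

    per_offset: np.ndarray
    per_peak: np.ndarray
    n_skipped: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-FOOTPRINT_HALF, FOOTPRINT_HALF + 1)

    @property
    def mean(self) -> float:
        return float(self.per_peak.mean())

    @property
    def sd(self) -> float:
        return float(self.per_peak.std(ddof=1)) if self.per_peak.size > 1 else 0.0


def gc_profile(peaks: list[NucleosomePeak], genome) -> GcProfile:
    """Per-offset mean GC fraction over peak footprints.

    ``genome`` is any mapping from chromosome name to a sliceable
    sequence (a dict of strings, or a ``pyfaidx.Fasta``).  Peaks whose
    footprint falls outside the available sequence are skipped and
    counted.
    """
    rows = []
    skipped = 0
    for p in peaks:
        try:
            seq = str(genome[p.chrom][p.start:p.end]).upper()
        except (KeyError, IndexError):
            skipped += 1
            continue
        if len(seq) != FOOTPRINT_SIZE:
            skipped += 1
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        rows.append((arr == ord("G")) | (arr == ord("C")))
    if skipped:
        logger.info("gc_profile skipped %d peaks without full sequence", skipped)
    if not rows:
        raise ValueError("no peaks with usable sequence")
    mat = np.asarray(rows, dtype=float)
    return GcProfile(mat.mean(axis=0), mat.mean(axis=1), skipped)


def compare_gc(a: GcProfile, b: GcProfile) -> tuple[float, float, float]:
    """Difference of mean per-peak GC between two peak sets.

    Returns (mean difference, Welch t statistic, two-sided p-value).
    """
    t, p = ttest_ind(a.per_peak, b.per_peak, equal_var=False)
    return a.mean - b.mean, float(t), float(p)


def load_genome(path: str):
    """Open an indexed FASTA as a chrom → sequence mapping."""
    from pyfaidx import Fasta

    return Fasta(path)
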