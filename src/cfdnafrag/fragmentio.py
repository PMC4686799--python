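"""Fragment ingestion: pairing, filtering, dyad trimming, coverage.

The unit of all downstream counting is a sequenced cfDNA fragment — the
outer span of a properly paired read pair (leftmost start, rightmost
end), 0-based half-open.  Filtering follows the standard cfDNA rules:
unpaired and secondary/supplementary records are dropped, as are
fragments longer than 1000 bp (necrotic/artefactual tail).  For peak
calling, fragments are trimmed to an 80 bp window centred on the dyad
(fragment midpoint), which sharpens the nucleosome positioning signal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .histograms import DistanceHistogram
from .regions import Region

logger = logging.getLogger(__name__)

MAX_INSERT = 1000       # fragments longer than this are removed
TRIM_HALF = 40          # trim to dyad ± 40 bp (80 bp total)
MONO_MAX = 250          # mono fraction: length < 250
DI_MAX = 350            # di fraction: 250 <= length <= 350

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length"]


class FragmentRecord(NamedTuple):
    """One cfDNA fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class TrimmedFragment(NamedTuple):
    """An 80 bp window centred on a fragment's dyad."""

    chrom: str
    dyad: int

    @property
    def start(self) -> int:
        return self.dyad - TRIM_HALF

    @property
    def end(self) -> int:
        return self.dyad + TRIM_HALF


def pair_and_filter(alignments: Iterable, max_insert: int = MAX_INSERT
                    ) -> tuple[pd.DataFrame, Counter]:
    """Couple read pairs into fragments and apply the standard filters.

    Parameters
    ----------
    alignments
        An iterable of :class:`pysam.AlignedSegment` (e.g. a
        ``pysam.AlignmentFile``), any sort order.
    max_insert
        Fragments strictly longer than this are dropped (default 1000 bp;
        a fragment of exactly ``max_insert`` is kept).

    Returns
    -------
    (fragments, dropped)
        A BED-like fragment table and a Counter of dropped records by
        reason (``unpaired``, ``secondary``, ``unmapped``, ``too_long``,
        ``malformed``).
    """
    dropped: Counter = Counter()
    pending: dict[str, tuple[str, int, int]] = {}
    rows: list[tuple[str, int, int]] = []

    for aln in alignments:
        try:
            if aln.is_secondary or aln.is_supplementary:
                dropped["secondary"] += 1
                continue
            if aln.is_unmapped:
                dropped["unmapped"] += 1
                continue
            if not aln.is_paired:
                dropped["unpaired"] += 1
                continue
            key = aln.query_name
            this = (aln.reference_name, aln.reference_start, aln.reference_end)
            if this[0] is None or this[1] is None or this[2] is None:
                dropped["malformed"] += 1
                continue
        except (AttributeError, ValueError):
            dropped["malformed"] += 1
            continue
        mate = pending.pop(key, None)
        if mate is None:
            pending[key] = this
            continue
        if mate[0] != this[0]:
            dropped["unpaired"] += 2
            continue
        start = min(mate[1], this[1])
        end = max(mate[2], this[2])
        if end - start > max_insert:
            dropped["too_long"] += 1
            continue
        rows.append((this[0], start, end))

    # reads whose mate never appeared
    dropped["unpaired"] += len(pending)
    if dropped:
        logger.info("pair_and_filter dropped records: %s", dict(dropped))

    frags = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frags["length"] = frags["end"] - frags["start"]
    return frags, dropped


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Load a BED3(+) fragment table; pairing is assumed already done."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["length"] = df["end"] - df["start"]
    return df


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    frags[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def trim_to_dyad(frag: FragmentRecord | tuple) -> TrimmedFragment:
    """Trim a fragment to dyad ± 40 bp.

    The dyad is ``start + floor(length / 2)``; the output always spans
    exactly 80 bp.  Fragments shorter than 80 bp cannot be trimmed.
    """
    chrom, start, end = frag[0], frag[1], frag[2]
    length = end - start
    if length < 2 * TRIM_HALF:
        raise ValueError(f"fragment of length {length} < {2 * TRIM_HALF} cannot be trimmed")
    return TrimmedFragment(chrom, start + length // 2)


def trim_fragments(frags: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Vectorised :func:`trim_to_dyad` over a fragment table.

    Fragments shorter than 80 bp are dropped (their count is returned
    alongside).  Output columns: chrom, dyad, start, end.
    """
    ok = frags["length"] >= 2 * TRIM_HALF
    n_dropped = int((~ok).sum())
    kept = frags.loc[ok]
    dyad = (kept["start"] + kept["length"] // 2).to_numpy(dtype=np.int64)
    out = pd.DataFrame({
        "chrom": kept["chrom"].to_numpy(),
        "dyad": dyad,
        "start": dyad - TRIM_HALF,
        "end": dyad + TRIM_HALF,
    })
    return out, n_dropped


@dataclass
class CoverageTrack:
    """Per-base fragment coverage over one region."""

    region: Region
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size != self.region.length:
            raise ValueError("values length must equal region length")


def build_coverage(frags: pd.DataFrame, region: Region) -> CoverageTrack:
    """Count, for every base of ``region``, the fragments overlapping it.

    Fragments are clipped to the region; fragments on other chromosomes
    are ignored.  Runs in O(n + L) via a difference array.
    """
    sel = frags.loc[frags["chrom"] == region.chrom]
    start = np.clip(sel["start"].to_numpy(np.int64), region.start, region.end)
    end = np.clip(sel["end"].to_numpy(np.int64), region.start, region.end)
    keep = end > start
    start, end = start[keep], end[keep]
    diff = np.zeros(region.length + 1, dtype=np.int64)
    np.add.at(diff, start - region.start, 1)
    np.add.at(diff, end - region.start, -1)
    return CoverageTrack(region, np.cumsum(diff[:-1]))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as bedGraph (runs of equal value)."""
    v = track.values
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], change]) + track.region.start
    ends = np.concatenate([change, [v.size]]) + track.region.start
    pd.DataFrame({
        "chrom": track.region.chrom,
        "start": starts,
        "end": ends,
        "value": v[starts - track.region.start],
    }).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class LengthSummary:
    """Fragment-length histogram plus mono/di fraction summaries.

    ``major_mean`` is the mean length of fragments shorter than 250 bp
    (mononucleosome fraction); ``minor_mean`` the mean of fragments in
    250..350 bp inclusive (dinucleosome fraction).  A fraction with no
    members has a NaN mean and its ``*_defined`` flag is False.
    """

    histogram: DistanceHistogram
    major_mean: float
    minor_mean: float
    n_major: int
    n_minor: int

    @property
    def major_defined(self) -> bool:
        return self.n_major > 0

    @property
    def minor_defined(self) -> bool:
        return self.n_minor > 0


def length_histogram(frags: pd.DataFrame) -> LengthSummary:
    """Integer-binned length histogram with mono/di summaries."""
    if len(frags) == 0:
        raise ValueError("no fragments")
    lengths = frags["length"].to_numpy(np.int64)
    counts = np.bincount(lengths)
    hist = DistanceHistogram(counts, label="length")
    major = lengths[lengths < MONO_MAX]
    minor = lengths[(lengths >= MONO_MAX) & (lengths <= DI_MAX)]
    return LengthSummary(
        histogram=hist,
        major_mean=float(major.mean()) if major.size else float("nan"),
        minor_mean=float(minor.mean()) if minor.size else float("nan"),
        n_major=int(major.size),
        n_minor=int(minor.size),
    )


def mono_di_split(frags: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fragments into the mono (<250) and di (250..350) fractions.

    Fragments longer than 350 bp belong to neither and are discarded.
    """
    mono = frags.loc[frags["length"] < MONO_MAX]
    di = frags.loc[(frags["length"] >= MONO_MAX) & (frags["length"] <= DI_MAX)]
    return mono, di
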