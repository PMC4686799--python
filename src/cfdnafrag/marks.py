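"""Association of called peaks with epigenetic-mark intervals.

Tests whether nucleosome peaks intersect mark intervals (histone
modifications, Pol II, ...) more often than equally many random 147 bp
sites placed uniformly within the targeted regions — a permutation test
for genomic-interval overlap enrichment.  One-sided, with the add-one
empirical p-value, so p is never smaller than 1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peakcall import FOOTPRINT_SIZE, NucleosomePeak
from .regions import contained_in_any, merge_intervals, overlaps_any


@dataclass
class AssociationResult:
    """Outcome of one peak-vs-mark permutation test."""

    observed: float
    null_mean: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


def _merged_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, g in df.groupby("chrom"):
        out[chrom] = merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
    return out


def _overlap_fraction(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                      merged_marks: dict) -> float:
    hits = np.zeros(starts.size, dtype=bool)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        if chrom in merged_marks:
            ms, me = merged_marks[chrom]
            hits[sel] = overlaps_any(starts[sel], ends[sel], ms, me)
    return float(hits.mean())


def mark_association_test(peaks: list[NucleosomePeak], marks: pd.DataFrame,
                          targeted_regions: pd.DataFrame,
                          n_permutations: int = 999, seed: int = 0
                          ) -> AssociationResult:
    """Permutation test of peak/mark overlap against random placement.

    The statistic is the fraction of peak footprints intersecting at
    least one mark interval.  The null places the same number of 147 bp
    sites uniformly at random wholly inside the targeted regions
    (regions chosen proportional to placeable length) and recomputes the
    statistic ``n_permutations`` times;
    p = (1 + #{null >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if len(marks) == 0:
        raise ValueError("no mark intervals supplied")
    if len(peaks) == 0:
        raise ValueError("no peaks supplied")

    p_chrom = np.asarray([p.chrom for p in peaks])
    p_start = np.asarray([p.start for p in peaks], dtype=np.int64)
    p_end = np.asarray([p.end for p in peaks], dtype=np.int64)

    merged_regions = _merged_by_chrom(targeted_regions)
    for chrom in np.unique(p_chrom):
        sel = p_chrom == chrom
        if chrom not in merged_regions:
            raise ValueError(f"peaks on {chrom} outside targeted regions")
        rs, re = merged_regions[chrom]
        if not contained_in_any(p_start[sel], p_end[sel], rs, re).all():
            raise ValueError("peak footprints must lie wholly inside targeted regions")

    merged_marks = _merged_by_chrom(marks)
    observed = _overlap_fraction(p_chrom, p_start, p_end, merged_marks)

    # placeable start ranges per merged region
    reg_chrom, reg_start, reg_len = [], [], []
    for chrom, (rs, re) in merged_regions.items():
        lengths = re - rs - FOOTPRINT_SIZE + 1
        ok = lengths > 0
        reg_chrom.extend([chrom] * int(ok.sum()))
        reg_start.extend(rs[ok])
        reg_len.extend(lengths[ok])
    reg_chrom = np.asarray(reg_chrom)
    reg_start = np.asarray(reg_start, dtype=np.int64)
    reg_len = np.asarray(reg_len, dtype=np.int64)
    if reg_len.size == 0:
        raise ValueError("no targeted region can hold a 147 bp site")

    rng = np.random.default_rng(seed)
    n_peaks = len(peaks)
    weights = reg_len / reg_len.sum()
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        ridx = rng.choice(reg_len.size, size=n_peaks, p=weights)
        offs = np.floor(rng.random(n_peaks) * reg_len[ridx]).astype(np.int64)
        s = reg_start[ridx] + offs
        null[i] = _overlap_fraction(reg_chrom[ridx], s, s + FOOTPRINT_SIZE,
                                    merged_marks)
    p = (1 + int(np.sum(null >= observed - 1e-12))) / (n_permutations + 1)
    return AssociationResult(observed, float(null.mean()), p, n_permutations)


def association_table(peaks_by_sample: dict[str, list[NucleosomePeak]],
                      marks_by_name: dict[str, pd.DataFrame],
                      targeted_regions: pd.DataFrame,
                      n_permutations: int = 999, seed: int = 0,
                      alpha: float = 0.01) -> pd.DataFrame:
    """Mark × sample association matrix.

    One permutation test per (mark, sample) cell; the ``significant``
    column uses the "+" convention at ``alpha`` with no multiplicity
    correction, and a Bonferroni-adjusted p is emitted alongside for
    reference.
    """
    n_tests = len(peaks_by_sample) * len(marks_by_name)
    rows = []
    for m_i, (mark, marks) in enumerate(marks_by_name.items()):
        for s_i, (sample, peaks) in enumerate(peaks_by_sample.items()):
            res = mark_association_test(
                peaks, marks, targeted_regions,
                n_permutations=n_permutations,
                seed=seed + 1000 * m_i + s_i,
            )
            rows.append({
                "mark": mark,
                "sample": sample,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "p": res.p_value,
                "p_bonferroni": min(res.p_value * n_tests, 1.0),
                "significant": "+" if res.p_value < alpha else "",
            })
    return pd.DataFrame(rows)
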