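"""Genomic interval primitives shared across modules.

All coordinates are 0-based, half-open ``[start, end)``; an interval's
length is ``end - start``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class Region(NamedTuple):
    """A half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping intervals into a sorted disjoint union.

    Abutting intervals (``end == next start``) are merged, so the result is
    the minimal set of disjoint intervals covering the same bases.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # an interval opens a new block iff its start exceeds the running max end
    running_end = np.maximum.accumulate(ends)
    new_block = np.ones(starts.size, dtype=bool)
    new_block[1:] = starts[1:] > running_end[:-1]
    block_id = np.cumsum(new_block) - 1
    merged_starts = starts[new_block]
    merged_ends = np.zeros(merged_starts.size, dtype=np.int64)
    np.maximum.at(merged_ends, block_id, ends)
    return merged_starts, merged_ends


def union_length(starts, ends) -> int:
    """Total number of bases covered by the union of the intervals."""
    ms, me = merge_intervals(starts, ends)
    return int(np.sum(me - ms))


def intersect_length(a_starts, a_ends, b_starts, b_ends) -> int:
    """Length of (union A) ∩ (union B) via an event sweep."""
    a_starts = np.asarray(a_starts, dtype=np.int64)
    b_starts = np.asarray(b_starts, dtype=np.int64)
    a_ends = np.asarray(a_ends, dtype=np.int64)
    b_ends = np.asarray(b_ends, dtype=np.int64)
    if a_starts.size == 0 or b_starts.size == 0:
        return 0
    pos = np.concatenate([a_starts, a_ends, b_starts, b_ends])
    d_a = np.concatenate(
        [
            np.ones(a_starts.size, dtype=np.int64),
            -np.ones(a_ends.size, dtype=np.int64),
            np.zeros(b_starts.size + b_ends.size, dtype=np.int64),
        ]
    )
    d_b = np.concatenate(
        [
            np.zeros(a_starts.size + a_ends.size, dtype=np.int64),
            np.ones(b_starts.size, dtype=np.int64),
            -np.ones(b_ends.size, dtype=np.int64),
        ]
    )
    order = np.argsort(pos, kind="stable")
    pos, d_a, d_b = pos[order], d_a[order], d_b[order]
    depth_a = np.cumsum(d_a)
    depth_b = np.cumsum(d_b)
    seg = pos[1:] - pos[:-1]
    active = (depth_a[:-1] > 0) & (depth_b[:-1] > 0)
    return int(np.sum(seg[active]))


def overlaps_any(q_starts, q_ends, merged_starts, merged_ends) -> np.ndarray:
    """For each query interval, whether it intersects the merged interval set.

    ``merged_*`` must come from :func:`merge_intervals` (sorted, disjoint).
    Returns a boolean array aligned with the queries.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if merged_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    # first merged interval whose end is strictly after the query start
    idx = np.searchsorted(merged_ends, q_starts, side="right")
    hit = idx < merged_starts.size
    out = np.zeros(q_starts.size, dtype=bool)
    out[hit] = merged_starts[idx[hit]] < q_ends[hit]
    return out


def contained_in_any(q_starts, q_ends, merged_starts, merged_ends) -> np.ndarray:
    """Whether each query interval lies wholly inside one merged interval."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if merged_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    idx = np.searchsorted(merged_starts, q_starts, side="right") - 1
    ok = idx >= 0
    out = np.zeros(q_starts.size, dtype=bool)
    out[ok] = q_ends[ok] <= merged_ends[idx[ok]]
    return out


def complement_within(starts, ends, region_start: int, region_end: int):
    """Gaps of ``[region_start, region_end)`` not covered by the intervals."""
    ms, me = merge_intervals(starts, ends)
    ms = np.clip(ms, region_start, region_end)
    me = np.clip(me, region_start, region_end)
    keep = me > ms
    ms, me = ms[keep], me[keep]
    gap_starts = np.concatenate([[region_start], me])
    gap_ends = np.concatenate([ms, [region_end]])
    keep = gap_ends > gap_starts
    return gap_starts[keep], gap_ends[keep]
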