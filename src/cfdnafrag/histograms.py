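"""Integer-binned distance/length histograms.

The same container backs read phasograms, peak-to-peak distance histograms
and fragment-length histograms: counts indexed directly by the integer
distance (or length) in base pairs, bin width 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DistanceHistogram:
    """Counts per integer distance ``0..max_distance`` (bin width 1 bp)."""

    counts: np.ndarray
    pile_order: int = 1
    label: str = "distance"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def max_distance(self) -> int:
        return self.counts.size - 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.label: np.arange(self.counts.size), "count": self.counts}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_pairs(cls, values, counts, *, pile_order: int = 1, label: str = "distance"):
        """Build from sparse (value, count) pairs."""
        values = np.asarray(values, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        size = int(values.max()) + 1 if values.size else 1
        dense = np.zeros(size, dtype=np.int64)
        np.add.at(dense, values, counts)
        return cls(dense, pile_order=pile_order, label=label)

    @classmethod
    def read_tsv(cls, path: str | Path, *, pile_order: int = 1):
        df = pd.read_csv(path, sep="\t")
        label = df.columns[0]
        return cls.from_pairs(
            df[label].to_numpy(), df["count"].to_numpy(), pile_order=pile_order, label=label
        )
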