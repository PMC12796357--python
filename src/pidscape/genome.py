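"""Genome layout and interval primitives shared by all stages.

All coordinates are 0-based half-open (BED convention); bins are indexed by
their start coordinate divided by the bin size. The last bin of a chromosome
may be partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomeLayout:
    """Fixed-bin partition of a genome.

    Parameters
    ----------
    chrom_names : tuple of str
    chrom_lengths : tuple of int
        Lengths in bp, parallel to ``chrom_names``.
    bin_size : int
        Bin width in bp (default 1000).
    """

    chrom_names: tuple
    chrom_lengths: tuple
    bin_size: int = 1000

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for length in self.chrom_lengths:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
        object.__setattr__(
            self, "chrom_names", tuple(str(c) for c in self.chrom_names)
        )
        object.__setattr__(
            self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths)
        )

    @property
    def lengths(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        return self.lengths[chrom]

    def n_bins(self, chrom: str) -> int:
        # last partial bin kept
        length = self.length_of(chrom)
        return -(-length // self.bin_size)

    def bin_of(self, chrom: str, pos: int) -> int:
        if pos < 0 or pos >= self.length_of(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_start(self, b: int) -> int:
        return b * self.bin_size

    def bin_interval(self, chrom: str, b: int) -> tuple:
        start = b * self.bin_size
        return start, min(start + self.bin_size, self.length_of(chrom))

    def __eq__(self, other):
        return (
            isinstance(other, GenomeLayout)
            and self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )

    def __hash__(self):
        return hash((self.chrom_names, self.chrom_lengths, self.bin_size))


def read_bed(path) -> pd.DataFrame:
    """Read a BED(3-6) file into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: BED interval with end <= start")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def merge_intervals(starts, ends):
    """Merge overlapping (not merely abutting) half-open intervals.

    Returns (starts, ends) as int arrays sorted by start.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < out_e[-1]:  # strict: abutting intervals stay separate
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def intervals_overlap(s1, e1, s2, e2) -> bool:
    """True iff [s1,e1) and [s2,e2) share >= 1 base."""
    return s1 < e2 and s2 < e1


def mask_bins(layout: GenomeLayout, mask: pd.DataFrame, chrom: str) -> np.ndarray:
    """Bins of `chrom` fully contained in the mask intervals."""
    bs = layout.bin_size
    sel = mask[mask["chrom"] == chrom]
    bins = []
    for s, e in zip(sel["start"], sel["end"]):
        first = -(-int(s) // bs)  # ceil: bin fully inside
        last = int(e) // bs  # exclusive
        if last > first:
            bins.append(np.arange(first, last))
    if not bins:
        return np.array([], dtype=np.int64)
    out = np.unique(np.concatenate(bins))
    return out[out < layout.n_bins(chrom)]
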