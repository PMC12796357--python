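"""Shared viewpoint-profile extraction used by the background fit and the caller."""

from __future__ import annotations

import numpy as np


def smooth_truncated(values: np.ndarray, avg_bins: int) -> np.ndarray:
    """Centered running mean of width `avg_bins`, truncated at the edges.

    At position b the mean is taken over the window [b-h, b+h] intersected
    with the array, h = avg_bins // 2.
    """
    if avg_bins < 1:
        raise ValueError("avg_bins must be >= 1")
    if avg_bins == 1:
        return values.astype(np.float64, copy=True)
    kernel = np.ones(avg_bins)
    sums = np.convolve(values, kernel, mode="same")
    norms = np.convolve(np.ones_like(values, dtype=np.float64), kernel, mode="same")
    return sums / norms


def window_profile(matrix, chrom, viewpoint_bins, center_bin, range_bins, avg_bins):
    """Raw/relative/smoothed interaction profile around a viewpoint.

    Returns (offsets, raw, rel, smoothed, total):
      offsets  signed distances in bins from `center_bin` (clipped at ends)
      raw      per-bin counts summed over viewpoint rows
      rel      raw / total (window sum)
      smoothed truncated centered running mean of rel
    Raises ValueError if the window total is 0.
    """
    n = matrix.layout.n_bins(chrom)
    viewpoint_bins = np.asarray(viewpoint_bins, dtype=np.int64)
    if viewpoint_bins.size == 0:
        raise ValueError("empty viewpoint")
    if viewpoint_bins.min() < 0 or viewpoint_bins.max() >= n:
        raise ValueError("viewpoint bin outside layout")
    lo = max(0, center_bin - range_bins)
    hi = min(n, center_bin + range_bins + 1)
    sym = matrix.sym_csr(chrom)
    raw = np.asarray(
        sym[viewpoint_bins, lo:hi].sum(axis=0)
    ).ravel().astype(np.float64)
    total = raw.sum()
    if total == 0:
        raise ValueError("window total is 0 (viewpoint should have failed QC)")
    rel = raw / total
    smoothed = smooth_truncated(rel, avg_bins)
    offsets = np.arange(lo, hi, dtype=np.int64) - center_bin
    return offsets, raw, rel, smoothed, float(total)


def viewpoint_row_nonzero(matrix, chrom, viewpoint_bins, fixate_bins):
    """Fraction of bins within +-fixate_bins (viewpoint bins excluded) with
    nonzero summed viewpoint-row count."""
    n = matrix.layout.n_bins(chrom)
    viewpoint_bins = np.asarray(viewpoint_bins, dtype=np.int64)
    center = int(np.round(viewpoint_bins.mean()))
    lo = max(0, center - fixate_bins)
    hi = min(n, center + fixate_bins + 1)
    sym = matrix.sym_csr(chrom)
    row = np.asarray(sym[viewpoint_bins, lo:hi].sum(axis=0)).ravel()
    bins = np.arange(lo, hi)
    keep = ~np.isin(bins, viewpoint_bins)
    if keep.sum() == 0:
        return 0.0
    return float((row[keep] != 0).mean())
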