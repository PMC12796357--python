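"""Per-distance negative-binomial background of relative interaction
frequencies, estimated from random single-bin regions in inactive chromatin,
with far-field flattening and viewpoint quality control."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._profile import viewpoint_row_nonzero, window_profile
from .genome import GenomeLayout, mask_bins


@dataclass
class QCResult:
    viewpoint_id: str
    sparsity: float
    passed: bool

    def __post_init__(self):
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must be in [0, 1]")


@dataclass
class BackgroundModel:
    """Method-of-moments (mu, var) of relative interaction frequency per
    signed bin offset, over background regions, optionally far-field
    flattened."""

    bin_size: int
    offsets: np.ndarray  # signed distances in bins, -R..R
    mu: np.ndarray
    var: np.ndarray
    n: np.ndarray
    fixate_range: int = 200_000
    flattened: np.ndarray = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.flattened is None:
            self.flattened = np.zeros(self.offsets.size, dtype=bool)
        if np.any(self.mu < 0):
            raise ValueError("mu must be non-negative")

    def lookup(self, offsets_bins) -> tuple:
        """(mu, var) aligned to the requested signed bin offsets."""
        idx = np.searchsorted(self.offsets, offsets_bins)
        bad = (
            (idx < 0)
            | (idx >= self.offsets.size)
            | (self.offsets[np.clip(idx, 0, self.offsets.size - 1)] != offsets_bins)
        )
        if np.any(bad):
            raise ValueError("offset outside background model coverage")
        return self.mu[idx], self.var[idx]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "offset_bp": self.offsets * self.bin_size,
                "mu": self.mu,
                "var": self.var,
                "n": self.n,
                "flattened": self.flattened.astype(int),
            }
        )
        with open(path, "w") as fh:
            fh.write(
                f"# pidscape_background\tbin_size={self.bin_size}"
                f"\tfixate_range={self.fixate_range}\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BackgroundModel":
        with open(path) as fh:
            header = fh.readline()
            fields = dict(
                tok.split("=", 1) for tok in header.strip().split("\t")[1:] if "=" in tok
            )
            df = pd.read_csv(fh, sep="\t")
        bin_size = int(fields["bin_size"])
        return cls(
            bin_size=bin_size,
            offsets=df["offset_bp"].to_numpy() // bin_size,
            mu=df["mu"].to_numpy(),
            var=df["var"].to_numpy(),
            n=df["n"].to_numpy(),
            fixate_range=int(fields["fixate_range"]),
            flattened=df["flattened"].to_numpy().astype(bool),
        )


def sample_background_regions(
    layout: GenomeLayout, inactive_mask: pd.DataFrame, n: int = 10_000, seed: int = 0
):
    """Uniform sample (without replacement) of `n` single bins from the
    inactive mask. Returns a list of (chrom, bin)."""
    candidates = []
    for chrom in layout.chrom_names:
        for b in mask_bins(layout, inactive_mask, chrom):
            candidates.append((chrom, int(b)))
    if not candidates:
        raise ValueError("inactive mask contains no full bins")
    rng = np.random.default_rng(seed)
    if len(candidates) <= n:
        if len(candidates) < n:
            warnings.warn(
                f"only {len(candidates)} maskable bins available "
                f"({n} requested); using all",
                stacklevel=2,
            )
        idx = np.arange(len(candidates))
    else:
        idx = rng.choice(len(candidates), size=n, replace=False)
        idx.sort()
    return [candidates[k] for k in idx]


def viewpoint_qc(
    matrix,
    chrom,
    viewpoint_bins,
    s: float = 0.06,
    fixate_range: int = 200_000,
    viewpoint_id: str = "",
) -> QCResult:
    """chicQualityControl-style sparsity check: fraction of bins within
    +-fixate_range (viewpoint bins excluded) with nonzero summed
    viewpoint-row count. Ties at exactly `s` pass."""
    fixate_bins = fixate_range // matrix.layout.bin_size
    sparsity = viewpoint_row_nonzero(matrix, chrom, viewpoint_bins, fixate_bins)
    return QCResult(viewpoint_id, sparsity, sparsity >= s)


def fit_background(
    merged_matrix,
    regions,
    range_bp: int = 1_000_000,
    avg_bins: int = 5,
    s: float = 0.06,
    fixate_range: int = 200_000,
    apply_qc: bool = True,
) -> BackgroundModel:
    """Pool smoothed relative profiles of single-bin background regions and
    record per-offset mean and sample variance.

    Regions failing viewpoint QC, and regions whose +-range window is clipped
    by a chromosome end, are dropped so every offset has the same n.
    """
    layout = merged_matrix.layout
    R = range_bp // layout.bin_size
    usable = []
    for chrom, b in regions:
        n_bins = layout.n_bins(chrom)
        if b - R < 0 or b + R + 1 > n_bins:
            continue
        if apply_qc and not viewpoint_qc(
            merged_matrix, chrom, [b], s=s, fixate_range=fixate_range
        ).passed:
            continue
        usable.append((chrom, b))
    if len(usable) < 2:
        raise ValueError(
            f"only {len(usable)} background regions usable (need >= 2)"
        )
    width = 2 * R + 1
    sums = np.zeros(width)
    sumsq = np.zeros(width)
    for chrom, b in usable:
        _, _, _, smoothed, _ = window_profile(
            merged_matrix, chrom, [b], b, R, avg_bins
        )
        sums += smoothed
        sumsq += smoothed * smoothed
    n = len(usable)
    mu = sums / n
    var = (sumsq - n * mu * mu) / (n - 1)
    var = np.maximum(var, 0.0)
    return BackgroundModel(
        bin_size=layout.bin_size,
        offsets=np.arange(-R, R + 1),
        mu=mu,
        var=var,
        n=np.full(width, n),
        fixate_range=fixate_range,
    )


def flatten_far_field(
    model: BackgroundModel, fixate_range: int = 200_000, tail_bins: int = 10
) -> BackgroundModel:
    """Replace (mu, var) beyond +-fixate_range with the mean over the
    `tail_bins` offsets immediately inside it, per side independently."""
    fixate_bins = fixate_range // model.bin_size
    mu = model.mu.copy()
    var = model.var.copy()
    flags = model.flattened.copy()
    for side in (-1, 1):
        inside = np.where(
            (np.sign(model.offsets) == side)
            & (np.abs(model.offsets) <= fixate_bins)
        )[0]
        outside = np.where(
            (np.sign(model.offsets) == side)
            & (np.abs(model.offsets) > fixate_bins)
        )[0]
        if outside.size == 0:
            continue
        if inside.size < tail_bins:
            raise ValueError(
                f"fewer than {tail_bins} offsets inside fixate_range on side {side}"
            )
        # the tail_bins offsets with the largest |offset| still inside
        order = inside[np.argsort(np.abs(model.offsets[inside]))]
        tail = order[-tail_bins:]
        mu[outside] = model.mu[tail].mean()
        var[outside] = model.var[tail].mean()
        flags[outside] = True
    return BackgroundModel(
        bin_size=model.bin_size,
        offsets=model.offsets.copy(),
        mu=mu,
        var=var,
        n=model.n.copy(),
        fixate_range=fixate_range,
        flattened=flags,
    )


def nb_tail(x, mu, var):
    """Upper tail P(X >= x) of a continuous negative binomial with mean `mu`
    and variance `var` (size r = mu^2/(var-mu), success prob q = r/(r+mu)),
    via the regularized incomplete beta function; falls back to the
    continuous Poisson tail (regularized lower incomplete gamma) when
    var <= mu. Vectorized over x/mu/var.

    At integer x this matches discrete pmf summation exactly:
    P(X >= x) = I_{1-q}(x, r)  and  P(Poisson >= x) = P(x, mu).
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    var = np.asarray(var, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    x, mu, var = np.broadcast_arrays(x, mu, var)
    out = np.ones(x.shape, dtype=np.float64)
    pos_mu = mu > 0
    active = (x > 0) & pos_mu
    nb = active & (var > mu * (1 + 1e-12))
    po = active & ~nb
    if np.any(nb):
        r = mu[nb] ** 2 / (var[nb] - mu[nb])
        q = r / (r + mu[nb])
        out[nb] = special.betainc(x[nb], r, 1.0 - q)
    if np.any(po):
        out[po] = special.gammainc(x[po], mu[po])
    # mu == 0: background saw nothing; stay maximally conservative (p = 1)
    out[(x > 0) & ~pos_mu] = 1.0
    if out.ndim == 0:
        return float(out)
    return out
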