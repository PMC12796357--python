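"""Promoter viewpoint profiles, per-bin significance against the distance
background, and promoter-interacting domain (PID) calling.

Domain calling follows the merge-recompute-reject scheme: bins whose smoothed
relative interaction exceeds xf times the background mean are merged into
maximal runs; each run's p-value is recomputed from a moment-matched NB on the
summed member means/variances; runs failing the p cutoff or the peak raw-count
guard, or touching the viewpoint-center exclusion window, are dropped.

Significance is evaluated on a count-equivalent scale: relative values and
the background moments are scaled by T = the number of window bins before
the tail is taken (mu -> mu*T, var -> var*T^2), so a relative frequency of
1/T — the flat-profile expectation — maps to one count-equivalent unit.
Because T depends only on the window geometry, p-values are invariant under
uniform depth rescaling of the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._profile import smooth_truncated, window_profile
from .background_model import BackgroundModel, viewpoint_qc
from .genome import GenomeLayout

_TINY = np.nextafter(0.0, 1.0)

PID_COLUMNS = [
    "gene", "chrom", "start", "end", "sum_rel", "fold", "p_value",
    "p_bonferroni", "peak_raw", "n_bins",
]


@dataclass
class ViewpointSpec:
    """A promoter viewpoint: TSS +- halfwidth, clipped at chromosome ends."""

    gene: str
    chrom: str
    tss: int
    halfwidth: int = 2_500

    def interval(self, layout: GenomeLayout) -> tuple:
        length = layout.length_of(self.chrom)
        start = max(0, self.tss - self.halfwidth)
        end = min(length, self.tss + self.halfwidth)
        return start, end

    def clipped(self, layout: GenomeLayout) -> bool:
        start, end = self.interval(layout)
        return (end - start) < 2 * self.halfwidth

    def bins(self, layout: GenomeLayout) -> np.ndarray:
        start, end = self.interval(layout)
        bs = layout.bin_size
        return np.arange(start // bs, -(-end // bs))

    def center_bin(self, layout: GenomeLayout) -> int:
        return min(self.tss // layout.bin_size, layout.n_bins(self.chrom) - 1)


@dataclass
class RelativeProfile:
    viewpoint: ViewpointSpec
    offsets: np.ndarray  # signed bin distances from the center bin
    raw: np.ndarray  # depth-scaled counts summed over viewpoint rows
    rel: np.ndarray  # raw / total
    smoothed: np.ndarray
    total: float
    avg_bins: int
    bin_size: int
    clipped: bool = False

    def bin_starts(self) -> np.ndarray:
        center = self.viewpoint.tss // self.bin_size
        return (center + self.offsets) * self.bin_size


def extract_profile(
    matrix, viewpoint: ViewpointSpec, range_bp: int = 1_000_000, avg_bins: int = 5
) -> RelativeProfile:
    """Relative interaction profile of a viewpoint over +-range_bp."""
    layout = matrix.layout
    R = range_bp // layout.bin_size
    center = viewpoint.center_bin(layout)
    offsets, raw, rel, smoothed, total = window_profile(
        matrix, viewpoint.chrom, viewpoint.bins(layout), center, R, avg_bins
    )
    clipped = offsets[0] != -R or offsets[-1] != R or viewpoint.clipped(layout)
    return RelativeProfile(
        viewpoint=viewpoint,
        offsets=offsets,
        raw=raw,
        rel=rel,
        smoothed=smoothed,
        total=total,
        avg_bins=avg_bins,
        bin_size=layout.bin_size,
        clipped=bool(clipped),
    )


def bin_pvalues(profile: RelativeProfile, model: BackgroundModel) -> np.ndarray:
    """Per-bin upper-tail p-values of the smoothed relative values against
    the background, on the count-equivalent scale (T = window bin count)."""
    from .background_model import nb_tail

    mu, var = model.lookup(profile.offsets)
    T = float(profile.offsets.size)
    p = nb_tail(profile.smoothed * T, mu * T, var * T * T)
    p = np.asarray(p, dtype=np.float64)
    p[p <= 0] = _TINY  # --truncateZeroPvalues
    return p


def _candidate_runs(mask: np.ndarray):
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    runs = []
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return runs
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        runs.append((int(idx[s]), int(idx[e])))
    return runs


def call_pids(
    profile: RelativeProfile,
    model: BackgroundModel,
    xf: float = 1.5,
    p_cutoff: float = 1e-10,
    peak_min: float = 10.0,
    exclusion: int = 10_000,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Call promoter-interacting domains for one viewpoint.

    Returns a PID table (possibly empty) with raw and Bonferroni-scaled
    p-values; `n_tests` defaults to the number of profile bins.
    """
    from .background_model import nb_tail

    mu, var = model.lookup(profile.offsets)
    T = float(profile.offsets.size)
    cand = (profile.smoothed >= xf * mu) & (profile.smoothed > 0)
    if n_tests is None:
        n_tests = profile.offsets.size
    layout_center = profile.viewpoint.tss // profile.bin_size
    chrom_len = None
    rows = []
    for s, e in _candidate_runs(cand):
        sl = slice(s, e + 1)
        sum_rel = float(profile.smoothed[sl].sum())
        sum_mu = float(mu[sl].sum())
        sum_var = float(var[sl].sum())
        p = float(nb_tail(sum_rel * T, sum_mu * T, sum_var * T * T))
        p = max(p, _TINY)
        peak = float(profile.raw[sl].max())
        if p > p_cutoff or peak < peak_min:
            continue
        start_bp = (layout_center + int(profile.offsets[s])) * profile.bin_size
        end_bp = (layout_center + int(profile.offsets[e]) + 1) * profile.bin_size
        # viewpoint-center exclusion window (center +- exclusion)
        if start_bp < profile.viewpoint.tss + exclusion and (
            end_bp > profile.viewpoint.tss - exclusion
        ):
            continue
        rows.append(
            {
                "gene": profile.viewpoint.gene,
                "chrom": profile.viewpoint.chrom,
                "start": start_bp,
                "end": end_bp,
                "sum_rel": sum_rel,
                "fold": sum_rel / sum_mu if sum_mu > 0 else np.inf,
                "p_value": p,
                "p_bonferroni": min(1.0, p * n_tests),
                "peak_raw": peak,
                "n_bins": e - s + 1,
            }
        )
    return pd.DataFrame(rows, columns=PID_COLUMNS)


def tiled_profile(
    matrix,
    viewpoint: ViewpointSpec,
    region: tuple,
    tile: int = 1_000,
    step: int = 1_000,
    range_bp: int = 1_000_000,
    avg_bins: int = 5,
) -> pd.DataFrame:
    """Tiled readout of a viewpoint's smoothed relative interactions over
    `region` = (start, end) bp: each tile's value is the mean smoothed
    relative value of its member bins."""
    start, end = region
    prof = extract_profile(matrix, viewpoint, range_bp=range_bp, avg_bins=avg_bins)
    starts_bp = prof.bin_starts()
    lo_bp, hi_bp = starts_bp[0], starts_bp[-1] + prof.bin_size
    if start < lo_bp or end > hi_bp:
        raise ValueError("region outside the viewpoint analysis window")
    rows = []
    t = start
    while t < end:
        t_end = min(t + tile, end)
        sel = (starts_bp < t_end) & (starts_bp + prof.bin_size > t)
        value = float(prof.smoothed[sel].mean()) if sel.any() else np.nan
        rows.append({"tile_start": t, "tile_end": t_end, "value": value})
        t += step
    return pd.DataFrame(rows)


def viewpoints_from_genes(genes: pd.DataFrame, halfwidth: int = 2_500) -> list:
    """One viewpoint per annotated TSS (BED `start` is the TSS)."""
    return [
        ViewpointSpec(
            gene=str(row["name"]), chrom=row["chrom"], tss=int(row["start"]),
            halfwidth=halfwidth,
        )
        for _, row in genes.iterrows()
    ]


def genomewide_pids(
    matrix,
    genes: pd.DataFrame,
    model: BackgroundModel,
    range_bp: int = 1_000_000,
    avg_bins: int = 5,
    qc_s: float = 0.06,
    fixate_range: int = 200_000,
    xf: float = 1.5,
    p_cutoff: float = 1e-10,
    peak_min: float = 10.0,
    exclusion: int = 10_000,
    halfwidth: int = 2_500,
):
    """QC -> profile -> call over all gene viewpoints on a merged group matrix.

    Returns (pid_table, per_gene_summary, qc_table). Bonferroni column uses
    m = total bins tested across all passing viewpoints.
    """
    layout = matrix.layout
    viewpoints = viewpoints_from_genes(genes, halfwidth=halfwidth)
    qc_rows, profiles = [], []
    for vp in viewpoints:
        qc = viewpoint_qc(
            matrix, vp.chrom, vp.bins(layout), s=qc_s,
            fixate_range=fixate_range, viewpoint_id=vp.gene,
        )
        qc_rows.append(
            {"gene": vp.gene, "sparsity": qc.sparsity, "qc_pass": qc.passed}
        )
        if qc.passed:
            profiles.append(extract_profile(matrix, vp, range_bp, avg_bins))
    if not profiles:
        raise ValueError("no gene viewpoint passed QC")
    m_total = int(sum(p.offsets.size for p in profiles))
    tables = [
        call_pids(
            p, model, xf=xf, p_cutoff=p_cutoff, peak_min=peak_min,
            exclusion=exclusion, n_tests=m_total,
        )
        for p in profiles
    ]
    tables = [t for t in tables if len(t)]
    pid_table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=PID_COLUMNS)
    )
    summary_rows = []
    for p in profiles:
        sub = pid_table[pid_table["gene"] == p.viewpoint.gene]
        if len(sub):
            mids = (sub["start"] + sub["end"]) / 2.0
            med = float(np.median(np.abs(mids - p.viewpoint.tss)))
        else:
            med = np.nan
        summary_rows.append(
            {
                "gene": p.viewpoint.gene,
                "pid_count": int(len(sub)),
                "total_pid_length": int((sub["end"] - sub["start"]).sum()),
                "median_distance": med,
                "sum_rel": float(sub["sum_rel"].sum()),
                "clipped": p.clipped,
            }
        )
    return pid_table, pd.DataFrame(summary_rows), pd.DataFrame(qc_rows)


def write_pid_bed(pids: pd.DataFrame, path) -> None:
    """BED6+ output: chrom start end gene -log10p strand fold sum_rel peak."""
    with open(path, "w") as fh:
        for _, r in pids.iterrows():
            neglog = -np.log10(r["p_value"])
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r['gene']}"
                f"\t{neglog:.4f}\t.\t{r['fold']:.6g}\t{r['sum_rel']:.6g}"
                f"\t{r['peak_raw']:.6g}\n"
            )
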