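"""Differential promoter-interacting domains between two replicate groups:
chi-square screen on merged matrices, replicate-based log2FC + t-test
post-hoc, and a raw-contact coverage filter.

All thresholds are inclusive at exact boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contact_store import merge_replicates
from .genome import merge_intervals
from .pid_caller import ViewpointSpec, extract_profile

DIFF_COLUMNS = [
    "gene", "chrom", "start", "end",
    "countA_target", "countA_rest", "countB_target", "countB_rest",
    "chi2", "chi2_p", "low_expected",
    "relA", "relB", "log2fc", "t_stat", "t_p", "degenerate",
    "coverageA", "coverageB",
    "screen_pass", "posthoc_pass", "coverage_pass", "called",
    "neg_log10_p", "bh_q",
]


def candidate_targets(pids_a: pd.DataFrame, pids_b: pd.DataFrame) -> pd.DataFrame:
    """Per viewpoint gene, the union of PID intervals from both groups,
    overlapping intervals merged."""
    both = pd.concat([pids_a, pids_b], ignore_index=True)
    rows = []
    for (gene, chrom), sub in both.groupby(["gene", "chrom"], sort=True):
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        for start, end in zip(s, e):
            rows.append({"gene": gene, "chrom": chrom, "start": int(start), "end": int(end)})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def chisq_screen(countA_target, countA_rest, countB_target, countB_rest):
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    [[target, rest]] per group. If any expected cell < 1, p is set to 1 and
    the low-expected flag raised. Returns (chi2, p, low_expected)."""
    obs = np.array(
        [[countA_target, countA_rest], [countB_target, countB_rest]], dtype=float
    )
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if row[0] == 0 or row[1] == 0:
        raise ValueError("both window totals must be positive")
    expected = np.outer(row, col) / total
    if np.any(expected < 1):
        return 0.0, 1.0, True
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, False


def replicate_posthoc(vals_a, vals_b):
    """Welch two-sided t-test on per-replicate relative interaction values.

    Returns (log2fc, t, p, degenerate). log2fc = log2(mean_a / mean_b);
    a zero group mean gives +-inf flagged via the value itself. Zero variance
    in both groups: p = 1 if the means are equal, else p = 0 with the
    degenerate flag set.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    mean_a, mean_b = a.mean(), b.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        if mean_a == 0 and mean_b == 0:
            log2fc = np.nan
        else:
            # difference of logs so that swapping groups negates it exactly
            log2fc = float(np.log2(mean_a) - np.log2(mean_b))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if mean_a == mean_b:
            return log2fc, 0.0, 1.0, False
        return log2fc, np.inf if mean_a > mean_b else -np.inf, 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return log2fc, float(t), float(p), False


def coverage_filter(coverage_a: float, coverage_b: float, min_contacts: float = 1000):
    """Pass iff both groups' raw target contacts >= min_contacts (inclusive)."""
    if coverage_a < 0 or coverage_b < 0:
        raise ValueError("coverage must be non-negative")
    pass_a = coverage_a >= min_contacts
    pass_b = coverage_b >= min_contacts
    return pass_a and pass_b, pass_a, pass_b


def _target_bins(profile, start, end, bin_size):
    """Boolean selector of profile bins overlapping [start, end) bp."""
    center = profile.viewpoint.tss // bin_size
    starts_bp = (center + profile.offsets) * bin_size
    return (starts_bp < end) & (starts_bp + bin_size > start)


def differential_pids(
    matrices_a,
    matrices_b,
    targets: pd.DataFrame,
    genes: pd.DataFrame,
    range_bp: int = 1_000_000,
    avg_bins: int = 5,
    halfwidth: int = 2_500,
    alpha_screen: float = 0.05,
    alpha_posthoc: float = 0.05,
    min_contacts: float = 1000,
) -> pd.DataFrame:
    """Full differential table over candidate targets.

    `matrices_a`/`matrices_b` are the RAW per-replicate matrices (coverage and
    the chi-square screen use raw counts; the post-hoc uses per-replicate
    relative values, which are depth-scale invariant).
    """
    tss_by_gene = dict(zip(genes["name"].astype(str), genes["start"].astype(int)))
    chrom_by_gene = dict(zip(genes["name"].astype(str), genes["chrom"]))
    merged_a = merge_replicates(matrices_a)
    merged_b = merge_replicates(matrices_b)
    layout = merged_a.layout
    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        gene = str(gene)
        if gene not in tss_by_gene:
            raise ValueError(f"target gene {gene!r} missing from annotation")
        vp = ViewpointSpec(
            gene=gene, chrom=chrom_by_gene[gene], tss=tss_by_gene[gene],
            halfwidth=halfwidth,
        )
        prof_a = extract_profile(merged_a, vp, range_bp, avg_bins)
        prof_b = extract_profile(merged_b, vp, range_bp, avg_bins)
        reps_a = [extract_profile(m, vp, range_bp, avg_bins) for m in matrices_a]
        reps_b = [extract_profile(m, vp, range_bp, avg_bins) for m in matrices_b]
        for _, trg in sub.iterrows():
            start, end = int(trg["start"]), int(trg["end"])
            sel_a = _target_bins(prof_a, start, end, layout.bin_size)
            sel_b = _target_bins(prof_b, start, end, layout.bin_size)
            ta = float(prof_a.raw[sel_a].sum())
            tb = float(prof_b.raw[sel_b].sum())
            ra = float(prof_a.total - ta)
            rb = float(prof_b.total - tb)
            chi2, chi2_p, low_exp = chisq_screen(ta, ra, tb, rb)
            vals_a = [
                float(p.rel[_target_bins(p, start, end, layout.bin_size)].sum())
                for p in reps_a
            ]
            vals_b = [
                float(p.rel[_target_bins(p, start, end, layout.bin_size)].sum())
                for p in reps_b
            ]
            log2fc, t_stat, t_p, degen = replicate_posthoc(vals_a, vals_b)
            cov_a = float(
                sum(
                    p.raw[_target_bins(p, start, end, layout.bin_size)].sum()
                    for p in reps_a
                )
            )
            cov_b = float(
                sum(
                    p.raw[_target_bins(p, start, end, layout.bin_size)].sum()
                    for p in reps_b
                )
            )
            cov_pass, _, _ = coverage_filter(cov_a, cov_b, min_contacts)
            screen_pass = chi2_p <= alpha_screen
            posthoc_pass = t_p <= alpha_posthoc
            rows.append(
                {
                    "gene": gene, "chrom": trg["chrom"], "start": start, "end": end,
                    "countA_target": ta, "countA_rest": ra,
                    "countB_target": tb, "countB_rest": rb,
                    "chi2": chi2, "chi2_p": chi2_p, "low_expected": low_exp,
                    "relA": ";".join(f"{v:.8g}" for v in vals_a),
                    "relB": ";".join(f"{v:.8g}" for v in vals_b),
                    "log2fc": log2fc, "t_stat": t_stat, "t_p": t_p,
                    "degenerate": degen,
                    "coverageA": cov_a, "coverageB": cov_b,
                    "screen_pass": screen_pass, "posthoc_pass": posthoc_pass,
                    "coverage_pass": cov_pass,
                    "called": bool(cov_pass and screen_pass and posthoc_pass),
                    "neg_log10_p": float(-np.log10(max(t_p, np.nextafter(0, 1)))),
                }
            )
    df = pd.DataFrame(rows, columns=[c for c in DIFF_COLUMNS if c != "bh_q"])
    # BH-adjusted post-hoc p for transparency; never used for the verdict
    if len(df):
        p = df["t_p"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(q)
        out[order] = np.minimum(q, 1.0)
        df["bh_q"] = out
    else:
        df["bh_q"] = pd.Series(dtype=float)
    return df
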