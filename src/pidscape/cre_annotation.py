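"""CRE classification by promoter interaction, per-gene PID statistics, and
linkage of interaction changes to expression fold-change groups."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def classify_cres(cres: pd.DataFrame, pids: pd.DataFrame) -> pd.DataFrame:
    """Classify each CRE as PI (overlaps >= 1 PID by >= 1 bp, half-open) or
    PN, recording the linked viewpoint genes."""
    out_rows = []
    pid_by_chrom = {
        chrom: sub.reset_index(drop=True) for chrom, sub in pids.groupby("chrom")
    }
    for _, cre in cres.iterrows():
        chrom, s, e = cre["chrom"], int(cre["start"]), int(cre["end"])
        sub = pid_by_chrom.get(chrom)
        genes = []
        if sub is not None:
            hit = (sub["start"].to_numpy() < e) & (sub["end"].to_numpy() > s)
            genes = sorted(set(sub.loc[hit, "gene"].astype(str)))
        out_rows.append(
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "name": cre.get("name", f"{chrom}:{s}-{e}"),
                "cre_class": "PI" if genes else "PN",
                "linked_genes": ";".join(genes),
            }
        )
    return pd.DataFrame(out_rows)


def cre_class_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and total lengths per CRE class."""
    rows = []
    for cls in ("PI", "PN"):
        sub = classified[classified["cre_class"] == cls]
        rows.append(
            {
                "cre_class": cls,
                "count": int(len(sub)),
                "total_length": int((sub["end"] - sub["start"]).sum()),
            }
        )
    return pd.DataFrame(rows)


def gene_pid_stats(pids: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene PID count, cumulative length, median |domain midpoint - TSS|,
    and summed relative interaction strength. Genes without PIDs get count 0
    and NA distance."""
    tss = dict(zip(genes["name"].astype(str), genes["start"].astype(int)))
    if len(pids) == 0:
        pids = pd.DataFrame(columns=["gene", "chrom", "start", "end", "sum_rel"])
    rows = []
    for gene in genes["name"].astype(str):
        sub = pids[pids["gene"].astype(str) == gene]
        if len(sub):
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
            med = float(np.median(np.abs(mids - tss[gene])))
            sum_rel = float(sub["sum_rel"].sum()) if "sum_rel" in sub else np.nan
        else:
            med, sum_rel = np.nan, 0.0
        rows.append(
            {
                "gene": gene,
                "pid_count": int(len(sub)),
                "total_pid_length": int((sub["end"] - sub["start"]).sum()),
                "median_distance": med,
                "sum_rel": sum_rel,
            }
        )
    return pd.DataFrame(rows)


def interaction_change_groups(diff_table: pd.DataFrame) -> dict:
    """Default gene grouping from the differential verdict and log2FC sign:
    'gained_a', 'gained_b', 'unchanged'. A gene is grouped by its strongest
    called target; genes with no called target are 'unchanged'."""
    groups = {}
    for gene, sub in diff_table.groupby("gene"):
        called = sub[sub["called"]]
        if len(called) == 0:
            groups[str(gene)] = "unchanged"
        else:
            best = called.loc[called["t_p"].idxmin()]
            groups[str(gene)] = "gained_a" if best["log2fc"] > 0 else "gained_b"
    return groups


def gex_linkage(
    diff_table: pd.DataFrame,
    expression_log2fc: pd.Series,
    grouping: dict | None = None,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Per interaction-change group, a two-sided one-sample Wilcoxon
    signed-rank test of expression log2FC against 0 (exact for n <= 25 after
    dropping zeros, normal approximation above). Returns n, median, p and a
    flag column."""
    grouping = grouping if grouping is not None else interaction_change_groups(diff_table)
    rows = []
    by_group = {}
    for gene, grp in grouping.items():
        by_group.setdefault(grp, []).append(gene)
    for grp in sorted(by_group):
        vals = np.array(
            [
                expression_log2fc[g]
                for g in by_group[grp]
                if g in expression_log2fc.index
            ],
            dtype=float,
        )
        nonzero = vals[vals != 0]  # zeros dropped before the signed-rank test
        flag = ""
        if vals.size and nonzero.size == 0:
            p = np.nan
            flag = "all-zero"
        elif nonzero.size < 3:
            p = np.nan
            flag = "n<3"
        else:
            method = "exact" if nonzero.size <= exact_max_n else "approx"
            res = stats.wilcoxon(
                nonzero, alternative="two-sided", method=method,
                zero_method="wilcox",
            )
            p = float(res.pvalue)
        rows.append(
            {
                "group": grp,
                "n": int(vals.size),
                "median_log2fc": float(np.median(vals)) if vals.size else np.nan,
                "wilcoxon_p": p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
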