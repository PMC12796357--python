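"""GREGOR-style enrichment of disease variants in region sets: LD-proxy
expansion, feature-matched control sampling, and exact Poisson-binomial
significance of the observed lead-or-proxy overlap count."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VariantSet:
    """A lead variant with its LD proxies and matching features."""

    lead_id: str
    chrom: str
    pos: int
    trait: str = ""
    assoc_p: float = np.nan
    proxies: list = field(default_factory=list)  # (chrom, pos, r2)
    features: dict = field(default_factory=dict)  # tss_decile, proxy_bin, ...


@dataclass
class EnrichmentResult:
    trait: str
    region_set: str
    observed: int
    expected: float
    fold: float
    p_value: float
    n_leads: int
    flag: str = ""

    def as_dict(self):
        return {
            "trait": self.trait,
            "region_set": self.region_set,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
            "n_leads": self.n_leads,
            "flag": self.flag,
        }


def expand_proxies(
    leads: pd.DataFrame,
    ld_table: pd.DataFrame | None,
    features: pd.DataFrame | None = None,
    r2_min: float = 0.7,
    window: int = 1_000_000,
) -> list:
    """Build VariantSets: proxies kept iff r2 > r2_min (strict) and within
    `window` bp of the lead; the lead is always a member of its own set."""
    feats = {}
    if features is not None:
        for _, row in features.iterrows():
            feats[str(row["lead_id"])] = {
                k: row[k] for k in features.columns if k != "lead_id"
            }
    by_lead = {}
    if ld_table is not None and len(ld_table):
        for lid, sub in ld_table.groupby("lead_id"):
            by_lead[str(lid)] = sub
    out = []
    for _, row in leads.iterrows():
        lid = str(row["lead_id"])
        proxies = []
        sub = by_lead.get(lid)
        if sub is not None:
            for _, pr in sub.iterrows():
                if pr["r2"] <= r2_min:
                    continue
                if abs(int(pr["pos"]) - int(row["pos"])) > window:
                    continue
                proxies.append((pr["chrom"], int(pr["pos"]), float(pr["r2"])))
        out.append(
            VariantSet(
                lead_id=lid,
                chrom=row["chrom"],
                pos=int(row["pos"]),
                trait=str(row.get("trait", "")),
                assoc_p=float(row.get("assoc_p", np.nan)),
                proxies=proxies,
                features=feats.get(lid, {}),
            )
        )
    return out


def _stratum(vs: VariantSet) -> tuple:
    return (vs.features.get("tss_decile"), vs.features.get("proxy_bin"))


def match_controls(
    lead: VariantSet, pool: list, n_controls: int, rng
) -> list:
    """Sample `n_controls` pool variants without replacement from the stratum
    matching the lead's (tss decile, proxy-count bin); fall back to the
    nearest non-empty decile stratum with a warning."""
    if not pool:
        raise ValueError("control pool is empty")
    target = _stratum(lead)
    candidates = [v for v in pool if _stratum(v) == target]
    if not candidates:
        # nearest stratum by decile distance within the same proxy bin,
        # then ignore the proxy bin entirely
        want_dec, want_bin = target
        scored = []
        for v in pool:
            dec, pbin = _stratum(v)
            try:
                dd = abs(int(dec) - int(want_dec))
            except (TypeError, ValueError):
                dd = 10
            scored.append((0 if pbin == want_bin else 1, dd, v))
        best = min(s[:2] for s in scored)
        candidates = [v for pb, dd, v in scored if (pb, dd) == best]
        warnings.warn(
            f"no pool variants in stratum {target}; using nearest stratum",
            stacklevel=2,
        )
    k = min(n_controls, len(candidates))
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


def overlap_indicator(variant_set: VariantSet, regions: pd.DataFrame) -> int:
    """1 iff the lead OR any proxy position falls inside any region
    (0-based half-open)."""
    if regions is None or len(regions) == 0:
        return 0
    positions = [(variant_set.chrom, variant_set.pos)] + [
        (c, p) for c, p, _ in variant_set.proxies
    ]
    for chrom, sub in regions.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for c, p in positions:
            if c != chrom:
                continue
            if np.any((starts <= p) & (p < ends)):
                return 1
    return 0


def poisson_binomial_tail(p_list, k: int) -> float:
    """Exact P(K >= k) for K a sum of independent Bernoulli(p_i), by
    dynamic-programming convolution. k <= 0 -> 1; k > n -> 0."""
    p = np.asarray(p_list, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    n = p.size
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for m, pi in enumerate(p, start=1):
        dist[1 : m + 1] = dist[1 : m + 1] * (1 - pi) + dist[:m] * pi
        dist[0] *= 1 - pi
    return float(dist[k:].sum())


def enrichment_test(
    variant_sets: list,
    regions: pd.DataFrame,
    pool: list,
    n_controls: int = 50,
    seed: int = 0,
    trait: str = "",
    region_set: str = "",
) -> EnrichmentResult:
    """Observed vs expected lead-or-proxy overlap with `regions`.

    Per lead i, p_i = fraction of its matched controls whose own variant set
    overlaps the regions; observed k = sum of overlap indicators; expected =
    sum p_i; fold = k / expected; p = Poisson-binomial upper tail at k.
    """
    if not variant_sets:
        raise ValueError("need >= 1 variant set")
    rng = np.random.default_rng(seed)
    # control overlap status is a property of the pool; compute once
    pool_overlap = {id(v): None for v in pool}
    p_list, k = [], 0
    for vs in variant_sets:
        k += overlap_indicator(vs, regions)
        controls = match_controls(vs, pool, n_controls, rng)
        hits = 0
        for c in controls:
            cached = pool_overlap.get(id(c))
            if cached is None:
                cached = overlap_indicator(c, regions)
                pool_overlap[id(c)] = cached
            hits += cached
        p_list.append(hits / len(controls))
    expected = float(np.sum(p_list))
    flag = ""
    if expected == 0:
        if k > 0:
            fold = np.inf
            p = poisson_binomial_tail(np.full(len(p_list), 1e-12), k)
            flag = "expected=0; p is a lower-bound"
        else:
            fold, p = np.nan, 1.0
            flag = "degenerate: expected=0, observed=0"
    else:
        fold = k / expected
        p = poisson_binomial_tail(p_list, k)
    return EnrichmentResult(
        trait=trait or (variant_sets[0].trait if variant_sets else ""),
        region_set=region_set,
        observed=int(k),
        expected=expected,
        fold=float(fold),
        p_value=float(p),
        n_leads=len(variant_sets),
        flag=flag,
    )


def bonferroni(results: list) -> pd.DataFrame:
    """Per-trait x region-set table with Bonferroni-corrected p over the run."""
    m = len(results)
    rows = []
    for r in results:
        d = r.as_dict()
        d["p_bonferroni"] = min(1.0, d["p_value"] * m)
        rows.append(d)
    return pd.DataFrame(rows)
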