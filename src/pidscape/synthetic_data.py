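"""Synthetic genomes, multi-replicate Hi-C contact maps with planted loops,
expression tables and variant sets with known ground truth.

The contact generator draws overdispersed counts around a power-law distance
decay: the expected count for a bin pair at distance d bins is A * d**(-alpha)
(the diagonal gets its own weight), multiplied by the enhancement factors of
any planted loops covering the pair, with NB noise var = mu + phi * mu**2
(phi = 0 degenerates to Poisson). Only intra-chromosomal contacts are
simulated. Everything is deterministic given the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_store import BinnedContacts
from .genome import GenomeLayout, intervals_overlap, merge_intervals


@dataclass(frozen=True)
class SimConfig:
    decay_amplitude: float = None  # None -> calibrated to target_depth
    decay_exponent: float = 0.85
    nb_dispersion: float = 0.2  # phi; var = mu + phi mu^2
    replicates_per_condition: int = 3
    target_depth: float = 500_000.0
    seed: int = 0
    bin_size: int = 1000
    max_distance_bins: int = 1050
    diag_weight: float = 0.5  # diagonal expected count = diag_weight * A

    def __post_init__(self):
        if self.decay_amplitude is not None and self.decay_amplitude <= 0:
            raise ValueError("decay_amplitude must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class LoopSpec:
    """A planted promoter-CRE loop: all bin pairs anchor_a x anchor_b get
    their expected count multiplied by base_enhancement times the current
    condition's factor."""

    chrom: str
    anchor_a: tuple  # (start, end) promoter side, bp, half-open
    anchor_b: tuple  # (start, end) CRE side
    base_enhancement: float = 1.0
    condition_factors: dict = field(default_factory=dict)
    gene: str = ""

    def __post_init__(self):
        if self.base_enhancement < 1:
            raise ValueError("base_enhancement must be >= 1")

    def factor(self, condition) -> float:
        return self.base_enhancement * float(
            self.condition_factors.get(condition, 1.0)
        )

    def anchor_bins(self, layout: GenomeLayout):
        bs = layout.bin_size
        n = layout.n_bins(self.chrom)
        out = []
        for start, end in (self.anchor_a, self.anchor_b):
            if start < 0 or end > layout.length_of(self.chrom) or end <= start:
                raise ValueError(
                    f"loop anchor ({start}, {end}) outside {self.chrom}"
                )
            out.append(np.arange(start // bs, -(-end // bs)))
        return out


@dataclass
class TruthTables:
    loops: list
    gene_log2fc: pd.DataFrame = None  # columns: gene, log2fc
    variant_labels: pd.DataFrame = None  # columns: lead_id, trait, planted_overlap
    inactive_mask: pd.DataFrame = None

    def write(self, prefix) -> None:
        rows = []
        for lp in self.loops:
            rows.append(
                {
                    "chrom": lp.chrom,
                    "a_start": lp.anchor_a[0],
                    "a_end": lp.anchor_a[1],
                    "b_start": lp.anchor_b[0],
                    "b_end": lp.anchor_b[1],
                    "base_enhancement": lp.base_enhancement,
                    "condition_factors": ";".join(
                        f"{k}={v}" for k, v in sorted(lp.condition_factors.items())
                    ),
                    "gene": lp.gene,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "chrom", "a_start", "a_end", "b_start", "b_end",
                "base_enhancement", "condition_factors", "gene",
            ],
        ).to_csv(f"{prefix}.loops.tsv", sep="\t", index=False)
        if self.gene_log2fc is not None:
            self.gene_log2fc.to_csv(f"{prefix}.gene_log2fc.tsv", sep="\t", index=False)
        if self.variant_labels is not None:
            self.variant_labels.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
        if self.inactive_mask is not None:
            self.inactive_mask.to_csv(
                f"{prefix}.mask.bed", sep="\t", index=False, header=False
            )

    @classmethod
    def read(cls, prefix) -> "TruthTables":
        df = pd.read_csv(f"{prefix}.loops.tsv", sep="\t", keep_default_na=False)
        loops = []
        for _, row in df.iterrows():
            factors = {}
            if row["condition_factors"]:
                for tok in str(row["condition_factors"]).split(";"):
                    k, v = tok.split("=")
                    factors[k] = float(v)
            loops.append(
                LoopSpec(
                    chrom=row["chrom"],
                    anchor_a=(int(row["a_start"]), int(row["a_end"])),
                    anchor_b=(int(row["b_start"]), int(row["b_end"])),
                    base_enhancement=float(row["base_enhancement"]),
                    condition_factors=factors,
                    gene=str(row["gene"]),
                )
            )
        truth = cls(loops=loops)
        import os

        if os.path.exists(f"{prefix}.gene_log2fc.tsv"):
            truth.gene_log2fc = pd.read_csv(f"{prefix}.gene_log2fc.tsv", sep="\t")
        if os.path.exists(f"{prefix}.variants.tsv"):
            truth.variant_labels = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
        if os.path.exists(f"{prefix}.mask.bed"):
            truth.inactive_mask = pd.read_csv(
                f"{prefix}.mask.bed", sep="\t", header=None,
                names=["chrom", "start", "end"],
            )
        return truth


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    parts = [seed & 0xFFFFFFFF]
    for tok in tokens:
        if isinstance(tok, str):
            parts.append(zlib.crc32(tok.encode()))
        else:
            parts.append(int(tok) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(parts))


def build_inactive_mask(layout: GenomeLayout, exclude_frames) -> pd.DataFrame:
    """Complement of the union of the given interval tables, per chromosome."""
    rows = []
    for chrom in layout.chrom_names:
        length = layout.length_of(chrom)
        starts, ends = [], []
        for df in exclude_frames:
            sel = df[df["chrom"] == chrom]
            starts.extend(sel["start"].tolist())
            ends.extend(sel["end"].tolist())
        if starts:
            ms, me = merge_intervals(
                np.clip(starts, 0, length), np.clip(ends, 0, length)
            )
        else:
            ms, me = np.array([], dtype=int), np.array([], dtype=int)
        cursor = 0
        for s, e in zip(ms, me):
            if s > cursor:
                rows.append((chrom, cursor, int(s)))
            cursor = max(cursor, int(e))
        if cursor < length:
            rows.append((chrom, cursor, length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_genome(
    config: SimConfig,
    n_genes: int,
    n_cres: int,
    chrom_length: int = 10_000_000,
    chrom_name: str = "chr1",
    gene_length: int = 10_000,
    cre_width: int = 1_000,
    promoter_halfwidth: int = 2_500,
):
    """Toy single-chromosome genome: gene/TSS BED, CRE BED, inactive mask.

    Genes are laid out on an even grid with jitter so each TSS keeps +-1 Mb
    of genome where the chromosome allows. CREs avoid promoters
    (TSS +- promoter_halfwidth); the inactive mask excludes gene bodies,
    promoters and CREs.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    layout = GenomeLayout((chrom_name,), (chrom_length,), config.bin_size)
    rng = _rng_for(config.seed, "genome")
    margin = min(1_000_000, chrom_length // 10)
    usable = chrom_length - 2 * margin
    spacing = usable / n_genes
    if spacing < gene_length + 2 * promoter_halfwidth + 4 * config.bin_size:
        raise ValueError(
            f"infeasible: {n_genes} genes do not fit a {chrom_length} bp chromosome"
        )
    jitter_max = max(1, int(spacing * 0.1))
    tss, seen_bins = [], set()
    for k in range(n_genes):
        base = margin + int((k + 0.5) * spacing)
        pos = int(base + rng.integers(-jitter_max, jitter_max + 1))
        pos = min(max(pos, 0), chrom_length - gene_length - 1)
        while pos // config.bin_size in seen_bins:
            pos += config.bin_size
        seen_bins.add(pos // config.bin_size)
        tss.append(pos)
    genes = pd.DataFrame(
        {
            "chrom": chrom_name,
            "start": tss,
            "end": [t + gene_length for t in tss],
            "name": [f"gene{k:03d}" for k in range(n_genes)],
            "score": 0,
            "strand": "+",
        }
    )
    promoters = pd.DataFrame(
        {
            "chrom": chrom_name,
            "start": np.maximum(np.array(tss) - promoter_halfwidth, 0),
            "end": np.minimum(np.array(tss) + promoter_halfwidth, chrom_length),
        }
    )
    cre_rows = []
    taken = list(zip(promoters["start"], promoters["end"])) + list(
        zip(genes["start"], genes["end"])
    )
    attempts = 0
    while len(cre_rows) < n_cres and attempts < 100 * max(n_cres, 1):
        attempts += 1
        s = int(rng.integers(0, chrom_length - cre_width))
        e = s + cre_width
        if any(intervals_overlap(s, e, ts, te) for ts, te in taken):
            continue
        if any(intervals_overlap(s, e, cs, ce) for _, cs, ce in cre_rows):
            continue
        cre_rows.append((chrom_name, s, e))
    if len(cre_rows) < n_cres:
        raise ValueError("infeasible: could not place all CREs")
    cres = pd.DataFrame(cre_rows, columns=["chrom", "start", "end"])
    cres = cres.sort_values("start", ignore_index=True)
    cres["name"] = [f"cre{k:04d}" for k in range(len(cres))]
    mask = build_inactive_mask(
        layout, [genes[["chrom", "start", "end"]], promoters, cres]
    )
    return layout, genes, cres, mask


def plant_loops(
    layout: GenomeLayout,
    genes: pd.DataFrame,
    n_loops: int,
    base_enhancement: float = 3.0,
    condition_factors: dict | None = None,
    distance_range: tuple = (14_000, 24_000),
    anchor_width: int = 10_000,
    promoter_halfwidth: int = 2_500,
    seed: int = 0,
):
    """Create one loop per gene for the first `n_loops` genes: the promoter
    anchor is TSS +- promoter_halfwidth, the CRE anchor an `anchor_width`
    interval whose near edge lies `distance_range` bp from the TSS (side
    chosen at random). Returns (loops, anchor CRE BED)."""
    if n_loops > len(genes):
        raise ValueError("more loops requested than genes available")
    rng = _rng_for(seed, "loops")
    loops, cre_rows = [], []
    for k in range(n_loops):
        row = genes.iloc[k]
        tss = int(row["start"])
        chrom = row["chrom"]
        length = layout.length_of(chrom)
        dist = int(rng.integers(distance_range[0], distance_range[1] + 1))
        side = 1 if rng.random() < 0.5 else -1
        if side > 0:
            b_start = tss + dist
        else:
            b_start = tss - dist - anchor_width
        if b_start < 0 or b_start + anchor_width > length:
            side = -side
            b_start = tss + dist if side > 0 else tss - dist - anchor_width
        a_start = max(0, tss - promoter_halfwidth)
        a_end = min(length, tss + promoter_halfwidth)
        loops.append(
            LoopSpec(
                chrom=chrom,
                anchor_a=(a_start, a_end),
                anchor_b=(b_start, b_start + anchor_width),
                base_enhancement=base_enhancement,
                condition_factors=dict(condition_factors or {}),
                gene=str(row["name"]),
            )
        )
        cre_rows.append((chrom, b_start, b_start + anchor_width, f"anchor_{row['name']}"))
    anchor_cres = pd.DataFrame(cre_rows, columns=["chrom", "start", "end", "name"])
    return loops, anchor_cres


def _expected_base_total(layout, config, A=1.0):
    """Expected genome total (loops excluded) for amplitude A."""
    total = 0.0
    D = config.max_distance_bins
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        d = np.arange(1, min(D, n - 1) + 1, dtype=np.float64)
        total += np.sum((n - d) * d ** (-config.decay_exponent))
        total += n * config.diag_weight
    return A * total


def _loop_pair_factors(layout, loops, condition):
    """dict: chrom -> dict: distance d -> (positions array, factors array)."""
    acc = {}
    for lp in loops:
        f = lp.factor(condition)
        if f == 1.0:
            continue
        bins_a, bins_b = lp.anchor_bins(layout)
        per = acc.setdefault(lp.chrom, {})
        for ia in bins_a:
            for jb in bins_b:
                i, j = (ia, jb) if ia <= jb else (jb, ia)
                d = int(j - i)
                per.setdefault(d, {})
                per[d][i] = per[d].get(i, 1.0) * f
    out = {}
    for chrom, per in acc.items():
        out[chrom] = {
            d: (
                np.fromiter(m.keys(), dtype=np.int64),
                np.fromiter(m.values(), dtype=np.float64),
            )
            for d, m in per.items()
        }
    return out


def expected_amplitude(layout, loops, config, conditions=("a",)) -> float:
    """Amplitude A giving expected total = target_depth (averaged over the
    given conditions' loop enhancements)."""
    if config.decay_amplitude is not None:
        return config.decay_amplitude
    base = _expected_base_total(layout, config, A=1.0)
    extra = 0.0
    for condition in conditions:
        pf = _loop_pair_factors(layout, loops, condition)
        for chrom, per in pf.items():
            for d, (pos, factors) in per.items():
                w = config.diag_weight if d == 0 else d ** (-config.decay_exponent)
                extra += np.sum(factors - 1.0) * w
    extra /= len(conditions)
    return config.target_depth / (base + extra)


def simulate_contacts(
    layout: GenomeLayout,
    loops,
    config: SimConfig,
    condition="a",
    n_replicates: int | None = None,
) -> list:
    """One BinnedContacts per replicate, NB counts around the decay law with
    planted loop enhancements for `condition`."""
    for lp in loops:
        lp.anchor_bins(layout)  # validates anchors
    n_replicates = n_replicates or config.replicates_per_condition
    A = expected_amplitude(layout, loops, config, conditions=(condition,))
    pair_factors = _loop_pair_factors(layout, loops, condition)
    phi = config.nb_dispersion
    out = []
    for rep in range(n_replicates):
        rng = _rng_for(config.seed, "contacts", condition, rep)
        m = BinnedContacts(layout, label=f"{condition}_rep{rep}")
        for chrom in layout.chrom_names:
            n = layout.n_bins(chrom)
            per = pair_factors.get(chrom, {})
            ii, jj, cc = [], [], []
            for d in range(0, min(config.max_distance_bins, n - 1) + 1):
                w = config.diag_weight if d == 0 else float(d) ** (-config.decay_exponent)
                mu = np.full(n - d, A * w)
                if d in per:
                    pos, factors = per[d]
                    mu[pos] *= factors
                if phi > 0:
                    r = 1.0 / phi
                    counts = rng.negative_binomial(r, r / (r + mu))
                else:
                    counts = rng.poisson(mu)
                nz = np.nonzero(counts)[0]
                if nz.size:
                    ii.append(nz)
                    jj.append(nz + d)
                    cc.append(counts[nz])
            if ii:
                m.set_chrom(
                    chrom,
                    np.concatenate(ii),
                    np.concatenate(jj),
                    np.concatenate(cc).astype(np.float64),
                )
        out.append(m)
    return out


def simulate_expression(
    truth: TruthTables,
    genes: pd.DataFrame,
    effect_per_log2_loop_change: float,
    noise_sd: float,
    seed: int = 0,
    conditions: tuple = ("a", "b"),
    baseline: float = 100.0,
) -> pd.DataFrame:
    """Expression table whose per-gene log2FC (condition a over b) equals
    effect * planted loop log2 condition-factor change + Gaussian noise."""
    rng = _rng_for(seed, "expression")
    ca, cb = conditions
    loop_lfc = {}
    for lp in truth.loops:
        ratio = lp.condition_factors.get(ca, 1.0) / lp.condition_factors.get(cb, 1.0)
        loop_lfc[lp.gene] = loop_lfc.get(lp.gene, 0.0) + np.log2(ratio)
    names = genes["name"].tolist()
    lfc = np.array(
        [effect_per_log2_loop_change * loop_lfc.get(g, 0.0) for g in names]
    )
    if noise_sd > 0:
        lfc = lfc + rng.normal(0.0, noise_sd, size=len(names))
    df = pd.DataFrame(
        {
            "gene": names,
            f"value_{ca}": baseline * np.exp2(lfc),
            f"value_{cb}": baseline,
            "log2fc": lfc,
        }
    )
    truth.gene_log2fc = df[["gene", "log2fc"]].copy()
    return df


# ---------------------------------------------------------------------------
# variants


def _nearest_tss_distance(pos, chrom, tss_by_chrom):
    arr = tss_by_chrom.get(chrom)
    if arr is None or arr.size == 0:
        return np.inf
    k = np.searchsorted(arr, pos)
    cands = []
    if k > 0:
        cands.append(abs(pos - arr[k - 1]))
    if k < arr.size:
        cands.append(abs(pos - arr[k]))
    return min(cands)


def _set_overlaps(lead_pos, proxy_pos, chrom, regions_by_chrom) -> bool:
    regs = regions_by_chrom.get(chrom)
    if regs is None or regs[0].size == 0:
        return False
    starts, ends = regs
    for p in [lead_pos, *proxy_pos]:
        k = np.searchsorted(starts, p, side="right") - 1
        if k >= 0 and p < ends[k]:
            return True
    return False


def _proxy_bin(count: int) -> str:
    if count == 0:
        return "0"
    if count <= 5:
        return "1-5"
    if count <= 20:
        return "6-20"
    return ">20"


def simulate_variants(
    layout: GenomeLayout,
    cres: pd.DataFrame,
    planted_trait_enrichment: float,
    n_leads: int,
    proxies_per_lead: int,
    seed: int = 0,
    *,
    tss_positions: pd.DataFrame,
    pi_regions: pd.DataFrame,
    pool_size: int | None = None,
    proxy_spread: int = 2_000,
    trait_name: str = "trait",
):
    """Lead/proxy/feature tables with a planted fold of (lead-or-proxy)
    overlap with `pi_regions` relative to a matched control pool.

    Returns dict with 'leads', 'pool', 'proxies', 'features', 'labels'.
    """
    if planted_trait_enrichment < 1:
        raise ValueError("planted fold must be >= 1")
    if n_leads < 1:
        raise ValueError("n_leads must be >= 1")
    rng = _rng_for(seed, "variants", trait_name)
    pool_size = pool_size or max(40 * n_leads, 2000)

    tss_by_chrom = {
        chrom: np.sort(
            tss_positions.loc[tss_positions["chrom"] == chrom, "start"].to_numpy()
        )
        for chrom in layout.chrom_names
    }
    regions_by_chrom = {}
    for chrom in layout.chrom_names:
        sel = pi_regions[pi_regions["chrom"] == chrom].sort_values("start")
        regions_by_chrom[chrom] = (
            sel["start"].to_numpy(dtype=np.int64),
            sel["end"].to_numpy(dtype=np.int64),
        )
    chrom_lengths = np.array(layout.chrom_lengths, dtype=np.float64)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    def draw_variant():
        ci = rng.choice(len(layout.chrom_names), p=chrom_p)
        chrom = layout.chrom_names[ci]
        length = layout.chrom_lengths[ci]
        pos = int(rng.integers(0, length))
        prox = []
        for _ in range(proxies_per_lead):
            off = int(rng.integers(-proxy_spread, proxy_spread + 1))
            prox.append(int(np.clip(pos + off, 0, length - 1)))
        return chrom, pos, prox

    def describe(chrom, pos, prox):
        dist = _nearest_tss_distance(pos, chrom, tss_by_chrom)
        ovl = _set_overlaps(pos, prox, chrom, regions_by_chrom)
        return dist, ovl

    # control pool from the base process
    pool = [draw_variant() for _ in range(pool_size)]
    pool_desc = [describe(*v) for v in pool]
    dists = np.array([d for d, _ in pool_desc])
    edges = np.quantile(dists, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf

    def decile_of(dist):
        return int(np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, 9))

    pool_strata = np.array([decile_of(d) for d, _ in pool_desc])
    pool_overlap = np.array([o for _, o in pool_desc], dtype=bool)
    q_s = {}
    for s in range(10):
        sel = pool_strata == s
        q_s[s] = float(pool_overlap[sel].mean()) if sel.sum() else 0.0

    # trait leads: per lead, draw a pool stratum, plant overlap at fold * q_s
    trait = []
    trait_labels = []
    for _ in range(n_leads):
        s = int(pool_strata[rng.integers(0, pool_size)])
        p_target = min(1.0, planted_trait_enrichment * q_s[s])
        want = bool(rng.random() < p_target)
        found = None
        for _ in range(3000):
            v = draw_variant()
            dist, ovl = describe(*v)
            if decile_of(dist) == s and ovl == want:
                found = v
                break
        if found is None:
            # fall back: place directly inside/outside a region, keep status
            if want and regions_by_chrom:
                chroms = [c for c in layout.chrom_names if regions_by_chrom[c][0].size]
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                starts, ends = regions_by_chrom[chrom]
                k = int(rng.integers(0, starts.size))
                pos = int(rng.integers(starts[k], ends[k]))
                prox = [
                    int(np.clip(pos + rng.integers(-proxy_spread, proxy_spread + 1),
                                0, layout.length_of(chrom) - 1))
                    for _ in range(proxies_per_lead)
                ]
                found = (chrom, pos, prox)
            else:
                found = draw_variant()
        trait.append(found)
        trait_labels.append(want)

    def tables(variants, prefix, trait_label):
        leads_rows, proxy_rows, feat_rows = [], [], []
        for k, (chrom, pos, prox) in enumerate(variants):
            lead_id = f"{prefix}{k:05d}"
            leads_rows.append((lead_id, chrom, pos, trait_label, 1e-9))
            for pp in prox:
                r2 = float(0.705 + 0.29 * rng.random())
                proxy_rows.append((lead_id, chrom, pp, r2))
            dist, _ = describe(chrom, pos, prox)
            feat_rows.append(
                (lead_id, decile_of(dist), len(prox), _proxy_bin(len(prox)))
            )
        leads = pd.DataFrame(
            leads_rows, columns=["lead_id", "chrom", "pos", "trait", "assoc_p"]
        )
        proxies = pd.DataFrame(
            proxy_rows, columns=["lead_id", "chrom", "pos", "r2"]
        )
        features = pd.DataFrame(
            feat_rows, columns=["lead_id", "tss_decile", "proxy_count", "proxy_bin"]
        )
        return leads, proxies, features

    t_leads, t_prox, t_feat = tables(trait, "lead", trait_name)
    p_leads, p_prox, p_feat = tables(pool, "pool", "control_pool")
    labels = pd.DataFrame(
        {
            "lead_id": t_leads["lead_id"],
            "trait": trait_name,
            "planted_overlap": np.array(trait_labels, dtype=int),
        }
    )
    return {
        "leads": t_leads,
        "pool": p_leads,
        "proxies": pd.concat([t_prox, p_prox], ignore_index=True),
        "features": pd.concat([t_feat, p_feat], ignore_index=True),
        "labels": labels,
    }
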