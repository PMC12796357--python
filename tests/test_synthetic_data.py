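import io

import numpy as np
import pandas as pd
import pytest

from pidscape import synthetic_data as synth
from pidscape.contact_store import write_contacts
from pidscape.genome import intervals_overlap


@pytest.fixture
def config():
    return synth.SimConfig(seed=7, target_depth=100_000.0)


class TestMakeGenome:
    def test_single_gene_promoter(self):
        cfg = synth.SimConfig(seed=1)
        layout, genes, cres, mask = synth.make_genome(cfg, 1, 5, chrom_length=3_000_000)
        assert len(genes) == 1
        tss = int(genes["start"].iloc[0])
        # promoter = TSS +- 2.5 kb must not overlap any CRE
        for _, c in cres.iterrows():
            assert not intervals_overlap(c["start"], c["end"], tss - 2500, tss + 2500)

    def test_no_cres(self):
        cfg = synth.SimConfig(seed=1)
        layout, genes, cres, mask = synth.make_genome(cfg, 3, 0, chrom_length=3_000_000)
        assert len(cres) == 0
        # inactive mask still excludes gene bodies
        for _, g in genes.iterrows():
            for _, mrow in mask.iterrows():
                assert not intervals_overlap(
                    g["start"], g["end"], mrow["start"], mrow["end"]
                )

    def test_unique_tss(self, config):
        _, genes, _, _ = synth.make_genome(config, 30, 0, chrom_length=5_000_000)
        assert genes["start"].nunique() == 30

    def test_determinism(self, config):
        out1 = synth.make_genome(config, 10, 20, chrom_length=4_000_000)
        out2 = synth.make_genome(config, 10, 20, chrom_length=4_000_000)
        for a, b in zip(out1[1:], out2[1:]):
            pd.testing.assert_frame_equal(a, b)

    def test_infeasible(self, config):
        with pytest.raises(ValueError, match="infeasible"):
            synth.make_genome(config, 500, 0, chrom_length=1_000_000)


class TestSimulateContacts:
    def test_poisson_limit(self):
        # phi=0, no loops: variance/mean of counts at fixed distance ~ 1
        cfg = synth.SimConfig(
            seed=2, nb_dispersion=0.0, target_depth=200_000.0, max_distance_bins=20
        )
        layout, genes, _, _ = synth.make_genome(cfg, 1, 0, chrom_length=12_000_000)
        (m,) = synth.simulate_contacts(layout, [], cfg, n_replicates=1)
        sym = m.sym_csr("chr1")
        n = layout.n_bins("chr1")
        d = 5
        counts = np.asarray(sym[np.arange(n - d), np.arange(d, n)]).ravel()
        assert counts.size >= 10_000
        ratio = counts.var() / counts.mean()
        assert 0.9 < ratio < 1.1

    def test_loop_enhancement_monte_carlo(self):
        cfg = synth.SimConfig(seed=3, target_depth=300_000.0, max_distance_bins=100)
        layout, genes, _, _ = synth.make_genome(cfg, 1, 0, chrom_length=10_000_000)
        loop = synth.LoopSpec(
            chrom="chr1",
            anchor_a=(2_000_000, 2_020_000),
            anchor_b=(2_050_000, 2_070_000),
            base_enhancement=3.0,
        )
        mats = synth.simulate_contacts(layout, [loop], cfg, n_replicates=8)
        d = 50  # distance between anchor starts in bins
        anchor_i = np.arange(2000, 2020)
        enh, base = [], []
        for m in mats:
            sym = m.sym_csr("chr1")
            enh.append(np.asarray(sym[anchor_i, anchor_i + d]).ravel())
            far = np.arange(5000, 7000)
            base.append(np.asarray(sym[far, far + d]).ravel())
        ratio = np.concatenate(enh).mean() / np.concatenate(base).mean()
        assert 2.5 < ratio < 3.5

    def test_decay_exponent_recovered(self):
        cfg = synth.SimConfig(seed=4, target_depth=500_000.0, max_distance_bins=256)
        layout, _, _, _ = synth.make_genome(cfg, 1, 0, chrom_length=10_000_000)
        (m,) = synth.simulate_contacts(layout, [], cfg, n_replicates=1)
        sym = m.sym_csr("chr1")
        n = layout.n_bins("chr1")
        ds = np.arange(2, 200)
        means = np.array(
            [
                np.asarray(sym[np.arange(n - d), np.arange(d, n)]).ravel().mean()
                for d in ds
            ]
        )
        slope = np.polyfit(np.log(ds), np.log(means), 1)[0]
        assert abs(slope + cfg.decay_exponent) < 0.1

    def test_depth_within_tolerance(self, config):
        layout, genes, _, _ = synth.make_genome(config, 5, 0, chrom_length=4_000_000)
        mats = synth.simulate_contacts(layout, [], config, n_replicates=2)
        for m in mats:
            assert abs(m.total_count - config.target_depth) < 0.1 * config.target_depth

    def test_determinism_bytes(self, tmp_path, config):
        layout, genes, _, _ = synth.make_genome(config, 3, 0, chrom_length=3_000_000)
        loops, _ = synth.plant_loops(layout, genes, 2, seed=config.seed)
        files = []
        for tag in ("x", "y"):
            (m,) = synth.simulate_contacts(layout, loops, config, n_replicates=1)
            path = tmp_path / f"{tag}.tsv"
            write_contacts(m, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_anchor_outside_layout_errors(self, config):
        layout, genes, _, _ = synth.make_genome(config, 1, 0, chrom_length=3_000_000)
        bad = synth.LoopSpec(
            chrom="chr1", anchor_a=(0, 1000), anchor_b=(2_999_000, 3_100_000)
        )
        with pytest.raises(ValueError, match="anchor"):
            synth.simulate_contacts(layout, [bad], config, n_replicates=1)

    def test_mass_header_total(self, tmp_path, config):
        layout, _, _, _ = synth.make_genome(config, 1, 0, chrom_length=3_000_000)
        (m,) = synth.simulate_contacts(layout, [], config, n_replicates=1)
        path = tmp_path / "m.tsv"
        write_contacts(m, path)
        header = path.read_text().splitlines()[0]
        total = float(dict(t.split("=", 1) for t in header.split("\t")[1:])["total"])
        assert total == m.total_count


class TestSimulateExpression:
    def _truth(self, genes, factor_a):
        loops = [
            synth.LoopSpec(
                chrom="chr1",
                anchor_a=(int(g.start), int(g.start) + 1000),
                anchor_b=(int(g.start) + 20_000, int(g.start) + 21_000),
                base_enhancement=2.0,
                condition_factors={"a": fa},
                gene=str(g["name"]),
            )
            for (_, g), fa in zip(genes.iterrows(), factor_a)
        ]
        return synth.TruthTables(loops=loops)

    def test_noise_free_exact(self, config):
        layout, genes, _, _ = synth.make_genome(config, 4, 0, chrom_length=3_000_000)
        truth = self._truth(genes, [2.0] * 4)
        df = synth.simulate_expression(truth, genes, 1.0, 0.0, seed=0)
        np.testing.assert_allclose(df["log2fc"], 1.0)

    def test_zero_effect_uncorrelated(self):
        cfg = synth.SimConfig(seed=9)
        layout, genes, _, _ = synth.make_genome(cfg, 100, 0, chrom_length=50_000_000)
        rng = np.random.default_rng(1)
        factors = rng.choice([0.5, 1.0, 2.0, 4.0], size=100)
        truth = self._truth(genes, factors)
        df = synth.simulate_expression(truth, genes, 0.0, 0.5, seed=5)
        r = np.corrcoef(np.log2(factors), df["log2fc"])[0, 1]
        assert abs(r) < 0.25

    def test_determinism(self, config):
        layout, genes, _, _ = synth.make_genome(config, 4, 0, chrom_length=3_000_000)
        truth = self._truth(genes, [2.0] * 4)
        df1 = synth.simulate_expression(truth, genes, 1.0, 0.3, seed=3)
        df2 = synth.simulate_expression(truth, genes, 1.0, 0.3, seed=3)
        pd.testing.assert_frame_equal(df1, df2)


class TestTruthRoundTrip:
    def test_lossless(self, tmp_path, config):
        layout, genes, cres, mask = synth.make_genome(config, 5, 10, chrom_length=3_000_000)
        loops, _ = synth.plant_loops(
            layout, genes, 3, condition_factors={"a": 2.0}, seed=1
        )
        truth = synth.TruthTables(loops=loops, inactive_mask=mask)
        truth.gene_log2fc = pd.DataFrame(
            {"gene": genes["name"], "log2fc": np.linspace(-1, 1, 5)}
        )
        prefix = str(tmp_path / "truth")
        truth.write(prefix)
        back = synth.TruthTables.read(prefix)
        assert len(back.loops) == 3
        for a, b in zip(truth.loops, back.loops):
            assert a.chrom == b.chrom
            assert a.anchor_a == b.anchor_a and a.anchor_b == b.anchor_b
            assert a.base_enhancement == b.base_enhancement
            assert a.condition_factors == b.condition_factors
            assert a.gene == b.gene
        np.testing.assert_allclose(
            back.gene_log2fc["log2fc"], truth.gene_log2fc["log2fc"]
        )


class TestSimulateVariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def genome():
        cfg = synth.SimConfig(seed=13)
        layout, genes, cres, _ = synth.make_genome(cfg, 30, 80, chrom_length=8_000_000)
        loops, anchors = synth.plant_loops(layout, genes, 15, seed=13)
        return layout, genes, cres, anchors

    def test_fold_below_one_errors(self, genome):
        layout, genes, cres, anchors = genome
        with pytest.raises(ValueError, match="fold"):
            synth.simulate_variants(
                layout, cres, 0.5, 10, 2, seed=0,
                tss_positions=genes[["chrom", "start"]],
                pi_regions=anchors[["chrom", "start", "end"]],
            )

    def test_no_proxies(self, genome):
        layout, genes, cres, anchors = genome
        v = synth.simulate_variants(
            layout, cres, 1.0, 10, 0, seed=0,
            tss_positions=genes[["chrom", "start"]],
            pi_regions=anchors[["chrom", "start", "end"]],
            pool_size=400,
        )
        assert len(v["proxies"]) == 0

    def test_planted_fold_recovered(self, genome):
        layout, genes, cres, anchors = genome
        pi = anchors[["chrom", "start", "end"]]
        v = synth.simulate_variants(
            layout, cres, 3.0, 150, 3, seed=21,
            tss_positions=genes[["chrom", "start"]], pi_regions=pi,
            pool_size=3000,
        )
        from pidscape.variant_enrichment import expand_proxies, overlap_indicator

        trait_sets = expand_proxies(v["leads"], v["proxies"], v["features"])
        pool_sets = expand_proxies(v["pool"], v["proxies"], v["features"])
        rate_t = np.mean([overlap_indicator(s, pi) for s in trait_sets])
        rate_p = np.mean([overlap_indicator(s, pi) for s in pool_sets])
        assert 2.0 <= rate_t / rate_p <= 4.0

    def test_null_fold_near_one(self, genome):
        layout, genes, cres, anchors = genome
        pi = anchors[["chrom", "start", "end"]]
        v = synth.simulate_variants(
            layout, cres, 1.0, 150, 3, seed=22,
            tss_positions=genes[["chrom", "start"]], pi_regions=pi,
            pool_size=3000,
        )
        from pidscape.variant_enrichment import expand_proxies, overlap_indicator

        trait_sets = expand_proxies(v["leads"], v["proxies"], v["features"])
        pool_sets = expand_proxies(v["pool"], v["proxies"], v["features"])
        rate_t = np.mean([overlap_indicator(s, pi) for s in trait_sets])
        rate_p = np.mean([overlap_indicator(s, pi) for s in pool_sets])
        assert 0.5 <= rate_t / rate_p <= 1.7

    def test_determinism(self, genome):
        layout, genes, cres, anchors = genome
        kwargs = dict(
            tss_positions=genes[["chrom", "start"]],
            pi_regions=anchors[["chrom", "start", "end"]],
            pool_size=300,
        )
        v1 = synth.simulate_variants(layout, cres, 2.0, 20, 2, seed=5, **kwargs)
        v2 = synth.simulate_variants(layout, cres, 2.0, 20, 2, seed=5, **kwargs)
        for key in v1:
            pd.testing.assert_frame_equal(v1[key], v2[key])
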