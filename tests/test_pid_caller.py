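import numpy as np
import pandas as pd
import pytest

from pidscape import background_model as bg
from pidscape import pid_caller as pc
from pidscape._profile import smooth_truncated
from pidscape.contact_store import BinnedContacts
from pidscape.genome import GenomeLayout, intervals_overlap


def _toy_model(offsets, mu, var, bin_size=1000):
    return bg.BackgroundModel(
        bin_size=bin_size,
        offsets=np.asarray(offsets),
        mu=np.asarray(mu, dtype=float),
        var=np.asarray(var, dtype=float),
        n=np.full(len(offsets), 10),
    )


def _profile(offsets, rel, raw=None, tss=500_000, gene="g", bin_size=1000, avg_bins=1):
    offsets = np.asarray(offsets)
    rel = np.asarray(rel, dtype=float)
    raw = rel * 100 if raw is None else np.asarray(raw, dtype=float)
    vp = pc.ViewpointSpec(gene=gene, chrom="chr1", tss=tss)
    return pc.RelativeProfile(
        viewpoint=vp, offsets=offsets, raw=raw, rel=rel,
        smoothed=smooth_truncated(rel, avg_bins) if avg_bins > 1 else rel.copy(),
        total=float(raw.sum()), avg_bins=avg_bins, bin_size=bin_size,
    )


class TestSmoothing:
    def test_constant_unchanged(self):
        x = np.full(20, 0.05)
        np.testing.assert_allclose(smooth_truncated(x, 5), x)

    def test_interior_impulse_convolution_oracle(self):
        x = np.zeros(11)
        x[5] = 1.0
        got = smooth_truncated(x, 5)
        # direct truncated-window convolution
        expected = np.array(
            [
                x[max(0, b - 2): b + 3].sum() / len(x[max(0, b - 2): b + 3])
                for b in range(11)
            ]
        )
        np.testing.assert_allclose(got, expected)
        np.testing.assert_allclose(got[3:8], 0.2)

    def test_width_one_identity(self):
        x = np.arange(7.0)
        np.testing.assert_allclose(smooth_truncated(x, 1), x)


class TestExtractProfile:
    def test_simple_arithmetic(self):
        layout = GenomeLayout(("chr1",), (9000,), 1000)
        m = BinnedContacts(layout)
        # viewpoint bin 4; window +-1 bin; counts 10, 20, 70
        m.set_chrom("chr1", [3, 4, 4], [4, 4, 5], [10.0, 20.0, 70.0])
        vp = pc.ViewpointSpec(gene="g", chrom="chr1", tss=4500, halfwidth=400)
        prof = pc.extract_profile(m, vp, range_bp=1000, avg_bins=1)
        np.testing.assert_allclose(prof.rel, [0.1, 0.2, 0.7])
        assert prof.total == 100

    def test_rel_sums_to_one(self, toy_stack):
        for _, row in toy_stack.genes.iterrows():
            vp = pc.ViewpointSpec(
                gene=str(row["name"]), chrom=row["chrom"], tss=int(row["start"])
            )
            prof = pc.extract_profile(toy_stack.merged, vp)
            assert abs(prof.rel.sum() - 1.0) < 1e-9

    def test_zero_window_errors(self):
        layout = GenomeLayout(("chr1",), (9000,), 1000)
        m = BinnedContacts(layout)
        m.set_chrom("chr1", [0], [1], [5.0])
        vp = pc.ViewpointSpec(gene="g", chrom="chr1", tss=7500, halfwidth=400)
        with pytest.raises(ValueError, match="total"):
            pc.extract_profile(m, vp, range_bp=1000, avg_bins=1)

    def test_clipped_at_edge(self, toy_stack):
        row = toy_stack.genes.iloc[0]
        vp = pc.ViewpointSpec(gene="edge", chrom="chr1", tss=50_000)
        prof = pc.extract_profile(toy_stack.merged, vp)
        assert prof.clipped
        assert prof.offsets[0] == -50  # window truncated at chromosome start


class TestBinPvalues:
    def test_scaled_oracle(self):
        # 5-bin window: T = 5. mu*T = 2, var*T^2 = 4, value*T = 1 -> p = 0.75
        offsets = np.arange(-2, 3)
        prof = _profile(offsets, np.full(5, 0.2))
        model = _toy_model(offsets, np.full(5, 0.4), np.full(5, 4 / 25))
        p = pc.bin_pvalues(prof, model)
        np.testing.assert_allclose(p, 0.75)

    def test_zero_value_p_one(self):
        offsets = np.arange(-2, 3)
        rel = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
        prof = _profile(offsets, rel)
        model = _toy_model(offsets, np.full(5, 0.1), np.full(5, 0.05))
        p = pc.bin_pvalues(prof, model)
        assert np.all(p[rel == 0] == 1.0)

    def test_below_mean_large_p(self):
        offsets = np.arange(-2, 3)
        prof = _profile(offsets, np.full(5, 0.1))
        model = _toy_model(offsets, np.full(5, 0.4), np.full(5, 0.5))
        assert np.all(pc.bin_pvalues(prof, model) > 0.5)

    def test_offset_outside_model_errors(self):
        offsets = np.arange(-3, 4)
        prof = _profile(offsets, np.full(7, 1 / 7))
        model = _toy_model(np.arange(-2, 3), np.full(5, 0.1), np.full(5, 0.2))
        with pytest.raises(ValueError, match="offset"):
            pc.bin_pvalues(prof, model)


class TestCallPids:
    def test_hand_thresholding(self):
        # relative [1,1,4,5,1] (unit-scaled) vs mu 1: candidates = bins 3-4
        offsets = np.arange(30, 35)
        rel = np.array([1, 1, 4, 5, 1]) / 12.0
        prof = _profile(offsets, rel, raw=np.array([1, 1, 4, 5, 1.0]) * 20)
        model = _toy_model(offsets, np.full(5, 1 / 12), np.full(5, 2 / 144))
        out = pc.call_pids(prof, model, xf=1.5, p_cutoff=1.0, peak_min=0.0)
        assert len(out) == 1
        row = out.iloc[0]
        center = prof.viewpoint.tss // 1000
        assert row["start"] == (center + 32) * 1000
        assert row["end"] == (center + 34) * 1000
        assert row["n_bins"] == 2
        assert row["fold"] == pytest.approx((9 / 12) / (2 / 12))

    def test_infinite_xf_empty(self):
        offsets = np.arange(20, 30)
        prof = _profile(offsets, np.full(10, 0.1))
        model = _toy_model(offsets, np.full(10, 0.1), np.full(10, 0.02))
        out = pc.call_pids(prof, model, xf=1e12)
        assert len(out) == 0

    def test_exhaustive_oracle_30_bins(self):
        rng = np.random.default_rng(5)
        offsets = np.arange(-15, 15)
        rel = rng.gamma(2.0, 0.02, size=30)
        rel /= rel.sum()
        raw = rel * 400
        prof = _profile(offsets, rel, raw=raw)
        mu = np.full(30, rel.mean() * 0.8)
        var = mu * 1.5 / 30
        model = _toy_model(offsets, mu, var)
        xf, p_cutoff, peak_min, exclusion = 1.5, 0.05, 2.0, 3000
        got = pc.call_pids(
            prof, model, xf=xf, p_cutoff=p_cutoff, peak_min=peak_min,
            exclusion=exclusion,
        )
        # independent brute force: enumerate maximal candidate runs by scan
        T = 30.0
        cand = rel >= xf * mu
        runs, run = [], []
        for k in range(30):
            if cand[k] and rel[k] > 0:
                run.append(k)
            elif run:
                runs.append(run)
                run = []
        if run:
            runs.append(run)
        expected = []
        center = prof.viewpoint.tss // 1000
        for run in runs:
            S = sum(rel[k] for k in run)
            M = sum(mu[k] for k in run)
            V = sum(var[k] for k in run)
            p = bg.nb_tail(S * T, M * T, V * T * T)
            if p > p_cutoff or max(raw[k] for k in run) < peak_min:
                continue
            start = (center + offsets[run[0]]) * 1000
            end = (center + offsets[run[-1]] + 1) * 1000
            if start < prof.viewpoint.tss + exclusion and end > prof.viewpoint.tss - exclusion:
                continue
            expected.append((start, end, p))
        assert len(got) == len(expected)
        for row, (start, end, p) in zip(got.itertuples(), expected):
            assert row.start == start and row.end == end
            assert row.p_value == pytest.approx(p)

    def test_depth_rescaling_invariance(self, toy_stack):
        m2 = toy_stack.merged.copy()
        for chrom in list(m2._data):
            i, j, c = m2._data[chrom]
            m2._data[chrom] = (i, j, c * 3.7)
        m2._sym_cache.clear()
        row = toy_stack.genes.iloc[0]
        vp = pc.ViewpointSpec(gene=str(row["name"]), chrom=row["chrom"], tss=int(row["start"]))
        p1 = pc.extract_profile(toy_stack.merged, vp)
        p2 = pc.extract_profile(m2, vp)
        np.testing.assert_allclose(p1.rel, p2.rel)
        out1 = pc.call_pids(p1, toy_stack.model, peak_min=0.0)
        out2 = pc.call_pids(p2, toy_stack.model, peak_min=0.0)
        pd.testing.assert_frame_equal(
            out1.drop(columns="peak_raw"), out2.drop(columns="peak_raw")
        )


class TestTiled:
    def test_uniform_matrix_flat(self):
        layout = GenomeLayout(("chr1",), (60_000,), 1000)
        n = 60
        iu, ju = np.triu_indices(n)
        m = BinnedContacts(layout)
        m.set_chrom("chr1", iu, ju, np.ones(iu.size))
        vp = pc.ViewpointSpec(gene="g", chrom="chr1", tss=30_000, halfwidth=500)
        out = pc.tiled_profile(m, vp, (20_000, 40_000), range_bp=20_000)
        np.testing.assert_allclose(out["value"], out["value"].iloc[0])

    def test_single_bin_tile_identity(self, toy_stack):
        row = toy_stack.genes.iloc[2]
        tss = int(row["start"])
        vp = pc.ViewpointSpec(gene=str(row["name"]), chrom="chr1", tss=tss)
        prof = pc.extract_profile(toy_stack.merged, vp)
        center = tss // 1000
        start = (center + 20) * 1000
        out = pc.tiled_profile(toy_stack.merged, vp, (start, start + 1000))
        idx = np.where(prof.offsets == 20)[0][0]
        assert out["value"].iloc[0] == pytest.approx(prof.smoothed[idx])

    def test_two_bin_tile_mean(self, toy_stack):
        row = toy_stack.genes.iloc[2]
        tss = int(row["start"])
        vp = pc.ViewpointSpec(gene=str(row["name"]), chrom="chr1", tss=tss)
        prof = pc.extract_profile(toy_stack.merged, vp)
        center = tss // 1000
        start = (center + 20) * 1000
        out = pc.tiled_profile(
            toy_stack.merged, vp, (start, start + 2000), tile=2000, step=2000
        )
        i1 = np.where(prof.offsets == 20)[0][0]
        assert out["value"].iloc[0] == pytest.approx(
            prof.smoothed[i1 : i1 + 2].mean()
        )

    def test_region_outside_window_errors(self, toy_stack):
        row = toy_stack.genes.iloc[2]
        vp = pc.ViewpointSpec(
            gene=str(row["name"]), chrom="chr1", tss=int(row["start"])
        )
        with pytest.raises(ValueError, match="window"):
            pc.tiled_profile(
                toy_stack.merged, vp,
                (int(row["start"]) + 2_000_000, int(row["start"]) + 2_010_000),
            )


class TestGenomewide:
    def test_planted_loops_recovered(self, toy_stack):
        pids, summary, qc = pc.genomewide_pids(
            toy_stack.merged, toy_stack.genes, toy_stack.model
        )
        assert qc["qc_pass"].all()
        for loop in toy_stack.loops:
            sub = pids[pids["gene"] == loop.gene]
            assert any(
                intervals_overlap(s, e, *loop.anchor_b)
                for s, e in zip(sub["start"], sub["end"])
            ), f"planted loop for {loop.gene} not recovered"

    def test_exclusion_and_threshold_invariants(self, toy_stack):
        pids, _, _ = pc.genomewide_pids(
            toy_stack.merged, toy_stack.genes, toy_stack.model
        )
        tss = dict(
            zip(toy_stack.genes["name"].astype(str), toy_stack.genes["start"])
        )
        for row in pids.itertuples():
            t = tss[row.gene]
            assert not intervals_overlap(
                row.start, row.end, t - 10_000, t + 10_000
            )
            assert row.p_value <= 1e-10
            assert row.peak_raw >= 10
            assert row.end - row.start >= 1000

    def test_no_viewpoint_passing_qc_errors(self, toy_stack):
        empty = BinnedContacts(toy_stack.layout)
        empty.set_chrom("chr1", [0], [1], [1.0])
        with pytest.raises(ValueError, match="QC"):
            pc.genomewide_pids(empty, toy_stack.genes, toy_stack.model)

    def test_gene_summary_semantics(self, toy_stack):
        pids, summary, _ = pc.genomewide_pids(
            toy_stack.merged, toy_stack.genes, toy_stack.model
        )
        gene = toy_stack.loops[0].gene
        row = summary[summary["gene"] == gene].iloc[0]
        sub = pids[pids["gene"] == gene]
        assert row["pid_count"] == len(sub)
        assert row["total_pid_length"] == (sub["end"] - sub["start"]).sum()
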