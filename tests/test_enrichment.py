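import numpy as np
import pandas as pd
import pytest

import tilepc as tp

from conftest import (
    assert_scores_close,
    brute_call_intervals,
    brute_window_mean,
    make_probe_map,
    random_instance,
)


def gene(chrom="chr1", start=1000, end=2000, strand="+", gene_id="g1"):
    return tp.GeneModels(
        pd.DataFrame(
            {"gene_id": [gene_id], "chrom": [chrom], "start": [start],
             "end": [end], "strand": [strand]}
        )
    ).df.iloc[0]


class TestTssWindowScore:
    def test_constant_track(self):
        pm = make_probe_map(np.arange(0, 3000, 100))
        track = tp.EnrichmentTrack(pm, np.full(len(pm), 2.0))
        assert tp.tss_window_score(track, gene()) == pytest.approx(2.0)

    def test_hand_checked_mean_over_window(self):
        tss = 1000
        pm = make_probe_map(tss + np.arange(-400, 401, 100))
        scores = np.array([0, 0, 0, 1, 2, 1, 0, 0, 0], dtype=float)
        track = tp.EnrichmentTrack(pm, scores)
        assert tp.tss_window_score(track, gene(start=tss)) == pytest.approx(4 / 9)

    def test_missing_when_too_few_probes(self):
        pm = make_probe_map([900, 1000, 1100])
        track = tp.EnrichmentTrack(pm, np.ones(3))
        assert np.isnan(tp.tss_window_score(track, gene()))

    def test_invalid_half_width(self):
        pm = make_probe_map([1000])
        track = tp.EnrichmentTrack(pm, [1.0])
        with pytest.raises(tp.ValidationError):
            tp.tss_window_score(track, gene(), half_width=0)


class TestIntervalWindowScore:
    def test_constant_track(self):
        pm = make_probe_map(np.arange(0, 3000, 100))
        track = tp.EnrichmentTrack(pm, np.full(len(pm), 1.25))
        assert tp.interval_window_score(track, "chr1", 1000, 2000) == pytest.approx(1.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_window_mean(self, seed):
        rng = np.random.default_rng(100 + seed)
        pm, scores = random_instance(rng, n_max=200)
        track = tp.EnrichmentTrack(pm, scores)
        chrom = pm.chroms[0]
        start, end = sorted(rng.integers(0, 60_000, size=2).tolist())
        got = tp.interval_window_score(track, chrom, start, end + 1)
        want = brute_window_mean(pm, scores, chrom, (start + end + 1) // 2, 500, 4)
        np.testing.assert_array_equal(got, want)


class TestCallIntervals:
    def test_single_run_above_threshold(self):
        pm = make_probe_map([100, 200, 300, 400])
        track = tp.EnrichmentTrack(pm, [0.5, 1.2, 1.3, 0.8])
        peaks = tp.call_intervals(track, threshold=1.0)
        assert len(peaks) == 1
        row = peaks.df.iloc[0]
        # spans first to last qualifying probe (mids 200 and 300)
        assert (row["start"], row["end"], row["n_probes"]) == (175, 325, 2)

    def test_all_below_threshold_gives_empty(self):
        pm = make_probe_map([0, 100, 200])
        track = tp.EnrichmentTrack(pm, [0.1, 0.2, 0.3])
        assert len(tp.call_intervals(track, threshold=1.0)) == 0

    def test_distant_runs_stay_separate(self):
        mids = [0, 100, 1500, 1600]  # 1 kb gap > max_gap
        pm = make_probe_map(mids)
        track = tp.EnrichmentTrack(pm, [2.0, 2.0, 2.0, 2.0])
        peaks = tp.call_intervals(track, threshold=1.0, max_gap=250)
        assert len(peaks) == 2

    def test_min_probes_drops_singletons(self):
        pm = make_probe_map([100, 1100, 1200])
        track = tp.EnrichmentTrack(pm, [2.0, 2.0, 2.0])
        peaks = tp.call_intervals(track, threshold=1.0, max_gap=250, min_probes=2)
        assert len(peaks) == 1 and peaks.df.iloc[0]["start"] == 1075

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        pm, scores = random_instance(rng, n_max=200)
        thr = float(rng.normal(0, 1))
        gap = int(rng.choice([0, 100, 250, 1000]))
        mp = int(rng.integers(1, 4))
        track = tp.EnrichmentTrack(pm, scores)
        got = tp.call_intervals(track, thr, gap, mp)
        want = brute_call_intervals(pm, scores, thr, gap, mp)
        assert [
            (r.chrom, r.start, r.end, r.n_probes) for r in got.df.itertuples()
        ] == want

    def test_interval_count_monotone_in_threshold(self):
        rng = np.random.default_rng(42)
        pm, scores = random_instance(rng, n_max=300, missing_frac=0.0)
        track = tp.EnrichmentTrack(pm, scores)
        counts = [
            len(tp.call_intervals(track, thr, min_probes=1))
            for thr in [-np.inf, 0.0, np.inf]
        ]
        # empty at +inf; at -inf exactly one interval per run of probes
        # separated by <= max_gap (the brute-force run count)
        assert counts[-1] == 0
        runs_at_minus_inf = brute_call_intervals(pm, scores, -np.inf, 250, 1)
        assert counts[0] == len(runs_at_minus_inf) >= 1


class TestMetagene:
    def test_constant_track_gives_flat_profile(self):
        pm = make_probe_map(np.arange(0, 30_000, 75))
        track = tp.EnrichmentTrack(pm, np.full(len(pm), 1.5))
        genes = tp.GeneModels(
            pd.DataFrame(
                {"gene_id": ["a", "b"], "chrom": "chr1", "start": [10_000, 20_000],
                 "end": [11_000, 21_000], "strand": ["+", "-"]}
            )
        )
        prof = tp.metagene_profile(track, genes)
        np.testing.assert_allclose(prof.mean[~np.isnan(prof.mean)], 1.5)

    def test_strand_orientation_mirrors_minus_genes(self):
        # identical asymmetric signal around both TSSs, mirrored for the
        # minus-strand gene: the pooled profile equals either oriented one
        pm = make_probe_map(np.arange(0, 40_000, 100))
        mids = pm.midpoints
        tss_plus, tss_minus = 10_000, 30_000  # both on the probe grid
        signal = np.zeros(len(pm))
        bump = lambda off: np.exp(-0.5 * ((off - 300) / 200.0) ** 2)  # peak downstream
        signal += bump(mids - tss_plus)
        signal += bump(-(mids - tss_minus))
        track = tp.EnrichmentTrack(pm, signal)
        both = tp.GeneModels(
            pd.DataFrame(
                {"gene_id": ["p", "m"], "chrom": "chr1",
                 "start": [tss_plus, tss_minus - 999], "end": [tss_plus + 1000, tss_minus + 1],
                 "strand": ["+", "-"]}
            )
        )
        prof_both = tp.metagene_profile(track, both)
        prof_plus = tp.metagene_profile(track, both, tp.GeneSet.from_ids("p", ["p"]))
        np.testing.assert_allclose(prof_both.mean, prof_plus.mean, atol=1e-12)
        # and the peak sits downstream of the TSS
        assert prof_both.offsets[np.nanargmax(prof_both.mean)] > 0

    def test_planted_gaussian_bump_recovered(self):
        # 200 target genes, log2 amplitude 1.5, sd 300 bp, noise sd 0.3
        cfg = tp.SimConfig(n_chroms=1, chrom_length=3_000_000, n_genes=200,
                           target_fraction=1.0, seed=3)
        rng = np.random.default_rng(cfg.seed)
        genes, probes = tp.simulate_genome(cfg, rng)
        mids = probes.midpoints
        signal = np.zeros(len(probes))
        for tss in genes.df["tss"]:
            off = mids - tss
            signal += 1.5 * np.exp(-0.5 * (off / 300.0) ** 2)
        track = tp.EnrichmentTrack(probes, signal + rng.normal(0, 0.3, len(probes)))
        prof = tp.metagene_profile(track, genes)
        peak_bin = np.nanargmax(prof.mean)
        assert abs(prof.offsets[peak_bin]) <= 50  # bin containing the TSS
        assert prof.mean[peak_bin] == pytest.approx(1.5, rel=0.2)

    def test_empty_gene_set_rejected(self):
        pm = make_probe_map([0, 100])
        track = tp.EnrichmentTrack(pm, [1.0, 1.0])
        genes = tp.GeneModels(
            pd.DataFrame({"gene_id": ["a"], "chrom": ["chr1"], "start": [0],
                          "end": [100], "strand": ["+"]})
        )
        with pytest.raises(tp.ValidationError):
            tp.metagene_profile(track, genes, tp.GeneSet.from_ids("empty", []))


class TestRandomBackground:
    def test_deterministic_for_fixed_seed(self):
        cfg = tp.SimConfig(n_chroms=1, chrom_length=1_000_000, n_genes=100,
                           target_fraction=0.0, seed=4)
        genes, probes = tp.simulate_genome(cfg)
        rng = np.random.default_rng(4)
        track = tp.EnrichmentTrack(probes, rng.normal(0, 1, len(probes)))
        a = tp.random_background_profile(track, genes, n_genes=30, n_samplings=3, seed=7)
        b = tp.random_background_profile(track, genes, n_genes=30, n_samplings=3, seed=7)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_mean_matches_signal_dilution_expectation(self):
        # 5% of genes carry a flat signal a; a uniformly sampled background
        # profile has expectation 0.05 * a at the TSS
        a = 2.0
        cfg = tp.SimConfig(n_chroms=1, chrom_length=6_000_000, n_genes=600,
                           target_fraction=0.05, seed=5)
        rng = np.random.default_rng(cfg.seed)
        genes, probes = tp.simulate_genome(cfg, rng)
        carriers = rng.choice(len(genes), size=30, replace=False)
        mids = probes.midpoints
        signal = np.zeros(len(probes))
        for tss in genes.df["tss"].to_numpy()[carriers]:
            signal[np.abs(mids - tss) < 750] = a
        track = tp.EnrichmentTrack(probes, signal)
        prof = tp.random_background_profile(
            track, genes, n_genes=300, n_samplings=20, span=500, seed=8
        )
        center = np.abs(prof.offsets).argmin()
        assert prof.mean[center] == pytest.approx(0.05 * a, abs=0.04)

    def test_sample_larger_than_universe_rejected(self):
        pm = make_probe_map([0, 100])
        track = tp.EnrichmentTrack(pm, [1.0, 1.0])
        genes = tp.GeneModels(
            pd.DataFrame({"gene_id": ["a"], "chrom": ["chr1"], "start": [0],
                          "end": [100], "strand": ["+"]})
        )
        with pytest.raises(tp.ValidationError):
            tp.random_background_profile(track, genes, n_genes=5, n_samplings=2)


class TestScoreGeneTable:
    def test_constant_tracks(self):
        pm = make_probe_map(np.arange(0, 5000, 100))
        tracks = {
            "wt": tp.EnrichmentTrack(pm, np.full(len(pm), 1.0)),
            "mut": tp.EnrichmentTrack(pm, np.full(len(pm), 2.0)),
        }
        genes = tp.GeneModels(
            pd.DataFrame({"gene_id": ["a", "b"], "chrom": "chr1",
                          "start": [1000, 3000], "end": [1500, 3500],
                          "strand": ["+", "-"]})
        )
        table = tp.score_gene_table(tracks, genes)
        np.testing.assert_array_equal(table.to_numpy(), [[1.0, 2.0], [1.0, 2.0]])

    def test_gene_without_probes_gets_missing_cell(self):
        pm = make_probe_map([100, 200, 300, 400])
        tracks = {"wt": tp.EnrichmentTrack(pm, np.ones(4))}
        genes = tp.GeneModels(
            pd.DataFrame({"gene_id": ["far"], "chrom": ["chr1"], "start": [50_000],
                          "end": [51_000], "strand": ["+"]})
        )
        assert np.isnan(tp.score_gene_table(tracks, genes).iloc[0, 0])

    def test_agrees_with_per_gene_scoring(self, small_sim):
        cfg, genes, probes, matrix, truth = small_sim
        tracks = tp.normalize_experiment(matrix)
        table = tp.score_gene_table(tracks, genes)
        rng = np.random.default_rng(0)
        for gid in rng.choice(genes.gene_ids, size=20, replace=False):
            expect = tp.tss_window_score(tracks["wildtype"], genes.df.loc[gid])
            assert_scores_close(table.at[gid, "wildtype"], expect)

    def test_recovers_planted_amplitudes(self, default_sim):
        table, truth = default_sim["table"], default_sim["truth"]
        joint = pd.concat([table["wildtype"], truth.genes["amplitude"]], axis=1).dropna()
        r = np.corrcoef(joint.iloc[:, 0], joint.iloc[:, 1])[0, 1]
        assert r > 0.9
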