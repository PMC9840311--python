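"""Copy-number depth, GC correction, baseline panel, segment calling."""
import numpy as np
import pytest

from ocscore import (FragmentSimulator, SimulationConfig, build_baseline,
                     build_toy_genome, call_cnv, gc_correct, window_depth)
from ocscore.cnv import BaselinePanel, DepthVector, depth_windows, smooth_depth
from ocscore.fragmentation import BinScheme

from helpers import fragments, genome_from_strings, random_sequence


def _flat_scheme(n, size=2000):
    return BinScheme(np.array(["chr1"] * n, dtype=object),
                     np.arange(n) * size, (np.arange(n) + 1) * size, size)


class TestWindowDepth:
    def test_counts_by_midpoint(self):
        rng = np.random.default_rng(0)
        g = genome_from_strings({"chrT": random_sequence(rng, 4000)})
        starts = np.full(100, 500)
        dv = window_depth(fragments("chrT", starts, starts + 100), g)
        assert dv.raw[0] == 100 and dv.raw[1] == 0
        assert dv.corrected.mean() == pytest.approx(1.0, abs=1e-9)

    def test_hand_built_fragments_match_midpoint_oracle(self):
        rng = np.random.default_rng(1)
        g = genome_from_strings({"chrT": random_sequence(rng, 10_000)})
        starts = np.array([0, 1900, 1990, 5000, 9800])
        ends = np.array([200, 2100, 2030, 5100, 9999])
        dv = window_depth(fragments("chrT", starts, ends), g)
        oracle = np.zeros(5)
        for s, e in zip(starts, ends):
            oracle[((s + e) // 2) // 2000] += 1
        assert np.array_equal(dv.raw, oracle)

    def test_uniform_fragments_give_flat_corrected_depth(self, small_genome, small_config):
        from ocscore import simulate_sample
        fs = simulate_sample(small_genome, "HC", small_config, seed=3,
                             n_fragments=200_000)
        dv = gc_correct(window_depth(fs, small_genome), small_genome.gc_concat())
        interior = dv.corrected[5:-5]
        assert abs(interior.mean() - 1.0) < 0.02
        assert interior.std() < 0.5  # pure counting noise at this depth


class TestGcCorrect:
    def test_identity_when_depth_flat_across_gc(self):
        rng = np.random.default_rng(5)
        gc = rng.uniform(0.3, 0.6, 2000)
        d = np.ones(2000)
        dv = DepthVector(d.copy(), d.copy(), _flat_scheme(2000))
        out = gc_correct(dv, gc)
        assert np.allclose(out.corrected, 1.0, atol=1e-9)

    def test_planted_linear_gc_bias_removed(self):
        rng = np.random.default_rng(6)
        gc = rng.uniform(0.3, 0.6, 5000)
        depth = 0.5 + gc + rng.normal(0, 0.01, 5000)
        depth = depth / depth.mean()
        dv = DepthVector(depth.copy(), depth.copy(), _flat_scheme(5000))
        out = gc_correct(dv, gc)
        assert depth.std() / out.corrected.std() >= 5.0
        assert out.corrected.mean() == pytest.approx(1.0, abs=1e-9)
        # per-decile medians agree after correction
        deciles = np.quantile(gc, np.linspace(0, 1, 11))
        meds = [np.median(out.corrected[(gc >= a) & (gc <= b)])
                for a, b in zip(deciles[:-1], deciles[1:])]
        assert np.allclose(meds, meds[0], atol=1e-6)
        assert meds[0] == pytest.approx(1.0, abs=0.02)

    def test_all_zero_depth_rejected(self):
        dv = DepthVector(np.zeros(100), np.zeros(100), _flat_scheme(100))
        with pytest.raises(ValueError, match="unusable"):
            gc_correct(dv, np.full(100, 0.4))


class TestBaselinePanel:
    def test_identical_samples_hit_sigma_floor(self):
        mat = np.ones((8, 50))
        panel = build_baseline(mat)
        assert np.allclose(panel.sigma, 0.03)  # 0.03 * mu floor everywhere
        assert np.allclose(panel.mu, 1.0)

    def test_too_few_samples_refused(self):
        with pytest.raises(ValueError, match=">= 5"):
            build_baseline(np.ones((4, 50)))

    def test_window_count_matches_genome_scheme(self, small_genome):
        scheme = depth_windows(small_genome)
        assert len(scheme) == small_genome.n_windows()

    def test_panel_mean_near_one_in_neutral_windows(self, cnv_experiment):
        assert cnv_experiment.panel.mu.mean() == pytest.approx(1.0, abs=1e-6)
        assert np.median(cnv_experiment.panel.mu) == pytest.approx(1.0, abs=0.02)


class TestCallCnv:
    def test_copy_neutral_sample_scores_zero(self):
        rng = np.random.default_rng(7)
        n = 5000
        panel = BaselinePanel(np.ones(n), np.full(n, 0.05), 10)
        d = 1.0 + rng.normal(0, 0.05, n)
        call = call_cnv(DepthVector(d, d, _flat_scheme(n)), panel)
        assert call.segments == []
        assert call.cnv_score == 0.0

    def test_single_significant_window_is_not_a_segment(self):
        n = 3000
        panel = BaselinePanel(np.ones(n), np.full(n, 0.05), 10)
        d = np.ones(n)
        d[1500] = 2.0
        call = call_cnv(DepthVector(d, d, _flat_scheme(n)), panel)
        assert call.segments == []

    def test_block_shorter_than_2mb_is_not_emitted(self):
        n = 3000
        panel = BaselinePanel(np.ones(n), np.full(n, 0.05), 10)
        d = np.ones(n)
        d[1000:1900] = 1.5  # 1.8 Mb block of clearly significant windows
        call = call_cnv(DepthVector(d, d, _flat_scheme(n)), panel)
        assert call.segments == []

    def test_planted_gain_recovered_with_tight_boundaries(self, cnv_experiment):
        call = cnv_experiment.call_gain
        gains = [s for s in call.segments if s[4] == "gain"]
        assert len(gains) == 1
        chrom, start, end, mean_z, _ = gains[0]
        w_err_start = abs(start - 7_000_000) // 2000
        w_err_end = abs(end - 12_000_000) // 2000
        assert w_err_start <= 10 and w_err_end <= 10
        assert mean_z > 3
        assert call.cnv_score > 0

    def test_score_monotone_in_copy_ratio(self, cnv_experiment):
        s_neutral = cnv_experiment.call_neutral.cnv_score
        s_15 = cnv_experiment.call_gain.cnv_score
        s_20 = cnv_experiment.call_gain_2x.cnv_score
        assert s_neutral == 0.0
        assert s_neutral < s_15 < s_20

    def test_score_zero_iff_no_segments(self, cnv_experiment):
        for call in (cnv_experiment.call_gain, cnv_experiment.call_neutral):
            assert (call.cnv_score == 0.0) == (len(call.segments) == 0)

    def test_mismatched_window_schemes_rejected(self):
        panel = BaselinePanel(np.ones(100), np.full(100, 0.05), 10)
        d = np.ones(50)
        with pytest.raises(ValueError):
            call_cnv(DepthVector(d, d, _flat_scheme(50)), panel)


class TestCopyNeutralSpecificity:
    def test_copy_neutral_cohort_scores_zero(self):
        """Fraction of 50 copy-neutral samples with cnv_score > 0 is <= 0.05."""
        config = SimulationConfig(
            n_healthy=20, n_tumor=1, fragments_per_sample=500_000,
            chrom_lengths=(("chr1", 20_000_000),), tss_per_chrom=20,
            n_ndr_altered=4, cnv_segments=(), seed=23,
        )
        genome = build_toy_genome(config)
        sim = FragmentSimulator(genome, config)
        gc = genome.gc_concat()
        rng = np.random.default_rng(200)

        def depth_of(fs):
            return smooth_depth(gc_correct(window_depth(fs, genome), gc))

        panel = build_baseline(np.vstack([
            depth_of(sim.sample(f"P{i}", "HC", rng)).corrected for i in range(20)
        ]))
        n_positive = 0
        for i in range(50):
            call = call_cnv(depth_of(sim.sample(f"N{i}", "HC", rng)), panel)
            n_positive += call.cnv_score > 0
        assert n_positive / 50 <= 0.05
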