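"""Simulator contracts: determinism, planted truth, mixture expectations."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from ocscore import (ConfigurationError, FragmentSimulator, SimulationConfig,
                     build_toy_genome, cohort_manifest, simulate_cohort,
                     simulate_sample, wilcoxon_rank_sum)
from ocscore.simulate import _sample_rng

from helpers import genome_from_strings


def tiny_build_config(**kw):
    base = dict(n_healthy=3, n_tumor=2, fragments_per_sample=2000,
                chrom_lengths=(("chr1", 4_000_000),), tss_per_chrom=10,
                n_ndr_altered=3, cnv_segments=(), seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestBuildToyGenome:
    def test_deterministic_for_fixed_seed(self):
        g1 = build_toy_genome(tiny_build_config())
        g2 = build_toy_genome(tiny_build_config())
        assert np.array_equal(g1.sequence["chr1"], g2.sequence["chr1"])
        pd.testing.assert_frame_equal(g1.tss, g2.tss)
        assert g1.truth.to_dict() == g2.truth.to_dict()

    def test_planted_gain_in_truth(self):
        cfg = tiny_build_config(
            chrom_lengths=(("chr1", 12_000_000),),
            cnv_segments=(("chr1", 3_000_000, 8_000_000, 1.5),))
        g = build_toy_genome(cfg)
        assert len(g.truth.cnv_segments) == 1
        seg = g.truth.cnv_segments[0]
        assert seg.end - seg.start == 5_000_000

    def test_gc_track_matches_bruteforce_recount(self):
        g = build_toy_genome(tiny_build_config())
        seq = g.sequence_str("chr1")
        track = g.gc_track["chr1"]
        for w in list(range(25)) + [len(track) - 1]:
            window = seq[w * 2000:(w + 1) * 2000]
            expected = (window.count("G") + window.count("C")) / len(window)
            assert track[w] == expected

    def test_genome_invariants(self, small_genome, small_config):
        g = small_genome
        for _, row in g.tss.iterrows():
            assert row["position"] >= 2000
            assert row["position"] <= g.lengths[row["chrom"]] - 2000
        for c in g.chrom_names:
            track = g.gc_track[c]
            assert np.all((track >= 0) & (track <= 1))
        assert g.n_windows() == sum(-(-g.lengths[c] // 2000) for c in g.chrom_names)
        assert len(g.tss) >= small_config.tss_per_chrom

    def test_default_scale_contract(self, default_result):
        g = default_result.genome
        assert len(g.chrom_names) == 3
        assert len(g.tss) >= 300
        assert len(g.truth.cnv_segments) >= 2
        assert all(s.end - s.start >= 2_000_000 for s in g.truth.cnv_segments)
        starts = sorted((s.chrom, s.start, s.end) for s in g.truth.cnv_segments)
        for (c1, _, e1), (c2, s2, _) in zip(starts, starts[1:]):
            assert c1 != c2 or e1 <= s2  # disjoint

    def test_short_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_build_config(chrom_lengths=(("chr1", 3_000_000),)).validate()


class TestSimulateSample:
    def test_fragment_count_contract(self, small_genome, small_config):
        fs = simulate_sample(small_genome, "HC", small_config, seed=2,
                             n_fragments=10_000)
        assert len(fs) == 10_000
        assert np.all(fs.start < fs.end)
        fs.validate_against(small_genome)

    def test_deterministic_for_fixed_seed(self, small_genome, small_config):
        a = simulate_sample(small_genome, "OC", small_config, seed=5, n_fragments=5000)
        b = simulate_sample(small_genome, "OC", small_config, seed=5, n_fragments=5000)
        assert np.array_equal(a.start, b.start)
        assert np.array_equal(a.end, b.end)
        assert np.array_equal(a.chrom.astype(str), b.chrom.astype(str))

    def test_zero_tumor_fraction_degenerates_to_healthy_law(self, small_genome, small_config):
        hc = simulate_sample(small_genome, "HC", small_config, seed=21, n_fragments=10_000)
        oc = simulate_sample(small_genome, "OC", small_config, seed=22,
                             n_fragments=10_000, tumor_fraction=0.0)
        p = wilcoxon_rank_sum(hc.lengths, oc.lengths)
        assert p > 0.01

    def test_tumor_mixture_shifts_lengths_down(self, small_genome, small_config):
        hc = simulate_sample(small_genome, "HC", small_config, seed=31, n_fragments=20_000)
        oc = simulate_sample(small_genome, "OC", small_config, seed=32, n_fragments=20_000)
        assert oc.lengths.mean() < hc.lengths.mean() - 2.0


class TestPlantedCnvSampling:
    def test_gain_enrichment_matches_mixture_expectation(self, cnv_experiment):
        """Mean per-2kb count inside the gain / outside matches the mixture
        sampling-rate expectation 1 + f*(r-1) = 1.15 within 0.03.

        The mixture is applied at the candidate level, so the local
        sampling density is proportional to (1-f)*w_healthy + f*w_tumor and
        the in/out enrichment is exactly 1 + f*(r-1)."""
        raw = cnv_experiment.tumor_depth.raw
        w0, w1 = cnv_experiment.gain_windows
        inside = raw[w0:w1].mean()
        outside = np.concatenate([raw[:w0], raw[w1:]]).mean()
        observed = inside / outside
        f, r = 0.3, 1.5
        expected = 1 + f * (r - 1)
        assert observed == pytest.approx(expected, abs=0.01)
        assert abs(observed - 1.15) <= 0.03

    def test_effect_monotone_in_tumor_fraction(self, cnv_experiment):
        """Raising f strictly raises both the genome-wide short/long ratio
        and the count enrichment inside the planted gain (n = 50k)."""
        g, cfg = cnv_experiment.genome, cnv_experiment.config
        sim = FragmentSimulator(g, cfg)
        w0, w1 = cnv_experiment.gain_windows
        ratios, enrich = [], []
        for i, f in enumerate((0.0, 0.1, 0.3)):
            fs = sim.sample("OC_f", "OC", np.random.default_rng(40 + i),
                            n_fragments=50_000, tumor_fraction=f)
            L = fs.lengths
            n_short = ((L >= 90) & (L <= 150)).sum()
            n_long = ((L >= 151) & (L <= 220)).sum()
            ratios.append(n_short / n_long)
            from ocscore import window_depth
            raw = window_depth(fs, g).raw
            enrich.append(raw[w0:w1].mean() / np.concatenate([raw[:w0], raw[w1:]]).mean())
        assert ratios[0] < ratios[1] < ratios[2]
        assert enrich[0] < enrich[1] < enrich[2]


class TestCohort:
    def test_manifest_counts_and_split(self):
        cfg = SimulationConfig(seed=4)
        m = cohort_manifest(cfg)
        assert len(m) == 159
        oc = m[m["label"] == "OC"]
        hc = m[m["label"] == "HC"]
        assert (oc["split"] == "train").sum() == 40
        assert (oc["split"] == "test").sum() == 19
        assert (hc["split"] == "train").sum() == 50
        assert (hc["split"] == "test").sum() == 50
        pd.testing.assert_frame_equal(m, cohort_manifest(cfg))

    def test_cohort_files_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = tiny_build_config()
        g = build_toy_genome(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(g, cfg, outdir=d1, keep_fragments=False)
        simulate_cohort(g, cfg, outdir=d2, keep_fragments=False)
        for name in sorted(p.name for p in d1.iterdir()):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_existing_manifest_refused_without_overwrite(self, tmp_path):
        cfg = tiny_build_config()
        g = build_toy_genome(cfg)
        simulate_cohort(g, cfg, outdir=tmp_path, keep_fragments=False)
        with pytest.raises(FileExistsError):
            simulate_cohort(g, cfg, outdir=tmp_path, keep_fragments=False)
        simulate_cohort(g, cfg, outdir=tmp_path, overwrite=True, keep_fragments=False)

    def test_per_sample_seeding_is_order_independent(self, small_genome, small_config):
        sim = FragmentSimulator(small_genome, small_config)
        fs5 = sim.sample("x", "HC", _sample_rng(small_config.seed, 5), n_fragments=1000)
        # regenerating sample index 5 in isolation reproduces it exactly
        fs5b = sim.sample("x", "HC", _sample_rng(small_config.seed, 5), n_fragments=1000)
        assert np.array_equal(fs5.start, fs5b.start)


class TestHealthyLengthLaw:
    def test_mode_is_167_and_di_nucleosome_shoulder(self, small_genome, small_config):
        fs = simulate_sample(small_genome, "HC", small_config, seed=9,
                             n_fragments=150_000)
        vals, counts = np.unique(fs.lengths, return_counts=True)
        assert vals[np.argmax(counts)] == 167
        # di-nucleosome shoulder present around 334
        assert counts[(vals >= 300) & (vals <= 370)].sum() > 0.05 * len(fs)
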