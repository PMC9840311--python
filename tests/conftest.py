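"""Session fixtures: shared simulated cohorts at test scale.

The expensive fixtures (default cohort run, CNV recovery experiment,
high-coverage NF cohort) are built once per session and shared across
test modules.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from ocscore import (FragmentSimulator, PipelineConfig, SimulationConfig,
                     build_baseline, build_toy_genome, call_cnv, gc_correct,
                     nf_score, run_pipeline, window_depth)
from ocscore.cnv import smooth_depth
from ocscore.selection import FeatureMatrix

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A cheap but fully featured simulation configuration."""
    return SimulationConfig(
        n_healthy=12, n_tumor=10, fragments_per_sample=40_000,
        chrom_lengths=(("chr1", 6_000_000),), tss_per_chrom=40,
        n_ndr_altered=8, cnv_segments=(), seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_toy_genome(small_config)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default study conditions (100 HC / 59 OC)."""
    return run_pipeline(PipelineConfig().with_seed(DEFAULT_SEED))


@dataclass
class CnvExperiment:
    genome: object
    config: SimulationConfig
    panel: object
    tumor_depth: object          # smoothed DepthVector of the f=0.3 sample
    call_gain: object            # planted ratio 1.5
    call_gain_2x: object         # same genome, truth ratio 2.0
    call_neutral: object         # tumor fraction 0
    gain_windows: tuple[int, int]
    deep_fragments: int


CNV_GAIN = (7_000_000, 12_000_000)
CNV_DEEP_N = 3_000_000


@pytest.fixture(scope="session")
def cnv_experiment() -> CnvExperiment:
    """Planted 5-Mb copy_ratio-1.5 gain at tumor fraction 0.3, deep panel."""
    config = SimulationConfig(
        n_healthy=6, n_tumor=1,
        chrom_lengths=(("chr1", 20_000_000),), tss_per_chrom=20,
        n_ndr_altered=4, cnv_segments=(("chr1", *CNV_GAIN, 1.5),), seed=11,
    )
    genome = build_toy_genome(config)
    sim = FragmentSimulator(genome, config)
    gc = genome.gc_concat()
    rng = np.random.default_rng(100)

    def depth_of(fs):
        return smooth_depth(gc_correct(window_depth(fs, genome), gc))

    panel = build_baseline(np.vstack([
        depth_of(sim.sample(f"HC_{i}", "HC", rng, n_fragments=CNV_DEEP_N)).corrected
        for i in range(6)
    ]))
    tumor_dv = depth_of(sim.sample("OC_gain", "OC", rng,
                                   n_fragments=CNV_DEEP_N, tumor_fraction=0.3))
    call_gain = call_cnv(tumor_dv, panel)

    truth_2x = dataclasses.replace(
        genome.truth,
        cnv_segments=tuple(dataclasses.replace(s, copy_ratio=2.0)
                           for s in genome.truth.cnv_segments),
    )
    genome_2x = dataclasses.replace(genome, truth=truth_2x)
    sim_2x = FragmentSimulator(genome_2x, config)
    call_2x = call_cnv(
        depth_of(sim_2x.sample("OC_gain2", "OC", rng,
                               n_fragments=CNV_DEEP_N, tumor_fraction=0.3)),
        panel)

    call_neutral = call_cnv(
        depth_of(sim.sample("OC_flat", "OC", rng,
                            n_fragments=CNV_DEEP_N, tumor_fraction=0.0)),
        panel)
    w0, w1 = CNV_GAIN[0] // 2000, CNV_GAIN[1] // 2000
    return CnvExperiment(genome, config, panel, tumor_dv, call_gain, call_2x,
                         call_neutral, (w0, w1), CNV_DEEP_N)


@dataclass
class NfCohort:
    genome: object
    config: SimulationConfig
    matrix: FeatureMatrix
    altered: list[str]


@pytest.fixture(scope="session")
def nf_cohort() -> NfCohort:
    """High-coverage small-genome cohort where per-gene NF has real power."""
    config = SimulationConfig(
        n_healthy=30, n_tumor=24, fragments_per_sample=1_200_000,
        tumor_fraction=0.3, chrom_lengths=(("chr1", 5_000_000),),
        tss_per_chrom=40, n_ndr_altered=10, cnv_segments=(), seed=7,
    )
    genome = build_toy_genome(config)
    sim = FragmentSimulator(genome, config)
    rng = np.random.default_rng(5)
    rows, ids, labels = [], [], []
    for i in range(config.n_healthy):
        sid = f"HC_{i:03d}"
        rows.append(nf_score(sim.sample(sid, "HC", rng), genome).scores)
        ids.append(sid)
        labels.append("HC")
    for i in range(config.n_tumor):
        sid = f"OC_{i:03d}"
        rows.append(nf_score(sim.sample(sid, "OC", rng), genome).scores)
        ids.append(sid)
        labels.append("OC")
    values = pd.DataFrame(rows, index=ids)
    labels = pd.Series(labels, index=ids)
    split = pd.Series("train", index=ids)
    matrix = FeatureMatrix(values, labels, split, "nf")
    return NfCohort(genome, config, matrix, sorted(genome.truth.ndr_altered))
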