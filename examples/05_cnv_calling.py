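"""Copy-number calling against a healthy baseline panel.

Plants a 3-Mb gain (copy ratio 2.0) and recovers it: per-2kb window
counts are GC-corrected, smoothed, z-scored against a healthy panel, and
runs of |z| > 3 windows longer than 2 Mb become segments.
"""
import numpy as np

from ocscore import (SimulationConfig, build_baseline, build_toy_genome,
                     call_cnv, gc_correct, simulate_sample, window_depth)
from ocscore.cnv import smooth_depth

config = SimulationConfig(
    n_healthy=5, n_tumor=1, fragments_per_sample=500_000, tumor_fraction=0.5,
    chrom_lengths=(("chr1", 12_000_000),), tss_per_chrom=20, n_ndr_altered=4,
    cnv_segments=(("chr1", 4_000_000, 7_000_000, 2.0),), seed=9,
)
genome = build_toy_genome(config)
gc = genome.gc_concat()


def depth_of(sample):
    return smooth_depth(gc_correct(window_depth(sample, genome), gc))


panel = build_baseline(np.vstack([
    depth_of(simulate_sample(genome, "HC", config, seed=i)).corrected
    for i in range(5)
]))
tumor = depth_of(simulate_sample(genome, "OC", config, seed=99))
call = call_cnv(tumor, panel)

print(f"planted: chr1:4,000,000-7,000,000 gain, copy ratio 2.0, "
      f"tumor fraction {config.tumor_fraction}")
for chrom, start, end, mean_z, direction in call.segments:
    print(f"called : {chrom}:{start:,}-{end:,} {direction}, mean z = {mean_z:.1f}")
print(f"cnv_score = {call.cnv_score:.3f}  (sum of |mean z| x span_Mb / 100)")

neutral = depth_of(simulate_sample(genome, "HC", config, seed=100))
print(f"copy-neutral control: {len(call_cnv(neutral, panel).segments)} segments, "
      f"score {call_cnv(neutral, panel).cnv_score}")
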