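"""Nucleosome-footprint (NF) scores at promoters.

NF = (background depth - NDR depth) / background depth contrasts coverage
in the nucleosome-depleted region (TSS -150..+50) against the TSS +/-2 kb
background.  The tumor class deepens the NDR of the planted altered genes,
raising their NF score.
"""
import numpy as np

from ocscore import SimulationConfig, build_toy_genome, nf_score, simulate_sample

config = SimulationConfig(
    n_healthy=1, n_tumor=1, fragments_per_sample=400_000,
    chrom_lengths=(("chr1", 5_000_000),), tss_per_chrom=40,
    n_ndr_altered=10, cnv_segments=(), seed=7,
)
genome = build_toy_genome(config)
hc = nf_score(simulate_sample(genome, "HC", config, seed=1), genome).scores
oc = nf_score(simulate_sample(genome, "OC", config, seed=2), genome).scores

altered = sorted(genome.truth.ndr_altered)
normal = [g for g in hc.index if g not in altered]
print(f"{len(hc)} genes scored at ~15x promoter coverage\n")
print(f"mean NF, altered genes ({len(altered)}):  "
      f"HC {hc[altered].mean():.3f}   OC {oc[altered].mean():.3f}")
print(f"mean NF, unaltered genes ({len(normal)}): "
      f"HC {hc[normal].mean():.3f}   OC {oc[normal].mean():.3f}")
print("\nThe OC sample's NF rises specifically at the altered genes — the "
      "signal the NF prefilter (zero-fraction, then Wilcoxon p<0.001) hunts.")
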