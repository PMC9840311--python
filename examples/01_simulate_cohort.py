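"""Simulate a small synthetic cfDNA cohort and write it to disk.

Builds a toy genome with planted truth (CNV segments, promoter
nucleosome-depletion alterations, cleavage-motif bias), then writes one
BED of fragment coordinates per sample plus a manifest and truth JSON.
"""
from pathlib import Path

from ocscore import SimulationConfig, build_toy_genome, simulate_cohort

config = SimulationConfig(
    n_healthy=6, n_tumor=4, fragments_per_sample=20_000,
    chrom_lengths=(("chr1", 6_000_000),), tss_per_chrom=40,
    n_ndr_altered=8, cnv_segments=(), seed=42,
)
genome = build_toy_genome(config)
outdir = Path("example-output/cohort")
cohort = simulate_cohort(genome, config, outdir=outdir, overwrite=True,
                         keep_fragments=True)

print(cohort.manifest.to_string(index=False))
print(f"\n{len(cohort.fragment_sets)} BED files written to {outdir}/")
fs = cohort.fragment_sets[0]
print(f"first sample {fs.sample_id}: {len(fs)} fragments, "
      f"mean length {fs.lengths.mean():.1f} bp")
# The manifest rows are the pipeline's cohort definition: label is the
# true class (HC/OC) and split marks which samples may train models.
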