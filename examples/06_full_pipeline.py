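"""End-to-end run: simulate -> features -> select -> train -> score.

Uses a reduced cohort for speed; the default study conditions
(100 HC / 59 OC, 3 x 30 Mb genome, 300k fragments/sample) run the same
way in a few minutes via `ocscore run-all --outdir out` or
`run_pipeline(PipelineConfig())`.
"""
from ocscore import PipelineConfig, SimulationConfig, run_pipeline
from ocscore.pipeline import format_report

config = PipelineConfig(
    simulation=SimulationConfig(
        n_healthy=30, n_tumor=21, fragments_per_sample=50_000,
        chrom_lengths=(("chr1", 6_000_000),), tss_per_chrom=40,
        n_ndr_altered=8, cnv_segments=(), seed=5,
    ),
    model_seed=5,
)
result = run_pipeline(config, outdir="example-output/pipeline", overwrite=True)
print(format_report(result.report))
print("Per-sample scores (test split):")
cols = ["label", "motif_score", "fragment_score", "logistic_score",
        "cnv_score", "oc_score", "predicted"]
print(result.scores.loc[result.scores["split"] == "test", cols]
      .round(3).to_string())
# The OC score is the logistic integration of the three family SVM scores
# plus the additive CNV burden; 'predicted' applies the train-set Youden
# cutoff.
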