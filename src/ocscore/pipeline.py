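"""End-to-end orchestration: simulate -> features -> select -> train ->
score -> evaluate.

The pipeline is leakage-safe by construction: rank tests, L1 penalty paths,
SVM fitting, calibration, integration fitting, the CNV baseline panel and
every cutoff are computed from training rows only (the NF zero-fraction
prefilter, a label-free missingness filter, is the one stage that sees the
whole cohort, as intended).
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .cnv import build_baseline, call_cnv, gc_correct, smooth_depth, window_depth
from .core import HEALTHY, TUMOR
from .evaluation import confusion_at, roc_auc, sensitivity_at_specificity
from .fragmentation import fragmentation_profile, make_bins
from .model import (FeatureModel, IntegrationModel, fit_integration,
                    fixed_integration, oc_score, train_feature_model,
                    youden_cutoff)
from .motifs import MOTIFS, motif_profile
from .nucleosome import nf_score
from .selection import FeatureMatrix, SelectionResult, select_family
from .simulate import Cohort, SimulationConfig, ToyGenome, build_toy_genome, simulate_cohort

logger = logging.getLogger(__name__)

FAMILIES = ("nf", "fragment", "motif")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a run (serialized next to outputs)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_folds: int = 10
    integration_mode: str = "refit"      # "refit" or "fixed"
    target_specificity: float = 0.98
    model_seed: int = 0

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, simulation=self.simulation.with_(seed=seed),
                       model_seed=seed)


@dataclass
class CohortFeatures:
    """All per-sample feature families for one cohort."""

    motif: FeatureMatrix
    fragment: FeatureMatrix
    nf: FeatureMatrix
    cnv_scores: pd.Series
    mean_insert: pd.Series
    manifest: pd.DataFrame

    def family(self, name: str) -> FeatureMatrix:
        return getattr(self, name)


def extract_cohort_features(genome: ToyGenome, cohort: Cohort) -> CohortFeatures:
    """Compute motif, fragmentation-ratio, NF and CNV features per sample.

    The CNV baseline panel is built from healthy *training* samples only;
    every sample is then z-scored against it.
    """
    manifest = cohort.manifest
    bins = make_bins(genome)
    gc = genome.gc_concat()
    motif_rows, ratio_rows, nf_rows, inserts = [], [], [], []
    depths = []
    ids = list(manifest["sample_id"])
    for fs in cohort.iter_fragments():
        t0 = time.perf_counter()
        motif_rows.append(motif_profile(fs, genome).frequencies)
        prof = fragmentation_profile(fs, bins)
        ratio_rows.append(prof.ratio)
        inserts.append(prof.mean_insert_size)
        nf_rows.append(nf_score(fs, genome).scores)
        depths.append(smooth_depth(gc_correct(window_depth(fs, genome), gc)).corrected)
        logger.info("features for %s: %d fragments in %.2fs",
                    fs.sample_id, len(fs), time.perf_counter() - t0)

    labels = manifest.set_index("sample_id")["label"]
    split = manifest.set_index("sample_id")["split"]
    motif_fm = FeatureMatrix(
        pd.DataFrame(motif_rows, index=ids, columns=list(MOTIFS)),
        labels, split, "motif")
    frag_fm = FeatureMatrix(
        pd.DataFrame(ratio_rows, index=ids, columns=bins.names),
        labels, split, "fragment")
    nf_fm = FeatureMatrix(
        pd.DataFrame(nf_rows, index=ids),
        labels, split, "nf")

    depth_mat = np.vstack(depths)
    train_hc = ((labels == HEALTHY) & (split == "train")).to_numpy()
    panel = build_baseline(depth_mat[train_hc])
    scheme = None
    cnv = []
    from .cnv import DepthVector, depth_windows
    scheme = depth_windows(genome)
    for row in depth_mat:
        call = call_cnv(DepthVector(row, row, scheme), panel)
        cnv.append(call.cnv_score)
    return CohortFeatures(
        motif_fm, frag_fm, nf_fm,
        pd.Series(cnv, index=ids, name="cnv_score"),
        pd.Series(inserts, index=ids, name="mean_insert_size"),
        manifest,
    )


@dataclass
class PipelineModels:
    selections: dict[str, SelectionResult]
    feature_models: dict[str, FeatureModel]
    integration: IntegrationModel
    oc_cutoff: float

    def to_dict(self) -> dict:
        return {
            "selections": {
                f: {"kept": list(s.kept),
                    "weights": {k: float(v) for k, v in s.weights.items()}}
                for f, s in self.selections.items()
            },
            "feature_models": {f: m.to_dict() for f, m in self.feature_models.items()},
            "integration": self.integration.to_dict(),
            "oc_cutoff": float(self.oc_cutoff),
        }


def fit_models(features: CohortFeatures, n_folds: int = 10, seed: int = 0,
               integration_mode: str = "refit") -> PipelineModels:
    """Select features and train every model on the training split."""
    selections, models, train_scores = {}, {}, {}
    for fam in FAMILIES:
        fm = features.family(fam)
        sel = select_family(fm, n_folds=n_folds, seed=seed)
        selections[fam] = sel
        model = train_feature_model(fm, sel, n_folds=n_folds, seed=seed)
        models[fam] = model
        train_scores[fam] = model.score(fm.values[fm.train_mask])
        logger.info("%s: %d features selected", fam, len(sel.kept))

    tr_mask = features.motif.train_mask
    tr_ids = features.motif.values.index[tr_mask]
    score_df = pd.DataFrame(
        {"nf": train_scores["nf"], "fragment": train_scores["fragment"],
         "motif": train_scores["motif"]},
        index=tr_ids,
    )
    labels = features.motif.labels[tr_mask]
    if integration_mode == "fixed":
        integration = fixed_integration()
    else:
        integration = fit_integration(score_df, labels, seed=seed)
    logistic_tr = integration.predict(score_df["nf"], score_df["fragment"],
                                      score_df["motif"])
    oc_tr = oc_score(logistic_tr, features.cnv_scores.loc[tr_ids])
    cutoff = youden_cutoff(oc_tr, labels)
    return PipelineModels(selections, models, integration, cutoff)


def score_cohort(models: PipelineModels, features: CohortFeatures) -> pd.DataFrame:
    """Per-sample family scores, logistic score, CNV score, OC score, call."""
    out = pd.DataFrame(index=features.motif.values.index)
    for fam in FAMILIES:
        fm = features.family(fam)
        out[f"{fam}_score"] = models.feature_models[fam].score(fm.values)
    out["logistic_score"] = models.integration.predict(
        out["nf_score"], out["fragment_score"], out["motif_score"])
    out["cnv_score"] = features.cnv_scores
    out["oc_score"] = oc_score(out["logistic_score"], out["cnv_score"])
    out["predicted"] = np.where(out["oc_score"] >= models.oc_cutoff, TUMOR, HEALTHY)
    out["label"] = features.motif.labels
    out["split"] = features.motif.split
    out.index.name = "sample_id"
    return out


def _roc_or_none(scores, labels):
    try:
        return roc_auc(scores, labels).auc
    except ValueError:
        return None


def evaluate_cohort(scores: pd.DataFrame, cutoff: float,
                    target_specificity: float = 0.98) -> dict:
    """Test-split (and train-split) performance report."""
    report: dict = {"cutoff": float(cutoff)}
    for split in ("train", "test"):
        sub = scores[scores["split"] == split]
        labels = sub["label"]
        entry: dict = {"n": int(len(sub)),
                       "n_oc": int((labels == TUMOR).sum()),
                       "n_hc": int((labels == HEALTHY).sum())}
        entry["auc"] = {
            col.replace("_score", ""): _roc_or_none(sub[col], labels)
            for col in ("nf_score", "fragment_score", "motif_score",
                        "cnv_score", "logistic_score", "oc_score")
        }
        conf = confusion_at(sub["oc_score"], labels, cutoff)
        entry["confusion"] = {
            "tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn,
            "sensitivity": conf.sensitivity, "specificity": conf.specificity,
            "accuracy": conf.accuracy, "ppv": conf.ppv, "npv": conf.npv,
        }
        sas = sensitivity_at_specificity(sub["oc_score"], labels, target_specificity)
        entry["sensitivity_at_specificity"] = {
            "target": target_specificity, "sensitivity": sas.sensitivity,
            "cutoff": sas.cutoff, "achieved_specificity": sas.achieved_specificity,
        }
        report[split] = entry
    return report


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: ToyGenome
    features: CohortFeatures
    models: PipelineModels
    scores: pd.DataFrame
    report: dict


def run_pipeline(config: PipelineConfig, genome: ToyGenome | None = None,
                 cohort: Cohort | None = None, outdir=None,
                 overwrite: bool = False) -> PipelineResult:
    """Execute the full pipeline; optionally persist all artifacts.

    Outputs (feature matrices, models, per-sample scores, report) all embed
    the configuration hash.  Two runs with the same config are
    byte-identical.
    """
    cfg_hash = _io.config_hash(config)
    t0 = time.perf_counter()
    if genome is None:
        logger.info("stage simulate: building toy genome (seed=%d)", config.seed)
        genome = build_toy_genome(config.simulation)
    if cohort is None:
        cohort = simulate_cohort(genome, config.simulation, keep_fragments=False)
    logger.info("stage features: %d samples", len(cohort.manifest))
    features = extract_cohort_features(genome, cohort)
    logger.info("stage select/train (seed=%d)", config.model_seed)
    models = fit_models(features, n_folds=config.n_folds, seed=config.model_seed,
                        integration_mode=config.integration_mode)
    scores = score_cohort(models, features)
    report = evaluate_cohort(scores, models.oc_cutoff, config.target_specificity)
    report["selected_features"] = {f: len(s.kept) for f, s in models.selections.items()}
    report["seed"] = config.seed
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.json"
        if report_path.exists() and not overwrite:
            raise FileExistsError(f"{report_path} exists; use overwrite")
        for fam in FAMILIES:
            _io.write_table(features.family(fam).values,
                            outdir / f"features_{fam}.tsv", cfg_hash)
        _io.write_json(models.to_dict(), outdir / "models.json", cfg_hash)
        _io.write_table(scores, outdir / "scores.tsv", cfg_hash)
        _io.write_json(report, report_path, cfg_hash)
        with open(outdir / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return PipelineResult(config, genome, features, models, scores, report)


def format_report(report: dict) -> str:
    lines = [f"OC-score pipeline report (seed {report.get('seed')})",
             f"OC-score cutoff: {report['cutoff']:.4f}", ""]
    for split in ("train", "test"):
        e = report[split]
        lines.append(f"[{split}] n={e['n']} ({e['n_oc']} OC / {e['n_hc']} HC)")
        aucs = ", ".join(f"{k}={v:.3f}" if v is not None else f"{k}=NA"
                         for k, v in e["auc"].items())
        lines.append(f"  AUC: {aucs}")
        c = e["confusion"]
        lines.append(
            f"  confusion @ cutoff: TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']}"
        )

        def _fmt(v):
            return "NA" if v is None else f"{v:.3f}"

        lines.append(
            f"  sens={_fmt(c['sensitivity'])} spec={_fmt(c['specificity'])} "
            f"acc={_fmt(c['accuracy'])} ppv={_fmt(c['ppv'])} npv={_fmt(c['npv'])}"
        )
        s = e["sensitivity_at_specificity"]
        lines.append(
            f"  sensitivity {s['sensitivity']:.3f} at specificity >= {s['target']}"
            f" (cutoff {s['cutoff']:.4f})"
        )
        lines.append("")
    sel = report.get("selected_features", {})
    if sel:
        lines.append("selected features: " +
                     ", ".join(f"{k}={v}" for k, v in sel.items()))
    return "\n".join(lines) + "\n"
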