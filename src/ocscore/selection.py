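"""Feature selection cascades.

Each feature family is filtered before modeling:

* nucleosome footprint: drop genes with NF == 0 in more than 10% of ALL
  samples (a missingness filter, so it sees the full cohort), then drop
  genes with a train-set Wilcoxon rank-sum p >= 0.001, then L1 selection;
* end motifs: drop motifs with train Wilcoxon p >= 0.05, then L1 selection;
* fragmentation ratios: L1 selection only;
* the CNV burden score bypasses selection and modeling entirely and enters
  the final score directly.

Only training rows ever influence the rank tests or the L1 penalty path.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .core import HEALTHY, TUMOR

NF_ZERO_FRACTION = 0.10
NF_P_THRESHOLD = 1e-3
MOTIF_P_THRESHOLD = 0.05
LASSO_N_CS = 50
LASSO_C_RANGE = (-4.0, 4.0)  # log10 bounds of the inverse-penalty grid


@dataclass
class FeatureMatrix:
    """Samples x features values for one family, with labels and split."""

    values: pd.DataFrame        # index: sample_id
    labels: pd.Series           # "HC" / "OC", same index
    split: pd.Series            # "train" / "test", same index
    family: str

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.labels = self.labels.reindex(self.values.index)
        self.split = self.split.reindex(self.values.index)

    @property
    def train_mask(self) -> pd.Series:
        return self.split == "train"

    def train_groups(self, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(OC rows, HC rows) of the training split."""
        v = self.values if columns is None else self.values[list(columns)]
        tr = v[self.train_mask]
        lab = self.labels[self.train_mask]
        return tr[lab == TUMOR], tr[lab == HEALTHY]


@dataclass
class SelectionResult:
    family: str
    kept: list[str]
    pvalues: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small tie-free samples, otherwise the normal approximation
    with tie and continuity corrections.  Degenerate input (all values
    identical across both groups, or an undefined statistic) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 1.0
    return min(max(p, np.nextafter(0, 1)), 1.0)


def _train_pvalues(matrix: FeatureMatrix, columns) -> pd.Series:
    oc, hc = matrix.train_groups(columns)
    return pd.Series(
        {c: wilcoxon_rank_sum(oc[c].to_numpy(), hc[c].to_numpy()) for c in columns},
        dtype=float,
    )


def nf_prefilter(
    matrix: FeatureMatrix,
    zero_fraction: float = NF_ZERO_FRACTION,
    p_threshold: float = NF_P_THRESHOLD,
) -> list[str]:
    """NF candidate genes: zero-fraction filter (all samples), then train
    Wilcoxon p < ``p_threshold``.

    A gene is dropped when strictly more than ``zero_fraction`` of the total
    cohort shows NF == 0.
    """
    if matrix.family != "nf":
        raise ValueError("nf_prefilter expects the nf family")
    zero_frac = (matrix.values == 0).mean(axis=0)
    candidates = [c for c in matrix.values.columns if zero_frac[c] <= zero_fraction]
    if candidates:
        p = _train_pvalues(matrix, candidates)
        candidates = [c for c in candidates if p[c] < p_threshold]
    if not candidates:
        warnings.warn("NF prefilter left no candidate genes; "
                      "pipeline continues with an empty NF block", stacklevel=2)
    return candidates


def motif_prefilter(
    matrix: FeatureMatrix, p_threshold: float = MOTIF_P_THRESHOLD
) -> list[str]:
    """Motif candidates: train Wilcoxon p < ``p_threshold``."""
    if matrix.family != "motif":
        raise ValueError("motif_prefilter expects the motif family")
    p = _train_pvalues(matrix, list(matrix.values.columns))
    kept = [c for c in matrix.values.columns if p[c] < p_threshold]
    if not kept:
        warnings.warn("motif prefilter left no candidates", stacklevel=2)
    return kept


def lasso_select(
    matrix: FeatureMatrix,
    candidates=None,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic selection at the minimum-CV-deviance penalty.

    Features are standardized on the training split; the inverse penalty is
    chosen on a 50-point logarithmic grid by stratified cross-validated
    deviance with a fixed seed; kept features are those with a nonzero
    coefficient at the chosen penalty.
    """
    cols = list(matrix.values.columns if candidates is None else candidates)
    pvalues = _train_pvalues(matrix, cols) if cols else pd.Series(dtype=float)
    if not cols:
        return SelectionResult(matrix.family, [], pvalues)
    tr = matrix.values.loc[matrix.train_mask, cols]
    y = (matrix.labels[matrix.train_mask] == TUMOR).to_numpy().astype(int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < 2:
        raise ValueError("LASSO selection needs >= 2 training samples per class")

    mean = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=0).replace(0.0, 1.0)
    X = ((tr - mean) / sd).to_numpy()

    folds = int(min(n_folds, class_counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(*LASSO_C_RANGE, LASSO_N_CS),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=5000,
        refit=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coef = model.coef_.ravel()
    weights = pd.Series(coef, index=cols)
    kept = [c for c, w in weights.items() if abs(w) > 1e-10]
    return SelectionResult(matrix.family, kept, pvalues, weights)


def select_family(matrix: FeatureMatrix, n_folds: int = 10, seed: int = 0) -> SelectionResult:
    """Apply the family-appropriate cascade and return the final selection."""
    if matrix.family == "nf":
        candidates = nf_prefilter(matrix)
    elif matrix.family == "motif":
        candidates = motif_prefilter(matrix)
    elif matrix.family == "fragment":
        candidates = list(matrix.values.columns)
    else:
        raise ValueError(f"no selection cascade for family {matrix.family!r}")
    if not candidates:
        return SelectionResult(matrix.family, [])
    return lasso_select(matrix, candidates, n_folds=n_folds, seed=seed)
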