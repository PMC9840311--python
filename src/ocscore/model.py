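"""Per-family SVM scorers and the logistic integration ("OC score").

Each selected feature family trains a linear-kernel SVM whose
regularization constant is tuned by stratified 10-fold cross-validation on
accuracy.  Decision values are mapped to [0, 1] by a sigmoid fitted on
out-of-fold decision values (never in-fold), and a train-score cutoff is
placed at the accuracy maximum (ties resolved toward higher specificity).

The three family scores are combined through a logistic model

    Z = b0 + bNF * NF + bFrag * Fragment + bMotif * Motif
    logistic score = exp(Z) / (1 + exp(Z))

either with a fixed reference coefficient set
(b0, bNF, bFrag, bMotif) = (-2.48, 2.84, 2.01, 0.56) — illustrative, since
the scale of its original inputs is not defined — or refit by maximum
likelihood on the training scores.  The final OC score adds the CNV burden:

    OC score = logistic score + CNV score

and a Youden-optimal train cutoff turns it into a prediction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import HEALTHY, TUMOR
from .selection import FeatureMatrix, SelectionResult

SVM_C_GRID = np.logspace(-3, 3, 13)
CALIBRATION_RIDGE_C = 10.0
FIXED_COEFFICIENTS = (-2.48, 2.84, 2.01, 0.56)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass
class FeatureModel:
    """A trained single-family scorer emitting probabilities in [0, 1]."""

    family: str
    features: list[str]
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    coef: np.ndarray | None = None
    intercept: float = 0.0
    calib_slope: float = 1.0
    calib_intercept: float = 0.0
    cutoff: float = 0.5
    best_c: float | None = None
    cv_accuracy: float | None = None
    constant: bool = False

    def decision(self, values: pd.DataFrame) -> np.ndarray:
        if self.constant:
            return np.zeros(len(values))
        X = (values[self.features].to_numpy() - self.mean) / self.scale
        return X @ self.coef + self.intercept

    def score(self, values: pd.DataFrame) -> np.ndarray:
        """Calibrated probability-like score per sample."""
        if self.constant:
            return np.full(len(values), 0.5)
        d = self.decision(values)
        return _sigmoid(self.calib_slope * d + self.calib_intercept)

    def predict(self, values: pd.DataFrame) -> np.ndarray:
        return np.where(self.score(values) >= self.cutoff, TUMOR, HEALTHY)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "features": list(self.features),
            "mean": None if self.mean is None else [float(v) for v in self.mean],
            "scale": None if self.scale is None else [float(v) for v in self.scale],
            "coef": None if self.coef is None else [float(v) for v in self.coef],
            "intercept": float(self.intercept),
            "calib_slope": float(self.calib_slope),
            "calib_intercept": float(self.calib_intercept),
            "cutoff": float(self.cutoff),
            "best_c": None if self.best_c is None else float(self.best_c),
            "cv_accuracy": None if self.cv_accuracy is None else float(self.cv_accuracy),
            "constant": bool(self.constant),
        }


def _accuracy_cutoff(scores: np.ndarray, y: np.ndarray) -> float:
    """Score threshold maximizing accuracy; ties go to the higher cutoff
    (higher specificity).  Predict positive iff score >= cutoff."""
    candidates = np.concatenate([np.unique(scores), [np.max(scores) + 1.0]])
    best_cut, best_acc = candidates[0], -1.0
    for c in candidates:
        pred = scores >= c
        acc = float((pred == y).mean())
        if acc > best_acc or (acc == best_acc and c > best_cut):
            best_acc, best_cut = acc, c
    return float(best_cut)


def train_feature_model(
    matrix: FeatureMatrix,
    selection: SelectionResult,
    n_folds: int = 10,
    seed: int = 0,
    c_grid: np.ndarray = SVM_C_GRID,
) -> FeatureModel:
    """Train one family's linear SVM on the training split.

    An empty selection degrades to a constant 0.5 scorer with a warning.
    Fixed seed => identical parameters and cutoff.
    """
    if not selection.kept:
        warnings.warn(f"{matrix.family}: empty selection; model emits a constant 0.5",
                      stacklevel=2)
        return FeatureModel(matrix.family, [], constant=True)
    cols = list(selection.kept)
    tr = matrix.values.loc[matrix.train_mask, cols]
    y = (matrix.labels[matrix.train_mask] == TUMOR).to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("training needs >= 2 samples per class")

    mean = tr.mean(axis=0).to_numpy()
    scale = tr.std(axis=0, ddof=0).replace(0.0, 1.0).to_numpy()
    X = (tr.to_numpy() - mean) / scale

    folds = int(min(n_folds, counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))

    accs = []
    for c in c_grid:
        correct = 0
        for tr_idx, te_idx in splits:
            svm = SVC(kernel="linear", C=c)
            svm.fit(X[tr_idx], y[tr_idx])
            correct += int((svm.predict(X[te_idx]) == y[te_idx]).sum())
        accs.append(correct / len(y))
    best_i = int(np.argmax(accs))  # ties -> smaller C (argmax takes first)
    best_c = float(c_grid[best_i])

    # out-of-fold decision values for sigmoid calibration (never in-fold)
    oof = np.empty(len(y))
    for tr_idx, te_idx in splits:
        svm = SVC(kernel="linear", C=best_c)
        svm.fit(X[tr_idx], y[tr_idx])
        oof[te_idx] = svm.decision_function(X[te_idx])
    calib = LogisticRegression(C=CALIBRATION_RIDGE_C, max_iter=1000)
    calib.fit(oof.reshape(-1, 1), y)

    final = SVC(kernel="linear", C=best_c)
    final.fit(X, y)
    model = FeatureModel(
        family=matrix.family,
        features=cols,
        mean=mean,
        scale=scale,
        coef=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        calib_slope=float(calib.coef_[0, 0]),
        calib_intercept=float(calib.intercept_[0]),
        best_c=best_c,
        cv_accuracy=float(accs[best_i]),
    )
    train_scores = model.score(matrix.values[matrix.train_mask])
    model.cutoff = _accuracy_cutoff(train_scores, y)
    return model


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

@dataclass
class IntegrationModel:
    """Logistic stacking of the NF / Fragment / Motif model scores."""

    mode: str                     # "fixed" or "refit"
    b0: float
    b_nf: float
    b_fragment: float
    b_motif: float

    def z(self, nf, fragment, motif):
        return (self.b0 + self.b_nf * np.asarray(nf, dtype=float)
                + self.b_fragment * np.asarray(fragment, dtype=float)
                + self.b_motif * np.asarray(motif, dtype=float))

    def predict(self, nf, fragment, motif):
        return _sigmoid(self.z(nf, fragment, motif))

    def to_dict(self) -> dict:
        return {"mode": self.mode, "b0": self.b0, "b_nf": self.b_nf,
                "b_fragment": self.b_fragment, "b_motif": self.b_motif}


def fixed_integration() -> IntegrationModel:
    """The reference coefficient set (illustrative input scale)."""
    return IntegrationModel("fixed", *FIXED_COEFFICIENTS)


def logistic_score(nf, fragment, motif, model: IntegrationModel | None = None):
    """exp(Z)/(1+exp(Z)) for Z = b0 + bNF*nf + bFrag*fragment + bMotif*motif."""
    if model is None:
        model = fixed_integration()
    return model.predict(nf, fragment, motif)


def fit_integration(scores: pd.DataFrame, labels: pd.Series, seed: int = 0) -> IntegrationModel:
    """Unpenalized 3-covariate logistic regression of label on family scores.

    Falls back to a small ridge penalty when the scores separate the
    classes perfectly (the MLE then diverges).
    """
    X = scores[["nf", "fragment", "motif"]].to_numpy(dtype=float)
    y = (np.asarray(labels) == TUMOR).astype(int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("integration fit needs >= 2 samples per class")
    # centering leaves the MLE invariant but keeps degenerate (constant)
    # covariates at exactly zero weight
    centre = X.mean(axis=0)
    Xc = X - centre
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mle = LogisticRegression(C=np.inf, solver="lbfgs",
                                 max_iter=20000, tol=1e-12)
        mle.fit(Xc, y)
    coef = mle.coef_.ravel()
    if not np.all(np.isfinite(coef)) or np.max(np.abs(coef)) > 50:
        ridge = LogisticRegression(C=1e3, solver="lbfgs",
                                   max_iter=20000, tol=1e-12)
        ridge.fit(Xc, y)
        if not np.all(np.isfinite(ridge.coef_)):
            raise RuntimeError("integration fit failed to converge")
        coef, intercept = ridge.coef_.ravel(), float(ridge.intercept_[0])
    else:
        intercept = float(mle.intercept_[0])
    intercept -= float(coef @ centre)
    return IntegrationModel("refit", intercept, float(coef[0]),
                            float(coef[1]), float(coef[2]))


# --------------------------------------------------------------------------
# OC score and classification
# --------------------------------------------------------------------------

def oc_score(logistic, cnv):
    """OC score = logistic score + CNV burden (additive; equal iff CNV = 0)."""
    return np.asarray(logistic, dtype=float) + np.asarray(cnv, dtype=float)


def youden_cutoff(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity; ties -> higher cutoff."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == TUMOR)
    candidates = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    best_cut, best_j = candidates[0], -np.inf
    for c in candidates:
        pred = scores >= c
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec
        if j > best_j or (j == best_j and c > best_cut):
            best_j, best_cut = j, c
    return float(best_cut)


def classify(scores, labels, cutoff: float | None = None):
    """Predict OC iff score >= cutoff; cutoff defaults to the Youden optimum
    computed from (scores, labels).  Returns (predictions, cutoff)."""
    scores = np.asarray(scores, dtype=float)
    if cutoff is None:
        cutoff = youden_cutoff(scores, labels)
    return np.where(scores >= cutoff, TUMOR, HEALTHY), float(cutoff)


@dataclass
class OCScoreResult:
    """Per-sample final scores; oc_score >= logistic_score always."""

    sample_id: str
    nf_score: float
    fragment_score: float
    motif_score: float
    logistic_score: float
    cnv_score: float
    oc_score: float
    predicted: str | None = None
    label: str | None = None
    split: str | None = None
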