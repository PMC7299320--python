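"""Leave-one-out cross-validated classification (LRA, QDA, SVM).

Every patient is scored by a model trained on all remaining patients;
features are standardized with training-fold statistics only.  Scores are
the continuous decision values — predicted positive-class probability for
logistic regression and QDA, the signed margin for the SVM — and form the
substrate for all ROC statistics.

Two evaluation modes are provided.  ``paper`` mode takes an
already-selected feature matrix and cross-validates only the classifier
(screening and LASSO having been run once on the full cohort, as the
sequential workflow describes).  ``leakage_safe`` mode re-runs the
univariate screen and the LASSO selection inside every training fold, so
the held-out patient never influences its own feature subset; on null data
this removes the selection optimism of paper mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .screening import ScreeningConfig, screen_matrix_fast
from .selection import lasso_select

__all__ = ["ClassifierSpec", "CVScores", "fit_predict_loocv"]


@dataclass
class ClassifierSpec:
    kind: str = "svm"                 # "lra" | "qda" | "svm"
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"  # sklearn's scale rule = 1/(p * Var[X])
    regularization_epsilon: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.kind not in ("lra", "qda", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")


@dataclass
class CVScores:
    patient_ids: List[str]
    y_true: np.ndarray            # 1 = positive class
    scores: np.ndarray
    classifier: ClassifierSpec
    phase: str = ""
    mode: str = "paper"

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.patient_ids) != len(set(self.patient_ids)):
            raise ValueError("duplicate patient ids in CV scores")
        if not (len(self.patient_ids) == len(self.y_true) == len(self.scores)):
            raise ValueError("inconsistent CV score lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "label": self.y_true,
                "score": self.scores,
                "classifier": self.classifier.kind,
                "phase": self.phase,
                "mode": self.mode,
            }
        )


class _GaussianQDA:
    """Quadratic discriminant with an explicit covariance ridge.

    Per class: maximum-likelihood mean and covariance, with
    epsilon * trace(S)/p added to the diagonal for numerical stability on
    small training folds.  Scores are posterior probabilities under
    empirical class priors.
    """

    def __init__(self, epsilon: float = 1e-6):
        self.epsilon = epsilon

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GaussianQDA":
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self._params = []
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise ValueError(f"class {c} has fewer than 2 training samples")
            mean = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=1).reshape(p, p)
            ridge = self.epsilon * np.trace(cov) / p
            if ridge <= 0:
                ridge = self.epsilon
            cov = cov + ridge * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ValueError("singular class covariance after ridge")
            self._params.append(
                (mean, np.linalg.inv(cov), logdet, np.log(len(Xc) / len(X)))
            )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logp = np.empty((len(X), len(self.classes_)))
        for k, (mean, prec, logdet, logprior) in enumerate(self._params):
            d = X - mean
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            logp[:, k] = -0.5 * (maha + logdet) + logprior
        logp -= logp.max(axis=1, keepdims=True)
        prob = np.exp(logp)
        return prob / prob.sum(axis=1, keepdims=True)


def _make_model(spec: ClassifierSpec):
    if spec.kind == "lra":
        # unpenalized maximum likelihood; separation is capped by max_iter
        return LogisticRegression(C=np.inf, max_iter=spec.max_iter)
    if spec.kind == "qda":
        return _GaussianQDA(epsilon=spec.regularization_epsilon)
    return SVC(kernel=spec.svm_kernel, C=spec.svm_C, gamma=spec.svm_gamma)


def _score_one(model, spec: ClassifierSpec, x: np.ndarray) -> float:
    if spec.kind == "svm":
        return float(model.decision_function(x)[0])
    return float(model.predict_proba(x)[0, 1])


def _standardize_pair(Xtr: np.ndarray, Xte: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def fit_predict_loocv(
    X,
    y,
    spec: ClassifierSpec,
    mode: str = "paper",
    patient_ids: Optional[Sequence[str]] = None,
    feature_names: Optional[Sequence[str]] = None,
    phase: str = "",
    seed: int = 0,
    screening_cfg: Optional[ScreeningConfig] = None,
    selection_folds: int = 10,
    selection_lambdas: int = 100,
) -> CVScores:
    """Out-of-fold decision scores under leave-one-out cross-validation.

    In ``paper`` mode `X` is the already-selected feature matrix.  In
    ``leakage_safe`` mode `X` is the full (screened-input) feature matrix and
    `feature_names` its columns; each fold repeats screening and LASSO on its
    own training data.  If a fold selects nothing it falls back to all
    screened features, and failing that to the full matrix.
    """
    if mode not in ("paper", "leakage_safe"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    if n < 4 or classes.size != 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need n >= 4 with at least 2 samples per class")
    y01 = (y == classes.max()).astype(int)
    ids = list(patient_ids) if patient_ids is not None else [f"P{i:03d}" for i in range(n)]
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]

    scores = np.empty(n)
    for i in range(n):
        tr = np.r_[0:i, i + 1 : n]
        assert i not in tr  # structural leakage check
        Xtr_full, ytr = X[tr], y01[tr]
        if ytr.min() == ytr.max():
            raise ValueError(f"class absent from training fold {i}")
        cols = np.arange(X.shape[1])
        if mode == "leakage_safe":
            scr = screening_cfg or ScreeningConfig()
            pvals = screen_matrix_fast(
                Xtr_full[ytr == 1], Xtr_full[ytr == 0], scr
            )
            kept_idx = np.nonzero(pvals < scr.alpha_screen)[0]
            if kept_idx.size:
                sel = lasso_select(
                    Xtr_full[:, kept_idx],
                    ytr,
                    feature_names=[names[j] for j in kept_idx],
                    k_folds=selection_folds,
                    seed=seed,
                    n_lambdas=selection_lambdas,
                )
                if sel.selected:
                    cols = kept_idx[
                        [j for j, nm in enumerate([names[k] for k in kept_idx]) if nm in sel.selected]
                    ]
                else:
                    cols = kept_idx
        Xtr, Xte = _standardize_pair(Xtr_full[:, cols], X[i : i + 1, cols])
        model = _make_model(spec).fit(Xtr, ytr)
        scores[i] = _score_one(model, spec, Xte)

    return CVScores(
        patient_ids=ids,
        y_true=y01,
        scores=scores,
        classifier=spec,
        phase=phase,
        mode=mode,
    )
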