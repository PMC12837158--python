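"""Endoleak Risk Index and the logistic risk model.

The composite index is

    raw = AC + SGS2 + SGM2 / 2
    ERI = raw / 2.5          (2.5 = maximum attainable raw score)

so the normalized ERI lies in [0, 1].  A case is predicted endoleak
positive when ERI >= cutoff; the default decision cutoff is 0.80,
selected by ROC analysis (Youden's J) on simulated cohorts.

The logistic risk model over (AC, SGS2, SGM2) follows the usual
model/results split: construct :class:`EndoleakRiskModel` from data,
``fit()`` returns an :class:`EndoleakRiskResults` carrying coefficients
and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .features import RiskFeatures

DEFAULT_CUTOFF = 0.80
_MAX_RAW = 2.5
FEATURE_NAMES = ("ac", "sgs2", "sgm2")


@dataclass(frozen=True)
class ERIResult:
    """Composite score of one case with its binary prediction."""

    raw: float
    eri: float
    cutoff: float
    positive: bool
    features: dict

    def as_dict(self) -> dict:
        return {
            "raw": self.raw,
            "eri": self.eri,
            "cutoff": self.cutoff,
            "prediction": "positive" if self.positive else "negative",
            "features": self.features,
        }


def compute_eri(features: RiskFeatures, cutoff: float = DEFAULT_CUTOFF) -> ERIResult:
    """ERI = (AC + SGS2 + SGM2/2) / 2.5, thresholded at ``cutoff``."""
    for name in FEATURE_NAMES:
        v = getattr(features, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"feature {name}={v} outside [0, 1]")
    raw = features.ac + features.sgs2 + features.sgm2 / 2.0
    eri = raw / _MAX_RAW
    return ERIResult(
        raw=float(raw),
        eri=float(eri),
        cutoff=float(cutoff),
        positive=bool(eri >= cutoff),
        features={k: float(getattr(features, k)) for k in FEATURE_NAMES},
    )


def classify(eri: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Binary prediction: endoleak positive iff ERI >= cutoff (boundary inclusive)."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    return bool(eri >= cutoff)


@dataclass
class RocAnalysis:
    """Full ROC over score thresholds with the Youden-optimal cutoff."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def select_cutoff_roc(scores: Sequence[float], labels: Sequence[int]) -> RocAnalysis:
    """ROC curve and Youden's-J optimal cutoff (ties -> higher specificity)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: degenerate ROC, AUC 0.5", stacklevel=2)
        return RocAnalysis(
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, scores[0]]),
            auc=0.5,
            optimal_cutoff=float(scores[0]),
        )
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    # ties broken toward higher specificity (lower FPR), then higher threshold
    order = np.lexsort((-thr[candidates], fpr[candidates]))
    k = candidates[order[0]]
    return RocAnalysis(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                       optimal_cutoff=float(thr[k]))


class ModelNotFittedError(RuntimeError):
    pass


class EndoleakRiskModel:
    """Logistic regression of endoleak on (AC, SGS2, SGM2).

    Maximum-likelihood fit with a small ridge penalty so separable
    simulated cohorts remain estimable.  Construct from arrays, a
    DataFrame (:meth:`from_dataframe`) or feature/label pairs
    (:meth:`from_cases`), then call :meth:`fit`.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float).reshape(-1, len(FEATURE_NAMES))
        y = np.asarray(y, dtype=int).ravel()
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(y) < 20:
            raise ValueError("need at least 20 training cases")
        if len(set(y.tolist())) < 2:
            raise ValueError("training data must contain both classes")
        self.X, self.y = X, y

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "leak") -> "EndoleakRiskModel":
        return cls(frame[list(FEATURE_NAMES)].to_numpy(), frame[label_col].to_numpy())

    @classmethod
    def from_cases(
        cls, cases: Sequence[tuple[RiskFeatures, int]]
    ) -> "EndoleakRiskModel":
        X = np.array([[getattr(f, k) for k in FEATURE_NAMES] for f, _ in cases])
        y = np.array([lab for _, lab in cases], dtype=int)
        return cls(X, y)

    def fit(self, seed: int = 0, alpha: float = 1e-2, max_iter: int = 2000) -> "EndoleakRiskResults":
        clf = LogisticRegression(
            C=1.0 / alpha, solver="lbfgs", max_iter=max_iter, tol=1e-10,
            random_state=seed,
        )
        clf.fit(self.X, self.y)
        n_iter = int(np.max(clf.n_iter_))
        if n_iter >= max_iter:
            raise RuntimeError(
                f"logistic fit did not converge within {max_iter} iterations "
                f"(reached {n_iter})"
            )
        return EndoleakRiskResults(
            coef=clf.coef_.ravel().copy(),
            intercept=float(clf.intercept_[0]),
            n_obs=len(self.y),
            seed=seed,
            alpha=alpha,
            n_iter=n_iter,
        )


@dataclass
class EndoleakRiskResults:
    """Fitted coefficients with the training descriptor for reproducibility."""

    coef: np.ndarray
    intercept: float
    n_obs: int
    seed: int
    alpha: float
    n_iter: int
    feature_names: tuple = FEATURE_NAMES

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy()
        X = np.asarray(X, dtype=float).reshape(-1, len(self.feature_names))
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def summary(self) -> str:
        lines = [
            "Endoleak logistic risk model",
            f"  n_obs: {self.n_obs}   ridge alpha: {self.alpha}   "
            f"iterations: {self.n_iter}   seed: {self.seed}",
            f"  intercept: {self.intercept:+.4f}",
        ]
        for name, c in zip(self.feature_names, self.coef):
            lines.append(f"  {name:>6s}: {c:+.4f}")
        return "\n".join(lines)

    def to_json(self, path: Optional[str] = None) -> str:
        payload = json.dumps(
            {
                "coef": dict(zip(self.feature_names, map(float, self.coef))),
                "intercept": self.intercept,
                "training": {"n_obs": self.n_obs, "seed": self.seed,
                             "alpha": self.alpha, "n_iter": self.n_iter},
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path: str) -> "EndoleakRiskResults":
        with open(path) as fh:
            d = json.load(fh)
        names = tuple(FEATURE_NAMES)
        return cls(
            coef=np.array([d["coef"][k] for k in names]),
            intercept=float(d["intercept"]),
            n_obs=int(d["training"]["n_obs"]),
            seed=int(d["training"]["seed"]),
            alpha=float(d["training"]["alpha"]),
            n_iter=int(d["training"]["n_iter"]),
            feature_names=names,
        )
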