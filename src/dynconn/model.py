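"""Sparse linear trait models: Lasso with the max-features rule.

The amount of L1 shrinkage is not tuned by nested search.  Instead the
regularization path is computed from heavy to light shrinkage and the
selected penalty is the smallest one whose active set is still no larger
than the training sample size — i.e. the least-regularized admissible
solution ("as many features as subjects").  Features are z-scored inside
every training fit; prediction on new data always reuses the training
statistics (pattern expression), never the new cohort's.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .features import FeatureTable

N_ALPHAS = 100
ALPHA_MIN_RATIO = 1e-4

MODEL_SCHEMA_VERSION = 1


@dataclass
class TraitModel:
    """A fitted sparse linear model from edge features to a trait score.

    Weights live on the standardized-feature scale; ``standardization``
    stores the training per-feature (mean, sd) needed to apply the model
    elsewhere.
    """

    seed_id: str
    outcome_name: str
    edge_ids: list[str]
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n_train: int
    penalty: float
    standardized: bool = True
    config_hash: str | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if np.count_nonzero(self.weights) > self.n_train:
            raise ValueError("more nonzero weights than training subjects")
        if (self.feature_sds <= 0).any():
            raise ValueError("standardization sds must be positive")

    @property
    def nonzero_edges(self) -> list[str]:
        return [e for e, w in zip(self.edge_ids, self.weights) if w != 0.0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema_version": MODEL_SCHEMA_VERSION,
            "seed_id": self.seed_id,
            "outcome_name": self.outcome_name,
            "edge_ids": self.edge_ids,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "n_train": self.n_train,
            "penalty": self.penalty,
            "standardized": self.standardized,
            "config_hash": self.config_hash,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "TraitModel":
        d = json.loads(Path(path).read_text())
        d.pop("schema_version", None)
        return cls(**d)


def _prepare(features: FeatureTable, outcome) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = np.asarray(outcome, dtype=float).ravel()
    X = features.values
    if X.shape[0] != y.size:
        raise ValueError("feature rows do not align with outcome length")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects")
    if y.std() <= 1e-12:
        raise ValueError("outcome is constant")
    sds = X.std(axis=0)
    keep = sds > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)",
                      stacklevel=3)
    return X[:, keep], y, [e for e, k in zip(features.edge_ids, keep) if k]


def _fit_core(X: np.ndarray, y: np.ndarray, standardize: bool
              ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    means = X.mean(axis=0)
    sds = X.std(axis=0) if standardize else np.ones(X.shape[1])
    Z = (X - means) / sds
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Z.T @ yc)) / n
    if alpha_max <= 0:
        raise ValueError("degenerate design: all features orthogonal to outcome")
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * ALPHA_MIN_RATIO),
                         N_ALPHAS)
    with warnings.catch_warnings():
        # the grid's light end sits near interpolation, where coordinate
        # descent may stop on its iteration cap; harmless for path selection
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(Z, yc, alphas=alphas, max_iter=2000)
    nnz = np.count_nonzero(coefs, axis=0)
    admissible = np.flatnonzero(nnz <= n)
    idx = admissible[np.argmin(alphas[admissible])]  # least-regularized admissible
    w = coefs[:, idx]
    return w, float(y.mean()), means, sds, float(alphas[idx])


def fit_lasso_max_features(
    features: FeatureTable, outcome, *, seed_id: str | None = None,
    outcome_name: str = "trait", standardize: bool = True,
) -> TraitModel:
    """Fit the Lasso and keep the least-regularized admissible solution.

    The active set at the selected penalty never exceeds the number of
    training subjects.  Constant feature columns are dropped with a warning
    before fitting.
    """
    X, y, edge_ids = _prepare(features, outcome)
    w, intercept, means, sds, penalty = _fit_core(X, y, standardize)
    return TraitModel(
        seed_id=seed_id or features.provenance.get("seed_id", "seed"),
        outcome_name=outcome_name,
        edge_ids=edge_ids,
        weights=w,
        intercept=intercept,
        feature_means=means,
        feature_sds=sds,
        n_train=X.shape[0],
        penalty=penalty,
        standardized=standardize,
        config_hash=features.provenance.get("config_hash"),
    )


def loocv_predict(features: FeatureTable, outcome, *, standardize: bool = True
                  ) -> np.ndarray:
    """Leave-one-participant-out cross-validated predictions.

    The whole fitting procedure — standardization, path computation and
    penalty selection — is repeated with each subject held out, so the
    held-out prediction never sees that subject's outcome.
    """
    X, y, _ = _prepare(features, outcome)
    n = X.shape[0]
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        w, intercept, means, sds, _ = _fit_core(X[mask], y[mask], standardize)
        preds[i] = w @ ((X[i] - means) / sds) + intercept
        mask[i] = True
    return preds


def pattern_expression(model: TraitModel, features: FeatureTable) -> np.ndarray:
    """Apply a fixed model to a (possibly new) cohort's features.

    score_i = sum_j w_j * (x_ij - mean_j) / sd_j + intercept with the
    model's stored training statistics.  Extra feature columns are ignored;
    a zero-weight edge missing from the table contributes nothing; a
    nonzero-weight edge missing is an error.
    """
    col = {e: k for k, e in enumerate(features.edge_ids)}
    scores = np.full(len(features.subject_ids), model.intercept)
    for j, edge in enumerate(model.edge_ids):
        w = model.weights[j]
        if edge not in col:
            if w != 0.0:
                raise KeyError(f"feature table lacks required edge {edge!r}")
            continue
        x = features.values[:, col[edge]]
        scores += w * (x - model.feature_means[j]) / model.feature_sds[j]
    return scores


def evaluate(y_true, y_pred) -> float:
    """Pearson correlation between observed and predicted scores."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 3:
        raise ValueError("need at least 3 pairs")
    if y_true.std() <= 1e-12 or y_pred.std() <= 1e-12:
        raise ValueError("constant input vector")
    return float(stats.pearsonr(y_true, y_pred).statistic)
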