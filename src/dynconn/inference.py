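"""Significance machinery for the model-selection cascade.

One-sided permutation tests on prediction-outcome correlations,
Benjamini-Hochberg FDR across the seed x outcome model family, percentile
bootstrap CIs, 3-sd outlier flagging, and the train -> validate -> test
cascade that mirrors a multi-study model-selection design: models must
survive FDR-corrected cross-validated significance on the training cohort,
then uncorrected p < 0.05 on an independent validation cohort (applied as
fixed pattern-expression models, never refit), before being reported on the
final test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTable
from .model import (TraitModel, evaluate, fit_lasso_max_features, loocv_predict,
                    pattern_expression)


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


@dataclass
class PermutationResult:
    r_observed: float
    n_permutations: int
    p_value: float
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def permutation_pvalue(y_true, y_pred, n_permutations: int = 10000, rng=None,
                       *, store_null: bool = False) -> PermutationResult:
    """One-sided permutation test of the prediction-outcome correlation.

    The null distribution shuffles the pairing of existing predictions with
    outcomes (the predictions themselves are not recomputed);
    p = (1 + #{r_null >= r_obs}) / (n_permutations + 1), so p is never 0 and
    never below 1/(n_permutations + 1).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    r_obs = evaluate(y_true, y_pred)
    rng = _as_rng(rng)
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    n = yt.size
    zt = (yt - yt.mean()) / yt.std()
    zp = (yp - yp.mean()) / yp.std()
    idx = rng.permuted(np.tile(np.arange(n), (n_permutations, 1)), axis=1)
    null_r = (zt[idx] @ zp) / n
    p = (1.0 + int(np.sum(null_r >= r_obs))) / (n_permutations + 1.0)
    return PermutationResult(r_obs, n_permutations, p,
                             null_r if store_null else None)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Returns per-test pass flags and the implied p threshold (the largest
    passing p; NaN when nothing passes).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = np.flatnonzero(ranked <= (np.arange(1, m + 1) / m) * q)
    if below.size == 0:
        return np.zeros(m, dtype=bool), float("nan")
    threshold = ranked[below[-1]]
    return p <= threshold, float(threshold)


def bootstrap_ci(y_true, y_pred, n_boot: int = 10000, level: float = 0.95,
                 rng=None) -> tuple[float, float]:
    """Percentile bootstrap CI for the prediction-outcome Pearson r.

    Subjects are resampled in pairs; a resample yielding a constant vector
    is redrawn.
    """
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size != yp.size or yt.size < 10:
        raise ValueError("need paired samples with n >= 10")
    rng = _as_rng(rng)
    n = yt.size

    def _batch_r(k: int) -> np.ndarray:
        idx = rng.integers(0, n, (k, n))
        a, c = yt[idx], yp[idx]
        sa = a.std(axis=1)
        sc = c.std(axis=1)
        good = (sa > 1e-12) & (sc > 1e-12)
        cov = (a * c).mean(axis=1) - a.mean(axis=1) * c.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / (sa * sc)
        return r[good]

    rs = _batch_r(n_boot)
    redraws = 0
    while rs.size < n_boot:  # degenerate (constant) resamples are redrawn
        redraws += n_boot - rs.size
        if redraws > 100 * n_boot:
            raise RuntimeError("bootstrap resamples persistently degenerate")
        rs = np.concatenate([rs, _batch_r(n_boot - rs.size)])
    lo = (1.0 - level) / 2.0
    return float(np.quantile(rs, lo)), float(np.quantile(rs, 1.0 - lo))


def flag_outliers(values) -> np.ndarray:
    """Mask of points more than 3 sample standard deviations from the mean.

    Single pass (no iterative re-screening); a constant vector flags
    nothing.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("need at least 3 values")
    sd = v.std(ddof=1)
    if sd <= 1e-12:
        return np.zeros(v.size, dtype=bool)
    return np.abs(v - v.mean()) > 3.0 * sd


@dataclass
class CohortFeatures:
    """Feature tables (one per seed) plus outcome columns for one cohort."""

    features: dict[str, FeatureTable]
    outcomes: pd.DataFrame


@dataclass
class CascadeReport:
    """Per-stage model results; later stages are subsets of earlier passers."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    stage3: pd.DataFrame
    models: dict[tuple[str, str], TraitModel] = field(repr=False)

    def __post_init__(self):
        s1_pass = set(map(tuple, self.stage1.loc[self.stage1["fdr_pass"],
                                                 ["seed", "outcome"]].to_numpy()))
        s2 = set(map(tuple, self.stage2[["seed", "outcome"]].to_numpy()))
        s2_pass = set(map(tuple, self.stage2.loc[self.stage2["pass"],
                                                 ["seed", "outcome"]].to_numpy()))
        s3 = set(map(tuple, self.stage3[["seed", "outcome"]].to_numpy()))
        if not s2 <= s1_pass or not s3 <= s2_pass:
            raise ValueError("cascade stages are not nested")

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("stage1", "stage2", "stage3"):
            getattr(self, name).to_csv(outdir / f"cascade_{name}.csv", index=False)

    def to_json(self, path: str | Path) -> None:
        import json
        payload = {name: getattr(self, name).to_dict(orient="records")
                   for name in ("stage1", "stage2", "stage3")}
        Path(path).write_text(json.dumps(payload, default=float))


def _safe_test(y_true, scores, n_permutations, rng):
    try:
        r = evaluate(y_true, scores)
        p = permutation_pvalue(y_true, scores, n_permutations, rng).p_value
    except ValueError:  # constant predictions: record as non-significant
        r, p = float("nan"), 1.0
    return r, p


def _resolve(cohort) -> CohortFeatures:
    return cohort() if callable(cohort) else cohort


def run_cascade(
    train: CohortFeatures,
    validation,
    test,
    seed_ids: list[str],
    outcome_names: list[str],
    *,
    q: float = 0.05,
    stage2_alpha: float = 0.05,
    n_permutations: int = 10000,
    n_boot: int = 10000,
    rng=None,
    screen_outliers: bool = False,
) -> CascadeReport:
    """Run the three-stage model-selection cascade over a model family.

    Stage 1 fits every seed x outcome model on the training cohort,
    evaluates it by LOOCV with a one-sided permutation test, and applies
    BH-FDR at level ``q`` across the family.  Stage-1 survivors are applied
    (fixed weights, no refit) to the validation cohort and kept at
    uncorrected p < ``stage2_alpha``.  Stage-2 survivors are reported on the
    test cohort with a percentile-bootstrap CI; ``screen_outliers``
    additionally reports the test r with >3-sd scatter points removed.

    ``validation`` and ``test`` may be :class:`CohortFeatures` or zero-arg
    callables returning one; callables are invoked only if the preceding
    stage has survivors, so a family that dies early never pays for later
    cohorts' feature extraction.
    """
    rng = _as_rng(rng)
    models: dict[tuple[str, str], TraitModel] = {}
    rows = []
    for seed in seed_ids:
        for outcome in outcome_names:
            y = train.outcomes[outcome].to_numpy(dtype=float)
            model = fit_lasso_max_features(train.features[seed], y,
                                           seed_id=seed, outcome_name=outcome)
            preds = loocv_predict(train.features[seed], y)
            r, p = _safe_test(y, preds, n_permutations, rng)
            models[(seed, outcome)] = model
            rows.append({"seed": seed, "outcome": outcome, "r": r, "p": p})
    stage1 = pd.DataFrame(rows)
    flags, thr = bh_fdr(stage1["p"].to_numpy(), q)
    stage1["fdr_pass"] = flags
    stage1.attrs["fdr_threshold"] = thr

    rows2 = []
    survivors1 = stage1[stage1["fdr_pass"]]
    if len(survivors1):
        validation = _resolve(validation)
    for _, row in survivors1.iterrows():
        key = (row["seed"], row["outcome"])
        scores = pattern_expression(models[key], validation.features[key[0]])
        y = validation.outcomes[key[1]].to_numpy(dtype=float)
        r, p = _safe_test(y, scores, n_permutations, rng)
        rows2.append({"seed": key[0], "outcome": key[1], "r": r, "p": p,
                      "pass": p < stage2_alpha})
    stage2 = pd.DataFrame(rows2, columns=["seed", "outcome", "r", "p", "pass"])

    rows3 = []
    passers2 = stage2[stage2["pass"]] if len(stage2) else stage2.iloc[0:0]
    if len(passers2):
        test = _resolve(test)
    for _, row in passers2.iterrows():
        key = (row["seed"], row["outcome"])
        scores = pattern_expression(models[key], test.features[key[0]])
        y = test.outcomes[key[1]].to_numpy(dtype=float)
        r, p = _safe_test(y, scores, n_permutations, rng)
        rec = {"seed": key[0], "outcome": key[1], "r": r, "p": p}
        if np.isfinite(r):
            rec["ci_low"], rec["ci_high"] = bootstrap_ci(y, scores, n_boot, rng=rng)
        else:
            rec["ci_low"] = rec["ci_high"] = float("nan")
        if screen_outliers:
            mask = flag_outliers(y) | flag_outliers(scores)
            if mask.any() and (~mask).sum() >= 3:
                rec["r_screened"], rec["p_screened"] = _safe_test(
                    y[~mask], scores[~mask], n_permutations, rng)
                rec["n_outliers"] = int(mask.sum())
        rows3.append(rec)
    stage3 = pd.DataFrame(rows3) if rows3 else pd.DataFrame(
        columns=["seed", "outcome", "r", "p", "ci_low", "ci_high"])
    return CascadeReport(stage1=stage1, stage2=stage2, stage3=stage3,
                         models=models)
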