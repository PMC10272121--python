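"""Virtual-lesion feature importance and model refinement.

A lesion zeroes one weight of a fixed linear model (no refit — for a linear
model this equals dropping the feature at its training mean) and measures
the drop in prediction-outcome correlation on an evaluation cohort:
delta_corr = r_full - r_reduced.  A feature is *important* when its lesion
decreases performance (delta > 0) on every evaluation cohort; the refined
model keeps only important features, weights and standardization copied
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTable
from .model import TraitModel, evaluate, pattern_expression


@dataclass
class LesionReport:
    """Per-feature delta_corr on one or more evaluation cohorts."""

    feature_ids: list[str]            # nonzero-weight edges of the full model
    cohort_names: list[str]
    delta_corr: pd.DataFrame          # rows = features, cols = cohorts (NaN = undefined)
    r_full: dict[str, float]
    model: TraitModel = field(repr=False)

    def to_csv(self, path: str | Path) -> None:
        long = self.delta_corr.reset_index(names="feature").melt(
            id_vars="feature", var_name="cohort", value_name="delta_corr")
        long.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        import json
        Path(path).write_text(json.dumps({
            "feature_ids": self.feature_ids,
            "cohort_names": self.cohort_names,
            "r_full": self.r_full,
            "delta_corr": {c: self.delta_corr[c].to_dict()
                           for c in self.cohort_names},
        }, default=float))


def virtual_lesion(model: TraitModel,
                   cohorts: list[tuple[FeatureTable, np.ndarray]],
                   cohort_names: list[str] | None = None) -> LesionReport:
    """Lesion each nonzero-weight feature and measure delta_corr per cohort.

    A reduction that yields constant predictions (possible when a single
    informative feature remains) records that delta as NaN with a warning.
    """
    if len(cohorts) < 1:
        raise ValueError("need at least one evaluation cohort")
    feats = model.nonzero_edges
    if len(feats) < 2:
        raise ValueError("model needs at least 2 nonzero weights to lesion")
    names = cohort_names or [f"cohort_{k + 1}" for k in range(len(cohorts))]
    r_full: dict[str, float] = {}
    delta = pd.DataFrame(index=feats, columns=names, dtype=float)
    for name, (table, y) in zip(names, cohorts):
        y = np.asarray(y, dtype=float).ravel()
        r_full[name] = evaluate(y, pattern_expression(model, table))
        for edge in feats:
            j = model.edge_ids.index(edge)
            w = model.weights.copy()
            w[j] = 0.0
            reduced = replace(model, weights=w)
            try:
                r_red = evaluate(y, pattern_expression(reduced, table))
            except ValueError:
                warnings.warn(f"lesioning {edge!r} on {name}: constant "
                              "predictions, delta undefined", stacklevel=2)
                delta.loc[edge, name] = np.nan
                continue
            delta.loc[edge, name] = r_full[name] - r_red
    return LesionReport(feature_ids=feats, cohort_names=names,
                        delta_corr=delta, r_full=r_full, model=model)


def important_features(report: LesionReport
                       ) -> tuple[list[str], dict[tuple[str, str], float]]:
    """Features whose lesion hurts on ALL cohorts, plus cross-cohort consistency.

    Importance requires strictly positive delta_corr in every evaluation
    cohort (an exact-zero or undefined delta excludes the feature).  The
    consistency value is the Pearson correlation of the per-feature delta
    patterns for each cohort pair.
    """
    if len(report.cohort_names) < 2:
        raise ValueError("importance needs at least 2 evaluation cohorts")
    d = report.delta_corr
    keep = d.index[(d > 0).all(axis=1) & d.notna().all(axis=1)].tolist()
    consistency = {}
    cn = report.cohort_names
    for a in range(len(cn)):
        for b in range(a + 1, len(cn)):
            ok = d[[cn[a], cn[b]]].dropna().to_numpy()
            if len(ok) < 2 or ok[:, 0].std() == 0 or ok[:, 1].std() == 0:
                consistency[(cn[a], cn[b])] = float("nan")
            else:
                consistency[(cn[a], cn[b])] = float(
                    np.corrcoef(ok[:, 0], ok[:, 1])[0, 1])
    return keep, consistency


def refine(model: TraitModel, keep: list[str]) -> TraitModel:
    """Restrict a fixed model to ``keep``, zeroing every other weight.

    Retained weights, intercept and standardization are copied unchanged
    (no refit).  ``keep`` must be a subset of the nonzero-weight features.
    """
    if not keep:
        raise ValueError("keep set is empty")
    nz = set(model.nonzero_edges)
    unknown = [e for e in keep if e not in nz]
    if unknown:
        raise ValueError(f"keep contains non-model features: {unknown}")
    keep_set = set(keep)
    w = np.array([wj if e in keep_set else 0.0
                  for e, wj in zip(model.edge_ids, model.weights)])
    return replace(model, weights=w)
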