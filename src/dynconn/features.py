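"""Cohort-level feature tables: DCC variance, DCC mean, or static Pearson.

One table holds one feature kind for one seed across a cohort: rows follow
the manifest, columns are (seed, target) edges.  Edges whose estimation
failed to converge for any subject are dropped table-wide (the Lasso stage
has no missing-data handling), with the dropped list recorded in the
table's provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dcc import seed_dcc_map
from .io import CohortData, config_hash

KINDS = ("dcc_variance", "dcc_mean", "static")


@dataclass
class FeatureTable:
    """Subjects x edges matrix of one feature kind."""

    kind: str
    subject_ids: list[str]
    edge_ids: list[str]
    values: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.edge_ids)):
            raise ValueError("values shape does not match subject/edge ids")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")
        if self.kind == "dcc_variance" and (self.values < 0).any():
            raise ValueError("dcc_variance features must be non-negative")
        if self.kind in ("dcc_mean", "static") and (np.abs(self.values) > 1).any():
            raise ValueError(f"{self.kind} features must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids,
                            name="subject_id"), columns=self.edge_ids)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path)
        sidecar = {"kind": self.kind, **self.provenance}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        prov = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        kind = prov.pop("kind", "static")
        return cls(kind=kind, subject_ids=[str(s) for s in df.index],
                   edge_ids=list(df.columns), values=df.to_numpy(), provenance=prov)


def edge_dynamics_table(dynamics) -> pd.DataFrame:
    """Tabulate a subject's edge-dynamics list (one row per edge)."""
    return pd.DataFrame(
        [{"seed": ed.seed_id, "target": ed.target_id, "dcc_mean": ed.dcc_mean,
          "dcc_variance": ed.dcc_variance, "converged": ed.converged}
         for ed in dynamics],
        columns=["seed", "target", "dcc_mean", "dcc_variance", "converged"])


def _static_row(subject, seed_id: str, target_ids: list[str]) -> np.ndarray:
    seed = subject.column(seed_id)
    seed = seed - seed.mean()
    out = np.empty(len(target_ids))
    for k, tid in enumerate(target_ids):
        tgt = subject.column(tid)
        out[k] = np.corrcoef(seed, tgt - tgt.mean())[0, 1]
    return out


def build_feature_table(
    cohort: CohortData,
    seed_id: str,
    kind: str = "dcc_variance",
    target_ids: list[str] | None = None,
    *,
    fisher_z: bool = False,
) -> FeatureTable:
    """Assemble one seed's feature table across a cohort.

    ``target_ids`` defaults to every region that is not a declared seed.
    For ``kind='static'`` the value is the full-run Pearson correlation of
    the raw (demeaned) seed and target series; the DCC kinds run the full
    two-stage estimator per subject, sharing stage-1 fits across edges.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    if cohort.seed_ids and seed_id not in cohort.seed_ids:
        raise ValueError(f"{seed_id!r} is not a declared seed")
    labels = cohort.series[0].labels
    if target_ids is None:
        seeds = set(cohort.seed_ids) or {seed_id}
        target_ids = [r for r in labels if r not in seeds]

    n = len(cohort.series)
    values = np.empty((n, len(target_ids)))
    bad_edges: set[int] = set()
    for i, subject in enumerate(cohort.series):
        if subject.n_timepoints < 100:
            raise ValueError(f"subject {i}: series shorter than 100 timepoints")
        if kind == "static":
            values[i] = _static_row(subject, seed_id, target_ids)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dyn = seed_dcc_map(subject, [seed_id], target_ids,
                                   fisher_z=fisher_z)
            for k, ed in enumerate(dyn):
                values[i, k] = ed.dcc_variance if kind == "dcc_variance" \
                    else ed.dcc_mean
                if not ed.converged:
                    bad_edges.add(k)

    edge_ids = [f"{seed_id}__{tid}" for tid in target_ids]
    dropped = [edge_ids[k] for k in sorted(bad_edges)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} non-converged edge(s) table-wide: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        keep = [k for k in range(len(edge_ids)) if k not in bad_edges]
        values = values[:, keep]
        edge_ids = [edge_ids[k] for k in keep]

    prov = {
        "seed_id": seed_id,
        "dropped_edges": dropped,
        "fisher_z": fisher_z,
        "config_hash": config_hash(
            {"seed": seed_id, "kind": kind, "targets": target_ids,
             "fisher_z": fisher_z}
        ),
    }
    return FeatureTable(kind=kind, subject_ids=cohort.subject_ids,
                        edge_ids=edge_ids, values=values, provenance=prov)
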