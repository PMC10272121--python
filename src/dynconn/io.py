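"""Readers/writers for series, manifests and run configuration.

Series files are plain delimited text: T rows x P columns with a mandatory
header row of region labels (TSV by default, comma accepted).  A cohort is a
manifest CSV (subject_id, series_path, outcome columns) plus one series file
per row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ParcellatedSeries:
    """One subject's T x P matrix of region time courses."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("series values must be a 2-D (T x P) array")
        if self.values.shape[1] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            return self.values[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None


def read_series(path: str | Path) -> ParcellatedSeries:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        raise ValueError(f"NaN values in series file {path}")
    return ParcellatedSeries(labels=[str(c) for c in df.columns],
                             values=df.to_numpy(dtype=float))


def write_series(series: ParcellatedSeries, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(series.values, columns=series.labels).to_csv(
        path, sep=sep, index=False, float_format="%.10g"
    )


@dataclass
class CohortData:
    """In-memory cohort: manifest rows aligned 1:1 with series matrices."""

    manifest: pd.DataFrame
    series: list[ParcellatedSeries] = field(repr=False)
    seed_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.series) != len(self.manifest):
            raise ValueError("manifest rows and series count differ")

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.manifest["subject_id"]]


def load_cohort(manifest_path: str | Path, seed_ids: list[str] | None = None,
                min_timepoints: int = 100) -> CohortData:
    """Load a cohort from a manifest CSV; series paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("subject_id", "series_path"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    series = []
    for _, row in manifest.iterrows():
        p = Path(row["series_path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        s = read_series(p)
        if s.n_timepoints < min_timepoints:
            raise ValueError(
                f"{row['subject_id']}: series has {s.n_timepoints} timepoints "
                f"(minimum {min_timepoints})"
            )
        series.append(s)
    return CohortData(manifest=manifest, series=series, seed_ids=seed_ids or [])


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def check_provenance(expected: str | None, found: str | None, what: str) -> None:
    """Refuse to mix artifacts generated under different configurations."""
    if expected and found and expected != found:
        raise ValueError(
            f"config-hash mismatch for {what}: expected {expected}, found {found}"
        )
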