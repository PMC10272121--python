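"""Ruminative Response Scale (RRS) scoring.

Two scale versions are supported; both rate items from 1 (never) to 4
(always) and score each subscale as a plain item sum (no reverse scoring):

* ``korean19`` — the Korean adaptation keeps 19 of the original 22 items
  (original items 2, 14 and 15 are excluded) with its own three-factor
  structure: brooding {5, 9, 10, 13, 16, 18}, reflective pondering
  {7, 11, 12, 20, 21, 22}, depressive rumination {1, 3, 4, 6, 8, 17, 19}
  (item numbers in the ORIGINAL 22-item numbering).
* ``original22`` — the classic three-factor assignment of the English
  scale (Treynor et al. 2003, external to the pipeline's own data):
  brooding {5, 10, 13, 15, 16}, reflection {7, 11, 12, 20, 21}, and the
  12 remaining depression-related items.

A 19-length response vector is ordered by ascending original item number
(1, 3, 4, 5, ..., 22 skipping 2, 14, 15), which round-trips unambiguously
with item-number-labeled CSV columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

KOREAN19_MAP = {
    "brooding": (5, 9, 10, 13, 16, 18),
    "reflective": (7, 11, 12, 20, 21, 22),
    "depressive": (1, 3, 4, 6, 8, 17, 19),
}
KOREAN19_EXCLUDED = (2, 14, 15)
KOREAN19_ITEMS = tuple(i for i in range(1, 23) if i not in KOREAN19_EXCLUDED)

ORIGINAL22_MAP = {
    "brooding": (5, 10, 13, 15, 16),
    "reflective": (7, 11, 12, 20, 21),
    "depressive": (1, 2, 3, 4, 6, 8, 9, 14, 17, 18, 19, 22),
}

_VERSIONS = {
    "korean19": (KOREAN19_MAP, KOREAN19_ITEMS),
    "original22": (ORIGINAL22_MAP, tuple(range(1, 23))),
}


@dataclass(frozen=True)
class ItemResponses:
    version: str
    values: tuple[int, ...]

    def __post_init__(self):
        if self.version not in _VERSIONS:
            raise ValueError(f"unknown RRS version {self.version!r}")
        _, items = _VERSIONS[self.version]
        if len(self.values) != len(items):
            raise ValueError(
                f"{self.version} expects {len(items)} responses, "
                f"got {len(self.values)}"
            )
        if any(v not in (1, 2, 3, 4) for v in self.values):
            raise ValueError("every rating must be an integer in {1, 2, 3, 4}")


@dataclass(frozen=True)
class SubscaleScores:
    brooding: int
    reflective: int
    depressive: int


def score_rrs(responses: ItemResponses) -> SubscaleScores:
    """Sum each subscale's items for one respondent."""
    subscale_map, items = _VERSIONS[responses.version]
    by_item = dict(zip(items, responses.values))
    return SubscaleScores(**{
        name: sum(by_item[i] for i in item_set)
        for name, item_set in subscale_map.items()
    })


def score_rrs_table(path: str | Path, version: str = "korean19") -> pd.DataFrame:
    """Score a CSV of item responses (one row per subject).

    Item columns may be labeled ``item_01`` .. ``item_22`` or by bare item
    number; for ``korean19`` only the 19 retained original item numbers must
    be present.  Non-item columns (e.g. subject_id) pass through; subscale
    columns are appended.
    """
    df = pd.read_csv(path)
    _, items = _VERSIONS[version]

    def find_col(i: int) -> str:
        for cand in (f"item_{i:02d}", f"item_{i}", str(i)):
            if cand in df.columns:
                return cand
        raise ValueError(f"missing column for item {i}")

    cols = [find_col(i) for i in items]
    scores = [
        score_rrs(ItemResponses(version, tuple(int(v) for v in row)))
        for row in df[cols].itertuples(index=False)
    ]
    out = df.copy()
    out["rrs_brooding"] = [s.brooding for s in scores]
    out["rrs_reflective"] = [s.reflective for s in scores]
    out["rrs_depressive"] = [s.depressive for s in scores]
    return out
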