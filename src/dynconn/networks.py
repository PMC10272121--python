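"""Map model features to large-scale functional networks and tally weights.

Target regions of a model's nonzero-weight edges are assigned to one of ten
functional groups (seven cortical networks plus subcortical, brainstem and
cerebellum), and the signed weights are summarized as counts and
percentages per group.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import TraitModel

CANONICAL_GROUPS = (
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "frontoparietal", "default_mode",
    "subcortical", "brainstem", "cerebellum",
)

DISPLAY_THRESHOLD_PCT = 5.0  # groups below this are flagged for hiding, data kept


def read_assignment(path: str | Path) -> dict[str, str]:
    """Read a region_id -> group CSV; every region maps to exactly one group."""
    df = pd.read_csv(path)
    if not {"region_id", "group"} <= set(df.columns):
        raise ValueError("assignment table needs columns region_id, group")
    if df["region_id"].duplicated().any():
        raise ValueError("a region maps to more than one group")
    return dict(zip(df["region_id"].astype(str), df["group"].astype(str)))


def _target_of(edge_id: str) -> str:
    if "__" not in edge_id:
        raise ValueError(f"edge id {edge_id!r} is not seed__target formatted")
    return edge_id.split("__", 1)[1]


def summarize_weights(model: TraitModel, assignment: dict[str, str]
                      ) -> dict[str, pd.DataFrame]:
    """Per-group counts and percentages of positive and negative weights.

    Returns {'positive': df, 'negative': df} with columns count, percent and
    below_display_threshold; percentages sum to 100 within each sign.  The
    display flag affects rendering only, never the data.
    """
    tallies = {"positive": {}, "negative": {}}
    for edge, w in zip(model.edge_ids, model.weights):
        if w == 0.0:
            continue
        region = _target_of(edge)
        if region not in assignment:
            raise KeyError(f"region {region!r} missing from network assignment")
        sign = "positive" if w > 0 else "negative"
        group = assignment[region]
        tallies[sign][group] = tallies[sign].get(group, 0) + 1

    out = {}
    for sign, counts in tallies.items():
        total = sum(counts.values())
        rows = [
            {"group": g, "count": c, "percent": 100.0 * c / total,
             "below_display_threshold": 100.0 * c / total < DISPLAY_THRESHOLD_PCT}
            for g, c in sorted(counts.items())
        ]
        out[sign] = pd.DataFrame(rows, columns=["group", "count", "percent",
                                                "below_display_threshold"])
    return out
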