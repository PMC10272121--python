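#!/usr/bin/env python
"""Virtual-lesion importance analysis and refined-model construction.

Takes the trait model trained by 03_train_and_cascade.py, lesions one
nonzero-weight edge at a time (weight zeroed, no refit) on the validation
and test cohorts, keeps the edges whose removal hurts prediction on both
(the important set), builds the refined model, and summarizes the refined
weights over large-scale network groups using a synthetic region-to-network
assignment table (round-robin over the ten canonical groups; real analyses
would supply an atlas-derived table).
"""

from pathlib import Path

import pandas as pd

from dynconn.features import FeatureTable
from dynconn.lesion import important_features, refine, virtual_lesion
from dynconn.model import TraitModel, evaluate, pattern_expression
from dynconn.networks import CANONICAL_GROUPS, summarize_weights

ROOT = Path(__file__).resolve().parent.parent
FEATURES = ROOT / "results" / "features"
COHORTS = ROOT / "results" / "cohorts"
CASCADE = ROOT / "results" / "cascade" / "dcc_variance"
OUT = ROOT / "results" / "lesion"


def cohort(name: str):
    table = FeatureTable.from_csv(FEATURES / f"{name}_dcc_variance.csv")
    manifest = pd.read_csv(COHORTS / name / "manifest.csv")
    return table, manifest["trait"].to_numpy(dtype=float)


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    model = TraitModel.from_json(CASCADE / "model_seed_1_trait.json")
    cohorts = [cohort("validation"), cohort("test")]
    report = virtual_lesion(model, cohorts, ["validation", "test"])
    report.to_csv(OUT / "lesion_deltas.csv")
    keep, consistency = important_features(report)
    print(f"full model: {len(model.nonzero_edges)} nonzero weights; "
          f"{len(keep)} important on both cohorts")
    for pair, r in consistency.items():
        print(f"cross-cohort delta consistency {pair[0]}-{pair[1]}: r = {r:.3f}")

    refined = refine(model, keep)
    refined.to_json(OUT / "refined_model.json")
    for name, (table, y) in zip(("validation", "test"), cohorts):
        r_full = evaluate(y, pattern_expression(model, table))
        r_ref = evaluate(y, pattern_expression(refined, table))
        print(f"{name}: r_full = {r_full:.3f}, r_refined = {r_ref:.3f}")

    # synthetic assignment: regions cycled over the ten canonical groups
    regions = [e.split("__", 1)[1] for e in model.edge_ids]
    assignment = {r: CANONICAL_GROUPS[i % len(CANONICAL_GROUPS)]
                  for i, r in enumerate(regions)}
    pd.DataFrame({"region_id": list(assignment),
                  "group": list(assignment.values())}).to_csv(
        OUT / "synthetic_network_assignment.csv", index=False)
    summary = summarize_weights(refined, assignment)
    for sign, df in summary.items():
        df.to_csv(OUT / f"network_summary_{sign}.csv", index=False)
        print(f"{sign} weights by network:\n"
              f"{df.to_string(index=False) if len(df) else '  none'}")
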