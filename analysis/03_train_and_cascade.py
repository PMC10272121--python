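#!/usr/bin/env python
"""Train the sparse trait models and run the selection cascade.

Fits one Lasso model per outcome (the coupled trait plus two nuisance
scores) on the training cohort's DCC-variance features, evaluates each by
leave-one-out cross-validation with a one-sided permutation test, applies
BH-FDR across the family, then carries survivors — as fixed
pattern-expression models — through the validation and test cohorts.  The
same cascade is repeated on static-connectivity features for contrast.
Writes per-stage CSVs and the trait model JSON under results/cascade/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dynconn.features import FeatureTable
from dynconn.inference import CohortFeatures, run_cascade

ROOT = Path(__file__).resolve().parent.parent
FEATURES = ROOT / "results" / "features"
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "cascade"
OUTCOMES = ["trait", "nuisance_1", "nuisance_2"]
RNG_SEED = 20260103


def cohort_features(name: str, kind: str) -> CohortFeatures:
    table = FeatureTable.from_csv(FEATURES / f"{name}_{kind}.csv")
    manifest = pd.read_csv(COHORTS / name / "manifest.csv")
    return CohortFeatures(features={"seed_1": table},
                          outcomes=manifest[OUTCOMES])


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    for kind in ("dcc_variance", "static"):
        report = run_cascade(
            cohort_features("train", kind),
            lambda: cohort_features("validation", kind),
            lambda: cohort_features("test", kind),
            ["seed_1"], OUTCOMES, n_permutations=10000, n_boot=10000,
            rng=np.random.default_rng(RNG_SEED),
        )
        subdir = OUT / kind
        report.to_csv(subdir)
        for key, model in report.models.items():
            model.to_json(subdir / f"model_{key[0]}_{key[1]}.json")
        s1 = report.stage1
        print(f"[{kind}] stage 1 (training LOOCV):")
        print(s1.to_string(index=False))
        print(f"[{kind}] survivors -> validation: "
              f"{report.stage2.to_string(index=False) if len(report.stage2) else 'none'}")
        print(f"[{kind}] final test: "
              f"{report.stage3.to_string(index=False) if len(report.stage3) else 'none'}")
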