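#!/usr/bin/env python
"""Simulate the three synthetic cohorts (train / validation / test).

Generates the reference study conditions: 60 training, 40 validation and 40
test subjects, each with one seed region, 100 targets and 5 signal edges
whose fluctuation amplitude is coupled to the latent trait.  Series go to
results/cohorts/<name>/ as TSV plus a manifest CSV and ground-truth JSON.
"""

from dataclasses import replace
from pathlib import Path

from dynconn.synthetic import SimulationConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "cohorts"
BASE_SEED = 20260101

if __name__ == "__main__":
    base = SimulationConfig(rng_seed=BASE_SEED)
    for name, cfg in [
        ("train", base),
        ("validation", replace(base, n_subjects=40, rng_seed=BASE_SEED + 1)),
        ("test", replace(base, n_subjects=40, rng_seed=BASE_SEED + 2)),
    ]:
        cohort, truth = simulate_cohort(cfg)
        manifest = write_cohort(cohort, truth, OUT / name)
        print(f"{name}: {cfg.n_subjects} subjects x T={cfg.n_timepoints}, "
              f"signal edges {truth.support} -> {manifest}")
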