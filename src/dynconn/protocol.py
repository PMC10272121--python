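"""Reference synthetic-study protocol: the package's end-to-end benchmarks.

Bundles the repeated-measures experiments that the analysis scripts, the
test suite and the acceptance script all run: parameter recovery of the
estimation stages, rank agreement of the variance feature, and full
train -> validate -> test recovery on synthetic cohorts with known sparse
support.  Each function is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from . import _kernels as K
from .dcc import edge_dynamics, fit_garch11
from .features import build_feature_table
from .inference import CohortFeatures, run_cascade
from .synthetic import NUISANCE_COLS, SimulationConfig, simulate_cohort

OUTCOMES = ("trait",) + NUISANCE_COLS
SEED_ID = "seed_1"


def garch_recovery(rng_seed: int, T: int = 8000,
                   params=(0.1, 0.1, 0.8)) -> dict:
    """Simulate GARCH(1,1) and re-estimate its parameters."""
    rng = np.random.default_rng(rng_seed)
    omega, alpha, beta = params
    x = K.garch_sim(T, omega, alpha, beta, rng.standard_normal(T))
    fit = fit_garch11(x)
    return {"alpha": fit.alpha, "beta": fit.beta,
            "unconditional_variance": fit.unconditional_variance, "n": T}


def constant_correlation_recovery(rng_seed: int, T: int = 4000,
                                  rho: float = 0.5) -> dict:
    """DCC on a constant-correlation pair: path mean, variance, static gap."""
    rng = np.random.default_rng(rng_seed)
    e1 = rng.standard_normal(T)
    e2 = rho * e1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(T)
    ed = edge_dynamics(e1, e2)
    static = float(np.corrcoef(e1, e2)[0, 1])
    return {"dcc_mean": ed.dcc_mean, "dcc_variance": ed.dcc_variance,
            "static_r": static, "gap": abs(ed.dcc_mean - static), "n": T}


def variance_rank_agreement(rng_seed: int, T: int = 1000,
                            amplitudes=(0.0, 0.1, 0.2, 0.3, 0.4),
                            n_per_amplitude: int = 5) -> dict:
    """Spearman rank agreement of estimated vs true edge variance.

    Edges of graded modulation amplitude share one seed series; the true
    variance is the 1/T variance of each constructed rho path.
    """
    rng = np.random.default_rng(rng_seed)
    t = np.arange(T)
    seed_series = rng.standard_normal(T)
    garch_seed = fit_garch11(seed_series)
    est, true = [], []
    for amp in amplitudes:
        for _ in range(n_per_amplitude):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            rho = 0.1 + amp * np.sin(2.0 * np.pi * t / (T / 2.0) + phi)
            tgt = rho * seed_series + np.sqrt(1.0 - rho**2) \
                * rng.standard_normal(T)
            ed = edge_dynamics(seed_series, tgt, garch_seed=garch_seed)
            est.append(ed.dcc_variance)
            true.append(rho.var() if np.ptp(rho) > 0 else 0.0)
    spearman = float(stats.spearmanr(est, true).statistic)
    return {"spearman": spearman, "n": len(est)}


def _cohort_features(cfg: SimulationConfig):
    cohort, truth = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_feature_table(cohort, SEED_ID, "dcc_variance")
    return CohortFeatures(features={SEED_ID: table},
                          outcomes=cohort.manifest[list(OUTCOMES)]), truth


@dataclass
class RecoveryResult:
    loocv_r: float
    support_hits: int
    n_signal: int
    survived: bool
    test_r: float


def signal_replicate(rng_seed: int, *, n_validation: int = 40,
                     n_test: int = 40, n_permutations: int = 1000,
                     config: SimulationConfig | None = None) -> RecoveryResult:
    """One end-to-end recovery replicate under the reference conditions.

    Simulates train/validation/test cohorts whose 'trait' outcome couples to
    five signal edges, runs the full cascade over the trait and two nuisance
    outcomes, and reports the trait model's cross-validated r, how many true
    signal edges its full fit selected, and whether it survived to the final
    test stage with positive r.
    """
    base = config if config is not None else SimulationConfig()
    base = replace(base, rng_seed=rng_seed)
    train, truth = _cohort_features(base)

    def later(n, offset):
        def build():
            cf, _ = _cohort_features(replace(base, n_subjects=n,
                                             rng_seed=rng_seed + offset))
            return cf
        return build

    report = run_cascade(
        train, later(n_validation, 1), later(n_test, 2), [SEED_ID],
        list(OUTCOMES), n_permutations=n_permutations,
        n_boot=max(200, n_permutations // 2),
        rng=np.random.default_rng(rng_seed + 3),
    )
    s1 = report.stage1.set_index(["seed", "outcome"])
    loocv_r = float(s1.loc[(SEED_ID, "trait"), "r"])

    model = report.models[(SEED_ID, "trait")]
    table = train.features[SEED_ID]
    nz = {e for e, w in zip(table.edge_ids, model.weights) if w != 0.0}
    signal_ids = {f"{SEED_ID}__{base.target_labels()[e % base.n_targets]}"
                  for e in truth.support}
    hits = len(nz & signal_ids)

    s3 = report.stage3
    row = s3[(s3["seed"] == SEED_ID) & (s3["outcome"] == "trait")]
    survived = bool(len(row)) and float(row["r"].iloc[0]) > 0
    test_r = float(row["r"].iloc[0]) if len(row) else float("nan")
    return RecoveryResult(loocv_r, hits, len(signal_ids), survived, test_r)


def null_replicate(rng_seed: int, *, n_validation: int = 40, n_test: int = 40,
                   n_permutations: int = 1000) -> int:
    """Stage-3 survivor count for an all-null model family.

    Edges still fluctuate (trait-independent amplitudes), but no outcome is
    coupled to anything, so any survivor is a false positive.
    """
    cfg = SimulationConfig(rng_seed=rng_seed, amp_slope=0.0, amp_jitter_sd=0.0)
    train, _ = _cohort_features(cfg)

    def later(n, offset):
        def build():
            cf, _ = _cohort_features(replace(cfg, n_subjects=n,
                                             rng_seed=rng_seed + offset))
            return cf
        return build

    report = run_cascade(
        train, later(n_validation, 1), later(n_test, 2), [SEED_ID],
        list(OUTCOMES), n_permutations=n_permutations,
        n_boot=max(200, n_permutations // 2),
        rng=np.random.default_rng(rng_seed + 3),
    )
    return len(report.stage3)
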