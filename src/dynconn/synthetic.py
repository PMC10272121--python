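"""Synthetic cohorts with known time-varying connectivity and trait coupling.

The generator emulates a resting-state cohort at the level the downstream
pipeline consumes: per-subject multivariate time series whose seed-target
correlations follow known paths rho*_t, and questionnaire-like trait scores
causally coupled to the temporal variance of a sparse subset of edges.

Generative model (per subject i with latent trait u_i ~ N(0,1)):

* each seed emits unit-variance innovations (optionally GARCH(1,1)-scaled,
  optionally AR(1)-smoothed to mimic band-passed BOLD);
* each target j is tied to one generating seed g(j); its correlation path is
  rho_t = clip(rho_bar_j + gamma_ij * sin(2*pi*t/period_j + phi_ij), -0.95, 0.95)
  with amplitude gamma_ij = max(0, amp_base + amp_slope * u_i) on signal
  edges and 0 elsewhere, phi_ij uniform;
* target_t = rho_t * seed_std_t + sqrt(1 - rho_t^2) * e_t with independent
  unit-variance noise e_t, so the instantaneous correlation equals rho_t by
  construction;
* the observed trait score is offset + multiplier * u_i + N(0, trait_noise_sd);
  two additional nuisance scores are built the same way from independent
  latents and are coupled to nothing.

Edges are indexed seed-major: edge e = s * n_targets + j.  Edges whose seed
is not the target's generating seed have true rho identically 0 (independent
processes); null edges on the generating seed have constant rho = rho_bar.
Either way non-signal edges have true temporal variance exactly 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels as K
from .io import CohortData, ParcellatedSeries, write_series

CLIP = 0.95
NUISANCE_COLS = ("nuisance_1", "nuisance_2")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one synthetic cohort.

    Defaults define the package's reference study conditions: 60 subjects,
    400 timepoints, one seed, 100 targets, 5 signal edges with strong
    trait-to-amplitude coupling (the high-SNR regime in which sparse
    recovery through the full estimation pipeline is achievable), a
    modulation period of half the run (two complete cycles, so the pre-clip
    sinusoid variance is exactly gamma^2/2 for any phase) and
    questionnaire-like trait scaling (offset 17, multiplier 4 spans roughly
    the 7-28 range of a summed subscale).
    """

    n_subjects: int = 60
    n_timepoints: int = 400
    n_targets: int = 100
    n_seeds: int = 1
    signal_edges: tuple[int, ...] = (0, 20, 40, 60, 80)
    baseline_corr: float = 0.0
    amp_base: float = 0.6
    amp_slope: float = 0.4
    modulation_period: float | None = None  # None -> T / 2
    garch_params: tuple[float, float, float] | None = None
    amp_jitter_sd: float = 0.2
    ar_coef: float = 0.0
    trait_noise_sd: float = 0.5
    trait_scale: tuple[float, float] = (17.0, 4.0)
    rng_seed: int = 0

    @property
    def n_edges(self) -> int:
        return self.n_seeds * self.n_targets

    @property
    def period(self) -> float:
        return self.modulation_period if self.modulation_period is not None \
            else self.n_timepoints / 2.0

    def validate(self) -> None:
        for name in ("baseline_corr", "amp_base", "amp_slope", "ar_coef",
                     "trait_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value: {name}")
        if self.n_timepoints < 100:
            raise ValueError("n_timepoints must be >= 100")
        if not -0.9 < self.baseline_corr < 0.9:
            raise ValueError("baseline_corr must lie in (-0.9, 0.9)")
        if self.amp_base < 0 or self.trait_noise_sd < 0 or self.amp_jitter_sd < 0:
            raise ValueError("amp_base, trait_noise_sd, amp_jitter_sd must be >= 0")
        if self.period < 4:
            raise ValueError("modulation period below 4 timepoints is unresolvable")
        if not all(0 <= e < self.n_edges for e in self.signal_edges):
            raise ValueError("signal_edges outside {0..n_seeds*n_targets-1}")
        if self.garch_params is not None:
            omega, alpha, beta = self.garch_params
            if omega <= 0 or alpha < 0 or beta < 0 or alpha + beta >= 1:
                raise ValueError("garch_params need omega > 0 and alpha+beta < 1")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")

    def seed_labels(self) -> list[str]:
        return [f"seed_{s + 1}" for s in range(self.n_seeds)]

    def target_labels(self) -> list[str]:
        return [f"region_{j + 1:03d}" for j in range(self.n_targets)]

    def edge_label(self, e: int) -> str:
        s, j = divmod(e, self.n_targets)
        return f"{self.seed_labels()[s]}__{self.target_labels()[j]}"

    def generating_seed(self, j: int) -> int:
        """Seed whose innovations drive target j.

        A target claimed by a signal edge is driven by that edge's seed (a
        target claimed by two seeds is rejected); unclaimed targets are
        assigned round-robin.
        """
        claims = {e // self.n_targets for e in self.signal_edges
                  if e % self.n_targets == j}
        if len(claims) > 1:
            raise ValueError(f"target {j} is claimed by multiple signal seeds")
        return claims.pop() if claims else j % self.n_seeds


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to estimate.

    True rho paths are stored explicitly only for modulated (signal) edges;
    all other paths are constant and reconstructed on demand, so their
    temporal variance is exactly 0.
    """

    config: SimulationConfig
    latent_trait: np.ndarray
    support: tuple[int, ...]
    true_edge_variance: np.ndarray  # (n_subjects, n_edges), 1/T convention
    signal_paths: dict[tuple[int, int], np.ndarray] = field(repr=False)

    def rho_path(self, subject: int, edge: int) -> np.ndarray:
        if (subject, edge) in self.signal_paths:
            return self.signal_paths[(subject, edge)]
        cfg = self.config
        s, j = divmod(edge, cfg.n_targets)
        const = cfg.baseline_corr if s == cfg.generating_seed(j) else 0.0
        return np.full(cfg.n_timepoints, const)

    def to_json(self, path: str | Path, include_paths: bool = False) -> None:
        payload = {
            "config": asdict(self.config),
            "latent_trait": self.latent_trait.tolist(),
            "support": list(self.support),
            "true_edge_variance": self.true_edge_variance.tolist(),
        }
        if include_paths:
            payload["signal_paths"] = {
                f"{i}:{e}": p.tolist() for (i, e), p in self.signal_paths.items()
            }
        Path(path).write_text(json.dumps(payload))


def _ar1(z: np.ndarray, phi: float) -> np.ndarray:
    """Unit-variance AR(1) smoothing of standard-normal innovations."""
    if phi == 0.0:
        return z
    u = np.empty_like(z)
    u[0] = z[0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, z.size):
        u[t] = phi * u[t - 1] + c * z[t]
    return u


def simulate_subject(
    config: SimulationConfig, latent_trait: float, rng: np.random.Generator
) -> tuple[ParcellatedSeries, dict[int, np.ndarray]]:
    """Generate one subject's series plus the true rho path of every edge.

    Returns the assembled T x (n_seeds + n_targets) matrix and a dict
    edge-index -> rho* path (constant-0 paths for non-generating-seed edges
    included), drawing seed innovations, phases and target noise from
    ``rng``.
    """
    config.validate()
    if not np.isfinite(latent_trait):
        raise ValueError("latent_trait must be finite")
    T = config.n_timepoints
    t_idx = np.arange(T, dtype=float)

    seed_std = np.empty((config.n_seeds, T))
    seed_obs = np.empty((config.n_seeds, T))
    for s in range(config.n_seeds):
        u = _ar1(rng.standard_normal(T), config.ar_coef)
        seed_std[s] = u
        if config.garch_params is not None:
            omega, alpha, beta = config.garch_params
            seed_obs[s] = K.garch_sim(T, omega, alpha, beta, u)
        else:
            seed_obs[s] = u

    targets = np.empty((config.n_targets, T))
    rho_paths: dict[int, np.ndarray] = {}
    signal = set(config.signal_edges)
    for j in range(config.n_targets):
        g = config.generating_seed(j)
        e_gen = g * config.n_targets + j
        if e_gen in signal:
            # per-edge amplitude perturbation: each signal edge carries its
            # own (subject x edge) realization around the trait-set level,
            # as exactly shared amplitudes would make the signal features
            # collinear across edges
            gamma = max(0.0, config.amp_base + config.amp_slope * latent_trait
                        + config.amp_jitter_sd * rng.standard_normal())
        else:
            gamma = 0.0
        phi = rng.uniform(0.0, 2.0 * np.pi)
        rho = np.clip(
            config.baseline_corr
            + gamma * np.sin(2.0 * np.pi * t_idx / config.period + phi),
            -CLIP, CLIP,
        )
        noise = _ar1(rng.standard_normal(T), config.ar_coef)
        targets[j] = rho * seed_std[g] + np.sqrt(1.0 - rho * rho) * noise
        for s in range(config.n_seeds):
            e = s * config.n_targets + j
            rho_paths[e] = rho if s == g else np.zeros(T)

    series = ParcellatedSeries(
        labels=config.seed_labels() + config.target_labels(),
        values=np.vstack([seed_obs, targets]).T,
    )
    return series, rho_paths


def simulate_cohort(config: SimulationConfig) -> tuple[CohortData, GroundTruth]:
    """Generate a full cohort plus its ground truth.

    Latent traits are standard normal; the observed trait score is
    offset + multiplier * latent + N(0, trait_noise_sd).  Two nuisance
    scores built from independent latents are appended for null-model
    exercises.  The same config (including rng_seed) reproduces the cohort
    bit-for-bit.
    """
    config.validate()
    if config.n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_subjects
    offset, mult = config.trait_scale

    latent = rng.standard_normal(n)
    trait = offset + mult * latent + rng.normal(0.0, config.trait_noise_sd, n)
    nuisance = {
        col: offset + mult * rng.standard_normal(n)
        + rng.normal(0.0, config.trait_noise_sd, n)
        for col in NUISANCE_COLS
    }

    series_list = []
    var = np.zeros((n, config.n_edges))
    signal_paths: dict[tuple[int, int], np.ndarray] = {}
    signal = set(config.signal_edges)
    for i in range(n):
        series, paths = simulate_subject(config, float(latent[i]), rng)
        series_list.append(series)
        for e, rho in paths.items():
            # 1/T convention; a constant path has variance exactly 0 (the
            # float sum of T identical values would give ~1e-34 instead)
            var[i, e] = float(rho.var()) if np.ptp(rho) > 0.0 else 0.0
            if e in signal:
                signal_paths[(i, e)] = rho

    manifest = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "series_path": [f"sub-{i + 1:03d}.tsv" for i in range(n)],
        "trait": trait,
        **nuisance,
    })
    cohort = CohortData(manifest=manifest, series=series_list,
                        seed_ids=config.seed_labels())
    truth = GroundTruth(
        config=config,
        latent_trait=latent,
        support=tuple(sorted(signal)),
        true_edge_variance=var,
        signal_paths=signal_paths,
    )
    return cohort, truth


def write_cohort(cohort: CohortData, truth: GroundTruth | None,
                 outdir: str | Path) -> Path:
    """Write series TSVs, the manifest CSV and (optionally) ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path, series in zip(cohort.manifest["series_path"], cohort.series):
        write_series(series, outdir / path)
    manifest_path = outdir / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
    return manifest_path
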