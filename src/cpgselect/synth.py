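"""Synthetic methylation-aging cohorts with planted age-informative CpGs.

Informative sites follow a continuous piecewise-linear function of age with
one slope per age regime, plus regime-specific Gaussian noise -- young-age
regimes can be made tight and old-age regimes noisy, mirroring the
observation that methylation drift is more regular early in life.
Uninformative sites are age-independent draws from a Beta-like marginal.
Missing cells and shifted outlier samples are injected on request, and
everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataError, MethylationDataset

__all__ = ["SynthConfig", "SynthTruth", "generate_cohort", "baseline_mad"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator."""

    n_samples: int = 300
    n_sites: int = 1000
    n_informative: int = 20
    age_min: float = 0.0
    age_max: float = 103.0
    #: age cutpoints separating noise/slope regimes (default mirrors the
    #: three-group pipeline: young < 20 <= middle < 50 <= old)
    regime_boundaries: tuple[float, ...] = (20.0, 50.0)
    noise_sd_per_regime: tuple[float, ...] = (0.01, 0.02, 0.04)
    #: optional per-regime multiplier on drift slopes (None = 1 everywhere)
    slope_scale_per_regime: tuple[float, ...] | None = None
    missing_rate: float = 0.0
    n_outlier_samples: int = 0
    outlier_shift: float = 0.4
    seed: int = 0

    @property
    def n_regimes(self) -> int:
        return len(self.regime_boundaries) + 1

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_sites < 1:
            raise DataError("n_samples and n_sites must be positive")
        if not 0 <= self.n_informative <= self.n_sites:
            raise DataError("n_informative must lie in [0, n_sites]")
        if not self.age_min < self.age_max:
            raise DataError("age_min must be below age_max")
        if self.age_min < 0:
            raise DataError("ages must be non-negative")
        bounds = list(self.regime_boundaries)
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise DataError("regime_boundaries must be strictly increasing")
        if bounds and not (self.age_min < bounds[0] and bounds[-1] < self.age_max):
            raise DataError("regime_boundaries must lie inside (age_min, age_max)")
        if len(self.noise_sd_per_regime) != self.n_regimes:
            raise DataError(
                f"noise_sd_per_regime needs {self.n_regimes} entries, "
                f"got {len(self.noise_sd_per_regime)}"
            )
        if self.slope_scale_per_regime is not None and \
                len(self.slope_scale_per_regime) != self.n_regimes:
            raise DataError(f"slope_scale_per_regime needs {self.n_regimes} entries")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must lie in [0, 1)")
        if not 0 <= self.n_outlier_samples <= self.n_samples:
            raise DataError("n_outlier_samples must lie in [0, n_samples]")


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    informative_site_ids: list[str]
    #: slope of beta per year, shape (n_informative, n_regimes)
    per_site_regime_slopes: np.ndarray
    outlier_sample_ids: list[str] = field(default_factory=list)


def _regime_edges(config: SynthConfig) -> np.ndarray:
    return np.array([config.age_min, *config.regime_boundaries, config.age_max])


def regime_of(ages: np.ndarray, config: SynthConfig) -> np.ndarray:
    """0-based regime index for each age (right-open bins, last bin closed)."""
    ages = np.asarray(ages, dtype=float)
    idx = np.searchsorted(np.asarray(config.regime_boundaries), ages, side="right")
    return idx


def generate_cohort(config: SynthConfig) -> tuple[MethylationDataset, SynthTruth]:
    """Draw a cohort per ``config``; returns the dataset and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n_samples, config.n_sites, config.n_informative

    ages = rng.uniform(config.age_min, config.age_max, size=n)
    site_ids = [f"cg{j:08d}" for j in range(p)]
    informative = np.sort(rng.choice(p, size=q, replace=False))
    info_ids = [site_ids[j] for j in informative]

    edges = _regime_edges(config)
    n_reg = config.n_regimes
    scale = np.ones(n_reg) if config.slope_scale_per_regime is None \
        else np.asarray(config.slope_scale_per_regime, dtype=float)

    # informative response: continuous piecewise linear in age; one drift
    # direction per site so the overall age correlation stays monotone
    magnitude = rng.uniform(0.002, 0.005, size=q)
    signs = rng.choice([-1.0, 1.0], size=q)
    # hypermethylating sites start low, hypomethylating high, so the total
    # drift (<= ~0.5 over 103 y) rarely hits the [0, 1] clip
    base = np.where(signs > 0, rng.uniform(0.1, 0.35, size=q),
                    rng.uniform(0.65, 0.9, size=q))
    slopes = signs[:, None] * magnitude[:, None] * scale[None, :]  # (q, n_regimes)

    # value(age) = base + sum of slope*length over completed regimes
    #            + slope_r * (age - regime start)
    seg_len = np.diff(edges)  # (n_regimes,)
    cum_drift = np.hstack([np.zeros((q, 1)), np.cumsum(slopes * seg_len[None, :], axis=1)[:, :-1]])
    reg = regime_of(ages, config)  # (n,)
    within = ages - edges[reg]
    info_clean = base[None, :] + cum_drift[:, reg].T + slopes[:, reg].T * within[:, None]

    noise_sd = np.asarray(config.noise_sd_per_regime, dtype=float)[reg]
    info_vals = info_clean + rng.normal(0.0, 1.0, size=(n, q)) * noise_sd[:, None]

    # uninformative marginals: Beta around a site-specific bimodal-ish mean
    mu = rng.beta(0.4, 0.4, size=p) * 0.9 + 0.05
    conc = 60.0
    other_vals = rng.beta(mu * conc, (1 - mu) * conc, size=(n, p))

    beta = other_vals
    beta[:, informative] = info_vals

    sample_ids = [f"s{i:05d}" for i in range(n)]
    outlier_ids: list[str] = []
    if config.n_outlier_samples:
        out_idx = rng.choice(n, size=config.n_outlier_samples, replace=False)
        beta[out_idx] += config.outlier_shift
        outlier_ids = [sample_ids[i] for i in np.sort(out_idx)]

    beta = np.clip(beta, 0.0, 1.0)

    if config.missing_rate > 0:
        mask = rng.random(size=beta.shape) < config.missing_rate
        beta[mask] = np.nan

    ds = MethylationDataset(
        sample_ids=sample_ids,
        site_ids=site_ids,
        beta=beta,
        age=ages,
        source=["synthetic"] * n,
    )
    truth = SynthTruth(
        informative_site_ids=info_ids,
        per_site_regime_slopes=slopes,
        outlier_sample_ids=outlier_ids,
    )
    return ds, truth


def baseline_mad(dataset: MethylationDataset) -> float:
    """Mean absolute deviation of ages from their mean (years).

    The error of always predicting the cohort mean age -- the floor any
    useful age model must beat.
    """
    if dataset.age is None or dataset.n_samples == 0:
        raise DataError("baseline_mad requires a non-empty dataset with ages")
    return float(np.mean(np.abs(dataset.age - dataset.age.mean())))
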