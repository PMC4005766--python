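"""Synthetic cohort generator for heart-rate / energy-expenditure studies.

Generates seed-reproducible long-format cohorts: one row per subject and
exertion level, with heart rate (bpm) and energy expenditure (VO2,
ml O2/kg/min) produced by a random-intercept / random-slope linear model on
heart rate. Default parameters reproduce the covariate distribution,
per-level heart-rate moments, fixed effects and variance components of a
five-level exertion protocol (rest, slow walk, customary walk, peak
sustained walk, maximal exertion) in an older-adult cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("hr2ee")

LEVELS: tuple[str, ...] = (
    "rest",
    "slow_walk",
    "customary_walk",
    "peak_walk",
    "maximal",
)
N_LEVELS = len(LEVELS)
LEVEL_INDEX = {name: j for j, name in enumerate(LEVELS)}

STRATA: tuple[str, ...] = ("M<65", "M>=65", "F<65", "F>=65")

#: CSV column order for cohort tables.
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "weight_kg",
    "level",
    "hr_bpm",
    "ee_mlkgmin",
]


def derive_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed sequence from a top-level integer seed.

    Uses a CRC32 hash of the stage name as the spawn key so any stage can be
    re-run in isolation while remaining reachable from the single top seed.
    """
    return np.random.SeedSequence(seed, spawn_key=(zlib.crc32(stage.encode()),))


def stratum_of(age: float, sex: str) -> str:
    """Sex/age stratum label; the age-65 boundary is 'age >= 65 is older'."""
    older = age >= 65.0
    if sex == "M":
        return "M>=65" if older else "M<65"
    if sex == "F":
        return "F>=65" if older else "F<65"
    raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


@dataclass(frozen=True)
class Subject:
    """One cohort member with the covariates entering the models."""

    id: str
    age: float
    sex: str  # 'M' or 'F'
    weight: float  # kg

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def stratum(self) -> str:
        return stratum_of(self.age, self.sex)

    @property
    def male(self) -> int:
        return 1 if self.sex == "M" else 0


class ConfigurationError(ValueError):
    """Invalid generator or model configuration."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the reference cohort: n=290 older adults (age
    67.6 +/- 11.5 years on 32-90, 59.3% male, weight 79.2 +/- 14.4 kg), the
    five-level heart-rate protocol means/SDs, and the continuous-age model's
    fixed effects and variance components.
    """

    n_subjects: int = 290
    male_fraction: float = 0.593
    age_mean: float = 67.6
    age_sd: float = 11.5
    age_bounds: tuple[float, float] = (32.0, 90.0)
    weight_mean: float = 79.2
    weight_sd: float = 14.4
    weight_bounds: tuple[float, float] = (45.0, 140.0)

    # Per-level heart-rate model: hr_j = mean_j + slope_j*(age - ref_age)
    #                                   + rho*sd_j*f_i + eps,  eps ~ N(0, sd_j^2*(1-rho^2))
    hr_means: tuple[float, ...] = (61.2, 85.7, 97.8, 120.4, 148.6)
    hr_sds: tuple[float, ...] = (9.7, 12.9, 15.7, 19.8, 21.0)
    hr_age_slopes: tuple[float, ...] = (0.0, 0.0, 0.0, -0.55, -1.05)
    hr_ref_age: float = 67.6
    hr_within_subject_corr: float = 0.7
    #: Adjust underlying level means so that post-monotonicity-enforcement
    #: sample means match ``hr_means`` (the enforcement conditions the
    #: distribution and would otherwise bias level means by 1-2 bpm).
    calibrate_hr_means: bool = True

    # Fixed effects. 'continuous' uses (intercept, hr, male, age, age*hr);
    # 'stratified' uses per-stratum intercepts/slopes in STRATA order.
    model_form: str = "continuous"
    fixed_continuous: tuple[float, float, float, float, float] = (
        -23.046,
        0.339,
        2.241,
        0.099,
        -0.0007,
    )
    stratum_intercepts: tuple[float, float, float, float] = (
        -15.392,
        -14.960,
        -17.591,
        -17.055,
    )
    stratum_slopes: tuple[float, float, float, float] = (0.296, 0.279, 0.297, 0.285)

    # Variance components of the random intercept/slope and residual.
    sd_b0: float = 3.966  # ml/kg/min
    sd_b1: float = 0.062  # ml/kg/min per bpm
    corr_b: float = -0.874
    sd_resid: float = 2.787  # ml/kg/min

    #: Optional lower floor for generated energy expenditure (ml/kg/min).
    #: None keeps the model-faithful homoscedastic Gaussian noise, under
    #: which a rare resting draw can be <= 0.
    ee_floor: float | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ConfigurationError("male_fraction must be in [0, 1]")
        for name, (lo, hi) in (
            ("age_bounds", self.age_bounds),
            ("weight_bounds", self.weight_bounds),
        ):
            if lo >= hi:
                raise ConfigurationError(f"{name} must be ordered (lower < upper)")
        for name, v in (
            ("age_sd", self.age_sd),
            ("weight_sd", self.weight_sd),
            ("sd_b0", self.sd_b0),
            ("sd_b1", self.sd_b1),
            ("sd_resid", self.sd_resid),
        ):
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(self.corr_b) > 1:
            raise ConfigurationError("|corr_b| must be <= 1")
        if abs(self.hr_within_subject_corr) > 1:
            raise ConfigurationError("|hr_within_subject_corr| must be <= 1")
        if len(self.hr_means) != N_LEVELS or len(self.hr_sds) != N_LEVELS:
            raise ConfigurationError(f"hr_means and hr_sds must have {N_LEVELS} entries")
        if any(s < 0 for s in self.hr_sds):
            raise ConfigurationError("hr_sds must be >= 0")
        if not all(a < b for a, b in zip(self.hr_means, self.hr_means[1:])):
            raise ConfigurationError("hr_means must be strictly increasing across levels")
        if self.model_form not in ("continuous", "stratified"):
            raise ConfigurationError("model_form must be 'continuous' or 'stratified'")

    @classmethod
    def stratified(cls, **overrides) -> "GeneratorConfig":
        """Config generating from the stratified (four sex/age group) model.

        Uses the stratified model's fixed effects and its slightly different
        variance components (sd_b0 4.007, sd_b1 0.063, corr -0.875,
        sd_resid 2.785) unless overridden.
        """
        defaults = dict(
            model_form="stratified",
            sd_b0=4.007,
            sd_b1=0.063,
            corr_b=-0.875,
            sd_resid=2.785,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def random_effects_cov(self) -> np.ndarray:
        """The 2x2 covariance of (random intercept, random slope)."""
        cov01 = self.corr_b * self.sd_b0 * self.sd_b1
        G = np.array([[self.sd_b0**2, cov01], [cov01, self.sd_b1**2]])
        if np.any(np.linalg.eigvalsh(G) < -1e-12):
            raise ConfigurationError("implied random-effects covariance is not PSD")
        return G

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in (
            "age_bounds",
            "weight_bounds",
            "hr_means",
            "hr_sds",
            "hr_age_slopes",
            "fixed_continuous",
            "stratum_intercepts",
            "stratum_slopes",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CohortTable:
    """Long-format cohort: one row per subject x exertion level."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"].unique())

    def subjects(self) -> list[Subject]:
        first = self.data.groupby("subject_id", sort=False).first()
        return [
            Subject(id=str(sid), age=row["age"], sex=row["sex"], weight=row["weight_kg"])
            for sid, row in first.iterrows()
        ]

    def rows_for(self, subject_id: str) -> pd.DataFrame:
        return self.data[self.data["subject_id"] == subject_id]

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the table as CSV, with generation metadata as sidecar JSON."""
        path = Path(path)
        self.data.to_csv(path, index=False, columns=COHORT_COLUMNS)
        if sidecar and self.metadata:
            path.with_suffix(".meta.json").write_text(
                json.dumps(self.metadata, indent=2, default=float)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(data=data, metadata=metadata)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def _matched_truncnorm(
    mean: float, sd: float, bounds: tuple[float, float]
) -> stats.rv_continuous:
    """Truncated normal whose *truncated* mean equals ``mean``.

    Truncation shifts the mean of a clipped normal away from its location
    parameter; solve for the location that restores the target mean (scale is
    kept at ``sd``; truncation shrinks the realised SD slightly).
    """
    lo, hi = bounds
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ConfigurationError("degenerate distribution outside bounds")
        return stats.uniform(loc=mean, scale=0.0)

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    # The truncated mean is increasing in loc; bracket generously.
    loc = optimize.brentq(
        lambda m: truncated_mean(m) - mean, lo - 10 * sd, hi + 10 * sd, xtol=1e-10
    )
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def sample_subjects(
    config: GeneratorConfig, n: int, seed: int | np.random.SeedSequence
) -> list[Subject]:
    """Draw ``n`` subjects: truncated-normal age and weight, Bernoulli sex."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    age_dist = _matched_truncnorm(config.age_mean, config.age_sd, config.age_bounds)
    weight_dist = _matched_truncnorm(
        config.weight_mean, config.weight_sd, config.weight_bounds
    )
    ages = age_dist.rvs(size=n, random_state=rng)
    male = rng.random(n) < config.male_fraction
    weights = weight_dist.rvs(size=n, random_state=rng)
    width = max(4, len(str(n)))
    return [
        Subject(
            id=f"S{i:0{width}d}",
            age=float(ages[i]),
            sex="M" if male[i] else "F",
            weight=float(weights[i]),
        )
        for i in range(n)
    ]


def sample_random_effects(
    n: int,
    sd_b0: float,
    sd_b1: float,
    corr_b: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Draw n pairs (b0, b1) from the zero-mean bivariate normal prior.

    Returns an (n, 2) array. The implied covariance must be positive
    semidefinite (guaranteed when sds >= 0 and |corr| <= 1).
    """
    if sd_b0 < 0 or sd_b1 < 0:
        raise ConfigurationError("random-effect sds must be >= 0")
    if abs(corr_b) > 1:
        raise ConfigurationError("|corr_b| must be <= 1")
    rng = np.random.default_rng(seed)
    # Cholesky-free construction that tolerates zero variances and |corr|=1
    # (the implied covariance is PSD exactly when the checks above hold).
    z = rng.standard_normal((n, 2))
    b0 = sd_b0 * z[:, 0]
    b1 = sd_b1 * (corr_b * z[:, 0] + np.sqrt(max(0.0, 1 - corr_b**2)) * z[:, 1])
    return np.column_stack([b0, b1])


def _raw_hr_draws(
    ages: np.ndarray,
    level_means: np.ndarray,
    config: GeneratorConfig,
    f: np.ndarray,
    eps: np.ndarray,
) -> np.ndarray:
    """Heart rates before monotonicity enforcement: shared fitness factor plus
    independent level noise, with a linear age trend per level."""
    slopes = np.asarray(config.hr_age_slopes)
    sds = np.asarray(config.hr_sds)
    rho = config.hr_within_subject_corr
    lam = rho * sds
    eps_sd = sds * np.sqrt(1 - rho**2)
    age_dev = ages[:, None] - config.hr_ref_age
    return level_means + slopes * age_dev + lam * f[:, None] + eps * eps_sd


def _enforce_monotone(
    hr: np.ndarray,
    redraw,
    max_retries: int = 100,
) -> np.ndarray:
    """Resample rows violating the non-decreasing level ordering; after the
    retry budget, sort the offending rows (marginal moments are preserved
    almost exactly because violations are rare by then)."""
    for _ in range(max_retries):
        bad = np.where(~np.all(np.diff(hr, axis=1) >= 0, axis=1))[0]
        if bad.size == 0:
            return hr
        hr[bad] = redraw(bad)
    bad = np.where(~np.all(np.diff(hr, axis=1) >= 0, axis=1))[0]
    if bad.size:
        logger.warning(
            "monotone-HR retry budget exhausted for %d subjects; sorting their draws",
            bad.size,
        )
        hr[bad] = np.sort(hr[bad], axis=1)
    return hr


def _hr_mean_key(config: GeneratorConfig) -> tuple:
    return (
        config.hr_means,
        config.hr_sds,
        config.hr_age_slopes,
        config.hr_within_subject_corr,
    )


_HR_MEAN_CACHE: dict[tuple, np.ndarray] = {}


def _calibrated_level_means(config: GeneratorConfig) -> np.ndarray:
    """Underlying level means such that post-enforcement sample means match
    the configured ones.

    Monotonicity enforcement conditions the joint HR distribution and shifts
    per-level means by 1-2 bpm at the default parameters; a short fixed-point
    pilot simulation (fixed internal seed, independent of the cohort seed)
    removes that bias. Cached per parameter set.
    """
    if not config.calibrate_hr_means:
        return np.asarray(config.hr_means, dtype=float)
    key = _hr_mean_key(config)
    if key in _HR_MEAN_CACHE:
        return _HR_MEAN_CACHE[key]

    target = np.asarray(config.hr_means, dtype=float)
    mu = target.copy()
    n_pilot = 50_000
    for it in range(6):
        rng = np.random.default_rng(np.random.SeedSequence(785631, spawn_key=(it,)))
        # age trend is centred at the reference age, so pilot at age_ref
        ages = np.full(n_pilot, config.hr_ref_age)
        f = rng.standard_normal(n_pilot)
        eps = rng.standard_normal((n_pilot, N_LEVELS))
        hr = _raw_hr_draws(ages, mu, config, f, eps)

        def redraw(idx: np.ndarray) -> np.ndarray:
            return _raw_hr_draws(
                ages[idx], mu, config, f[idx], rng.standard_normal((idx.size, N_LEVELS))
            )

        hr = _enforce_monotone(hr, redraw)
        realized = hr.mean(axis=0)
        mu = mu + (target - realized)
    _HR_MEAN_CACHE[key] = mu
    return mu


def sample_heart_rate_matrix(
    ages: np.ndarray, config: GeneratorConfig, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Heart rates for many subjects at once; (n, 5), non-decreasing rows."""
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    rng = np.random.default_rng(seed)
    mu = _calibrated_level_means(config)
    f = rng.standard_normal(n)
    hr = _raw_hr_draws(ages, mu, config, f, rng.standard_normal((n, N_LEVELS)))

    def redraw(idx: np.ndarray) -> np.ndarray:
        return _raw_hr_draws(
            ages[idx], mu, config, f[idx], rng.standard_normal((idx.size, N_LEVELS))
        )

    return _enforce_monotone(hr, redraw)


def sample_heart_rates(
    subject: Subject, config: GeneratorConfig, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Five heart rates (bpm) for one subject, one per exertion level,
    non-decreasing in level order."""
    return sample_heart_rate_matrix(np.array([subject.age]), config, seed)[0]


def fixed_effect_surface(
    config: GeneratorConfig, ages: np.ndarray, male: np.ndarray, hr: np.ndarray
) -> np.ndarray:
    """Population-mean energy expenditure at given covariates and heart rate.

    ``hr`` may be (n, 5) with ages/male of length n (broadcast per level).
    """
    ages = np.asarray(ages, dtype=float)
    male = np.asarray(male, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if config.model_form == "continuous":
        b_int, b_hr, b_male, b_age, b_agehr = config.fixed_continuous
        return (
            b_int
            + b_hr * hr
            + (b_male * male)[..., None] * np.ones_like(hr)
            + (b_age * ages)[..., None] * np.ones_like(hr)
            + b_agehr * ages[..., None] * hr
        )
    # stratified: per-stratum intercept and slope
    older = ages >= 65.0
    idx = np.where(male == 1, np.where(older, 1, 0), np.where(older, 3, 2))
    icpt = np.asarray(config.stratum_intercepts)[idx]
    slope = np.asarray(config.stratum_slopes)[idx]
    return icpt[:, None] + slope[:, None] * hr


def simulate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a full cohort table from the configuration.

    For each subject i and level j:
        ee_ij = fixed(x_i, hr_ij) + b0_i + b1_i * hr_ij + W_ij,
    with (b0, b1) bivariate normal and W homoscedastic Gaussian noise.
    Deterministic given ``config.seed``.
    """
    config.validate()
    n = config.n_subjects
    top = config.seed
    subjects = sample_subjects(config, n, derive_seed(top, "subjects"))
    ages = np.array([s.age for s in subjects])
    male = np.array([s.male for s in subjects], dtype=float)
    weights = np.array([s.weight for s in subjects])

    b = sample_random_effects(
        n, config.sd_b0, config.sd_b1, config.corr_b, derive_seed(top, "random_effects")
    )
    hr = sample_heart_rate_matrix(ages, config, derive_seed(top, "heart_rates"))

    resid_rng = np.random.default_rng(derive_seed(top, "residuals"))
    resid = resid_rng.standard_normal((n, N_LEVELS)) * config.sd_resid

    ee = fixed_effect_surface(config, ages, male, hr) + b[:, [0]] + b[:, [1]] * hr + resid
    if config.ee_floor is not None:
        ee = np.maximum(ee, config.ee_floor)

    data = pd.DataFrame(
        {
            "subject_id": np.repeat([s.id for s in subjects], N_LEVELS),
            "age": np.repeat(ages, N_LEVELS),
            "sex": np.repeat([s.sex for s in subjects], N_LEVELS),
            "weight_kg": np.repeat(weights, N_LEVELS),
            "level": list(LEVELS) * n,
            "hr_bpm": hr.ravel(),
            "ee_mlkgmin": ee.ravel(),
        }
    )
    metadata = {"generator": config.to_dict()}
    return CohortTable(data=data, metadata=metadata)
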