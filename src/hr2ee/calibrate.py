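"""Subject-level calibration via conditional-normal (BLUP) prediction.

Given a fitted population model, a subject's k calibration measurements
(k = 0, 1, 2 or 5 in the standard scenarios) determine the conditional
distribution of that subject's random intercept and slope; predictions at
any heart rate then combine the population line with the predicted
subject-level deviations. Includes the kcal conversion (5 kcal per litre of
oxygen) and the per-day bias extrapolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LEVELS, Subject
from .lmm import FittedLMM

logger = logging.getLogger("hr2ee")

#: Calibration scenarios: which exertion levels supply calibration data.
#: 'peak' is the peak *sustained walking* level, not maximal exertion.
SCENARIO_LEVELS: dict[str, tuple[str, ...]] = {
    "none": (),
    "rest_only": ("rest",),
    "rest_peak": ("rest", "peak_walk"),
    "all_five": LEVELS,
}

SCENARIO_ORDER = ("none", "rest_only", "rest_peak", "all_five")


@dataclass(frozen=True)
class CalibrationScenario:
    """A named subset of exertion levels used for calibration."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_LEVELS:
            raise ValueError(
                f"unknown scenario {self.name!r}; choose from {list(SCENARIO_LEVELS)}"
            )

    @property
    def levels(self) -> tuple[str, ...]:
        return SCENARIO_LEVELS[self.name]


@dataclass
class RandomEffectsPosterior:
    """Conditional mean and covariance of a subject's (b0, b1) deviations."""

    subject_id: str
    mean: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2)
    k_used: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) < -1e-8):
            raise ValueError("posterior covariance must be PSD")


def posterior_random_effects(
    fit: FittedLMM,
    subject: Subject,
    calib: pd.DataFrame | None,
) -> RandomEffectsPosterior:
    """Conditional-normal prediction of (b0, b1) from calibration rows.

    With residuals r = y - X beta_hat on the k calibration rows and
    Z = per-row (1, hr):

        mean = G Z' (Z G Z' + sigma^2 I)^-1 r
        cov  = G - G Z' (Z G Z' + sigma^2 I)^-1 Z G

    An empty calibration set returns the prior (mean 0, covariance G) —
    the "no calibration, subject effects set to zero" case. Fixed effects
    are the training fit's, never refit per subject.
    """
    G = fit.vc.G
    if calib is None or len(calib) == 0:
        return RandomEffectsPosterior(
            subject_id=subject.id, mean=np.zeros(2), covariance=G, k_used=0
        )
    ages = calib["age"].to_numpy(dtype=float)
    sexes = calib["sex"].to_numpy()
    if not (np.allclose(ages, subject.age, atol=1e-6) and np.all(sexes == subject.sex)):
        raise ValueError(
            f"calibration rows do not match subject {subject.id} covariates"
        )
    hr = calib["hr_bpm"].to_numpy(dtype=float)
    y = calib["ee_mlkgmin"].to_numpy(dtype=float)
    X = np.stack([fit.spec.design_row(subject.age, subject.sex, h) for h in hr])
    r = y - X @ fit.fixed
    Z = np.column_stack([np.ones_like(hr), hr])
    V = Z @ G @ Z.T + fit.vc.sigma2 * np.eye(len(hr))
    # pinv keeps the degenerate zero-variance limit (G=0, sigma=0) finite
    K = G @ Z.T @ np.linalg.pinv(V)  # 2 x k gain
    mean = K @ r
    cov = G - K @ Z @ G
    cov = 0.5 * (cov + cov.T)
    return RandomEffectsPosterior(
        subject_id=subject.id, mean=mean, covariance=cov, k_used=len(hr)
    )


def predict_ee(
    fit: FittedLMM,
    subject: Subject,
    hr,
    re: RandomEffectsPosterior | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict energy expenditure (ml/kg/min) at heart rate(s) ``hr``.

    Returns (prediction, prediction variance). Without a posterior the
    population line is used (subject effects set to zero) and the prediction
    variance integrates over the random-effects prior; with a posterior, the
    conditional mean shifts the line by b0 + b1*hr and the posterior
    covariance replaces the prior in the variance.
    """
    hr_arr = np.atleast_1d(np.asarray(hr, dtype=float))
    if np.any((hr_arr < 30) | (hr_arr > 220)):
        warnings.warn(
            "heart rate outside the plausible physiologic range 30-220 bpm",
            stacklevel=2,
        )
    pred = fit.predict_population(subject.age, subject.sex, hr_arr)
    C = fit.vc.G if re is None else re.covariance
    if re is not None:
        pred = pred + re.mean[0] + re.mean[1] * hr_arr
    z = np.column_stack([np.ones_like(hr_arr), hr_arr])
    var = np.einsum("ij,jk,ik->i", z, C, z) + fit.vc.sigma2
    if np.isscalar(hr) or np.ndim(hr) == 0:
        return float(pred[0]), float(var[0])
    return pred, var


def to_kcal_per_min(ee_mlkgmin, weight_kg: float):
    """Convert VO2 (ml O2/kg/min) to kcal/min at 5 kcal per litre of oxygen.

    kcal/min = VO2 * weight / 1000 * 5.
    """
    weight = np.asarray(weight_kg, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    out = np.asarray(ee_mlkgmin, dtype=float) * weight / 1000.0 * 5.0
    return float(out) if np.ndim(out) == 0 else out


def daily_bias(bias_kcal_per_min: float) -> float:
    """Extrapolate a constant per-minute bias to kcal per day (x 1440)."""
    return bias_kcal_per_min * 1440.0
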