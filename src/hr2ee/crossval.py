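"""Cross-validated prediction error under the calibration hierarchy.

Subjects are split 80/20 (optionally stratified by the four sex/age groups),
the mixed model is fit on the training subjects, and each validation
subject's energy expenditure is predicted at all five exertion levels under
each calibration scenario (0, 1, 2 or 5 calibration measurements). Errors
(observed - predicted) are converted to kcal/min with each subject's own
weight, pooled across subjects and levels, and summarised by their standard
deviation and a kernel density estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import (
    SCENARIO_ORDER,
    CalibrationScenario,
    posterior_random_effects,
    predict_ee,
    to_kcal_per_min,
)
from .cohort import (
    CohortTable,
    GeneratorConfig,
    Subject,
    derive_seed,
    simulate_cohort,
    stratum_of,
)
from .lmm import FittedLMM, ModelSpec, fit_lmm

logger = logging.getLogger("hr2ee")


@dataclass
class SplitResult:
    """A subject-level train/validation partition."""

    training_ids: list
    validation_ids: list
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.validation_ids):
            raise ValueError("training and validation sets must be disjoint")


def split_subjects(
    cohort: CohortTable,
    frac: float = 0.8,
    stratified: bool = False,
    seed: int = 0,
) -> SplitResult:
    """Random subject-level split with ``frac`` of subjects in training.

    Stratified splitting allocates training counts within each of the four
    sex/age strata by floor with largest-remainder assignment, so the
    overall training fraction is within one subject of ``frac``.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    first = cohort.data.groupby("subject_id", sort=False).first()
    ids = np.array(first.index)
    rng = np.random.default_rng(derive_seed(seed, "split"))

    def allocate(n: int, f: float) -> int:
        return int(np.floor(n * f))

    if not stratified:
        n_train = int(round(len(ids) * frac))
        perm = rng.permutation(len(ids))
        train = ids[perm[:n_train]]
        valid = ids[perm[n_train:]]
    else:
        strata = np.array(
            [stratum_of(a, s) for a, s in zip(first["age"], first["sex"])]
        )
        groups = {}
        for st in np.unique(strata):
            members = ids[strata == st]
            if len(members) < 2:
                raise ValueError(
                    f"stratum {st!r} has fewer than 2 subjects; cannot split"
                )
            groups[st] = members
        n_total_train = int(round(len(ids) * frac))
        floors = {st: allocate(len(m), frac) for st, m in groups.items()}
        remainders = {st: len(m) * frac - floors[st] for st, m in groups.items()}
        leftover = n_total_train - sum(floors.values())
        for st in sorted(remainders, key=remainders.get, reverse=True)[:leftover]:
            floors[st] += 1
        train_parts, valid_parts = [], []
        for st, members in groups.items():
            perm = rng.permutation(len(members))
            train_parts.append(members[perm[: floors[st]]])
            valid_parts.append(members[perm[floors[st]:]])
        train = np.concatenate(train_parts)
        valid = np.concatenate(valid_parts)
    return SplitResult(
        training_ids=list(train),
        validation_ids=list(valid),
        stratified=stratified,
        seed=seed,
    )


@dataclass
class DensityEstimate:
    """A kernel (or point-mass) density estimate on a fixed grid."""

    grid: np.ndarray
    height: np.ndarray
    bandwidth: float
    point_mass: bool = False


def error_density(
    errors: np.ndarray, bandwidth: str | float = "silverman"
) -> DensityEstimate:
    """Gaussian-kernel density of prediction errors.

    512 evenly spaced points spanning mean +/- 4 SD; Silverman's
    rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5) by default.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least 2 errors for a density estimate")
    sd = errors.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance errors: returning a point mass", stacklevel=2)
        return DensityEstimate(
            grid=np.array([errors[0]]),
            height=np.array([np.inf]),
            bandwidth=0.0,
            point_mass=True,
        )
    if bandwidth == "silverman":
        iqr = np.subtract(*np.percentile(errors, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bw = 0.9 * spread * errors.size ** (-0.2)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    mean = errors.mean()
    grid = np.linspace(mean - 4 * sd, mean + 4 * sd, 512)
    z = (grid[:, None] - errors[None, :]) / bw
    height = np.exp(-0.5 * z**2).sum(axis=1) / (errors.size * bw * np.sqrt(2 * np.pi))
    return DensityEstimate(grid=grid, height=height, bandwidth=bw)


@dataclass
class ScenarioErrorSummary:
    """Pooled prediction errors for one calibration scenario."""

    scenario: str
    errors: np.ndarray  # kcal/min, pooled over validation subjects x levels
    sd: float
    mean: float
    n_errors: int
    density: DensityEstimate | None = None

    @classmethod
    def from_errors(
        cls, scenario: str, errors: np.ndarray, with_density: bool = True
    ) -> "ScenarioErrorSummary":
        errors = np.asarray(errors, dtype=float)
        dens = None
        if with_density and errors.size >= 2 and errors.std() > 0:
            dens = error_density(errors)
        return cls(
            scenario=scenario,
            errors=errors,
            sd=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
            mean=float(errors.mean()),
            n_errors=int(errors.size),
            density=dens,
        )


def _scenario_errors(
    fit: FittedLMM,
    cohort: CohortTable,
    validation_ids,
    scenario: CalibrationScenario,
    holdout_only: bool = False,
) -> np.ndarray:
    """Pooled kcal/min errors for one scenario over the validation subjects."""
    data = cohort.data
    vset = set(validation_ids)
    errors = []
    for sid, g in data.groupby("subject_id", sort=False):
        if sid not in vset:
            continue
        row0 = g.iloc[0]
        subject = Subject(
            id=str(sid), age=row0["age"], sex=row0["sex"], weight=row0["weight_kg"]
        )
        calib = g[g["level"].isin(scenario.levels)] if scenario.levels else None
        post = posterior_random_effects(fit, subject, calib)
        target = g if not holdout_only else g[~g["level"].isin(scenario.levels)]
        if target.empty:
            continue
        hr = target["hr_bpm"].to_numpy(dtype=float)
        obs = target["ee_mlkgmin"].to_numpy(dtype=float)
        re = post if post.k_used > 0 else None
        pred, _ = predict_ee(fit, subject, hr, re)
        errors.append(to_kcal_per_min(obs - pred, subject.weight))
    return np.concatenate(errors) if errors else np.array([])


@dataclass
class ReplicateResult:
    """One replicate: the split, the training fit, per-scenario summaries."""

    split: SplitResult
    fit: FittedLMM
    summaries: dict  # scenario name -> ScenarioErrorSummary


def run_scenarios(
    cohort: CohortTable,
    spec: ModelSpec | str,
    scenarios=SCENARIO_ORDER,
    seed: int = 0,
    replicates: int = 1,
    frac: float = 0.8,
    stratified: bool | None = None,
    method: str = "ML",
    holdout_only: bool = False,
    with_density: bool = True,
) -> list[ReplicateResult]:
    """Repeated split/fit/predict cross-validation on one cohort.

    Each replicate draws a fresh subject-level split (stratified by the four
    sex/age groups for the stratified model unless overridden), fits the
    model on training subjects, and scores all four calibration scenarios on
    the validation subjects. Predictions are made at all five levels
    (including calibration levels) unless ``holdout_only``. Replicates whose
    training fit fails to converge are excluded with a warning.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    if stratified is None:
        stratified = spec.form == "m1"
    scenarios = [CalibrationScenario(s) if isinstance(s, str) else s for s in scenarios]
    results = []
    for r in range(replicates):
        rep_seed = int(derive_seed(seed, f"replicate-{r}").generate_state(1)[0] % 2**31)
        split = split_subjects(cohort, frac=frac, stratified=stratified, seed=rep_seed)
        train = cohort.data[cohort.data["subject_id"].isin(split.training_ids)]
        fit = fit_lmm(train, spec, method=method)
        if not fit.converged:
            logger.warning("replicate %d: training fit did not converge; skipped", r)
            continue
        summaries = {}
        for sc in scenarios:
            errs = _scenario_errors(
                fit, cohort, split.validation_ids, sc, holdout_only=holdout_only
            )
            summaries[sc.name] = ScenarioErrorSummary.from_errors(
                sc.name, errs, with_density=with_density
            )
        results.append(ReplicateResult(split=split, fit=fit, summaries=summaries))
    return results


def replicate_experiment(
    config: GeneratorConfig,
    spec: ModelSpec | str,
    replicates: int = 20,
    seed: int = 0,
    scenarios=SCENARIO_ORDER,
    frac: float = 0.8,
    stratified: bool | None = None,
    method: str = "ML",
    holdout_only: bool = False,
    with_density: bool = False,
) -> list[ReplicateResult]:
    """Replicated experiment with a fresh cohort per replicate.

    Each replicate generates a new synthetic cohort (seeded from the top
    seed), performs one split, fit and scenario evaluation. This is the
    protocol for reproducing the calibration-hierarchy error SDs.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    results = []
    for r in range(replicates):
        rep_seed = int(
            derive_seed(seed, f"cohort-replicate-{r}").generate_state(1)[0] % 2**31
        )
        cfg = GeneratorConfig.from_dict({**config.to_dict(), "seed": rep_seed})
        cohort = simulate_cohort(cfg)
        reps = run_scenarios(
            cohort,
            spec,
            scenarios=scenarios,
            seed=rep_seed,
            replicates=1,
            frac=frac,
            stratified=stratified,
            method=method,
            holdout_only=holdout_only,
            with_density=with_density,
        )
        results.extend(reps)
    return results


def scenario_sd_table(results: list[ReplicateResult]) -> pd.DataFrame:
    """Per-replicate and mean pooled-error SDs (kcal/min) per scenario."""
    rows = []
    for i, rep in enumerate(results):
        for name, summ in rep.summaries.items():
            rows.append(
                {"replicate": i, "scenario": name, "sd": summ.sd, "mean": summ.mean}
            )
    return pd.DataFrame(rows)


def mean_scenario_sds(results: list[ReplicateResult]) -> dict:
    """Replicate-averaged pooled-error SD per scenario, in kcal/min."""
    table = scenario_sd_table(results)
    return table.groupby("scenario")["sd"].mean().to_dict()


@dataclass
class IntraPersonCorrelation:
    """Per-subject Pearson r between heart rate and energy expenditure."""

    per_subject: pd.Series
    mean: float
    min: float
    max: float
    n_excluded: int


def intra_person_correlation(cohort: CohortTable) -> IntraPersonCorrelation:
    """Within-subject Pearson correlation of (hr, ee) and its summary.

    Subjects with constant heart rate (undefined correlation) are excluded
    from the summary with a warning.
    """
    rs = {}
    excluded = 0
    for sid, g in cohort.data.groupby("subject_id", sort=False):
        hr = g["hr_bpm"].to_numpy(dtype=float)
        ee = g["ee_mlkgmin"].to_numpy(dtype=float)
        if len(g) < 3:
            raise ValueError(f"subject {sid} has fewer than 3 measurements")
        if np.ptp(hr) == 0 or np.std(ee) == 0:
            rs[sid] = np.nan
            excluded += 1
            continue
        rs[sid] = float(np.corrcoef(hr, ee)[0, 1])
    if excluded:
        warnings.warn(
            f"{excluded} subject(s) with undefined intra-person correlation excluded",
            stacklevel=2,
        )
    series = pd.Series(rs, name="r")
    valid = series.dropna()
    if valid.empty:
        raise ValueError("no subject has a defined intra-person correlation")
    return IntraPersonCorrelation(
        per_subject=series,
        mean=float(valid.mean()),
        min=float(valid.min()),
        max=float(valid.max()),
        n_excluded=excluded,
    )
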