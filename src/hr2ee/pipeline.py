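"""End-to-end orchestration: generate -> fit -> cross-validate -> report.

Also provides schema/sanity validation for externally supplied cohort CSVs.
All randomness derives from a single top-level seed via stable per-stage
hashing (see :func:`hr2ee.cohort.derive_seed`), so any stage can be re-run
in isolation and full runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    COHORT_COLUMNS,
    LEVELS,
    CohortTable,
    GeneratorConfig,
    derive_seed,
    simulate_cohort,
)
from .crossval import (
    SCENARIO_ORDER,
    intra_person_correlation,
    mean_scenario_sds,
    run_scenarios,
    scenario_sd_table,
)
from .lmm import ModelSpec, fit_lmm

logger = logging.getLogger("hr2ee")


class CohortValidationError(ValueError):
    """Raised when an input cohort table fails schema validation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid cohort table:\n- " + "\n- ".join(problems))


def validate_input_table(path: str | Path) -> CohortTable:
    """Load and validate a cohort CSV.

    Schema errors (missing columns, unknown levels, missing or duplicated
    subject x level rows, inconsistent per-subject covariates) are collected
    into one itemized :class:`CohortValidationError`. Unit-range oddities
    (heart rate outside 30-220 bpm, energy expenditure outside 0-70
    ml/kg/min) are logged as warnings, not errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    problems: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing columns: {missing}"])

    bad_sex = df.loc[~df["sex"].isin(["M", "F"]), "sex"].unique()
    if bad_sex.size:
        problems.append(f"unknown sex codes: {list(bad_sex)} (expected M/F)")
    bad_levels = df.loc[~df["level"].isin(LEVELS), "level"].unique()
    if bad_levels.size:
        problems.append(f"unknown levels: {list(bad_levels)} (expected {list(LEVELS)})")

    dup = df.duplicated(subset=["subject_id", "level"])
    if dup.any():
        dupes = df.loc[dup, ["subject_id", "level"]].drop_duplicates()
        for _, row in dupes.iterrows():
            problems.append(f"duplicated subject x level: {row.subject_id}/{row.level}")

    for sid, g in df.groupby("subject_id", sort=False):
        have = set(g["level"])
        lacking = [lv for lv in LEVELS if lv not in have]
        if lacking:
            problems.append(f"subject {sid} missing level(s): {lacking}")
        for col in ("age", "sex", "weight_kg"):
            if g[col].nunique() > 1:
                problems.append(f"subject {sid} has inconsistent {col}")

    if problems:
        raise CohortValidationError(problems)

    hr_bad = (~df["hr_bpm"].between(30, 220)).sum()
    if hr_bad:
        logger.warning("%d heart-rate values outside 30-220 bpm", hr_bad)
    ee_bad = (~df["ee_mlkgmin"].between(0, 70)).sum()
    if ee_bad:
        logger.warning("%d energy-expenditure values outside 0-70 ml/kg/min", ee_bad)
    return CohortTable(data=df)


@dataclass
class RunConfig:
    """Configuration for a full generate/fit/cross-validate experiment."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: tuple[str, ...] = ("m1", "m2")
    method: str = "ML"
    frac: float = 0.8
    scenarios: tuple[str, ...] = SCENARIO_ORDER
    replicates: int = 20
    seed: int = 0
    out_dir: str = "hr2ee_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}) or {})
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "scenarios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)


def run_full_experiment(config: RunConfig) -> dict:
    """Run the whole pipeline and write all artifacts to the output directory.

    Writes: the simulated cohort (CSV + metadata JSON), a fit JSON per model
    form, a cross-validation summary JSON, and a plain-text report with the
    fitted coefficients and the per-scenario error SDs. Returns the summary
    dict. Partial outputs are preserved on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    gen_cfg = GeneratorConfig.from_dict(
        {**config.generator.to_dict(), "seed": config.seed}
    )
    cohort = simulate_cohort(gen_cfg)
    cohort.to_csv(out / "cohort.csv")
    logger.info("generated cohort n=%d (%.2fs)", cohort.n_subjects, time.time() - t0)

    summary: dict = {
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
        "models": {},
    }
    ipc = intra_person_correlation(cohort)
    summary["intra_person_r"] = {"mean": ipc.mean, "min": ipc.min, "max": ipc.max}

    report_lines = [
        f"hr2ee experiment (seed={config.seed}, n={cohort.n_subjects}, "
        f"replicates={config.replicates})",
        "",
        f"intra-person correlation: mean {ipc.mean:.3f} "
        f"(range {ipc.min:.3f}-{ipc.max:.3f})",
    ]

    for form in config.models:
        spec = ModelSpec(form)
        t1 = time.time()
        fit = fit_lmm(cohort, spec, method=config.method)
        fit.to_json(out / f"fit_{spec.form}.json")
        reps = run_scenarios(
            cohort,
            spec,
            scenarios=config.scenarios,
            seed=config.seed,
            replicates=config.replicates,
            frac=config.frac,
            method=config.method,
            with_density=False,
        )
        sds = mean_scenario_sds(reps)
        table = scenario_sd_table(reps)
        summary["models"][spec.form] = {
            "loglik": fit.loglik,
            "converged": fit.converged,
            "fixed": dict(zip(fit.names, map(float, fit.fixed))),
            "variance_components": {
                "sd_b0": fit.vc.sd_b0,
                "sd_b1": fit.vc.sd_b1,
                "corr_b": fit.vc.corr_b,
                "sd_resid": fit.vc.sd_resid,
            },
            "scenario_sds_mean": {s: float(sds[s]) for s in sds},
            "scenario_sds_per_replicate": {
                s: [float(v) for v in table.loc[table.scenario == s, "sd"]]
                for s in sds
            },
        }
        logger.info("model %s done (%.2fs)", spec.form, time.time() - t1)

        report_lines += ["", f"== model {spec.form} ({fit.method}) =="]
        report_lines += [
            f"  {n:>10s}: {v: .4f} (se {se:.4f})"
            for n, v, se in zip(fit.names, fit.fixed, fit.se_fixed)
        ]
        report_lines += [
            f"  sd(b0)={fit.vc.sd_b0:.3f}  sd(b1)={fit.vc.sd_b1:.4f}  "
            f"corr={fit.vc.corr_b:.3f}  sd(resid)={fit.vc.sd_resid:.3f}",
            "  scenario error SDs (kcal/min, mean over replicates):",
        ]
        report_lines += [
            f"    {s:>10s}: {sds[s]:.3f}" for s in config.scenarios if s in sds
        ]

    (out / "crossval_summary.json").write_text(json.dumps(summary, indent=2))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    logger.info("experiment complete (%.2fs)", time.time() - t0)
    return summary
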