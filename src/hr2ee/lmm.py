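"""Random-intercept / random-slope linear mixed model, fit from scratch.

The model for subject i at measurement j is

    y_ij = x_ij' beta + b0_i + b1_i * hr_ij + W_ij,

with (b0_i, b1_i) ~ N(0, G) (unconstrained 2x2 covariance) and
W_ij ~ N(0, sigma^2) iid. Two fixed-effect forms are supported:

* ``m1`` (stratified): intercept and heart-rate slope per sex/age stratum,
  coded as indicator contrasts against the reference group (men < 65):
  (1, G2, G3, G4, hr, hr*G2, hr*G3, hr*G4).
* ``m2`` (continuous age): (1, hr, male, age, age*hr).

Estimation maximises the (restricted) likelihood over a log-Cholesky
parameterization of G/sigma^2, with beta and sigma^2 profiled out in closed
form; standard errors for the variance components come from the numerically
differentiated observed information mapped to the sd/correlation scale by
the delta method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable, stratum_of

logger = logging.getLogger("hr2ee")

_TWO_PI = 2.0 * np.pi

M1_NAMES = ["intercept", "g2", "g3", "g4", "hr", "hr:g2", "hr:g3", "hr:g4"]
M2_NAMES = ["intercept", "hr", "male", "age", "age:hr"]

_FORM_ALIASES = {
    "m1": "m1",
    "stratified": "m1",
    "model1": "m1",
    "m2": "m2",
    "continuous": "m2",
    "model2": "m2",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed-effect design to use; the random design is always (1, hr)."""

    form: str  # 'm1' (stratified) or 'm2' (continuous age)

    def __post_init__(self) -> None:
        canon = _FORM_ALIASES.get(self.form)
        if canon is None:
            raise ValueError(f"unknown model form {self.form!r}")
        object.__setattr__(self, "form", canon)

    @property
    def names(self) -> list[str]:
        return list(M1_NAMES if self.form == "m1" else M2_NAMES)

    def design_row(self, age: float, sex: str, hr: float) -> np.ndarray:
        """Fixed-effect covariate row for one measurement."""
        if self.form == "m1":
            s = stratum_of(age, sex)
            g2 = 1.0 if s == "M>=65" else 0.0
            g3 = 1.0 if s == "F<65" else 0.0
            g4 = 1.0 if s == "F>=65" else 0.0
            return np.array([1.0, g2, g3, g4, hr, hr * g2, hr * g3, hr * g4])
        male = 1.0 if sex == "M" else 0.0
        return np.array([1.0, hr, male, age, age * hr])

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        """Design matrix for a long-format cohort frame (vectorised)."""
        age = df["age"].to_numpy(dtype=float)
        hr = df["hr_bpm"].to_numpy(dtype=float)
        male = (df["sex"] == "M").to_numpy(dtype=float)
        if self.form == "m2":
            return np.column_stack([np.ones_like(hr), hr, male, age, age * hr])
        older = (age >= 65.0).astype(float)
        g2 = male * older
        g3 = (1 - male) * (1 - older)
        g4 = (1 - male) * older
        return np.column_stack(
            [np.ones_like(hr), g2, g3, g4, hr, hr * g2, hr * g3, hr * g4]
        )


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect SDs/correlation and residual SD, on the natural scale."""

    sd_b0: float  # ml/kg/min
    sd_b1: float  # ml/kg/min per bpm
    corr_b: float
    sd_resid: float  # ml/kg/min

    def __post_init__(self) -> None:
        if min(self.sd_b0, self.sd_b1, self.sd_resid) < 0:
            raise ValueError("sds must be >= 0")
        if abs(self.corr_b) > 1 + 1e-12:
            raise ValueError("|corr_b| must be <= 1")

    @property
    def G(self) -> np.ndarray:
        c = self.corr_b * self.sd_b0 * self.sd_b1
        return np.array([[self.sd_b0**2, c], [c, self.sd_b1**2]])

    @property
    def sigma2(self) -> float:
        return self.sd_resid**2


@dataclass
class FittedLMM:
    """Result of a mixed-model fit."""

    spec: ModelSpec
    fixed: np.ndarray
    names: list[str]
    vc: VarianceComponents
    se_fixed: np.ndarray
    se_vc: dict
    loglik: float
    method: str
    converged: bool
    n_subjects: int
    n_obs: int
    cov_fixed: np.ndarray
    pvalues: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.fixed[self.names.index(name)])

    def predict_population(self, age: float, sex: str, hr) -> np.ndarray:
        """Fixed-effect (population-mean) prediction at given heart rate(s)."""
        hr = np.atleast_1d(np.asarray(hr, dtype=float))
        X = np.stack([self.spec.design_row(age, sex, h) for h in hr])
        return X @ self.fixed

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.spec.form,
            "method": self.method,
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "loglik": float(self.loglik),
            "fixed": {n: float(v) for n, v in zip(self.names, self.fixed)},
            "se_fixed": {n: float(v) for n, v in zip(self.names, self.se_fixed)},
            "pvalues": {n: float(v) for n, v in zip(self.names, self.pvalues)},
            "variance_components": {
                "sd_b0": self.vc.sd_b0,
                "sd_b1": self.vc.sd_b1,
                "corr_b": self.vc.corr_b,
                "sd_resid": self.vc.sd_resid,
            },
            "se_variance_components": {k: float(v) for k, v in self.se_vc.items()},
            "cov_fixed": self.cov_fixed.tolist(),
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_parameters(
        cls,
        spec: "ModelSpec | str",
        fixed,
        vc: VarianceComponents,
        method: str = "ML",
    ) -> "FittedLMM":
        """Build a model object from known coefficients (e.g. a published
        equation) rather than a fit; SEs and the log-likelihood are NaN."""
        if isinstance(spec, str):
            spec = ModelSpec(spec)
        fixed = np.asarray(fixed, dtype=float)
        p = len(spec.names)
        if fixed.size != p:
            raise ValueError(f"expected {p} coefficients for {spec.form}")
        nan = np.full(p, np.nan)
        return cls(
            spec=spec,
            fixed=fixed,
            names=spec.names,
            vc=vc,
            se_fixed=nan.copy(),
            se_vc={k: float("nan") for k in ("sd_b0", "sd_b1", "corr_b", "sd_resid")},
            loglik=float("nan"),
            method=method,
            converged=True,
            n_subjects=0,
            n_obs=0,
            cov_fixed=np.full((p, p), np.nan),
            pvalues=nan.copy(),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedLMM":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        spec = ModelSpec(payload["model"])
        names = spec.names
        vcd = payload["variance_components"]
        return cls(
            spec=spec,
            fixed=np.array([payload["fixed"][n] for n in names]),
            names=names,
            vc=VarianceComponents(**vcd),
            se_fixed=np.array([payload["se_fixed"][n] for n in names]),
            se_vc=payload.get("se_variance_components", {}),
            loglik=payload["loglik"],
            method=payload["method"],
            converged=payload["converged"],
            n_subjects=payload["n_subjects"],
            n_obs=payload["n_obs"],
            cov_fixed=np.array(payload["cov_fixed"]),
            pvalues=np.array([payload["pvalues"][n] for n in names]),
            diagnostics=payload.get("diagnostics", {}),
        )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


class _Blocks:
    """Per-subject (y_i, X_i, Z_i) stacks, batched by group size."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if data.empty:
            raise ValueError("empty data")
        X = spec.design_matrix(data)
        y = data["ee_mlkgmin"].to_numpy(dtype=float)
        hr = data["hr_bpm"].to_numpy(dtype=float)
        codes, _ = pd.factorize(data["subject_id"], sort=False)
        order = np.argsort(codes, kind="stable")
        X, y, hr, codes = X[order], y[order], hr[order], codes[order]
        counts = np.bincount(codes)
        self.p = X.shape[1]
        self.n_obs = y.size
        self.n_subjects = counts.size
        # batch subjects by identical group size -> 3-D stacks
        self.batches: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        starts = np.concatenate([[0], np.cumsum(counts)])
        for size in np.unique(counts):
            sel = np.where(counts == size)[0]
            idx = np.concatenate(
                [np.arange(starts[s], starts[s] + size) for s in sel]
            )
            Xb = X[idx].reshape(len(sel), size, self.p)
            yb = y[idx].reshape(len(sel), size)
            Zb = np.stack(
                [np.ones((len(sel), size)), hr[idx].reshape(len(sel), size)], axis=2
            )
            self.batches.append((yb, Xb, Zb))

    def whitened(self, D: np.ndarray):
        """Whiten all rows under V0_i = Z_i D Z_i' + I.

        Returns (WX, Wy, logdet_sum): stacked whitened design/response such
        that WX'WX = sum_i X_i' V0_i^-1 X_i etc. Solving the GLS normal
        equations by QR on the whitened stack keeps precision on poorly
        scaled designs (age*hr columns reach ~2e4).
        """
        WX_parts, Wy_parts = [], []
        logdet = 0.0
        for yb, Xb, Zb in self.batches:
            m = yb.shape[1]
            V0 = Zb @ D @ np.swapaxes(Zb, 1, 2) + np.eye(m)
            L = np.linalg.cholesky(V0)
            logdet += 2.0 * float(np.sum(np.log(np.einsum("bii->bi", L))))
            Wy_parts.append(np.linalg.solve(L, yb[:, :, None])[:, :, 0].ravel())
            WX_parts.append(np.linalg.solve(L, Xb).reshape(-1, self.p))
        return np.vstack(WX_parts), np.concatenate(Wy_parts), logdet

    def gls(self, D: np.ndarray):
        """GLS fixed effects under V0(D): returns (beta, rss, logdet,
        logdet_xvx, XtVX_inverse)."""
        WX, Wy, logdet = self.whitened(D)
        Q, R = np.linalg.qr(WX)
        diag = np.abs(np.diag(R))
        if np.any(diag < 1e-10 * diag.max()):
            raise np.linalg.LinAlgError(
                "singular profiled design; check for collinear fixed-effect columns"
            )
        beta = np.linalg.solve(R, Q.T @ Wy)
        resid = Wy - WX @ beta
        rss = float(resid @ resid)
        logdet_xvx = 2.0 * float(np.sum(np.log(diag)))
        Rinv = np.linalg.inv(R)
        XtVX_inv = Rinv @ Rinv.T
        return beta, rss, logdet, logdet_xvx, XtVX_inv


def _theta_to_D(theta3: np.ndarray) -> np.ndarray:
    """Log-Cholesky: theta=(a, b, c) -> L=[[e^a,0],[b,e^c]], D = L L'."""
    a, b, c = theta3
    l11, l22 = np.exp(a), np.exp(c)
    return np.array([[l11**2, l11 * b], [l11 * b, b**2 + l22**2]])


def _profiled_neg_loglik(
    theta3: np.ndarray, blocks: _Blocks, method: str
) -> tuple[float, np.ndarray, float]:
    """Negative log-likelihood with beta and sigma^2 profiled out.

    Returns (nll, beta_hat, sigma2_hat). REML uses the projected-design
    log-determinant correction and the N - p denominator.
    """
    if np.max(np.abs(theta3)) > 50:  # guard against optimizer excursions
        return 1e12, np.zeros(blocks.p), 1.0
    D = _theta_to_D(theta3)
    try:
        beta, rss, logdet, logdet_xvx, _ = blocks.gls(D)
    except np.linalg.LinAlgError as err:
        if "singular profiled design" in str(err):
            raise
        # numerically non-PD at extreme D scales: penalize, don't abort
        return 1e12, np.zeros(blocks.p), 1.0
    rss = max(rss, 1e-300)
    N, p = blocks.n_obs, blocks.p
    if method == "ml":
        sigma2 = rss / N
        nll = 0.5 * (N * np.log(_TWO_PI * sigma2) + logdet + N)
    else:  # reml
        sigma2 = rss / (N - p)
        # (N-p)log 2pi + N log s2 + logdet + [log|XtVX| - p log s2] + (N-p)
        # collapses to the form below: the p log s2 terms cancel
        nll = 0.5 * (
            (N - p) * np.log(_TWO_PI * sigma2) + logdet + logdet_xvx + (N - p)
        )
    return float(nll), beta, sigma2


def neg_loglik(
    theta: Sequence[float],
    data: CohortTable | pd.DataFrame,
    spec: ModelSpec,
    method: str = "ml",
) -> float:
    """Negative (restricted) log-likelihood at unconstrained variance
    parameters, with fixed effects profiled out by generalized least squares.

    ``theta`` = (a, b, c, log sigma): log-Cholesky of G = sigma^2 * D with
    L = [[e^a, 0], [b, e^c]] parameterizing D, plus log residual SD. Finite
    for any finite theta.
    """
    df = data.data if isinstance(data, CohortTable) else data
    method = _canon_method(method)
    blocks = _Blocks(df, spec)
    if blocks.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    theta = np.asarray(theta, dtype=float)
    a, b, c, log_sigma = theta
    sigma2 = np.exp(2 * log_sigma)
    # D = G / sigma^2; rescale the Cholesky factor of G by 1/sigma
    D = _theta_to_D(np.array([a - log_sigma, b / np.exp(log_sigma), c - log_sigma]))
    beta, rss, logdet, logdet_xvx, _ = blocks.gls(D)
    N, p = blocks.n_obs, blocks.p
    nll = 0.5 * (N * np.log(_TWO_PI * sigma2) + logdet + rss / sigma2)
    if method == "reml":
        # log|X' V^-1 X| = log|XtVX in V0 metric| - p log sigma^2
        nll += 0.5 * (logdet_xvx - p * np.log(sigma2)) - 0.5 * p * np.log(_TWO_PI)
    return float(nll)


def _canon_method(method: str) -> str:
    m = method.lower()
    if m not in ("ml", "reml"):
        raise ValueError("method must be 'ML' or 'REML'")
    return m


def _moment_start(df: pd.DataFrame) -> tuple[float, float, float, float]:
    """Truth-agnostic start: per-subject OLS lines give rough scales for the
    random-effect SDs; pooled within-subject residuals give sigma."""
    icpts, slopes, res_var = [], [], []
    for _, g in df.groupby("subject_id", sort=False):
        hr = g["hr_bpm"].to_numpy(dtype=float)
        y = g["ee_mlkgmin"].to_numpy(dtype=float)
        if len(g) >= 3 and np.ptp(hr) > 0:
            A = np.column_stack([np.ones_like(hr), hr])
            coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            icpts.append(coef[0])
            slopes.append(coef[1])
            if len(g) > 2 and res.size:
                res_var.append(res[0] / (len(g) - 2))
    if len(icpts) >= 3:
        sd0 = float(np.std(icpts, ddof=1))
        sd1 = float(np.std(slopes, ddof=1))
        corr = float(np.corrcoef(icpts, slopes)[0, 1]) if sd0 > 0 and sd1 > 0 else 0.0
        sigma = float(np.sqrt(np.mean(res_var))) if res_var else float(np.std(y))
    else:
        sd_y = float(df["ee_mlkgmin"].std() or 1.0)
        sd0, sd1, corr, sigma = sd_y, sd_y / 100.0, 0.0, sd_y
    sd0 = max(sd0, 1e-3)
    sd1 = max(sd1, 1e-5)
    sigma = max(sigma, 1e-3)
    corr = float(np.clip(np.nan_to_num(corr), -0.95, 0.95))
    return sd0, sd1, corr, sigma


def _vc_to_theta3(sd0: float, sd1: float, corr: float, sigma: float) -> np.ndarray:
    """Map natural-scale components to the 3-dim profiled parameterization
    of D = G / sigma^2 (log-Cholesky)."""
    g11 = (sd0 / sigma) ** 2
    g21 = corr * sd0 * sd1 / sigma**2
    g22 = (sd1 / sigma) ** 2
    l11 = np.sqrt(g11)
    b = g21 / l11
    l22 = np.sqrt(max(g22 - b**2, 1e-30))
    return np.array([np.log(l11), b, np.log(l22)])


def vc_to_theta(vc: VarianceComponents) -> np.ndarray:
    """Map variance components to the unconstrained 4-vector accepted by
    :func:`neg_loglik`: log-Cholesky of G/sigma^2 scaled to G, plus log sigma."""
    t3 = _vc_to_theta3(vc.sd_b0, vc.sd_b1, vc.corr_b, vc.sd_resid)
    ls = np.log(vc.sd_resid)
    return np.array([t3[0] + ls, t3[1] * vc.sd_resid, t3[2] + ls, ls])


def _theta3_to_vc(theta3: np.ndarray, sigma2: float) -> VarianceComponents:
    D = _theta_to_D(theta3)
    G = sigma2 * D
    sd0 = float(np.sqrt(G[0, 0]))
    sd1 = float(np.sqrt(G[1, 1]))
    corr = float(G[0, 1] / (sd0 * sd1)) if sd0 > 0 and sd1 > 0 else 0.0
    return VarianceComponents(
        sd_b0=sd0, sd_b1=sd1, corr_b=float(np.clip(corr, -1, 1)),
        sd_resid=float(np.sqrt(sigma2)),
    )


def fit_lmm(
    data: CohortTable | pd.DataFrame,
    spec: ModelSpec | str,
    method: str = "ML",
    n_starts: int = 3,
    xtol: float = 1e-10,
) -> FittedLMM:
    """Fit the mixed model by maximum (or restricted maximum) likelihood.

    The optimizer works on the 3-parameter log-Cholesky parameterization of
    G/sigma^2, with beta and sigma^2 profiled out analytically; quasi-Newton
    (L-BFGS-B on numerical gradients) is followed by a Nelder-Mead polish
    from several dispersed starting points. Non-convergence is reported via
    ``converged=False`` with diagnostics, not an exception.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    method = _canon_method(method)
    df = data.data if isinstance(data, CohortTable) else data
    blocks = _Blocks(df, spec)
    if blocks.n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    sd0, sd1, corr, sigma = _moment_start(df)
    starts = [
        _vc_to_theta3(sd0, sd1, corr, sigma),
        _vc_to_theta3(3.0 * sd0, 0.3 * sd1, 0.0, 2.0 * sigma),
        _vc_to_theta3(0.3 * sd0, 3.0 * sd1, 0.0, 0.5 * sigma),
    ][:n_starts]

    def objective(t3: np.ndarray) -> float:
        return _profiled_neg_loglik(t3, blocks, method)[0]

    best = None
    n_fev = 0
    for t0 in starts:
        try:
            r1 = optimize.minimize(
                objective, t0, method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
            )
            r2 = optimize.minimize(
                objective, r1.x, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": xtol, "maxiter": 2000},
            )
        except np.linalg.LinAlgError:
            raise
        except Exception as err:  # pragma: no cover - defensive
            logger.warning("optimizer start failed: %s", err)
            continue
        n_fev += int(r1.nfev + r2.nfev)
        if best is None or r2.fun < best.fun:
            best = r2
    converged = best is not None and np.isfinite(best.fun) and best.fun < 1e11
    if best is None:
        theta3 = starts[0]
        nll, beta, sigma2 = _profiled_neg_loglik(theta3, blocks, method)
    else:
        theta3 = best.x
        nll, beta, sigma2 = _profiled_neg_loglik(theta3, blocks, method)

    vc = _theta3_to_vc(theta3, sigma2)
    D = _theta_to_D(theta3)
    _, _, _, _, XtVX_inv = blocks.gls(D)
    cov_fixed = sigma2 * XtVX_inv
    se_fixed = np.sqrt(np.diag(cov_fixed))
    z = beta / se_fixed
    pvalues = 2.0 * stats.norm.sf(np.abs(z))

    se_vc = _vc_standard_errors(df, spec, method, vc)

    fit = FittedLMM(
        spec=spec,
        fixed=beta,
        names=spec.names,
        vc=vc,
        se_fixed=se_fixed,
        se_vc=se_vc,
        loglik=-nll,
        method=method.upper(),
        converged=bool(converged),
        n_subjects=blocks.n_subjects,
        n_obs=blocks.n_obs,
        cov_fixed=cov_fixed,
        pvalues=pvalues,
        diagnostics={"n_starts": len(starts), "nfev": n_fev},
    )
    if not converged:
        fit.diagnostics["warning"] = "optimizer did not converge from any start"
        logger.warning("fit_lmm: %s", fit.diagnostics["warning"])
    return fit


def _vc_standard_errors(
    df: pd.DataFrame, spec: ModelSpec, method: str, vc: VarianceComponents
) -> dict:
    """Delta-method SEs for (sd_b0, sd_b1, corr_b, sd_resid) from the
    numerically differentiated observed information in the unconstrained
    4-parameter space."""
    nan_out = {k: float("nan") for k in ("sd_b0", "sd_b1", "corr_b", "sd_resid")}
    sigma = vc.sd_resid
    # near-degenerate components: the information matrix is not usable there
    if min(vc.sd_b0, vc.sd_b1, sigma) <= 1e-6 or abs(vc.corr_b) > 1 - 1e-8:
        return nan_out
    t3 = _vc_to_theta3(vc.sd_b0, vc.sd_b1, vc.corr_b, sigma)
    # unconstrained theta for the non-profiled-sigma likelihood:
    # G-cholesky = sigma * D-cholesky
    log_sigma = np.log(sigma)
    theta4 = np.array(
        [t3[0] + log_sigma, t3[1] * sigma, t3[2] + log_sigma, log_sigma]
    )

    def f(t: np.ndarray) -> float:
        return neg_loglik(t, df, spec, method)

    try:
        H = _numerical_hessian(f, theta4)
    except np.linalg.LinAlgError:
        return nan_out

    def natural(t: np.ndarray) -> np.ndarray:
        a, b, c, ls = t
        s = np.exp(ls)
        Dv = _theta_to_D(np.array([a - ls, b / s, c - ls]))
        G = s**2 * Dv
        sd0 = np.sqrt(G[0, 0])
        sd1 = np.sqrt(G[1, 1])
        return np.array([sd0, sd1, G[0, 1] / (sd0 * sd1), s])

    J = _numerical_jacobian(natural, theta4)
    try:
        cov_theta = np.linalg.inv(H)
        cov_nat = J @ cov_theta @ J.T
        with np.errstate(invalid="ignore"):
            ses = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(4, np.nan)
    return dict(zip(("sd_b0", "sd_b1", "corr_b", "sd_resid"), map(float, ses)))


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def _numerical_jacobian(g, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    n = x.size
    cols = []
    for i in range(n):
        e = np.zeros(n); e[i] = h
        cols.append((g(x + e) - g(x - e)) / (2 * h))
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# Stratified-model summaries
# ---------------------------------------------------------------------------


@dataclass
class StratumLines:
    """Per-stratum composed intercepts and slopes from a stratified fit."""

    intercepts: dict
    slopes: dict
    contrast_pvalues: dict

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.intercepts:
            rows.append(
                {
                    "stratum": s,
                    "intercept": self.intercepts[s],
                    "slope": self.slopes[s],
                    "p_intercept_contrast": self.contrast_pvalues[s][0],
                    "p_slope_contrast": self.contrast_pvalues[s][1],
                }
            )
        return pd.DataFrame(rows)


def compare_strata(fit: FittedLMM) -> StratumLines:
    """Compose the four stratum lines from a stratified (m1) fit.

    Intercepts are (b01, b01+b02, b01+b03, b01+b04) for (men<65, men>=65,
    women<65, women>=65), slopes analogously; p-values test each *contrast*
    coefficient (the deviation from the reference group) by a Wald z-test,
    with the reference group's own p-values testing its raw coefficients.
    """
    if fit.spec.form != "m1":
        raise ValueError("compare_strata requires a stratified (m1) fit")
    b = dict(zip(fit.names, fit.fixed))
    strata = ("M<65", "M>=65", "F<65", "F>=65")
    contrast_cols = {"M<65": None, "M>=65": ("g2", "hr:g2"),
                     "F<65": ("g3", "hr:g3"), "F>=65": ("g4", "hr:g4")}
    intercepts, slopes, pvals = {}, {}, {}
    pv = dict(zip(fit.names, fit.pvalues))
    for s in strata:
        cols = contrast_cols[s]
        if cols is None:
            intercepts[s] = b["intercept"]
            slopes[s] = b["hr"]
            pvals[s] = (pv["intercept"], pv["hr"])
        else:
            ci, cs = cols
            intercepts[s] = b["intercept"] + b[ci]
            slopes[s] = b["hr"] + b[cs]
            pvals[s] = (pv[ci], pv[cs])
    return StratumLines(intercepts=intercepts, slopes=slopes, contrast_pvalues=pvals)
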