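"""Mixed-model likelihood, fitting, and stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from hr2ee import (
    FittedLMM,
    GeneratorConfig,
    ModelSpec,
    VarianceComponents,
    compare_strata,
    fit_lmm,
    neg_loglik,
    simulate_cohort,
    vc_to_theta,
)


class TestDesign:
    def test_m1_row_for_younger_man(self):
        row = ModelSpec("m1").design_row(age=70.0, sex="M", hr=100.0)
        assert np.allclose(row, [1, 1, 0, 0, 100, 100, 0, 0])

    def test_m2_row_products(self):
        row = ModelSpec("m2").design_row(age=60.0, sex="F", hr=90.0)
        assert np.allclose(row, [1, 90, 0, 60, 5400])

    def test_m1_age_boundary_is_reference_group(self):
        row = ModelSpec("m1").design_row(age=64.99, sex="M", hr=80.0)
        assert np.allclose(row, [1, 0, 0, 0, 80, 0, 0, 0])
        row65 = ModelSpec("m1").design_row(age=65.0, sex="M", hr=80.0)
        assert np.allclose(row65, [1, 1, 0, 0, 80, 80, 0, 0])

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("m3")

    def test_design_matrix_matches_rows(self, small_cohort):
        for form in ("m1", "m2"):
            spec = ModelSpec(form)
            d = small_cohort.data.head(20)
            X = spec.design_matrix(d)
            rows = np.stack(
                [
                    spec.design_row(r.age, r.sex, r.hr_bpm)
                    for r in d.itertuples()
                ]
            )
            assert np.allclose(X, rows)


def _dense_ml_loglik(df, spec, vc):
    """Brute-force ML log-likelihood: GLS fixed effects, then the sum of
    per-subject multivariate-normal log-densities."""
    G, s2 = vc.G, vc.sigma2
    Xl, yl, Vl = [], [], []
    for _, g in df.groupby("subject_id", sort=False):
        hr = g["hr_bpm"].to_numpy()
        X = np.stack([spec.design_row(g["age"].iloc[0], g["sex"].iloc[0], h) for h in hr])
        Z = np.column_stack([np.ones_like(hr), hr])
        Xl.append(X)
        yl.append(g["ee_mlkgmin"].to_numpy())
        Vl.append(Z @ G @ Z.T + s2 * np.eye(len(hr)))
    XtViX = sum(X.T @ np.linalg.solve(V, X) for X, V in zip(Xl, Vl))
    XtViy = sum(X.T @ np.linalg.solve(V, y) for X, y, V in zip(Xl, yl, Vl))
    beta = np.linalg.solve(XtViX, XtViy)
    return sum(
        stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
        for X, y, V in zip(Xl, yl, Vl)
    )


class TestLoglik:
    def test_matches_brute_force_mvn_density(self):
        """Profiled likelihood equals the joint multivariate-normal density
        evaluated per subject on a 3-subject toy set."""
        cohort = simulate_cohort(GeneratorConfig(n_subjects=3, seed=21))
        spec = ModelSpec("m2")
        vc = VarianceComponents(3.0, 0.05, -0.5, 2.0)
        ours = -neg_loglik(vc_to_theta(vc), cohort, spec, "ml")
        brute = _dense_ml_loglik(cohort.data, spec, vc)
        assert ours == pytest.approx(brute, abs=1e-10)

    def test_reduces_to_ols_likelihood_without_random_effects(self):
        """sd_b0 = sd_b1 = 0 collapses to the iid-normal regression
        log-likelihood in closed form."""
        cohort = simulate_cohort(GeneratorConfig(n_subjects=12, seed=22))
        spec = ModelSpec("m2")
        sigma = 2.5
        vc = VarianceComponents(1e-12, 1e-12, 0.0, sigma)
        ours = -neg_loglik(vc_to_theta(vc), cohort, spec, "ml")
        X = spec.design_matrix(cohort.data)
        y = cohort.data["ee_mlkgmin"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ beta) ** 2)
        n = len(y)
        ols_ll = -0.5 * (n * np.log(2 * np.pi * sigma**2) + rss / sigma**2)
        assert ours == pytest.approx(ols_ll, abs=1e-6)

    def test_subject_permutation_invariance(self, small_cohort):
        spec = ModelSpec("m2")
        vc = VarianceComponents(3.9, 0.06, -0.8, 2.7)
        theta = vc_to_theta(vc)
        base = neg_loglik(theta, small_cohort.data, spec, "ml")
        rng = np.random.default_rng(0)
        ids = small_cohort.data["subject_id"].unique()
        shuffled = pd.concat(
            [small_cohort.data[small_cohort.data.subject_id == i]
             for i in rng.permutation(ids)]
        ).reset_index(drop=True)
        assert neg_loglik(theta, shuffled, spec, "ml") == pytest.approx(base, abs=1e-10)


class TestFit:
    def test_noise_free_fit_recovers_generator_exactly(self, noise_free_cohort):
        fit = fit_lmm(noise_free_cohort, ModelSpec("m2"), method="ML")
        cfg = GeneratorConfig.from_dict(noise_free_cohort.metadata["generator"])
        assert np.allclose(fit.fixed, cfg.fixed_continuous, atol=1e-8)

    def test_optimum_beats_generating_parameters(self):
        truth = VarianceComponents(3.966, 0.062, -0.874, 2.787)
        for seed in (31, 32, 33):
            cohort = simulate_cohort(GeneratorConfig(n_subjects=60, seed=seed))
            fit = fit_lmm(cohort, ModelSpec("m2"), method="ML")
            ll_truth = -neg_loglik(vc_to_theta(truth), cohort, ModelSpec("m2"), "ml")
            assert fit.loglik >= ll_truth - 1e-8

    def test_profile_gls_identity(self, small_cohort, m2_fit):
        """Refitting the fixed effects at the returned variance components by
        GLS reproduces the returned fixed effects."""
        spec = ModelSpec("m2")
        G, s2 = m2_fit.vc.G, m2_fit.vc.sigma2
        XtViX, XtViy = 0.0, 0.0
        for _, g in small_cohort.data.groupby("subject_id", sort=False):
            hr = g["hr_bpm"].to_numpy()
            X = np.stack(
                [spec.design_row(g["age"].iloc[0], g["sex"].iloc[0], h) for h in hr]
            )
            Z = np.column_stack([np.ones_like(hr), hr])
            V = Z @ G @ Z.T + s2 * np.eye(len(hr))
            XtViX = XtViX + X.T @ np.linalg.solve(V, X)
            XtViy = XtViy + X.T @ np.linalg.solve(V, g["ee_mlkgmin"].to_numpy())
        beta = np.linalg.solve(XtViX, XtViy)
        assert np.allclose(beta, m2_fit.fixed, rtol=1e-8, atol=1e-10)

    def test_two_parameter_grid_search_oracle(self):
        """Restricted to (sd_b0, sd_resid) with the other components fixed at
        truth, the continuous optimizer lands on the dense-grid optimum."""
        cohort = simulate_cohort(GeneratorConfig(n_subjects=10, seed=41))
        spec = ModelSpec("m2")

        def nll(sd0, sig):
            vc = VarianceComponents(sd0, 0.062, -0.874, sig)
            return neg_loglik(vc_to_theta(vc), cohort, spec, "ml")

        sd0_grid = np.linspace(1.0, 8.0, 57)
        sig_grid = np.linspace(1.5, 4.5, 57)
        vals = np.array([[nll(a, s) for s in sig_grid] for a in sd0_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        res = optimize.minimize(
            lambda t: nll(np.exp(t[0]), np.exp(t[1])),
            x0=[np.log(3.0), np.log(2.5)],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        step0 = sd0_grid[1] - sd0_grid[0]
        step1 = sig_grid[1] - sig_grid[0]
        assert abs(np.exp(res.x[0]) - sd0_grid[i]) <= step0
        assert abs(np.exp(res.x[1]) - sig_grid[j]) <= step1

    def test_agrees_with_statsmodels_mixedlm(self, small_cohort):
        """Independent cross-check: the likelihood function agrees with
        statsmodels MixedLM at statsmodels' solution, and our optimum is at
        least as good."""
        smf = pytest.importorskip("statsmodels.formula.api")
        d = small_cohort.data.copy()
        d["male"] = (d.sex == "M").astype(float)
        md = smf.mixedlm(
            "ee_mlkgmin ~ hr_bpm + male + age + age:hr_bpm",
            d,
            groups=d["subject_id"],
            re_formula="~hr_bpm",
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = md.fit(reml=False, method="lbfgs", maxiter=500)
        # evaluate our likelihood at the statsmodels solution
        # (cov_re is already on the natural scale)
        G_sm = mf.cov_re.to_numpy()
        sd0, sd1 = np.sqrt(G_sm[0, 0]), np.sqrt(G_sm[1, 1])
        vc_sm = VarianceComponents(
            sd0, sd1, G_sm[0, 1] / (sd0 * sd1), np.sqrt(mf.scale)
        )
        ours_at_sm = -neg_loglik(vc_to_theta(vc_sm), small_cohort, ModelSpec("m2"), "ml")
        assert ours_at_sm == pytest.approx(mf.llf, abs=1e-4)
        fit = fit_lmm(small_cohort, ModelSpec("m2"), method="ML")
        assert fit.loglik >= mf.llf - 1e-6

    def test_variance_component_recovery_direction(self, cohort):
        """One default-size cohort: estimates land near the generating values
        (loose sanity bound; the replicated recovery study is elsewhere)."""
        fit = fit_lmm(cohort, ModelSpec("m2"), method="ML")
        assert fit.converged
        assert fit.vc.sd_b0 == pytest.approx(3.966, abs=1.0)
        assert fit.vc.sd_b1 == pytest.approx(0.062, abs=0.02)
        assert fit.vc.corr_b == pytest.approx(-0.874, abs=0.1)
        assert fit.vc.sd_resid == pytest.approx(2.787, abs=0.3)

    def test_json_roundtrip(self, tmp_path, m2_fit):
        p = tmp_path / "fit.json"
        m2_fit.to_json(p)
        back = FittedLMM.from_json(p)
        assert np.allclose(back.fixed, m2_fit.fixed)
        assert back.vc == m2_fit.vc
        assert back.loglik == pytest.approx(m2_fit.loglik)
        assert back.spec.form == "m2"


def _m1_fit_from_composed(intercepts, slopes):
    """Build an m1 fit whose composed lines are the given values."""
    fixed = [
        intercepts[0],
        intercepts[1] - intercepts[0],
        intercepts[2] - intercepts[0],
        intercepts[3] - intercepts[0],
        slopes[0],
        slopes[1] - slopes[0],
        slopes[2] - slopes[0],
        slopes[3] - slopes[0],
    ]
    vc = VarianceComponents(4.007, 0.063, -0.875, 2.785)
    return FittedLMM.from_parameters("m1", fixed, vc)


class TestCompareStrata:
    def test_composed_lines_from_reference_coefficients(self):
        intercepts = (-15.392, -14.960, -17.591, -17.055)
        slopes = (0.296, 0.279, 0.297, 0.285)
        fit = _m1_fit_from_composed(intercepts, slopes)
        lines = compare_strata(fit)
        order = ("M<65", "M>=65", "F<65", "F>=65")
        assert np.allclose([lines.intercepts[s] for s in order], intercepts)
        assert np.allclose([lines.slopes[s] for s in order], slopes)

    def test_zero_contrasts_give_identical_lines(self):
        fit = _m1_fit_from_composed((-15.0,) * 4, (0.3,) * 4)
        lines = compare_strata(fit)
        assert len(set(lines.intercepts.values())) == 1
        assert len(set(lines.slopes.values())) == 1

    def test_rejects_continuous_fit(self, reference_m2_fit):
        with pytest.raises(ValueError):
            compare_strata(reference_m2_fit)

    def test_reference_swap_oracle(self):
        """Composed lines agree with a GLS refit using a different reference
        group, at the same variance components."""
        cfg = GeneratorConfig.stratified(n_subjects=40, seed=43)
        cohort = simulate_cohort(cfg)
        fit = fit_lmm(cohort, ModelSpec("m1"), method="ML")
        lines = compare_strata(fit)

        # refit fixed effects by GLS with reference group swapped to M>=65
        from hr2ee.cohort import stratum_of

        G, s2 = fit.vc.G, fit.vc.sigma2
        XtViX, XtViy = 0.0, 0.0
        order = ("M>=65", "M<65", "F<65", "F>=65")
        for _, g in cohort.data.groupby("subject_id", sort=False):
            hr = g["hr_bpm"].to_numpy()
            st_i = stratum_of(g["age"].iloc[0], g["sex"].iloc[0])
            k = order.index(st_i)
            ind = np.zeros(4)
            ind[k] = 1.0
            X = np.stack(
                [
                    np.concatenate(
                        [[1.0], ind[1:], [h], h * ind[1:]]
                    )
                    for h in hr
                ]
            )
            Z = np.column_stack([np.ones_like(hr), hr])
            V = Z @ G @ Z.T + s2 * np.eye(len(hr))
            XtViX = XtViX + X.T @ np.linalg.solve(V, X)
            XtViy = XtViy + X.T @ np.linalg.solve(V, g["ee_mlkgmin"].to_numpy())
        beta = np.linalg.solve(XtViX, XtViy)
        swapped_intercepts = {
            "M>=65": beta[0],
            "M<65": beta[0] + beta[1],
            "F<65": beta[0] + beta[2],
            "F>=65": beta[0] + beta[3],
        }
        swapped_slopes = {
            "M>=65": beta[4],
            "M<65": beta[4] + beta[5],
            "F<65": beta[4] + beta[6],
            "F>=65": beta[4] + beta[7],
        }
        for s in swapped_intercepts:
            assert lines.intercepts[s] == pytest.approx(swapped_intercepts[s], abs=1e-6)
            assert lines.slopes[s] == pytest.approx(swapped_slopes[s], abs=1e-6)
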