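"""Additive mixed model: solver identities, mixed-model duality, REML
behaviour, inference calibration, and an external mgcv cross-check."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sedtemp.gamm import (
    AdditiveMixedModel,
    ModelSpec,
    RankDeficiencyError,
    compare_smooth_vs_linear,
    fit_univariable,
    linear_term,
    minutes_equivalent,
    random_intercept_term,
    smooth_term,
)

MEAN_AWAKE_MIN = 474.0 / 0.560  # cohort mean awake time implied by 56.0% = 474 min


def _balanced_data(n_groups=30, n_per=5, sigma_u=2.0, sigma_e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_per)
    u = rng.normal(0, sigma_u, n_groups)
    y = 5.0 + u[g] + rng.normal(0, sigma_e, n_groups * n_per)
    return pd.DataFrame({"y": y, "child_id": [f"c{i:03d}" for i in g]}), u


class TestMixedModelDuality:
    def test_blup_matches_closed_form_on_balanced_design(self):
        """With lambda fixed at sigma_e^2/sigma_u^2, the ridge-penalized
        intercepts equal the classical BLUP shrinkage
        n*sigma_u^2/(n*sigma_u^2 + sigma_e^2) of group-mean deviations."""
        sigma_u, sigma_e, n_per = 2.0, 1.0, 5
        df, _ = _balanced_data(sigma_u=sigma_u, sigma_e=sigma_e, n_per=n_per)
        lam = sigma_e**2 / sigma_u**2
        spec = ModelSpec("y", [random_intercept_term("child_id")])
        res = AdditiveMixedModel(df, spec).fit(fixed_rho=np.array([np.log(lam)]))
        shrink = n_per * sigma_u**2 / (n_per * sigma_u**2 + sigma_e**2)
        grand = df["y"].mean()
        group_means = df.groupby("child_id")["y"].mean()
        expected = shrink * (group_means - grand)
        np.testing.assert_allclose(res.random_effects, expected, atol=1e-6)
        np.testing.assert_allclose(res.params["(Intercept)"], grand, atol=1e-6)

    def test_reml_estimates_variance_components(self):
        df, _ = _balanced_data(n_groups=200, n_per=6, sigma_u=2.0, sigma_e=1.0, seed=3)
        res = AdditiveMixedModel(
            df, ModelSpec("y", [random_intercept_term("child_id")])
        ).fit()
        assert res.sigma_u == pytest.approx(2.0, rel=0.15)
        assert np.sqrt(res.scale) == pytest.approx(1.0, rel=0.1)

    def test_identical_groups_get_equal_intercepts(self):
        base = pd.DataFrame({"y": [1.0, 2.0, 4.0], "child_id": "a"})
        other = base.assign(child_id="b")
        third = pd.DataFrame({"y": [7.0, 9.0, 8.0], "child_id": "c"})
        df = pd.concat([base, other, third], ignore_index=True)
        res = AdditiveMixedModel(
            df, ModelSpec("y", [random_intercept_term("child_id")])
        ).fit(fixed_rho=np.array([0.0]))
        assert res.random_effects["a"] == pytest.approx(res.random_effects["b"], abs=1e-10)

    def test_heavy_shrinkage_zeroes_singletons(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"y": rng.normal(size=20), "child_id": [f"c{i}" for i in range(20)]}
        )
        res = AdditiveMixedModel(
            df, ModelSpec("y", [random_intercept_term("child_id")])
        ).fit(fixed_rho=np.array([20.0]))
        assert np.abs(res.random_effects).max() < 1e-6

    def test_null_variance_recovered(self):
        """sigma_u = 0 planted -> estimated variance component near zero."""
        rng = np.random.default_rng(5)
        g = np.repeat(np.arange(80), 5)
        df = pd.DataFrame(
            {"y": 3.0 + rng.normal(0, 1.0, 400), "child_id": [f"c{i}" for i in g]}
        )
        res = AdditiveMixedModel(
            df, ModelSpec("y", [random_intercept_term("child_id")])
        ).fit()
        assert res.sigma_u**2 <= 0.1


class TestSolverIdentities:
    def test_schur_and_dense_paths_agree(self, mixed_dataset):
        spec = ModelSpec("y", [linear_term("x"), random_intercept_term("child_id")])
        # exact algebraic equivalence at fixed smoothing
        rho = np.array([0.7])
        a = AdditiveMixedModel(mixed_dataset, spec).fit(fixed_rho=rho)
        b = AdditiveMixedModel(mixed_dataset, spec).fit(force_dense=True, fixed_rho=rho)
        np.testing.assert_allclose(a.params, b.params, atol=1e-6)
        # dense path applies the stabilising ridge to the indicator block
        # too, so agreement is at the ridge scale, not machine precision
        np.testing.assert_allclose(a.random_effects, b.random_effects, atol=1e-6)
        assert a.edf_total == pytest.approx(b.edf_total, abs=1e-5)
        # REML-optimised fits agree to optimizer tolerance
        a = AdditiveMixedModel(mixed_dataset, spec).fit()
        b = AdditiveMixedModel(mixed_dataset, spec).fit(force_dense=True)
        np.testing.assert_allclose(a.params, b.params, atol=1e-4)
        assert a.sigma_u == pytest.approx(b.sigma_u, rel=1e-3)

    def test_unpenalized_model_equals_ols(self, mixed_dataset):
        spec = ModelSpec("y", [linear_term("x")])
        res = AdditiveMixedModel(mixed_dataset, spec).fit()
        X = np.column_stack([np.ones(len(mixed_dataset)), mixed_dataset["x"]])
        beta = np.linalg.lstsq(X, mixed_dataset["y"], rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_duplicate_column_raises_named_error(self, mixed_dataset):
        df = mixed_dataset.assign(x2=mixed_dataset["x"])
        spec = ModelSpec("y", [linear_term("x"), linear_term("x2")])
        with pytest.raises(RankDeficiencyError, match="x2"):
            AdditiveMixedModel(df, spec).fit()

    def test_determinism(self, mixed_dataset):
        spec = ModelSpec("y", [smooth_term("x"), random_intercept_term("child_id")])
        a = AdditiveMixedModel(mixed_dataset, spec).fit()
        b = AdditiveMixedModel(mixed_dataset, spec).fit()
        assert a.aic == b.aic
        assert a.reml == b.reml

    def test_projected_gradient_small_at_interior_optimum(self):
        """REML gradient norm at convergence (away from the box bounds)."""
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 6, 500)
        g = np.repeat(np.arange(50), 10)
        u = rng.normal(0, 1.0, 50)
        y = np.sin(x) + u[g] + rng.normal(0, 0.4, 500)
        df = pd.DataFrame({"y": y, "x": x, "child_id": [f"c{i}" for i in g]})
        spec = ModelSpec("y", [smooth_term("x"), random_intercept_term("child_id")])
        res = AdditiveMixedModel(df, spec).fit()
        assert np.all(np.abs(res.rho) < 17)  # interior
        assert np.abs(res.reml_grad).max() < 1e-4

    def test_reml_score_decreases_from_start(self, mixed_dataset):
        spec = ModelSpec("y", [smooth_term("x"), random_intercept_term("child_id")])
        m = AdditiveMixedModel(mixed_dataset, spec)
        res = m.fit()
        start = m._reml(np.zeros(len(res.rho)))[0]
        assert res.reml <= start + 1e-9


class TestInference:
    def test_ci_coverage_for_linear_terms(self):
        """95% Bayesian intervals achieve close to nominal coverage for a
        linear coefficient under the Gaussian generating model."""
        covered = 0
        reps = 150
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            g = np.repeat(np.arange(40), 4)
            x = rng.normal(size=160)
            u = rng.normal(0, 1.5, 40)
            y = 1.0 + 0.8 * x + u[g] + rng.normal(0, 1.0, 160)
            df = pd.DataFrame({"y": y, "x": x, "child_id": [f"c{i}" for i in g]})
            res = AdditiveMixedModel(
                df, ModelSpec("y", [linear_term("x"), random_intercept_term("child_id")])
            ).fit()
            lo, hi = res.conf_int().loc["x"]
            covered += lo <= 0.8 <= hi
        assert 0.91 <= covered / reps <= 0.99

    def test_univariable_null_covariate_ci_covers_zero(self):
        covered = 0
        for rep in range(40):
            rng = np.random.default_rng(2000 + rep)
            g = np.repeat(np.arange(40), 4)
            u = rng.normal(0, 1.5, 40)
            df = pd.DataFrame(
                {
                    "pct_sedentary": 50 + u[g] + rng.normal(0, 2.0, 160),
                    "z": rng.normal(size=160),
                    "child_id": [f"c{i}" for i in g],
                }
            )
            res = fit_univariable(df, "z")
            lo, hi = res.conf_int().loc["z"]
            covered += lo <= 0.0 <= hi
        assert covered >= 33  # ~95% nominal; binomial slack at 40 reps

    def test_univariable_recovers_planted_slope(self):
        rng = np.random.default_rng(11)
        g = np.repeat(np.arange(100), 6)
        x = rng.normal(22, 2.5, 600)
        u = rng.normal(0, 4.0, 100)
        y = 60 - 0.5 * x + u[g] + rng.normal(0, 4.5, 600)
        df = pd.DataFrame({"pct_sedentary": y, "x": x, "child_id": [f"c{i}" for i in g]})
        res = fit_univariable(df, "x")
        assert res.linear_coef("x") == pytest.approx(-0.5, abs=0.15)
        smo = fit_univariable(df, "x", smooth=True)
        assert smo.edf_by_term["s(x)"] == pytest.approx(1.0, abs=0.6)


class TestSmoothVsLinear:
    def _data(self, curvature, seed, n_groups=300, n_per=6):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_groups), n_per)
        t = rng.normal(22.1, 2.5, n_groups * n_per)
        u = rng.normal(0, 4.0, n_groups)
        y = 56 - 0.26 * (t - 22.1) + curvature * (t - 22.1) ** 2
        y = y + u[g] + rng.normal(0, 4.5, n_groups * n_per)
        return pd.DataFrame(
            {"pct_sedentary": y, "tmax": t, "child_id": [f"c{i:04d}" for i in g]}
        )

    @pytest.fixture
    def spec(self):
        return ModelSpec(
            "pct_sedentary", [linear_term("tmax"), random_intercept_term("child_id")]
        )

    def test_linear_truth_typically_prefers_linear(self, spec):
        """Median over replicates: EDF ~ 1 and near-identical AICs."""
        edfs, daics = [], []
        for seed in range(5):
            c = compare_smooth_vs_linear(self._data(0.0, 300 + seed), spec, "tmax")
            edfs.append(c["edf_smooth"])
            daics.append(abs(c["aic_smooth"] - c["aic_linear"]))
        assert np.median(edfs) == pytest.approx(1.0, abs=0.1)
        assert np.median(daics) < 2.0

    def test_material_false_curvature_rate_is_low(self, spec):
        """Strong spurious preference for the smooth (AIC improvement
        beyond the conventional 2-point evidence threshold) stays rare
        under linear truth."""
        strong = 0
        reps = 12
        for seed in range(reps):
            c = compare_smooth_vs_linear(self._data(0.0, 400 + seed), spec, "tmax")
            strong += (c["aic_linear"] - c["aic_smooth"]) > 2.0
        assert strong <= 3

    def test_quadratic_truth_prefers_smooth_decisively(self, spec):
        c = compare_smooth_vs_linear(self._data(0.08, 77), spec, "tmax")
        assert c["preferred"] == "smooth"
        assert c["aic_linear"] - c["aic_smooth"] > 10
        assert c["edf_smooth"] > 1.5

    def test_tie_goes_to_linear(self, spec, mixed_dataset):
        df = self._data(0.0, 55)
        c = compare_smooth_vs_linear(df, spec, "tmax")
        if c["aic_smooth"] >= c["aic_linear"]:
            assert c["preferred"] == "linear"


class TestMinutesEquivalent:
    @pytest.mark.parametrize(
        "coef, expected",
        [(-0.26, -2.2), (0.0, 0.0), (-0.27, -2.29)],
    )
    def test_printed_conversions(self, coef, expected):
        got = minutes_equivalent(coef, MEAN_AWAKE_MIN)
        assert got == pytest.approx(expected, abs=0.05)

    def test_sign_preserved(self):
        assert minutes_equivalent(0.5, 800) > 0
        assert minutes_equivalent(-0.5, 800) < 0

    def test_invalid_awake_time(self):
        with pytest.raises(ValueError):
            minutes_equivalent(-0.26, 0.0)


def test_against_mgcv_reference():
    """Independent cross-check: mgcv's gam() with a thin plate smooth and
    a random-effect smooth on the same data gives the same linear
    coefficient and variance components (different bases, so estimates
    agree to modelling — not numerical — precision)."""
    rng = np.random.default_rng(42)
    n_g, n_per = 120, 6
    g = np.repeat(np.arange(n_g), n_per)
    x = rng.normal(22, 2.5, n_g * n_per)
    r = rng.uniform(0, 10, n_g * n_per)
    u = rng.normal(0, 3.0, n_g)
    y = 50 - 0.3 * x + 0.5 * np.sin(r) + u[g] + rng.normal(0, 2.0, n_g * n_per)
    df = pd.DataFrame(
        {"y": y, "x": x, "r": r, "child_id": [f"c{i:03d}" for i in g]}
    )
    spec = ModelSpec(
        "y",
        [linear_term("x"), smooth_term("r", k=10), random_intercept_term("child_id")],
    )
    mine = AdditiveMixedModel(df, spec).fit()

    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        csv = os.path.join(td, "d.csv")
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(mgcv))
            d <- read.csv("{csv}")
            d$child_id <- factor(d$child_id)
            m <- gam(y ~ x + s(r, k=10, bs="tp") + s(child_id, bs="re"),
                     data=d, method="REML")
            vc <- gam.vcomp(m)
            cat(coef(m)["x"], sqrt(m$sig2), vc["s(child_id)", 1], sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        beta_x, sigma_e, sigma_u = map(float, out.stdout.strip().split("\n")[-3:])
    assert mine.linear_coef("x") == pytest.approx(beta_x, abs=0.01)
    assert np.sqrt(mine.scale) == pytest.approx(sigma_e, rel=0.03)
    assert mine.sigma_u == pytest.approx(sigma_u, rel=0.05)
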