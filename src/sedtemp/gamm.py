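"""Penalized-spline Gaussian additive mixed models.

The model is

    y_ij = alpha + u_j + beta' x_ij + f_1(v_ij) + ... + f_M(v_ij) + e_ij

with participant random intercepts u_j ~ N(0, sigma_u^2), Gaussian
day-level residuals e_ij ~ N(0, sigma^2), linear covariates x, and smooth
functions f represented by penalized spline bases (thin plate, cyclic
cubic, or a 2-D thin plate surface for residential location). Random
intercepts are estimated as a ridge-penalized block of indicator columns,
which is exactly the Gaussian mixed-model formulation with
sigma_u^2 = sigma^2 / lambda_u.

All smoothing parameters (including the random-intercept precision) are
chosen by restricted maximum likelihood: the REML score is minimised over
log-smoothing-parameters by quasi-Newton (L-BFGS-B) with an analytic
gradient. GCV is available as an alternative criterion.

The public surface follows the statsmodels convention: build an
:class:`AdditiveMixedModel` from a DataFrame and a :class:`ModelSpec`,
call :meth:`~AdditiveMixedModel.fit`, and read estimates, Bayesian
credible intervals, per-term effective degrees of freedom, variance
components and AIC off the returned :class:`GAMMResults`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .bases import CyclicCubicBasis, ThinPlateBasis1D, ThinPlateBasis2D

__all__ = [
    "TermSpec",
    "ModelSpec",
    "AdditiveMixedModel",
    "GAMMResults",
    "linear_term",
    "smooth_term",
    "cyclic_term",
    "spatial_term",
    "random_intercept_term",
    "sedentary_model_spec",
    "fit_univariable",
    "compare_smooth_vs_linear",
    "minutes_equivalent",
    "ConvergenceError",
    "RankDeficiencyError",
]

TEMPERATURE_METRICS = ("tmax", "tmean", "tmin", "diurnal")


class ConvergenceError(RuntimeError):
    """Smoothing-parameter optimisation failed; carries last diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design is rank deficient; names the aliased columns."""


@dataclasses.dataclass(frozen=True)
class TermSpec:
    """One model term.

    kind is one of linear, smooth_1d, smooth_cyclic, smooth_2d,
    random_intercept. ``k`` is the basis dimension for smooths; ``ref``
    the reference level for categorical linear terms; lower/upper the
    cyclic period (day-of-year wraps at 366 so leap years close the
    circle).
    """

    name: str
    kind: Literal["linear", "smooth_1d", "smooth_cyclic", "smooth_2d", "random_intercept"]
    variables: tuple[str, ...]
    k: int | None = None
    ref: str | None = None
    lower: float = 1.0
    upper: float = 366.0


def linear_term(var: str, ref: str | None = None) -> TermSpec:
    return TermSpec(var, "linear", (var,), ref=ref)


def smooth_term(var: str, k: int = 10) -> TermSpec:
    return TermSpec(f"s({var})", "smooth_1d", (var,), k=k)


def cyclic_term(var: str, k: int = 10, lower: float = 1.0, upper: float = 366.0) -> TermSpec:
    if k < 4:
        raise ValueError("cyclic smooth needs k >= 4")
    return TermSpec(f"s({var},cc)", "smooth_cyclic", (var,), k=k, lower=lower, upper=upper)


def spatial_term(xvar: str, yvar: str, k: int = 30) -> TermSpec:
    return TermSpec(f"s({xvar},{yvar})", "smooth_2d", (xvar, yvar), k=k)


def random_intercept_term(group: str) -> TermSpec:
    return TermSpec(f"s({group},re)", "random_intercept", (group,))


@dataclasses.dataclass
class ModelSpec:
    """Declarative description of one additive mixed model."""

    response: str
    terms: list[TermSpec]
    name: str = ""

    def replace_term(self, old_name: str, new_term: TermSpec) -> "ModelSpec":
        terms = [new_term if t.name == old_name else t for t in self.terms]
        if all(t is not new_term for t in terms):
            raise KeyError(f"no term named {old_name!r}")
        return ModelSpec(self.response, terms, self.name)

    def term(self, name: str) -> TermSpec:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")


def sedentary_model_spec(
    metric: str = "tmax",
    *,
    ndvi_col: str = "ndvi",
    k_smooth: int = 10,
    k_day: int = 10,
    k_spatial: int = 30,
    bmi: Literal["auto", "linear", "smooth"] = "auto",
) -> ModelSpec:
    """The study's model for one temperature metric.

    Exactly one temperature metric enters per model (the four metrics are
    highly correlated). BMI z-score enters as a thin plate smooth in the
    diurnal-variation model and linearly otherwise; all other covariates
    follow the reference specification: NDVI, daylight and sleep linear,
    sex / maternal education / day type categorical, thin plate smooths
    for rain and age, a cyclic cubic smooth for day of year, a 2-D thin
    plate surface for home location, and child random intercepts.
    """
    if metric not in TEMPERATURE_METRICS:
        raise ValueError(f"temperature metric must be one of {TEMPERATURE_METRICS}")
    if bmi == "auto":
        bmi = "smooth" if metric == "diurnal" else "linear"
    terms = [
        linear_term(metric),
        linear_term(ndvi_col),
        linear_term("daylight_hours"),
        linear_term("sleep_minutes"),
        (smooth_term("bmi_z", k=k_smooth) if bmi == "smooth" else linear_term("bmi_z")),
        linear_term("sex", ref="male"),
        linear_term("maternal_edu", ref="less_than_HS"),
        linear_term("day_type", ref="school_day"),
        smooth_term("precip_mm", k=k_smooth),
        smooth_term("age", k=k_smooth),
        cyclic_term("day_of_year", k=k_day, lower=1.0, upper=366.0),
        spatial_term("home_lon", "home_lat", k=k_spatial),
        random_intercept_term("child_id"),
    ]
    return ModelSpec("pct_sedentary", terms, name=f"sedentary~{metric}")


@dataclasses.dataclass
class _PenaltyBlock:
    name: str
    sl: slice
    S: np.ndarray
    rank: int
    logdet: float


class AdditiveMixedModel:
    """Gaussian additive mixed model built from a tidy child-day frame.

    Rows with missing values in any referenced column are dropped
    (complete-case analysis); the count is available as ``n_dropped``.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        used = {spec.response}
        for t in spec.terms:
            used.update(t.variables)
        missing = used - set(data.columns)
        if missing:
            raise KeyError(f"data is missing columns {sorted(missing)}")
        frame = data.loc[:, sorted(used)].copy()
        keep = frame.notna().all(axis=1)
        self.n_dropped = int((~keep).sum())
        self.data = data.loc[keep].reset_index(drop=True)
        self.endog = self.data[spec.response].to_numpy(dtype=float)
        self.nobs = len(self.endog)

        cols: list[np.ndarray] = [np.ones((self.nobs, 1))]
        names: list[str] = ["(Intercept)"]
        self.term_slices: dict[str, slice] = {"(Intercept)": slice(0, 1)}
        self.bases: dict[str, object] = {}
        self._dummy_cols: dict[str, list[str]] = {}
        self.blocks: list[_PenaltyBlock] = []
        self.group_term: TermSpec | None = None
        pos = 1
        for t in spec.terms:
            if t.kind == "random_intercept":
                if self.group_term is not None:
                    raise ValueError("only one random-intercept term is supported")
                if self.data[t.variables[0]].nunique() < 2:
                    raise ValueError("random intercept needs >= 2 participants")
                self.group_term = t
                continue
            block = self._build_term(t)
            ncol = block.shape[1]
            cols.append(block)
            self.term_slices[t.name] = slice(pos, pos + ncol)
            if t.kind != "linear":
                basis = self.bases[t.name]
                self.blocks.append(
                    _PenaltyBlock(
                        t.name,
                        slice(pos, pos + ncol),
                        basis.penalty,
                        basis.penalty_rank,
                        basis.penalty_logdet,
                    )
                )
                names.extend(f"{t.name}.{i+1}" for i in range(ncol))
            else:
                names.extend(self._dummy_cols.get(t.name, [t.name]))
            pos += ncol
        self.exog = np.hstack(cols)
        self.exog_names = names

        if self.group_term is not None:
            codes, levels = pd.factorize(
                self.data[self.group_term.variables[0]], sort=True
            )
            self.group_codes = codes
            self.group_levels = levels
        else:
            self.group_codes = None
            self.group_levels = None

    # -- design -----------------------------------------------------------
    def _build_term(self, t: TermSpec) -> np.ndarray:
        if t.kind == "linear":
            col = self.data[t.variables[0]]
            if t.ref is not None or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype
            ):
                levels = sorted(col.astype(str).unique())
                ref = t.ref if t.ref is not None else levels[0]
                if ref not in levels:
                    raise ValueError(
                        f"reference level {ref!r} absent from {t.variables[0]!r}"
                    )
                keep = [lv for lv in levels if lv != ref]
                block = np.column_stack(
                    [(col.astype(str) == lv).to_numpy(float) for lv in keep]
                ) if keep else np.empty((len(col), 0))
                self._dummy_cols[t.name] = [f"{t.variables[0]}[{lv}]" for lv in keep]
                return block
            return col.to_numpy(dtype=float).reshape(-1, 1)
        if t.kind == "smooth_1d":
            basis = ThinPlateBasis1D(self.data[t.variables[0]].to_numpy(float), k=t.k or 10)
        elif t.kind == "smooth_cyclic":
            basis = CyclicCubicBasis(
                self.data[t.variables[0]].to_numpy(float),
                k=t.k or 10,
                lower=t.lower,
                upper=t.upper,
            )
        elif t.kind == "smooth_2d":
            basis = ThinPlateBasis2D(
                self.data[t.variables[0]].to_numpy(float),
                self.data[t.variables[1]].to_numpy(float),
                k=t.k or 30,
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown term kind {t.kind!r}")
        self.bases[t.name] = basis
        return basis.design

    # -- penalized least squares machinery --------------------------------
    def _prepare(self, force_dense: bool):
        X, y = self.exog, self.endog
        self._dense = force_dense or self.group_codes is None
        if self._dense and self.group_codes is not None:
            g = len(self.group_levels)
            Z = np.zeros((self.nobs, g))
            Z[np.arange(self.nobs), self.group_codes] = 1.0
            Xf = np.hstack([X, Z])
            blocks = list(self.blocks)
            sl = slice(X.shape[1], X.shape[1] + g)
            blocks.append(_PenaltyBlock(self.group_term.name, sl, np.eye(g), g, 0.0))
            self._X = Xf
            self._blocks = blocks
            self._has_random_special = False
        else:
            self._X = X
            self._blocks = list(self.blocks)
            self._has_random_special = self.group_codes is not None
        self._XtX = self._X.T @ self._X
        self._Xty = self._X.T @ y
        self._yty = float(y @ y)
        # Tiny fixed ridge: keeps the normal equations well posed under
        # concurvity (e.g. daylight is a smooth function of day of year).
        # It is constant in the smoothing parameters, so REML gradients
        # remain exact, and it sits ~8 orders below the data scale.
        self._ridge = 1e-8 * float(np.mean(np.diag(self._XtX)))
        # rank check on the unpenalized columns only (penalized blocks may
        # be design-singular; their penalties make the problem well posed)
        unpen = np.ones(self._X.shape[1], dtype=bool)
        for blk in self._blocks:
            pen_cols = np.diag(blk.S) > 0
            unpen[blk.sl] = ~pen_cols
        Xu = self._X[:, unpen]
        if 0 < Xu.shape[1] <= 512:
            norms = np.linalg.norm(Xu, axis=0)
            sv = np.linalg.svd(Xu / np.where(norms > 0, norms, 1.0), compute_uv=False)
            if sv[-1] < 1e-10 * sv[0]:
                raise RankDeficiencyError(
                    "design is rank deficient; aliased columns: "
                    + ", ".join(self._aliased_columns())
                )
        if self._has_random_special:
            g = len(self.group_levels)
            self._g = g
            self._counts = np.bincount(self.group_codes, minlength=g).astype(float)
            self._Zty = np.bincount(self.group_codes, weights=y, minlength=g)
            B = np.zeros((self._X.shape[1], g))
            for j in range(self._X.shape[1]):
                B[j] = np.bincount(self.group_codes, weights=self._X[:, j], minlength=g)
            self._B = B
        self._n_lam = len(self._blocks) + (1 if self._has_random_special else 0)
        # unpenalized coefficient count (null space of the total penalty)
        p_total = self._X.shape[1] + (self._g if self._has_random_special else 0)
        pen_rank = sum(b.rank for b in self._blocks) + (
            self._g if self._has_random_special else 0
        )
        self._M_p = p_total - pen_rank

    def _chol(self, M: np.ndarray):
        jitter = 0.0
        base = np.mean(np.diag(M))
        for _ in range(6):
            try:
                return scipy.linalg.cho_factor(
                    M + (jitter * np.eye(M.shape[0]) if jitter else 0.0), lower=True
                )
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-12 * base)
        raise RankDeficiencyError(
            "penalized normal equations are singular; aliased columns: "
            + ", ".join(self._aliased_columns())
        )

    def _aliased_columns(self) -> list[str]:
        norms = np.linalg.norm(self._X, axis=0)
        R = np.linalg.qr(self._X / np.where(norms > 0, norms, 1.0), mode="r")
        d = np.abs(np.diag(R))
        bad = d < d.max() * 1e-9
        names = list(self.exog_names)
        if self.group_term is not None and self._X.shape[1] > len(names):
            names += [f"{self.group_term.name}.{i}" for i in range(len(self.group_levels))]
        return [names[i] for i in np.flatnonzero(bad)]

    def _solve(self, rho: np.ndarray):
        """Penalized normal-equation solve at log-smoothing rho.

        Returns a dict of everything the REML score, its gradient and the
        final results need.
        """
        lam = np.exp(rho)
        p = self._X.shape[1]
        S_f = np.diag(np.full(p, self._ridge))
        for i, blk in enumerate(self._blocks):
            S_f[blk.sl, blk.sl] += lam[i] * blk.S
        out = {"lam": lam}
        if self._has_random_special:
            lam_u = lam[-1]
            D = self._counts + lam_u
            BD = self._B / D
            M = self._XtX + S_f - BD @ self._B.T
            cf = self._chol(M)
            rhs = self._Xty - BD @ self._Zty
            beta = scipy.linalg.cho_solve(cf, rhs)
            u = (self._Zty - self._B.T @ beta) / D
            rss_p = self._yty - beta @ self._Xty - u @ self._Zty
            logdetA = 2.0 * np.log(np.diag(cf[0])).sum() + np.log(D).sum()
            T1 = scipy.linalg.solve_triangular(cf[0], self._B, lower=True)
            colsq = (T1**2).sum(axis=0)  # diag of B' M^-1 B
            out.update(M_chol=cf, beta=beta, u=u, D=D, colsq=colsq, lam_u=lam_u)
        else:
            M = self._XtX + S_f
            cf = self._chol(M)
            beta = scipy.linalg.cho_solve(cf, self._Xty)
            rss_p = self._yty - beta @ self._Xty
            logdetA = 2.0 * np.log(np.diag(cf[0])).sum()
            out.update(M_chol=cf, beta=beta, u=None)
        out.update(rss_p=max(float(rss_p), 1e-300), logdetA=float(logdetA), S_f=S_f)
        return out

    def _reml(self, rho: np.ndarray):
        """REML score (negative restricted log-likelihood) and gradient."""
        sol = self._solve(rho)
        n_eff = self.nobs - self._M_p
        sigma2 = sol["rss_p"] / n_eff
        logdetS = 0.0
        for i, blk in enumerate(self._blocks):
            logdetS += blk.rank * rho[i] + blk.logdet
        if self._has_random_special:
            logdetS += self._g * rho[-1]
        score = (
            0.5 * n_eff * (np.log(2 * np.pi * sigma2) + 1.0)
            + 0.5 * sol["logdetA"]
            - 0.5 * logdetS
        )
        grad = np.zeros_like(rho)
        cf = sol["M_chol"]
        beta = sol["beta"]
        for i, blk in enumerate(self._blocks):
            b = beta[blk.sl]
            quad = float(b @ blk.S @ b)
            ncol = blk.sl.stop - blk.sl.start
            E = np.zeros((self._X.shape[1], ncol))
            E[blk.sl] = np.eye(ncol)
            Minv_cols = scipy.linalg.cho_solve(cf, E)
            tr = float(np.sum(Minv_cols[blk.sl] * blk.S.T))
            lam_i = sol["lam"][i]
            grad[i] = 0.5 * lam_i * quad / sigma2 + 0.5 * lam_i * tr - 0.5 * blk.rank
        if self._has_random_special:
            D, colsq = sol["D"], sol["colsq"]
            quad = float(sol["u"] @ sol["u"])
            tr = float(np.sum(1.0 / D) + np.sum(colsq / D**2))
            lam_u = sol["lam_u"]
            grad[-1] = 0.5 * lam_u * quad / sigma2 + 0.5 * lam_u * tr - 0.5 * self._g
        return float(score), grad, sol, sigma2

    def _gcv(self, rho: np.ndarray, gamma: float = 1.0):
        sol = self._solve(rho)
        edf = self._edf_total(sol)
        rss = self._rss(sol)
        n = self.nobs
        denom = max(n - gamma * edf, 1e-8)
        return n * rss / denom**2

    def _rss(self, sol) -> float:
        fitted = self._X @ sol["beta"]
        if self._has_random_special:
            fitted = fitted + sol["u"][self.group_codes]
        return float(np.sum((self.endog - fitted) ** 2))

    def _edf_total(self, sol) -> float:
        return float(sum(self._edf_diag(sol)))

    def _edf_diag(self, sol) -> np.ndarray:
        """Diagonal of the hat-ish matrix F = A^-1 C'C over all coefficients."""
        cf = sol["M_chol"]
        p = self._X.shape[1]
        if self._has_random_special:
            D = sol["D"]
            G = self._XtX - (self._B / D) @ self._B.T
            diag_fixed = np.diag(scipy.linalg.cho_solve(cf, G))
            colsq = sol["colsq"]
            diag_rand = self._counts / D - colsq * sol["lam_u"] / D**2
            return np.concatenate([diag_fixed, diag_rand])
        return np.diag(scipy.linalg.cho_solve(cf, self._XtX))

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        criterion: Literal["reml", "gcv"] = "reml",
        maxiter: int = 200,
        tol: float = 1e-8,
        force_dense: bool = False,
        rho0: np.ndarray | None = None,
        fixed_rho: np.ndarray | None = None,
    ) -> "GAMMResults":
        """Estimate the model.

        ``fixed_rho`` skips smoothing-parameter selection and fits at the
        given log smoothing parameters (one per penalty, the random
        intercept's last).
        """
        self._prepare(force_dense)
        bounds = [(-18.0, 22.0)] * self._n_lam
        if fixed_rho is not None:
            rho_hat = np.broadcast_to(
                np.asarray(fixed_rho, float), (self._n_lam,)
            ).copy()
            opt = None
        elif self._n_lam == 0:
            rho_hat = np.empty(0)
            opt = None
        else:
            x0 = np.zeros(self._n_lam) if rho0 is None else np.asarray(rho0, float)
            if criterion == "reml":
                fun = lambda r: self._reml(r)[:2]
                opt = scipy.optimize.minimize(
                    fun,
                    x0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
                )
            elif criterion == "gcv":
                opt = scipy.optimize.minimize(
                    self._gcv,
                    x0,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": tol},
                )
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            if not opt.success and "ABNORMAL" in str(opt.message).upper():
                raise ConvergenceError(
                    f"smoothing-parameter optimisation failed: {opt.message}",
                    diagnostics={"rho": opt.x, "criterion": criterion},
                )
            rho_hat = opt.x
        return GAMMResults(self, rho_hat, criterion, opt)


class GAMMResults:
    """Fitted additive mixed model.

    Exposes coefficient estimates with Bayesian (posterior) standard
    errors and 95% intervals, per-term effective degrees of freedom,
    smoothing parameters, variance components, REML score, AIC, adjusted
    R^2, fitted values and residuals, plus ``summary()`` and
    ``predict()``.
    """

    def __init__(self, model: AdditiveMixedModel, rho: np.ndarray, criterion, opt):
        self.model = model
        self.rho = np.asarray(rho, float)
        self.criterion = criterion
        self.optimize_result = opt
        if len(self.rho):
            score, grad, sol, sigma2 = model._reml(self.rho)
        else:
            score, grad, sol, sigma2 = self._unpenalized(model)
        self.reml = score
        self.reml_grad = grad
        self.scale = sigma2  # REML residual variance estimate
        self._sol = sol
        n_fixed = len(model.exog_names)
        self.params = pd.Series(sol["beta"][:n_fixed], index=model.exog_names)
        cf = sol["M_chol"]
        Minv = scipy.linalg.cho_solve(cf, np.eye(model._X.shape[1]))
        cov = sigma2 * Minv[:n_fixed, :n_fixed]
        if len(self.rho) and self.criterion == "reml":
            # smoothing-parameter-uncertainty correction: the conditional
            # Bayesian covariance understates variability when smooths
            # compete with linear terms (concurvity); add J V_rho J' with
            # J = d beta / d log(lambda) and V_rho from the REML Hessian
            cov = cov + self._smoothing_uncertainty(model, sol, Minv)[:n_fixed, :n_fixed]
        self.cov_params = pd.DataFrame(
            cov, index=model.exog_names, columns=model.exog_names
        )
        self.bse = pd.Series(np.sqrt(np.diag(self.cov_params)), index=model.exog_names)

        diag_F = model._edf_diag(sol)
        self.edf_by_coef = diag_F[:n_fixed]
        self.edf_by_term = {}
        for name, sl in model.term_slices.items():
            self.edf_by_term[name] = float(self.edf_by_coef[sl].sum())
        if model.group_term is not None:
            self.edf_by_term[model.group_term.name] = float(diag_F[n_fixed:].sum())
        self.edf_total = float(diag_F.sum())

        self.fittedvalues = model._X @ sol["beta"]
        if model._has_random_special:
            self.random_effects = pd.Series(sol["u"], index=model.group_levels)
            self.fittedvalues = self.fittedvalues + sol["u"][model.group_codes]
            self.lambda_u = float(sol["lam_u"])
            self.sigma_u = float(np.sqrt(sigma2 / self.lambda_u))
        else:
            self.random_effects = None
            self.sigma_u = None
            # dense path: recover sigma_u if a random block was folded into X
            for i, blk in enumerate(model._blocks):
                if model.group_term is not None and blk.name == model.group_term.name:
                    self.lambda_u = float(np.exp(self.rho[i]))
                    self.sigma_u = float(np.sqrt(sigma2 / self.lambda_u))
                    sl = blk.sl
                    self.random_effects = pd.Series(
                        sol["beta"][sl], index=model.group_levels
                    )
        self.resid = model.endog - self.fittedvalues
        rss = float(self.resid @ self.resid)
        n = model.nobs
        sigma2_ml = rss / n
        self.llf = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
        self.aic = -2.0 * self.llf + 2.0 * (self.edf_total + 1.0)
        tss = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.rsquared_adj = 1.0 - (rss / max(n - self.edf_total, 1.0)) / (
            tss / (n - 1)
        )
        self.lambdas = {
            blk.name: float(np.exp(self.rho[i])) for i, blk in enumerate(model._blocks)
        }
        if model._has_random_special:
            self.lambdas[model.group_term.name] = float(sol["lam_u"])

    def _smoothing_uncertainty(self, model, sol, Minv):
        """First-order covariance inflation for estimated log-smoothing
        parameters (the analogue of mgcv's unconditional=TRUE)."""
        rho = self.rho
        k = len(rho)
        p = model._X.shape[1]
        # J columns: d beta_fixed / d rho_i = -lambda_i A^-1 S_i beta
        J = np.zeros((p, k))
        beta = sol["beta"]
        for i, blk in enumerate(model._blocks):
            v = np.zeros(p)
            v[blk.sl] = sol["lam"][i] * (blk.S @ beta[blk.sl])
            J[:, i] = -(Minv @ v)
        if model._has_random_special:
            vu = sol["lam_u"] * sol["u"] / sol["D"]
            J[:, -1] = Minv @ (model._B @ vu)
        # REML Hessian by forward differences of the analytic gradient
        interior = np.abs(rho) < 17.5
        H = np.zeros((k, k))
        g0 = self.reml_grad
        h = 1e-4
        for i in range(k):
            if not interior[i]:
                continue
            r = rho.copy()
            r[i] += h
            H[i] = (model._reml(r)[1] - g0) / h
        H = (H + H.T) / 2.0
        V_rho = np.zeros((k, k))
        idx = np.flatnonzero(interior)
        if len(idx):
            sub = H[np.ix_(idx, idx)]
            eigval, eigvec = np.linalg.eigh(sub)
            pos = eigval > 1e-8 * max(eigval.max(), 1.0)
            inv = (eigvec[:, pos] / eigval[pos]) @ eigvec[:, pos].T
            V_rho[np.ix_(idx, idx)] = inv
        return J @ V_rho @ J.T

    @staticmethod
    def _unpenalized(model):
        sol = model._solve(np.empty(0))
        n_eff = model.nobs - model._M_p
        sigma2 = sol["rss_p"] / n_eff
        score = 0.5 * n_eff * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * sol["logdetA"]
        return float(score), np.empty(0), sol, sigma2

    # -- inference ---------------------------------------------------------
    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    @property
    def pvalues(self) -> pd.Series:
        df = max(self.model.nobs - self.edf_total, 1.0)
        t = self.params / self.bse
        return pd.Series(
            2 * scipy.stats.t.sf(np.abs(t), df), index=self.params.index
        )

    def linear_coef(self, term: str) -> float:
        """Coefficient of a single-column linear term."""
        sl = self.model.term_slices[term]
        if sl.stop - sl.start != 1:
            raise ValueError(f"{term!r} is not a single-column linear term")
        return float(self.params.iloc[sl.start])

    def smooth_test(self, term: str) -> tuple[float, float]:
        """Approximate Wald F test of a smooth term (no exact reference
        distribution exists for penalized fits; treat p as indicative)."""
        sl = self.model.term_slices[term]
        b = self.params.iloc[sl].to_numpy()
        V = self.cov_params.iloc[sl, sl].to_numpy()
        r = max(1, int(round(self.edf_by_term[term])))
        stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
        F = stat / r
        df2 = max(self.model.nobs - self.edf_total, 1.0)
        p = float(scipy.stats.f.sf(F, r, df2))
        return F, p

    def term_effect(self, term: str, *values) -> np.ndarray:
        """Evaluate a fitted smooth at new covariate values (centred scale)."""
        basis = self.model.bases[term]
        sl = self.model.term_slices[term]
        return basis.transform(*values) @ self.params.iloc[sl].to_numpy()

    def predict(self, newdata: pd.DataFrame, include_random: bool = False) -> np.ndarray:
        model = self.model
        cols = [np.ones((len(newdata), 1))]
        for t in model.spec.terms:
            if t.kind == "random_intercept":
                continue
            if t.kind == "linear":
                if t.name in model._dummy_cols:
                    col = newdata[t.variables[0]].astype(str)
                    block = np.column_stack(
                        [
                            (col == name.split("[")[1][:-1]).to_numpy(float)
                            for name in model._dummy_cols[t.name]
                        ]
                    )
                else:
                    block = newdata[t.variables[0]].to_numpy(float).reshape(-1, 1)
            else:
                block = model.bases[t.name].transform(
                    *[newdata[v].to_numpy(float) for v in t.variables]
                )
            cols.append(block)
        X = np.hstack(cols)
        out = X @ self.params.to_numpy()
        if include_random and self.random_effects is not None:
            re = newdata[model.group_term.variables[0]].map(self.random_effects)
            out = out + re.fillna(0.0).to_numpy()
        return out

    def plot_smooths(self, terms: Sequence[str] | None = None, n_points: int = 200):
        """Quick diagnostic panels of the fitted 1-D smooths (centred
        scale) with pointwise 95% bands. Returns the matplotlib figure."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        model = self.model
        names = [
            t.name
            for t in model.spec.terms
            if t.kind in ("smooth_1d", "smooth_cyclic")
            and (terms is None or t.name in terms)
        ]
        fig, axes = plt.subplots(1, max(len(names), 1), figsize=(4 * max(len(names), 1), 3))
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, names):
            term = model.spec.term(name)
            var = term.variables[0]
            x = model.data[var].to_numpy(float)
            grid = np.linspace(x.min(), x.max(), n_points)
            B = model.bases[name].transform(grid)
            sl = model.term_slices[name]
            f = B @ self.params.iloc[sl].to_numpy()
            V = self.cov_params.iloc[sl, sl].to_numpy()
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
            ax.plot(grid, f, color="C0")
            ax.fill_between(grid, f - 1.96 * se, f + 1.96 * se, alpha=0.25, color="C0")
            ax.set_xlabel(var)
            ax.set_ylabel(f"{name} (EDF {self.edf_by_term[name]:.2f})")
        fig.tight_layout()
        return fig

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Additive mixed model: {self.model.spec.name or self.model.spec.response}",
            f"n = {self.model.nobs}, criterion = {self.criterion},"
            f" REML score = {self.reml:.4f}",
            f"scale (sigma^2) = {self.scale:.4f}"
            + (
                f", sigma_u = {self.sigma_u:.4f}" if self.sigma_u is not None else ""
            ),
            f"AIC = {self.aic:.2f}, adj. R^2 = {self.rsquared_adj:.3f},"
            f" total EDF = {self.edf_total:.2f}",
            "",
            "Parametric terms:",
            f"{'term':<34}{'estimate':>10}{'SE':>9}{'95% CI':>22}{'p':>9}",
        ]
        ci = self.conf_int()
        pv = self.pvalues
        smooth_names = set(self.model.bases)
        for name, sl in self.model.term_slices.items():
            if name in smooth_names:
                continue
            for i in range(sl.start, sl.stop):
                cname = self.model.exog_names[i]
                lines.append(
                    f"{cname:<34}{self.params.iloc[i]:>10.4f}{self.bse.iloc[i]:>9.4f}"
                    f"   ({ci.iloc[i, 0]:>7.3f}, {ci.iloc[i, 1]:>7.3f})"
                    f"{pv.iloc[i]:>9.3g}"
                )
        lines += ["", "Smooth terms:", f"{'term':<34}{'EDF':>8}{'F':>10}{'p':>9}"]
        for name in self.model.bases:
            F, p = self.smooth_test(name)
            lines.append(f"{name:<34}{self.edf_by_term[name]:>8.3f}{F:>10.3f}{p:>9.3g}")
        if self.sigma_u is not None:
            gname = self.model.group_term.name
            lines.append(
                f"{gname:<34}{self.edf_by_term.get(gname, float('nan')):>8.1f}"
                f"   sigma_u = {self.sigma_u:.3f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient report (one row per parametric coefficient)."""
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "p": self.pvalues,
            }
        )


# ---------------------------------------------------------------------------
# Higher-level operations
# ---------------------------------------------------------------------------

def fit_univariable(
    data: pd.DataFrame,
    covariate: str,
    response: str = "pct_sedentary",
    group: str = "child_id",
    smooth: bool = False,
    k: int = 10,
    criterion: str = "reml",
) -> GAMMResults:
    """Single-covariate model with a participant random intercept."""
    term = smooth_term(covariate, k=k) if smooth else linear_term(covariate)
    spec = ModelSpec(response, [term, random_intercept_term(group)],
                     name=f"{response}~{covariate}")
    return AdditiveMixedModel(data, spec).fit(criterion=criterion)


def compare_smooth_vs_linear(
    data: pd.DataFrame,
    spec: ModelSpec,
    term_name: str,
    k: int = 10,
    criterion: str = "reml",
) -> dict:
    """AIC comparison of a smooth vs a linear version of one term.

    Ties (or equal AIC) prefer the linear model. Also reports the EDF of
    the smooth variant's term: under a truly linear relationship REML
    shrinks the smooth to its linear null space and the EDF approaches 1.
    """
    base = spec.term(term_name)
    var = base.variables[0]
    spec_lin = spec.replace_term(term_name, linear_term(var)) if base.kind != "linear" else spec
    spec_smo = (
        spec.replace_term(term_name, smooth_term(var, k=k))
        if base.kind != "smooth_1d"
        else spec
    )
    res_lin = AdditiveMixedModel(data, spec_lin).fit(criterion=criterion)
    res_smo = AdditiveMixedModel(data, spec_smo).fit(criterion=criterion)
    smooth_name = f"s({var})"
    return {
        "aic_linear": res_lin.aic,
        "aic_smooth": res_smo.aic,
        "edf_smooth": res_smo.edf_by_term[smooth_name],
        "preferred": "smooth" if res_smo.aic < res_lin.aic else "linear",
        "results_linear": res_lin,
        "results_smooth": res_smo,
    }


def minutes_equivalent(coef_pct_per_unit: float, mean_awake_minutes: float) -> float:
    """Convert a percent-of-awake-time coefficient to minutes per unit.

    A coefficient of -0.26 %/degC with 846.4 mean awake minutes is about
    -2.2 minutes of sedentary time per degree.
    """
    if mean_awake_minutes <= 0:
        raise ValueError("mean_awake_minutes must be positive")
    return coef_pct_per_unit / 100.0 * mean_awake_minutes
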