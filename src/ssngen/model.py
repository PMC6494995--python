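"""Spatial stream-network linear mixed models.

The model is y = Xβ + ε with Cov(ε) = Σ(θ), a mixture of tail-up,
tail-down and Euclidean autocovariances plus a nugget.  β is profiled out
by generalized least squares, and θ (log sills, log ranges, log nugget)
is maximised numerically by ML or REML from a deterministic multi-start
grid.  The fitted object exposes the quantities a stream-network analysis
reports: coefficient table with Wald t tests, AIC (on the ML likelihood),
leave-one-out universal-kriging predictions and their RMSPE, and the
variance decomposition into an R² for the fixed effects and per-component
shares of the residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .covariance import CovarianceSpec, correlation_matrix, mixture_matrix
from .network import DistanceSet

__all__ = ["SSNRegressor", "fit_ssn", "loocv_rmspe", "variance_decomposition", "vif"]

_RIDGE = 1e-8


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _safe_cholesky(S: np.ndarray):
    """Cholesky with an escalating diagonal ridge for ill-conditioned Σ."""
    tr = np.trace(S)
    jitter = 0.0
    for _ in range(6):
        try:
            return linalg.cholesky(S + jitter * np.eye(len(S)), lower=True)
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, _RIDGE * tr)
    raise linalg.LinAlgError("covariance matrix not positive definite even after ridging")


def _gls(L: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS pieces given the Cholesky factor of Σ."""
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtSiX = Xw.T @ Xw
    beta = linalg.solve(XtSiX, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    return beta, XtSiX, float(resid @ resid), Xw, yw


def _neg2loglik(S, X, y, reml: bool):
    n, p = X.shape
    L = _safe_cholesky(S)
    beta, XtSiX, rss, _, _ = _gls(L, X, y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    if reml:
        sign, logdet_x = np.linalg.slogdet(XtSiX)
        if sign <= 0:
            return np.inf, beta
        val = (n - p) * np.log(2 * np.pi) + logdet + logdet_x + rss
    else:
        val = n * np.log(2 * np.pi) + logdet + rss
    return val, beta


@dataclass
class _Prepared:
    """Distance-derived quantities reused across optimizer evaluations."""

    dset: DistanceSet
    stream_scale: float     # typical/maximal finite in-stream distance
    euclid_scale: float

    @classmethod
    def from_dset(cls, dset: DistanceSet) -> "_Prepared":
        h = dset.h
        finite = h[np.isfinite(h) & (h > 0)]
        hscale = float(finite.max()) if finite.size else 1.0
        e = dset.E[dset.E > 0]
        escale = float(e.max()) if e.size else 1.0
        return cls(dset, hscale, escale)


class SSNRegressor(BaseEstimator):
    """Gaussian stream-network regression with a mixed covariance structure.

    Parameters
    ----------
    skeleton : CovarianceSpec
        Names the components to fit; sills/ranges in it are ignored and
        re-estimated.  An empty skeleton (no components) is the
        nugget-only model, which reduces to ordinary least squares.
    method : {'REML', 'ML'}
        Objective for the covariance parameters.
    fit_intercept : bool
        Prepend a column of ones to X.
    n_starts : int
        Optimizer restarts kept from the deterministic starting grid.
    maxiter : int
        L-BFGS-B iteration cap per start.

    Attributes (after fit)
    ----------------------
    beta_, beta_se_, beta_t_, beta_pvalues_ : coefficient table arrays
    spec_ : fitted CovarianceSpec (sills, ranges, nugget)
    loglik_ : maximised log-likelihood of `method`
    aic_ : −2·loglik_ML(θ̂) + 2·(p + covariance parameters)
    loocv_, rmspe_ : leave-one-out kriging predictions and their RMSPE
    r2_, varcomp_ : fixed-effect share and per-component variance shares
    objective_trace_ : accepted objective values (monotone non-increasing)
    range_at_bound_ : True when a fitted range hit its box bound
    """

    def __init__(
        self,
        skeleton: CovarianceSpec | None = None,
        method: str = "REML",
        fit_intercept: bool = True,
        n_starts: int = 3,
        maxiter: int = 200,
    ):
        self.skeleton = skeleton
        self.method = method
        self.fit_intercept = fit_intercept
        self.n_starts = n_starts
        self.maxiter = maxiter

    # ------------------------------------------------------------- fitting

    def fit(self, X, y, dset: DistanceSet):
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1) if X.size else np.empty((len(y), 0))
        Xd = _add_intercept(X) if self.fit_intercept else X.copy()
        n, p = Xd.shape
        if len(dset) != n or len(y) != n:
            raise ValueError("X, y and dset must agree in length and order")
        if np.linalg.matrix_rank(Xd) < p:
            raise ValueError("design matrix is singular")
        if n <= p:
            raise ValueError("need more observations than fixed-effect parameters")
        skeleton = self.skeleton if self.skeleton is not None else CovarianceSpec()
        reml = self.method == "REML"

        prep = _Prepared.from_dset(dset)
        comps = skeleton.components
        k = len(comps)
        var_y = float(np.var(y, ddof=1)) if n > 1 else 1.0
        var_y = max(var_y, 1e-12)

        if k == 0:
            self._fit_nugget_only(Xd, y, dset, reml, var_y)
            return self

        scales = np.array(
            [prep.euclid_scale if c.ctype == "euclidean" else prep.stream_scale for c in comps]
        )
        lo_r = np.log(1e-2)
        hi_r = np.log(10.0 * scales)
        bounds = (
            [(np.log(var_y * 1e-10), np.log(var_y * 1e6))] * k
            + list(zip([lo_r] * k, hi_r))
            + [(np.log(var_y * 1e-10), np.log(var_y * 1e6))]
        )

        def unpack(theta):
            sills = np.exp(theta[:k])
            ranges = np.exp(theta[k : 2 * k])
            nugget = np.exp(theta[2 * k])
            return skeleton.with_params(sills, ranges, nugget)

        def objective(theta):
            spec = unpack(theta)
            try:
                S = mixture_matrix(spec, dset)
                val, _ = _neg2loglik(S, Xd, y, reml)
            except (linalg.LinAlgError, FloatingPointError):
                return np.inf
            return val if np.isfinite(val) else np.inf

        # deterministic starting grid: 3 range quantiles per component,
        # equal variance split; pre-screen the cartesian grid, keep the best
        range_grid = [np.log(np.array([0.1, 0.5, 1.5]) * s) for s in scales]
        base_var = np.log(var_y / (k + 1))
        starts = []
        from itertools import product

        for combo in product(*range_grid):
            starts.append(np.array([base_var] * k + list(combo) + [base_var]))
        scored = sorted(((objective(s), tuple(s)) for s in starts), key=lambda t: t[0])
        keep = [np.array(s) for v, s in scored[: max(1, self.n_starts)] if np.isfinite(v)]
        if not keep:
            keep = [np.array([base_var] * k + [np.log(s) for s in scales] + [base_var])]

        best_val, best_theta, best_trace = np.inf, keep[0], [np.inf]
        for x0 in keep:
            trace = [objective(x0)]

            def cb(xk):
                trace.append(objective(xk))

            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                callback=cb,
                options={"maxiter": self.maxiter},
            )
            val = res.fun if np.isfinite(res.fun) else objective(res.x)
            if val < best_val:
                best_val, best_theta, best_trace = val, res.x, trace
        self.objective_trace_ = np.minimum.accumulate(np.asarray(best_trace))
        self.converged_ = bool(np.isfinite(best_val))
        spec = unpack(best_theta)
        self.range_at_bound_ = bool(
            np.any(np.isclose(best_theta[k : 2 * k], lo_r, atol=1e-6))
            or np.any(np.isclose(best_theta[k : 2 * k], hi_r, atol=1e-6))
        )
        self._finalize(spec, Xd, y, dset, reml)
        return self

    def _fit_nugget_only(self, Xd, y, dset, reml, var_y):
        n, p = Xd.shape
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rss = float(((y - Xd @ beta) ** 2).sum())
        sigma2 = rss / (n - p) if reml else rss / n
        sigma2 = max(sigma2, var_y * 1e-12)
        self.objective_trace_ = np.array([])
        self.converged_ = True
        self.range_at_bound_ = False
        self._finalize(CovarianceSpec(nugget=sigma2), Xd, y, dset, reml)

    def _finalize(self, spec: CovarianceSpec, Xd, y, dset, reml):
        n, p = Xd.shape
        S = mixture_matrix(spec, dset)
        L = _safe_cholesky(S)
        beta, XtSiX, rss, _, _ = _gls(L, Xd, y)
        val, _ = _neg2loglik(S, Xd, y, reml)
        val_ml, _ = _neg2loglik(S, Xd, y, False)
        cov_beta = linalg.inv(XtSiX)
        se = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df=max(n - p, 1))

        self.X_, self.y_, self.dset_ = Xd, y, dset
        self.spec_ = spec
        self.beta_ = beta
        self.beta_se_ = se
        self.beta_t_ = t
        self.beta_pvalues_ = pvals
        self.loglik_ = -0.5 * val
        self.loglik_ml_ = -0.5 * val_ml
        self.n_cov_params_ = spec.n_params
        self.aic_ = -2.0 * self.loglik_ml_ + 2.0 * (p + self.n_cov_params_)
        self.Sigma_ = S
        self.loocv_ = self._loocv_predictions()
        self.rmspe_ = float(np.sqrt(np.mean((y - self.loocv_) ** 2)))
        self.r2_, self.varcomp_ = self._decompose()

    # ---------------------------------------------------------- prediction

    def _loocv_predictions(self) -> np.ndarray:
        """Leave-one-out universal-kriging predictions with θ̂ held fixed.

        Uses the cross-validation identity for universal kriging: with
        Q = Σ⁻¹ − Σ⁻¹X(XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹ (the REML projection), the LOO
        residual at i is (Qy)_i / Q_ii, which equals the prediction error
        of the kriging predictor built from the other n−1 points.
        """
        S, X, y = self.Sigma_, self.X_, self.y_
        Si = linalg.inv(S)
        SiX = Si @ X
        Q = Si - SiX @ linalg.solve(X.T @ SiX, SiX.T, assume_a="pos")
        resid = (Q @ y) / np.diag(Q)
        return y - resid

    def loocv(self):
        """(predictions, rmspe) of the fitted model."""
        if len(self.y_) < 3:
            raise ValueError("leave-one-out cross-validation needs n >= 3")
        return self.loocv_, self.rmspe_

    def _decompose(self):
        y, X = self.y_, self.X_
        fitted = X @ self.beta_
        if np.std(fitted) <= 1e-12 * max(np.std(y), 1e-300) or np.std(y) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        total = sum(c.sill for c in self.spec_.components) + self.spec_.nugget
        shares = {}
        for c in self.spec_.components:
            shares[c.ctype] = (1.0 - r2) * c.sill / total if total > 0 else 0.0
        shares["nugget"] = (1.0 - r2) * self.spec_.nugget / total if total > 0 else 1.0 - r2
        return r2, shares

    def variance_decomposition(self):
        """(r2, shares): fixed-effect share and residual-variance split.

        r2 is the squared Pearson correlation between the GLS fitted
        values and y; the residual share of each covariance component is
        (1−r2)·σ²_c/(Σσ² + σ₀²), so r2 + Σ shares = 1.
        """
        return self.r2_, self.varcomp_

    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        p = len(self.beta_)
        if names is None:
            names = [f"x{i}" for i in range(p - self.fit_intercept)]
        labels = (["(intercept)"] if self.fit_intercept else []) + list(names)
        return pd.DataFrame(
            {
                "estimate": self.beta_,
                "std_error": self.beta_se_,
                "t": self.beta_t_,
                "p_value": self.beta_pvalues_,
            },
            index=labels,
        )


# ---------------------------------------------------------- thin wrappers

def fit_ssn(
    y,
    X,
    dset: DistanceSet,
    skeleton: CovarianceSpec | None = None,
    method: str = "REML",
    **controls,
) -> SSNRegressor:
    """Fit an SSN mixed model; functional wrapper over :class:`SSNRegressor`."""
    return SSNRegressor(skeleton=skeleton, method=method, **controls).fit(X, y, dset)


def loocv_rmspe(fit: SSNRegressor):
    return fit.loocv()


def variance_decomposition(fit: SSNRegressor):
    return fit.variance_decomposition()


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate, 1/(1−R²_j).

    Each covariate is regressed on the others (intercept included);
    perfectly collinear columns get an infinite sentinel with a warning.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    import statsmodels.api as sm

    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"covariate {col!r} is perfectly collinear; VIF set to inf")
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")
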