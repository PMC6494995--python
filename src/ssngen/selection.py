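"""Two-step model selection for stream-network mixed models.

Step 1 fixes a permissive covariance structure (exponential tail-up +
tail-down + Euclidean + nugget) and screens every subset of the candidate
covariates by maximum likelihood, ranking on AIC.  Step 2 fixes the
selected covariates and enumerates every combination of
{absent, 4 functions} for the tail-up, tail-down and Euclidean component
types — 5 × 5 × 5 = 125 candidate structures, the nugget always present —
fitting each by REML and ranking on leave-one-out RMSPE.  Comparing REML
fits with different fixed effects is invalid, which is why the covariates
are frozen before the covariance search.
"""

from __future__ import annotations

import warnings
from itertools import combinations, product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .covariance import (
    COMPONENT_TYPES,
    EUCLID_FUNCTIONS,
    STREAM_FUNCTIONS,
    CovarianceComponent,
    CovarianceSpec,
)
from .model import SSNRegressor
from .network import DistanceSet

__all__ = [
    "DEFAULT_STEP1_SKELETON",
    "enumerate_skeletons",
    "select_covariates",
    "select_covariance",
    "SSNModelSelector",
]

DEFAULT_STEP1_SKELETON = CovarianceSpec(
    components=(
        CovarianceComponent("tailup", "exponential"),
        CovarianceComponent("taildown", "exponential"),
        CovarianceComponent("euclidean", "exponential"),
    )
)


def enumerate_skeletons(components=COMPONENT_TYPES) -> list[CovarianceSpec]:
    """All covariance-structure skeletons over the enabled component types.

    Each enabled type contributes 5 choices (absent or one of its four
    autocovariance functions); the nugget is always present, and the
    all-absent combination is the nugget-only model.  With all three types
    this yields 125 candidates.
    """
    choices = []
    for ctype in components:
        fns = EUCLID_FUNCTIONS if ctype == "euclidean" else STREAM_FUNCTIONS
        choices.append([None] + [(ctype, fn) for fn in fns])
    specs = []
    for combo in product(*choices):
        comps = tuple(CovarianceComponent(c, f) for c, f in (x for x in combo if x))
        specs.append(CovarianceSpec(components=comps))
    return specs


def select_covariates(
    y,
    X_all: pd.DataFrame,
    dset: DistanceSet,
    fixed_skeleton: CovarianceSpec | None = None,
    **controls,
) -> pd.DataFrame:
    """Exhaustive ML/AIC screen of every covariate subset.

    All 2^k subsets (intercept always included) are fitted by ML with the
    fixed covariance skeleton; the result is ranked by AIC ascending, ties
    broken by fewer covariates then lexicographic names.  Rank-deficient
    subsets are skipped with a warning.
    """
    X_all = pd.DataFrame(X_all)
    names = list(X_all.columns)
    if len(names) > 12:
        raise ValueError("exhaustive screening supports at most 12 candidates")
    skeleton = DEFAULT_STEP1_SKELETON if fixed_skeleton is None else fixed_skeleton
    rows = []
    for size in range(len(names) + 1):
        for subset in combinations(names, size):
            sub = sorted(subset)
            X = X_all[sub].to_numpy() if sub else np.empty((len(X_all), 0))
            try:
                fit = SSNRegressor(skeleton=skeleton, method="ML", **controls).fit(X, y, dset)
            except ValueError as err:
                warnings.warn(f"skipping covariate subset {sub}: {err}")
                continue
            rows.append({"covariates": "+".join(sub) if sub else "(intercept)",
                         "k": len(sub), "aic": fit.aic_, "loglik_ml": fit.loglik_ml_})
    out = pd.DataFrame(rows)
    out = out.sort_values(["aic", "k", "covariates"], kind="stable").reset_index(drop=True)
    out.index.name = "rank"
    return out


def select_covariance(
    y,
    X_best: pd.DataFrame | np.ndarray,
    dset: DistanceSet,
    components=COMPONENT_TYPES,
    **controls,
):
    """REML fit of every covariance skeleton, ranked by LOOCV RMSPE.

    Returns ``(table, final_fit)``; non-convergent candidates are kept in
    the table with infinite RMSPE, and ties are broken by fewer covariance
    parameters then enumeration order.  The final model is the
    RMSPE-minimising REML fit.
    """
    X = pd.DataFrame(X_best).to_numpy() if not isinstance(X_best, np.ndarray) else X_best
    skeletons = enumerate_skeletons(components)
    rows, fits = [], []
    for order, skel in enumerate(skeletons):
        try:
            fit = SSNRegressor(skeleton=skel, method="REML", **controls).fit(X, y, dset)
            rmspe = fit.rmspe_ if np.isfinite(fit.rmspe_) else np.inf
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"candidate {skel.label()} failed to converge: {err}")
            fit, rmspe = None, np.inf
        fits.append(fit)
        rows.append(
            {
                "structure": skel.label(),
                "n_cov_params": skel.n_params,
                "order": order,
                "rmspe": rmspe,
                "aic": fit.aic_ if fit is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["rmspe", "n_cov_params", "order"], kind="stable"
    )
    best_ix = int(table.index[0])
    table = table.reset_index(drop=True)
    table.index.name = "rank"
    final = fits[best_ix]
    if final is None:
        raise RuntimeError("no covariance candidate converged")
    return table, final


class SSNModelSelector(BaseEstimator):
    """The full two-step selection as a single estimator.

    ``fit(X, y, dset)`` takes the candidate-covariate frame, runs the
    ML/AIC covariate screen with the fixed step-1 skeleton, freezes the
    AIC-best subset, then runs the REML/RMSPE covariance-structure search.

    Attributes: ``step1_`` and ``step2_`` ranking tables,
    ``best_covariates_``, and ``best_fit_`` (the final REML fit).
    """

    def __init__(self, components=COMPONENT_TYPES, step1_skeleton=None, **controls):
        self.components = components
        self.step1_skeleton = step1_skeleton
        self.controls = controls

    def fit(self, X, y, dset: DistanceSet):
        X = pd.DataFrame(X)
        self.step1_ = select_covariates(
            y, X, dset, fixed_skeleton=self.step1_skeleton, **self.controls
        )
        best = self.step1_.iloc[0]["covariates"]
        self.best_covariates_ = [] if best == "(intercept)" else best.split("+")
        X_best = X[self.best_covariates_]
        self.step2_, self.best_fit_ = select_covariance(
            y, X_best, dset, components=self.components, **self.controls
        )
        return self
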