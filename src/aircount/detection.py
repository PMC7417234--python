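"""Bernoulli models for detection, false-detection and duplicate probability.

Three logit-link models underpin the modified Horvitz-Thompson estimator:

* *detection* ``p_i`` — fitted on koalas that were either detected or
  missed (duplicates and false positives excluded), response Y = 1 for a
  detection; candidate covariates: ambient temperature, wind speed,
  distance to habitat edge;
* *false* ``f_i`` — fitted on all algorithm-identified objects (misses
  excluded), response W = 1 for a misidentified object; same candidates;
* *duplicate* ``d_i`` — fitted on verified koala detections only, response
  Z = 1 for a repeat record of an already-detected animal; candidates:
  distance to nearest detection, time since previous detection.

Fitting goes through statsmodels (binomial GLM; penalized-spline GAM with
GCV-chosen smoothing). Model selection is stepwise: univariate screens at a
p-value threshold, exhaustive combinations of the survivors, then an
additive (GAM) variant of the best linear model which is adopted only if it
lowers AIC by more than 2 points.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from sklearn.base import BaseEstimator
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "ROLE_COVARIATES",
    "PerfectSeparationError",
    "build_response",
    "LogisticDetector",
    "AdditiveLogisticDetector",
    "StepwiseSelector",
    "fit_logistic",
    "fit_additive",
    "stepwise_select",
    "mcfadden_r2",
    "predict_with_ci",
    "save_fit",
    "load_fit",
]

#: candidate covariates per model role
ROLE_COVARIATES = {
    "detection": ("temperature", "wind_speed", "dist_edge"),
    "false": ("temperature", "wind_speed", "dist_edge"),
    "duplicate": ("dist_nearest", "time_since_prev"),
}


class PerfectSeparationError(ValueError):
    """A covariate (or combination) separates the response perfectly."""


def build_response(table: pd.DataFrame, role: str):
    """Extract the binary response and design rows for one model role.

    Returns ``(y, X)`` where *y* is a 0/1 integer array and *X* a DataFrame
    of the role's candidate covariates, row-aligned with *y*.
    """
    if role == "detection":
        sub = table[table["klass"].isin(["unique_detection", "missed"])]
        y = (sub["klass"] == "unique_detection").to_numpy(dtype=int)
    elif role == "false":
        sub = table[table["klass"] != "missed"]
        y = (sub["klass"] == "false_positive").to_numpy(dtype=int)
    elif role == "duplicate":
        sub = table[table["klass"].isin(["unique_detection", "duplicate"])]
        y = (sub["klass"] == "duplicate").to_numpy(dtype=int)
    else:
        raise ValueError(f"unknown role {role!r}; expected detection, false or duplicate")
    cols = list(ROLE_COVARIATES[role])
    missing = [c for c in cols if c not in sub.columns or sub[c].isna().all()]
    if missing:
        raise ValueError(f"covariate(s) required for role {role!r} absent: {missing}")
    return y, sub[cols].reset_index(drop=True).astype(float)


def _check_separation(X: pd.DataFrame, y: np.ndarray, probs: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        return
    fitted_extreme = np.all((probs > 1 - 1e-8) == (y == 1)) and np.all(
        (probs < 1e-8) == (y == 0)
    )
    if not fitted_extreme:
        return
    culprit = "a linear combination of covariates"
    for c in X.columns:
        x0, x1 = X[c][y == 0], X[c][y == 1]
        if len(x0) and len(x1) and (x0.max() < x1.min() or x1.max() < x0.min()):
            culprit = repr(c)
            break
    raise PerfectSeparationError(f"perfect separation of the response by {culprit}")


class LogisticDetector(BaseEstimator):
    """Maximum-likelihood logistic regression for one Bernoulli model.

    Parameters
    ----------
    covariates : list of str or None
        Columns of the design frame to use; ``None`` means all columns and
        ``[]`` the intercept-only (null) model.
    role : str
        Informational tag (``detection``/``false``/``duplicate``).

    Fitted attributes (trailing underscore): ``coef_``, ``se_``,
    ``loglik_``, ``null_loglik_``, ``aic_``, ``deviance_``,
    ``null_deviance_``, ``pvalues_``, ``cov_``, ``nobs_``.
    """

    def __init__(self, covariates=None, role: str = "detection"):
        self.covariates = covariates
        self.role = role

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates_ if c not in X.columns]
        if missing:
            raise ValueError(f"covariate(s) missing from new data: {missing}")
        mat = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in self.covariates_])
        return mat

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        X = pd.DataFrame(X)
        self.covariates_ = list(X.columns) if self.covariates is None else list(self.covariates)
        if y.min() == y.max():
            raise ValueError("response needs at least one success and one failure")
        design = self._design(X)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient design matrix (collinear covariates)")
        with warnings.catch_warnings():
            # separation is detected and raised explicitly below
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10, scale=1.0
            )
        _check_separation(X[self.covariates_], y.astype(int), res.fittedvalues)
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit(scale=1.0)
        self.names_ = ["intercept"] + self.covariates_
        self.coef_ = pd.Series(res.params, index=self.names_)
        self.cov_ = np.asarray(res.cov_params())
        self.se_ = pd.Series(np.sqrt(np.diag(self.cov_)), index=self.names_)
        self.loglik_ = float(res.llf)
        self.null_loglik_ = float(null.llf)
        self.deviance_ = float(res.deviance)
        self.null_deviance_ = float(null.deviance)
        self.n_params_ = design.shape[1]
        self.aic_ = -2 * self.loglik_ + 2 * self.n_params_
        self.pvalues_ = pd.Series(res.pvalues, index=self.names_)
        self.nobs_ = len(y)
        self.smooth_ = False
        return self

    def linpred(self, X: pd.DataFrame):
        """Linear predictor and its standard error on the logit scale."""
        design = self._design(pd.DataFrame(X))
        eta = design @ self.coef_.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", design, self.cov_, design))
        return eta, se

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta, _ = self.linpred(X)
        return expit(eta)

    def predict_interval(self, X: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
        """Fitted probability with Wald limits mapped through the inverse link.

        The interval is ``invlogit(eta_hat -/+ z * SE(eta_hat))``, so the
        limits are ordered and lie in [0, 1] by construction.
        """
        eta, se = self.linpred(X)
        return pd.DataFrame(
            {"fit": expit(eta), "lower": expit(eta - z * se), "upper": expit(eta + z * se)}
        )

    @property
    def mcfadden_r2_(self) -> float:
        return mcfadden_r2(self)


class AdditiveLogisticDetector(BaseEstimator):
    """Logit-link additive model with penalized B-spline smooths.

    One cubic B-spline smooth per covariate (``basis_size`` basis functions
    each); the smoothing penalty is chosen by generalized cross-validation
    unless ``alpha`` is given. The effective degrees of freedom (trace of
    the penalized hat matrix) enter the AIC.
    """

    def __init__(self, covariates=None, basis_size: int = 6, alpha=None, role: str = "detection"):
        self.covariates = covariates
        self.basis_size = basis_size
        self.alpha = alpha
        self.role = role

    def fit(self, X: pd.DataFrame, y):
        if self.basis_size < 3:
            raise ValueError("basis_size must be at least 3")
        y = np.asarray(y, dtype=float)
        X = pd.DataFrame(X)
        self.covariates_ = list(X.columns) if self.covariates is None else list(self.covariates)
        if not self.covariates_:
            raise ValueError("additive model needs at least one covariate")
        if y.min() == y.max():
            raise ValueError("response needs at least one success and one failure")
        xs = X[self.covariates_].to_numpy(dtype=float)
        self.smoother_ = BSplines(
            xs, df=[self.basis_size] * xs.shape[1], degree=[3] * xs.shape[1], include_intercept=False
        )
        exog = np.ones((len(y), 1))
        if self.alpha is None:
            # generalized cross-validation over a shared log-spaced penalty grid;
            # the B-spline curvature penalty's null space is the linear fit, so
            # large penalties recover it rather than flattening the smooth
            n = len(y)
            best = (np.inf, None, None)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for a in [0.0, *np.logspace(-2, 10, 13)]:
                    try:
                        cand = GLMGam(
                            y, exog, smoother=self.smoother_, family=sm.families.Binomial(),
                            alpha=[a] * xs.shape[1],
                        ).fit(maxiter=200)
                    except Exception:
                        continue
                    edf = float(cand.hat_matrix_trace)
                    if not np.isfinite(edf) or edf <= 0 or edf >= n:
                        continue
                    gcv = n * float(cand.deviance) / (n - edf) ** 2
                    if gcv < best[0]:
                        best = (gcv, [a] * xs.shape[1], cand)
            if best[1] is None:
                raise RuntimeError("additive fit failed at every smoothing penalty")
            alpha, res = best[1], best[2]
        else:
            alpha = (
                [float(self.alpha)] * xs.shape[1]
                if np.ndim(self.alpha) == 0
                else list(np.asarray(self.alpha, dtype=float))
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = GLMGam(
                    y, exog, smoother=self.smoother_, family=sm.families.Binomial(), alpha=alpha
                ).fit(maxiter=200)
        _check_separation(X[self.covariates_], y.astype(int), res.fittedvalues)
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit(scale=1.0)
        self.alpha_ = alpha
        self.res_ = res
        self.edf_ = float(res.hat_matrix_trace)
        self.loglik_ = float(res.llf)
        self.null_loglik_ = float(null.llf)
        self.deviance_ = float(res.deviance)
        self.null_deviance_ = float(null.deviance)
        self.n_params_ = self.edf_
        self.aic_ = -2 * self.loglik_ + 2 * self.edf_
        self.coef_ = pd.Series(res.params)
        self.cov_ = np.asarray(res.cov_params())
        self.se_ = pd.Series(np.sqrt(np.diag(self.cov_)))
        # per-smooth significance of the spline terms
        pvals = {}
        k0 = 1
        for j, c in enumerate(self.covariates_):
            k = self.smoother_.smoothers[j].dim_basis
            sl = slice(k0, k0 + k)
            beta = res.params[sl]
            covb = self.cov_[sl, sl]
            try:
                stat = float(beta @ np.linalg.pinv(covb) @ beta)
                dof = max(np.linalg.matrix_rank(covb), 1)
                from scipy.stats import chi2

                pvals[c] = float(chi2.sf(stat, dof))
            except np.linalg.LinAlgError:
                pvals[c] = np.nan
            k0 += k
        self.pvalues_ = pd.Series(pvals)
        self.nobs_ = len(y)
        self.smooth_ = True
        return self

    def linpred(self, X: pd.DataFrame):
        X = pd.DataFrame(X)
        missing = [c for c in self.covariates_ if c not in X.columns]
        if missing:
            raise ValueError(f"covariate(s) missing from new data: {missing}")
        basis = self.smoother_.transform(X[self.covariates_].to_numpy(dtype=float))
        design = np.column_stack([np.ones(len(X)), basis])
        eta = design @ self.coef_.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", design, self.cov_, design))
        return eta, se

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta, _ = self.linpred(X)
        return expit(eta)

    def predict_interval(self, X: pd.DataFrame, z: float = 1.96) -> pd.DataFrame:
        eta, se = self.linpred(X)
        return pd.DataFrame(
            {"fit": expit(eta), "lower": expit(eta - z * se), "upper": expit(eta + z * se)}
        )

    @property
    def mcfadden_r2_(self) -> float:
        return mcfadden_r2(self)


def mcfadden_r2(fit) -> float:
    """McFadden pseudo-R^2: ``1 - loglik / null_loglik``."""
    if fit.null_loglik_ >= 0:
        raise ValueError("null log-likelihood must be negative")
    return 1.0 - fit.loglik_ / fit.null_loglik_


@dataclass
class RankingRow:
    description: str
    model_type: str
    covariates: tuple
    null_deviance: float
    residual_deviance: float
    pvalues: tuple
    aic: float
    n_params: float


class StepwiseSelector(BaseEstimator):
    """Stepwise model selection for one Bernoulli model role.

    Stage 1 fits the null model and every univariate GLM, ranking them by
    AIC alongside their p-values and deviance reductions; covariates with a
    Wald p-value below ``alpha`` advance. Stage 2 fits every combination of
    the advanced covariates. Stage 3 fits the additive (GAM) variant of the
    best linear model and adopts it only when it beats that model's AIC by
    more than 2 points. Final selection is the lowest AIC, ties broken
    toward fewer parameters. The ranking reports all three criteria even
    where they disagree; AIC is the operative selector.
    """

    def __init__(self, role: str = "detection", alpha: float = 0.05, basis_size: int = 6, use_gam: bool = True):
        self.role = role
        self.alpha = alpha
        self.basis_size = basis_size
        self.use_gam = use_gam

    def fit(self, table: pd.DataFrame, y=None):
        yv, X = build_response(table, self.role) if y is None else (np.asarray(y), pd.DataFrame(table))
        candidates = [c for c in X.columns if X[c].nunique() > 1]
        rows: list[RankingRow] = []
        fits: dict[tuple, LogisticDetector] = {}

        null = LogisticDetector(covariates=[], role=self.role).fit(X, yv)
        fits[()] = null
        rows.append(
            RankingRow("null model", "GLM", (), null.null_deviance_, null.deviance_, (), null.aic_, 1)
        )
        advanced = []
        for c in candidates:
            m = LogisticDetector(covariates=[c], role=self.role).fit(X, yv)
            p = float(m.pvalues_[c])
            rows.append(
                RankingRow(c, "GLM", (c,), m.null_deviance_, m.deviance_, (p,), m.aic_, m.n_params_)
            )
            if p < self.alpha:
                # only covariates explaining a significant amount of variance
                # stay candidates for the final selection
                advanced.append(c)
                fits[(c,)] = m

        for r in range(2, len(advanced) + 1):
            for combo in itertools.combinations(advanced, r):
                m = LogisticDetector(covariates=list(combo), role=self.role).fit(X, yv)
                fits[combo] = m
                rows.append(
                    RankingRow(
                        " + ".join(combo),
                        "GLM",
                        combo,
                        m.null_deviance_,
                        m.deviance_,
                        tuple(float(m.pvalues_[c]) for c in combo),
                        m.aic_,
                        m.n_params_,
                    )
                )

        best_key = min(fits, key=lambda k: (round(fits[k].aic_, 10), fits[k].n_params_))
        best = fits[best_key]
        selected = best

        if self.use_gam and best_key:
            try:
                gam = AdditiveLogisticDetector(
                    covariates=list(best_key), basis_size=self.basis_size, role=self.role
                ).fit(X, yv)
                rows.append(
                    RankingRow(
                        " + ".join(best_key),
                        "GAM",
                        best_key,
                        gam.null_deviance_,
                        gam.deviance_,
                        tuple(float(gam.pvalues_[c]) for c in best_key),
                        gam.aic_,
                        gam.n_params_,
                    )
                )
                if best.aic_ - gam.aic_ > 2.0:
                    selected = gam
            except Exception:
                pass  # additive fit is optional; selection falls back to the linear model

        ranking = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
            ["aic", "n_params"], kind="stable"
        )
        ranking.insert(0, "rank", range(1, len(ranking) + 1))
        self.ranking_ = ranking.reset_index(drop=True)
        self.best_estimator_ = selected
        self.selected_covariates_ = tuple(selected.covariates_)
        self.selected_type_ = "GAM" if getattr(selected, "smooth_", False) else "GLM"
        self.advanced_ = tuple(advanced)
        self.nobs_ = len(yv)
        return self

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)

    def predict_interval(self, X, z: float = 1.96):
        return self.best_estimator_.predict_interval(X, z=z)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_logistic(y, X, covariates=None, role: str = "detection") -> LogisticDetector:
    return LogisticDetector(covariates=covariates, role=role).fit(pd.DataFrame(X), y)


def fit_additive(y, X, basis_size: int = 6, covariates=None, role: str = "detection") -> AdditiveLogisticDetector:
    return AdditiveLogisticDetector(covariates=covariates, basis_size=basis_size, role=role).fit(
        pd.DataFrame(X), y
    )


def stepwise_select(table: pd.DataFrame, role: str, alpha: float = 0.05, **kw) -> StepwiseSelector:
    return StepwiseSelector(role=role, alpha=alpha, **kw).fit(table)


def predict_with_ci(fit, newdata, z: float = 1.96) -> pd.DataFrame:
    return fit.predict_interval(pd.DataFrame(newdata), z=z)


def save_fit(fit: LogisticDetector, path) -> None:
    """Serialize a fitted linear logistic model to a YAML key-value file."""
    if getattr(fit, "smooth_", False):
        raise ValueError("additive (GAM) fits are not serializable; refit from data instead")
    doc = dict(
        role=fit.role,
        covariates=list(fit.covariates_),
        names=list(fit.names_),
        coefficients=[float(v) for v in fit.coef_],
        standard_errors=[float(v) for v in fit.se_],
        covariance=[[float(v) for v in row] for row in fit.cov_],
        loglik=fit.loglik_,
        null_loglik=fit.null_loglik_,
        deviance=fit.deviance_,
        null_deviance=fit.null_deviance_,
        aic=fit.aic_,
        nobs=int(fit.nobs_),
    )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_fit(path) -> LogisticDetector:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    fit = LogisticDetector(covariates=doc["covariates"], role=doc.get("role", "detection"))
    fit.covariates_ = list(doc["covariates"])
    fit.names_ = list(doc["names"])
    fit.coef_ = pd.Series(doc["coefficients"], index=fit.names_)
    fit.cov_ = np.asarray(doc["covariance"], dtype=float)
    fit.se_ = pd.Series(doc["standard_errors"], index=fit.names_)
    fit.loglik_ = float(doc["loglik"])
    fit.null_loglik_ = float(doc["null_loglik"])
    fit.deviance_ = float(doc["deviance"])
    fit.null_deviance_ = float(doc["null_deviance"])
    fit.aic_ = float(doc["aic"])
    fit.n_params_ = len(fit.names_)
    fit.pvalues_ = pd.Series(np.nan, index=fit.names_)
    fit.nobs_ = int(doc["nobs"])
    fit.smooth_ = False
    return fit
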