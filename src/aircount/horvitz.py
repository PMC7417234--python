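"""Modified Horvitz-Thompson abundance estimation.

Every object the detection algorithm flags contributes
``(1 - d_i - f_i) / p_i`` to the survey's abundance estimate: the inverse
detection probability inflates for missed animals, while the duplicate and
false-detection probabilities discount records that are likely not a new
true animal. Confidence limits come from plugging the per-object interval
limits of the three fitted probabilities into the same sum: the lower limits
of p, f and d give the upper abundance limit, and vice versa (abundance
rises when detection is believed unlikely and the detections are believed
real and unique).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .detection import LogisticDetector, StepwiseSelector

__all__ = [
    "AbundanceEstimate",
    "modified_ht_point",
    "modified_ht_interval",
    "estimate_surveys",
    "ModifiedHTEstimator",
]

#: floor for predicted detection probability; prevents exploding terms
P_FLOOR = 1e-3


@dataclass
class AbundanceEstimate:
    """Per-survey abundance estimate with interval and clamping diagnostics."""

    survey_id: str
    C: int
    n_hat: float
    n_lower: float
    n_upper: float
    level: float = 0.95
    clamped_objects: int = 0

    def __post_init__(self):
        assert self.n_lower <= self.n_hat <= self.n_upper, "interval limits out of order"
        assert self.n_hat >= 0 and self.C >= 0

    @property
    def estimate(self) -> int:
        return int(round(self.n_hat))

    @property
    def lower(self) -> int:
        return int(round(self.n_lower))

    @property
    def upper(self) -> int:
        return int(round(self.n_upper))

    def as_dict(self) -> dict:
        return dict(
            survey_id=self.survey_id,
            raw_count=self.C,
            estimate=self.estimate,
            lower=self.lower,
            upper=self.upper,
            n_hat=self.n_hat,
            n_lower=self.n_lower,
            n_upper=self.n_upper,
            level=self.level,
            clamped_objects=self.clamped_objects,
        )


def _ht_sum(p, f, d, eps: float = P_FLOOR):
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (len(p) == len(f) == len(d)):
        raise ValueError(f"probability vectors differ in length: {len(p)}, {len(f)}, {len(d)}")
    if np.any(p <= 0):
        raise ValueError("detection probabilities must be positive before clamping")
    numer = 1.0 - d - f
    clamped = int(np.sum(numer < 0) + np.sum(p < eps))
    value = float(np.sum(np.clip(numer, 0.0, None) / np.clip(p, eps, None)))
    return value, clamped


def modified_ht_point(p_hat, f_hat, d_hat) -> float:
    """Point estimate ``sum_i (1 - d_i - f_i) / p_i`` over detected objects.

    Per-object numerators are clamped below at zero and detection
    probabilities below at 1e-3; the unrounded value is returned (round for
    reporting).
    """
    return _ht_sum(p_hat, f_hat, d_hat)[0]


def modified_ht_interval(
    pred_p: pd.DataFrame, pred_f: pd.DataFrame, pred_d: pd.DataFrame,
    survey_id: str = "", level: float = 0.95,
) -> AbundanceEstimate:
    """Estimate with plug-in interval from per-object prediction intervals.

    Each ``pred_*`` frame has columns ``fit``, ``lower``, ``upper`` on the
    probability scale, one row per detected object.
    """
    n_hat, clamped = _ht_sum(pred_p["fit"], pred_f["fit"], pred_d["fit"])
    n_upper, c_u = _ht_sum(pred_p["lower"], pred_f["lower"], pred_d["lower"])
    n_lower, c_l = _ht_sum(pred_p["upper"], pred_f["upper"], pred_d["upper"])
    return AbundanceEstimate(
        survey_id=survey_id,
        C=len(pred_p),
        n_hat=n_hat,
        n_lower=min(n_lower, n_hat),
        n_upper=max(n_upper, n_hat),
        level=level,
        clamped_objects=clamped + c_u + c_l,
    )


def estimate_surveys(test: pd.DataFrame, fit_p, fit_f, fit_d, level: float = 0.95) -> list[AbundanceEstimate]:
    """Per-survey modified H-T estimates from fitted probability models.

    The test table must contain only algorithm-identified objects
    (``klass != missed``); ground-truth-only misses never enter estimation.
    """
    if (test["klass"] == "missed").any():
        raise ValueError(
            "test table contains klass='missed' rows; ground-truthed misses are not "
            "algorithm output and cannot enter abundance estimation"
        )
    z = float(norm.ppf(0.5 + level / 2))
    out = []
    for survey_id, sub in test.groupby("survey_id", sort=True):
        pred_p = fit_p.predict_interval(sub, z=z)
        pred_f = fit_f.predict_interval(sub, z=z)
        pred_d = fit_d.predict_interval(sub, z=z)
        out.append(modified_ht_interval(pred_p, pred_f, pred_d, survey_id=str(survey_id), level=level))
    return out


class ModifiedHTEstimator(BaseEstimator):
    """End-to-end modified Horvitz-Thompson abundance estimator.

    ``fit`` learns the three Bernoulli probability models from a training
    observation table — by stepwise selection when the ``*_covariates``
    parameters are ``None``, or as fixed-form logistic fits otherwise.
    ``predict`` maps a test table of detected objects to one abundance
    estimate (with interval) per survey.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        level: float = 0.95,
        use_gam: bool = True,
        p_covariates=None,
        f_covariates=None,
        d_covariates=None,
    ):
        self.alpha = alpha
        self.level = level
        self.use_gam = use_gam
        self.p_covariates = p_covariates
        self.f_covariates = f_covariates
        self.d_covariates = d_covariates

    def _fit_role(self, table, role, covariates):
        from .detection import build_response

        if covariates is None:
            sel = StepwiseSelector(role=role, alpha=self.alpha, use_gam=self.use_gam).fit(table)
            return sel.best_estimator_
        y, X = build_response(table, role)
        return LogisticDetector(covariates=list(covariates), role=role).fit(X, y)

    def fit(self, table: pd.DataFrame, y=None):
        self.fit_p_ = self._fit_role(table, "detection", self.p_covariates)
        self.fit_f_ = self._fit_role(table, "false", self.f_covariates)
        self.fit_d_ = self._fit_role(table, "duplicate", self.d_covariates)
        return self

    def predict(self, test: pd.DataFrame) -> pd.DataFrame:
        estimates = estimate_surveys(test, self.fit_p_, self.fit_f_, self.fit_d_, level=self.level)
        return pd.DataFrame([e.as_dict() for e in estimates])

    def estimates(self, test: pd.DataFrame) -> list[AbundanceEstimate]:
        return estimate_surveys(test, self.fit_p_, self.fit_f_, self.fit_d_, level=self.level)
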