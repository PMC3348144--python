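"""Predicted-vs-observed regression for kriging validation.

The calibration regression of observed on predicted values: for any optimal
(or near-optimal) linear predictor, cov(zhat, z) = var(zhat), so the
observed-on-predicted slope has expectation 1 under a correctly specified
model, while the predicted-on-observed slope has expectation r-squared < 1
(smoothing shrinks predictions toward the mean).  A well-calibrated
interpolator therefore has an observed-on-predicted slope whose 95%
confidence interval contains 1.  The CI is t-based with n - 2 degrees of
freedom.  The reverse direction remains available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ValidationResult", "validate"]


@dataclass(frozen=True)
class ValidationResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci_low: float
    slope_ci_high: float
    slope_se: float
    p_value: float
    df: int
    contains_one: bool

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_ci_low": self.slope_ci_low,
            "slope_ci_high": self.slope_ci_high,
            "slope_se": self.slope_se,
            "p_value": self.p_value,
            "df": self.df,
            "contains_one": self.contains_one,
        }


def validate(observed, predicted, direction: str = "obs_on_pred") -> ValidationResult:
    """OLS validation regression with a slope-vs-1:1 check.

    direction='obs_on_pred' (default) regresses observed on predicted — the
    calibration direction whose slope is 1 in expectation for a calibrated
    predictor; 'pred_on_obs' swaps the roles.  Requires n >= 3 and nonzero
    variance in the regressor.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must have equal length")
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if direction == "pred_on_obs":
        x, y = obs, pred
    elif direction == "obs_on_pred":
        x, y = pred, obs
    else:
        raise ValueError("direction must be 'pred_on_obs' or 'obs_on_pred'")
    if np.var(x) == 0:
        raise ValueError("regressor has zero variance")

    fit = stats.linregress(x, y)
    df = n - 2
    t_crit = stats.t.ppf(0.975, df)
    lo = fit.slope - t_crit * fit.stderr
    hi = fit.slope + t_crit * fit.stderr
    return ValidationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_ci_low=float(lo),
        slope_ci_high=float(hi),
        slope_se=float(fit.stderr),
        p_value=float(fit.pvalue),
        df=df,
        contains_one=bool(lo <= 1.0 <= hi),
    )
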