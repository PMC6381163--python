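"""Points-based nomogram over a fitted logistic model.

The nomogram is an exact reparameterization of an unpenalized logistic fit:
each feature axis maps a value to nonnegative points via

    points_f(x) = 100 * (beta_f * x - min over the range of beta_f * x)
                  / max_g(|beta_g| * range_g)

so the feature with the largest |beta|*range spans exactly 0-100 points,
and the total-points axis maps back to probability through the logistic
function.  Scoring a patient through the nomogram therefore returns the
same probability as the direct model prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = ["NomogramAxis", "NomogramSpec", "SeparationError", "fit_logistic",
           "build_nomogram", "score_patient"]


class SeparationError(RuntimeError):
    """Perfect separation: the unpenalized logistic MLE diverges.

    Refit with a penalized model (e.g. the LASSO fit itself) instead.
    """


@dataclass
class NomogramAxis:
    feature: str
    lo: float
    hi: float
    coefficient: float
    points_per_unit: float     # signed: d(points)/dx
    ref_value: float           # value scoring 0 points

    def points(self, x: float) -> float:
        return self.points_per_unit * (x - self.ref_value)

    @property
    def max_points(self) -> float:
        return abs(self.points_per_unit) * (self.hi - self.lo)


@dataclass
class NomogramSpec:
    axes: dict[str, NomogramAxis]
    intercept: float
    scale: float               # linear-predictor units per point

    def probability_from_points(self, total_points: float) -> float:
        offset = sum(min(ax.coefficient * ax.lo, ax.coefficient * ax.hi)
                     for ax in self.axes.values())
        lp = self.intercept + offset + self.scale * total_points
        return float(1.0 / (1.0 + np.exp(-lp)))

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "scale": self.scale,
            "axes": {name: {"lo": ax.lo, "hi": ax.hi,
                            "coefficient": ax.coefficient,
                            "points_per_unit": ax.points_per_unit,
                            "ref_value": ax.ref_value}
                     for name, ax in self.axes.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NomogramSpec":
        with open(path) as fh:
            payload = json.load(fh)
        axes = {name: NomogramAxis(feature=name, **vals)
                for name, vals in payload["axes"].items()}
        return cls(axes=axes, intercept=payload["intercept"],
                   scale=payload["scale"])


def fit_logistic(X: pd.DataFrame, y, tol: float = 1e-8,
                 coef_bound: float = 30.0) -> tuple[pd.Series, float]:
    """Unpenalized maximum-likelihood logistic fit on the selected features.

    Raises :class:`SeparationError` when the data are (quasi-)separated,
    detected by statsmodels or by coefficients diverging past ``coef_bound``
    on standardized-scale features.
    """
    y = np.asarray(y)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    try:
        res = sm.Logit(y, design).fit(disp=0, method="newton", tol=tol, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic MLE failed ({exc}); "
                              "use a penalized fit instead") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:])) > coef_bound:
        raise SeparationError("coefficients diverged: data are separated; "
                              "use a penalized fit instead")
    return pd.Series(params[1:], index=X.columns), float(params[0])


def build_nomogram(coefficients: pd.Series, intercept: float,
                   feature_ranges: dict[str, tuple[float, float]]) -> NomogramSpec:
    """Translate logistic coefficients + observed feature ranges into axes."""
    if coefficients.empty:
        raise ValueError("no coefficients to build a nomogram from")
    if not np.all(np.isfinite(coefficients.to_numpy())):
        raise ValueError("coefficients must be finite")
    spans = {}
    for feat, beta in coefficients.items():
        lo, hi = feature_ranges[feat]
        if hi <= lo:
            logger.warning("dropping zero-range feature %s from the nomogram", feat)
            continue
        spans[feat] = abs(beta) * (hi - lo)
    if not spans:
        raise ValueError("every feature has zero range")
    M = max(spans.values())
    axes = {}
    for feat in spans:
        beta = float(coefficients[feat])
        lo, hi = (float(v) for v in feature_ranges[feat])
        ref = lo if beta >= 0 else hi
        axes[feat] = NomogramAxis(feature=feat, lo=lo, hi=hi, coefficient=beta,
                                  points_per_unit=100.0 * beta / M, ref_value=ref)
    return NomogramSpec(axes=axes, intercept=float(intercept), scale=M / 100.0)


def score_patient(spec: NomogramSpec, feature_values: dict[str, float] | pd.Series,
                  range_slack: float = 0.2) -> tuple[float, float]:
    """Total points and predicted probability for one patient.

    Values outside the training range by more than ``range_slack`` of the
    range width trigger a warning (extrapolation).  The probability equals
    the direct logistic prediction from the underlying coefficients.
    """
    values = dict(feature_values)
    missing = [f for f in spec.axes if f not in values]
    if missing:
        raise ValueError(f"missing feature values: {missing}")
    total = 0.0
    for feat, ax in spec.axes.items():
        x = float(values[feat])
        width = ax.hi - ax.lo
        if x < ax.lo - range_slack * width or x > ax.hi + range_slack * width:
            logger.warning("feature %s=%.4g outside training range [%.4g, %.4g]",
                           feat, x, ax.lo, ax.hi)
        total += ax.points(x)
    return total, spec.probability_from_points(total)
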