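"""Linear calibration of normalized FTIR peak heights to wet chemistry.

Carbohydrate content (% cellulose + hemicellulose by acid hydrolysis) is
regressed on the carb band height; aromatic content (% Klason lignin) on an
aromatic band predictor, choosing among arom15, arom16 and their sum by fit
quality.  Fitted models carry slope, intercept, R^2, the slope-test p value,
and the standard error of the y-estimate (SEE = sqrt(SSE/(n-2))), which is
used as the per-sample uncertainty of predicted compositions.

Class-based exclusions reflect known spectral interferences in the standard
set: glossy-magazine paper (OMG) carries a clay-coating band overlapping the
carbohydrate peak and is dropped from the carbohydrate calibration; office
paper (OFF) is a chemical pulp with its lignin removed and is dropped from
the aromatic calibration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_CLASSES",
    "CalibrationStandard",
    "CalibrationModel",
    "select_standards",
    "fit_calibration",
    "compare_aromatic_predictors",
    "predict_composition",
    "LinearPeakCalibration",
    "calibrate_from_standards",
    "save_models",
    "load_models",
]

STANDARD_CLASSES = (
    "hardwood", "softwood", "leaves_grasses", "needles", "OCC", "ONP", "OMG", "OFF",
)

# analyte -> standard class excluded from its calibration
_ANALYTE_EXCLUSIONS = {"carbohydrates": "OMG", "aromatics": "OFF"}


@dataclass
class CalibrationStandard:
    """One reference material: band heights + measured composition."""

    sample_id: str
    standard_class: str
    carb_height: float
    arom15_height: float
    arom16_height: float
    pct_cellulose_hemicellulose: float
    pct_klason_lignin: float

    def __post_init__(self) -> None:
        if self.standard_class not in STANDARD_CLASSES:
            raise ValueError(
                f"{self.sample_id!r}: unknown standard class {self.standard_class!r}"
            )
        for attr in ("pct_cellulose_hemicellulose", "pct_klason_lignin"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.sample_id!r}: {attr}={v:g} outside [0, 100]")
        for attr in ("carb_height", "arom15_height", "arom16_height"):
            v = getattr(self, attr)
            if not np.isfinite(v):
                raise ValueError(f"{self.sample_id!r}: non-finite {attr}")
            if v < 0:
                logger.warning("%r: negative %s (%.4g)", self.sample_id, attr, v)


@dataclass(frozen=True)
class CalibrationModel:
    """Simple-regression calibration curve for one analyte.

    ``see`` (standard error of the y-estimate, sqrt(SSE/(n-2)), in wt%) is
    the constant per-sample uncertainty attached to predictions.
    """

    analyte: str          # carbohydrates | aromatics
    predictor: str        # carb | arom15 | arom16 | arom15_plus_arom16
    slope: float          # wt% per cm of normalized height
    intercept: float      # wt%
    r_squared: float
    p_value: float
    n: int
    see: float            # wt%

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared:g} outside [0, 1]")
        if self.n < 3:
            raise ValueError("calibration requires n >= 3")
        if self.see < 0:
            raise ValueError("see must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def select_standards(
    standards: Sequence[CalibrationStandard], analyte: str
) -> list[CalibrationStandard]:
    """Apply the per-analyte class exclusion, preserving input order."""
    if analyte not in _ANALYTE_EXCLUSIONS:
        raise ValueError(f"unknown analyte {analyte!r}")
    for s in standards:
        if s.standard_class not in STANDARD_CLASSES:
            raise ValueError(f"unknown standard class {s.standard_class!r}")
    drop = _ANALYTE_EXCLUSIONS[analyte]
    return [s for s in standards if s.standard_class != drop]


def fit_calibration(
    x: Iterable[float],
    y: Iterable[float],
    analyte: str = "carbohydrates",
    predictor: str = "carb",
) -> CalibrationModel:
    """Ordinary least squares ``y = slope*x + intercept`` with fit statistics.

    ``r_squared = 1 - SSE/SStot``; the p value is the two-sided t-test on the
    slope (equivalent to the model F-test for a single predictor);
    ``see = sqrt(SSE/(n-2))``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points to calibrate, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate design: predictor is constant")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float(np.sum(resid**2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if sstot == 0.0 else 1.0 - sse / sstot
    see = float(np.sqrt(sse / (n - 2)))
    slope_se = see / np.sqrt(sxx)
    if slope_se == 0.0:
        p_value = 0.0 if slope != 0.0 else 1.0
    else:
        t = slope / slope_se
        p_value = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CalibrationModel(
        analyte=analyte,
        predictor=predictor,
        slope=float(slope),
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        p_value=p_value,
        n=int(n),
        see=see,
    )


_AROMATIC_PREDICTORS = ("arom15", "arom16", "arom15_plus_arom16")


def _predictor_values(s: CalibrationStandard, predictor: str) -> float:
    if predictor == "carb":
        return s.carb_height
    if predictor == "arom15":
        return s.arom15_height
    if predictor == "arom16":
        return s.arom16_height
    if predictor == "arom15_plus_arom16":
        return s.arom15_height + s.arom16_height
    raise ValueError(f"unknown predictor {predictor!r}")


def compare_aromatic_predictors(
    standards: Sequence[CalibrationStandard],
) -> list[CalibrationModel]:
    """Fit % Klason lignin against each aromatic predictor; rank by R^2.

    Candidates are arom15, arom16, and their sum (a single summed x-variable,
    not a two-covariate fit).  Returns the three models sorted by descending
    R^2; ties preserve the listed candidate order.
    """
    kept = select_standards(standards, "aromatics")
    y = [s.pct_klason_lignin for s in kept]
    models = [
        fit_calibration(
            [_predictor_values(s, pred) for s in kept], y,
            analyte="aromatics", predictor=pred,
        )
        for pred in _AROMATIC_PREDICTORS
    ]
    return sorted(models, key=lambda m: -m.r_squared)  # stable sort keeps order on ties


def predict_composition(m: CalibrationModel, height: float) -> tuple[float, float]:
    """Apply a calibration curve: ``estimate = slope*height + intercept``.

    The attached uncertainty is the calibration's constant SEE.  Estimates
    outside [0, 100] wt% are returned unclipped with a warning (clipping
    would bias cross-sample comparisons).
    """
    estimate = m.slope * height + m.intercept
    if not 0.0 <= estimate <= 100.0:
        warnings.warn(
            f"{m.analyte} estimate {estimate:.2f} wt% outside [0, 100]; "
            "returned unclipped",
            stacklevel=2,
        )
    return float(estimate), m.see


class LinearPeakCalibration(RegressorMixin, BaseEstimator):
    """scikit-learn regressor wrapping the peak-height calibration curve.

    Fit with ``X`` of shape (n, 1) holding normalized corrected peak heights
    (cm) and ``y`` the wet-chemistry composition (wt%).  Fitted attributes
    mirror :class:`CalibrationModel`: ``slope_``, ``intercept_``,
    ``r_squared_``, ``p_value_``, ``n_``, ``see_``, ``model_``.

    Parameters
    ----------
    analyte : {"carbohydrates", "aromatics"}
    predictor : str
        Label recorded on the fitted model (e.g. ``"carb"`` or
        ``"arom15_plus_arom16"``).
    """

    def __init__(self, analyte: str = "carbohydrates", predictor: str = "carb"):
        self.analyte = analyte
        self.predictor = predictor

    def fit(self, X, y) -> "LinearPeakCalibration":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must have exactly one column of peak heights")
        m = fit_calibration(X[:, 0], y, analyte=self.analyte, predictor=self.predictor)
        self.model_ = m
        self.slope_ = m.slope
        self.intercept_ = m.intercept
        self.r_squared_ = m.r_squared
        self.p_value_ = m.p_value
        self.n_ = m.n
        self.see_ = m.see
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        est = self.slope_ * X[:, 0] + self.intercept_
        out = est[(est < 0) | (est > 100)]
        if out.size:
            warnings.warn(
                f"{out.size} {self.analyte} estimate(s) outside [0, 100] wt%; "
                "returned unclipped",
                stacklevel=2,
            )
        return est

    def predict_with_se(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus the constant SEE as the per-sample uncertainty."""
        est = self.predict(X)
        return est, np.full_like(est, self.see_)


def calibrate_from_standards(
    standards: Sequence[CalibrationStandard],
) -> dict[str, CalibrationModel]:
    """Run the full calibration protocol on a standard set.

    Carbohydrates: OMG excluded, carb height vs % cellulose + hemicellulose.
    Aromatics: OFF excluded, best of {arom15, arom16, arom15+arom16} vs
    % Klason lignin (the summed predictor wins on real standard sets).
    """
    carb_std = select_standards(standards, "carbohydrates")
    carb_model = fit_calibration(
        [s.carb_height for s in carb_std],
        [s.pct_cellulose_hemicellulose for s in carb_std],
        analyte="carbohydrates", predictor="carb",
    )
    arom_models = compare_aromatic_predictors(standards)
    return {
        "carbohydrates": carb_model,
        "aromatics": arom_models[0],
        "aromatics_candidates": arom_models,
    }


def save_models(models: dict, path: str | Path) -> None:
    """Serialize calibration models to JSON at full precision."""
    payload = {}
    for key, val in models.items():
        if isinstance(val, CalibrationModel):
            payload[key] = val.to_dict()
        elif isinstance(val, (list, tuple)):
            payload[key] = [m.to_dict() for m in val]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> dict:
    raw = json.loads(Path(path).read_text())
    out: dict = {}
    for key, val in raw.items():
        if isinstance(val, dict):
            out[key] = CalibrationModel(**val)
        else:
            out[key] = [CalibrationModel(**m) for m in val]
    return out
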