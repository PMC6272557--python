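"""Standard-curve calibration math for the four indicator assays.

Two curve families cover the assays used to quantify the quality
indicators:

* ``linear`` — ordinary least squares of instrument response on analyte
  amount, as used for the colorimetric betaine (525 nm) and
  phenol-sulfuric polysaccharide (488 nm) readings;
* ``loglog`` — OLS in log10-log10 space, the standard linearisation of
  an evaporative light scattering detector's power-law response, as used
  for astragaloside IV and calycosin-glucoside.

Content prediction inverts the fitted curve (in log space for loglog)
and applies a dilution factor. Predictions outside the calibration range
are allowed but flagged rather than rejected. The aqueous-extract
percentage is a closed-form gravimetric formula, included here because
it feeds the same indicator panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    """A fitted calibration line: response = slope * x + intercept.

    For ``kind="loglog"`` the relation holds between log10(amount) and
    log10(response); ``calibration_range`` is always on the original
    (un-logged) amount scale.
    """

    kind: str  # "linear" | "loglog"
    slope: float
    intercept: float
    r_squared: float
    calibration_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "loglog"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")
        lo, hi = self.calibration_range
        if not lo < hi:
            raise ValueError("calibration range must satisfy min < max")


class Prediction(NamedTuple):
    """Inverse-predicted content; ``extrapolated`` flags out-of-range responses."""

    value: float
    extrapolated: bool


def fit_standard_curve(
    x: Sequence[float], y: Sequence[float], kind: str = "linear"
) -> StandardCurve:
    """Fit a calibration curve by OLS on (x, y) or (log10 x, log10 y).

    Parameters
    ----------
    x : concentrations / amounts of the standard levels
    y : instrument responses (absorbance or peak area)
    kind : {"linear", "loglog"}

    Raises
    ------
    ValueError
        Fewer than 2 distinct x values, or non-positive data under
        ``loglog``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if np.unique(x).size < 2:
        raise ValueError("standard curve needs at least 2 distinct x values")
    if kind == "loglog":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-log curve requires strictly positive x and y")
        fx, fy = np.log10(x), np.log10(y)
    elif kind == "linear":
        fx, fy = x, y
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    fit = stats.linregress(fx, fy)
    # rvalue is NaN when y is constant (perfectly flat response): define r^2 = 0
    r2 = 0.0 if math.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    return StandardCurve(
        kind=kind,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        calibration_range=(float(x.min()), float(x.max())),
    )


def predict_content(
    curve: StandardCurve, response: float, dilution_factor: float = 1.0
) -> Prediction:
    """Invert the curve: instrument response -> analyte content.

    The inverse prediction is multiplied by ``dilution_factor`` to map
    the measured aliquot back to the original sample. A prediction whose
    back-calculated amount falls outside the calibration range is
    returned with ``extrapolated=True``.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    if curve.slope == 0:
        raise ZeroDivisionError("curve with zero slope is not invertible")
    if curve.kind == "loglog":
        if response <= 0:
            raise ValueError("log-log curve cannot invert a non-positive response")
        amount = 10.0 ** ((math.log10(response) - curve.intercept) / curve.slope)
    else:
        amount = (response - curve.intercept) / curve.slope
    lo, hi = curve.calibration_range
    extrapolated = not (lo <= amount <= hi)
    return Prediction(value=amount * dilution_factor, extrapolated=extrapolated)


def extract_percent(
    residue_g: float, aliquot_ml: float, total_ml: float, sample_g: float
) -> float:
    """Aqueous-extract content (%) from the gravimetric assay.

    A ``sample_g`` mass of powder is extracted into ``total_ml`` of
    water; an ``aliquot_ml`` portion of the filtrate is dried to
    constant weight ``residue_g``. The extract percentage is

        100 * residue_g * (total_ml / aliquot_ml) / sample_g
    """
    if aliquot_ml <= 0 or total_ml <= 0 or sample_g <= 0:
        raise ValueError("aliquot_ml, total_ml and sample_g must all be > 0")
    if residue_g < 0:
        raise ValueError("residue_g must be >= 0")
    if aliquot_ml > total_ml:
        raise ValueError("aliquot volume cannot exceed total filtrate volume")
    return 100.0 * residue_g * (total_ml / aliquot_ml) / sample_g
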