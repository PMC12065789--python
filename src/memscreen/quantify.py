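"""Reporter-fluorescence quantification.

Split-GFP fluorescence is converted to solubilized-protein amount through a
four-parameter sigmoid calibration

    y = L / (1 + exp(-k (x - x0))) + b

fit to (known amount, fluorescence) points of a GFP11-tagged standard, and
inverted analytically for unknowns.  Also provides the pmol -> ug/mL unit
conversion for the 2 uL reaction format and the single-liposome flow
cytometry event normalization (Cy5/SSC gating, log10 GFP/Cy5 ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationFit",
    "sigmoid",
    "fit_calibration",
    "fluorescence_to_amount",
    "amount_to_concentration",
    "normalize_flow_events",
    "FlowResult",
]


def sigmoid(x, L, k, x0, b):
    """Four-parameter logistic: L / (1 + exp(-k (x - x0))) + b."""
    return L / (1.0 + np.exp(-k * (np.asarray(x, float) - x0))) + b


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted sigmoid calibration parameters.

    L: fluorescence span; k: steepness (1/amount); x0: midpoint amount;
    b: baseline fluorescence.  ``span_warning`` is set when the data do not
    bracket the inflection (near-linear regime) so the parameters are
    poorly identified even though a least-squares fit is returned.
    """

    L: float
    k: float
    x0: float
    b: float
    residual_rms: float = float("nan")
    span_warning: bool = False

    def __post_init__(self):
        if self.L <= 0 or self.k <= 0:
            raise ValueError("calibration requires L > 0 and k > 0")

    def predict(self, x):
        return sigmoid(x, self.L, self.k, self.x0, self.b)


class CalibrationError(RuntimeError):
    """Sigmoid fit failed to converge; carries the initial guess."""

    def __init__(self, msg, p0=None):
        super().__init__(msg)
        self.p0 = p0


def fit_calibration(amount, fluorescence) -> CalibrationFit:
    """Nonlinear least-squares fit of the four-parameter sigmoid.

    Initial guesses: L = range of y, b = min y, x0 = median x,
    k = 4 / range of x (the slope-matching heuristic for a logistic).
    """
    x = np.asarray(amount, float)
    y = np.asarray(fluorescence, float)
    if x.size < 5:
        raise ValueError("need >= 5 calibration points")
    yr = float(np.ptp(y))
    xr = float(np.ptp(x))
    if xr == 0:
        raise ValueError("calibration amounts are all identical")
    p0 = [max(yr, 1e-9), 4.0 / xr, float(np.median(x)), float(y.min())]
    try:
        popt, _ = curve_fit(
            sigmoid, x, y, p0=p0, maxfev=20000,
            bounds=([1e-12, 1e-12, -np.inf, -np.inf], np.inf),
        )
    except RuntimeError as err:
        raise CalibrationError(f"sigmoid fit did not converge: {err}", p0=p0) from err
    L, k, x0, b = (float(v) for v in popt)
    resid = y - sigmoid(x, L, k, x0, b)
    rms = float(np.sqrt(np.mean(resid**2)))
    # the inflection must be bracketed for all four parameters to be
    # identifiable; otherwise the curve is locally linear in the data
    span_warning = not (x.min() < x0 < x.max()) or k * xr < 1.0
    if span_warning:
        warnings.warn(
            "calibration points do not span the sigmoid inflection; "
            "parameters are weakly identified",
            stacklevel=2,
        )
    return CalibrationFit(L, k, x0, b, residual_rms=rms, span_warning=span_warning)


def fluorescence_to_amount(fit: CalibrationFit, y, clip: bool = False):
    """Analytic inverse of the calibration sigmoid.

    ``y`` must lie in the open range (b, b + L).  With ``clip=True``
    out-of-range values are clipped just inside the range (batch screening
    mode); the default raises, since extrapolating a sigmoid inverse is
    unbounded.
    """
    y = np.asarray(y, float)
    lo, hi = fit.b, fit.b + fit.L
    out_of_range = (y <= lo) | (y >= hi)
    if np.any(out_of_range):
        if not clip:
            raise ValueError(
                f"fluorescence outside open calibration range ({lo:g}, {hi:g})"
            )
        eps = 1e-9 * fit.L
        y = np.clip(y, lo + eps, hi - eps)
    x = fit.x0 - np.log(fit.L / (y - fit.b) - 1.0) / fit.k
    return x if x.ndim else float(x)


def amount_to_concentration(amount_pmol, mw_kda, volume_ul):
    """Convert a protein amount to mass concentration.

    pmol * kDa / uL = (1e-12 mol * 1e3 g/mol) / (1e-6 L) = 1e-3 g/L
    = ug/mL, so the conversion is a plain product/quotient:
    1 pmol at 40 kDa in 2 uL -> 20 ug/mL.
    """
    amount_pmol = np.asarray(amount_pmol, float)
    mw_kda = np.asarray(mw_kda, float)
    volume_ul = np.asarray(volume_ul, float)
    if np.any(amount_pmol <= 0) or np.any(mw_kda <= 0) or np.any(volume_ul <= 0):
        raise ValueError("amount, molecular weight, and volume must all be > 0")
    c = amount_pmol * mw_kda / volume_ul
    return c if c.ndim else float(c)


@dataclass(frozen=True)
class FlowResult:
    """Gated flow-cytometry events with per-event log10(GFP/Cy5)."""

    log_ratio: np.ndarray
    gate_mask: np.ndarray
    retained_fraction: float
    n_dropped_nonpositive: int


def normalize_flow_events(
    events, ratio_low: float = 0.5, ratio_high: float = 5.0
) -> FlowResult:
    """Gate liposome events and normalize GFP by liposome size.

    ``events`` is an (n, 3) array or DataFrame of (gfp_area, cy5_area,
    ssc_area).  Events with any non-positive channel are dropped and
    counted; liposomes are identified by cy5/ssc in [ratio_low,
    ratio_high]; retained events get log10(gfp/cy5).
    """
    if isinstance(events, pd.DataFrame):
        arr = events.to_numpy(float)
    else:
        arr = np.asarray(events, float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("events must be (n, 3): gfp_area, cy5_area, ssc_area")
    gfp, cy5, ssc = arr.T
    positive = (gfp > 0) & (cy5 > 0) & (ssc > 0)
    n_dropped = int((~positive).sum())
    ratio = np.full(arr.shape[0], np.nan)
    ratio[positive] = cy5[positive] / ssc[positive]
    gate = positive & (ratio >= ratio_low) & (ratio <= ratio_high)
    log_ratio = np.log10(gfp[gate] / cy5[gate])
    retained = float(gate.sum() / arr.shape[0]) if arr.shape[0] else 0.0
    return FlowResult(log_ratio, gate, retained, n_dropped)
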