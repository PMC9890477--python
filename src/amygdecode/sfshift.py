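"""Spatial-frequency reference-frame analysis (shift index).

Each neuron's tuning surface gives a 7-point spatial-frequency tuning curve
at each of 5 stimulus sizes.  The preferred image-based SF per size is the
peak of a Gaussian in log2(SF) fitted by least squares (argmax fallback),
clamped to the tested 2-16 cycles/image span.  The shift index is the
least-squares slope of log2(preferred image-based SF) on log2(size):

* 1  - preferred image-based SF proportional to size (retina-based frame,
       constant preferred cycles/degree),
* 0  - preferred image-based SF constant across sizes (image-based frame),
* <0 - shift opposite to the retina-based prediction; values > 1 indicate a
       larger-than-proportional shift.

Responses enter as mean rates over a fixed 500-ms window; this module never
sees spike times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .stats import CorrelationResult, spearman
from .synthetic import TuningSurface

SF_MIN, SF_MAX = 2.0, 16.0
MIN_VALID_SIZES = 3


@dataclass
class ShiftIndexResult:
    neuron_id: int | None
    preferred_per_size: np.ndarray  # cycles/image, NaN where undefined
    shift_index: float
    clamped: np.ndarray  # bool per size: preferred hit the grid span
    fit_r2: np.ndarray  # Gaussian-fit quality per size (NaN for argmax fallback)


def _gauss(u, amp, mu, sigma):
    return amp * np.exp(-((u - mu) ** 2) / (2.0 * sigma**2))


def preferred_sf_per_size(surface: TuningSurface, size_index: int) -> tuple[float, bool, float]:
    """Preferred image-based SF (cycles/image) of the tuning curve at one
    size: peak of a least-squares Gaussian in log2(SF), falling back to the
    argmax grid SF if the fit fails; the value is clamped to [2, 16].

    Returns (preferred, clamped?, fit R^2 or NaN).  An all-zero curve is
    undefined (ValueError).
    """
    curve = surface.rates[:, size_index]
    if np.all(curve == 0):
        raise ValueError("all-zero tuning curve: preferred SF undefined")
    u = np.log2(np.asarray(surface.center_sfs))
    u0 = u[int(np.argmax(curve))]
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            u,
            curve,
            p0=[float(curve.max()), float(u0), 1.0],
            bounds=([0.0, u.min() - 3.0, 0.05], [np.inf, u.max() + 3.0, 10.0]),
            maxfev=5000,
        )
        mu = float(popt[1])
        resid = curve - _gauss(u, *popt)
        ss_tot = float(((curve - curve.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    except RuntimeError:
        mu = float(u0)
        r2 = np.nan
    preferred = float(2.0**mu)
    clamped = preferred < SF_MIN or preferred > SF_MAX
    return float(np.clip(preferred, SF_MIN, SF_MAX)), clamped, r2


def shift_index(surface: TuningSurface, neuron_id: int | None = None) -> ShiftIndexResult:
    """Shift index of one neuron's SF x size tuning surface (see module
    docs); requires a defined preferred SF for at least 3 of the 5 sizes."""
    sizes = np.asarray(surface.sizes)
    prefs = np.full(sizes.size, np.nan)
    clamped = np.zeros(sizes.size, dtype=bool)
    r2 = np.full(sizes.size, np.nan)
    for j in range(sizes.size):
        try:
            prefs[j], clamped[j], r2[j] = preferred_sf_per_size(surface, j)
        except ValueError:
            continue
    valid = ~np.isnan(prefs)
    if valid.sum() < MIN_VALID_SIZES:
        raise ValueError("preferred SF defined for fewer than 3 sizes; shift index undefined")
    if clamped.any():
        warnings.warn("preferred SF clamped to the tested grid span for some sizes")
    slope, _ = np.polyfit(np.log2(sizes[valid]), np.log2(prefs[valid]), 1)
    return ShiftIndexResult(
        neuron_id=neuron_id,
        preferred_per_size=prefs,
        shift_index=float(slope),
        clamped=clamped,
        fit_r2=r2,
    )


@dataclass
class ShiftCorrelation:
    correlation: CorrelationResult
    slope: float
    intercept: float


def shift_weight_correlation(shift_indices, values) -> ShiftCorrelation:
    """Spearman correlation (plus an OLS line for reporting) between
    per-neuron shift indices and classifier weights or response measures."""
    x = np.asarray(shift_indices, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired values")
    corr = spearman(x, y)
    reg = sps.linregress(x, y)
    return ShiftCorrelation(correlation=corr, slope=float(reg.slope), intercept=float(reg.intercept))
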