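"""One-site specific binding fits for ELISA-style concentration/response data.

Fits y = Bmax * x / (Kd + x) by nonlinear least squares, the saturation model
behind "one site - specific binding" presets of standard curve-fitting
software.  Replicates are fitted jointly with equal weights; reported
diagnostics are R^2 and the asymptotic standard error of Kd.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BindingCurve", "FitError", "one_site", "fit_one_site"]


class FitError(RuntimeError):
    """Raised when a binding curve cannot be fitted."""


@dataclasses.dataclass
class BindingCurve:
    concentrations_nm: np.ndarray
    responses: np.ndarray
    bmax: float
    kd_nm: float
    r_squared: float
    se_kd_nm: float


def one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Saturation binding model y = Bmax x / (Kd + x)."""
    return bmax * x / (kd + x)


def _kd_initial(x: np.ndarray, y: np.ndarray) -> float:
    """Concentration at half-maximal mean response, by linear interpolation."""
    xs = np.unique(x)
    ym = np.array([y[x == xi].mean() for xi in xs])
    half = ym.max() / 2.0
    if ym[0] >= half:
        return float(xs[0]) if xs[0] > 0 else float(xs[xs > 0].min())
    for i in range(1, len(xs)):
        if ym[i] >= half:
            x0, x1, y0, y1 = xs[i - 1], xs[i], ym[i - 1], ym[i]
            if y1 == y0:
                return float(x1)
            return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    return float(xs[-1])


def fit_one_site(
    concentrations_nm: np.ndarray, responses: np.ndarray
) -> BindingCurve:
    """Least-squares fit of the one-site model to (possibly replicated) data.

    Requires >= 4 distinct concentrations and at least one positive response.
    Initial values: Bmax0 = max(y), Kd0 = concentration at half-max response.
    """
    x = np.asarray(concentrations_nm, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("concentrations and responses must have the same length")
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    if len(np.unique(x)) < 4:
        raise FitError("need at least 4 distinct concentrations")
    if np.ptp(y) == 0:
        raise FitError("all responses equal: Kd is unidentifiable")
    if not np.any(y > 0):
        raise FitError("need at least one positive response")

    p0 = (float(y.max()), _kd_initial(x, y))
    try:
        popt, pcov = curve_fit(
            one_site,
            x,
            y,
            p0=p0,
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            maxfev=10_000,
        )
    except RuntimeError as exc:  # non-convergence
        raise FitError(f"one-site fit did not converge (p0={p0}): {exc}") from exc

    bmax, kd = float(popt[0]), float(popt[1])
    if kd <= 0:
        raise FitError("fit collapsed to non-positive Kd")
    resid = y - one_site(x, bmax, kd)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    with np.errstate(invalid="ignore"):
        se_kd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return BindingCurve(
        concentrations_nm=x,
        responses=y,
        bmax=bmax,
        kd_nm=kd,
        r_squared=r2,
        se_kd_nm=se_kd,
    )
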