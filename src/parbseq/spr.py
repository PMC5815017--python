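"""Equilibrium Kd estimation from surface plasmon resonance titrations.

The binding model is the 1:1 Langmuir steady-state isotherm

    R(c) = Rmax * c / (Kd + c)

for analyte concentration ``c``: a single protein dimer binding one
immobilised double-stranded DNA oligomer. Responses may be expressed as a
percentage of the theoretical maximum response Rmax so that titrations
recorded on surfaces with different amounts of tethered DNA are directly
comparable. Fitting minimises unweighted squared residuals over
(Kd, Rmax), both constrained positive; no kinetic (on/off-rate)
sensorgram analysis is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TitrationSeries:
    """Concentration/response pairs from one titration.

    ``concentrations`` are analyte concentrations (conventionally nM,
    strictly positive and distinct); ``responses`` are the equilibrium
    response levels per cycle (response units). At least three points are
    required for a two-parameter isotherm fit.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.ndim != 1 or conc.shape != resp.shape:
            raise ValueError("concentrations and responses must be 1-D arrays of equal length")
        if conc.size < 3:
            raise ValueError("need at least 3 titration points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(conc).size != conc.size:
            raise ValueError("concentrations must be distinct")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    def __len__(self) -> int:
        return self.concentrations.size


@dataclass(frozen=True)
class KdFit:
    """Result of a 1:1 isotherm least-squares fit."""

    kd: float
    rmax: float
    residual_sum_of_squares: float
    standard_error_kd: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and (self.kd <= 0 or self.rmax <= 0):
            raise ValueError("a converged fit must have kd > 0 and rmax > 0")


def percent_rmax(responses, rmax: float) -> np.ndarray:
    """Express responses as a percentage of the theoretical maximum Rmax."""
    if rmax <= 0:
        raise ValueError("rmax must be > 0")
    return 100.0 * np.asarray(responses, dtype=float) / rmax


def predict_response(kd: float, rmax: float, concentration) -> np.ndarray | float:
    """1:1 isotherm response ``rmax * c / (kd + c)`` (0 at c = 0, Rmax/2 at c = Kd)."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = rmax * c / (kd + c)
    return float(out) if out.ndim == 0 else out


def fit_kd(series: TitrationSeries) -> KdFit:
    """Nonlinear least-squares fit of the 1:1 isotherm to a titration.

    Initialisation: Kd0 is the concentration whose response is nearest half
    the maximum observed response; Rmax0 is 1.1x the maximum response. Both
    parameters are constrained positive. Non-convergence is reported via
    ``converged=False`` with the solver message, never a silent bad fit.
    The asymptotic standard error of Kd comes from the fit covariance.
    """
    conc = series.concentrations
    resp = series.responses
    rmax_obs = float(resp.max())
    if np.all(resp == 0):
        raise ValueError("responses are all zero: no binding signal to fit")
    kd0 = float(conc[np.argmin(np.abs(resp - rmax_obs / 2.0))])
    p0 = (kd0, 1.1 * rmax_obs)
    try:
        popt, pcov = curve_fit(
            lambda c, kd, rmax: rmax * c / (kd + c),
            conc,
            resp,
            p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10_000,
            x_scale="jac",  # scale-free trust region: unit conversions commute
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
        )
    except RuntimeError as exc:  # no convergence within maxfev
        return KdFit(
            kd=float("nan"),
            rmax=float("nan"),
            residual_sum_of_squares=float("nan"),
            standard_error_kd=float("nan"),
            converged=False,
            message=str(exc),
        )
    kd, rmax = float(popt[0]), float(popt[1])
    rss = float(np.sum((resp - predict_response(kd, rmax, conc)) ** 2))
    se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return KdFit(
        kd=kd,
        rmax=rmax,
        residual_sum_of_squares=rss,
        standard_error_kd=se_kd,
        converged=True,
    )
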