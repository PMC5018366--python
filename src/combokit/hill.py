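"""Single-agent Hill dose-response curves: prediction, inversion and fitting.

The curve is the 3-parameter sigmoid

    E(c) = E0 + (E_inf - E0) / (1 + (EC50 / c)^h)

with the baseline pinned at E0 = 100 (responses are % of untreated control,
so the control itself defines the top of the curve).  Free parameters are
``e_inf`` (plateau at infinite dose), ``ec50`` (dose of half-maximal effect)
and ``h`` (Hill slope).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillCurve",
    "HillFit",
    "FitError",
    "hill_response",
    "inverse_hill",
    "fit_hill",
    "extract_single_agents",
    "SingleAgentSeries",
]

E0 = 100.0

# fitting bounds: plateau in % points, ec50 relative to the dose range, slope
EINF_BOUNDS = (-20.0, 100.0)
H_BOUNDS = (0.1, 10.0)
EC50_RANGE_PAD = 100.0  # ec50 allowed within [min_dose/100, max_dose*100]

INACTIVE_EINF_MARGIN = 5.0  # |100 - e_inf| below this => agent called inactive
INACTIVE_R2 = 0.3


class FitError(ValueError):
    """Raised when a Hill fit cannot be attempted (too few doses)."""


@dataclass(frozen=True)
class HillCurve:
    """A fitted (or specified) 3-parameter Hill curve with baseline 100.

    Parameters
    ----------
    e_inf : float
        Response plateau at infinite dose, in % of control.
    ec50 : float
        Dose producing the response halfway between 100 and ``e_inf``.
        Must be positive; same units as the dose axis.
    h : float
        Hill slope, dimensionless and positive.
    """

    e_inf: float
    ec50: float
    h: float
    e0: float = E0

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if not (self.h > 0):
            raise ValueError(f"Hill slope must be positive, got {self.h}")

    def response(self, dose):
        """Predicted response (% control) at ``dose`` (scalar or array)."""
        return hill_response(self, dose)

    def inverse(self, response: float) -> float:
        """Dose producing ``response``; inverse of :meth:`response`."""
        return inverse_hill(self, response)


def hill_response(curve: HillCurve, dose):
    """Evaluate the Hill curve at one or more doses.

    Returns ``e0`` exactly at dose 0; strictly monotone from ``e0`` toward
    ``e_inf`` for positive doses.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    out = np.full(d.shape, curve.e0, dtype=float)
    pos = d > 0
    with np.errstate(over="ignore"):
        ratio = (curve.ec50 / d[pos]) ** curve.h
    out[pos] = curve.e0 + (curve.e_inf - curve.e0) / (1.0 + ratio)
    if np.isscalar(dose) or np.ndim(dose) == 0:
        return float(out)
    return out


def inverse_hill(curve: HillCurve, response: float) -> float:
    """Unique dose at which the curve attains ``response``.

    ``response`` must lie strictly between ``e_inf`` and ``e0``; outside
    that open interval the effect is not achievable by this agent and a
    ``ValueError`` is raised.
    """
    lo, hi = min(curve.e_inf, curve.e0), max(curve.e_inf, curve.e0)
    if not (lo < response < hi):
        raise ValueError(
            f"response {response} not achievable: must lie strictly within "
            f"({lo}, {hi}) for this curve"
        )
    # E = e0 + (e_inf - e0)/(1 + (ec50/d)^h)  =>  d = ec50 * ((e0-E)/(E-e_inf))^(1/h)
    return curve.ec50 * ((curve.e0 - response) / (response - curve.e_inf)) ** (
        1.0 / curve.h
    )


@dataclass
class HillFit:
    """Result of a Hill fit: the curve, uncertainties and diagnostics."""

    curve: HillCurve
    rmse: float
    r_squared: float
    stderr_e_inf: float = math.nan
    stderr_ec50: float = math.nan
    stderr_h: float = math.nan
    inactive: bool = False
    poor_fit: bool = False
    n_points: int = 0
    message: str = ""

    def params_frame(self):
        """Fitted parameters and diagnostics as a one-row DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "e_inf": self.curve.e_inf,
                    "ec50": self.curve.ec50,
                    "h": self.curve.h,
                    "se_e_inf": self.stderr_e_inf,
                    "se_ec50": self.stderr_ec50,
                    "se_h": self.stderr_h,
                    "rmse": self.rmse,
                    "r_squared": self.r_squared,
                    "inactive": self.inactive,
                    "poor_fit": self.poor_fit,
                    "n_points": self.n_points,
                }
            ]
        )


@dataclass
class SingleAgentSeries:
    """Dose series for one agent with replicate-wise responses retained."""

    doses: np.ndarray
    responses: np.ndarray  # shape (n_replicates, n_doses)

    @property
    def mean(self) -> np.ndarray:
        return self.responses.mean(axis=0)


def extract_single_agents(exp) -> tuple[SingleAgentSeries, SingleAgentSeries]:
    """Pull the two single-agent dose-response series out of a checkerboard.

    Agent A's series is the matrix row at dose_b = 0 (one value per column
    dose); agent B's is the column at dose_a = 0.  Replicate-wise values are
    kept so the fit can weight individual points.
    """
    doses_a = np.asarray(exp.doses_a, dtype=float)
    doses_b = np.asarray(exp.doses_b, dtype=float)
    i0 = int(np.flatnonzero(doses_b == 0)[0])
    j0 = int(np.flatnonzero(doses_a == 0)[0])
    rows = np.stack([np.asarray(r, dtype=float)[i0, :] for r in exp.replicates])
    cols = np.stack([np.asarray(r, dtype=float)[:, j0] for r in exp.replicates])
    return (
        SingleAgentSeries(doses=doses_a, responses=rows),
        SingleAgentSeries(doses=doses_b, responses=cols),
    )


def _prepare_points(doses, responses_by_replicate):
    doses = np.asarray(doses, dtype=float)
    resp = np.asarray(responses_by_replicate, dtype=float)
    if resp.ndim == 1:
        resp = resp[None, :]
    if resp.shape[1] != doses.size:
        raise ValueError(
            f"responses have {resp.shape[1]} dose columns, expected {doses.size}"
        )
    # flatten replicates into (dose, response) points; order-invariant loss
    d = np.tile(doses, resp.shape[0])
    y = resp.ravel()
    ok = np.isfinite(y)
    return d[ok], y[ok]


def fit_hill(doses, responses_by_replicate, *, weights=None) -> HillFit:
    """Fit the 3-parameter Hill model by bounded least squares.

    Parameters
    ----------
    doses : array-like
        Dose values; zero-dose points are kept as baseline anchors.
    responses_by_replicate : array-like
        Either a 1-D response vector or a (n_replicates, n_doses) matrix in
        % of control.  All replicate points enter the loss individually
        (unweighted by default).
    weights : array-like, optional
        Per-dose weights applied to every replicate (sqrt-weighted residuals).

    Notes
    -----
    The optimisation runs over (e_inf, log ec50, h) from a fixed multi-start
    grid (5 log-spaced ec50 starts x 3 slope starts), so the result is
    deterministic.  Bounds: e_inf in [-20, 100], ec50 within the dose range
    padded by 100x either side, h in [0.1, 10].
    """
    d, y = _prepare_points(doses, responses_by_replicate)
    nz = np.unique(d[d > 0])
    if nz.size < 3:
        raise FitError(
            f"need >= 3 distinct non-zero doses to fit 3 parameters, got {nz.size}"
        )
    if weights is not None:
        w_by_dose = dict(zip(np.asarray(doses, dtype=float), np.asarray(weights, float)))
        w = np.array([w_by_dose[di] for di in d])
        sw = np.sqrt(w)
    else:
        sw = None

    log_lo, log_hi = math.log(nz.min() / EC50_RANGE_PAD), math.log(
        nz.max() * EC50_RANGE_PAD
    )
    lb = np.array([EINF_BOUNDS[0], log_lo, H_BOUNDS[0]])
    ub = np.array([EINF_BOUNDS[1], log_hi, H_BOUNDS[1]])

    pos = d > 0
    logd = np.zeros_like(d)
    logd[pos] = np.log(d[pos])

    def predict(theta):
        e_inf, log_ec50, h = theta
        out = np.full_like(d, E0)
        out[pos] = E0 + (e_inf - E0) / (1.0 + np.exp(h * (log_ec50 - logd[pos])))
        return out

    def resid(theta):
        r = predict(theta) - y
        return r * sw if sw is not None else r

    e_inf0 = float(np.clip(np.min(y), *EINF_BOUNDS))
    ec50_starts = np.log(np.geomspace(nz.min(), nz.max(), 5))
    h_starts = (0.5, 1.0, 3.0)

    best = None
    n_failed = 0
    for le in ec50_starts:
        for h0 in h_starts:
            x0 = np.clip(np.array([e_inf0, le, h0]), lb, ub)
            try:
                sol = least_squares(
                    resid, x0, bounds=(lb, ub), method="trf",
                    ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception:  # pragma: no cover - optimizer hard failure
                n_failed += 1
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:  # pragma: no cover - all starts failed
        # fall back to the best point of the start grid itself
        grid = [
            np.clip(np.array([e_inf0, le, h0]), lb, ub)
            for le in ec50_starts
            for h0 in h_starts
        ]
        costs = [float(np.sum(resid(g) ** 2)) for g in grid]
        theta = grid[int(np.argmin(costs))]
        curve = HillCurve(float(theta[0]), float(math.exp(theta[1])), float(theta[2]))
        r = predict(theta) - y
        rmse = float(np.sqrt(np.mean(r**2)))
        return HillFit(
            curve=curve, rmse=rmse, r_squared=math.nan, poor_fit=True,
            n_points=y.size, message="all optimizer starts failed; grid fallback",
        )

    theta = best.x
    e_inf, ec50, h = float(theta[0]), float(math.exp(theta[1])), float(theta[2])
    curve = HillCurve(e_inf=e_inf, ec50=ec50, h=h)
    r = predict(theta) - y
    rmse = float(np.sqrt(np.mean(r**2)))
    ss_res = float(np.sum(r**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan

    se = _param_stderr(best.jac, ss_res, y.size)
    inactive = abs(E0 - e_inf) < INACTIVE_EINF_MARGIN or (
        not math.isnan(r2) and r2 < INACTIVE_R2
    )
    return HillFit(
        curve=curve,
        rmse=rmse,
        r_squared=r2,
        stderr_e_inf=se[0],
        stderr_ec50=ec50 * se[1],  # delta method from log-ec50 space
        stderr_h=se[2],
        inactive=inactive,
        n_points=y.size,
        message="inactive agent (flat response)" if inactive else "",
    )


def _param_stderr(jac, ss_res, n):
    dof = n - 3
    if dof <= 0:
        return (math.nan,) * 3
    s2 = ss_res / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        var = np.diag(cov)
        if np.any(var < 0):
            return (math.nan,) * 3
        return tuple(float(v) for v in np.sqrt(var))
    except np.linalg.LinAlgError:
        return (math.nan,) * 3
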