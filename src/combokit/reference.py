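"""Non-synergistic reference surfaces for a drug pair.

Given the two fitted single-agent Hill curves, each classical null model
predicts the combination response expected in the absence of interaction:

* **Loewe additivity** (dose equivalence): at dose pair (a, b) the reference
  effect E* solves the combination-index equation a/A(E*) + b/B(E*) = 1,
  where A(E), B(E) are the single-agent doses producing effect E.  A drug is
  exactly additive with itself under this model.
* **Bliss independence**: surviving fractions multiply, so the reference is
  E_A * E_B / 100 with responses read as surviving fraction x 100.
* **HSA** (highest single agent): the stronger of the two single-agent
  effects, min(E_A, E_B).

All three surfaces agree with the single-agent curves on the two axes by
construction (axis cells are assigned directly from the curves).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .hill import HillCurve, hill_response

__all__ = [
    "Model",
    "CellFlag",
    "ReferenceSurface",
    "bliss_surface",
    "hsa_surface",
    "loewe_surface",
    "reference_surface",
    "LOEWE_TOL",
]

LOEWE_TOL = 1e-8


class Model(str, enum.Enum):
    """Identifier of a non-interaction reference model."""

    LOEWE = "LOEWE"
    BLISS = "BLISS"
    HSA = "HSA"

    @classmethod
    def parse(cls, value) -> "Model":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unknown model {value!r}; expected one of "
                f"{[m.value.lower() for m in cls]}"
            ) from None


class CellFlag(enum.IntEnum):
    """Per-cell solver status recorded in a reference surface."""

    EXACT = 0       # closed form or converged root
    CLAMPED = 1     # Bliss inputs clamped into [0, 100]
    CAPPED = 2      # Loewe effect unreachable; capped at the weaker asymptote
    FALLBACK = 3    # inactive agent; reference fell back to single agent


@dataclass
class ReferenceSurface:
    """Model-predicted non-synergistic response matrix on the dose grids."""

    model: Model
    doses_a: np.ndarray
    doses_b: np.ndarray
    values: np.ndarray          # shape (n_doses_b, n_doses_a), % control
    flags: np.ndarray           # same shape, CellFlag codes

    @property
    def shape(self):
        return self.values.shape

    def flagged_cells(self, flag: CellFlag):
        """Indices (i, j) of cells carrying ``flag``."""
        return [tuple(ix) for ix in np.argwhere(self.flags == int(flag))]


def _axis_template(curve_a, curve_b, doses_a, doses_b):
    """Allocate value/flag matrices with the single-agent axes pre-filled."""
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    ea = hill_response(curve_a, doses_a)
    eb = hill_response(curve_b, doses_b)
    values = np.empty((doses_b.size, doses_a.size))
    flags = np.zeros(values.shape, dtype=np.int8)
    i0 = int(np.flatnonzero(doses_b == 0)[0])
    j0 = int(np.flatnonzero(doses_a == 0)[0])
    values[i0, :] = ea
    values[:, j0] = eb
    return doses_a, doses_b, ea, eb, values, flags, i0, j0


def bliss_surface(curve_a: HillCurve, curve_b: HillCurve, doses_a, doses_b
                  ) -> ReferenceSurface:
    """Bliss-independence surface: product of surviving fractions.

    Fitted plateaus below 0 (or above 100) are clamped into [0, 100] before
    the product, since the probabilistic law is only defined for fractions;
    clamped cells are flagged.
    """
    doses_a, doses_b, ea, eb, values, flags, i0, j0 = _axis_template(
        curve_a, curve_b, doses_a, doses_b
    )
    clamped_a = (ea < 0) | (ea > 100)
    clamped_b = (eb < 0) | (eb > 100)
    fa = np.clip(ea, 0.0, 100.0) / 100.0
    fb = np.clip(eb, 0.0, 100.0) / 100.0
    interior = np.ones(values.shape, dtype=bool)
    interior[i0, :] = False
    interior[:, j0] = False
    prod = np.outer(fb, fa) * 100.0
    values[interior] = prod[interior]
    flag_cells = interior & (clamped_b[:, None] | clamped_a[None, :])
    flags[flag_cells] = int(CellFlag.CLAMPED)
    return ReferenceSurface(Model.BLISS, doses_a, doses_b, values, flags)


def hsa_surface(curve_a: HillCurve, curve_b: HillCurve, doses_a, doses_b
                ) -> ReferenceSurface:
    """Highest-single-agent surface: the lower % control of the two agents."""
    doses_a, doses_b, ea, eb, values, flags, i0, j0 = _axis_template(
        curve_a, curve_b, doses_a, doses_b
    )
    interior = np.ones(values.shape, dtype=bool)
    interior[i0, :] = False
    interior[:, j0] = False
    m = np.minimum(eb[:, None], ea[None, :])
    values[interior] = m[interior]
    return ReferenceSurface(Model.HSA, doses_a, doses_b, values, flags)


def loewe_surface(curve_a: HillCurve, curve_b: HillCurve, doses_a, doses_b,
                  tol: float = LOEWE_TOL, *, inactive_a: bool = False,
                  inactive_b: bool = False) -> ReferenceSurface:
    """Loewe-additivity surface by root-finding on the combination index.

    For each interior cell the reference effect E* is bracketed on
    (max(e_inf_a, e_inf_b), 100) — the combination index a/A(E) + b/B(E) is
    strictly increasing in E there — and solved with Brent's method to a
    residual |CI - 1| < ``tol``.  Cells demanding an effect deeper than the
    weaker agent's plateau have no root; they are capped at that plateau and
    flagged ``CAPPED``.  If one agent is inactive the dose-equivalence
    equation is ill-posed and the surface falls back to the active agent's
    own curve (``FALLBACK``); with both inactive it falls back to HSA.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if inactive_a and inactive_b:
        surf = hsa_surface(curve_a, curve_b, doses_a, doses_b)
        flags = np.full(surf.values.shape, int(CellFlag.FALLBACK), dtype=np.int8)
        return ReferenceSurface(Model.LOEWE, surf.doses_a, surf.doses_b,
                                surf.values, flags)
    if inactive_a or inactive_b:
        active = curve_b if inactive_a else curve_a
        doses_a2, doses_b2, ea, eb, values, flags, i0, j0 = _axis_template(
            curve_a, curve_b, doses_a, doses_b
        )
        interior = np.ones(values.shape, dtype=bool)
        interior[i0, :] = False
        interior[:, j0] = False
        if inactive_a:
            base = np.broadcast_to(eb[:, None], values.shape)
        else:
            base = np.broadcast_to(ea[None, :], values.shape)
        values[interior] = base[interior]
        flags[interior] = int(CellFlag.FALLBACK)
        return ReferenceSurface(Model.LOEWE, doses_a2, doses_b2, values, flags)

    doses_a, doses_b, ea, eb, values, flags, i0, j0 = _axis_template(
        curve_a, curve_b, doses_a, doses_b
    )
    lo = max(curve_a.e_inf, curve_b.e_inf)
    span = 100.0 - lo
    e_lo = lo + 1e-9 * span
    e_hi = 100.0 - 1e-13 * span

    def ci_minus_one(E, a, b):
        da = curve_a.ec50 * ((100.0 - E) / (E - curve_a.e_inf)) ** (1.0 / curve_a.h)
        db = curve_b.ec50 * ((100.0 - E) / (E - curve_b.e_inf)) ** (1.0 / curve_b.h)
        return a / da + b / db - 1.0

    for i, b in enumerate(doses_b):
        if b == 0:
            continue
        for j, a in enumerate(doses_a):
            if a == 0:
                continue
            f_lo = ci_minus_one(e_lo, a, b)
            if f_lo >= 0.0:
                # demanded effect lies beyond the weaker agent's asymptote
                values[i, j] = lo
                flags[i, j] = int(CellFlag.CAPPED)
                continue
            root = brentq(ci_minus_one, e_lo, e_hi, args=(a, b),
                          xtol=1e-12, rtol=8.9e-16, maxiter=200)
            if abs(ci_minus_one(root, a, b)) > tol and (e_hi - e_lo) > 1e-10:
                root = brentq(ci_minus_one, e_lo, e_hi, args=(a, b),
                              xtol=1e-15, rtol=8.9e-16, maxiter=400)
            values[i, j] = root
    return ReferenceSurface(Model.LOEWE, doses_a, doses_b, values, flags)


def reference_surface(model, curve_a, curve_b, doses_a, doses_b,
                      tol: float = LOEWE_TOL, *, inactive_a=False,
                      inactive_b=False) -> ReferenceSurface:
    """Dispatch to the requested model's surface constructor."""
    model = Model.parse(model)
    if model is Model.BLISS:
        return bliss_surface(curve_a, curve_b, doses_a, doses_b)
    if model is Model.HSA:
        return hsa_surface(curve_a, curve_b, doses_a, doses_b)
    return loewe_surface(curve_a, curve_b, doses_a, doses_b, tol,
                         inactive_a=inactive_a, inactive_b=inactive_b)
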