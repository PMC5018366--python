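"""Scalar summaries of a synergy distribution for ranking combinations.

All "integrated" metrics are means over interior cells (both doses > 0),
not sums, so values are comparable across screens mixing grid sizes.
Units are % points throughout; dose coordinates are in the experiment's
concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synergy import SynergyDistribution

__all__ = ["MetricsRecord", "compute_metrics"]


@dataclass
class MetricsRecord:
    """Named scalar summaries of one synergy distribution under one model.

    ``sum_synergy`` / ``sum_antagonism`` are the means of the positive /
    negative parts, so ``integrated_total = sum_synergy + sum_antagonism``.
    ``weighted_integrated`` re-weights cells toward high-effect regions of
    the observed surface.  ``peak_dose_a/b`` locate where synergy is most
    dense: the argmax after 3x3 uniform smoothing.
    """

    model: str
    max_synergy: float
    max_antagonism: float
    sum_synergy: float
    sum_antagonism: float
    integrated_total: float
    weighted_integrated: float
    peak_dose_a: float
    peak_dose_b: float
    n_cells: int

    FIELDS = (
        "max_synergy",
        "max_antagonism",
        "sum_synergy",
        "sum_antagonism",
        "integrated_total",
        "weighted_integrated",
        "peak_dose_a",
        "peak_dose_b",
        "n_cells",
    )


def _smooth_3x3(values: np.ndarray) -> np.ndarray:
    """3x3 uniform smoothing with the kernel truncated at borders.

    Weights stay 1/9 everywhere (zero padding, no renormalization): a
    renormalized border kernel would inflate cells with fewer neighbors and
    could move the density peak to an empty corner.
    """
    k = np.full((3, 3), 1.0 / 9.0)
    return ndimage.convolve(values, k, mode="constant", cval=0.0)


def compute_metrics(dist: SynergyDistribution, exp) -> MetricsRecord:
    """Summarize one synergy distribution into a :class:`MetricsRecord`.

    Only interior cells (both doses positive) enter: axis cells measure
    single-agent fit residual, not interaction.  The density peak is the
    argmax of the 3x3-smoothed interior distribution; exact ties break
    first on the unsmoothed value, then to the lexicographically lowest
    (dose_a, dose_b) pair, so the result is deterministic and favors lower
    doses.
    """
    interior = dist.interior_mask()
    if not interior.any():
        raise ValueError("no interior cells: grid has no positive-dose pairs")
    rows = np.asarray(dist.doses_b) > 0
    cols = np.asarray(dist.doses_a) > 0
    V = dist.values[np.ix_(rows, cols)]        # interior block, doses ascending
    da = np.asarray(dist.doses_a, dtype=float)[cols]
    db = np.asarray(dist.doses_b, dtype=float)[rows]

    smoothed = _smooth_3x3(V)
    smax = smoothed.max()
    tol = 1e-12 * max(1.0, abs(smax))
    cand = np.argwhere(smoothed >= smax - tol)
    raw = V[cand[:, 0], cand[:, 1]]
    rmax = raw.max()
    rtol = 1e-12 * max(1.0, abs(rmax))
    cand = cand[raw >= rmax - rtol]
    # lexicographic on (dose_a, dose_b): doses ascending => compare indices (j, i)
    j_best, i_best = min((int(j), int(i)) for i, j in cand)

    mean_data = exp.mean_response[np.ix_(rows, cols)]
    w = np.clip((100.0 - mean_data) / 100.0, 0.0, 1.0)
    wsum = w.sum()
    weighted = float((w * V).sum() / wsum) if wsum > 0 else float(V.mean())

    return MetricsRecord(
        model=str(getattr(dist.model, "value", dist.model)),
        max_synergy=float(max(V.max(), 0.0)),
        max_antagonism=float(min(V.min(), 0.0)),
        sum_synergy=float(np.maximum(V, 0.0).mean()),
        sum_antagonism=float(np.minimum(V, 0.0).mean()),
        integrated_total=float(V.mean()),
        weighted_integrated=weighted,
        peak_dose_a=float(da[j_best]),
        peak_dose_b=float(db[i_best]),
        n_cells=int(V.size),
    )
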