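"""Synergy/antagonism distribution: reference surface minus observed data.

The per-cell score is ``reference - mean(observed)`` in % points, so a
combination killing *more* than the null model predicts (observed % control
below the reference) scores positive synergy, and one killing less scores
negative (antagonism).  The opposite convention is available via
``sign="data_minus_reference"`` since usage in the literature is split.

Axis cells (either dose zero) measure single-agent fit residual rather than
interaction; they are kept in the matrix but excluded from metrics by
default via :meth:`SynergyDistribution.interior_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reference import Model, ReferenceSurface

__all__ = ["SynergyDistribution", "synergy_distribution", "significance_mask"]


@dataclass
class SynergyDistribution:
    model: Model
    doses_a: np.ndarray
    doses_b: np.ndarray
    values: np.ndarray            # % points; positive = synergy
    per_cell_sd: np.ndarray | None  # replicate SD, None if < 2 replicates
    n_replicates: int

    def interior_mask(self) -> np.ndarray:
        """Cells where both doses are positive (true combination cells)."""
        return np.outer(np.asarray(self.doses_b) > 0,
                        np.asarray(self.doses_a) > 0)

    @property
    def interior_values(self) -> np.ndarray:
        return self.values[self.interior_mask()]


def synergy_distribution(exp, ref: ReferenceSurface, *,
                         sign: str = "reference_minus_data"
                         ) -> SynergyDistribution:
    """Compare the observed surface to a reference surface cell by cell.

    Parameters
    ----------
    exp : CombinationExperiment
        Observed checkerboard; replicates are averaged per cell.
    ref : ReferenceSurface
        Null-model prediction on the same dose grids.
    sign : {"reference_minus_data", "data_minus_reference"}
        Which deviation counts as positive.  The default scores excess kill
        (data below reference) as positive synergy.
    """
    if sign not in ("reference_minus_data", "data_minus_reference"):
        raise ValueError(f"unknown sign convention {sign!r}")
    mean = exp.mean_response
    if mean.shape != ref.values.shape:
        raise ValueError(
            f"shape mismatch: data {mean.shape} vs reference {ref.values.shape}"
        )
    if not (np.array_equal(exp.doses_a, ref.doses_a)
            and np.array_equal(exp.doses_b, ref.doses_b)):
        raise ValueError("dose grids of data and reference differ")
    values = ref.values - mean
    if sign == "data_minus_reference":
        values = -values
    return SynergyDistribution(
        model=ref.model,
        doses_a=ref.doses_a,
        doses_b=ref.doses_b,
        values=values,
        per_cell_sd=exp.replicate_sd,
        n_replicates=exp.n_replicates,
    )


def significance_mask(exp, ref: ReferenceSurface, *, alpha: float = 0.05,
                      bonferroni: bool = True) -> np.ndarray:
    """Optional per-cell significance of the deviation from the reference.

    For each interior cell a two-sided one-sample t-test of the replicate
    deviations (reference - replicate value) against 0; requires >= 3
    replicates.  With ``bonferroni`` the level is divided by the number of
    interior cells.  Returns a boolean matrix (axis cells always False).
    This is an extension beyond the core surface workflow and is off by
    default in the pipeline.
    """
    if exp.n_replicates < 3:
        raise ValueError("significance testing requires >= 3 replicates")
    interior = np.outer(exp.doses_b > 0, exp.doses_a > 0)
    stack = np.stack(exp.replicates)           # (n_rep, nb, na)
    dev = ref.values[None, :, :] - stack
    level = alpha / interior.sum() if bonferroni else alpha
    mask = np.zeros(interior.shape, dtype=bool)
    res = stats.ttest_1samp(dev, popmean=0.0, axis=0)
    with np.errstate(invalid="ignore"):
        mask[interior] = res.pvalue[interior] < level
    return mask
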