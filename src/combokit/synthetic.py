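"""Synthetic checkerboard experiments with known ground truth.

Responses are generated from a chosen null model's reference surface built
on two known Hill curves, minus an optional planted synergy field (in %
points, positive = synergy under the reference-minus-data convention), plus
i.i.d. Gaussian noise on the % scale.  Defaults mirror a typical viability
checkerboard: an 8x8 grid (zero dose plus 7 log-spaced doses per agent),
3 replicates and 3 % points of noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .experiment import CombinationExperiment, write_experiment
from .hill import HillCurve
from .reference import Model, reference_surface

__all__ = ["SimulationSpec", "simulate_experiment", "simulate_screen",
           "log_dose_grid", "DEFAULT_CURVE_A", "DEFAULT_CURVE_B"]

DEFAULT_CURVE_A = HillCurve(e_inf=5.0, ec50=1.0, h=1.2)
DEFAULT_CURVE_B = HillCurve(e_inf=15.0, ec50=2.0, h=0.9)
DEFAULT_NOISE_SD = 3.0
DEFAULT_N_REPLICATES = 3


def log_dose_grid(n: int = 8, ec50: float = 1.0, decades: float = 2.5
                  ) -> np.ndarray:
    """Zero dose plus ``n - 1`` log-spaced doses centered on ``ec50``.

    The positive doses span ``decades`` orders of magnitude symmetrically
    around ``ec50`` so the sigmoid's full range is sampled.
    """
    if n < 2:
        raise ValueError("need at least 2 doses (zero + one positive)")
    half = 10.0 ** (decades / 2.0)
    pos = np.geomspace(ec50 / half, ec50 * half, n - 1)
    return np.concatenate([[0.0], pos])


@dataclass
class SimulationSpec:
    """Ground truth for one simulated experiment; ``seed`` is mandatory."""

    seed: int
    curve_a: HillCurve = DEFAULT_CURVE_A
    curve_b: HillCurve = DEFAULT_CURVE_B
    model: Model = Model.BLISS
    doses_a: np.ndarray = None
    doses_b: np.ndarray = None
    synergy_field: np.ndarray = None   # % points; 0 = non-synergistic
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = DEFAULT_N_REPLICATES
    name: str = "simulated"

    def __post_init__(self):
        self.model = Model.parse(self.model)
        if self.doses_a is None:
            self.doses_a = log_dose_grid(8, self.curve_a.ec50)
        if self.doses_b is None:
            self.doses_b = log_dose_grid(8, self.curve_b.ec50)
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        shape = (self.doses_b.size, self.doses_a.size)
        if self.synergy_field is None:
            self.synergy_field = np.zeros(shape)
        self.synergy_field = np.asarray(self.synergy_field, dtype=float)
        if self.synergy_field.shape != shape:
            raise ValueError(
                f"synergy_field shape {self.synergy_field.shape} != grid {shape}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_experiment(spec: SimulationSpec) -> CombinationExperiment:
    """Generate a checkerboard experiment from the ground-truth spec.

    Each replicate is ``reference - synergy_field + noise`` with independent
    N(0, noise_sd^2) noise in every cell including the control, so the
    output is exactly reproducible under ``spec.seed``.
    """
    ref = reference_surface(spec.model, spec.curve_a, spec.curve_b,
                            spec.doses_a, spec.doses_b)
    rng = np.random.default_rng(spec.seed)
    truth = ref.values - spec.synergy_field
    reps = [
        truth + rng.normal(0.0, spec.noise_sd, size=truth.shape)
        if spec.noise_sd > 0 else truth.copy()
        for _ in range(spec.n_replicates)
    ]
    return CombinationExperiment.build(
        name=spec.name, doses_a=spec.doses_a, doses_b=spec.doses_b,
        replicates=reps, agent_a_name="AgentA", agent_b_name="AgentB",
    )


def simulate_screen(out_dir, n_experiments: int, seed: int, *,
                    model: Model = Model.BLISS, grid: int = 8,
                    noise_sd: float = DEFAULT_NOISE_SD,
                    n_replicates: int = DEFAULT_N_REPLICATES) -> list[Path]:
    """Write ``n_experiments`` ready-to-analyze experiment folders.

    Each experiment gets randomized (seeded) Hill curves — plateau in
    [0, 40] % control, ec50 log-uniform over one decade, slope in [0.5, 4] —
    and its files go through the package's own writer, so reading them back
    also exercises the parser.  Returns the experiment folder paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    folders = []
    for k in range(n_experiments):
        curves = []
        for _ in range(2):
            curves.append(HillCurve(
                e_inf=float(rng.uniform(0.0, 40.0)),
                ec50=float(10.0 ** rng.uniform(-0.5, 0.5)),
                h=float(rng.uniform(0.5, 4.0)),
            ))
        name = f"combo_{k + 1:03d}"
        spec = SimulationSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            curve_a=curves[0], curve_b=curves[1], model=model,
            doses_a=log_dose_grid(grid, curves[0].ec50),
            doses_b=log_dose_grid(grid, curves[1].ec50),
            noise_sd=noise_sd, n_replicates=n_replicates, name=name,
        )
        exp = simulate_experiment(spec)
        folder = out_dir / name
        folder.mkdir(exist_ok=True)
        write_experiment(exp, folder)
        folders.append(folder)
    return folders
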