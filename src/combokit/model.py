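"""Model/Results interface tying the analysis pipeline together.

:class:`CombinationModel` wraps one checkerboard experiment plus analysis
settings; :meth:`CombinationModel.fit` runs the full pipeline — single-agent
extraction, Hill fits, reference surface per requested null model, synergy
distribution, metrics — and returns a :class:`CombinationResults` carrying
the estimates, their standard errors, diagnostics and a ``summary()`` table.

    >>> model = CombinationModel.from_file("experiment.csv")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.metrics["BLISS"].max_synergy
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import (CombinationExperiment, read_experiment,
                         write_matrix_csv)
from .hill import HillFit, extract_single_agents, fit_hill
from .metrics import MetricsRecord, compute_metrics
from .reference import LOEWE_TOL, Model, ReferenceSurface, reference_surface
from .synergy import SynergyDistribution, significance_mask, synergy_distribution

__all__ = ["CombinationModel", "CombinationResults", "ALL_MODELS"]

ALL_MODELS = (Model.LOEWE, Model.BLISS, Model.HSA)


class CombinationModel:
    """Synergy analysis of one drug-combination checkerboard.

    Parameters
    ----------
    experiment : CombinationExperiment
        Dose grids and replicate response matrices in % of control.
    models : sequence of str or Model
        Null models to evaluate (default: Loewe, Bliss and HSA).
    loewe_tol : float
        Residual tolerance on the Loewe combination index.
    sign : str
        Synergy sign convention, see :func:`combokit.synergy.synergy_distribution`.
    """

    def __init__(self, experiment: CombinationExperiment,
                 models=ALL_MODELS, *, loewe_tol: float = LOEWE_TOL,
                 sign: str = "reference_minus_data"):
        self.experiment = experiment
        self.models = tuple(Model.parse(m) for m in models)
        if not self.models:
            raise ValueError("at least one reference model must be selected")
        self.loewe_tol = loewe_tol
        self.sign = sign

    @classmethod
    def from_file(cls, path, *, raw_normalize: bool = False, **kwargs
                  ) -> "CombinationModel":
        """Build the model from a template CSV/XLSX file or folder."""
        exp = read_experiment(path, raw_normalize=raw_normalize)
        return cls(exp, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "experiment",
                       **kwargs) -> "CombinationModel":
        """Build from a DataFrame whose index holds doses_b and columns doses_a."""
        exp = CombinationExperiment.build(
            name=name,
            doses_a=np.asarray(df.columns, dtype=float),
            doses_b=np.asarray(df.index, dtype=float),
            replicates=[df.to_numpy(dtype=float)],
        )
        return cls(exp, **kwargs)

    def fit(self) -> "CombinationResults":
        """Run the full pipeline and return the results object."""
        exp = self.experiment
        series_a, series_b = extract_single_agents(exp)
        fit_a = fit_hill(series_a.doses, series_a.responses)
        fit_b = fit_hill(series_b.doses, series_b.responses)
        references: dict[str, ReferenceSurface] = {}
        distributions: dict[str, SynergyDistribution] = {}
        metrics: dict[str, MetricsRecord] = {}
        for m in self.models:
            ref = reference_surface(
                m, fit_a.curve, fit_b.curve, exp.doses_a, exp.doses_b,
                self.loewe_tol, inactive_a=fit_a.inactive,
                inactive_b=fit_b.inactive,
            )
            dist = synergy_distribution(exp, ref, sign=self.sign)
            references[m.value] = ref
            distributions[m.value] = dist
            metrics[m.value] = compute_metrics(dist, exp)
        return CombinationResults(
            model=self, experiment=exp, fit_a=fit_a, fit_b=fit_b,
            references=references, distributions=distributions, metrics=metrics,
        )


@dataclass
class CombinationResults:
    """Fitted pipeline outputs for one experiment.

    Attributes
    ----------
    fit_a, fit_b : HillFit
        Single-agent Hill estimates with standard errors and diagnostics.
    references, distributions, metrics : dict
        Keyed by model name ("LOEWE", "BLISS", "HSA").
    """

    model: CombinationModel
    experiment: CombinationExperiment
    fit_a: HillFit
    fit_b: HillFit
    references: dict
    distributions: dict
    metrics: dict

    def hill_params(self) -> pd.DataFrame:
        """Both agents' fitted Hill parameters, SEs and diagnostics."""
        frames = []
        for agent, f in ((self.experiment.agent_a_name, self.fit_a),
                         (self.experiment.agent_b_name, self.fit_b)):
            df = f.params_frame()
            df.insert(0, "agent", agent)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def metrics_frame(self) -> pd.DataFrame:
        """Long-form metrics table: one row per model."""
        rows = []
        for mname, rec in self.metrics.items():
            row = {"experiment": self.experiment.name, "model": mname}
            row.update({f: getattr(rec, f) for f in MetricsRecord.FIELDS})
            rows.append(row)
        return pd.DataFrame(rows)

    def significance(self, alpha: float = 0.05, model=None) -> np.ndarray:
        """Per-cell significance mask (needs >= 3 replicates); extension."""
        m = Model.parse(model) if model is not None else self.model.models[0]
        return significance_mask(self.experiment, self.references[m.value],
                                 alpha=alpha)

    def summary(self) -> str:
        """Human-readable report: Hill estimates then per-model metrics."""
        exp = self.experiment
        lines = [
            "Drug Combination Synergy Analysis",
            "=" * 60,
            f"Experiment: {exp.name}",
            f"Agents: {exp.agent_a_name} (columns) x {exp.agent_b_name} (rows)",
            f"Grid: {exp.doses_b.size} x {exp.doses_a.size} doses, "
            f"{exp.n_replicates} replicate(s)",
            "",
            "Single-agent Hill fits (baseline fixed at 100% control)",
            "-" * 60,
            f"{'agent':<16}{'e_inf':>9}{'(se)':>9}{'ec50':>10}{'(se)':>9}"
            f"{'h':>7}{'(se)':>8}{'R2':>7}",
        ]
        for agent, f in ((exp.agent_a_name, self.fit_a),
                         (exp.agent_b_name, self.fit_b)):
            c = f.curve
            lines.append(
                f"{agent:<16}{c.e_inf:>9.2f}{f.stderr_e_inf:>9.2g}"
                f"{c.ec50:>10.4g}{f.stderr_ec50:>9.2g}"
                f"{c.h:>7.2f}{f.stderr_h:>8.2g}{f.r_squared:>7.3f}"
                + ("  [inactive]" if f.inactive else "")
            )
        lines += ["", "Synergy metrics (% points; positive = synergy)",
                  "-" * 60]
        header = f"{'metric':<22}" + "".join(
            f"{m:>12}" for m in self.metrics
        )
        lines.append(header)
        for fname in MetricsRecord.FIELDS:
            vals = "".join(
                f"{getattr(self.metrics[m], fname):>12.4g}" for m in self.metrics
            )
            lines.append(f"{fname:<22}{vals}")
        if exp.warnings:
            lines += ["", f"Warnings: {len(exp.warnings)} value(s) outside "
                          "the plausible range (see experiment.warnings)"]
        return "\n".join(lines)

    def save(self, out_dir, *, plots: bool = False, plot_format: str = "png"
             ) -> list[Path]:
        """Write fitted parameters, reference/synergy matrices and metrics.

        Returns the list of files written (one folder per experiment).
        """
        out_dir = Path(out_dir) / self.experiment.name
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        p = out_dir / "hill_parameters.csv"
        self.hill_params().to_csv(p, index=False)
        written.append(p)
        for mname in self.metrics:
            ref = self.references[mname]
            dist = self.distributions[mname]
            written.append(write_matrix_csv(
                out_dir / f"reference_{mname.lower()}.csv",
                ref.doses_a, ref.doses_b, ref.values))
            written.append(write_matrix_csv(
                out_dir / f"synergy_{mname.lower()}.csv",
                dist.doses_a, dist.doses_b, dist.values))
        p = out_dir / "metrics.csv"
        self.metrics_frame().to_csv(p, index=False)
        written.append(p)
        if plots:
            from .viz import PlotSpec, default_specs, render
            specs = default_specs(self.metrics, fmt=plot_format)
            written.extend(render(self.experiment, (self.fit_a, self.fit_b),
                                  self.references, self.distributions,
                                  specs, out_dir))
        return written
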