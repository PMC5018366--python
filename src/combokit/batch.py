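"""Screen-level batch processing: one experiment per sub-folder.

Experiments are processed sequentially in name order; a failing experiment
is recorded and does not abort the batch, so corrupting one folder changes
only that folder's rows.  Output tables are formatted deterministically, so
two runs on the same input are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .experiment import read_experiment_dir, write_metrics_table
from .model import ALL_MODELS, CombinationModel
from .reference import Model

__all__ = ["BatchResult", "run_batch"]


@dataclass
class BatchRow:
    experiment: str
    model: str
    metrics: object                 # MetricsRecord
    fit_a: object                   # HillFit
    fit_b: object
    warnings: list


@dataclass
class BatchResult:
    rows: list = field(default_factory=list)
    failures: list = field(default_factory=list)   # (experiment, message)

    @property
    def n_experiments(self) -> int:
        return len({r.experiment for r in self.rows})

    def metrics_long(self) -> pd.DataFrame:
        """Long-form table: one row per (experiment, model)."""
        from .metrics import MetricsRecord

        recs = []
        for r in self.rows:
            row = {"experiment": r.experiment, "model": r.model}
            row.update({f: getattr(r.metrics, f) for f in MetricsRecord.FIELDS})
            row["n_warnings"] = len(r.warnings)
            recs.append(row)
        return pd.DataFrame(recs)

    def metrics_wide_records(self):
        """Per-experiment records for the wide metrics CSV writer."""
        by_exp: dict[str, dict] = {}
        for r in self.rows:
            by_exp.setdefault(r.experiment, {})[r.model] = r.metrics
        return sorted(by_exp.items())


def run_batch(root, models=ALL_MODELS, *, out_dir=None,
              raw_normalize: bool = False, loewe_tol=None,
              save_per_experiment: bool = False, plots: bool = False
              ) -> BatchResult:
    """Analyze every experiment sub-folder under ``root``.

    Parameters
    ----------
    root : path
        Directory of experiment sub-folders (loose CSV/XLSX files directly
        under ``root`` are treated as single-file experiments).
    models : sequence
        Null models to evaluate for every experiment.
    out_dir : path, optional
        If given, the wide metrics table (``metrics_table.csv``), a failure
        list (``failures.csv``) and, with ``save_per_experiment``, each
        experiment's full result folder are written there.

    Returns
    -------
    BatchResult with one row per (experiment, model) and one failure entry
    per unreadable or unanalyzable experiment.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"batch root {root} is not a directory")
    models = tuple(Model.parse(m) for m in models)
    targets: list[tuple[str, Path]] = []
    for p in sorted(root.iterdir(), key=lambda q: q.name):
        if p.is_dir():
            targets.append((p.name, p))
        elif p.suffix.lower() in (".csv", ".xlsx", ".xls"):
            targets.append((p.stem, p))
    if not targets:
        raise FileNotFoundError(f"no experiment folders or files under {root}")

    result = BatchResult()
    kwargs = {} if loewe_tol is None else {"loewe_tol": loewe_tol}
    for name, path in targets:
        try:
            if path.is_dir():
                exp = read_experiment_dir(path, raw_normalize=raw_normalize)
            else:
                from .experiment import read_experiment
                exp = read_experiment(path, raw_normalize=raw_normalize)
            res = CombinationModel(exp, models=models, **kwargs).fit()
            for m in models:
                result.rows.append(BatchRow(
                    experiment=name, model=m.value,
                    metrics=res.metrics[m.value],
                    fit_a=res.fit_a, fit_b=res.fit_b,
                    warnings=list(exp.warnings),
                ))
            if out_dir is not None and save_per_experiment:
                res.save(out_dir, plots=plots)
        except Exception as e:  # noqa: BLE001 - isolation is the contract
            result.failures.append((name, f"{type(e).__name__}: {e}"))
    result.rows.sort(key=lambda r: (r.experiment, r.model))
    result.failures.sort(key=lambda f: f[0])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if result.rows:
            write_metrics_table(result.metrics_wide_records(),
                                out_dir / "metrics_table.csv")
        with open(out_dir / "failures.csv", "w") as fh:
            fh.write("experiment,error\n")
            for name, msg in result.failures:
                fh.write(f"{name},\"{msg}\"\n")
    return result
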