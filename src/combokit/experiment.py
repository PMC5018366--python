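"""Reading and writing checkerboard combination experiments and result tables.

File template (CSV or XLSX): the first row holds the doses of drug A (laid
out in columns), the first column holds the doses of drug B (rows), and the
body holds responses in % of untreated control.  The top-left cell is either
blank or ``agentA|agentB``.  Replicates are either sibling files sharing a
stem (``name_rep1.csv``, ``name_rep2.csv``) or multiple sheets of one
workbook.  Lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _VERSION

__all__ = [
    "CombinationExperiment",
    "ParseError",
    "ValidationError",
    "read_experiment",
    "read_experiment_dir",
    "write_experiment",
    "write_metrics_table",
    "read_metrics_table",
    "write_matrix_csv",
]

VALUE_WARN_RANGE = (-20.0, 200.0)
_REP_STEM = re.compile(r"^(?P<stem>.+?)_rep\d+$")


class ParseError(ValueError):
    """A file does not parse as a rectangular dose-response grid."""


class ValidationError(ValueError):
    """A parsed grid violates the experiment invariants."""


@dataclass
class CombinationExperiment:
    """A checkerboard assay: two dose grids and >= 1 replicate response matrix.

    ``doses_a`` index the columns (first drug), ``doses_b`` the rows (second
    drug); each must contain exactly one zero (the single-agent axis) and is
    stored strictly increasing.  Values are % of control: 100 = untreated,
    0 = complete effect.
    """

    name: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    replicates: list
    agent_a_name: str = "Drug A"
    agent_b_name: str = "Drug B"
    warnings: list = field(default_factory=list)

    @classmethod
    def build(cls, name, doses_a, doses_b, replicates, agent_a_name="Drug A",
              agent_b_name="Drug B", raw_normalize=False):
        """Canonicalize (sort doses, permute matrices) and validate."""
        doses_a = np.asarray(doses_a, dtype=float)
        doses_b = np.asarray(doses_b, dtype=float)
        mats = [np.asarray(m, dtype=float) for m in replicates]
        if not mats:
            raise ValidationError(f"{name}: at least one replicate required")
        for k, m in enumerate(mats):
            if m.shape != (doses_b.size, doses_a.size):
                raise ValidationError(
                    f"{name}: replicate {k + 1} has shape {m.shape}, expected "
                    f"{(doses_b.size, doses_a.size)}"
                )
        order_a = np.argsort(doses_a, kind="stable")
        order_b = np.argsort(doses_b, kind="stable")
        doses_a = doses_a[order_a]
        doses_b = doses_b[order_b]
        mats = [m[np.ix_(order_b, order_a)] for m in mats]
        for label, d in (("columns (drug A)", doses_a), ("rows (drug B)", doses_b)):
            if np.count_nonzero(d == 0) != 1:
                raise ValidationError(
                    f"{name}: dose {label} must contain exactly one zero entry "
                    "(the untreated control axis)"
                )
            if np.any(np.diff(d) <= 0):
                raise ValidationError(f"{name}: duplicate dose in {label}")
            if np.any(d < 0):
                raise ValidationError(f"{name}: negative dose in {label}")
        if raw_normalize:
            normed = []
            for k, m in enumerate(mats):
                ctrl = m[0, 0]
                if ctrl == 0 or not np.isfinite(ctrl):
                    raise ValidationError(
                        f"{name}: replicate {k + 1} control cell is {ctrl}; "
                        "cannot normalize raw signal"
                    )
                normed.append(m / ctrl * 100.0)
            mats = normed
        warnings = []
        lo, hi = VALUE_WARN_RANGE
        for k, m in enumerate(mats):
            bad = np.argwhere((m < lo) | (m > hi))
            for i, j in bad:
                warnings.append(
                    f"replicate {k + 1} cell (dose_b={doses_b[i]:g}, "
                    f"dose_a={doses_a[j]:g}) value {m[i, j]:g} outside "
                    f"[{lo:g}, {hi:g}]"
                )
        return cls(
            name=name, doses_a=doses_a, doses_b=doses_b, replicates=mats,
            agent_a_name=agent_a_name, agent_b_name=agent_b_name,
            warnings=warnings,
        )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def mean_response(self) -> np.ndarray:
        """Mean over replicates, shape (n_doses_b, n_doses_a)."""
        return np.mean(np.stack(self.replicates), axis=0)

    @property
    def replicate_sd(self):
        """Per-cell sample SD over replicates; None with a single replicate."""
        if self.n_replicates < 2:
            return None
        return np.std(np.stack(self.replicates), axis=0, ddof=1)

    def interior_mask(self) -> np.ndarray:
        """Boolean mask of cells where both doses are positive."""
        return np.outer(self.doses_b > 0, self.doses_a > 0)


def _parse_grid(df: pd.DataFrame, source: str):
    """Split a raw headerless frame into (doses_a, doses_b, matrix, names)."""
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ParseError(f"{source}: grid must be at least 2x2 including headers")
    corner = df.iat[0, 0]
    names = ("Drug A", "Drug B")
    if isinstance(corner, str) and "|" in corner:
        a, _, b = corner.partition("|")
        names = (a.strip() or names[0], b.strip() or names[1])

    def _num(cell, where):
        try:
            v = float(cell)
        except (TypeError, ValueError):
            raise ParseError(f"{source}: non-numeric value {cell!r} at {where}") from None
        return v

    doses_a = np.array(
        [_num(df.iat[0, j], f"header row, column {j + 1}") for j in range(1, df.shape[1])]
    )
    doses_b = np.array(
        [_num(df.iat[i, 0], f"row {i + 1}, header column") for i in range(1, df.shape[0])]
    )
    body = np.empty((doses_b.size, doses_a.size))
    for i in range(doses_b.size):
        for j in range(doses_a.size):
            cell = df.iat[i + 1, j + 1]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ParseError(
                    f"{source}: missing value at row {i + 2}, column {j + 2} "
                    "(ragged grid)"
                )
            body[i, j] = _num(cell, f"row {i + 2}, column {j + 2}")
    return doses_a, doses_b, body, names


def _read_one_file(path: Path):
    """Read one CSV/XLSX file; returns list of (doses_a, doses_b, matrix, names)."""
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None, header=None)
        return [_parse_grid(df, f"{path.name}[{sn}]") for sn, df in sheets.items()]
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path.name}: {e}") from None
    return [_parse_grid(df, path.name)]


def _replicate_group(path: Path) -> tuple[str, list[Path]]:
    """Experiment name and the sorted sibling files forming its replicates."""
    m = _REP_STEM.match(path.stem)
    if not m:
        return path.stem, [path]
    stem = m.group("stem")
    sibs = sorted(
        p for p in path.parent.iterdir()
        if p.suffix.lower() == path.suffix.lower()
        and (mm := _REP_STEM.match(p.stem)) and mm.group("stem") == stem
    )
    return stem, sibs


def read_experiment(path, *, raw_normalize=False, collect_replicates=True
                    ) -> CombinationExperiment:
    """Read one combination experiment from a file (or folder of files).

    ``path`` may be a single CSV/XLSX file, a ``*_repN`` replicate file (its
    siblings are collected automatically unless ``collect_replicates=False``),
    or a directory holding one experiment's files.  With ``raw_normalize``
    each replicate is divided by its own untreated-control cell and scaled to
    100, for data recorded as raw plate readouts rather than % of control.
    """
    path = Path(path)
    if path.is_dir():
        return read_experiment_dir(path, raw_normalize=raw_normalize)
    if not path.exists():
        raise FileNotFoundError(path)
    if collect_replicates:
        name, files = _replicate_group(path)
    else:
        name, files = path.stem, [path]
    grids = []
    for f in files:
        grids.extend(_read_one_file(f))
    return _assemble(name, grids, raw_normalize)


def read_experiment_dir(folder, *, raw_normalize=False) -> CombinationExperiment:
    """Read an experiment folder: every CSV/XLSX inside is a replicate source."""
    folder = Path(folder)
    files = sorted(
        p for p in folder.iterdir()
        if p.suffix.lower() in (".csv", ".xlsx", ".xls") and not p.name.startswith(".")
    )
    if not files:
        raise ParseError(f"{folder}: no experiment files (.csv/.xlsx) found")
    grids = []
    for f in files:
        grids.extend(_read_one_file(f))
    return _assemble(folder.name, grids, raw_normalize)


def _assemble(name, grids, raw_normalize):
    da0, db0, _, names = grids[0]
    mats = []
    for da, db, m, _ in grids:
        oa, ob = np.argsort(da, kind="stable"), np.argsort(db, kind="stable")
        da_s, db_s = da[oa], db[ob]
        if not (np.array_equal(da_s, np.sort(da0)) and np.array_equal(db_s, np.sort(db0))):
            raise ValidationError(
                f"{name}: replicate dose grids differ "
                f"(A: {da_s.tolist()} vs {np.sort(da0).tolist()})"
            )
        mats.append(m[np.ix_(ob, oa)])
    return CombinationExperiment.build(
        name=name, doses_a=np.sort(da0), doses_b=np.sort(db0), replicates=mats,
        agent_a_name=names[0], agent_b_name=names[1], raw_normalize=raw_normalize,
    )


def _header_line(extra: str = "") -> str:
    return f"# combokit {_VERSION}{(' ' + extra) if extra else ''}\n"


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{float(v):.10g}"


def write_matrix_csv(path, doses_a, doses_b, values, corner="") -> Path:
    """Write one matrix in the template layout (doses as headers)."""
    path = Path(path)
    lines = [_header_line()]
    lines.append(",".join([corner] + [_fmt(d) for d in doses_a]) + "\n")
    for i, db in enumerate(doses_b):
        lines.append(",".join([_fmt(db)] + [_fmt(v) for v in values[i]]) + "\n")
    path.write_text("".join(lines))
    return path


def write_experiment(exp: CombinationExperiment, directory) -> list[Path]:
    """Write an experiment as template CSV file(s); replicates become
    ``<name>_rep<k>.csv`` siblings (a single replicate gets ``<name>.csv``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    corner = f"{exp.agent_a_name}|{exp.agent_b_name}"
    paths = []
    if exp.n_replicates == 1:
        paths.append(
            write_matrix_csv(directory / f"{exp.name}.csv", exp.doses_a,
                             exp.doses_b, exp.replicates[0], corner)
        )
    else:
        for k, m in enumerate(exp.replicates, start=1):
            paths.append(
                write_matrix_csv(directory / f"{exp.name}_rep{k}.csv",
                                 exp.doses_a, exp.doses_b, m, corner)
            )
    return paths


def write_metrics_table(records, path) -> Path:
    """Write the screen-level metrics table: experiments in rows, one column
    per (model, metric).

    ``records`` is a list of ``(experiment_name, {model: MetricsRecord})``.
    All records must share the same models and metric names.
    """
    from .metrics import MetricsRecord

    if not records:
        raise ValidationError("no records to write")
    models0 = sorted(records[0][1])
    for name, per_model in records:
        if sorted(per_model) != models0:
            raise ValidationError(
                f"inconsistent model sets across records (at {name!r})"
            )
    fields = MetricsRecord.FIELDS
    cols = [f"{m}_{f}" for m in models0 for f in fields]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line())
        fh.write(",".join(["experiment"] + cols) + "\n")
        for name, per_model in records:
            vals = [
                _fmt(getattr(per_model[m], f)) for m in models0 for f in fields
            ]
            fh.write(",".join([name] + vals) + "\n")
    return path


def read_metrics_table(path) -> pd.DataFrame:
    """Read back a metrics table written by :func:`write_metrics_table`."""
    return pd.read_csv(path, comment="#", index_col="experiment")
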