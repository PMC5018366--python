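"""Graphical outputs: dose-response fits, checkerboard matrices, contours,
3-D surfaces and the synergy-mapped surface.

Synergy displays always use a diverging colormap centered at zero with
symmetric limits (max |value| on both sides) so synergy and antagonism are
visually comparable.  Dose axes are drawn as categorical ticks labeled with
the concentrations, since checkerboard grids are log-like but irregular;
the 3-D surfaces offer a log-dose option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .hill import hill_response

__all__ = ["PlotSpec", "PLOT_KINDS", "render", "default_specs"]

PLOT_KINDS = (
    "single_agent_fit",
    "combination_matrix",
    "combination_contour",
    "combination_surface",
    "reference_matrix",
    "reference_contour",
    "reference_surface",
    "synergy_matrix",
    "synergy_contour",
    "synergy_surface",
    "synergy_mapped_surface",
)

RESPONSE_CMAP = "viridis"
SYNERGY_CMAP = "RdBu_r"  # diverging; red = synergy under default limits


@dataclass(frozen=True)
class PlotSpec:
    kind: str
    model: str | None = None     # required for model-specific kinds
    format: str = "png"
    dpi: int = 150

    def __post_init__(self):
        if self.kind not in PLOT_KINDS:
            raise ValueError(
                f"unknown plot kind {self.kind!r}; expected one of {PLOT_KINDS}"
            )


def default_specs(metrics_by_model, fmt: str = "png") -> list[PlotSpec]:
    """The four display families for every analyzed model."""
    specs = [PlotSpec("single_agent_fit", format=fmt)]
    for m in metrics_by_model:
        for kind in ("combination_matrix", "reference_matrix",
                     "synergy_matrix", "synergy_mapped_surface"):
            specs.append(PlotSpec(kind, model=m, format=fmt))
    return specs


def _dose_labels(doses):
    return [f"{d:g}" for d in doses]


def _categorical_matrix(ax, values, doses_a, doses_b, cmap, vmin=None,
                        vmax=None, title=""):
    im = ax.imshow(values, origin="lower", aspect="auto", cmap=cmap,
                   vmin=vmin, vmax=vmax)
    ax.set_xticks(range(len(doses_a)), _dose_labels(doses_a))
    ax.set_yticks(range(len(doses_b)), _dose_labels(doses_b))
    ax.set_title(title)
    return im


def _symmetric_limits(values) -> tuple[float, float]:
    m = float(np.max(np.abs(values))) if np.size(values) else 0.0
    if m == 0.0:
        m = 1.0  # degenerate all-zero field: keep a valid, centered scale
    return -m, m


def plot_single_agent_fit(exp, fits, ax=None):
    """Single-agent points (replicate-wise) with fitted Hill curves."""
    from .hill import extract_single_agents

    if ax is None:
        _, ax = plt.subplots()
    series = extract_single_agents(exp)
    colors = ("C0", "C1")
    names = (exp.agent_a_name, exp.agent_b_name)
    for s, f, c, label in zip(series, fits, colors, names):
        pos = s.doses > 0
        for rep in s.responses:
            ax.semilogx(s.doses[pos], rep[pos], "o", color=c, alpha=0.5)
        grid = np.geomspace(s.doses[pos].min(), s.doses[pos].max(), 200)
        ax.semilogx(grid, hill_response(f.curve, grid), "-", color=c,
                    label=f"{label} (ec50={f.curve.ec50:.3g})")
    ax.set_xlabel("dose")
    ax.set_ylabel("response (% control)")
    ax.legend()
    ax.set_title("Single-agent dose-response and Hill fits")
    return ax


def plot_matrix(values, doses_a, doses_b, *, synergy=False, ax=None,
                title=""):
    """Checkerboard heatmap; synergy mode centers a diverging map at 0."""
    if ax is None:
        _, ax = plt.subplots()
    if synergy:
        vmin, vmax = _symmetric_limits(values)
        im = _categorical_matrix(ax, values, doses_a, doses_b, SYNERGY_CMAP,
                                 vmin, vmax, title)
    else:
        im = _categorical_matrix(ax, values, doses_a, doses_b, RESPONSE_CMAP,
                                 title=title)
    ax.figure.colorbar(im, ax=ax)
    ax.set_xlabel("dose A")
    ax.set_ylabel("dose B")
    return ax


def plot_contour(values, doses_a, doses_b, *, synergy=False, ax=None,
                 title=""):
    if ax is None:
        _, ax = plt.subplots()
    X, Y = np.meshgrid(range(len(doses_a)), range(len(doses_b)))
    if synergy:
        vmin, vmax = _symmetric_limits(values)
        cs = ax.contourf(X, Y, values, levels=21, cmap=SYNERGY_CMAP,
                         vmin=vmin, vmax=vmax)
    else:
        cs = ax.contourf(X, Y, values, levels=21, cmap=RESPONSE_CMAP)
    ax.set_xticks(range(len(doses_a)), _dose_labels(doses_a))
    ax.set_yticks(range(len(doses_b)), _dose_labels(doses_b))
    ax.figure.colorbar(cs, ax=ax)
    ax.set_xlabel("dose A")
    ax.set_ylabel("dose B")
    ax.set_title(title)
    return ax


def _surface_axes():
    fig = plt.figure()
    return fig.add_subplot(projection="3d")


def plot_surface(values, doses_a, doses_b, *, synergy=False, ax=None,
                 title="", log_dose=False, facecolors=None):
    """3-D surface; ``facecolors`` overrides the value-based coloring
    (used by the synergy-mapped display)."""
    if ax is None:
        ax = _surface_axes()
    if log_dose:
        xa = np.where(np.asarray(doses_a) > 0, doses_a, np.nan)
        xb = np.where(np.asarray(doses_b) > 0, doses_b, np.nan)
        X, Y = np.meshgrid(np.log10(xa), np.log10(xb))
    else:
        X, Y = np.meshgrid(range(len(doses_a)), range(len(doses_b)))
    kwargs = {}
    if facecolors is not None:
        kwargs["facecolors"] = facecolors
    elif synergy:
        vmin, vmax = _symmetric_limits(values)
        kwargs.update(cmap=SYNERGY_CMAP, vmin=vmin, vmax=vmax)
    else:
        kwargs["cmap"] = RESPONSE_CMAP
    ax.plot_surface(X, Y, np.asarray(values, dtype=float), **kwargs)
    ax.set_xlabel("dose A index" if not log_dose else "log10 dose A")
    ax.set_ylabel("dose B index" if not log_dose else "log10 dose B")
    ax.set_zlabel("% control")
    ax.set_title(title)
    return ax


def plot_mapped_surface(response_values, synergy_values, doses_a, doses_b,
                        ax=None, title=""):
    """Dose-response surface colored by the synergy distribution."""
    vmin, vmax = _symmetric_limits(synergy_values)
    norm = matplotlib.colors.Normalize(vmin=vmin, vmax=vmax)
    cmap = matplotlib.colormaps[SYNERGY_CMAP]
    # plot_surface colors quads; sample synergy at quad corners' mean
    sv = np.asarray(synergy_values, dtype=float)
    quads = (sv[:-1, :-1] + sv[1:, :-1] + sv[:-1, 1:] + sv[1:, 1:]) / 4.0
    colors = cmap(norm(quads))
    ax = plot_surface(response_values, doses_a, doses_b, ax=ax, title=title,
                      facecolors=colors)
    return ax


def render(exp, fits, refs, dists, specs, out_dir) -> list[Path]:
    """Render a list of :class:`PlotSpec` to files.

    File names are deterministic: ``<experiment>_<model>_<kind>.<ext>``
    (model omitted for the single-agent plot).  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in specs:
        if spec.kind == "single_agent_fit":
            ax = plot_single_agent_fit(exp, fits)
            fname = f"{exp.name}_single_agent_fit.{spec.format}"
        else:
            if spec.model is None:
                raise ValueError(f"plot kind {spec.kind!r} needs a model")
            mname = str(getattr(spec.model, "value", spec.model))
            ref = refs[mname]
            dist = dists[mname]
            family, _, display = spec.kind.partition("_")
            if family == "combination":
                vals, syn = exp.mean_response, False
                title = f"{exp.name}: combination dose-response"
            elif family == "reference":
                vals, syn = ref.values, False
                title = f"{exp.name}: {mname} reference"
            else:
                vals, syn = dist.values, True
                title = f"{exp.name}: {mname} synergy distribution"
            if spec.kind == "synergy_mapped_surface":
                ax = plot_mapped_surface(exp.mean_response, dist.values,
                                         exp.doses_a, exp.doses_b,
                                         title=f"{exp.name}: {mname} "
                                               "synergy-mapped surface")
            elif display == "matrix":
                ax = plot_matrix(vals, exp.doses_a, exp.doses_b, synergy=syn,
                                 title=title)
            elif display == "contour":
                ax = plot_contour(vals, exp.doses_a, exp.doses_b, synergy=syn,
                                  title=title)
            else:
                ax = plot_surface(vals, exp.doses_a, exp.doses_b, synergy=syn,
                                  title=title)
            fname = f"{exp.name}_{mname}_{spec.kind}.{spec.format}"
        path = out_dir / fname
        ax.figure.savefig(path, dpi=spec.dpi)
        plt.close(ax.figure)
        paths.append(path)
    return paths
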