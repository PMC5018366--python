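# Methods

This note documents the statistical and numerical choices behind
`combokit`: the models, the defaults and their rationale, what the
synthetic-data generator does and does not emulate, and known limitations.

## Data model

A combination experiment is a checkerboard: drug A doses in columns, drug B
doses in rows, responses in % of untreated control (100 = no effect,
0 = complete kill).  Each dose series must contain exactly one zero — the
single-agent axes — and the (0, 0) cell is the untreated control.  Doses
are canonicalized to ascending order on read, so analysis is invariant to
the ordering in the file.  Replicates (sibling `*_repN` files or workbook
sheets) must share one dose grid.  Values are accepted as-is; values
outside [−20, 200] % are retained but flagged, since over-100 growth
stimulation and assay noise are real features of viability data.  An
optional raw-signal mode divides each replicate by its own control cell,
for data recorded as raw readouts.

## Single-agent Hill fits

The 3-parameter Hill model E(c) = E₀ + (E_inf − E₀)/(1 + (EC50/c)^h) is
fitted with the baseline fixed at E₀ = 100: because responses are already
normalized to the control, freeing the baseline would let the fit trade
control noise against potency.  The fit is unweighted least squares over
all replicate points individually (not replicate means), run in
(e_inf, log EC50, h) space with `scipy.optimize.least_squares` under bounds
e_inf ∈ [−20, 100] % (a drug may overshoot complete kill slightly, or fail
to reach it), EC50 within the assayed dose range padded 100-fold either
side, and h ∈ [0.1, 10].  Initialisation uses a fixed multi-start grid
(5 log-spaced EC50 starts across the dose range × slope starts 0.5, 1, 3),
so fitting is fully deterministic: no random restarts, identical results
for permuted inputs.  Standard errors come from the Gauss–Newton
covariance s²(JᵀJ)⁻¹, with the EC50 error delta-transformed from log
space.  Zero-dose points stay in the loss as baseline anchors.

An agent is called *inactive* when the fitted plateau is within 5 % points
of baseline or R² < 0.3.  The threshold matters only for Loewe (below);
Bliss and HSA degrade gracefully for flat curves.  Fitting requires at
least 3 distinct non-zero doses (3 free parameters).

## Reference surfaces

All three null-model surfaces are computed from the *fitted* curves, not
from the raw single-agent data, so axis residuals measure fit quality
rather than contaminating the interior.  Axis cells are assigned directly
from the curves, making the three models agree on the axes bit-exactly.

**Bliss.** % control is interpreted as surviving fraction × 100 — the
product law is only meaningful for effects scaled to [0, 1].  Fitted
plateaus below 0 are clamped to 0 before the product and the affected
cells flagged.

**HSA.** The cellwise minimum of the two single-agent responses; no
numerics involved.

**Loewe.** For each interior cell, the reference effect E* solves
a/A(E) + b/B(E) = 1 with A, B the inverse Hill curves.  On the interval
(max(e_inf_A, e_inf_B), 100) this combination index is strictly increasing
in E, from ~0 up to +∞, so the root — when it exists — is unique and
bracketed.  It is found with Brent's method (`scipy.optimize.brentq`,
xtol 1e−12) and checked against a residual tolerance of 1e−8 on |CI − 1|;
a bracketed bisection-family solve was chosen over dose-space iteration
because the bracket is guaranteed.  When the cell demands an effect deeper
than the weaker agent's plateau the equation has no root; rather than
extrapolate a Hill curve beyond its asymptote (which would fabricate doses
for unachievable effects) the cell is capped at that plateau and flagged
`CAPPED`, so users can see where Loewe is only partially defined.  With an
inactive agent the dose-equivalence equation is ill-posed; the surface
falls back to the active agent's own curve (flag `FALLBACK`), and to HSA
if both are inactive.

## Synergy distribution

Synergy = reference − mean(data), cellwise, in % points: positive where
the combination kills more than predicted.  The subtraction is linear, so
computing on replicate means or per replicate then averaging commute; the
opposite sign convention is available as a switch.  Replicate SD per cell
is carried alongside when ≥ 2 replicates exist.  Axis cells hold the
single-agent fit residual, not interaction, and are excluded from metrics.
As an optional extension (off by default), with ≥ 3 replicates a two-sided
one-sample t-test of each interior cell's replicate deviations against
zero yields a significance mask (default α = 0.05, Bonferroni over
interior cells).

## Metrics

Over interior cells only: maximum synergy (clamped at ≥ 0) and maximum
antagonism (≤ 0); the means of the positive part, the negative part, and
of all values ("integrated" metrics are means, not sums, so 6×6 and 8×8
grids are comparable within one screen); and an effect-weighted mean with
weights w = clip((100 − observed)/100, 0, 1), which emphasizes synergy in
high-effect regions.  The synergy-density peak is the argmax of the
distribution after 3×3 uniform smoothing, so a lone noisy cell cannot
define the peak.  The kernel keeps weight 1/9 everywhere with zero padding
(no border renormalization — a renormalized kernel would inflate border
cells with fewer neighbors and could move the peak to an empty corner).
Exact ties in the smoothed field break first on the unsmoothed value —
smoothing locates the dense region, the raw value pinpoints the peak
within it — then to the lexicographically lowest (dose_a, dose_b) pair,
which is deterministic and biologically conservative.

## Synthetic data generator

`SimulationSpec`/`simulate_experiment` generate checkerboards from known
ground truth: a reference surface built on two specified Hill curves under
a chosen null model, minus a planted synergy field, plus i.i.d. Gaussian
noise on the % scale, replicated.  Defaults model a typical viability
checkerboard: an 8×8 grid (zero dose plus 7 log-spaced doses spanning 2.5
decades centered on each EC50), 3 replicates, and 3 % points of noise;
screen generation draws curves with plateaus in [0, 40] % control, EC50
log-uniform over one decade and slopes in [0.5, 4].  Generated files go
through the package's own CSV writer, so fixtures exercise the parser too.

The generator deliberately omits features of real plates: heteroscedastic
or multiplicative noise, edge/drift plate artifacts, scattered-replicate
layouts, and biphasic or stimulatory dose responses.  Tests passing on
synthetic data therefore validate the *mathematics* of the pipeline
(solver exactness, calibration, recovery, determinism), not robustness to
every assay pathology.

## Problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale problems:
50-curve sham checks, 20 random curve pairs against a brute-force
effect-grid oracle (two-stage scan, effective step 1e−6), 100-curve
parameter-recovery studies with 3 replicates of N(0, 2²) noise, and a
20-experiment screen for batch determinism/isolation — sizes at which
every check runs in seconds while still averaging over the parameter box.

## Limitations

* Loewe is partially defined when the agents' plateaus differ; capped
  cells are reported, not hidden, and metrics include them like any other
  cell.
* Bliss requires effects in [0, 100] %; growth stimulation (> 100 %
  control) is clamped for the reference even though the data retain it.
* Metrics definitions are this package's own (documented above); other
  synergy tools ("integrated synergy" etc.) may normalize differently, so
  absolute values should not be compared across software.
* No plate-map deconvolution, LIMS connectivity, isobolograms, or
  Fa-plot-style analyses.
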