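# combokit

Model-based analysis of drug-combination checkerboard assays, for laboratory
scientists and bioinformaticians who screen drug pairs for synergy.

A checkerboard experiment measures cell viability (in % of untreated
control) for all pairwise doses of two drugs.  `combokit` answers the
question *"did the combination do more than the two drugs would have done
without interacting?"* by the surface approach:

1. The single-agent dose–response series are extracted from the zero-dose
   row and column of the matrix and each is fitted with a 3-parameter Hill
   curve, E(c) = E₀ + (E_inf − E₀) / (1 + (EC50/c)^h), with the baseline
   pinned at E₀ = 100 (the untreated control defines the top of the curve).
2. From the two fitted curves a *reference surface* — the response expected
   if the drugs do **not** interact — is built under one or more classical
   null models:
   * **Loewe additivity** (dose equivalence): the reference effect E* at dose
     pair (a, b) solves the combination-index equation a/A(E*) + b/B(E*) = 1,
     where A(E), B(E) are the single-agent doses producing effect E.
   * **Bliss independence**: surviving fractions multiply, E_A·E_B/100.
   * **HSA** (highest single agent): min(E_A, E_B).
3. The observed surface is subtracted from the reference, giving a
   *synergy distribution* over concentration space (% points; positive =
   more kill than predicted = synergy, negative = antagonism).
4. The distribution is summarized by scalar metrics (maximum synergy,
   mean/weighted-mean synergy, the dose pair where synergy is most dense)
   so thousands of combinations can be ranked in a screen.

Single experiments and whole screens (one sub-folder per combination) are
supported, with figures (dose–response fits, checkerboard matrices,
contours, 3-D surfaces and the synergy-mapped surface) and CSV outputs.

## Worked example

`examples/combination_template.csv` holds the documented input template
(drug A doses in columns, drug B in rows, body in % control):

```python
import combokit as ck

res = ck.CombinationModel.from_file("examples/combination_template.csv").fit()
print(res.summary())
```

```
Drug Combination Synergy Analysis
============================================================
Experiment: combination_template
Agents: DrugA (columns) x DrugB (rows)
Grid: 6 x 6 doses, 1 replicate(s)

Single-agent Hill fits (baseline fixed at 100% control)
------------------------------------------------------------
agent               e_inf     (se)      ec50     (se)      h    (se)     R2
DrugA                4.38      1.8    0.9538    0.052   1.07   0.043  1.000
DrugB               10.42      1.3     1.517    0.061   1.02   0.025  1.000

Synergy metrics (% points; positive = synergy)
------------------------------------------------------------
metric                       LOEWE       BLISS         HSA
max_synergy                  18.62       10.91       28.98
max_antagonism             -0.6187     -0.7507           0
sum_synergy                   8.71       4.479       12.09
sum_antagonism            -0.02475    -0.04893           0
integrated_total             8.686        4.43       12.09
weighted_integrated          9.433       4.462       12.42
peak_dose_a                      1           1           1
peak_dose_b                      3           1           1
n_cells                         25          25          25
```

Both agents are active (EC50 ≈ 0.95 and 1.5, Hill slopes ≈ 1, near-complete
kill); the combination kills more than every null model predicts — e.g. up
to 18.6 % points more than Loewe additivity, with the synergy densest
around (dose_a = 1, dose_b = 3).  The HSA reference is the weakest null
model, so it always reports the largest apparent synergy; results should be
read in the context of the model used.

The same analysis from the shell, plus a simulated screen in batch mode:

```sh
combokit analyze examples/combination_template.csv --out results/ --plots
combokit simulate --model bliss --grid 8x8 --noise 3 --reps 3 --seed 42 \
    --n-experiments 20 --out screen/
combokit analyze screen/ --batch --models loewe,bliss,hsa --out screen_results/
```

Batch mode writes `metrics_table.csv` (experiments in rows, model × metric
in columns) and `failures.csv`; a failing experiment never aborts the rest
of the screen.

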