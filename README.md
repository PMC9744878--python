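# progrnn

Densely connected, batch-normalized recurrent networks for predicting a
patient's **next-visit disease-severity score** from high-dimensional
longitudinal transcriptomic data.

The package is aimed at disease-progression modelling in cohorts like
those assembled for Parkinson's disease: each subject contributes a
variable number of irregularly spaced visits, each visit carries a
TPM-scale RNA-seq profile plus non-transcriptomic clinical columns, and
the outcome is the MDS-UPDRS total score — an integer on a 0–272 scale
(0 normal, 272 severe) obtained by summing its four parts. Because such
repositories are access-restricted, the package ships a synthetic cohort
generator with the same statistical skeleton, so the full pipeline is
runnable and testable out of the box.

## The model

Given a subject's visit history, the predictor is

  ŷ⟨n+1⟩ = f(X⟨1⟩…X⟨n⟩; Δt⟨1⟩…Δt⟨n⟩; y⟨1⟩…y⟨n⟩)

where X⟨i⟩ is the Q-dimensional feature vector at visit i (genes then
clinical columns), Δt⟨i⟩ the gap to the following visit, and y⟨i⟩ the
observed score. f is a stack of **dense blocks** (DB), each a stack of
**composite blocks** (CB). A composite block is a recurrent layer whose
per-time-step output activations are batch-normalized:

  H⟨t⟩ = BN_{γ,β}(h⟨t⟩),  h⟨t⟩ = cell(x⟨t⟩, h⟨t−1⟩),
  BN_{γ,β}(h) = β + γ ⊙ (h − E[ĥ]) / √(Var[ĥ] + ε)

with vanilla (tanh), GRU, or LSTM cells. Within a dense block, CB_j
receives the concatenation of the block input and every earlier CB's
output; dense blocks are chained under the same concatenation rule, and
the last block's final-time-step output feeds a single affine unit. The
reference configuration is 256 vanilla cells per CB, 4 CBs per DB, 3 DBs.
Training minimizes mean squared error with the Nadam optimizer, L2 on the
recurrent weight matrices, mini-batches of 16 same-length histories, and
a learning rate cut to 1/5 after every 10 epochs without validation
improvement.

Evaluation uses two cohort-level metrics: **PIE** (progression
identification error), the mean over prediction time points of the
per-time-point RMSE, and **PIC** (progression identification
correlation), the mean over time points of the Spearman correlation
between predicted and true scores. A comparison arm aggregates each
subject's history column-wise (mean/median/mode for
numerical/ordinal/nominal columns) and fits linear regression, SVR, a
decision tree, and a random forest on the collapsed vectors; fold-level
metrics are compared with paired t-tests.

## Worked example

```python
import progrnn as pg

sim = pg.SimConfig(n_subjects=120, n_genes=60, n_clinical=20,
                   n_signal_genes=8, effect_size=2.0, seed=7)
cohort = pg.simulate_cohort(sim)

model_cfg = pg.ModelConfig(cells_per_cb=16, cbs_per_db=2, n_dbs=2, seed=0)
train_cfg = pg.TrainConfig(max_epochs=60, early_stop_patience=20, seed=0)
cv = pg.crossvalidate(cohort, model_cfg, train_cfg, n_folds=5, seed=7)
print(f"dense model   PIE {cv.pie_mean:.2f} +/- {cv.pie_se:.2f}   "
      f"PIC {cv.pic_mean:.2f} +/- {cv.pic_se:.2f}")

baselines = pg.run_baselines(cohort, cv.folds, seed=7)
for name, res in baselines.items():
    print(f"{name:18s} PIE {res.pie_mean:.2f} +/- {res.pie_se:.2f}   "
          f"PIC {res.pic_mean:.2f}")

t = pg.ttest_from_folds(cv.pie_values,
                        [r.pie for r in baselines["random_forest"].fold_reports])
print(f"dense vs random forest: t = {t.t_stat:.2f}, p = {pg.format_p(t.p_value)}")
print(f"instrument noise floor: {pg.noise_floor([4.87, 3.66, 15.52]):.3f}")
```

Output (about 20 s on one CPU):

```
dense model   PIE 6.26 +/- 0.32   PIC 0.79 +/- 0.03
linear_regression  PIE 15.93 +/- 1.62   PIC 0.45
svr                PIE 14.02 +/- 0.82   PIC 0.74
decision_tree      PIE 9.39 +/- 0.19   PIC 0.67
random_forest      PIE 6.41 +/- 0.39   PIC 0.78
dense vs random forest: t = -0.33, p = 0.7565
instrument noise floor: 8.059
```

Reading: on this small synthetic cohort the dense recurrent model attains
a 5-fold cross-validated PIE of 6.26 score points (mean ± standard error
across folds) and ranks subjects at PIC 0.79, beating the
history-aggregation baselines; the gap to the random forest is not
significant at this cohort size (paired t on 5 folds, p = 0.76). The
noise floor — the sum of per-part error standard deviations of the
instrument itself — is 8.059 points, so a sub-8 RMSE is within the
instrument's own measurement noise.

A command-line interface mirrors the library:
`progrnn simulate | train | evaluate | ablate-history | compare-baselines |
compare | noise-floor` (see `progrnn --help`).

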