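# shrinktune

Penalized logistic regression for clinical risk prediction, with
**modified cross-validation** and **bootstrap** selection of the penalty
strength — plus the comparator shrinkage methods and the Monte-Carlo
simulation machinery needed to measure how often each method actually
delivers a well-calibrated model.

## The problem

A risk model fitted by maximum likelihood with logit P(Y=1|x) = β₀ + βᵀx
on a development sample of size *n* is usually overfitted: on external
validation data its calibration slope (CS — the slope from regressing the
outcome on the model's linear predictor) falls below 1. Ridge and lasso
shrink coefficients by maximizing the penalized likelihood

    (1/n)·l(β) − λ·s(β),     s(β) = Σⱼ βⱼ²  (ridge)  or  Σⱼ |βⱼ|  (lasso),

but the tuning parameter λ chosen by standard k-fold cross-validation is
biased upward: the cv-training sets have size n·(k−1)/k, smaller than the
data the final model is fitted on, so the selected λ over-shrinks —
often yielding CS > 1 and, worse, large variability in CS across
datasets.

**Modified tuning** fixes the size mismatch: bootstrap a pseudo-dataset
of size n_pseudo = n·k/(k−1) (so every cv-training fold has the original
size n), cross-validate it over a fixed λ grid, repeat B times, average
the B deviance curves, and take the argmin. **Bootstrap tuning** fits the
path on bootstrap resamples of size n and scores deviance on the original
data. Both select a smaller, far less variable λ than standard tuning and
raise the probability of landing in the well-calibrated band CS ∈
[0.9, 1.1]. Also implemented: Firth's bias-reduced logistic regression
with intercept correction, bootstrap uniform shrinkage, and validation
metrics (CS, calibration-in-the-large, C-statistic, Brier score, RMSPE)
with across-replicate summaries (RMSD(log-CS), p_well_cal, paired
head-to-head wins).

## Worked example

```python
import shrinktune as st

scn = st.main_scenario()                      # C=0.7, prevalence 0.5, p=12
dev = st.generate_dataset(scn, n=450, seed=20)
val = st.generate_dataset(scn, n=50_000, seed=21)

standard = st.standard_tune(dev, "ridge", k=10, seed=22)
modified = st.modified_tune(dev, "ridge", k=10, B=50, seed=22)
boot     = st.bootstrap_tune(dev, "ridge", B=50, seed=22)
```

Fitting the final model on `dev` at each selected λ and validating on
`val` (this is `examples/03_modified_tuning.py`) prints:

```
pseudo-dataset size: 500 (n=450, k=10)
standard   lambda =   0.04766   validation CS = 1.215
modified   lambda =   0.02993   validation CS = 1.078
bootstrap  lambda =   0.02727   validation CS = 1.057
```

Standard tuning picks a λ ~60% larger and over-shrinks (CS 1.22 — the
prediction range is too narrow); modified and bootstrap tuning nearly
agree with each other and land much closer to the ideal CS = 1.

The `examples/` directory has one short script per capability: data
generation and calibration of the generator (`01`), fitting and
validating all shrinkage methods (`02`), tuning (`03`), a small
replicate-level simulation with summary metrics (`04`), and the
simulation-based recommended-sample-size search (`05`). A thin CLI
mirrors the library (`shrinktune simulate|tune|fit|validate|recommend-n|
folds-sensitivity`).

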