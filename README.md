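# smtl — subclass-based multi-task feature selection

`smtl` is a Python library for sparse feature selection in binary diagnostic
classification when the classes are **multipeak**: each class is a mixture of
several sub-populations (disease subtypes, cohort heterogeneity) rather than
a single Gaussian blob. Standard embedded selectors such as the lasso regress
one response — the class label — and can miss features whose class-conditional
means barely differ even though their subtype structure is strongly
discriminative. The package targets the neuroimaging-biomarker setting
(e.g. ROI-wise MRI/PET measures plus CSF markers for dementia diagnosis) but
works on any samples-by-features table with a binary label and a
feature-to-modality map.

## The method

Given training data `X ∈ R^{N×D}` with labels `y ∈ {+1, −1}^N`:

1. **Subclass discovery.** K-means is run separately on the samples of each
   class; every cluster is treated as a subclass (a peak of the class's
   mixture distribution).
2. **Discriminative sparse codes.** Subclass *l* of the positive class gets
   the code `s_l^(+) = [+1, e_l, 0]`; subclass *m* of the negative class gets
   `s_m^(−) = [−1, 0, −e_m]`, where `e_l` is a one-hot block indicator. Any
   two codes of the same class sit at squared Euclidean distance 2; codes of
   different classes sit at distance 6. Stacking each sample's code gives the
   target matrix `Y ∈ {−1,0,1}^{N×S}` with `S = 1 + K(+) + K(−)`; its first
   column is the original label vector.
3. **Multi-task selection.** Solve

       min_W ‖Y − XW‖_F² + λ₂‖W‖_{2,1},    ‖W‖_{2,1} = Σ_i ‖w^i‖₂

   by monotone accelerated proximal gradient (row-wise group
   soft-thresholding). The ℓ2,1 penalty zeroes whole rows of `W`, so a
   feature is kept or dropped jointly across all subclass tasks; the selected
   support is the set of rows with non-zero norm. The single-task baseline
   (STL) replaces `Y` with `y` and the penalty with `λ₁‖w‖₁`.
4. **Classification.** A soft-margin linear SVM on the selected features, or
   a multi-kernel linear SVM `K = Σ_m β_m K_m` with one kernel per modality
   and weights `β` searched on a 0.1-step simplex lattice.
5. **Protocol.** Stratified outer 10-fold CV with an inner 5-fold grid
   search over `K ∈ {1..5}`, the sparsity penalty, and `C ∈ {2^−10..2^5}`;
   per-fold ACC/SEN/SPEC/BAC/AUC; paired t-test between methods on shared
   folds; Henze–Zirkler multivariate normality test as the multipeak
   diagnostic.

A synthetic-data module generates multipeak cohorts with known informative
features and peak memberships, so every claim the pipeline makes can be
checked against ground truth.

## Worked example

`examples/04_full_experiment.py` runs the full nested-CV comparison on a
synthetic two-peak cohort (100 samples, 10 informative of 100 features,
reduced grids) and prints:

```
method            ACC (%)     SEN    SPEC     BAC     AUC
STL         60.00 ± 17.00   62.00   58.00   60.00   72.00
SMTL        71.00 ± 20.25   70.00   72.00   71.00   76.80
paired t (SMTL vs STL fold ACCs): t = 2.400, p = 0.03987

chosen K per outer fold: [3, 2, 2, 1, 2, 2, 2, 3, 2, 2]
informative-feature recall per fold: [0.9, 0.8, 1.0, 0.9, 1.0, 0.8, 0.8, 0.8, 0.9, 0.8]
```

Rows are mean ± SD over the 10 outer folds, in percent. On this cohort the
subclass-based selector (SMTL) beats the single-task baseline by 11 accuracy
points (paired p < 0.05), the inner CV mostly identifies the generating
number of peaks (K = 2), and the selection recovers 80–100% of the truly
informative features per fold. Other scripts in `examples/` demonstrate the
generator, the code construction, plain selection, the normality diagnostic,
and multi-kernel fusion.

A thin CLI wraps the same stages:

```bash
smtl simulate --preset bimodal --seed 0 --out data/
smtl run --table data/table.csv --modmap data/modmap.json --reduced-grids --out results/
smtl normtest --table data/table.csv --modmap data/modmap.json
```

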