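# Methods

## Scope and data model

`fcdiff` analyses two-group cohorts of ROI time series (one T×R matrix per
subject, R shared, T free to vary) and classifies subjects from their
connectivity patterns. The pipeline starts **after** fMRI preprocessing and
atlas extraction: volumes, motion correction, smoothing and parcellation are
out of scope, and the TSV time-series manifest is the contract boundary.

## Synthetic cohorts

Each group g has a correlation matrix Σ_g; subject time points are drawn
i.i.d. from N(0, noise_sd²·Σ_g) (an optional AR(1) temporal coefficient is
exposed, default 0). Σ₁ comes from a random sparse precision matrix: a
fraction `base_sparsity` (default 0.1) of off-diagonal entries is set to
±U(0.2, 0.4), the diagonal is lifted so the minimum eigenvalue is ≥ 0.1, and
the inverse is rescaled to unit diagonal. This is the minimal generative
model under which Pearson correlation, the graphical LASSO and the
edge-prevalence statistic are all well-posed.

Group differences are *planted*: Σ₂ = Σ₁ + Δ where Δ is nonzero only at the
requested edges. If the sum would lose positive definiteness, all planted
deltas are shrunk by the largest common factor γ ∈ (0, 1] that keeps the
minimum eigenvalue ≥ 10⁻³ (bisection; error if γ < 0.05). The achieved
deltas γ·δ are recorded in the truth table. Shrinking the deltas — rather
than ridging the whole matrix — keeps every non-planted edge *exactly* equal
between groups, so "null edge" in a recovery test means genuinely null; a
global ridge would leak small real differences onto every edge and corrupt
specificity measurements.

Defaults mirror a mid-sized clinical resting-state study: 142 + 102
subjects, 150 time points, 32 ROIs (the functional-network template scale
used by the partial-correlation analysis; 246 supported for atlas-scale
checks, used only in dimension tests to keep runtimes at desk scale).

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation (by default), motion and scanner artifacts, site effects,
non-Gaussian marginals. Passing recovery tests therefore demonstrates
statistical correctness of the pipeline, not robustness to fMRI artifacts.

## Pearson channel

Per subject, pairwise Pearson correlations are Fisher-transformed
(z = arctanh r). Correlations are clipped at |r| ≤ 1 − 10⁻⁷ first so
degenerate inputs (duplicated columns) give large finite z rather than ∞;
the diagonal is set to 0 and excluded everywhere (self-connections carry no
information). Edge-wise group comparison uses the classical pooled-variance
two-sample t-test (Welch behind `equal_var=False`), two-sided, with
Benjamini–Hochberg FDR over all R(R−1)/2 edges as one family and a
significance flag at p-FDR < 0.05 (configurable).

## Partial channel

Columns are standardized, then the precision matrix is estimated by
graphical LASSO (scikit-learn). The penalty defaults to 3-fold
cross-validation over {0.01, 0.02, 0.05, 0.1, 0.2, 0.5} on the correlation
scale; a fixed α is accepted and is what the scaled test runs use (CV
multiplies the fit count by ~18 and the chosen α is stable on synthetic
data). Partial correlations follow as −Θ_ij/√(Θ_ii·Θ_jj); binarization
keeps |pc| **strictly** greater than the threshold (default 0.1) — the
boundary has measure zero, so the choice is a tie-break convention, recorded
here.

## Edge-prevalence Score and permutation inference

For each edge, S = L₁/N₁ − L₂/N₂ (group-wise prevalence difference,
|S| ≤ 1). The null distribution is built by re-partitioning subjects at
random into groups of the original sizes; each resample yields one S′ for
every edge from a shared partition stream, preserving the dependence between
edges. Partitions are canonicalised on the smaller group, which makes the
sampled p-values exactly invariant under swapping the group labels whenever
N₁ ≠ N₂ (the label swap flips the sign of every S′ along with S).

Three tail rules are implemented. The default is the symmetric two-sided
tail, Pr(|S′| ≥ |S|), with P = 1 when S = 0. A *directional* tail
(Pr(S′ ≥ S) for S > 0, Pr(S′ ≤ S) for S < 0) is available but not the
default: choosing the tail direction from the observed sign doubles the
unconditional null exceedance rate (measured ≈ 0.09 at α = 0.05), so it is
not a calibrated p-value. A *literal* rule that assigns the **lower** tail
to positive scores (so extreme positive S gets P near 1, an
evidence-for-the-null reading) is retained purely for auditability of the
formula it reproduces.

The null is discrete: conditional on an edge's total count K, the group-1
count is hypergeometric, so S′ lives on a lattice with non-trivial atoms.
The classical tie-inclusive estimate (1 + #{at least as extreme})/(1 +
n_perm) is therefore systematically conservative (measured null exceedance
0.033–0.045 at α = 0.05 for group sizes 50–700). The default estimator is
the permutation **mid-p** — strict tail plus half the tie mass, add-one
smoothed:

    P = (#{S′ more extreme} + ½·(1 + #{S′ tied})) / (1 + n_perm)

which tracks the nominal level closely (measured 0.048–0.055 at α = 0.05
and 0.006–0.013 at α = 0.01) while never returning 0. The guaranteed-valid
tie-inclusive estimator stays available via `estimator="tail"`, and the
exact-enumeration oracle computes both quantities exactly over all
C(N₁+N₂, N₁) partitions (test-scale cohorts only).

Defaults: 10⁵ resamples, flag at P < 0.001, no multiplicity correction
across edges (the raw-P rule is deliberate and configurable). Note that
published tables of this statistic sometimes print |Score| > 1, which is
impossible for a difference of two proportions; this implementation follows
the defining formula and makes no attempt to guess a rescaled variant.

## Effect-size screening and channels

ES_i = |x̄_{i,1} − x̄_{i,2}| / S_i with
S_i = √(((n₁−1)S²_{i,1} + (n₂−1)S²_{i,2})/(n₁+n₂)), per-group sample SDs
with ddof 1. The n₁+n₂ pooling (rather than the textbook Cohen
n₁+n₂−2) is kept as defined; the two differ by the constant factor
√((n₁+n₂)/(n₁+n₂−2)) and induce identical rankings, which the tests assert.
A feature with zero pooled deviation gets ES = +∞ and a `degenerate` flag if
the means differ, ES = 0 otherwise.

Selection is top-k with k = side² (default 484 = 22²): a fixed count, not an
ES-value cutoff, because a square channel must be filled exactly. The grid
order is row-major by descending ES with ties broken by ascending feature
index — the CNN is layout-sensitive, so the ordering rule is part of the
artifact contract and serialised with every layout. Each channel (Fisher-z
Pearson features, partial-correlation features) gets its own ranking and
layout; the two channels of one subject are stacked into a side×side×2
tensor and z-scored per channel with statistics from the training split only.

## Classifier

The CNN stack is implemented in NumPy (3×3 same-padding convolutions via
einsum, 2×2 max-pooling, global average pooling, dense layers, inverted
dropout, softmax cross-entropy, Adam). Three backbones: `tiny` (two conv
layers, native side×side×2 input — the desk-scale default), `vgg16` (paired
3×3 convs between pools, 32×32×3 input) and `resnet50` (initial conv plus
two identity-skip residual blocks, 32×32×3). Dual-channel tensors reach the
larger backbones through bilinear upsampling (align-corners; exact on
constants and linear ramps) with a third channel synthesized as the mean of
the two (zeros behind a flag). Backbone weights are randomly initialised by
default; a local `.npz` checkpoint can be loaded via
`pretrained_weights` — no network access is ever required.

Transfer strategies: `freeze` trains only the fully-connected head
(gradients are not propagated into the backbone, so its parameters are
bit-identical afterwards — asserted in tests); `fine_tune` trains
everything. Head variants: softmax only, or one hidden layer of 128/512/1024
neurons (default 1024) with ReLU and dropout. Training hyperparameters
default to Adam, lr 10⁻³, batch 32, 60 epochs, conv dropout 0.1, fc dropout
0.2. Runs are deterministic given the seed (pure NumPy, seeded generator for
init, shuffling, dropout).

Data augmentation is limited to optional Gaussian jitter on the feature
tensors (`augment_sd`, off by default); it is an extrapolation, not a
documented part of the procedure this pipeline follows.

Evaluation: positive class = patient group; accuracy/sensitivity/specificity
in percent from the confusion matrix at the 0.5 softmax threshold; ROC by
sweeping the positive-class score (scikit-learn) and AUC by trapezoidal
integration (equal to Mann–Whitney concordance, asserted to 10⁻¹⁰). Splits
are stratified random holdouts (default 50 test subjects) with the split
seed derived from the run seed; a repeated-split averaging mode is also
provided since single-holdout and averaged protocols are both common. On
short training budgets the *ranking* of test subjects is typically perfect
(AUC 1.0 on strongly planted cohorts) an epoch or two before the 0.5
threshold is calibrated, so accuracy can trail AUC.

## Pipeline

One YAML `RunConfig` drives all stages; a single global seed fans out to
per-stage seeds through fixed `SeedSequence` spawn keys, so any stage can be
re-run in isolation reproducibly. Stages communicate only through their
documented TSV/JSON artifacts; each run directory carries the resolved
config and a SHA-256 manifest of every output. Logging is per-stage;
per-edge detail stays at debug level (a 246-ROI run has ~30k edges).

## Scaled study sizes

The shipped tests and the acceptance script run everything at desk scale,
sizes chosen once as representative rather than tuned: planted-edge recovery
at 60+60 subjects, T = 200, delta 0.5; permutation calibration on binary
cohorts of 100 per group (large enough that the discrete null is
fine-grained; at smaller n the mid-p estimator remains near-nominal while
the tie-inclusive one grows conservative), 200 edges × 20 seeds at
n_perm = 10⁴; graphical-LASSO support recovery at R = 10, T = 500; the
end-to-end classification study at 32 ROIs, 30 planted edges, fixed
glasso α = 0.05, tiny backbone, 30 epochs, 40-subject holdout, 5 seeds.

## Known limitations

- The permutation mid-p is near-nominal but not guaranteed conservative;
  for strict validity use `estimator="tail"`.
- Covariates (age, sex, motion) are not modelled in the edge tests.
- The CNN is CPU-bound NumPy: adequate for feature images up to ~64×64, not
  for ImageNet-scale inputs.
- Published headline accuracies from real clinical cohorts are not
  reproducible here by design: they depend on restricted data, an
  unspecified preprocessing chain and pretrained backbone weights. The
  acceptance suite instead verifies structural contracts, exact oracles,
  calibration and ground-truth recovery on synthetic cohorts.
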