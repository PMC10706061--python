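# Methods

This package re-implements, end to end, a Vis-NIR chemometric procedure
for assigning and discriminating five wine-grape maturity stages. The
original study measured diffuse reflectance of Cabernet Sauvignon
berries (400-1029 nm, 1507 channels) together with four quality
indicators — soluble solids content (SSC, °Brix), total acids (TA, g/L),
total phenols (TP, mg gallic-acid eq./g skin) and tannins (TN, mg
epicatechin eq./g) — constructed stage labels by spectral clustering of
the indicators, and classified the spectra into those stages. No raw
spectra accompany the study, so this package pairs the procedure with a
synthetic-data generator that emulates the statistical structure the
procedure assumes; all quantitative claims made by the tests concern
that synthetic material, not real grapes.

## Synthetic data generator (`synthio`)

**Chemistry.** Each of the five stages draws its indicators from
independent truncated normals (lower bound 0) with the published
per-stage means/SDs and stage sizes 32/34/55/49/30 (200 samples).
Truncation prevents negative concentrations; at the published mean/SD
ratios it biases stage means by < 0.04 units. The SSC/TA ratio is
derived per sample. Setting all SDs to zero collapses each stage onto
its published mean, which pins, e.g., the stage-V SSC/TA ratio at
18.71/3.42 ≈ 5.47.

**Spectra.** A clean spectrum is a smooth sigmoidal baseline (rising
through the red edge, ~0.3 → ~0.75 reflectance) minus four Gaussian
absorption bands:

| centre (nm) | sigma (nm) | depth linked to | base depth |
|---|---|---|---|
| 535 | 22 | TP (anthocyanin/phenolics) | 0.18 |
| 680 | 18 | stage index (chlorophyll decay) | 0.22 |
| 820 | 25 | SSC (sugar O-H overtone) | 0.06 |
| 970 | 30 | TA (O-H/C-H overtone) | 0.05 |

Indicator-linked depths scale the base depth by the sample's value over
the count-weighted grand mean, so a typical sample shows the base
depth; the chlorophyll depth decays linearly from 100% at stage I to
20% at stage V, emulating veraison colour loss. Each sample yields 10
replicate sub-spectra distorted as `a*s + b + eps` with
`a ~ N(1, 0.08)`, `b ~ N(0, 0.015)` and i.i.d. channel noise
`eps ~ N(0, 0.004)`, clipped to [0, 1.5]. The scatter layer is exactly
the affine model that MSC inverts, so the preprocessing step has a
well-defined optimum; the noise and scatter scales are typical of
benchtop diffuse-reflectance instruments. Channels within ±2 sigma of a
band centre are recorded as "informative" so wavelength-selection
recovery can be scored against the generator's own truth.

**What the generator does not emulate.** Real berry spectra have
correlated (not i.i.d.) channel noise, wavelength-dependent instrument
response, pigment bands that shift and skew with ripening, and
chemistry indicators that are correlated *within* a stage (here they are
drawn independently). TN influences the stage construction but is
deliberately not encoded in the spectra (the band links are TP, SSC, TA
and stage), which puts a ceiling of roughly 92% on spectra-based stage
prediction at the default noise — comparable to, and a useful analogue
of, the original study's 88-94% accuracies. Passing tests therefore
demonstrate that the pipeline machinery is correct and that its
qualitative behaviour (MSC optimality, CARS channel recovery, early/late
stage separation) emerges under the assumed structure; they say nothing
about real grapes.

## Preprocessing (`preprocess`)

Replicates are reduced to one representative per sample — the replicate
minimising the summed Euclidean distance to its siblings (ties to the
lowest index) — then trimmed to 400-1029 nm inclusive. Three
pretreatments are provided:

* **SNV**: per-row centre/scale with the n−1 SD (the chemometric
  convention; a constant row is a named error).
* **MSC**: each row is regressed on a reference spectrum by OLS and
  inverted, `(x − b)/a`. The reference is the calibration-set column
  mean, frozen into an `MscFit` and re-applied to prediction spectra —
  no statistic ever crosses the split. MSC is idempotent and exactly
  inverts the generator's scatter layer. A slope below 1e-8 is a
  degenerate-sample error.
* **Savitzky–Golay**: window 23, polynomial order 5, 0th derivative,
  mirror-padded edges (keeps output length equal to input; the edge rule
  is this package's choice).

Pretreatments are applied after representative selection and after the
SPXY split, matching the acquisition → partition → pretreat order of the
original workflow.

## Stage construction (`staging`)

Ng–Jordan–Weiss normalised spectral clustering on the four z-scored
indicators: Gaussian affinity `exp(−d²/2σ²)` with the median pairwise
distance as σ (median heuristic), zero diagonal; normalised symmetric
Laplacian; row-normalised embedding from the k = 5 smallest eigenvectors;
k-means with 10 restarts at a fixed seed. Clusters are relabelled so
stages I→V follow ascending cluster-mean SSC — SSC rises monotonically
through ripening, making it the natural anchor; this also makes the
output deterministic up to the k-means seed. On zero-noise chemistry the
clustering recovers the five generating stages exactly; at the default
SDs it reproduces the published qualitative picture (stages I–II well
separated from III–V, with blur among the last three).

## Partitioning (`partition`)

SPXY: joint-distance Kennard–Stone. Combined distance
`d = dx/max(dx) + dy/max(dy)` with Euclidean distances in the spectra
(x) and the standardized four-indicator chemistry (y); the two mutually
farthest samples seed the calibration set, then max–min accretion adds
one sample per step (the canonical single-sample rule; the alternative
two-sample reading of "longest and shortest" is not used) until
`round(0.75·n)` — exactly 150 of 200. Ties break to the lowest index;
the algorithm has no randomness. Stage labels are not used as y: they
are discrete and would collapse the y-distance. A seeded random split is
provided for ablation only.

## PLS and CARS (`plscars`)

The PLS core is NIPALS PLS1 on column-centred data; for a univariate
response each component is a closed-form deflation step. With full
components it reproduces least squares (tested to 1e-6); a response
orthogonal to X yields the null model. RMSECV uses a seeded shuffled
near-equal k-fold partition (default 10 folds).

CARS runs N = 100 Monte-Carlo rounds. Each round: draw 80% of the
calibration samples without replacement; fit PLS (components capped at
10 and at the data rank) on the currently retained channels; rank |b|;
enforce the exponentially-decreasing cap `ceil(r_i · p)` with
`r_i = a·e^(−k·i)`, `a = (p/2)^(1/(N−1))`, `k = ln(p/2)/(N−1)` (so
r_1 = 1 and r_N = 2/p); then adaptive reweighted sampling — `ceil(r_i·p)`
draws with replacement, probability ∝ |b|, keeping the unique set.
Every round's set is scored by 10-fold RMSECV; the arg-min round
(earliest on ties) supplies the selected wavelengths. The response is
the stage index 0–4 treated as one continuous variable — the original
workflow ran regression machinery on a staging problem without stating
the encoding, and the ordinal stage index is the natural univariate
choice (one-hot PLS2 would be the alternative). On the default fixture
the RMSECV trajectory falls and then rises, with an interior minimum,
and the selection concentrates inside the planted bands.

## Classifiers (`models`, `nn`)

All three share fit(X, labels)/predict(X). The deep models standardize
each channel with calibration statistics frozen at fit time; the SVM
standardizes inside its pipeline.

* **SVM**: RBF kernel, one-vs-one, 50 log-uniform (C, γ) candidates in
  [1e-4, 1e3]² scored by stratified 5-fold CV accuracy, best refit.
* **1D-CNN**: conv(64 kernels, size 2, stride 2) → BN → ReLU →
  maxpool(3, stride 1) → conv(32, 2, 2) → BN → ReLU → flatten →
  dense 512 → BN → ReLU → dropout 0.5 → dense 64 → BN → ReLU → dropout
  → dense 5. Dense widths switch to 128/32 when the input is the
  CARS-selected subset. Convolutions are valid (unpadded), so the
  feature lengths follow `floor((L−k)/s)+1`: 753/751/375 at 1507 input,
  77/75/37 at 154. Conv→BN→ReLU ordering and the ReLUs after the dense
  batch-norms are this package's documented choices where the layer
  table is silent.
* **SAE**: two dense autoencoders pretrained greedily (each reconstructs
  its own input under MSE; learning rate 1e-3 for pretraining, which
  otherwise barely moves in 200 epochs), then the encoder stack plus a
  fresh softmax head fine-tuned end to end. Encoder widths default to
  256/64 for full spectra and 64/16 for selected subsets.

The gradient models train with batch size 10, learning rate 1e-4,
decoupled weight decay 1e-4 and dropout 0.5 — the published settings —
on this package's numpy layer/optimiser core (AdamW, explicit backprop,
single seeded generator), which makes training bit-reproducible. The
published epoch count is 1000; the test and analysis profile uses 100
epochs, which already saturates calibration accuracy on the synthetic
fixture at the sizes used (150 calibration / 50 prediction samples).

## Evaluation (`evalstats`)

Accuracy is the percentage of matching labels; confusion matrices are
5×5 true-by-predicted counts. Pipelines are compared per stage with a
2×2 table of correct/incorrect counts under each pipeline, tested either
by Yates-corrected chi-squared (`Σ(|O−E|−0.5)²/E`, 1 df — the corrected
variant is the one that reproduces the published 0.036 and 0.48;
uncorrected Pearson gives ≈0.015 and ≈0.36) or by the two-sided Fisher
exact test computed by full hypergeometric enumeration (all tables with
the observed margins whose probability ≤ the observed, within 1e-12
relative tolerance). The method is an explicit argument: the published
per-stage choices follow no single expected-count rule (two stages with
expected counts of 4.5 used chi-squared), so the package flags small
expected counts (< 5) but performs no automatic override when a method
is requested.

## Pipeline (`pipeline`) and numerical choices

`run_pipeline` executes simulate → representative/trim → stage → split →
pretreat → CARS → train → evaluate. A single global seed expands through
`numpy.random.SeedSequence` into independent per-stage seeds (all below
2^31), so one integer reproduces a run bit for bit; the manifest records
the derived seeds and content hashes of every intermediate. CARS runs on
calibration data only; the MSC reference and standardization statistics
are calibration-only; prediction labels are touched only at evaluation.

Degenerate inputs are errors, not warnings: constant spectra (SNV/MSC),
zero-variance indicators (staging), identical samples (SPXY), constant
response (PLS), empty retention (CARS), single-class training (SVM).
Ties are always broken toward the lowest index (replicate choice, SPXY
accretion, |b| ranking, arg-min RMSECV run) so every path is
deterministic.

Two behaviours of the default fixture are worth knowing. SPXY seeds the
calibration set with the mutually farthest samples and accretes by
max–min distance, so the chemically extreme stage-I samples are drafted
into calibration wholesale: the prediction set covers stages II–V, and
`compare_runs` reports one contingency row per stage actually present
in the prediction truth. And because the synthetic spectra carry no
redundant noisy-channel burden, full-spectrum models match or slightly
beat the CARS-selected ones on prediction accuracy at the default
sizes; wavelength selection here buys a ~90% smaller input, not an
accuracy gain — the accuracy-improvement direction reported on real
grape data is not a property the generator is designed to reproduce.

## Known limitations

* The spectral forward model is phenomenological; band positions are
  fixed and depths are affine in chemistry, with no physical radiative
  transfer. Nothing here validates against measured grape spectra.
* The TN indicator is not spectrally encoded, so stage labels are not
  perfectly recoverable from spectra by construction (ceiling ≈ 92% at
  default noise).
* CARS is implemented for a univariate response only (stage index);
  PLS2/one-hot responses are out of scope.
* The contingency tests assume the two compared pipelines' errors are
  independent samples, as in the original analysis; a paired test
  (McNemar) would be more powerful but is deliberately not provided.
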