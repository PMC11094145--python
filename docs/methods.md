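# Methods

## Model and assumptions

The audit rests on one assumption: clinically generalizable signal in
unstructured data lives in *structural/semantic* features — spatial and
temporal relationships within a sample — while acquisition bias lives
in *first-order histogram* features (brightness, contrast, noise level)
that differ between acquisition pathways and correlate with labels
through passive collection. Randomly permuting every element of a
sample along its structured axes destroys the first family exactly
while preserving the second exactly, so the test AUROC of a model
trained and evaluated on shuffled data, `P_DABIS`, measures the
histogram-level (bias-accessible) signal *as seen by that architecture*.
The calibrated external estimate is

    P_Est = P_Source − P_DABIS + Ō,      Ō = 0.5 for AUROC,

clipped to [0, 1] (with a warning when clipping fires) so it remains a
valid AUROC. The method is model-relative by design: a different
architecture may be more or less shortcut-prone, and the audit must be
run with the model one intends to deploy.

## Shuffling semantics

* One flat permutation over all selected structured axes per sample;
  by default the same permutation is applied to every channel
  ("shared"), since mixing values across channels would blend
  per-channel bias distributions. An independent-per-channel policy is
  available.
* Training data is reshuffled every epoch; validation and test splits
  receive a single fixed shuffle (a reserved epoch key) so validation
  AUROC is comparable across epochs and early stopping is meaningful.
* Permutation RNGs are keyed by `(base_seed, epoch, sample_id)` —
  reordering a manifest cannot silently change any permutation.
* Text: word order is permuted, then letters within each word;
  whitespace runs stay in place, so the character multiset and
  whitespace count are preserved. Punctuation travels with its word.

## Measurement layer

AUROC uses the Mann–Whitney convention (ties 0.5 per pair; delegated to
scikit-learn), with one-vs-rest unweighted averaging for multi-class
scores. Confidence intervals are (2.5, 97.5) percentile intervals over
1000 sample-level bootstrap resamples; resamples missing a class are
redrawn (max 100 attempts), or stratified resampling can be requested.
The interval is widened if needed to contain the full-sample point
estimate. The `P_Est` interval applies the calibration formula to
paired bootstrap replicates of the two arms.

ROC curves are stored at all distinct thresholds. Curve calibration
evaluates `tpr_est(f) = tpr_src(f) − tpr_dabis(f) + f` on the union of
both curves' FPR breakpoints (linear interpolation in FPR; vertical
segments resolved to their upper envelope), then clips to [0, 1],
rectifies with a running maximum, and forces the (0,0)/(1,1)
endpoints. The output's area recovers the scalar formula exactly
before clipping/rectification; clipping inflates the area when the
shuffled curve sits far above the source curve, a regime real audits
do not produce (there the shuffled model is at or below the source
model), so the area-consistency check fuzzes realistic curve pairs.

## Training harness

Splits are drawn at the patient level (70/10/20 by default,
configurable; a zero validation ratio is allowed for models that do not
early-stop), retrying with derived seeds until every class appears in
every non-empty split. Normalisation statistics (population mean/sd;
per-channel for 1-D signals) are fitted on the training split only and
reused unchanged for the shuffled arm — shuffling commutes with
per-channel affine normalisation, so the shuffled arm sees exactly the
same histograms. Training is Adam (betas 0.9/0.999) with
cross-entropy, early stopping on validation AUROC (patience 5), the
learning rate divided by 10 after `⌊max_epochs/3⌋` consecutive
non-improving epochs, and best-validation weights restored before test
evaluation. Both audit arms use identical splits, schedules and
stopping rules so the two AUROCs are comparable.

The default learning rate is 1e-3. The schedule mirrors common
practice for full-size clinical models (which typically start at 1e-4),
scaled up because the reference models here are orders of magnitude
smaller and train for at most a few dozen epochs.

## Reference models

Compact numpy implementations (dense layers; N-dimensional stride-1
convolution via sliding-window matrix multiplication; 2× max-pooling;
ReLU): a 2-D CNN for images, a 1-D multi-channel CNN for signals, a
small 3-D CNN for volumes, a character-level CNN with global max
pooling for text (letter-shuffle sensitivity requires a sub-word
model; a bag-of-words model would be word-order invariant and
understate the shortcut estimate), and an MLP. All are deterministic
under a seed, stay under 500k parameters, and expose the same
fit-step/score contract the harness consumes, so any externally
supplied model implementing that contract can be audited.

The histogram-only logistic baseline computes per-channel mean, sd and
deciles from each channel's *sorted* values, which makes its features —
and hence its scores — bit-identical on original and shuffled inputs.
It certifies both directions of the audit's premise: what shuffling
preserves (its AUROC is unchanged) and what the bias ceiling is (it
approaches the analytic optimum for offset bias).

## Synthetic two-site data

Each sample is i.i.d. Gaussian noise (sd `σ = 1`) plus a structural
class signal plus a sample-wide bias. The structural signal is a
constant-area bright bar whose **orientation** encodes the class in
images, or a constant-width pulse whose **position** encodes the class
in 1-D signals (small positional jitter in both). Because the signal
occupies the same number of elements at the same amplitude in both
classes, the per-channel value multiset is class-independent by
construction: the structure is learnable by small CNNs/MLPs and exactly
invisible to histogram features. (An earlier candidate — class-coded
bar *size* — was rejected because it changes the histogram.) Bias is a
per-(site, class) additive offset `β` and/or noise-scale factor `γ`
applied to the whole sample, the scanner-level framing; per-channel
bias is available as an option. Patients carry 1–3 samples each to
exercise patient-level splitting. For a pure offset gap `β` over `N`
elements the best achievable histogram AUROC is `Φ(β√N/(σ√2))`,
recorded as ground truth.

### Frozen study conditions

All on 32×32 single-channel images, ~600 samples per site (150
patients per site-class cell):

* **bias-free** — structure amplitude 1.0, no bias: shuffled-arm AUROC
  should be chance.
* **bias-only** — no structure, source offset `β = 0.04` (best
  histogram AUROC ≈ 0.82): plain and shuffled arms should agree.
* **mixed two-site** — structure amplitude 0.25 plus source offset
  `β = 0.057` (≈ 0.90): the regime shortcut learning actually
  arises in, where the true signal is subtle relative to the bias.
  The external site shares the structure and carries no bias.
* **pooled opposite-bias** — two source sites with opposite per-class
  offsets; the second site also has a class-independent brightness
  offset (0.3) as a site fingerprint. Without such a fingerprint the
  pooled offsets cancel exactly and *no* model could recover the
  shortcut; real pooled hospital datasets are trivially
  site-identifiable, and the fingerprint restores that property. The
  audit shows pooling does not remove bias: the model identifies the
  site, then applies the per-site shortcut.

These parameters are the package's study conditions and are not tuned
per run; experiments derive all randomness from a single seed via
seed-sequence spawning.

## What the simulator does and does not show

It emulates class-correlated, sample-wide first-order bias and
structure that is perfectly histogram-invisible — the clean extremes of
the audit's assumption. Real data has partially structural bias
(undetected by shuffling; the estimate is then optimistic), partially
transferable histogram signal (e.g. body habitus; the estimate is then
conservative — the published audits underestimate external AUROC for
this reason), correlated textures, and label noise, none of which are
modelled. In the simulator's fully non-transferring-bias regime the
calibrated estimate is approximately unbiased rather than
systematically low (measured +0.03 against external truth over 5
replicates, within sampling noise); passing tests therefore validate
the estimator's mechanics and its comparative advantage over raw
reporting, not the real-data magnitude of either effect.

## Numerical choices and degenerate inputs

* Single-class labels raise a dedicated error everywhere an AUROC is
  computed — never silently 0.5.
* Table aggregation averages instances of a source dataset before
  averaging across datasets; display rounding is half-even at 2
  decimals, internal arithmetic unrounded. Re-entered published tables
  may carry deltas rounded from unrounded inputs, so delta-column
  validation allows a 0.015 slack.
* Non-finite training losses abort with diagnostics; normalisation
  sds are floored at 1e-8; empty arrays and channel-axis shuffles are
  rejected.
* Problem sizes in the validation suite (~600 samples, ≤30 epochs,
  ≤500k-parameter models, 5–10 replicates) were chosen so the full
  ground-truth recovery battery runs on a single CPU in a few minutes.

## Known limitations

Bias that is structural rather than first-order is invisible to the
shuffle transform (the estimate is then too optimistic); the transform
is pluggable for task-specific alternatives, but only full shuffling
ships. The estimate is not a strict lower bound on external
performance. Multi-label scoring (independent per-label AUROCs) is not
implemented; tasks are single-label multi-class. The simulator's bias
model is a modelling choice, so validation is parameter recovery
against its ground truth, not replication of published real-data
values.
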