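# Methods

This note documents the models and procedures implemented in `odorml`, the
defaults they ship with, and the reasoning behind the design choices that
were genuinely open.

## Problem setting

Each odorant molecule carries a *set* of odor descriptors (multi-label
classification). Descriptor frequencies in real odor datasets are heavily
long-tailed — the most frequent descriptor appears on roughly a quarter of
molecules, the rarest on under one percent, with about three descriptors
per molecule on average — so plain training under-serves exactly the rare
descriptors a perfumer or e-nose designer cares about. The pipeline
addresses this from three directions: quantify the imbalance, resample the
training data, and make the classifier's loss cost-sensitive.

## Featurization

**Vibrational spectra.** A peak list (wavenumber, intensity) is projected
onto a bounded frequency scale (BFS) of 1–4000 cm⁻¹ — wide enough for all
fundamental vibrational modes — and each peak is broadened with a
unit-area Gaussian kernel of width σ (default 10 cm⁻¹). Broadening lets
molecules whose corresponding modes are shifted by a few wavenumbers still
be compared bin-by-bin. The smoothed signal is sampled every L cm⁻¹
(default 5), giving ⌊4000/L⌋ = 800 descriptors, and max-normalised to
[0, 1]. Choices worth noting:

- The kernel is evaluated exactly (no truncation radius); at 800 grid
  points × a few dozen peaks this costs microseconds.
- Grid convention: bin centers at k·L for k = 1..800 (5, 10, …, 4000),
  which yields exactly the 800-descriptor design; configurable.
- Normalisation is per-spectrum (divide by the spectrum's own maximum), by
  analogy with the mass-spectrum normalisation that is unambiguous. A
  global normalisation across the dataset would preserve relative overall
  intensity between molecules; per-spectrum was chosen because peak-list
  intensities from heterogeneous sources are not on a common scale.
- A peak outside the BFS contributes through its kernel tail rather than
  raising an error; negative intensities are rejected.

**Mass spectra.** Intensities at integer m/z are kept within the inclusive
window 50–262 (213 bins): below 50 m/z fragments are dominated by odorless
small species, above 262 by low-volatility compounds. Each windowed
spectrum is divided by its in-window maximum; a spectrum with no peaks in
the window stays all-zero. Non-integer m/z values are rounded to the
nearest integer with a warning (or rejected, per flag); two peaks rounding
to the same bin are summed before normalisation.

**Fingerprints.** 1024-bit path-based (Daylight-style) binary fingerprints
computed with RDKit from SMILES. These depend on the molecular graph, so
different SMILES spellings of one molecule give identical bits. Count-based
Morgan fingerprints are out of scope.

**Fusion** is plain column-wise concatenation with the block boundaries
recorded, so any fused column can be traced to its modality.

## Imbalance measures

Standard multi-label imbalance metrics over a binary label matrix Y:
IRLbl(y) = (max label count)/(count of y); MeanIR and MaxIR are its mean
and max; CVIR = sd(IRLbl)/MeanIR with the sample standard deviation
(divisor |Y|−1, following the printed definition); Card = mean labels per
instance; Dens = Card/|Y|. Labels left with zero positives (possible after
splitting or undersampling) are excluded from IRLbl with a warning rather
than producing infinite ratios; the exclusion count is reported.

## Resampling

A label is a *minority* label when its IRLbl exceeds MeanIR. **ML-ROS**
appends exactly ⌊|D|·P/100⌋ clones, each copying an instance drawn
uniformly from the bag of (instance, current-minority-label) pairs —
instances carrying several minority labels are proportionally likelier to
be cloned. **ML-RUS** removes ⌊|D|·P/100⌋ instances drawn uniformly from
those carrying no minority label, so minority positives are never lost.
Both refresh IRLbl and MeanIR after every single edit (configurable via
`recompute_every` for speed), so a label that crosses MeanIR immediately
stops driving resampling. Clones keep their source's exact label set and
features and get a `.cN` id suffix for provenance.

Resampling is applied to the **training partition only** (split first,
then resample). Resampling before splitting would leak clones of one
molecule into both partitions and inflate test scores; this ordering is
the conservative choice.

One subtlety: cloning an instance that carries the majority label alongside
a minority label raises the majority count and with it every other label's
IRLbl. On realistic long-tailed data the net effect of a P=10 pass is a
clear MeanIR/CVIR reduction (asserted in the acceptance suite), but on
tiny near-balanced matrices single clones can nudge MeanIR upward — the
reduction is a strong statistical tendency, not a theorem, and the
property test states it that way.

**Iterative stratified splitting** assigns instances greedily: process the
label with the fewest remaining positives first; send each of its
instances to the split whose desired count for that label is largest (ties:
larger total remaining capacity, then seeded RNG). A label with a single
positive necessarily lands in the larger (training) split, with a warning.

## Classifiers

**CSMLP.** A feed-forward network — ReLU hidden layers, per-label sigmoid
outputs, inverted dropout — trained with Adam on the focal loss

FL = −(1/N) Σᵢ Σⱼ [(1−pᵢⱼ)^γ yᵢⱼ log(pᵢⱼ+ε) + pᵢⱼ^γ (1−yᵢⱼ) log(1−pᵢⱼ+ε)],

summed over labels and averaged over instances. γ (default 2) downweights
cells the model already classifies confidently, which on long-tailed data
are overwhelmingly negative majority cells; ε (default 1e-7) guards the
logarithms. γ = 0 recovers binary cross-entropy exactly, which the tests
assert to 1e-10. Cost-sensitivity enters solely through this loss — no
explicit class-weight matrix. Gradients are analytic; probabilities are
clipped to [1e-7, 1−1e-7] inside the gradient so the γ < 1 powers stay
finite.

Defaults: two hidden layers (512, 256), dropout 0.3, learning rate 1e-3,
batch 32, 100 epochs, decision threshold 0.5. The architecture is
config-exposed; the test and analysis runs use smaller nets (one or two
layers of 32–128 units, 25–40 epochs) matched to their smaller synthetic
problems. 10% of the training set, split by iterative stratification, is
held out for checkpointing: the returned weights are from the epoch with
the greatest validation micro-F1 (ties resolved toward the later epoch).
Training is deterministic given the config seed.

**Binary Relevance / Classifier Chains.** One binary model per label
(default base learner: scikit-learn logistic regression, config-injectable).
The chain variant augments classifier j's features with the 0/1 relevances
of labels 1..j−1 — true labels during training, the chain's own thresholded
outputs at prediction — so label correlations can be exploited; chain order
defaults to dataset label order with an optional seeded shuffle. A label
column that is constant in training yields a constant-probability
classifier with a warning rather than an error.

**Random forest** is scikit-learn's native multi-output forest, kept as
the tree-ensemble baseline; hyperparameters pass through.

## Evaluation

Micro scores pool TP/FP/FN over all (instance, label) cells; zero
denominators yield 0 with a warning. Macro scores average per-label scores
unweighted and *skip* labels with no positive ground truth, reporting the
skip count — on rare labels this convention visibly changes macro values,
which is why it is stated. AUROC is computed per label by the rank
statistic (midrank ties) and macro-averaged over labels where both classes
occur; both micro- and macro-style summaries are derivable from the report
since the per-label vector is returned. The K-S comparison of two
per-label proportion vectors uses the asymptotic two-sample statistic.

## Shapley attribution

The attribution of feature i to a prediction f(x) is the classical Shapley
value over the feature "coalition game", with absent features imputed from
background rows (the value of coalition S is the model output averaged
over background-completed inputs). For K ≤ 12 features the 2^K coalitions
are enumerated exactly — this is the oracle regime where efficiency
(base value + Σφ = f(x)) holds to 1e-6 and the null-player and symmetry
axioms are asserted exactly. Above that, a Monte-Carlo estimate over
sampled feature orderings is used: each permutation reveals features one
by one from a background row to x, accumulating marginal output changes.
Background rows are cycled evenly; when the permutation count is a
multiple of the background size the telescoping sum makes the efficiency
identity exact for the sampled estimate as well. The estimator is
self-contained and deterministic given its seed; a brute-force enumeration
serves as its cross-check in the tests.

Defaults mirror attribution practice in this domain: background = held-out
test rows, top k = 20 features per odor label, ranking by mean |φ| over
evaluation instances (the absolute value is the standard importance
convention; plain mean φ would cancel opposing contributions). Per-label
top-20 sets are pooled and each pooled feature weighted by the number of
labels that selected it, normalised to sum 1; the overlay table places
those weights on the averaged-spectrum grid for plotting.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical skeleton of a real odor dataset:

- **Label marginals** follow a warped geometric decay
  f_ℓ = head·(tail/head)^((ℓ/(L−1))^β) from the head frequency (default
  0.27) to the tail (default 0.01). A pure geometric interpolation cannot
  satisfy head, tail *and* a cardinality target simultaneously (over 109
  labels it implies ≈8.9 labels/molecule), so the shape exponent β is
  calibrated by root finding against the expected cardinality conditional
  on at least one label (default target 3.16). Labels are sampled
  independently per molecule; empty molecules are redrawn; columns are
  re-ordered by empirical count so marginals are monotone in design rank.
- **Planted signal**: each label owns fixed diagnostic wavenumbers (on a
  10 cm⁻¹ lattice within 100–3990), integer m/z fragments in 50–262, and
  fingerprint bits (3/2/5 per label by default). A molecule carrying the
  label includes each with probability `signal_strength` (default 0.9);
  `noise_peaks` (default 3) random peaks/bits are added per molecule.
  Diagnostic intensities are drawn from U(0.5, 1.0) and noise from
  U(0.1, 0.5) — strong modes over weaker background. The truth mapping is
  returned for recovery tests.
- **SMILES** come from a built-in vocabulary of 50 small valid odorant-like
  molecules reused with replacement; real-chemistry fingerprints are
  available through RDKit, but recovery tests use the planted-bit
  generator so the signal is controllable.

One seed governs everything, with independent child streams spawned in a
fixed order (label matrix; diagnostic positions; per-molecule spectra;
fingerprints; SMILES assignment).

Deliberately *not* emulated: label co-occurrence structure (labels are
independent given their marginals, so CVIR of the generated data is well
below that of real odor data, where rare labels cluster on few molecules);
vibrational-spectrum physics (no DFT, no mode shapes); mass-fragmentation
chemistry; any coupling between a molecule's SMILES and its planted
labels. Consequently, passing recovery tests show the pipeline's machinery
is correct — they do not show that real odors are predictable at any
particular accuracy, and absolute synthetic scores should never be read as
forecasts for NIST-derived spectra.

## Problem sizes

Imbalance and resampling analyses run at full study scale (2606 molecules
× 109 labels) since they cost well under a second. Model training and
attribution runs use scaled-down studies — 300–600 molecules, 8–25 labels,
one or two hidden layers, 25–40 epochs, and an 80-bin coarse wavenumber
grid (L = 50 cm⁻¹) for the Shapley recovery — sizes chosen so the planted
signal remains comfortably learnable while the whole suite runs on a
laptop-class single core in minutes.

## Known limitations

- The CSMLP is a plain numpy implementation: no GPU, no early stopping
  beyond best-epoch checkpointing, no learning-rate schedule.
- ML-ROS/ML-RUS refresh metrics after every edit by default, which is
  O(edits × |D|·|Y|); raise `recompute_every` for large datasets.
- The sampled Shapley estimator's variance grows with feature count;
  for the 2037-wide fused space, attribute on a reduced grid or per
  modality.
- Macro scores on rare labels depend on the stated skip convention;
  compare conventions before comparing numbers across packages.
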