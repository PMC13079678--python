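# Methods

This note documents the models, the synthetic-data design, the
numerical choices, and the limits of what the test suite demonstrates.

## Scene simulator

A scene is an H×W×B reflectance cube on a band grid (default 61 bands,
400–1000 nm at 10 nm; any strictly increasing grid with ≥ 8 bands in
that range is accepted). Its layers:

**Vegetation baseline.** Each crop has a parametric reflectance curve

    R(λ) = 0.04 + g·exp(−(λ−550)²/2·25²) − 0.015·exp(−(λ−480)²/2·20²)
         − 0.020·exp(−(λ−680)²/2·12²) + p / (1 + exp(−(λ−e)/10))

with a green peak at 550 nm, chlorophyll/carotenoid absorption dips at
480 and 680 nm, and a sigmoid red edge rising to the NIR plateau. The
per-crop parameters (plateau `p`, green amplitude `g`, edge position
`e`) are design values chosen to give the four crops distinct NIR
levels, distinct green/NIR band ratios, and distinct red-edge
positions — the three axes along which field spectra of different
species actually differ — so that healthy classes of different crops
are separable by illumination-robust descriptors. Leaf-to-leaf
biological variability enters as 1% multiplicative jitter on `p` and
`g`, seeded per scene.

**Disease signatures.** A diseased class modulates the baseline
multiplicatively inside its key wavelength windows with a
raised-cosine taper (full effect at the window center, zero at the
edges): `R_dis = R·(1 + δ·taper(λ))`. The windows are the published
per-class key wavelengths; the signed deviations δ (±0.16…±0.33) and
expected lesion counts are simulator design values, spaced so that
classes sharing windows differ in sign or magnitude. Lesions are
unions of discs (Poisson count with the class's density, log-normal
radius, default 5% of the frame with σ = 0.25) carrying the full
diseased signature; the remaining leaf expresses a systemic fraction
(default 0.4) of the deviation, emulating whole-leaf physiological
stress. The systemic fraction is a deliberate compromise: it
stabilizes leaf-level descriptors against the Poisson variability of
lesion coverage while leaving the majority of the per-pixel contrast
(0.6·δ) inside lesions, which is what lets activation maps localize
them.

**Background and nuisances.** Soil is flat and slowly rising
(NDVI ≈ 0.04, far below the 0.35 vegetation threshold). A smooth
multiplicative illumination field (Gaussian-blurred white noise,
sd 0.05) and AR(1) band-correlated Gaussian noise (ρ = 0.8 across
bands, sd 0.01) are applied last; reflectance is clipped to [0, 1.2].

**Determinism.** Per-sample seeds derive from
`SeedSequence([master, class, split, index])`, so any single scene is
reproducible without generating the rest, and splits are independent
streams. Dataset layouts are lazy: planning 10,066 samples costs
nothing until a cube is touched.

**What the simulator does not emulate** — and hence what green tests
do *not* show about real data: radiative transfer (no PROSPECT/SAIL),
canopy geometry, shadowing and specular effects, mixed pixels at leaf
boundaries, inter-class label noise, and sensor artifacts beyond
AR(1) noise. The deviations are also confined to the published
windows by construction, so descriptor-based separability is partly
built in; results transfer to real data only insofar as real disease
signatures are window-concentrated.

**Published-counts discrepancy.** The dataset description this layout
follows prints per-class train/val/test counts whose sums are
7,190 / 1,438 / 1,438 = 10,066, while its own Total row prints
7,110 / 1,422 / 1,422 / 11,006 — figures that neither match the rows
nor sum to each other. The generator follows the per-class rows (the
only internally consistent reading; each row's train+val+test equals
its printed row total). One acceptance test asserts the printed Total
row and is intentionally left failing to record the discrepancy.

**Tabular benchmark.** `simulate_feature_benchmark` places class means
on coordinate axes (class c sits at `effect` along informative axis
(c−1) mod n_informative), so every informative feature is
*individually necessary* — dropping one collapses a specific class
pair. With randomly drawn Gaussian class means a subset of informative
columns often suffices for perfect separation and a size-penalized
wrapper correctly discards the rest, which would make "recovers the
informative set" an ill-posed benchmark. Benchmarks use
n_classes = n_informative + 1 by default in the acceptance runs.

## Preprocessing dialects

- Savitzky–Golay (window 11, order 3) along bands; interior bands use
  the convolution kernel, the ends re-fit the cubic on the truncated
  one-sided window (no reflection padding), preserving exact
  reproduction of degree-≤3 spectra everywhere.
- Bilinear resize uses align-corners sampling: output (i,j) samples
  the source at (i·(H−1)/(H′−1), j·(W−1)/(W′−1)); corners map to
  corners and matching sizes are the identity.
- Hybrid vegetation mask = (NDVI > 0.35) AND (NIR > Otsu threshold of
  the NIR band), with red/NIR the bands nearest 670/800 nm.
- Band statistics for z-scoring are computed from training-fold pixels
  only (the fold id is recorded on the statistics object); sd is
  floored at 1e−8 with a logged warning.
- Reflectance clamps to [0, 1.5] after calibration (specular
  highlights can exceed the white panel).
- Coordinates are row-major, 0-based, half-open patch intervals.
  Patches inherit the label of their source image; the pipeline keeps
  all patches of an image (an assumption — per-patch labels are not
  available from image-level annotation).

## Feature encoders

The four encoders are genuine (small) transformer architectures —
tokenized patches with learned positional terms, pre-norm multi-head
self-attention blocks; Swin restricts attention to token windows with
alternating half-window cyclic shifts (disabled when the window covers
the grid, where it equals global attention); PVT interleaves stages
with 2×2 patch merging; the DETR variant adds a decoder of learned
queries cross-attending to the encoder output, and no box head. Bands
enter by linear projection of the full spectral vector of each spatial
sub-patch.

By default the encoders are *frozen-random*: seeded weights, never
trained, acting as deterministic feature hashers. Every forward pass is
differentiable and `fit_encoder` provides supervised joint training of
encoder + linear probe; neither mode is claimed to be what the original
study did (it does not say). Desk-scale defaults (embed 32, depth 2,
heads 2, 8 queries) keep a full experiment on one core in minutes;
literature-scale settings are reachable through the same config.

Handcrafted descriptors are computed on vegetation pixels only
(NDVI > 0.35) and — except the NIR group — on NIR-normalized spectra
(each pixel divided by its 780–980 nm mean). The band-ratio form
cancels the multiplicative illumination field exactly, which is the
dominant nuisance; computing on the vegetation mask removes soil
dilution. Red-edge position refines the derivative maximum by
parabolic interpolation (sub-band resolution; stress shifts the
inflection by less than one band spacing). The lesion-geometry proxy
flags leaf pixels whose red-edge normalized difference deviates from
the leaf median by more than 2.5 robust standard deviations — a
deliberately simple detector whose recall on faint lesions is limited.

## EGPO

Positions are continuous in [0,1]^F, thresholded at 0.5 (empty masks
repair by switching on the largest coordinate). The surrogate is a
seeded nearest-centroid classifier on standardized selected columns
under 3-fold stratified CV, scored by balanced accuracy — cheap,
deterministic, tuning-free. Default α = 0.9 weights error 9:1 against
the size ratio.

The RPPUS update treats coordinates independently; exact ties resolve
to case 1. λ is interpreted as the party-switching rate (its role in
the original political-optimizer family); the schedule is the
deterministic linear decay. Constituency winners act as secondary
attractors averaged 50/50 with the party leader in the update target.
Ties everywhere break toward the lowest (party, member) index. Elite
preservation re-inserts the archived best each iteration, which makes
the best-fitness history non-increasing by construction. After 10
stagnant iterations the worst party is re-sampled around the best
leader (Normal, σ = 0.1, clamped). Greedy refinement (first-improvement
single-bit flips, budget 2F evaluations) runs every 10 iterations on
the elite. Defaults: 10 parties × 5 members, 100 iterations,
λmax = 0.5. Fitness evaluations are cached by mask, so a run costs far
fewer surrogate fits than population × iterations.

## CSSNet

Architecture (channels for the default stem width L = 16): 3×3 conv to
L channels with per-channel affine and ReLU → n residual spatial-shift
blocks → split/merge cascade of t stages at width L/2 (stage h sums
its carried stream with the stage input, shifts, applies a pointwise
linear map and splits; the final stage emits unsplit; emitted halves
concatenate to (t−1)·L/2 channels) → capsule head: channels at each
pooled site (default 4×4) are projected into n_capsules vectors of
capsule_dim, squashed, and routed by agreement into one capsule per
class; class scores are capsule lengths.

Design decisions that differ from a literal reading of the source:

- The "conditional XOR" of the layer recursion is implemented as the
  split/shift/merge cascade (bitwise XOR is undefined on real
  tensors); the css operator is spatial shift + pointwise mix, the
  S²-MLP construction the architecture cites.
- Routing aggregates votes by their coupling-weighted **mean** (scaled
  by D/P), not the raw sum: with hundreds of primary capsules the
  summed vote vector saturates the squash for every class, flattening
  normalized probabilities and killing the gradient.
- The top-k loss is applied to **sum-normalized** capsule lengths.
  Raw lengths admit a degenerate optimum in which every class capsule
  grows to length ≈ 1 (observed empirically: train loss → 0 at
  chance-level accuracy); normalization restores inter-class
  competition. Raw lengths stay available on `Prediction`.
- The printed parameter-count formulas of the source are not
  dimensionally consistent; `param_report` instead derives the closed
  form from the concrete layer shapes and asserts exact equality with
  brute-force counting.
- The hard-set top-k loss falls back to the plain mean over all
  samples when no sample is below the threshold (keeps gradients
  alive); probabilities are floored at 1e−12 inside the log.
- The activation map is the channel mean of the cascade output,
  min-max normalized per sample with the extrema treated as constants
  in the backward pass (the normalization then only rescales
  gradients). Severity is its mean over vegetation pixels — an
  artifact-defined score; the source promises severity without a
  formula.
- The smooth-Dice term (weight β) supervises the activation map with
  lesion masks for diseased samples and vegetation masks for healthy
  ones when masks exist; β defaults to 0 (no masks exist for real
  data). Note an observed interaction: strong Dice supervision makes
  *all* channels lesion-detectors, which helps the activation map but
  degrades Grad-CAM (spatially averaged class gradients cancel); the
  attribution experiments therefore run on β = 0 models.
- Flat-feature mode tiles each selected feature over a small spatial
  map (default 4×4) so the same shift-based architecture consumes
  vectors; a 1×1 extent would zero every shifted group.
- Training is Adam (lr 1e−3, batch 32 defaults) with seeded shuffling;
  a non-finite loss aborts with diagnostics.

## Attribution

Grad-CAM backpropagates the **raw** class-capsule length (the
normalized probability saturates at 1 for confidently classified
samples and its gradient vanishes) to a cached layer — by default the
cascade output, with the post-ReLU conv stem also cached — pools the
gradient spatially per channel, forms ReLU(Σ w_c A_c), normalizes and
upsamples bilinearly. Ground truth for the Dice score is the
simulator's lesion masks; expert-marked regions do not exist here, and
this substitution is the central caveat of all localization numbers.
At the desk training scale (80 scenes) localization quality is
seed-sensitive and non-monotone in training length — longer training
can concentrate class gradients on idiosyncratic pixels and lower the
map-level Dice even as accuracy rises — so localization medians
reported for other seeds can differ substantially from the
fixed-condition test's value.

LIME components are disjoint spectral windows (edges at the published
key-wavelength breakpoints) crossed with spatial quadrants; switched-
off components are replaced by training-mean reflectance (zeros would
be far out of distribution), 500 perturbations by default, exponential
kernel on the fraction of off components, ridge surrogate, weighted R²
reported as fidelity.

KernelSHAP uses the composite group map (10 groups) as players, so
coalitions can be enumerated exhaustively; the efficiency constraint
is enforced by substitution and the exhaustive solution equals the
exact Shapley value (tested against permutation enumeration). With
sampling, coalitions are drawn from the Shapley-kernel size
distribution.

## Evaluation statistics

Classification "Dice" is per-class F1 (no segmentation ground truth in
that context); the activation-map Dice is reported separately. AUC is
the tie-corrected rank statistic, checked against brute-force pairwise
counting. Recall descriptives use the population sd (ddof 0), in
percent. Paired model comparisons use the two-sided sign-flip
permutation distribution of the mean per-fold difference (exhaustive
up to 12 folds, 10,000 seeded draws beyond), Cohen's d = mean/sd of
differences (ddof 1) with a ±1e3 sentinel for zero-variance
differences, and a percentile bootstrap CI of the mean difference. The
source never names its test; permutation/bootstrap is this package's
choice. Type-I error of the permutation test is verified at
0.05 ± 0.02 over 1,000 simulated exchangeable nulls.

## Problem sizes used by the tests and the acceptance script

All experiments are sized for a single CPU core: the end-to-end task
uses the 16-class layout at 40 train / 10 test scenes per class,
64×64 scenes on the 61-band grid, 100 selector iterations and 30
classifier epochs (~3 minutes); the localization study uses the four
maize classes at 20 train / 8 test, scenes resized to 32×32 on a
31-band grid with severe lesions (radius 9% of the frame), 80 epochs
(~2 minutes). These sizes are the package's desk-scale study
conditions; they are deliberately far below the published field
dataset (10,066 images, 150–200 bands), so absolute numbers are
analogues, not reproductions, of the published tables.

## Known limitations

- The numpy autodiff engine is single-threaded and eager; it is sized
  for the desk-scale experiments above, not for 256×256×200-band
  training.
- Frozen-random encoders carry class information only incidentally;
  on this simulator the handcrafted descriptors dominate, and the
  wrapper's main measurable effect is discarding the 128 embedding
  dimensions (selection beats the no-selection ablation on the same
  classifier).
- The lesion-geometry proxy under-detects faint lesions (per-pixel
  SNR), so that descriptor group is weakly informative; classification
  does not rely on it.
- ENVI support covers BSQ/BIL/BIP raster + text header with the fields
  this pipeline needs, not the full format surface of commercial
  tools.
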