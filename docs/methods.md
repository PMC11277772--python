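# Methods

`pulmotex` re-implements a hybrid pipeline for grading lung nodules on 2-D
CT slices as *normal*, *benign* or *malignant*. Every stage is written
against seeded synthetic phantoms with known ground truth; real CT
archives (e.g. LUNA16-style collections) are only touched at the level of
their annotation CSV dialect. This note records the models, the defaults
and why, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Synthetic phantoms and planted tables

A phantom is a 128×128 (configurable, ≥64) 8-bit slice: two dark
elliptical lung fields (≈60 on the 0–255 scale) on brighter body tissue
(≈170), additive Gaussian acquisition noise (σ=5). Nodule classes add a
bright blob (≈225) inside a lung field whose geometry encodes the class:

* **benign** — diameter drawn U(4, 10) px, smooth outline (radial
  perturbation amplitude ≤ 0.04), crisp margin;
* **malignant** — diameter U(12, 25) px, strong radial sinusoidal
  boundary perturbation (amplitude 0.25–0.45, 8–14 spikes) plus 2–4
  lobes, less defined margin.

Geometry maps monotonically onto the six LIDC-style ordinal attributes
(diameter, margin, spiculation, lobulation, subtlety, malignancy; 1–5).
By construction benign spiculation ≤ 2 and malignant ≥ 4. The boundary
spikes give malignant slices measurably higher GLCM contrast than benign
ones — the texture signal the pipeline exploits. Edge softness is
controlled so this ordering holds: the sigmoidal edge width is
`0.6 + 1.2·(1 − margin)` pixels; wider mappings smear the spiculation
high frequencies and invert the contrast ordering.

Every generator is a pure function of its arguments including the seed;
master seeds are split per item through a counter-based `SeedSequence`
spawn so extending a dataset never reshuffles existing items.

Planted feature tables draw `n_informative` columns from class-shifted
unit Gaussians (means `(class − 2)·effect` for classes {1,2,3}) among
pure-noise standard Gaussians — the substrate for the selection
algorithms, with exact knowledge of which columns matter.

**What the phantoms do not capture:** anatomical variability, scanner
point-spread functions, Hounsfield calibration, 3-D partial-volume
effects, vessels and airway structure that mimic nodules, and annotation
noise in the semantic attributes (here they are exact functions of the
generating geometry). Passing tests demonstrate the algorithms behave as
specified on controlled structure, not clinical performance.

## Butterworth smoothing

Filtering runs in the frequency domain: centered FFT, point-wise
multiplication by the Butterworth kernel, inverse FFT, modulus. The
kernel at distance d from the centered zero-frequency bin is
`1/(1 + (d/di)^{2n})` (low-pass) or `1/(1 + (di/d)^{2n})` (high-pass,
defined as 0 at d = 0, its continuous limit). Both modes pass exactly
half power at d = di. Defaults: order n = 2, cutoff `0.35·min(H,W)/2` —
low order and generous cutoff keep the transition smooth and ringing
minimal, which is what a denoising pre-pass wants; the high-pass mode is
available but the pipeline default is low-pass denoising. The modulus
after the inverse transform rectifies any negative ringing; PSNR
(`10·log10(peak²/MSE)`, +∞ for identical images) reports filter quality.

## GLCM texture and the MIR diagnostic

Images are min–max quantized to L = 8 grey levels (uniform binning;
constant images map to level 0). Co-occurrences are counted at the four
standard offsets (0°, 45°, 90°, 135°; rows increase downward),
symmetrized and normalized — standard Haralick practice, and the four
statistics (contrast, correlation, energy, homogeneity) presume
probabilities. Correlation of a constant region (zero marginal variance)
is defined as 1 and flagged degenerate: constant texture is perfectly
self-correlated, and the convention avoids 0/0. The 16-element feature
vector is angle-major. The counting was verified against both a
per-pixel brute-force loop and `skimage.feature.graycomatrix` (whose
angle convention mirrors ours: its 45° equals our 135° transposed;
symmetric matrices coincide).

The MIR objective `∂ = ϑ + τ_s·s` with fit `ϑ = Σ(α_out − α_in)² − φ`
and sparsity `s = (1/n)Σ −r_i log r_i` (natural log, floor 1e-12 inside
the log) is exposed as a reconstruction-quality diagnostic over
normalized activation magnitudes; φ defaults to 0. No optimizer is
attached to it — nothing in the formulation defines an update rule — so
it scores reconstructions rather than driving them.

## Bi-level feature selection

### Random forest core

Trees are Gini CARTs grown unpruned on bootstrap bags (size N) until
purity or minimum node size `nmin = 1`; `mtry = ⌈√M⌉` candidate features
per node; `K = 100` trees by default. Ties in split quality break to the
lowest feature index, then the lowest threshold, making forests
bit-reproducible for a fixed seed. Tree growth and prediction are
numba-compiled; each tree records its bag, enabling exact OOB votes
(~36.8% of samples per tree), OOB error, and per-tree permutation
importances. The implementation was cross-checked against sklearn's
forest for held-out accuracy on planted tables.

### Shadow screening

Each of R = 20 replicates appends an independently permuted copy of
every column (the shadows), fits a forest (K = 50 by default; the tests
use 30) on the doubled table, and records each real column's permutation
importance (mean OOB error increase when that column is shuffled within
each tree's OOB samples) along with the maximum importance among the
shadows. A feature is kept when the one-sided rank-sum test (exact when
untied) says its R scores exceed the R shadow maxima at θ = 0.05.
Gini-decrease importances are also reported, but the screen uses the
permutation scores: shadows are a permutation null, so like must compare
with like. Kept features split into strongly/weakly label-associated
groups by a chi-square test on 4-quantile-bin × class contingency
tables (α₂ = 0.05; empty rows/columns are dropped, duplicate quantile
edges merge bins). Group-stratified forests then draw ⌈mtry/2⌉
candidates from the strong and ⌊mtry/2⌋ from the weak group, never
leaving a node without a strong candidate.

### Chaotic crow search wrapper

Binary CCSA with the published parameters: H = 30 crows, awareness
AP = 0.1, flight length 2, bounds [0,1], 50 iterations, 10-fold
stratified CV in the fitness. The chaotic value ς comes from one of ten
standard 1-D maps (logistic default; the sources never name their ten,
so the canonical metaheuristic set is provided) and a single draw per
crow per iteration both gates the follow/relocate branch (follow when
ς ≥ AP) and scales the step — matching the single ς in the update
equation. Positions binarize through the steep sigmoid
`v = 1/(1+e^{10(α−0.5)})` with bit = 1 iff v ≥ u; the transfer is
decreasing in α exactly as printed (a flag flips it). Fitness is
`accuracy + λ_F(1 − L_F/L_τ)` with λ_F = 0.01, the printed additive
form; all-zero masks are repaired by setting one random bit.

Two performance choices matter: fold assignment is frozen per run, so
fitness differences reflect masks rather than fold noise (and an
exhaustive-search oracle over the same folds is directly comparable),
and mask fitnesses are memoised. The wrapper's internal forest (K = 25)
grows histogram trees on 32-quantile-binned features — split thresholds
coarsen to the quantile grid, which leaves CV accuracy essentially
unchanged but makes a full 30×50 run take seconds instead of minutes.
The exact-threshold CART remains the forest module's implementation.

## Sparse-coding super-resolution (SCNN)

The network maps a bicubically upscaled low-resolution slice (cubic
spline, `grid_mode`, reflect boundary) to a high-resolution prediction:

1. 9×9 conv + ReLU → n1 feature maps (zero-padded to preserve shape).
2. For each patch (p = 2, stride 1 by default) the feature vector at the
   patch center is sparse-coded against Dlow (n1 × m) by k = 3 unrolled
   ISTA steps `z ← h_θ(Dlowᵀx/L + (I − DlowᵀDlow/L)z)`, with the clamped
   soft threshold `h_θ(v) = sign(v)·max(|v| − θ, 0)`, θ = α/L. The
   positive-part clamp is essential: without it the operator is not a
   shrinkage and the iteration diverges.
3. A 1×1 conv + ReLU (F3: m → n2) maps the code to the high-resolution
   code space; DHigh (p² × n2) emits a p×p patch of detail.
4. Each patch adds the mean of its input window (standard sparse-coding
   SR normalization: dictionaries code the mean-free structure, the DC
   level rides along from the input); overlapping patches are averaged
   into the canvas; a final 5×5 conv whose pre-activation also receives
   the upscaled input, then ReLU, produces the output. Anchoring the
   output layer on the input means the network learns the *refinement*
   of bicubic; without it, the prescribed near-zero initialization
   leaves the plain feed-forward network unable to even reach bicubic's
   own reconstruction error (training loss plateaus above it), and the
   learned-enhancement experiment below cannot demonstrate anything.

`L` is the largest eigenvalue of DlowᵀDlow (dense symmetric
eigensolve, ×(1+1e-6)) stored as a parameter: it is refreshed from Dlow
after every optimizer step and treated as constant inside the unrolled
graph, so the analytic gradients (verified against central finite
differences to 1e-4 relative, block by block) are exact for the
computation as executed.

Initialization follows the stated scheme: filters Gaussian(0, 0.001),
biases 0, dictionaries Gaussian with unit-normalized columns. Two
consequences are handled explicitly: backward masks use ≥ 0 (subgradient
1 at the kink) so zero biases are not a dead point, and the sparsity
weight starts at α = 1e-4 — any θ = α/L above the initial code
magnitudes makes the shrinkage output exactly zero and cuts all gradient
to the first layer and dictionary. α is itself trained and grows (to
≈0.2 in the phantom runs) as code magnitudes grow.

Training is full-batch Adam on the mean-squared reconstruction error
over (low, high) pairs on the [0,1] scale (default lr 1e-4; the phantom
experiments in the tests use lr 1e-3 for 600 epochs, stated in the test
itself). Divergence (loss > 10× initial for 3 consecutive epochs)
aborts with a diagnostic. On 64 patch pairs cut from degraded phantoms
(factor 2, low-resolution noise σ=5), the trained network's held-out
PSNR exceeds the bicubic baseline by ≈0.9 dB on average — the check is
that learning extracts real signal, not a clinical enhancement claim.

## PNN classifier

Training standardizes features (training mean/sd) and stores the
patterns verbatim. Classification evaluates the Parzen density
`f_k(x) = (1/m_k)Σ exp(−‖x−w‖²/2σ²)` per class (single scalar σ,
default 0.3 in standardized space — the canonical PNN with a Gaussian
kernel, since the source never states the kernel) and decides
`argmax_k prior_k·cost_k·f_k`, ties to the smallest label. Priors
default to class frequencies (explicit priors normalize with a
warning), costs to 1. All scoring is in the log domain (logsumexp);
normalized scores are a softmax of the log Bayes scores, so σ → 0
recovers exact 1-nearest-neighbour behaviour without underflow and
σ → ∞ decays to argmax prior·cost. The two-class summation unit with
weight `v_b = −(℘_b C_b m_a)/(℘_a C_a m_b)` (the sign restored — without
it the positivity decision is meaningless) is kept alongside and tested
algebraically equivalent to the argmax rule.

## Evaluation and pipeline

Metrics follow the confusion-count definitions; sensitivity is
TP/(TP+FN) (the printed sensitivity formula duplicates precision — an
evident typo — and the standard form is used). Zero-denominator ratios
surface as NaN with a flag rather than silently becoming 0 or 1.
Multiclass evaluation is one-vs-rest per class plus macro averages;
malignant is the headline positive class, and the malignant ROC uses
the normalized malignant score with a threshold sweep that includes
every observed score, making the trapezoid area exactly the pairwise
concordance statistic.

`run_pipeline` wires the stages: phantom generation → Butterworth
smoothing → GLCM texture (16 features) → concatenation with the six
semantic attributes (zeros for nodule-free slices) → CCSA selection on
the training split → PNN on the selected features → metrics/ROC on the
test split. Feature extraction necessarily precedes selection — the
wrapper's fitness needs a feature table to exist — even though the
high-level stage list puts selection first. Super-resolution enhancement
is opt-in (`enhance_factor`): the phantoms are generated at full
resolution, so there is nothing to upscale unless slices are explicitly
degraded first. The pipeline's CCSA budget (15 crows, 15 iterations) is
smaller than the selection module default; the 22-feature pool with
strong semantic features needs far less search than a blind run, and the
end-to-end phantom study (201 train / 99 test) classifies essentially
perfectly either way.

## Problem sizes used by the test suite

Exact identities run at toy sizes. The stochastic checks use: screening
calibration N=200–300, M=10–20, R=20 replicates, 10 seeds; CCSA recovery
N=200, M=12, 10 master seeds, plus an exhaustive-oracle comparison at
M=8; SCNN training on 64 patch pairs with 5 held-out phantoms; the full
pipeline at 201 training and 99 test slices. These sizes make the whole
suite run in a few minutes on one CPU while leaving each statistical
assertion comfortably powered.

## Known limitations

* 2-D only; every method is per-slice.
* The MIR objective is a diagnostic, not an optimizer.
* PNN bandwidth is a single scalar; no per-class or per-feature σ.
* The SCNN is a small CPU network; its experiments demonstrate a
  learning signal on phantoms, not state-of-the-art super-resolution.
* Semantic attributes are treated as annotation inputs; on real data
  they would carry radiologist noise that the phantoms do not model.
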