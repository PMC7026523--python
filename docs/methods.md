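# Methods

## The problem

Epithelial and mesenchymal cell morphologies mark the two ends of a
phenotypic axis that matters in cancer biology: epithelial-like cells are
rounded, tall and clustered; mesenchymal-like cells are elongated, flat,
large and solitary. `emscore` implements a transfer-learning recipe for
placing single cells on this axis using label-free quantitative phase
imaging (QPI): train a binary classifier on two *archetype* populations
(one epithelial, one mesenchymal), then apply it, without refitting, to
cells of unknown phenotype. The classifier's continuous decision value —
not its hard label — is the epithelial–mesenchymal (EM) score: negative
means epithelial-like, positive mesenchymal-like, and magnitude means
distance from the boundary between the two morphological archetypes.

Because no raw holograms are publicly available for this kind of study,
the package ships a synthetic-data generator that emulates the study
design end to end, with known per-cell ground truth. Every pipeline stage
is exercised against that ground truth.

## Hologram reconstruction (`emscore.holography`)

An off-axis hologram records `I = |1 + exp(i(φ_obj + φ_ab + 2π f·r))|²`,
where `f` is the carrier frequency of the tilted reference beam and
`φ_ab` collects residual tilt and quadratic (defocus) aberrations that a
telecentric microscope does not cancel optically. The chain is:

1. **Fresnel propagation** — transfer-function form,
   `H(ν) = exp(-iπλz|ν|²)` with orthonormal FFTs, so propagation is
   unitary (power-conserving) and `z = 0` is the identity. At microscope
   geometries the Fresnel approximation is comfortably valid.
2. **+1-order demodulation** — the spectrum is rolled so the carrier peak
   (auto-detected as the strongest non-DC peak, or given) sits at DC, then
   low-pass masked with radius equal to half the carrier offset.
3. **Phase unwrapping** — scikit-image's quality-guided 2-D unwrapper. Any
   congruent unwrapper is acceptable; the contract is output ≡ input
   modulo 2π pixelwise.
4. **Aberration compensation** — SVD of the unwrapped phase matrix;
   quadratic polynomials fitted to the two dominant singular-vector pairs;
   the synthesized surface projected onto the separable basis
   {1, r, c, r², c²}; the field multiplied by `exp(-iφ_fit)`. The
   coefficients are then *re-estimated on background pixels only*: the
   object is detected as the positive residual above 0.1 rad and dilated by
   8 px so the dome tails stay out of the fit, and a 12-px border ring is
   excluded — band-limiting the quadratic chirp during demodulation
   distorts the phase precisely where the x² leverage peaks, and removing
   the ring cuts the quadratic-coefficient error by an order of magnitude.
   Without these exclusions the fit is biased at the percent level; with
   them, noiseless coefficients are recovered to ≲0.1% relative error. The
   background median is subtracted so cell-free pixels sit at phase ≈ 0,
   and the (circular-convolution-corrupted) border ring of the output is
   reported at the background level. The demodulation pass band is
   apodized with a raised cosine over its outer 30% so cell edges do not
   ring into the reconstructed background.
5. **Phase to height** — `h = (φ·λ/2π)/Δn` with Δn = 1.381 − 1.337 =
   0.044, the assumed cell/medium refractive-index mismatch. 2π rad of
   phase at 632 nm is ≈ 14 363.6 nm of cell height.

Numerical conventions: carriers are in cycles/pixel on raw pixel indices;
aberration polynomials use integer pixel coordinates centered at
`(n//2, m//2)`; tilt is rad/px, quadratic terms rad/px². A carrier that is
not an integer FFT bin leaves a sub-bin residual that is indistinguishable
from tilt; round-trip validations therefore use integer-bin carriers.

## Synthetic cells (`emscore.simulate`)

The generator models four populations along a **mesenchymal blend
fraction** `blend_m ∈ [0, 1]`:

| line  | role                   | n   | blend                  |
|-------|------------------------|-----|------------------------|
| GIE   | epithelial archetype   | 332 | 0                      |
| HGF   | mesenchymal archetype  | 309 | 1                      |
| MCF7  | cancer-like, epithelial-skewed  | 307 | Beta(1.4, 4.4) |
| MDA   | cancer-like, mesenchymal-skewed | 347 | Beta(4.4, 1.4) |

(1295 cells in total.) Per-cell morphology is drawn from blend-interpolated
distributions: area and peak height are lognormal (log-medians interpolate
linearly in log space), eccentricity is Beta (interpolated in mean and
concentration), speckle granularity, clustering tendency and boundary
irregularity interpolate linearly. Archetype defaults encode the standard
contrasts: epithelial cells are smaller (median 140 vs 260 μm²), rounder
(mean eccentricity 0.37 vs 0.72), taller (median peak 4500 vs 2330 nm),
smoother-textured and more clustered than mesenchymal cells.

Shapes are superellipses (exponent 1.9–2.5) with Fourier boundary
perturbations restricted to harmonics 3–6 — harmonic 2 would change the
second moments and contaminate eccentricity — and total amplitude capped
at 0.22 so no shape develops a dumbbell waist that would genuinely read as
two touching cells. The phase profile is a smooth dome,
`φ = φ_peak (0.12 + 0.88(1−R²)^1.2)`, feathered to zero over ~6 px at the
boundary: the 12% pedestal models the fact that a cell is never optically
empty anywhere on its footprint (it is what makes the segmented footprint
equal the generated mask), and the feather is wider than the demodulation
band limit so the edge does not ring in reconstructed maps. Band-limited speckle (Gaussian-filtered
white noise at the profile's spatial frequency, 12% of peak, tapered by
the dome) supplies intracellular texture. Placement is rejection sampling
with a 2-px rim gap; "clustering" seeds a cell adjacent to an existing one
at that same gap, so aggregated cells touch visually but remain resolvable.
Fields are auto-sized for ~22% packing unless a size is given.

**Calibration.** Archetype separability is the one genuinely coupled
choice in the generator. Two study-level requirements pull on it: archetype
classification accuracy (cross-validated ≥95%, held-out ≥96%) and
transfer-score validity (Spearman ≥0.8 between the true blend fraction and
the transferred SVM score over the blended populations). With archetype
separation `d` (in pooled-SD units of the decision value) and blend-mixture
SD `σ_b`, the attainable blend–score correlation is approximately
`dσ_b/√(1+d²σ_b²)`; for any plausible skewed-Beta blend mixture
(σ_b ≤ ~0.35) a separation in the mid-90s accuracy range (d ≈ 3.5–4) caps
the correlation near 0.75. The defaults therefore set the overlap at
d ≈ 4.6 (about 1% Bayes error, cross-validated accuracy ≈ 99%), the
smallest separation at which both requirements hold with margin. The blend
Betas are wide enough that blend deciles remain distinguishable — a
spikier Beta piles near-tied blends into the extreme deciles, where
sampling noise breaks the monotonicity of decile mean scores. These
defaults are calibration constants of the synthetic study, not estimates
of any real cell line's parameters.

## Segmentation and features (`emscore.features`)

Height maps are thresholded automatically. The default policy is the
**triangle** rule, not Otsu: a QPI height map's histogram is a large
background spike at zero with a long foreground tail, and Otsu bisects the
dome interior, eroding the footprint to ~55% of the true mask, whereas the
triangle rule thresholds at the foot of the spike and retains ~98%. Otsu
remains available (`threshold="otsu"`), as do fixed numeric thresholds.

Touching cells are split by a watershed on the Euclidean distance
transform. Seeds are the connected components of
`{EDT ≥ 0.5 × component peak}`: a single cell's medial ridge stays above
half its peak thickness (the boundary-irregularity cap guarantees this for
generated shapes), so a bent or elongated cell contributes exactly one
seed, while two touching cells meet at a neck far below it and contribute
one seed each. This replaced h-maxima seeding, which fragments exactly
tied ridge maxima (common in discrete EDTs) into separate seeds regardless
of h. Components under 50 px or with peak height under 500 nm are dropped —
no adherent cell is thinner than that at its apex, while reconstruction
ripples stay well below it; cells touching the field border are kept but
flagged.

The 17-parameter phase signature per cell: area, perimeter, circularity
(4πA/P²), eccentricity, solidity, aspect ratio; mean/max/SD, skewness and
kurtosis of height; phase volume (Σ height × pixel area); Shannon entropy
(bits) of the 32-bin height histogram; and GLCM contrast, correlation,
energy and homogeneity. The GLCM quantizes interior heights to 32 levels
over the cell's own range, accumulates offsets (0,1), (1,0), (1,1), (1,−1)
symmetrically, strips background pairs, and normalizes; a constant
interior yields energy 1, contrast 0 and correlation 1 by convention.
When ground truth is available, each segmented cell inherits the blend
fraction of the generated cell contributing the majority of its pixels.

## Classifier and EM scores (`emscore.classify`)

Class coding is epithelial = −1 ("E"), mesenchymal = +1 ("M"). The 17
features are standardized (training mean/SD; a constant feature gets unit
scale with a warning) and projected onto principal components fitted on
training data only — the features carry incommensurate units (μm², nm,
bits, unitless), so standardization precedes PCA. Six components are the
default; `select_pc_count` reruns repeated stratified fivefold CV for each
candidate count with paired fold shuffles, applies a repeated-measures
ANOVA (explicit sums of squares), compares each count to the 1-component
control with a Dunnett-style many-to-one adjustment (equicorrelated
multivariate-t reference simulated by seeded Monte Carlo; a
sign-permutation fallback is provided), and picks the smallest
significantly better count beyond which no further significant paired gain
exists.

Four scores per cell:

* **SVM decision value** `s = (x/s_k)'β + b` from a soft-margin linear SVM
  (C = 1). The kernel scale s_k defaults to 1; it is a configuration value,
  not a fitted quantity. `s` is the EM score proper.
* **Platt posterior** `P(s) = 1/(1+exp(As+B))`, fitted by regularized
  maximum likelihood with Platt's target coding; A < 0 so higher scores
  mean higher mesenchymal probability.
* **AdaBoost score** `f(x) = Σ_t a_t h_t(x)` over depth-3 trees with
  `a_t = ½·log[(1−ε_t)/ε_t]` exactly; a 0.1 learning rate shrinks each
  learner's contribution to reweighting and to the score. A learner with
  ε_t = 0 is capped (warning); ε_t ≥ 0.5 stops training (logged).
* **Bagged-trees posterior**
  `P̂(c|x) = Σ_t a_t P̂_t(c|x)1[t∈S] / Σ_t a_t 1[t∈S]` over 200
  bootstrap-trained trees, uniform a_t, S = all learners by default. The
  nominal 0.1 "learning rate" is carried as configuration metadata only —
  it has no role in bagging.

Trees are stored as plain arrays (children/feature/threshold/leaf
posteriors) so the whole bundle — PCA, SVM, Platt, boost, bag — serializes
to a single JSON file and reloads without scikit-learn object state;
predictions after a save/load round trip are bit-identical.

Transfer scoring applies the training-fitted standardization and
projection (never refit) and assigns class by the SVM sign convention:
score > 0 ⇒ mesenchymal, ties ⇒ epithelial.

## Evaluation (`emscore.evaluate`)

ROC curves sweep score thresholds; the AUC equals the Mann–Whitney
statistic (pair-counting with half-credit ties), which the tests verify
exactly. Score outliers are excluded in a single pass — mean and SD
computed once on the full population, |score − mean| > 5.6 SD excluded —
and the rule applies to SVM scores only. Correlation reports give Pearson
and Spearman per score pair (undefined for constant columns, reported as
NaN). Representative cells are those nearest the min, Q1, median, Q3 and
max of a line's score distribution (quartiles by linear interpolation,
distance ties to the lower cell id). Model accuracy vectors are compared
with a two-tailed two-sample t-test (pooled variance by default, Welch
optional). Histograms use Freedman–Diaconis bins on the pooled score range
so all lines are binned identically.

## Pipeline (`emscore.pipeline`, `emscore.cli`)

`run_full` executes simulate → (reconstruct) → features → train → score →
report, writing a manifest with per-stage counts and SHA-256 checksums; a
stage re-runs unless its config hash and outputs are intact. The optics
stage is optional because the feature and classifier stages are
independent of it: the default route consumes the generator's phase maps
directly, and `use_holography: true` renders and reconstructs holograms
instead (on noiseless phantoms the two routes agree within reconstruction
tolerance). The `emscore` console script exposes each stage and `run-all`.
The numbered scripts under `analysis/` run the same stages as a narrative:
simulate, optics validation, features, training, transfer scoring.

## Problem sizes and determinism

Default study scale is the full 1295-cell, four-population design; fields
are ~2700–3300 px square at 0.18 μm pitch and generate in ~5 s per line.
Optics validations use 256² fields with four cells. All randomness flows
from named integer seeds through `numpy.random.default_rng`; generator
output, partitions, CV shuffles and ensembles are pure functions of
(config, seed).

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline is internally correct: the
optics inverse problem is solved to stated tolerance, features measure
what they claim, the classifier reproduces its textbook definitions
against independent oracles, and the transferred score ranks cells by the
generator's ground-truth blend. They do not show that real cancer cells
are scored correctly: the generator's populations are parametric stand-ins
whose separability is a calibration constant, real QPI data carry
aberrations beyond tilt+defocus, segmentation of confluent cultures is
harder than of synthetic fields with guaranteed gaps, and the 17
reconstructed parameters approximate, but need not match, any particular
instrument's feature set. Known limitations: no astigmatism or
higher-order Zernike compensation, no autofocus, no time-lapse tracking,
and no dry-mass calibration.
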