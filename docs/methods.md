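# Methods

## Scope and model

The package computes two irregularity measures of a grayscale image
`U = {u(i,j)}`, 1 ≤ i ≤ H, 1 ≤ j ≤ W, their multiscale extensions, and
classifier-based summaries of how well the resulting features separate
texture classes.  Pixels are real numbers in the native 8-bit range
[0, 255] (16-bit inputs are linearly mapped into it at load); both
measures are invariant under positive affine intensity transforms, so
the range convention carries no information.

### Bidimensional fuzzy entropy

For embedding dimension `m`, the `m×m` template of origin `(i, j)` is
`X^m_{i,j}`.  Origins range over `i ≤ H−m`, `j ≤ W−m` — the *same* set,
of size `N_m = (H−m)(W−m)`, for both the `m` and `m+1` template sizes.
Keeping the two origin sets identical is what makes the measure
provably non-negative: on an identical pair set the `(m+1)`-template
Chebyshev distance dominates the `m`-template distance, so
`Φ^{m+1} ≤ Φ^m`.  An alternative convention would give `m`-templates
their full `(H−m+1)(W−m+1)` origin grid; it changes values slightly and
loses the guarantee, so it is not used.

The distance between two templates is the Chebyshev
(maximum-absolute-component) distance `d`, and their graded similarity
is the fuzzy membership

    D = exp(−d^n / r),

with `n ≥ 1` the fuzzy power (gradient of the similarity boundary) and
`r > 0` the tolerance (boundary width).  `Φ^m` averages `D` over all
ordered origin pairs excluding self-pairs (inner normalizer `N_m − 1`,
outer `N_m`), and

    FuzzyEn2D(U, m, n, r) = ln(Φ^m / Φ^{m+1})  ≥ 0.

**Tolerance convention.**  Template distances are measured in units of
the image standard deviation σ (population divisor H·W): the image is
standardized before the kernel runs, and `r` is a dimensionless
fraction of σ.  This is equivalent to an effective tolerance
`r_eff = r·σ^n` in raw intensity units.  The convention is chosen
deliberately: the common alternative, `r_eff = r·σ` with the exponent
applied to the raw distance, is *not* invariant under intensity
rescaling for `n > 1` (a gain factor `a` leaves a residual `a^{n−1}`
inside the exponential), whereas entropy values that depend on whether
an image was stored as 8-bit, 16-bit, or normalized floats would be an
artifact, not a texture property.  Under the convention used here both
measures satisfy `E(a·u + b) = E(u)` for `a > 0` to double precision,
and the listed `r` grid {0.12, 0.24, 0.36, 0.48} has the same meaning
for any input range.  σ is recomputed on each coarse-grained image, not
inherited from scale 1, so every scale is standardized on its own
terms.

No template-mean subtraction is applied inside the distance (some fuzzy
entropy variants subtract the window mean; this implementation does
not).  A constant image (σ = 0) is completely regular: both measures
return exactly 0 with a `degenerate` flag rather than attempting the
0/0 standardization.

### Bidimensional dispersion entropy

Pixels are mapped to `y ∈ (0, 1)` by the normal CDF of the image's own
mean and SD — a sigmoid that keeps outliers from collapsing the
interior classes — then to integer classes

    z = round(c·y + 0.5),  clamped to [1, c],

with rounding half away from zero (the MATLAB `round` convention; the
clamp also resolves the y → 0 boundary).  `c` must lie in 3..9.  Every
`m×m` window of the class map, flattened row-major, is a dispersion
pattern π out of `c^(m²)` possibilities; windows run over all
`(h−m+1)(w−m+1)` origins.  The measure is the Shannon entropy of the
empirical pattern frequencies, with unobserved patterns contributing
nothing (0·ln 0 := 0):

    DispEn2D(U, m, c) = −Σ_π p(π) ln p(π)  ∈ [0, m²·ln c].

The value is reported unnormalized; a variant divided by `m²·ln c` is
available behind a flag.  Pattern flattening order is irrelevant to the
entropy (any fixed bijection permutes labels only); row-major is used
for serialized pattern identities.

### Coarse-graining and multiscale profiles

The scale-τ image replaces each non-overlapping τ×τ block by its
arithmetic mean; the output is ⌊H/τ⌋ × ⌊W/τ⌋ and trailing rows/columns
that do not fill a block are dropped.  Each scale is computed from the
original image, not recursively from the previous scale (the two differ
only when τ does not divide the dimensions).  A multiscale profile
evaluates the chosen measure at τ = 1..τ_max; the feature vector "depth
τ" is the profile prefix `values[1..τ]`.

Interpretation: entropy that decays across scales marks an image as
irregular but not structurally complex; entropy sustained across scales
marks complexity.  Two verified signatures on synthetic data:

* White-noise profiles decrease strictly with τ, but through two
  different mechanisms, one per measure.  For the fuzzy measure the
  decrease is distribution-shape driven: block means of *uniform* noise
  approach a Gaussian, whose standardized form has lower fuzzy entropy
  (128×128, 10-seed mean: 2.871 → 2.725 over τ = 1..5); iid *Gaussian*
  noise is shape-stable under averaging and its fuzzy profile is flat.
  For the dispersion measure the decrease is sampling driven: Gaussian
  noise keeps exactly equal class occupancies at every scale while the
  shrinking window count increasingly under-samples the `c^(m²)`
  patterns (4.392 → 4.333); *uniform* noise instead first **rises**
  (4.322 → 4.382 at τ = 2) because averaging equalizes the NCDF class
  occupancies, which at τ = 1 are uneven (≈ 0.376/0.249/0.376 at
  c = 3).  The validation suite therefore checks the fuzzy signature on
  uniform noise and the dispersion signature on Gaussian noise.
* Strictly periodic patterns do **not** have flat profiles when the
  block size resonates with their period: coarse-graining a period-4
  checkerboard reduces it exactly at τ = 2 and τ = 4 (at τ = 4 to the
  single-pixel checkerboard, where FuzzyEn2D is legitimately 0 because
  similarity statistics are identical at both template sizes) and
  aliases it into higher-entropy quasi-periodic mixtures at τ = 3 and
  τ = 5.  Its profile range consequently *exceeds* the gentle
  white-noise decline by an order of magnitude.  Flat-profile
  reasoning applies to textures with structure at many scales, not to
  single-period patterns; the corresponding check in the validation
  suite documents this as an expected failure of the naive claim.

### Classification harness

Features are multiscale profile prefixes.  The split is stratified
75/25 with a fixed seed, implemented on a canonical row ordering
(label, then feature values) so the partition does not depend on
accidental row order; total train size is ⌊0.75·n⌋ with per-class
largest-remainder allocation (825+551 rows → 1032/344; 41+41 → 61/21).
Classifier hyperparameters are frozen: `GaussianNB(priors=None,
var_smoothing=1e-9)`, `DecisionTreeClassifier(random_state=0)`, `SVC()`
with library defaults (RBF kernel), `MLPClassifier(random_state=1,
max_iter=10000)`, `KNeighborsClassifier` with k swept 1..9.  Features
are passed unstandardized by default (a standardization flag exists).
k-NN is one classifier family with two reductions: its *average*
accuracy is the mean over k, its *max* accuracy the best k.

Summary metrics over a sweep:

* **average accuracy** — mean of all (cell, family) accuracies × 100;
* **average max accuracy** — mean over the five families of each
  family's single best accuracy anywhere in the sweep (≥ average
  accuracy by construction);
* **parameter optimality map** — per parameter, each family votes for
  the value with the highest marginal average accuracy (marginalized
  over the other parameters, scales and class pairs); ties go to the
  smallest value, so votes always sum to 5;
* **best scale table** — per family, the τ prefix with the highest
  average accuracy, smallest τ on ties; τ > 1 reads as "complexity
  beats single-scale irregularity";
* **pairwise texture matrix** — per unordered class pair, the
  algorithm with the higher sweep-average accuracy and the band
  high (85, 100] / mid [70, 85] / low [0, 70) (closed at both stated
  boundaries, which the banding prose leaves ambiguous).

## Synthetic data

The texture generator emulates class-structured texture datasets with
four kinds: period-p checkerboards (two intensities, alternating p×p
blocks), horizontal sinusoidal gratings `127.5·(1 + sin 2πj/p)` with
optional additive Gaussian noise (clipped to [0, 255]), white noise
(iid uniform(0, 255), or Gaussian around 127.5 when a noise SD is
given), and box-smoothed noise.  Every image is a pure function of its
spec; dataset image i uses seed `master + i`.  The default benchmark —
40 images per class of 64×64 gratings with periods 4 vs 16 and noise
SD 20 — is deliberately an easy, well-separated two-class problem: it
validates the pipeline end to end (all five families reach ≥ 90% with
τ = 5 fuzzy features while permuted labels stay within 3 binomial SDs
of chance), but passing it says nothing about performance on natural
or histological textures, which carry illumination, pose and staining
variation the generator does not model.

## Numerical choices and problem sizes

* Pairwise fuzzy kernels run in row blocks (2048 origins) over the
  symmetric distance matrix's upper triangle; masked pairs are set to
  +inf so their similarity underflows to exactly 0.  Parameter grids
  sharing an embedding dimension reuse one distance computation, and
  `d^n` is reused across tolerances with the same `n`.  Results match
  a naive quadruple-loop transcription to 1e-10 on 12×12 images.
* Dispersion patterns are encoded as base-c integers and counted with
  a vectorized unique; counts match a dictionary tally exactly.
* Validation problem sizes are chosen for minutes-scale runs on one
  CPU: oracle equivalence at 12×12 / 20×20, bound saturation at
  256×256 (within 2% of 4·ln 3), profile signatures at 128×128 × 10
  seeds, grid-wide ordering checks at 64×64 × 5 seeds, and the
  classification benchmark at 80 × 64×64 images with scales τ = 1..5.
  The sweep machinery itself accepts τ up to any depth for which the
  coarse-grained image still satisfies the entropy preconditions.
* Center-crop offsets use ⌊(dim − size)/2⌋ (extra pixel to the
  bottom/right).  Grayscale conversion uses the fixed 4-decimal BT.601
  luma weights (0.2989, 0.5870, 0.1140), which sum to 0.9999, matching
  the MATLAB convention rather than an exactly-normalized variant.

## Known limitations

* FuzzyEn2D cost grows with the square of the origin count; 128×128 is
  comfortable (seconds), 512×512 is not.  DispEn2D is near-linear and
  fast at any tested size, but for large `m` and `c` the pattern space
  `c^(m²)` dwarfs the number of windows and the entropy saturates at
  `ln(window count)` — values there measure sample size, not texture.
* The NCDF class map assumes unimodal, roughly symmetric intensity
  distributions; strongly bimodal images put most mass in the end
  classes.
* Dispersion entropy is exactly tie-sensitive at class boundaries:
  images engineered to place pixels on boundary values can flip classes
  under 1-ulp changes in the CDF evaluation.
* The harness evaluates one fixed split; it reports no variance across
  splits or seeds, and deliberately omits ensembling, cross-validation
  and hyperparameter tuning.
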