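# entropy2d

Bidimensional fuzzy entropy (FuzzyEn2D), bidimensional dispersion
entropy (DispEn2D), their multiscale extensions, and a classifier-based
parameter-sweep harness for grayscale texture analysis.

Entropy measures quantify how unpredictable the pixel patterns of an
image are: repeating periodic structure scores low, non-repeating
structure scores high.  Because pattern repeatability is exactly what
texture is, these measures work as compact texture features — for
example for telling epithelium from stroma in histology images, or one
material from another in texture benchmarks.  This package is for
researchers who want those features, their multiscale (complexity)
profiles, and a systematic way to ask *which parameter values of the
entropy measures produce the most discriminative features* for a given
image collection.

## The measures

**FuzzyEn2D(U, m, n, r)** is the negative log conditional probability
that pixel templates similar at size `m×m` remain similar at size
`(m+1)×(m+1)`:

```
Φ^m  = mean over template pairs of exp(−d^n / r),   d = Chebyshev distance
FuzzyEn2D = ln(Φ^m / Φ^{m+1})
```

Template origins run over `i ≤ H−m, j ≤ W−m` for *both* template sizes,
which keeps the origin sets identical and the entropy non-negative.
Distances are measured in units of the image standard deviation, so the
tolerance `r` is dimensionless and the measure is invariant under
positive affine intensity changes.

**DispEn2D(U, m, c)** maps pixels through the normal CDF of the image's
own mean and SD into `c` classes, `z = round(c·y + 0.5)`, reads every
`m×m` window of the class map as a *dispersion pattern*
π ∈ {1..c}^(m²), and returns the Shannon entropy of the empirical
pattern frequencies, `−Σ p(π) ln p(π)` ∈ [0, m²·ln c].

**Multiscale extensions** coarse-grain the image by non-overlapping
τ×τ block averaging (τ = 1, 2, …) and evaluate the measure at each
scale.  A falling profile means irregular-but-not-complex (white
noise); sustained values across scales indicate structural complexity.
Gathering the values from scale 1 to τ yields a τ-dimensional feature
vector per image.

**The sweep harness** evaluates those feature vectors over the full
parameter grids (fuzzy: m ∈ {1,2}, n ∈ {2..5}, r ∈ {0.12..0.48};
dispersion: m ∈ {2,3}, c ∈ {3..6}) with five classifier families
(Gaussian naive Bayes, decision tree, SVM, MLP, k-NN with k = 1..9) on
a stratified 75/25 split, and reports average accuracy, average max
accuracy, per-parameter optimality votes, best scale depth per
classifier, and banded pairwise texture matrices.

## Worked example

```python
from entropy2d import (DispParams, FuzzyParams, TextureSpec,
                       disp_en2d, fuzzy_en2d, make_texture)

fuzzy_p, disp_p = FuzzyParams(m=1, n=2, r=0.36), DispParams(m=2, c=3)
for name in ("checkerboard", "white_noise"):
    img = make_texture(TextureSpec(name, 64, period=4, seed=1))
    print(name, fuzzy_en2d(img, fuzzy_p).value, disp_en2d(img, disp_p).value)
```

prints

```
checkerboard 0.9021 1.7909
white_noise  2.8759 4.3222
```

The checkerboard's repeating 4×4 blocks make template similarity highly
predictable (low entropy in both measures); white noise approaches the
dispersion-entropy ceiling `4·ln 3 ≈ 4.3944` nats.  The narrative
scripts in `examples/` extend this to multiscale profiles and a full
parameter sweep; `examples/03_parameter_sweep.py` separates two noisy
gratings (periods 4 vs 16) with an average accuracy of 98.33% and an
average max accuracy of 100% across all five classifier families, every
family preferring multiscale (τ = 2) features over single-scale ones.

## Command line

```bash
entropy2d entropy image.png -a fuzzy -m 1 -n 2 -r 0.36 --tau-max 5
entropy2d synth config.yaml dataset/      # write a synthetic PNG tree
entropy2d sweep config.yaml               # run a full sweep from YAML
entropy2d report out/sweep.csv report/    # render color-map summaries
```

A single YAML config drives a sweep; see `tests/test_cli.py` for a
minimal one.

## Layout

- `src/entropy2d/entropy.py` — single-scale FuzzyEn2D / DispEn2D kernels
- `src/entropy2d/multiscale.py` — coarse-graining and scale profiles
- `src/entropy2d/textures.py` — seeded synthetic texture datasets
- `src/entropy2d/images.py` — loading, grayscale, crop, dataset manifests
- `src/entropy2d/classify.py` — sweep harness and summary metrics
- `src/entropy2d/cli.py`, `config.py` — thin command-line front end
- `docs/methods.md` — models, conventions, numerical choices, limits
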