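# Methods

This note records the models implemented in `mnf3d`, the defaults that
matter, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Nakagami envelope model

The RF-envelope amplitude in a small neighborhood is modeled as
Nakagami(μ, ω): μ > 0 dimensionless (scatterer concentration; μ = 1 is
fully developed Rayleigh speckle), ω > 0 in squared-amplitude units
(ω = E[x²], local backscattered energy). Two estimators are provided:

- **Moments** (closed form): ω̂ = mean(x²),
  μ̂ = mean(x²)² / Var(x²). Used stand-alone and as the MLE initializer.
- **MLE**: because x² ~ Gamma(μ, ω/μ), the fit reduces to the Gamma
  shape MLE on y = x²: solve log μ − ψ(μ) = log(mean y) − mean(log y)
  by Newton iteration with the digamma/trigamma functions
  (relative tolerance 1e−8, max 100 iterations, iterates floored at
  1e−3 of the previous value to stay positive; a Minka-style
  closed-form start replaces invalid moment initializers). ω̂ = mean y
  exactly. Samples equal to zero carry no log-likelihood information
  and are dropped before fitting.

Degenerate inputs are errors, not guesses: fewer than `min_samples`
(default 8) usable samples, or constant squared samples.

### Parametric volumes

`fit_parametric_volume` evaluates one lattice per voxel
(mode="sliding", default; estimates at the lattice center) or tiles the
volume (mode="block"). All window sums (count, Σy, Σlog y, Σy²) are
computed with box filters, so the sliding MLE is fully vectorized: one
Newton iteration array over all valid voxels. Voxels outside the ROI are
excluded from every sum; cells with fewer than `min_samples` in-ROI
voxels are invalid rather than extrapolated. The default lattice edge of
7 voxels balances sample support (343 voxels) against spatial
resolution.

### Lattice-size selection

The goodness-of-fit score for a candidate lattice size tiles the volume,
fits each lattice by MLE, and measures the quantile-matching RMSE
between the sorted observed amplitudes and the fitted Nakagami quantiles
at plotting positions (i − 0.5)/n — **standardized by √n**. The raw
quantile RMSE shrinks as n^(−1/2) under a correct model, which would
always favor the largest lattice regardless of tissue structure; after
standardization the statistic converges to a size-independent constant
under a correct fit, while lattices that mix distinct tissue regions add
an O(1) quantile mismatch that grows with lattice size. This makes the
curve flat (within sampling noise) on homogeneous volumes and penalizes
lattices larger than the tissue's heterogeneity scale, which is the
behavior the selection rule needs. The reported optimum is the size with
the smallest mean per-lattice score.

### Scattering regimes

μ: pre-Rician (0 < μ < 0.5), generalized Rician (μ = 0.5), pre-Rayleigh
(0.5 < μ < 1), Rayleigh (μ = 1), post-Rayleigh (μ > 1); the two
measure-zero categories use a ±1e−6 tolerance band. ω: low (< 3),
mid (3 ≤ ω < 7), high (≥ 7); the boundary value 7 is assigned to "high"
(the printed ranges leave ω = 7 unassigned; the closed upper boundary
mirrors the closed lower one at 3).

## Octant wavelet packets

The transform is a separable, **undecimated** (à-trous) filter bank: at
level ℓ the analysis filters are upsampled by 2^(ℓ−1) and applied along
each axis in all 8 low/high combinations, so every sub-band keeps the
input shape — the overcompleteness preserves voxel correspondence, which
the voxel-wise fractal estimation requires. Decimated packets were
rejected for that reason. Boundaries are whole-sample symmetric (mirror)
extensions, applied per axis; the same convention is used everywhere in
the package (wavelets, shell profiles) and in the brute-force test
oracles.

Filters: the orthogonal 8-tap Daubechies pair with 4 vanishing moments,
L²-normalized (Σh0 = √2, Σh0² = 1); the highpass is built from the
quadrature-mirror rule h1[k] = (−1)^k h0[N−1−k]. Normalization matters
because the undecimated lowpass has DC gain √2 per axis (a constant c
maps to c·2^(3/2) in LLL). Filter alignment is centered
(output[n] = Σ_k h[k]·x̃(n + k − span//2)).

`max_levels` (default 3) is clipped with a warning so the effective
filter span 8·2^(ℓ−1) never exceeds the smallest axis. Expansion
policies: "full" (every node) or "selective" (per level, only the node
whose caller-supplied signature — in the pipeline, the ROI-mean fractal
dimension — is maximal), following the principle of growing the basis
along fractal significance rather than energy.

## Fractal maps

Under the fBm model E|v(x+r) − v(x)| = K·r^H. The voxel-wise estimator
uses Chebyshev (max-norm) cubic shells of radius d = 1…j (default
j = 4): Δv(d) is the mean absolute difference between the center voxel
and all (2d+1)³ − (2d−1)³ shell voxels, and H is the OLS slope of
log Δv on log d. The Chebyshev reading of the multi-scale neighborhood
is isolated behind `scale_profile`/`shell_offsets` so a
Euclidean-distance-binned variant can be swapped in. Normalization
constants shift only the intercept (log K), never the slope, so plain
logarithms are used.

Numerical rules:

- scales with Δv = 0 are dropped; if fewer than 2 scales remain the
  voxel is a flat neighborhood and gets H = 1, I = 2 (smoothest);
- H is clamped to [0, 1] so I = 3 − H stays in the surface-dimension
  range [2, 3] for 3D data; the raw slope is kept in `hurst_raw` for
  diagnostics;
- computation is vectorized over the ROI bounding box; neighbors beyond
  the physical volume come from mirror extension (identical to the
  whole-volume computation, which the oracle tests check).

Because the OLS slope is invariant to scaling of Δv and shifts of v,
fractal maps — and hence the whole descriptor — are exactly invariant
under affine intensity changes v → a·v + b (a > 0), which is what makes
the features robust to local speckle attenuation.

## MNF descriptor

For each parametric map (μ block first, then ω): level-1 octant bands
are computed, each reduced to its ROI-mean fractal dimension f (8
features); deeper levels re-decompose the band with the highest f. After
each new level i ≥ 2 the difference statistic
D_i = max over maps of max_j |f_{i,j} − f_{i,j+1}| (adjacent bands in
LLL…HHH order) is compared with D_{i−1}; decomposition terminates when
D_i ≤ D_{i−1}, keeping level i. The per-pair termination condition is
aggregated by the maximum — the strictest reading — and applied
**jointly** over the two maps so the concatenated descriptor has one
common depth (the per-map variant would give ragged blocks). If the rule
never fires before `max_levels` the descriptor is returned at
`max_levels` with `terminated=False` and a warning. Fractal maps are
computed on wavelet sub-bands only, not on the raw parametric map.

Invalid voxels of a parametric map (outside the ROI or unfittable) are
filled with the ROI-mean before the transform so border wavelet
coefficients see tissue-scale values rather than zeros; the fractal
features are then averaged over the ROI only.

## Synthetic data

The generators define the conditions under which the package is tested;
they are first-class, tested code.

- **Nakagami sampling** uses the exact Gamma transform
  x = √g, g ~ Gamma(μ, ω/μ) — no rejection sampling.
- **Phantoms**: spherical inclusions in homogeneous background speckle;
  every voxel is drawn from its region's Nakagami law. Inclusions may
  carry a log-normal fBm modulation of ω
  (ω(x) = ω·exp(σ·z(x)), z standardized fBm with chosen H), emulating
  rough vs smooth intra-lesion echogenicity. Overlapping inclusions are
  rejected (ambiguous labels).
- **fBm volumes**: spectral synthesis with isotropic power spectrum
  |f|^−(2H+3) (the f^−(2H+d) convention for a d = 3 field with
  increment exponent H), DC bin zeroed. Plain single-grid synthesis has
  two known discretization biases at the unit-voxel lags the fractal
  estimator uses: Nyquist truncation smooths lag-1 increments (inflating
  low-H slopes) and the stationary approximation on a finite domain
  saturates increments at lags comparable to the domain (deflating
  high-H slopes). The generator therefore synthesizes 2× finer and on a
  2× larger domain, then subsamples and crops. Measured against the
  pooled increment oracle (global log–log fit of mean |Δv| vs d over the
  whole volume, lags 1–4), recovered H is within ~0.1 of the requested
  value across H ∈ {0.2, 0.5, 0.8} and strictly monotone; the residual
  bias still shrinks estimates toward 0.5, which passing tests should be
  read against. A small part of that bias (−0.01 … −0.05, growing with
  H) is the Chebyshev shell convention itself (shell voxels sit at
  Euclidean distances d…d√3 while the regression uses d).
- **Cohorts**: two phantom templates, per-volume seeded jitter of
  inclusion centers (±2 voxels) and radii (±10%), lesion mask = union of
  inclusion balls dilated by 2 voxels. The default templates (48³ grid,
  radius-14 inclusion; class 0: μ = 0.7, ω = 2.0, smooth ω texture
  H = 0.8; class 1: μ = 1.3, ω = 4.0, rough ω texture H = 0.25; both σ
  = 0.6 over background (1.0, 1.0)) are deliberately well separated in
  both backscatter contrast and texture roughness: they emulate
  a necrotic-core lesion vs a uniformly aggressive one. They do **not**
  emulate point-spread-function blur, attenuation with depth, log
  compression, or scan-conversion geometry, so classification accuracy
  on these cohorts demonstrates pipeline correctness and feature
  expressiveness, not clinical performance.

All generators are pure functions of (specification, integer seed).

## Pipeline and evaluation

Per volume: slices whose ROI area strictly exceeds the median area are
kept (all kept, with a warning, if the rule would keep none); the
volume is cropped to the ROI bounding box plus a 6-voxel margin to bound
transform cost; the parametric fit and descriptor follow. The classifier
is Gaussian naïve Bayes (frequency priors by default, equal-prior
switch; zero-variance features are variance-floored with a warning).
Cross-validation: leave-one-out, or seeded stratified k-fold repeated 60
times by default with mean ± SD over repeats. Metrics are computed from
pooled confusion counts per scheme — recall, FP rate = FP/(FP+TN),
accuracy, precision, F-measure (harmonic mean), Jaccard
J = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN), and rank-based ROC area on
pooled posterior scores. The positive-class values are reported
alongside per-class and macro averages, since Jaccard/Dice/F are not
class-symmetric.

## Problem sizes

Defaults used by the test suite and the acceptance script: estimator
studies at n = 343 (= 7³, one default lattice) with 50 replicates; fBm
calibration on 64³ volumes; cohort runs with 10 volumes per class at
48³. These sizes were chosen so that a full run of the suite and the
acceptance script completes in minutes on a single CPU while keeping
every statistical check comfortably powered.

## Known limitations

- The Nakagami MLE assumes within-lattice homogeneity; mixtures at
  region boundaries bias both parameters (the lattice-size sweep makes
  this visible but does not remove it).
- The fBm generator is an approximate (stationary, spectral) synthesis;
  exact circulant-embedding synthesis was not implemented.
- The Hurst estimator's four-scale regression trades variance for
  locality; its residual bias toward 0.5 is characterized above.
- The paper-style evaluation metrics are computed from standard
  definitions; no attempt is made to mimic non-standard variants.
- No PSF convolution, attenuation modeling, log compression or fan-beam
  scan conversion: acquired-data performance is out of scope.
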