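# mnf3d — multifractal Nakagami features for 3D ultrasound

`mnf3d` quantifies the texture heterogeneity of tissue in 3D ultrasound
RF-envelope volumes, for researchers in quantitative ultrasound tissue
characterization (e.g. monitoring liver-tumor response to chemotherapy).
Subtle low-activity (necrotic) regions inside a tumor change the local
speckle statistics long before they are visible in B-mode images; this
package turns those statistics into a compact feature vector suitable for
classifying progressive vs non-progressive disease.

## Method

The toolchain has four stages:

1. **Nakagami parametric volumes.** The envelope amplitude x in a small
   cubic voxel lattice is modeled by the Nakagami law
   N(x | μ, ω) = 2 (μ/ω)^μ x^(2μ−1) e^(−μx²/ω) / Γ(μ),
   where μ (shape) tracks the local scatterer concentration — from
   pre-Rician (μ < 0.5) through Rayleigh (μ = 1, fully developed speckle)
   to post-Rayleigh (μ > 1) — and ω = E[x²] (scale) is the local
   backscattered energy. Since x² is Gamma(μ, ω/μ), the maximum-likelihood
   fit reduces to the Gamma shape MLE on squared samples (digamma Newton
   iteration); sliding the lattice voxel-by-voxel yields μ- and ω-maps.
   Out-of-ROI voxels never enter a fit, and the lattice edge length can be
   chosen by a goodness-of-fit sweep (default 7 voxels).
2. **Octant wavelet packets.** Each parametric map is decomposed with an
   undecimated (à-trous) separable 8-tap Daubechies transform along the
   three axes, giving eight same-shape sub-bands (LLL … HHH) per node;
   packet recursion expands the band with the strongest *fractal*
   signature rather than the most energy.
3. **Fractal maps.** Under a fractional-Brownian-motion model,
   E|v(x+r) − v(x)| = K·r^H. At every voxel, the mean absolute difference
   to the Chebyshev shell of radius d = 1…4 is regressed on log d; the
   slope estimates the Hurst exponent H and the local fractal dimension is
   I = 3 − H ∈ [2, 3] (rougher texture → higher I).
4. **MNF descriptor and classification.** Each sub-band contributes its
   ROI-mean fractal dimension f. Levels are added until the between-band
   feature contrast of a new level stops growing (differential-threshold
   termination), giving 8 features per level per parametric map,
   concatenated as Λ. A Gaussian naïve-Bayes classifier is evaluated with
   leave-one-out or repeated stratified k-fold cross-validation (recall,
   FP rate, accuracy, precision, F-measure, Jaccard, Dice, ROC area).

A `synthetic` module generates every input needed to exercise the
pipeline: Nakagami speckle phantoms with spherical inclusions at
controlled (μ, ω) contrast, fBm volumes with known H, and labeled
two-class cohorts.

## Worked example

```python
import numpy as np
from mnf3d import (sample_nakagami, estimate_mle, classify_scattering,
                   PhantomSpec, Inclusion, make_phantom,
                   fit_parametric_volume, LatticeConfig,
                   mnf_descriptor, MNFConfig)

# fit one voxel lattice worth of speckle
x = sample_nakagami(mu=0.8, omega=2.0, n=343, seed=0)
params = estimate_mle(x)
print(params)                      # NakagamiParams(mu=0.8752..., omega=2.0461...)
print(classify_scattering(params)) # ('pre-Rayleigh', 'low')

# a lesion phantom with 4x backscatter-energy contrast
spec = PhantomSpec(grid_size=(32, 32, 32), background_params=(1.0, 1.0),
                   inclusions=(Inclusion((16, 16, 16), 10, mu=1.0, omega=4.0),),
                   seed=0)
vol, labels = make_phantom(spec)
pv = fit_parametric_volume(vol.data, config=LatticeConfig(lattice_size=7))

desc = mnf_descriptor(pv, config=MNFConfig(scales=4, max_levels=3))
print(desc.levels_used, desc.terminated)   # 2 True
print(np.round(desc.threshold_trace, 4))   # [0.5697 0.0376]
print(desc.features.size)                  # 32
```

The descriptor stopped after two decomposition levels (the level-2
between-band contrast 0.038 no longer exceeds the level-1 contrast
0.570), so Λ holds 2 maps × 8 bands × 2 levels = 32 mean fractal
dimensions, each in [2, 3].

The same stages are scriptable from the shell:

```sh
mnf3d simulate --kind cohort --grid 48 --n-per-class 10 --seed 1 --out data/
mnf3d features data/manifest.csv --out features.csv
mnf3d classify features.csv --scheme loo --out metrics.json
```

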