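# plumespect

Spectral Fisher information about odour-source separation, extracted from the
correlations of multisource plume concentration timeseries.

## The problem

Two odour sources released into a chaotic flow produce concentration
timeseries whose Pearson correlation, measured downwind, decreases as the
sources move apart — so correlations carry spatial information. Animals can
resolve odour fluctuations at surprisingly high frequencies (tens of Hz in
mice, >100 Hz in insects), which raises the question this package is built to
answer quantitatively: *which frequency bands of the correlation carry the
most information about how far apart two sources are?*

`plumespect` is for researchers in computational neuroethology, olfactory
navigation and environmental fluid dynamics who have (or simulate)
multisource concentration timeseries and want a band-by-band information
budget.

## The method

Over a window of length *T*, the Pearson correlation of two z-scored signals
decomposes over harmonics of the fundamental 1/*T*:

    r = Σₙ rₙ,   rₙ = ½(aₙcₙ + bₙdₙ),

with (aₙ, bₙ), (cₙ, dₙ) the cosine/sine coefficients of the two windowed,
z-scored segments. Modelling the coefficients as zero-mean bivariate
Gaussians with in-phase correlation ρₙ(s) at source separation *s*, the
component rₙ follows an asymmetric Laplacian (a two-sided exponential with
branch scales σₙ²(1 ± ρₙ)/2), and the Fisher information rₙ carries about
*s* is

    I(rₙ, s) = 2 ρₙ′(s)² / (1 − ρₙ(s)²).

Fitting the empirical decay ρₙ(s) = (1 − bₙ)e^(−s/γₙ) + bₙ per harmonic
gives a closed form for I on a frequency × separation grid; a Huber
regression of log₁₀ I on frequency per separation (the "elbow" profile)
summarises whether high or low frequencies are more informative, with
uncertainty from bootstrap resampling of time windows. Observed correlation
components can additionally be fitted with intermittent (Bernoulli mixture
with Gaussian noise) exponential / Gamma / generalized-inverse-Gaussian
sandwich distributions by EM, ranked by nested cross-validation.

A built-in surrogate generator draws multisource signals from per-harmonic
covariance kernels k(i, j, n) = G(|i−j|, n) S(n) with a plume-like 1/f⁴
power spectrum, providing ground-truth datasets in which the spatial
information content is known by construction.

## Worked example

Analyse a surrogate dataset in which correlations of harmonics in the upper
half of the band decay six times faster with separation than the lower half
(decay lengths 12 and 2 source spacings; sources 0.3 pitch apart):

```python
import numpy as np
from plumespect import PlumeCorrelationModel
from plumespect.surrogate import SurrogateSpec, build_kernel, sample_signals

spec = SurrogateSpec(kernel="high_gt_low", n_realizations=2000)
sample = sample_signals(build_kernel(spec), seed=0)
positions = np.column_stack([np.zeros(16), np.arange(16) * 0.3])
model = PlumeCorrelationModel(coeffs=sample.as_trig_coefficients(),
                              positions=positions, units="pitch")
res = model.fit(n_boot=50, seed=0)
print(res.summary())
```

prints (abridged):

```
harmonic  freq_Hz     gamma         b   near_flat
       1        1     3.583  9.088e-18       False
       ...
       9        9     3.721  2.406e-19       False
      10       10    0.5939  3.52e-11       False
       ...
      20       20    0.5987   3.9e-13       False

elbow slopes (log10 I per Hz) over 1-15 Hz:
  s =     0.3: beta = +0.0552   [+0.0545, +0.0556]
  s =     0.6: beta = +0.0327   [+0.0317, +0.0331]
  s =     0.9: beta = +0.0072   [+0.0055, +0.0080]
  s =     1.2: beta = -0.0202   [-0.0221, -0.0190]
  ...
  s =     4.5: beta = -0.3795   [-0.3891, -0.3739]
```

The fitted decay lengths recover the generating kernel: ~3.6 pitch
(= 12 × 0.3) for low harmonics, ~0.6 pitch (= 2 × 0.3) for high ones. The
elbow slopes (with 5–95% bootstrap bands) are positive at small separations
— high frequencies are more informative when sources are close — and turn
negative beyond ~1 pitch, where only the slowly decaying low frequencies
still change with distance.

`res.plot_heatmap()` and `res.plot_elbow()` render the information grid and
the elbow profile; `res.stats`, `res.decay`, `res.fisher_table()` and
`res.elbow_table()` expose the tidy tables.

The same analysis runs from the shell on HDF5/CSV timeseries:

```sh
psi fixture --kind ar1-pair --out data.h5
psi run --input data.h5 --out results/ --seed 0
```

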