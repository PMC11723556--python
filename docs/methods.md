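# Methods

## Spectral decomposition of windowed correlations

Each source's concentration timeseries is cut into half-overlapping segments
of a fixed length (1 s by default). A segment is multiplied by the window
weights (boxcar, Hann, or Kaiser with β = 16), then z-scored with the
population (1/L) standard deviation, and its DFT X[k] = uₖ + jvₖ
(normalised by L) is converted to trigonometric coefficients aₖ = 2uₖ
(aₖ = uₖ at DC and, for even L, at Nyquist) and bₖ = −2vₖ. The component of
the Pearson correlation contributed by harmonic n of two segments is
rₙ = wₙ(aₙcₙ + bₙdₙ) with wₙ = ½, except wₙ = 1 at the Nyquist harmonic of
an even-length segment. These two conventions — population z-scoring and
the Nyquist weight — make the decomposition identity exact: with a boxcar
window, Σₙ rₙ equals the plain Pearson correlation of the raw segments to
machine precision, for both segment parities; with a tapered window it
equals the Pearson correlation of the windowed, z-scored segments. Segments
with zero variance after windowing have undefined correlation; they are
flagged and excluded from every downstream pool rather than zero-filled.
Trailing samples that do not fill a window are dropped (no padding).

## Coefficient statistics at each separation

Separations are signed coordinate differences along the source axis
(optionally folded to |s| for symmetric layouts, which the pipeline does by
default) and binned with a 10⁻⁹ m tolerance, appropriate for exact
simulation grids and configurable for irregular ones. For harmonic n and
separation s, coefficients from all ordered source pairs at s and all
windows are pooled into a 2 × N(s) matrix (cosine and sine blocks
concatenated; N(s) = 2 × windows × pairs; separation 0 holds self-pairs).
All second moments are uncentred: non-DC coefficients are zero-mean under
temporal stationarity, and uncentred moments make the two estimators of the
in-phase correlation — the principal-variance route (λ − μ)/(2σₙ²) from
projections onto [1, ±1]/√2, and the product route ⟨ac + bd⟩/(2σₙ²) —
agree exactly rather than only asymptotically. The pooled marginal variance
is σₙ² = λₙ(0)/2, independent of separation under location independence.
The out-of-phase (quadrature) correlation is ρₙ⊥ = ⟨bc − ad⟩/(2σₙ²); the
coupling gain and phase are β = √(ρ² + ρ⊥²), θ = atan2(ρ⊥, ρ), and the
conditional residual variance is η² = σ²(1 − β²).

## Distribution of correlation components

Under the bivariate-Gaussian coefficient model, rₙ = ½(ac + bd) follows an
asymmetric Laplacian: density (1/Z)exp(−2|r|/(Z ± σ²ρ)) with
Z = σ²√(1 − ρ⊥²), i.e. a two-sided exponential with branch mean-scales
(Z ± σ²ρ)/2 and mean σ²ρ. We adopt the √(1 − ρ⊥²) normaliser because it is
what the conditional-variance algebra (η² = σ²(1 − β²)) produces, and it is
the form our Monte-Carlo checks validate. Observed correlation components
from turbulent signals are intermittent — they contain an excess of
near-zero values — so the package also fits, by hard-assignment EM:

* a Bernoulli mixture (intermittency ι of true correlations, zero-mean
  Gaussian noise of variance ν² otherwise), and
* generalised one-sided branch families glued at zero with a shared
  normaliser: exponential, Gamma (shape k, singular at 0 for k < 1), and
  generalized inverse Gaussian with density ∝ r^(k−1)e^(−α(r/λ + λ/r)/2)
  and normaliser 2λᵏKₖ(α) (modified Bessel function of the second kind).
  The GIG normaliser carries the λᵏ factor required for the density to
  integrate to one; the test suite verifies normalisation by quadrature
  over random in-bounds parameter draws.

The E-step flags an observation as correlation when its correlation/noise
log-likelihood ratio exceeds log((1 − ι)/ι) (ties flagged as correlation; a
measure-zero event). The M-step shrinks ι toward a prior mean ῑ₀ with
strength 1, sets ν² to the mean square of noise-flagged observations
(falling back to var(y)/1000 when none are flagged, so the noise branch
cannot collapse permanently to zero), and updates branch parameters in
closed form for the exponential — the unique solution of the sandwiched
score equations, λ = (N⁺|ȳ⁺| + √(N⁺N⁻|ȳ⁺||ȳ⁻|))/(N + 10⁻⁸) and its mirror
with a 10⁻⁶ floor, verified against a Nelder–Mead MLE oracle — and by
bounded Nelder–Mead minimisation of the mean negative log-likelihood for
Gamma/GIG, warm-started at the previous iterate clipped to the bounds
(scales in [10⁻⁶, 10], Gamma shapes in [0, 10], GIG shapes in [10⁻⁶, 10]);
GIG updates are damped, new = ½ old + ½ argmin. Families are fitted
ancestrally: the exponential fit seeds the Gamma at shapes 1 (where the
Gamma reduces to it), and the Gamma fit seeds the GIG near its small-α
Gamma limit at fixed mean scale 2λ/α (α₀ = 0.1). EM stops when the
log-likelihood changes by less than 10⁻⁸ or after 500 iterations. Fit
quality is 1 − maxᵢ|F_pred(rᵢ) − F_data(rᵢ)| with F_data(rᵢ) = i/N on the
sorted observations and F_pred the ι-weighted mixture CDF; numerically
invalid CDF values (outside [0, 1], which the GIG special functions can
produce) are excluded, not clamped. Model families and intermittency priors
ῑ₀ ∈ {0.1, …, 0.9} are compared by nested cross-validation: three outer
67/33 train/test splits give held-out performance; three inner 67/33
sub-splits of each training set rank the settings (ties averaged), so
ranking never sees the data used to score performance. One seed drives all
splits.

The hard E-step assigns low-magnitude true correlations to the noise
branch, so the data intermittency ῑ underestimates ι slightly; the prior
compensates when ῑ₀ is selected by grid search on fit quality, which is how
the recovery tests drive it. Intermittency recovery is therefore accurate
to ~10% rather than the ~1% Monte-Carlo limit of the scale parameters.

## Fisher information and the elbow profile

The in-phase correlation is modelled as exponential decay with separation,
ρₙ(s) = (1 − bₙ)e^(−s/γₙ) + bₙ, fitted by non-negative nonlinear least
squares (initialised at γ = 1, b = 0) using separations up to one pitch —
the decay length of the data can itself change beyond that range, and the
fit is global, so restricting the range keeps the small-separation
information estimates honest. Near-flat inputs produce a degenerate, very
large γ and are flagged. The Fisher information about separation carried by
rₙ is I = 2ρ′²/(1 − ρ²), which for the decay model has the closed form

    I(s) = (2/γ²)(1 − b)e^(−2sₙ) / [(1 + b + (1 − b)e^(−sₙ))(1 − e^(−sₙ))],

sₙ = s/γ. The two forms are verified identical to 10⁻¹⁰ relative on a
random (γ, b, s) grid; the closed form diverges at s = 0 (reported as +∞
and excluded from regressions) and scales as 1/γ², so rescaling all lengths
by c rescales I by c⁻². Estimated ρ is clipped to ±0.999 before entering
1/(1 − ρ²), since finite-sample estimates can exceed 1.

A fuller expression keeping a nonzero out-of-phase correlation is provided:
with λ = σ²ρ, λ⊥ = σ²ρ⊥ and Z = √(σ⁴ − λ⊥²), the expected squared score of
the asymmetric Laplacian is

    I = −(Z′/Z)² + (1/Z)[(Z′ + λ′)²/(Z + λ) + (Z′ − λ′)²/(Z − λ)],

with Z′ = −λ⊥λ⊥′/Z. We derived this by direct integration of the squared
score (the score is α + β_sgn(r)|r| with α = −Z′/Z; its mean is zero, and
the constant plus linear terms collapse to −(Z′/Z)²), and validate it in
the test suite against a Monte-Carlo finite-difference Fisher oracle at a
point with ρ⊥ ≠ 0; it reduces exactly to 2ρ′²/(1 − ρ²) when ρ⊥ ≡ 0. The
headline analyses use the ρ⊥ = 0 form, as quadrature correlations are
near zero in the data this method targets.

Uncertainty bands (5/50/95 percentiles) come from resampling time windows
with replacement to the original count — jointly across sources, preserving
within-window pairing — and re-running estimation, decay fits and the
information grid per resample; 50 resamples by default. The spectral trend
is summarised per separation by Huber robust regression (iteration cap
10⁴) of log₁₀ I on frequency over 1–15 Hz by default; non-finite and
non-positive I values are dropped, and a separation with fewer than three
valid frequencies gets an undefined slope, not zero.

## Surrogate generator

The validation instrument draws signals for M sources whose trigonometric
coefficients have prescribed covariance k(i, j, n) = G(|i − j|, n) S(n),
block-diagonal by harmonic (cross-harmonic covariances are exactly zero).
S(n) = max(n·fs/(2⌊L/2⌋ + 1), 1)^(−α) is a 1/f power law with the power
clamped to 1 below 1 Hz; α = 4 mimics plume spectra, α = 0 is white. Two
presets fix G: `equal_informative` uses G(d) = 2e^(−d/12) − 1 at every
harmonic, and `high_gt_low` uses G(d, n) = e^(−d/R(n)) with R(n) = 12 for
harmonics in the lower half of the range (n < ⌊L/2⌋/2) and R(n) = 2 in the
upper half — a six-fold faster decay at high frequencies. Cosine and sine
coefficients are independent draws c = Lu, s = Lv from the Cholesky factor
K = LLᵀ, so the out-of-phase correlation is zero by construction; signals
are x_m[t] = Σₙ c_mn cos(πnt/⌊L/2⌋) + s_mn sin(πnt/⌊L/2⌋) over
2⌊L/2⌋ + 1 samples. Numerically semidefinite kernels get a logged diagonal
jitter (10⁻¹⁰·trace/dim, escalating ×10 at most three times); indefinite
kernels are rejected with the offending eigenvalue. Defaults are M = 16
sources, 20 harmonics and 2000 independent realizations standing in for
time windows — matching the simulation source count this generator
emulates, with realization count chosen so per-harmonic correlation
estimates have ~0.02 Monte-Carlo error, comfortably resolving the
prescribed decay lengths. Distances are in source-index units; mapping to
pitch is a user-supplied scale (the analyses here use 0.3 pitch per index,
the source spacing of the emulated configuration).

What the surrogates do and do not emulate: they reproduce the power
spectrum, the distance-decaying coefficient correlations, and the zero
quadrature coupling of the target data, but they are Gaussian and
non-intermittent, with realizations independent rather than overlapping
windows of one long series. Pipeline results on surrogates therefore
validate the estimator chain and the information calculus, not robustness
to intermittency or non-Gaussianity — those are exercised separately by the
mixture-model fits. One measurement interaction worth knowing: feeding the
synthesized signals (rather than the generating coefficients) through the
decomposition z-scores each 41-sample realization, and when a single
harmonic dominates the variance (α = 4) the shared per-window scale mildly
shrinks recovered correlations (≈0.1 at most) while preserving their decay
shape; with a flat spectrum the round trip matches the kernel to
Monte-Carlo error. Ground-truth coefficient analyses are unaffected.

## Integral length scales

Velocity autocorrelations along an axis are computed from time-demeaned
series (standard turbulence convention) as the average of the +r and −r
two-point products, falling back to the available side at domain edges, and
normalised by the zero-displacement value. The integral length scale is the
rectangle-rule sum Σ f(nΔr)Δr with Δr = 0.02 pitch by convention; negative
lobes of f are included (an optional first-zero-crossing truncation is off
by default), and the discretization error is O(Δr).

## Numerical and design choices

* Population (1/L) z-scoring and the Nyquist weight were chosen to make the
  correlation decomposition an identity rather than an approximation.
* All coefficient moments are uncentred; see above for why.
* Observations with |y| below 10⁻³⁰⁰ are floored in branch log-densities to
  avoid log(0) in shape-parameter likelihoods.
* EM E-step ties assign the correlation label; convergence is declared at
  |Δ log-likelihood| < 10⁻⁸ or 500 iterations.
* The decay fit at a harmonic whose correlations never clearly exceed the
  noise floor is flagged `near_flat` (range < 10⁻³ or γ > 10³) so that the
  strongly γ-sensitive information formula is not over-interpreted there.
* Every pipeline output embeds the configuration hash, seed and package
  version; a single integer seed drives all randomness (bootstrap, CV
  splits, surrogate draws), making runs bit-reproducible.

## Known limitations

* The Fisher calculus assumes the Gaussian coefficient model and the
  exponential decay form; the mixture fits quantify, but do not propagate,
  departures from it (the information is not recomputed under the
  Gamma/GIG models, whose extra parameters would each need their own
  distance dependence).
* Hard-assignment EM biases ι downward without the grid-searched prior.
* The decay fit is global over the fit range; local (e.g. spline)
  estimates of ρₙ(s) are out of scope.
* Fisher information here is local; no mutual-information alternative is
  provided.
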