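# Methods

## Scope and model

`nmrmixsim` simulates two groups of one-dimensional ¹H-NMR spectra of
complex metabolite mixtures. The central assumption is superposition:
a mixture spectrum is a linear combination of experimentally acquired
pure-compound spectra, weighted by concentration × proton count, plus
additive Gaussian noise. Intra-molecular relaxation is inherited from
the experimental standards; differential inter-molecular relaxation is
not simulated, and intensities are in arbitrary units with no absolute
concentration calibration.

## Concentration model

Independent metabolites are drawn from a normal distribution truncated
to (0, ∞) via the inverse CDF: with α = −µ/σ, a draw is
µ + σ·Q(Φ(α) + u(1 − Φ(α))), u ~ U(0,1). σ = 0 degenerates to the
constant µ (µ > 0 required). A template entry with a blank SD gets
σ = µ/1.95, reading the reported mean (or half-range) as roughly a 95%
half-width.

Correlated metabolites are drawn from N(µ, Σ) with rejection of any
vector containing a non-positive component. The user's pairwise
correlation matrix is first repaired to the nearest (Frobenius)
positive-semidefinite correlation matrix by alternating projections
with Dykstra's correction between the PSD cone and the unit-diagonal
set (stopping at max-norm change < 1e-8 or 200 iterations; an input
with minimum eigenvalue ≥ −1e-10 is returned unchanged). The
covariance Σ = diag(σ) R diag(σ) has its whole diagonal inflated by
|λ_min| + 1e-8·tr(Σ)/K whenever λ_min ≤ 0, restoring strict positive
definiteness for the Cholesky factor. Every matrix (requested,
repaired, covariance, inflated) is kept on the draw object and written
to CSV for inspection. Rejection sampling aborts with advice when the
online acceptance-rate estimate falls below 1/max_attempts (default
max_attempts 1000) rather than silently biasing the sample.

Case templates may be specified explicitly or as fold changes on the
control template. Fold changes scale the SD by the same factor as the
mean, keeping each metabolite's coefficient of variation constant
between groups; an explicit case template overrides this choice.

## Standard-spectrum preprocessing

Order: regrid → exclusion zeroing → baseline correction →
negative-artifact removal → kernel smoothing → unit-integral
normalization. This order is a contract; tests pin it.

- **Regrid**: linear interpolation onto the target grid; points outside
  the source range are zero.
- **Exclusions**: closed ppm intervals set to exactly zero. Defaults:
  below 0.2 ppm (internal reference, TSP) and 4.5–6.0 ppm (residual
  water and urea), both clipped to the grid.
- **Baseline**: the grid is split into consecutive *disjoint* windows
  of width ω (default 0.3125 ppm); the per-window median, assigned at
  the window centre and linearly interpolated between centres (held
  constant beyond the outermost), estimates the baseline. It is
  subtracted only where intensity < max/divisor (default divisor 10),
  protecting peaks. Interpolating between centres avoids the staircase
  a piecewise-constant estimate would imprint.
- **Negative artifacts**: the intensity vector is split into n
  contiguous bins (default 32, equal in points); σ_med is the median of
  the per-bin sample SDs (ddof = 1, matching the original MATLAB-style
  convention) and every intensity below l = M − 3σ_med (M the global
  median) is raised to l.
- **Kernel smoothing**: points below threshold_fraction × max (default
  0.8) are replaced by a kernel-weighted mean of their neighbours
  (normal, box, triangle or epanechnikov kernels on index distance /
  bandwidth). The unbounded normal kernel is truncated at ±3
  bandwidths; compact kernels at ±1. Weights are renormalized over the
  neighbours actually available, so edges need no padding. All
  threshold comparisons throughout the pipeline are strict (<): a point
  exactly at a threshold is never modified.
- **Normalization**: residual negative values (at most the floor l,
  i.e. below the noise floor) are zeroed, then the spectrum is scaled
  to unit summed intensity, making concentration and proton count the
  only weights in the mixture. A spectrum with no positive signal —
  e.g. all peaks inside exclusion regions — raises here.

A caution established while validating the pipeline: the median
baseline and the thresholded smoothing are *not* exactly
area-preserving for heavy-tailed Lorentzian lines, and the size of the
distortion depends on where a line sits relative to the window
partition and the grid (a few percent of a line's area at typical
linewidths). Relative areas of lines with equal heights and equal
grid/window phase are preserved to ~1e-5; lines of very different
heights can shift their area ratio by ~1%. This mirrors the behaviour
of these standard preprocessing steps on real spectra and is why the
simulator's final SNR is only approximately controlled.

## Peak shifts

Peaks are local maxima strictly above both neighbours (flat tops count
once at their centre point, ties toward lower ppm) and above
max(min_height_fraction × max, noise_multiple × σ_med). Detected peaks
are matched to the nearest tabulated multiplet position within a
tolerance (default 0.03 ppm); unmatched peaks never move, and
equidistant ties go to the lower-ppm entry with a logged warning.

The shift η = [e^(pH−pKa)(a − δ) − δ + b]/[e^(pH−pKa) + 1] is computed
in logistic form (s·(a−δ) + (1−s)·(b−δ), s the sigmoid of pH − pKa),
which is algebraically identical but immune to overflow. Note the
convention as adopted: the high-pH limit of this formula is the
*acid*-limit position a, which is the mirror image of the chemical
convention (high pH deprotonates toward the base form). The formula is
implemented as stated rather than "corrected", so tabulated a/b values
prepared for it behave consistently; users preparing their own
multiplet tables should list the position approached at high pH under
`acid=` and at low pH under `base=`.

One η per multiplet, evaluated at the multiplet's mean tabulated
position with mean acid/base limits, moves the multiplet rigidly —
peaks of one multiplet must not drift apart. The moved segment spans
from the nearest local minimum left of the leftmost assigned apex to
the nearest local minimum right of the rightmost; it translates by
round(η/grid step) points, vacated points are filled with the
pre-shift intensity at the segment edge on the vacated side, and a
shift that would leave the grid is clipped at the edge with a warning.
The whole spectrum is then re-smoothed (below the smoothing threshold)
to suppress translation artifacts.

pKa is a per-metabolite quantity; the table loader rejects conflicting
values. Missing pKa values draw once per metabolite-replicate from
N(pka_fallback_mean, pka_fallback_sd²) (defaults 7.0, 0.5); missing
limits draw a positive offset |N(0.05, 0.01²)| ppm and place the acid
limit at δ + offset and the base limit at δ − offset, keeping the
ordering sane. One pH per replicate is shared by all metabolites (one
sample, one pH); pH is either fixed or N(ph_mean, ph_sd²) (defaults
7.0, 0.5).

## Mixture and noise

Replicates are assembled as y = Σ yₖ·cₖ·pₖ with σₙ = max(y)/SNR white
noise (SNR = ∞ gives a noise-free run), then one thresholded
kernel-smoothing pass over the composite. Smoothing the added white
noise is what produces the autocorrelated noise texture of apodized
real spectra; the threshold keeps tall peaks from being broadened a
second time. In a signal-free region the realized noise SD equals
σₙ·sqrt(Σw²)/Σw for the kernel weights w — the tests compute this
attenuation factor rather than assuming it. Because the individual
standards retain some residual noise of their own, the final SNR is
approximate by construction. Switches exist to disable noise and/or the
final smoothing for exact-arithmetic testing.

## Determinism and seeding

A single root seed determines the whole experiment. Both groups restart
from the same derived substreams (common random numbers): the
concentration, pH and per-replicate shift/noise streams are spawned
identically for control and case. Group contrasts therefore reflect
the template difference, not sampling noise, and two groups simulated
from identical templates with noise off are bit-identical — a useful
null. Per-replicate streams are spawned from the root, so changing the
replicate count does not perturb earlier replicates.

## Synthetic standards database

The fixture generator emulates a real standards library with Lorentzian
multiplets (singlet/doublet/1:2:1 triplet patterns, J-spacings
0.01–0.02 ppm, half-widths 0.0015–0.003 ppm, optional asymmetric
half-widths since real lines are rarely ideal), a low-order polynomial
baseline and additive noise, placed in 0.8–4.2 and 6.3–9.5 ppm so
signal survives the default exclusions. Default concentration means
are uniform on 100–1000 µM-like units with SD = mean/5, a realistic
coefficient of variation for abundant urinary metabolites. Titration
data (pKa, acid/base limits) are written for alternating metabolites so
the fallback-sampling path is always exercised. Every line's exact
position and analytic area (height × π × mean half-width) is recorded
as truth, enabling end-to-end recovery checks of cₖ·pₖ.

What the synthetic database does **not** emulate: phase errors,
spectrometer-dependent lineshape distortions, contaminant signals,
ridges from imperfect water suppression, and the dense peak overlap of
a real 48-metabolite urine library. Passing tests therefore demonstrate
the correctness of the algorithmic pipeline, not the fidelity of any
particular real biofluid simulation.

## Problem sizes

The test suite runs on 4096-point grids (one area-preservation test
uses 4033 points so the 0.3125-ppm baseline window is a whole number of
grid steps) with up to six metabolites and 20 replicates per group; the
correlated-concentration checks use 2·10⁴ replicate vectors, and the
smoothed-noise check a 2¹⁴-point grid. These sizes put Monte-Carlo
standard errors comfortably inside the asserted tolerances while
keeping the suite fast. Production defaults are 2¹⁴ points, 50
replicates per group and SNR 200.

## Known limitations

- Only the Bruker processed-data subset (`1r` + `procs`: size, offset,
  spectral width, byte order, scaling exponent, 32-bit integers) and a
  two-column text dialect are read; no JCAMP-DX, 2D or time-domain
  data.
- The SNR of the final mixture is only approximately the requested
  value (residual standard noise, smoothing attenuation).
- Lineshape does not respond to pH; only position does.
- No log-normal or mixture concentration models; no time-course
  designs.
- The segment-translation shift cannot split a multiplet across an
  exclusion-region boundary; shifts are whole grid steps, so shifts
  smaller than half a grid step are invisible.
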