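# Methods

This note documents the models implemented in `chromodwell`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Two-state single-particle-tracking model

Molecules are modelled as belonging to one of two kinetic states:

* **bound** — chromatin-associated, with a small *apparent* diffusion
  coefficient `d_bound` (default 0.02 µm² s⁻¹; chromatin itself moves, so
  bound molecules are not strictly immobile). A bound molecule stays bound
  for a residence time drawn from an exponential mixture and is then
  censored: re-binding is not simulated, because the residence-time analysis
  treats each binding event independently.
* **diffusing** — free 2D Brownian motion with `d_free` (default
  1.5 µm² s⁻¹).

Positions evolve by Gaussian increments with per-axis variance 2·D·dt,
integrated in 10 sub-steps per exposure (the scheme is converged for the
D·exposure products at these scales; doubling the sub-step count changes
rendered images negligibly). Boundaries are reflecting. Coordinates are
0-based pixel indices, origin top-left, x = column, y = row; physical units
enter only through the pixel size.

The *reported* per-frame position is the true position at the start of the
exposure plus isotropic Gaussian localization noise (`localization_sigma`,
default 30 nm). The noise is applied to the report, not to the underlying
truth, which adds a σ²/Δt floor to the apparent diffusion coefficient of
bound molecules (≈0.07 µm² s⁻¹ at 13.5 ms with the defaults). This floor is
reported as-is and not corrected; it is why the bound class threshold
(D ≤ 0.1 µm² s⁻¹) sits well above `d_bound`.

### Imaging model and defaults

The study this pipeline targets did not need to publish pixel size, PSF
width or photon budgets, so the simulator declares defaults rather than
inferring them:

| parameter | default | rationale |
|---|---|---|
| pixel size | 156 nm | makes the 6-pixel linking radius equal 936 nm |
| PSF σ | 170 nm | diffraction-limited spot for ~580 nm emission at NA 1.4 |
| photons/molecule/frame | 200 | bright organic dye (JF549-class) on an EMCCD |
| background | 0.8 photons px⁻¹ frame⁻¹ | cellular autofluorescence |
| EM gain | 250 ADU/photon | typical EMCCD setting |
| localization σ | 30 nm | consistent with the photon budget above |

Rendering integrates each emitter's photons over the exposure by summing a
Gaussian PSF at every sub-step position, adds the background, Poisson-samples
*at the photon level*, and multiplies by the EM gain to produce 16-bit
counts. Sampling at the photon level matters: noise amplified by EM gain
scales with the gain, and applying Poisson noise to ADU counts directly
would understate shot noise by √gain and make motion-blurred molecules look
far more detectable than they are.

With these defaults an immobile emitter at 500 ms exposure has peak SNR ≈ 18
and an integrated spot intensity ≈ 50,000 counts, while a D = 1 µm² s⁻¹
molecule at the same brightness spreads its photons over ≈ √(4·D·t) ≈ 1.4 µm
and drops to median peak SNR ≈ 6 — below the SNR > 8 detection gate. This is
the motion-blurring principle: long exposures image only bound molecules.

What the generator does **not** emulate: photoactivation scheduling (all
molecules are visible from frame 0), 3D motion and defocus, anisotropic
PSFs, EMCCD excess noise factor and read noise, camera offset, and molecular
re-binding. Passing tests therefore demonstrate correctness of the analysis
chain under the stated model, not robustness to every artefact of real
movies (e.g. drift, uneven illumination, overlapping emitters at high
density).

## Detection

Fast mode (short exposure) band-passes each frame with a difference of
Gaussians (smoothing scale 1 px, background scale 4 px), takes local maxima,
and computes a brightness-weighted centroid in a 7×7 window (ties between
equal maxima are broken toward lower row, then column). The window median is
subtracted before the moment computation so residual background does not
inflate the size estimate. Gates: second-moment FWHM < 3 px and SNR > 8,
where SNR = (peak − median of an 11×11 annulus) / (1.4826·MAD of the
annulus) — the size estimator and SNR definition are implementation choices,
as puncta "size" and "signal to noise" admit several conventions.

Slow mode (500 ms) replaces the band-pass with rolling-ball background
correction (grayscale opening with a disk, radius 5 px) and gates on a fixed
global threshold of 25,000 background-corrected counts integrated over the
centroid window. The threshold is scale-relative (it assumes the 16-bit
EM-amplified scale above) and configurable; whether the original convention
thresholded raw or corrected counts is not determinable, so corrected counts
are the documented default.

## Tracking

Localizations in consecutive frames are linked by minimum-cost one-to-one
assignment with matches restricted to a radius (default 6 px = 936 nm). The
objective is explicit: minimize Σ(matched distances) + radius × (number of
unmatched localizations), solved exactly per frame pair via an augmented
linear assignment problem. No gap closing: a missed frame terminates the
trajectory, which is conservative for dwell times (it can only shorten
them). The dwell of an n-point trajectory is (n−1)·Δt — the time actually
spanned by observations; the (n)·Δt convention is available behind
`plus_one_frame=True`. Trajectories touching the movie's last frame are
flagged right-censored and excluded from survival fitting by default; with
heavy censoring (observation window not ≫ slowest τ) this biases residence
times downward, so the movie length should exceed several multiples of the
slowest expected component (1000 frames at 500 ms against τ ≈ 30–50 s gives
a 10–17× margin).

No photobleaching correction is applied. An optional bleach-rate divisor
hook exists in the simulator configuration for sensitivity analyses, but the
fitted residence times are apparent (bleaching-convolved) values, as in the
analysis this package mirrors.

## Jump-distance mixture fitting

The empirical CDF of pooled jump magnitudes is fit by trust-region least
squares to Σᵢ fᵢ·(1 − exp(−r²/(4·Dᵢ·Δt))). Fitting the cumulative
distribution is bin-free; the points are unweighted (whether the original
fits weighted them is unknowable, and unweighted is the simplest documented
choice). Diffusion coefficients are parameterized on the log scale and
fractions as normalized positive weights (the last weight fixed at 1), which
enforces the simplex without a softmax. Multi-start initialisation places
D guesses at the {25, 75}% (two components) or {25, 50, 75}% (three) CDF
quantiles inverted through the single-component law, with uniform fractions,
plus a wider-spread second start. Component count is capped at 3.

## Residence-time fitting, BIC and bootstrap

The empirical survival S(t_k) = #(dwell ≥ k·Δt)/n is fit to
F(t) = Σᵢ fᵢ·exp(−t/τᵢ) by the same constrained least-squares machinery
(τ on log scale, simplex weights). Fitting the survival fraction rather than
a binned dwell histogram avoids bin-width choices and matches the RSS-based
BIC below. τ is capped at 100× the last grid point: residence times far
beyond the observation span are unidentifiable from the curve, and an
unbounded τ occasionally escapes during bootstrap refits.

Model selection uses, verbatim,

    BIC = ln(n)·(p + 1) + n·(ln(2π·RSS/n) + 1)

with n the number of fitted curve points and p = 2k−1 free parameters. The
(p+1) multiplier is kept as printed in the formula this implements; the
textbook p·ln(n) penalty is available via `bic(..., textbook=True)` (the two
never disagreed on selection in our simulations).

**Resolvability guard.** Survival-curve (and empirical-CDF) residuals are
strongly autocorrelated, so raw lowest-BIC systematically over-selects: a
spurious component with a ~1% fraction, a duplicated timescale, or an
intermediate timescale can absorb a correlated noise excursion and halve the
RSS. `fit_select` therefore only considers a k-component model eligible if
every fraction is ≥ 0.05 and successive timescales are separated by ≥ 5×.
Both cuts are detectability limits, not tuning: populations below ~5% are
not distinguishable from ECDF noise at these sample sizes, and it is a
classical result of exponential analysis that components closer than ~4–5×
in timescale cannot be resolved from noisy decay data. The smallest real
populations this pipeline targets (≈12% specific binding; τ ratios of 12–20;
D ratios of ~75) sit far inside the eligible region. All fits and their BIC
values are still reported in `bic_table`.

Uncertainties come from a parametric bootstrap: `n_boot` (default 1000)
synthetic dwell datasets are drawn from the fitted mixture at the original
sample size, rebuilt into survival curves on the same frame grid, and refit
with the same component count, warm-started at the base estimates. The
bootstrap mean is the reported parameter estimate and the bootstrap SD its
uncertainty; an error is raised if more than 10% of refits fail. A
maximum-likelihood EM fit on the raw dwells (`exponential_mixture_mle`) is
provided as an independent cross-check of the least-squares estimates.

Condition comparisons (e.g. wild type vs mutant specific residence time) use
a two-sided Z-test on replicate-level means:
z = (mean_A − mean_B)/√(se_A² + se_B²), se = sd/√n_replicates. This is
appropriate when replicate means are approximately normal with similar
variances and at least 2–3 replicates per condition exist.

## PTM site localization

Theoretical fragments are singly-charged b/y ions from monoisotopic residue
masses; citrulline is arginine + 0.984016 Da. Only b/y ions are generated
(the HCD fragmentation this models produces predominantly those), with no
neutral losses and charge 1 only. Candidate sites are arginines.

The spectrum is reduced to its 10 most intense peaks per 100 amu (windows
anchored at the spectrum minimum). For each placement of the modifications,
k of the n in-range theoretical ions are matched within ±20 ppm, each peak
consumed at most once (nearest pair first). The chance-match probability is
binomial, p = C(n,k)·0.04ᵏ·(0.96)ⁿ⁻ᵏ — 0.04 being the approximate chance of
a random match with 10 peaks per 100 amu — and the configuration score is
−10·log₁₀(p). A variant that drops the (0.96)ⁿ⁻ᵏ survivor factor is
available behind `truncated=True`; it changes scores but not site
probabilities when configurations share n. Note the score is strictly
increasing in k only while k·matches stay below the binomial mode (n ≤ 23 at
match probability 0.04), a property of the pmf itself.

The mapping from configuration scores to site probabilities is not uniquely
determined by the score definition; this implementation weights each
configuration by 1/p (equivalently 10^(score/10)) and normalizes, so a
site's probability is the summed weight of configurations containing it.
With one modification the probabilities sum to 1; with m modifications they
sum to m. `n` counts all in-range theoretical ions by default;
discriminating-only counting is an option. A spectrum whose matched ions are
all shared between two candidate sites yields exactly 0.50/0.50.

## Problem sizes used in the shipped analyses

The recovery analyses run on: 5,000 dwell times per dataset (5 datasets) for
the two-exponential regime; 10,000 jumps per dataset (5 datasets) for each
population-fraction recovery; and 3 experiment repetitions × 3 replicates ×
2,000 dwells for the condition-level mean, each with the full 1000× 
bootstrap. These sizes match the scale of the source experiments (>5,000
fast-mode trajectories; >1,000 slow-mode trajectories per condition) while
keeping a full run at a few minutes on one CPU.

## Known limitations

* Dwell times are quantized by the frame interval; components with
  τ ≲ 2·Δt are not reliably recoverable at 500 ms resolution.
* Censoring is handled by exclusion, not by survival-aware likelihoods;
  heavy censoring biases τ downward.
* The apparent-D noise floor is documented but not deconvolved.
* The linking stage assumes sparse fields (≲0.1 molecules per linking
  disc); dense fields need motion-model tracking, which is out of scope.
* Site localization assumes the peptide identification itself is correct;
  database-search scoring and FDR control are out of scope.
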