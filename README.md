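# chromodwell

Analysis of chromatin-binding dynamics from live-cell single-particle
tracking (SPT), plus a PTM site-localization score for citrullination.

The package is built for experiments of the following kind: a chromatin
protein (e.g. the H3K9me2/3 reader HP1γ, fluorophore-tagged) is imaged in
live cells at two time resolutions. Fast movies (≈13.5 ms/frame) capture
both freely diffusing and chromatin-bound molecules; jump-distance analysis
of the trajectories separates the two populations and estimates their
diffusion coefficients. Slow movies (500 ms/frame) exploit *motion
blurring* — long exposures smear diffusing molecules below detectability,
so only bound molecules are imaged — and the distribution of trajectory
durations then measures how long the protein stays bound (its residence
time). A companion module scores which arginine of a peptide carries a
citrulline (+0.984 Da) from an MS/MS fragment spectrum.

## Models

**Jump-distance (JD) mixture.** For 2D Brownian motion with coefficient
*D*, displacements *r* over a lag Δ*t* follow
P(r) = Σᵢ fᵢ·(1 − exp(−r²/(4 Dᵢ Δt))). The model is fit to the empirical
cumulative distribution by constrained least squares; components with
D ≤ 0.1 µm² s⁻¹ are classified *bound*, D ≥ 0.6 µm² s⁻¹ *diffusing*.

**Residence-time exponential mixture.** The fraction of molecules still
bound at time *t* is F(t) = Σᵢ fᵢ·exp(−t/τᵢ), Σfᵢ = 1. The empirical
survival curve on the frame grid is fit for 1–3 components; the number of
components is selected by the Bayesian Information Criterion

    BIC = ln(n)·(p + 1) + n·(ln(2π·RSS/n) + 1)

(lowest BIC wins), and parameter means/SDs come from a 1000× parametric
bootstrap. Conditions are compared with a Z-test on replicate-level means.

**PTM localization score.** For every placement of the citrulline(s) over
the candidate arginines, singly-charged b/y ions are matched (20 ppm)
against the 10 most intense peaks per 100 amu; each configuration is scored
−10·log₁₀(p) with p = C(n,k)·0.04ᵏ·0.96ⁿ⁻ᵏ, and per-site probabilities are
the normalized configuration weights 1/p.

A generative simulator (two-state Brownian motion, exponential dwell
mixtures, Gaussian PSF, photon-level Poisson noise, EM gain, motion-blur
rendering, bleaching) makes the whole pipeline testable end to end.

## Worked example

```python
import numpy as np
from chromodwell import (simulate_dwell_times, DwellTimeModel)

dwells = simulate_dwell_times([(0.88, 2.4), (0.12, 28.8)], 5000,
                              seed=1, frame_interval=0.5)
res = DwellTimeModel(dwells).fit_select(3)
res.parametric_bootstrap(n_boot=1000, seed=2)
print(res.summary())
```

prints

```
Residence-time exponential-mixture fit
==================================================
n dwells: 5000    grid points: 332
components: 2    RSS: 0.0002128    BIC: -3769.08
BIC by model: k=1: -1497.8, k=2: -3769.1, k=3: -3757.9
--------------------------------------------------
   tau (s)  fraction   boot mean   boot sd
     2.393     0.877       2.394     0.048
    28.817     0.123      28.813     1.571
(bootstrap: 1000 refits)
```

Two binding modes are identified: an unspecific population (τ ≈ 2.4 s,
≈88% of bound molecules) and a specific one (τ ≈ 28.8 s, ≈12%), with
bootstrap uncertainties; the two-component model has the lowest BIC. The
same flow applies to jump distances:

```python
from chromodwell import JumpDistanceDataset, JumpDistanceMixtureModel
rng = np.random.default_rng(1)
nb = rng.binomial(10_000, 0.374)
jumps = np.concatenate([
    np.sqrt(rng.exponential(4 * 0.02 * 0.0135, nb)),       # bound
    np.sqrt(rng.exponential(4 * 1.5 * 0.0135, 10_000 - nb))  # diffusing
])
fit = JumpDistanceMixtureModel(JumpDistanceDataset(jumps, 0.0135)).fit_select()
print(fit.summary())
```

```
Jump-distance mixture fit
==========================================
n jumps: 10000    lag: 13.5 ms
components: 2    RSS: 0.0219    BIC: -101898.54
------------------------------------------
  D (um^2/s)  fraction         class
      0.0198     0.371         bound
      1.5219     0.629     diffusing
------------------------------------------
bound fraction: 0.371    diffusing fraction: 0.629
```

A command line covers the movie-level pipeline:

```bash
chromodwell simulate --out-prefix run1 --seed 7
chromodwell localize --movie run1.tif --mode fast --out locs.csv
chromodwell track    --locs locs.csv --radius-px 6 --out tracks.csv
chromodwell jd       --tracks tracks.csv --dt 0.0135
chromodwell dwell    --tracks tracks.csv --dt 0.5 --n-boot 1000 --seed 7
chromodwell ptmscore --peptide VLDRRVVNGK --mods 1 --spectrum spec.csv
```

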