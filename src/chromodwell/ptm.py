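"""PTM site-localization scoring for citrullination.

Citrullination converts peptidyl-arginine to citrulline, a +0.984016 Da mass
shift.  When a modified peptide is fragmented (HCD), b- and y-ions that
contain the modified residue carry the shift, so the fragment spectrum can
discriminate between candidate arginines.  The localization score works as
follows:

1. keep the 10 most intense fragment peaks per 100 amu window of the MS/MS
   spectrum;
2. for every possible placement ("configuration") of the citrulline(s) over
   the candidate arginines, compute the theoretical singly-charged b/y ions
   in the observed mass range and count the matches ``k`` (out of ``n``
   theoretical ions, 20 ppm tolerance);
3. score each configuration as ``-10 * log10(p)`` with
   ``p = C(n, k) * 0.04^k * 0.96^(n-k)`` — the binomial probability of ``k``
   chance matches given a 4% per-ion match probability (10 peaks per 100 amu
   at a ~20 ppm window);
4. convert scores to per-site localization probabilities by normalising the
   configuration weights ``1/p`` (equivalently ``10^(score/10)``) and summing
   the weights of configurations containing each site.

A spectrum with no site-discriminating matches yields equal probabilities
over the candidate sites (e.g. 0.50/0.50 for one citrulline over two
arginines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "CITRULLINE_DELTA",
    "PeptideSpectrum",
    "SiteConfiguration",
    "PTMLocalizationResult",
    "theoretical_fragments",
    "top_peaks_per_window",
    "match_fragments",
    "ptm_score",
    "site_probabilities",
    "synth_spectrum",
]

#: monoisotopic mass shift of citrulline relative to arginine (Da)
CITRULLINE_DELTA = 0.984016

PROTON = 1.00727646688
H2O = 18.0105646863

_AA_MASS = dict(_pmass.std_aa_mass)

DEFAULT_MATCH_P = 0.04
DEFAULT_TOL_PPM = 20.0


@dataclass(frozen=True)
class PeptideSpectrum:
    """An MS/MS spectrum paired with its peptide and modification count."""

    peptide: str
    n_mods: int
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 2
    fragment_tolerance_ppm: float = DEFAULT_TOL_PPM

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if inten.size and inten.min() <= 0:
            raise ValueError("intensities must be positive")
        order = np.argsort(mz)
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        pep = self.peptide.upper()
        object.__setattr__(self, "peptide", pep)
        n_arg = pep.count("R")
        if self.n_mods < 0 or self.n_mods > n_arg:
            raise ValueError(f"peptide has {n_arg} arginines; cannot place "
                             f"{self.n_mods} citrullines")

    @property
    def candidate_sites(self) -> tuple[int, ...]:
        """1-based positions of candidate (arginine) residues."""
        return tuple(i + 1 for i, aa in enumerate(self.peptide) if aa == "R")


@dataclass(frozen=True)
class SiteConfiguration:
    """One placement of the modifications with its match statistics."""

    sites: tuple[int, ...]   # 1-based modified positions
    k: int                   # matched theoretical fragments
    n: int                   # theoretical fragments in range
    p_binom: float
    score: float             # -10 log10(p_binom)


@dataclass
class PTMLocalizationResult:
    """Per-configuration scores and per-site localization probabilities."""

    peptide: str
    n_mods: int
    configurations: list[SiteConfiguration]
    site_probabilities: dict[int, float] = field(default_factory=dict)

    @property
    def best_configuration(self) -> SiteConfiguration:
        return max(self.configurations, key=lambda c: c.score)

    def to_dict(self) -> dict:
        return {
            "peptide": self.peptide,
            "n_mods": self.n_mods,
            "site_probabilities": {str(s): p
                                   for s, p in self.site_probabilities.items()},
            "configurations": [
                {"sites": list(c.sites), "k": c.k, "n": c.n,
                 "p_binom": c.p_binom, "score": c.score}
                for c in self.configurations
            ],
        }


def theoretical_fragments(peptide: str, modified_positions=(),
                          mz_range: tuple[float, float] | None = None) -> np.ndarray:
    """Singly-charged b- and y-ion m/z values from monoisotopic residue masses.

    ``modified_positions`` are 1-based indices of citrullinated arginines;
    every fragment containing such a site is shifted by +0.984016 Da.
    Restricted to ``mz_range`` when given.
    """
    pep = peptide.upper()
    mods = set(int(p) for p in modified_positions)
    for p in mods:
        if not 1 <= p <= len(pep):
            raise ValueError(f"modified position {p} outside peptide")
        if pep[p - 1] != "R":
            raise ValueError(f"position {p} is {pep[p - 1]}, not arginine")
    try:
        residue = [_AA_MASS[aa] for aa in pep]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    for p in mods:
        residue[p - 1] += CITRULLINE_DELTA

    npep = len(pep)
    frags = []
    prefix = np.cumsum(residue)
    for i in range(1, npep):       # b1 .. b(n-1), y1 .. y(n-1)
        frags.append(prefix[i - 1] + PROTON)                    # b_i
        frags.append(prefix[-1] - prefix[npep - i - 1] + H2O + PROTON)  # y_i
    out = np.sort(np.array(frags))
    if mz_range is not None:
        lo, hi = mz_range
        out = out[(out >= lo) & (out <= hi)]
    return out


def top_peaks_per_window(mz, intensity, peaks_per_window: int = 10,
                         window: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Keep the most intense peaks per contiguous m/z window.

    Windows of ``window`` amu start at the spectrum minimum; within each, the
    ``peaks_per_window`` largest intensities are retained.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if peaks_per_window < 1:
        raise ValueError("peaks_per_window must be >= 1")
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        return mz, intensity
    bins = np.floor((mz - mz.min()) / window).astype(int)
    keep = np.zeros(mz.size, dtype=bool)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        if idx.size <= peaks_per_window:
            keep[idx] = True
        else:
            top = idx[np.argsort(intensity[idx])[-peaks_per_window:]]
            keep[top] = True
    return mz[keep], intensity[keep]


def match_fragments(theoretical, peak_mz,
                    tolerance_ppm: float = DEFAULT_TOL_PPM) -> tuple[int, int]:
    """Count theoretical fragments matched by filtered peaks.

    ``n`` is the number of theoretical fragments offered; ``k`` the number
    matched within +-tolerance (ppm of the theoretical m/z).  Each peak is
    consumed by at most one fragment and each fragment by at most one peak;
    pairs are accepted nearest-first.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    theo = np.asarray(theoretical, dtype=float)
    peaks = np.asarray(peak_mz, dtype=float)
    n = theo.size
    if n == 0 or peaks.size == 0:
        return 0, n
    pairs = []
    for i, t in enumerate(theo):
        tol = t * tolerance_ppm * 1e-6
        close = np.flatnonzero(np.abs(peaks - t) <= tol)
        for j in close:
            pairs.append((abs(peaks[j] - t), i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    for _, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
    return len(used_t), n


def ptm_score(n: int, k: int, match_p: float = DEFAULT_MATCH_P,
              truncated: bool = False) -> tuple[float, float]:
    """Binomial chance-match probability and localization score.

    ``p = C(n, k) * match_p^k * (1 - match_p)^(n - k)`` and the score is
    ``-10 * log10(p)``.  ``truncated=True`` drops the ``(1-match_p)^(n-k)``
    factor (the truncated product some MaxQuant descriptions print).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < match_p < 1:
        raise ValueError("match_p must be in (0, 1)")
    p = math.comb(n, k) * match_p**k
    if not truncated:
        p *= (1.0 - match_p) ** (n - k)
    p = min(p, 1.0)
    score = -10.0 * math.log10(p) if p > 0 else math.inf
    return p, score


def site_probabilities(spectrum: PeptideSpectrum,
                       match_p: float = DEFAULT_MATCH_P,
                       peaks_per_window: int = 10,
                       window: float = 100.0,
                       truncated: bool = False) -> PTMLocalizationResult:
    """Enumerate citrulline placements and derive per-site probabilities.

    Configuration weights are proportional to ``1/p_binom`` (equivalently
    ``10^(score/10)``); a site's probability is the summed weight of
    configurations containing it.  With ``n_mods`` modifications the per-site
    probabilities sum to ``n_mods``.
    """
    sites = spectrum.candidate_sites
    if not sites:
        raise ValueError("peptide has no candidate (arginine) sites")
    if spectrum.n_mods < 1:
        raise ValueError("spectrum carries no modification to localize")
    if spectrum.mz.size:
        mz_range = (float(spectrum.mz.min()), float(spectrum.mz.max()))
    else:
        mz_range = None
    fmz, _ = top_peaks_per_window(spectrum.mz, spectrum.intensity,
                                  peaks_per_window=peaks_per_window,
                                  window=window)
    configs = []
    for combo in combinations(sites, spectrum.n_mods):
        theo = theoretical_fragments(spectrum.peptide, combo, mz_range=mz_range)
        k, n = match_fragments(theo, fmz, spectrum.fragment_tolerance_ppm)
        if n == 0:
            continue
        p, score = ptm_score(n, k, match_p=match_p, truncated=truncated)
        configs.append(SiteConfiguration(sites=combo, k=k, n=n,
                                         p_binom=p, score=score))
    if not configs:
        raise ValueError("no configuration produced theoretical fragments "
                         "in the observed mass range")
    weights = np.array([1.0 / c.p_binom for c in configs])
    weights /= weights.sum()
    site_prob: dict[int, float] = {s: 0.0 for s in sites}
    for c, w in zip(configs, weights):
        for s in c.sites:
            site_prob[s] += float(w)
    return PTMLocalizationResult(peptide=spectrum.peptide,
                                 n_mods=spectrum.n_mods,
                                 configurations=configs,
                                 site_probabilities=site_prob)


def synth_spectrum(peptide: str, true_sites=(), coverage: float = 1.0,
                   noise_peaks: int = 0,
                   seed: int | np.random.Generator | None = None,
                   signal_intensity: float = 1e5,
                   noise_intensity: float = 1e3,
                   tolerance_ppm: float = DEFAULT_TOL_PPM) -> PeptideSpectrum:
    """Generate a synthetic HCD spectrum for localization tests.

    Emits a random ``coverage`` fraction of the theoretical b/y ions of the
    true configuration (intensities ~ Exponential(signal_intensity)) plus
    ``noise_peaks`` uniform-random decoy peaks at lower intensity.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    theo = theoretical_fragments(peptide, true_sites)
    n_emit = int(round(coverage * theo.size))
    chosen = rng.choice(theo.size, size=n_emit, replace=False) if n_emit else []
    mz = list(theo[chosen])
    inten = list(rng.exponential(signal_intensity, size=len(mz)) + 1.0)
    lo, hi = theo.min() - 5.0, theo.max() + 5.0
    for _ in range(noise_peaks):
        mz.append(rng.uniform(lo, hi))
        inten.append(rng.exponential(noise_intensity) + 1.0)
    mz_arr = np.asarray(mz, dtype=float)
    inten_arr = np.asarray(inten, dtype=float)
    if mz_arr.size == 0:
        # uninformative spectrum: tiny peaks at the range edges, matching
        # no fragment but spanning the full observed mass range
        mz_arr = np.array([lo, hi])
        inten_arr = np.array([1.0, 1.0])
    return PeptideSpectrum(peptide=peptide, n_mods=len(tuple(true_sites)) or 1,
                           mz=mz_arr, intensity=inten_arr,
                           fragment_tolerance_ppm=tolerance_ppm)
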