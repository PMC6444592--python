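"""Jump-distance (JD) diffusion analysis.

For a molecule diffusing in 2D with coefficient ``D``, the displacement
magnitude ``r`` over a lag ``dt`` follows a Rayleigh law with CDF
``1 - exp(-r^2 / (4 D dt))``.  A population containing several diffusive
states produces a mixture,

    P(r; {D_i, f_i}) = sum_i f_i * (1 - exp(-r^2 / (4 D_i dt))),

and fitting this cumulative form to the empirical jump-distance distribution
yields the minimum number of diffusion coefficients needed to describe the
motion, together with the fraction of molecules in each state.  Components
with ``D <= 0.1 um^2/s`` are classified as chromatin-*bound* and components
with ``D >= 0.6 um^2/s`` as freely *diffusing*; anything in between is
reported as intermediate.

The model is fit by nonlinear least squares on the empirical CDF
(bin-free), with multi-start initialisation from CDF quantiles, and the
number of components (1-3) is selected by the Bayesian Information
Criterion shared with the dwell-time module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datasets import JumpDistanceDataset
from .dwell import bic

__all__ = [
    "jd_cdf_model",
    "classify_fractions",
    "JumpDistanceMixtureModel",
    "JumpDistanceResults",
    "fit_jd",
    "select_jd_model",
    "BOUND_D_MAX",
    "DIFFUSING_D_MIN",
]

BOUND_D_MAX = 0.1      # um^2/s: components at or below are "bound"
DIFFUSING_D_MIN = 0.6  # um^2/s: components at or above are "diffusing"


def jd_cdf_model(r, components, lag_s: float):
    """Mixture CDF of 2D Brownian jump distances.

    ``components`` is a sequence of ``(D, f)`` pairs (um^2/s, proportion).
    A ``D = 0`` component is the degenerate zero-jump state and contributes
    a step at ``r = 0``.
    """
    r = np.asarray(r, dtype=float)
    if lag_s <= 0:
        raise ValueError("lag_s must be positive")
    out = np.zeros_like(r, dtype=float)
    for d, f in components:
        if d < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if d == 0:
            out += f * (r >= 0).astype(float)
        else:
            out += f * (1.0 - np.exp(-(r**2) / (4.0 * d * lag_s)))
    return out


def classify_fractions(components, bound_max: float = BOUND_D_MAX,
                       diff_min: float = DIFFUSING_D_MIN) -> tuple[float, float]:
    """Sum component fractions into bound (D <= bound_max) and diffusing
    (D >= diff_min) populations."""
    if not (0 < bound_max < diff_min):
        raise ValueError("require 0 < bound_max < diff_min")
    bound = sum(f for d, f in components if d <= bound_max)
    diffusing = sum(f for d, f in components if d >= diff_min)
    return float(bound), float(diffusing)


def _unpack(params: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Parameter vector -> (D, f).  D on log scale; fractions from k-1
    positive weights normalised against an implicit unit weight."""
    ds = np.exp(params[:k])
    if k == 1:
        return ds, np.ones(1)
    w = np.concatenate([params[k:], [1.0]])
    return ds, w / w.sum()


class JumpDistanceMixtureModel:
    """Mixture-of-diffusion-states model for pooled jump distances.

    Parameters
    ----------
    data : JumpDistanceDataset or array-like
        Jump magnitudes in micrometres.
    lag_s : float, optional
        Lag time in seconds; required when ``data`` is a bare array.
    """

    MAX_COMPONENTS = 3

    def __init__(self, data, lag_s: float | None = None):
        if isinstance(data, JumpDistanceDataset):
            jumps, lag = data.jumps, data.lag_s
        else:
            jumps = np.asarray(data, dtype=float)
            if lag_s is None:
                raise ValueError("lag_s is required with a bare jump array")
            lag = float(lag_s)
        if jumps.size < 100:
            raise ValueError("need at least 100 jumps for a JD fit")
        self.jumps = np.sort(jumps)
        self.lag_s = lag
        # right-continuous empirical CDF evaluated at the sorted jumps
        self.ecdf = np.arange(1, self.jumps.size + 1) / self.jumps.size

    # -- initial guesses ---------------------------------------------------
    def _starts(self, k: int) -> list[np.ndarray]:
        qs_by_k = {1: [(0.5,)], 2: [(0.25, 0.75), (0.1, 0.9)],
                   3: [(0.25, 0.5, 0.75), (0.1, 0.5, 0.9)]}
        starts = []
        for qs in qs_by_k[k]:
            ds = []
            for q in qs:
                r_q = np.quantile(self.jumps, q)
                d = max(r_q**2 / (4.0 * self.lag_s * -np.log1p(-q)), 1e-6)
                ds.append(np.log(d))
            params = np.array(ds + [1.0] * (k - 1))
            starts.append(params)
        return starts

    def fit(self, n_components: int = 2) -> "JumpDistanceResults":
        """Least-squares fit of the mixture CDF with ``n_components`` states."""
        k = int(n_components)
        if not 1 <= k <= self.MAX_COMPONENTS:
            raise ValueError(f"n_components must be 1..{self.MAX_COMPONENTS}")

        def residuals(params):
            ds, fs = _unpack(params, k)
            return jd_cdf_model(self.jumps, list(zip(ds, fs)), self.lag_s) - self.ecdf

        lb = np.concatenate([np.full(k, np.log(1e-6)), np.full(k - 1, 1e-8)])
        ub = np.concatenate([np.full(k, np.log(1e3)), np.full(k - 1, 1e8)])
        best = None
        for x0 in self._starts(k):
            sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                f"JD mixture fit with {k} components failed to converge "
                f"from all starts (n={self.jumps.size}, lag={self.lag_s})")
        ds, fs = _unpack(best.x, k)
        order = np.argsort(ds)
        components = [(float(ds[i]), float(fs[i])) for i in order]
        rss = float(np.sum(best.fun**2))
        n = self.jumps.size
        p = 2 * k - 1
        return JumpDistanceResults(model=self, components=components,
                                   rss=rss, bic=bic(n, p, rss) if rss > 0 else -np.inf,
                                   n_jumps=n)

    def fit_select(self, max_components: int = 3, min_fraction: float = 0.05,
                   min_separation: float = 5.0) -> "JumpDistanceResults":
        """Fit 1..max_components mixtures and return the lowest-BIC fit.

        A candidate model is eligible only if all its components are
        resolvable: every fraction >= ``min_fraction`` and successive
        diffusion coefficients separated by at least a factor
        ``min_separation`` (like exponential decays, diffusive components
        closer than ~4-5x are not distinguishable in noisy jump-distance
        data).  Without this guard, a vanishing or duplicate component can
        absorb the correlated noise of the empirical CDF and win on BIC
        while adding no distinct population.
        """
        fits, eligible = [], []
        for k in range(1, max_components + 1):
            try:
                f = self.fit(k)
            except RuntimeError:
                continue
            fits.append(f)
            ds = f.diffusion_coefficients
            resolvable = (np.all(f.fractions >= min_fraction)
                          and np.all(ds[1:] >= min_separation * ds[:-1]))
            if k == 1 or resolvable:
                eligible.append(f)
        if not eligible:
            raise RuntimeError("no JD mixture model converged")
        best = min(eligible, key=lambda f: f.bic)
        best.bic_table = [(f.n_components, f.bic, f.rss) for f in fits]
        return best


@dataclass
class JumpDistanceResults:
    """Fitted jump-distance mixture: diffusion coefficients, fractions,
    goodness of fit, and the bound/diffusing classification."""

    model: JumpDistanceMixtureModel
    components: list[tuple[float, float]]  # (D um^2/s, fraction), D ascending
    rss: float
    bic: float
    n_jumps: int
    bic_table: list | None = None

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def diffusion_coefficients(self) -> np.ndarray:
        return np.array([d for d, _ in self.components])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.components])

    @property
    def bound_fraction(self) -> float:
        return classify_fractions(self.components)[0]

    @property
    def diffusing_fraction(self) -> float:
        return classify_fractions(self.components)[1]

    def predict(self, r) -> np.ndarray:
        """Model CDF at the given jump distances (um)."""
        return jd_cdf_model(r, self.components, self.model.lag_s)

    def summary(self) -> str:
        lines = [
            "Jump-distance mixture fit",
            "=" * 42,
            f"n jumps: {self.n_jumps}    lag: {self.model.lag_s * 1e3:.1f} ms",
            f"components: {self.n_components}    RSS: {self.rss:.4g}    "
            f"BIC: {self.bic:.2f}",
            "-" * 42,
            f"{'D (um^2/s)':>12}  {'fraction':>8}  {'class':>12}",
        ]
        for d, f in self.components:
            cls = ("bound" if d <= BOUND_D_MAX
                   else "diffusing" if d >= DIFFUSING_D_MIN else "intermediate")
            lines.append(f"{d:>12.4f}  {f:>8.3f}  {cls:>12}")
        lines.append("-" * 42)
        lines.append(f"bound fraction: {self.bound_fraction:.3f}    "
                     f"diffusing fraction: {self.diffusing_fraction:.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Empirical CDF of jump distances with the fitted mixture overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.step(m.jumps, m.ecdf, where="post", lw=1, label="empirical CDF")
        grid = np.linspace(0, m.jumps[-1], 400)
        ax.plot(grid, self.predict(grid), "r-", lw=1.5,
                label=f"{self.n_components}-component fit")
        ax.set_xlabel("jump distance (um)")
        ax.set_ylabel("cumulative fraction of jumps")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "components": [{"D_um2_s": d, "fraction": f} for d, f in self.components],
            "rss": self.rss,
            "bic": self.bic,
            "n_jumps": self.n_jumps,
            "bound_fraction": self.bound_fraction,
            "diffusing_fraction": self.diffusing_fraction,
            "bic_table": self.bic_table,
        }


def fit_jd(jumps: JumpDistanceDataset, n_components: int = 2) -> JumpDistanceResults:
    """Convenience wrapper: fit a fixed-size mixture to a jump dataset."""
    return JumpDistanceMixtureModel(jumps).fit(n_components)


def select_jd_model(jumps: JumpDistanceDataset,
                    max_components: int = 3) -> JumpDistanceResults:
    """Convenience wrapper: BIC model selection over 1..max_components."""
    return JumpDistanceMixtureModel(jumps).fit_select(max_components)
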