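"""Generative simulator for single-particle-tracking experiments.

Emulates fluorophore-tagged chromatin proteins (e.g. HaloTag-labelled HP1)
undergoing two-state 2D Brownian motion inside a camera field of view:

* a *bound* population with a small apparent diffusion coefficient
  (chromatin-associated; residence times drawn from an exponential mixture),
* a *diffusing* population moving freely,

imaged either at short exposure (fast mode, e.g. 13.5 ms, for jump-distance
diffusion analysis) or long exposure (slow mode, e.g. 500 ms), where motion
blurring spreads the photons of fast molecules over many pixels so that only
bound molecules remain detectable.

The simulator produces three linked artefacts:

* a trajectory table (per-frame reported positions with localization noise),
* a :class:`GroundTruth` record (states, true dwell times, sub-step positions),
* rendered movies (:func:`render_movie`) with Gaussian PSF, Poisson photon
  noise and within-exposure motion blur integrated over sub-steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import DwellDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trajectories",
    "simulate_dwell_times",
    "render_movie",
]

#: sub-steps used to integrate Brownian motion across one exposure
N_SUBSTEPS = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a two-state SPT simulation.

    Lengths are nanometres, times seconds, diffusion coefficients um^2/s.
    ``photons_per_molecule`` is the integrated photon signal of one emitter
    over one exposure and ``background_level`` the mean background photon
    count per pixel per frame; rendered movies are scaled to camera counts by
    ``em_gain`` (ADU per photon) after Poisson sampling, so shot noise acts
    at the photon level as on an EM-amplified camera.
    """

    pixel_size: float = 156.0          # nm per pixel (6 px = 936 nm)
    frame_interval: float = 0.0135     # s
    exposure: float = 0.0135           # s, <= frame_interval
    n_frames: int = 100
    field_size: tuple[int, int] = (64, 64)   # (rows, cols) px
    d_bound: float = 0.02              # um^2/s, apparent (chromatin motion)
    d_free: float = 1.5                # um^2/s
    fraction_bound: float = 0.374
    dwell_components: tuple[tuple[float, float], ...] = ((0.88, 2.4), (0.12, 28.8))
    localization_sigma: float = 30.0   # nm
    photons_per_molecule: float = 200.0
    background_level: float = 0.8      # photons / pixel / frame
    psf_sigma: float = 170.0           # nm
    em_gain: float = 250.0             # ADU per photon
    bleach_rate: float = 0.0           # s^-1
    n_molecules: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "exposure", "psf_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not np.isfinite(self.em_gain) or self.em_gain <= 0:
            raise ValueError("em_gain must be positive and finite")
        for name in ("d_bound", "d_free", "localization_sigma",
                     "photons_per_molecule", "background_level", "bleach_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative and finite, got {v}")
        if self.exposure > self.frame_interval + 1e-12:
            raise ValueError("exposure must not exceed frame_interval")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not 0.0 <= self.fraction_bound <= 1.0:
            raise ValueError("fraction_bound must lie in [0, 1]")
        if 0.0 < self.fraction_bound < 1.0 and not self.d_bound < self.d_free:
            raise ValueError("d_bound must be < d_free when both populations "
                             "are requested")
        comps = tuple((float(f), float(t)) for f, t in self.dwell_components)
        if not comps:
            raise ValueError("dwell_components must not be empty")
        fracs = np.array([f for f, _ in comps])
        taus = np.array([t for _, t in comps])
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("dwell-component fractions must sum to 1")
        if (fracs < 0).any() or (taus <= 0).any():
            raise ValueError("dwell-component fractions must be >= 0 and "
                             "residence times > 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        object.__setattr__(self, "dwell_components", comps)
        object.__setattr__(self, "field_size",
                           (int(self.field_size[0]), int(self.field_size[1])))

    # -- unit helpers -----------------------------------------------------
    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size / 1000.0

    def diffusion_step_px(self, d_um2_s: float, dt: float) -> float:
        """Per-axis Brownian std (pixels) for coefficient ``d`` over ``dt``."""
        return np.sqrt(2.0 * d_um2_s * dt) / self.pixel_size_um

    # -- (de)serialisation ------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["field_size"] = list(d["field_size"])
        d["dwell_components"] = [list(c) for c in d["dwell_components"]]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        if "dwell_components" in d:
            d["dwell_components"] = tuple(tuple(c) for c in d["dwell_components"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-molecule truth underlying a simulated movie.

    ``molecules`` has one row per molecule: molecule_id, state ("bound" or
    "diffusing"), dwell_s (NaN for diffusing), bleach_frame (first frame at
    which the fluorophore is dark; ``n_frames`` if it never bleaches).
    ``substeps`` holds the noiseless sub-step positions inside each exposure
    (molecule_id, frame, substep, x_px, y_px) used for blur rendering.
    """

    molecules: pd.DataFrame
    substeps: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore


def simulate_dwell_times(
    components: Sequence[tuple[float, float]],
    n: int,
    seed: int | np.random.Generator | None = None,
    frame_interval: float = 0.5,
) -> DwellDataset:
    """Draw i.i.d. residence times from an exponential mixture.

    ``components`` is a sequence of ``(fraction_i, tau_i)`` pairs with
    fractions summing to 1; each sample has probability ``fraction_i`` of
    being Exponential(mean ``tau_i``).
    """
    comps = [(float(f), float(t)) for f, t in components]
    if not comps:
        raise ValueError("components must not be empty")
    fracs = np.array([f for f, _ in comps])
    taus = np.array([t for _, t in comps])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("component fractions must sum to 1")
    if (taus <= 0).any():
        raise ValueError("residence times must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(comps), size=n, p=fracs / fracs.sum())
    dwells = rng.exponential(scale=taus[which])
    return DwellDataset(dwells=dwells, frame_interval=frame_interval)


def _draw_dwell(rng: np.random.Generator, comps) -> float:
    fracs = np.array([f for f, _ in comps])
    idx = rng.choice(len(comps), p=fracs / fracs.sum())
    return float(rng.exponential(scale=comps[idx][1]))


def simulate_trajectories(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate two-state Brownian trajectories under ``config``.

    Each molecule is assigned bound/diffusing with probability
    ``fraction_bound``.  Positions evolve by 2D Brownian increments with
    per-axis variance ``2 D dt`` at each sub-step; the reported per-frame
    position is the true position at the start of the exposure plus isotropic
    Gaussian localization noise of std ``localization_sigma``.  Bound
    molecules unbind after a residence time drawn from the configured
    exponential mixture and are then censored (no re-binding).  Fluorophores
    bleach with rate ``bleach_rate`` (s^-1).  Reflecting boundaries keep
    molecules inside the field.

    Returns
    -------
    trajectories : DataFrame
        Columns molecule_id, frame, x_px, y_px, state, dwell_s.
    truth : GroundTruth
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    rows_f, cols_f = config.field_size
    n_sub = N_SUBSTEPS
    dt_sub = config.exposure / n_sub
    dt_gap = config.frame_interval - config.exposure
    sigma_loc_px = config.localization_sigma / config.pixel_size
    margin = 4.0  # keep initial positions clear of the border

    traj_rows = []
    mol_rows = []
    sub_rows = []

    for mid in range(config.n_molecules):
        bound = rng.random() < config.fraction_bound
        state = "bound" if bound else "diffusing"
        d_coef = config.d_bound if bound else config.d_free
        step_sub = config.diffusion_step_px(d_coef, dt_sub)
        step_gap = config.diffusion_step_px(d_coef, dt_gap) if dt_gap > 0 else 0.0

        dwell = _draw_dwell(rng, config.dwell_components) if bound else np.nan
        if config.bleach_rate > 0:
            bleach_t = rng.exponential(1.0 / config.bleach_rate)
            bleach_frame = int(np.ceil(bleach_t / config.frame_interval))
        else:
            bleach_frame = config.n_frames
        bleach_frame = min(bleach_frame, config.n_frames)

        # number of frames in which the molecule is visible
        if bound:
            n_vis = int(np.ceil(dwell / config.frame_interval))
        else:
            n_vis = config.n_frames
        n_vis = max(1, min(n_vis, bleach_frame, config.n_frames))

        x = margin + rng.random() * (cols_f - 2 * margin)
        y = margin + rng.random() * (rows_f - 2 * margin)

        for frame in range(n_vis):
            # reported position: truth at exposure start + localization noise
            rx = x + rng.normal(0.0, sigma_loc_px) if sigma_loc_px > 0 else x
            ry = y + rng.normal(0.0, sigma_loc_px) if sigma_loc_px > 0 else y
            traj_rows.append((mid, frame, rx, ry, state, dwell))
            for s in range(n_sub):
                sub_rows.append((mid, frame, s, x, y))
                dx, dy = rng.normal(0.0, step_sub, size=2) if step_sub > 0 else (0.0, 0.0)
                x, y = _reflect(x + dx, cols_f), _reflect(y + dy, rows_f)
            if step_gap > 0:
                dx, dy = rng.normal(0.0, step_gap, size=2)
                x, y = _reflect(x + dx, cols_f), _reflect(y + dy, rows_f)

        mol_rows.append((mid, state, dwell, bleach_frame))

    trajectories = pd.DataFrame(
        traj_rows, columns=["molecule_id", "frame", "x_px", "y_px", "state", "dwell_s"]
    )
    molecules = pd.DataFrame(
        mol_rows, columns=["molecule_id", "state", "dwell_s", "bleach_frame"]
    )
    substeps = pd.DataFrame(
        sub_rows, columns=["molecule_id", "frame", "substep", "x_px", "y_px"]
    )
    return trajectories, GroundTruth(molecules=molecules, substeps=substeps,
                                     config=config)


def _reflect(v: float, size: float) -> float:
    """Reflecting boundary on [0, size)."""
    period = 2.0 * size
    v = v % period
    return period - v if v >= size else v


def render_movie(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render a uint16 movie from simulated ground truth.

    Each frame integrates every visible emitter's photons over the exposure by
    summing an isotropic Gaussian PSF at each of its sub-step positions
    (``photons_per_molecule / N_SUBSTEPS`` per sub-step), so fast molecules at
    long exposure are motion-blurred over a region of roughly
    ``sqrt(4 D exposure)``.  A constant mean background is added, each pixel
    is Poisson-sampled at the photon level and the result is scaled by
    ``em_gain`` to camera counts.

    Returns an array of shape ``(n_frames, rows, cols)``, dtype uint16.
    """
    config = config or truth.config
    if config is None:
        raise ValueError("a SimulationConfig is required to render")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    rows_f, cols_f = config.field_size
    psf_px = config.psf_sigma / config.pixel_size
    support = int(np.ceil(4 * psf_px))
    if 2 * support + 1 > min(rows_f, cols_f):
        raise ValueError("field_size too small for the PSF support")

    expected = np.full((config.n_frames, rows_f, cols_f),
                       float(config.background_level))
    photons_sub = config.photons_per_molecule / N_SUBSTEPS

    sub = truth.substeps
    frames = sub["frame"].to_numpy()
    xs = sub["x_px"].to_numpy()
    ys = sub["y_px"].to_numpy()

    mol = truth.molecules.set_index("molecule_id")
    bleach = mol.loc[sub["molecule_id"].to_numpy(), "bleach_frame"].to_numpy()
    visible = frames < bleach

    for f, x, y in zip(frames[visible], xs[visible], ys[visible]):
        if f >= config.n_frames:
            continue
        _add_gaussian(expected[f], x, y, photons_sub, psf_px, support)

    movie = rng.poisson(expected) * config.em_gain
    return np.clip(movie, 0, np.iinfo(np.uint16).max).astype(np.uint16)


def _add_gaussian(frame: np.ndarray, x: float, y: float, amplitude_photons: float,
                  sigma_px: float, support: int) -> None:
    """Accumulate an integrated-Gaussian spot onto ``frame`` in place."""
    rows, cols = frame.shape
    r0 = max(int(np.floor(y)) - support, 0)
    r1 = min(int(np.floor(y)) + support + 1, rows)
    c0 = max(int(np.floor(x)) - support, 0)
    c1 = min(int(np.floor(x)) + support + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None]
    xx = np.arange(c0, c1)[None, :]
    g = np.exp(-(((xx - x) ** 2) + ((yy - y) ** 2)) / (2.0 * sigma_px**2))
    g *= amplitude_photons / (2.0 * np.pi * sigma_px**2)
    frame[r0:r1, c0:c1] += g
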