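"""Lightweight containers shared between the simulator, the tracker and the
fitting models.

Jump-distance and dwell-time datasets are deliberately thin: a numpy array of
magnitudes/durations plus the acquisition metadata the downstream mixture
models need (lag time, frame interval, censoring flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class JumpDistanceDataset:
    """Pooled per-lag displacement magnitudes from a set of trajectories.

    Attributes
    ----------
    jumps : ndarray
        Displacement magnitudes in micrometres, all >= 0.
    lag_s : float
        The time lag separating the paired localizations, in seconds.
    """

    jumps: np.ndarray
    lag_s: float

    def __post_init__(self) -> None:
        jumps = np.asarray(self.jumps, dtype=float)
        if jumps.ndim != 1:
            raise ValueError("jumps must be a 1-D array of magnitudes")
        if jumps.size and jumps.min() < 0:
            raise ValueError("jump distances must be non-negative")
        if not np.isfinite(self.lag_s) or self.lag_s <= 0:
            raise ValueError("lag_s must be positive and finite")
        object.__setattr__(self, "jumps", jumps)

    def __len__(self) -> int:
        return self.jumps.size


@dataclass(frozen=True)
class DwellDataset:
    """Binding-event durations measured on a frame grid.

    Attributes
    ----------
    dwells : ndarray
        Durations in seconds. For track-derived data these are non-negative
        multiples of ``frame_interval``; simulated data may be continuous.
    frame_interval : float
        Acquisition frame interval in seconds (the survival-curve grid step).
    censored : ndarray of bool
        True where the event is right-censored (the trajectory reached the
        last movie frame, so the dwell is a lower bound).
    """

    dwells: np.ndarray
    frame_interval: float
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dwells = np.asarray(self.dwells, dtype=float)
        if dwells.ndim != 1:
            raise ValueError("dwells must be a 1-D array of durations")
        if dwells.size and dwells.min() < 0:
            raise ValueError("dwell times must be non-negative")
        if not np.isfinite(self.frame_interval) or self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive and finite")
        censored = self.censored
        if censored is None:
            censored = np.zeros(dwells.size, dtype=bool)
        censored = np.asarray(censored, dtype=bool)
        if censored.shape != dwells.shape:
            raise ValueError("censored flags must match dwells in length")
        object.__setattr__(self, "dwells", dwells)
        object.__setattr__(self, "censored", censored)

    def __len__(self) -> int:
        return self.dwells.size

    @property
    def uncensored(self) -> np.ndarray:
        """Durations of events observed in full."""
        return self.dwells[~self.censored]

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())
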