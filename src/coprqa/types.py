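"""Core domain containers shared across the pipeline.

Conventions: the laboratory frame has its origin midway between the two
force plates, ML = x (participant's rightward positive), AP = y (forward
positive). All positions are expressed in centimetres, forces in newtons
and moments in newton-metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CONDITIONS = ("Free", "RF", "RP")


@dataclass
class TrialMeta:
    """Identity of a trial: participant, condition, trial index (0-based)."""

    participant: str = "P00"
    condition: str = "Free"
    trial: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class PlateRecording:
    """Raw six-component recording from one force plate.

    forces: (N, 3) array of Fx, Fy, Fz in N; moments: (N, 3) array of
    Mx, My, Mz in N*m, both about the plate origin. ``origin_lab`` is the
    (x, y) position of the plate origin in the lab frame (cm) and
    ``surface_offset`` the vertical distance from the plate origin to its
    top surface (cm). Fz may drop to near zero during unloaded epochs;
    downstream COP extraction guards those samples.
    """

    forces: np.ndarray
    moments: np.ndarray
    rate_hz: float
    origin_lab: tuple[float, float] = (0.0, 0.0)
    surface_offset: float = 0.0
    side: str = "left"

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise ValueError("forces must be an (N, 3) array: Fx, Fy, Fz")
        if self.moments.shape != self.forces.shape:
            raise ValueError("moments must match forces in shape (Mx, My, Mz)")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def fz(self) -> np.ndarray:
        return self.forces[:, 2]


@dataclass
class MarkerTrajectory:
    """3D trajectory of a single passive marker, positions in cm."""

    xyz: np.ndarray
    rate_hz: float
    label: str = "right_wrist"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (N, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("marker coordinates must be finite")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")

    @property
    def ml(self) -> np.ndarray:
        """Mediolateral (x) component, rightward positive."""
        return self.xyz[:, 0]

    @property
    def ap(self) -> np.ndarray:
        return self.xyz[:, 1]


@dataclass
class PlateCop:
    """Per-plate COP in the lab frame with the plate's vertical load.

    ``valid`` flags samples where the vertical force exceeded the minimum
    load for a trustworthy COP.
    """

    ml: np.ndarray
    ap: np.ndarray
    fz: np.ndarray
    valid: np.ndarray
    rate_hz: float
    side: str = "left"

    def __post_init__(self) -> None:
        n = len(self.ml)
        if not (len(self.ap) == len(self.fz) == len(self.valid) == n):
            raise ValueError("ml, ap, fz, valid must have equal length")


@dataclass
class CopTrajectory:
    """Total-body COP trajectory: the pipeline's central object.

    ml/ap in cm, expressed in the lab frame centred between the two
    plates; ``valid`` marks samples where at least one plate carried load.
    """

    ml: np.ndarray
    ap: np.ndarray
    rate_hz: float
    valid: np.ndarray | None = None
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.shape != self.ap.shape or self.ml.ndim != 1:
            raise ValueError("ml and ap must be 1D arrays of equal length")
        if self.valid is None:
            self.valid = np.ones(self.ml.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.ml.shape:
                raise ValueError("valid mask must match ml/ap length")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.ml)

    def segment(self, start: int, end: int) -> "CopTrajectory":
        """Half-open sample slice [start, end) keeping rate and metadata."""
        return CopTrajectory(
            ml=self.ml[start:end],
            ap=self.ap[start:end],
            rate_hz=self.rate_hz,
            valid=self.valid[start:end],
            meta=self.meta,
        )


@dataclass
class CycleSet:
    """Ordered manipulation-phase intervals within one trial.

    Intervals are half-open [start, end) sample index pairs at the
    kinematic rate, non-overlapping and strictly increasing.
    """

    intervals: list[tuple[int, int]]
    rate_hz: float
    n_expected: int = 5

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if not end > start:
                raise ValueError(f"empty interval [{start}, {end})")
            if start <= prev_end - 1 or start < 0:
                raise ValueError("intervals must be non-overlapping and increasing")
            if start < prev_end:
                raise ValueError("intervals must be non-overlapping and increasing")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def lengths(self) -> np.ndarray:
        return np.array([end - start for start, end in self.intervals], dtype=int)

    def durations_s(self) -> np.ndarray:
        return self.lengths() / self.rate_hz


def as_series(x: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1D series")
    return arr
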