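"""Movement-cycle segmentation from the right-wrist marker.

Each repetition of the manipulation task ends with the hand returning
the object to its station on the participant's right, so the completion
instant is the local maximum of the wrist's mediolateral (rightward
positive) coordinate. Within each cycle only the manipulation phase —
when the hand is displaced leftward, away from the rest/grasp station —
enters the analysis; rest, pick-up and release epochs are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import find_peaks

from .types import CycleSet, MarkerTrajectory


class SegmentationError(RuntimeError):
    """Raised when no usable cycle structure can be found in a trial."""


def detect_cycle_boundaries(
    wrist: MarkerTrajectory,
    n_expected: int = 5,
    prominence_frac: float = 0.10,
) -> np.ndarray:
    """Find repetition-completion instants on the wrist ML coordinate.

    A first permissive peak pass (prominence >= ``prominence_frac`` of
    the trial ML range) establishes the typical inter-peak spacing; a
    second pass additionally requires peaks to be at least half the
    median spacing apart, which suppresses jitter doublets without
    assuming a fixed cycle duration.

    Returns the boundary sample indices (0-based). Emits a warning if
    fewer than ``n_expected - 1`` boundaries are found and raises
    :class:`SegmentationError` if none are.
    """
    ml = wrist.ml
    ml_range = float(np.ptp(ml))
    if ml_range == 0.0:
        raise SegmentationError("wrist ML coordinate is constant: no cycles found")
    prominence = prominence_frac * ml_range
    peaks, _ = find_peaks(ml, prominence=prominence)
    if peaks.size == 0:
        raise SegmentationError("no wrist ML peaks above prominence threshold")
    if peaks.size > 1:
        d_min = 0.5 * float(np.median(np.diff(peaks)))
        peaks, _ = find_peaks(ml, prominence=prominence, distance=max(d_min, 1))
    if peaks.size < n_expected - 1:
        warnings.warn(
            f"found {peaks.size} cycle boundaries, expected about {n_expected}; "
            "returning partial segmentation",
            stacklevel=2,
        )
    return peaks.astype(int)


def extract_manipulation_phases(
    boundaries: np.ndarray,
    wrist: MarkerTrajectory,
    n_expected: int = 5,
    depth_frac: float = 0.8,
) -> CycleSet:
    """Restrict each cycle to its manipulation phase.

    Cycle k spans the samples between consecutive completion boundaries
    (the first cycle starts at sample 0). Within a cycle, the hand is
    considered "at the task" while the wrist ML coordinate is left of

        theta = rest_ml - depth_frac * (rest_ml - min_ml)

    where rest_ml is the rightmost and min_ml the leftmost wrist ML value
    of that cycle; the manipulation interval is the [first, last) sample
    below theta. Cycles whose interval comes out empty are dropped with a
    warning.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size == 0:
        raise SegmentationError("no boundaries supplied")
    ml = wrist.ml
    edges = np.concatenate([[0], boundaries])
    intervals: list[tuple[int, int]] = []
    for c0, c1 in zip(edges[:-1], edges[1:]):
        if c1 <= c0 + 1:
            continue
        seg = ml[c0:c1]
        rest_ml = float(seg.max())
        min_ml = float(seg.min())
        if rest_ml == min_ml:
            warnings.warn(f"cycle [{c0}, {c1}) has flat wrist ML; dropped", stacklevel=2)
            continue
        theta = rest_ml - depth_frac * (rest_ml - min_ml)
        below = np.flatnonzero(seg < theta)
        if below.size == 0:
            warnings.warn(
                f"cycle [{c0}, {c1}) never crosses the manipulation threshold; dropped",
                stacklevel=2,
            )
            continue
        intervals.append((c0 + int(below[0]), c0 + int(below[-1]) + 1))
    if not intervals:
        raise SegmentationError("all cycles dropped: no manipulation phase found")
    return CycleSet(intervals=intervals, rate_hz=wrist.rate_hz, n_expected=n_expected)


def segment_trial(
    wrist: MarkerTrajectory,
    n_expected: int = 5,
    prominence_frac: float = 0.10,
    depth_frac: float = 0.8,
) -> CycleSet:
    """Boundary detection followed by manipulation-phase extraction."""
    boundaries = detect_cycle_boundaries(
        wrist, n_expected=n_expected, prominence_frac=prominence_frac
    )
    return extract_manipulation_phases(
        boundaries, wrist, n_expected=n_expected, depth_frac=depth_frac
    )
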