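"""Linear COP sway statistics, computed per manipulation cycle.

Four stabilogram measures summarise each cycle's COP segment:

* mean distance (cm) — mean radial distance from the segment centroid;
* mean velocity (cm/s) — total path length over segment duration;
* 95% confidence-ellipse area (cm^2) — pi * chi2_{2,0.95} * sqrt(l1*l2)
  with l1, l2 the eigenvalues of the 2x2 sample covariance of (ML, AP);
* sway area (cm^2/s) — area swept per unit time by the centroid-to-COP
  vector, accumulated triangle-wise (shoelace) over consecutive samples.

Invalid samples inside a cycle are dropped, not interpolated: position
statistics use the valid subset, and the path-length sum for mean
velocity skips chords that bridge a gap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CopTrajectory, CycleSet

#: chi-square quantile at 0.95 with 2 degrees of freedom.
CHI2_2_95 = 5.991464547107979

SWAY_COLUMNS = ("mdist_cm", "mvelo_cm_s", "area_ce_cm2", "area_sw_cm2_s")


def _valid_xy(segment: CopTrajectory) -> tuple[np.ndarray, np.ndarray]:
    m = segment.valid
    return segment.ml[m], segment.ap[m]


def mean_distance(segment: CopTrajectory) -> float:
    """Mean radial distance (cm) of the COP from the segment centroid."""
    x, y = _valid_xy(segment)
    if x.size < 2:
        return float("nan")
    return float(np.mean(np.hypot(x - x.mean(), y - y.mean())))


def mean_velocity(segment: CopTrajectory) -> float:
    """Total COP path length divided by segment duration (cm/s).

    Duration is (N-1)/rate over the full segment; chords spanning an
    invalid sample are excluded from the path length.
    """
    if len(segment) < 2:
        return float("nan")
    ok = segment.valid[:-1] & segment.valid[1:]
    if not ok.any():
        return float("nan")
    dx = np.diff(segment.ml)[ok]
    dy = np.diff(segment.ap)[ok]
    duration = (len(segment) - 1) / segment.rate_hz
    return float(np.sum(np.hypot(dx, dy)) / duration)


def confidence_ellipse_area(segment: CopTrajectory) -> float:
    """Area (cm^2) of the 95% bivariate-normal confidence ellipse.

    Uses the large-sample chi-square form pi * 5.991 * sqrt(det(S)) on
    the sample covariance S of (ML, AP). A rank-deficient covariance
    (perfectly collinear sway) yields area 0.
    """
    x, y = _valid_xy(segment)
    if x.size < 3:
        return float("nan")
    cov = np.cov(np.vstack([x, y]))
    det = float(np.linalg.det(cov))
    if det <= 0:
        return 0.0
    return float(np.pi * CHI2_2_95 * np.sqrt(det))


def sway_area(segment: CopTrajectory) -> float:
    """Area swept per unit time (cm^2/s) about the segment centroid.

    Shoelace accumulation (1/2T) * sum |x_{n+1} y_n - x_n y_{n+1}| on
    centroid-centred coordinates; consecutive-sample pairs bridging an
    invalid sample are skipped. T is the full segment duration.
    """
    if len(segment) < 3:
        return float("nan")
    m = segment.valid
    if m.sum() < 3:
        return float("nan")
    x = segment.ml - segment.ml[m].mean()
    y = segment.ap - segment.ap[m].mean()
    ok = m[:-1] & m[1:]
    cross = np.abs(x[1:] * y[:-1] - x[:-1] * y[1:])[ok]
    duration = (len(segment) - 1) / segment.rate_hz
    return float(np.sum(cross) / (2.0 * duration))


def cycle_metrics(cop: CopTrajectory, cycles: CycleSet) -> pd.DataFrame:
    """All four sway metrics for every manipulation cycle of a trial.

    Returns a long-form frame with one row per cycle, keyed by
    participant / condition / trial / cycle.
    """
    rows = []
    for k, (start, end) in enumerate(cycles.intervals):
        seg = cop.segment(start, end)
        rows.append(
            {
                "participant": cop.meta.participant,
                "condition": cop.meta.condition,
                "trial": cop.meta.trial,
                "cycle": k,
                "duration_s": (end - start) / cop.rate_hz,
                "mdist_cm": mean_distance(seg),
                "mvelo_cm_s": mean_velocity(seg),
                "area_ce_cm2": confidence_ellipse_area(seg),
                "area_sw_cm2_s": sway_area(seg),
            }
        )
    return pd.DataFrame(rows)


def aggregate(per_cycle: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle -> per-trial -> per-participant-per-condition means.

    Cycles are averaged within each trial, then the trial means are
    averaged within each condition, giving one value per participant x
    condition x metric (unweighted at both levels). Participants with a
    condition contributing no valid cycle keep a NaN cell, which the
    statistics stage treats as an incomplete block.
    """
    metrics = [c for c in SWAY_COLUMNS if c in per_cycle.columns]
    extra = [c for c in per_cycle.columns if c not in metrics
             and c not in ("participant", "condition", "trial", "cycle", "duration_s")
             and pd.api.types.is_numeric_dtype(per_cycle[c])]
    value_cols = metrics + extra
    per_trial = (
        per_cycle.groupby(["participant", "condition", "trial"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    per_condition = (
        per_trial.groupby(["participant", "condition"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    return per_condition
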