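"""Force-plate kinetics: per-plate COP, two-plate combination, resampling.

A plate measures the ground reaction force (Fx, Fy, Fz) and the moment
(Mx, My, Mz) about its own origin. With the origin a vertical distance h
below the top surface, the point of application of the vertical load on
the surface satisfies

    COPx = (-My - Fx * h) / Fz      COPy = (Mx - Fy * h) / Fz

in plate coordinates (SI units), translated into the lab frame by the
plate-origin offset. Samples with |Fz| below a minimum load are flagged
invalid rather than propagating a division blow-up.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import CopTrajectory, PlateCop, PlateRecording, TrialMeta

#: Minimum vertical load (N) for a trustworthy per-plate COP sample.
FZ_MIN_N = 20.0


def cop_from_plate(rec: PlateRecording, fz_min: float = FZ_MIN_N) -> PlateCop:
    """Extract the per-plate COP trajectory in lab-frame cm.

    Parameters
    ----------
    rec
        Plate recording with forces in N, moments in N*m and geometry
        (``origin_lab``, ``surface_offset``) in cm.
    fz_min
        Vertical-load validity threshold in N; samples with
        ``|Fz| < fz_min`` get NaN coordinates and ``valid=False``.

    Raises
    ------
    ValueError
        If no sample carries load (entire recording unloaded).
    """
    fx, fy, fz = rec.forces.T
    mx, my, _ = rec.moments.T
    valid = np.abs(fz) >= fz_min
    if not valid.any():
        raise ValueError(
            f"unusable plate recording ({rec.side}): no sample with |Fz| >= {fz_min} N"
        )
    h_m = rec.surface_offset / 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cop_x_m = (-my - fx * h_m) / fz
        cop_y_m = (mx - fy * h_m) / fz
    ml = cop_x_m * 100.0 + rec.origin_lab[0]
    ap = cop_y_m * 100.0 + rec.origin_lab[1]
    ml[~valid] = np.nan
    ap[~valid] = np.nan
    return PlateCop(ml=ml, ap=ap, fz=fz, valid=valid, rate_hz=rec.rate_hz, side=rec.side)


def combine_cop(
    left: PlateCop, right: PlateCop, meta: TrialMeta | None = None
) -> CopTrajectory:
    """Total-body COP as the load-weighted average of the two plate COPs.

    Per sample the weights are the instantaneous vertical forces clamped
    at zero. Where only one plate is valid the total equals that plate's
    COP (single-support); where neither is, the sample is flagged invalid.
    """
    if len(left.ml) != len(right.ml):
        raise ValueError("left and right plate series must have equal length")
    if left.rate_hz != right.rate_hz:
        raise ValueError("left and right plate rates differ")

    w_l = np.where(left.valid, np.clip(left.fz, 0.0, None), 0.0)
    w_r = np.where(right.valid, np.clip(right.fz, 0.0, None), 0.0)
    w_sum = w_l + w_r

    n = len(left.ml)
    ml = np.full(n, np.nan)
    ap = np.full(n, np.nan)

    weighted = w_sum > 0  # zero weights contribute nothing, so single support is automatic
    num_ml = np.where(w_l > 0, left.ml * w_l, 0.0) + np.where(w_r > 0, right.ml * w_r, 0.0)
    num_ap = np.where(w_l > 0, left.ap * w_l, 0.0) + np.where(w_r > 0, right.ap * w_r, 0.0)
    ml[weighted] = num_ml[weighted] / w_sum[weighted]
    ap[weighted] = num_ap[weighted] / w_sum[weighted]

    # valid plates but both clamped to zero load: unweighted mean of the valid COPs
    degenerate = ~weighted & (left.valid | right.valid)
    if degenerate.any():
        stack_ml = np.where(left.valid, left.ml, np.nan), np.where(right.valid, right.ml, np.nan)
        stack_ap = np.where(left.valid, left.ap, np.nan), np.where(right.valid, right.ap, np.nan)
        ml[degenerate] = np.nanmean(np.column_stack(stack_ml), axis=1)[degenerate]
        ap[degenerate] = np.nanmean(np.column_stack(stack_ap), axis=1)[degenerate]

    valid = weighted | degenerate

    return CopTrajectory(
        ml=ml, ap=ap, rate_hz=left.rate_hz, valid=valid, meta=meta or TrialMeta()
    )


def resample_to(series: np.ndarray, from_hz: float, to_hz: float) -> np.ndarray:
    """Anti-aliased decimation from ``from_hz`` to ``to_hz``.

    ``from_hz`` must be an integer multiple of ``to_hz``. A zero-phase
    (forward-backward) 4th-order Butterworth low-pass with cutoff at
    0.4 * to_hz precedes the down-pick, so velocities derived downstream
    carry no filter phase lag. Output length is floor(N / k) with
    k = from_hz / to_hz. Works on 1D series or (N, C) channel stacks.
    """
    series = np.asarray(series, dtype=float)
    ratio = from_hz / to_hz
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"from_hz ({from_hz}) must be an integer multiple of to_hz ({to_hz})"
        )
    if k == 1:
        return series.copy()
    sos = signal.butter(4, 0.4 * to_hz, btype="low", fs=from_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, series, axis=0)
    n_out = series.shape[0] // k
    return filtered[: n_out * k : k]


def resample_cop(cop: CopTrajectory, to_hz: float) -> CopTrajectory:
    """Decimate a COP trajectory to the kinematic rate.

    Invalid samples are bridged by linear interpolation before filtering
    (a filtfilt across NaN would poison the whole record) and re-flagged
    afterwards at the decimated rate.
    """
    ml = _fill_invalid(cop.ml, cop.valid)
    ap = _fill_invalid(cop.ap, cop.valid)
    stacked = np.column_stack([ml, ap])
    out = resample_to(stacked, cop.rate_hz, to_hz)
    k = int(round(cop.rate_hz / to_hz))
    valid = cop.valid[: out.shape[0] * k : k]
    return CopTrajectory(
        ml=out[:, 0], ap=out[:, 1], rate_hz=to_hz, valid=valid, meta=cop.meta
    )


def _fill_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return x
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise ValueError("cannot resample a fully invalid COP trajectory")
    return np.interp(np.arange(len(x)), idx, x[idx])
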