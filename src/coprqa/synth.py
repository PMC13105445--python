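"""Synthetic force-plate and wrist-marker recordings for a full cohort.

The generator emulates the study conditions of a standing human
cyclically manipulating an object at a workbench, with or without a
collaborating robot arm: 14 participants x 3 conditions (Free, RF, RP)
x 3 trials x 5 manipulation repetitions. Each trial is built as

* a ground-truth total COP: per cycle, a smooth quasi-periodic loop in
  the (ML, AP) plane (amplitude and period jittered cycle-to-cycle)
  gated by a manipulation envelope, superimposed on low-pass-filtered
  Gaussian drift that emulates quiet-stance sway; during rest the COP
  collapses onto the stance baseline;
* a right-wrist ML trajectory with one rightward maximum per repetition
  (the hand returning the object to its station), whose leftward
  plateau marks the manipulation phase;
* two 6-channel plate recordings synthesised by exact inversion of the
  plate COP kinetics for a stated body weight split dynamically across
  the plates, so extracting the COP from the emitted channels
  reproduces the ground truth to numerical precision.

Condition presets differ chiefly in the anteroposterior loop range:
free manipulation keeps the COP within ~5 cm in both directions while
robot-assisted manipulation roughly doubles to triples the AP range.
Loop amplitudes are calibrated so cohort-mean sway metrics land near
mean distances of ~1.7 cm (Free) and ~2.3-2.4 cm (robot conditions).

All randomness flows from a single seed through numpy SeedSequence
spawning: cohort seed -> participant -> trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import signal

from .types import (
    CONDITIONS,
    CopTrajectory,
    MarkerTrajectory,
    PlateRecording,
    TrialMeta,
)

GRAVITY = 9.81
BODY_MASS_KG = 71.0  # cohort mean body mass
STANCE_WIDTH_CM = 20.0  # lateral separation of the per-plate COPs
PLATE_OFFSET_CM = 10.0  # plate origins at (-10, 0) and (+10, 0)
SURFACE_OFFSET_CM = 4.0  # plate origin sits below the top surface

WRIST_SIDE_ML = 15.0  # cm, hand resting at the participant's side
WRIST_STATION_ML = 30.0  # cm, object station on the far right
WRIST_TASK_ML = 0.0  # cm, hand over the workpiece
WRIST_PEAK_BUMP = 2.0  # cm overshoot marking repetition completion

# within-cycle phase fractions: rest, pick-up, manipulation, release
PHASE_REST, PHASE_PICKUP, PHASE_MANIP, PHASE_RELEASE = 0, 1, 2, 3
TRANSITION_FRAC = 0.04  # pick-up and release ramps, each


@dataclass(frozen=True)
class ConditionPreset:
    """Target sway geometry and timing for one experimental condition.

    Ranges are peak-to-peak loop excursions in cm. ``drift_cm`` is the
    RMS of the low-pass quiet-stance drift, band-limited at
    ``drift_bw_hz``. ``rest_fraction`` is the share of each cycle spent
    outside the manipulation phase (rest plus the two transfers).
    """

    name: str
    ap_range: float
    ml_range: float
    cycle_period_s: float = 8.0
    period_jitter: float = 0.06
    amp_jitter: float = 0.12
    drift_cm: float = 0.45
    drift_bw_hz: float = 1.0
    rest_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.ap_range <= 0 or self.ml_range <= 0:
            raise ValueError("loop ranges must be positive")
        if not 0 <= self.rest_fraction < 0.5:
            raise ValueError("rest_fraction must be in [0, 0.5)")
        if self.drift_cm > min(self.ap_range, self.ml_range):
            raise ValueError(
                "drift amplitude exceeds the loop range; preset rejected"
            )


DEFAULT_PRESETS: dict[str, ConditionPreset] = {
    "Free": ConditionPreset(name="Free", ap_range=3.2, ml_range=3.2),
    "RF": ConditionPreset(name="RF", ap_range=5.9, ml_range=3.0),
    "RP": ConditionPreset(name="RP", ap_range=5.6, ml_range=3.0),
}


@dataclass
class SyntheticTrial:
    """One generated trial with its ground truth."""

    left: PlateRecording
    right: PlateRecording
    wrist: MarkerTrajectory
    true_cop: CopTrajectory  # at the plate rate, pre-decimation
    true_boundaries: np.ndarray  # kinematic-rate sample indices
    phase_labels: np.ndarray  # kinematic-rate int labels (PHASE_*)
    preset: ConditionPreset
    meta: TrialMeta
    seed: int


def _lowpass_noise(rng: np.random.Generator, n: int, rate_hz: float,
                   bw_hz: float, rms: float) -> np.ndarray:
    """Band-limited stationary Gaussian drift with the requested RMS."""
    if rms == 0.0 or n < 24:
        return np.zeros(n)
    white = rng.standard_normal(n)
    bw = min(bw_hz, 0.45 * rate_hz)
    sos = signal.butter(2, bw, btype="low", fs=rate_hz, output="sos")
    drift = signal.sosfiltfilt(sos, white)
    sd = drift.std()
    if sd == 0.0:
        return np.zeros(n)
    return drift * (rms / sd)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Cosine ramp 0 -> 1 on x in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(x, 0.0, 1.0)))


def generate_trial(
    preset: ConditionPreset,
    seed: int | np.random.SeedSequence,
    meta: TrialMeta | None = None,
    n_cycles: int = 5,
    rate_plates: float = 500.0,
    rate_kin: float = 250.0,
    sway_scale: float = 1.0,
    period_scale: float = 1.0,
) -> SyntheticTrial:
    """Generate one trial of raw recordings plus ground truth.

    ``sway_scale`` and ``period_scale`` are participant-level random
    effects (1.0 = cohort average) applied to the loop amplitudes/drift
    and to the cycle period respectively.
    """
    if isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(seed)
    else:
        seed_int = int(seed)
        rng = np.random.default_rng(seed_int)
    meta = meta or TrialMeta(condition=preset.name)
    k = int(round(rate_plates / rate_kin))
    if abs(rate_plates / rate_kin - k) > 1e-9:
        raise ValueError("rate_plates must be an integer multiple of rate_kin")

    # --- per-cycle timing ----------------------------------------------
    periods = preset.cycle_period_s * period_scale * np.exp(
        preset.period_jitter * rng.standard_normal(n_cycles)
    )
    cycle_samps = np.maximum((periods * rate_plates).round().astype(int), 24)
    tail = int(round(0.5 * preset.cycle_period_s * rate_plates * 0.2)) + k
    n = int(cycle_samps.sum()) + tail
    t_starts = np.concatenate([[0], np.cumsum(cycle_samps)])

    # per-sample phase label, manipulation loop phase and envelope
    labels = np.full(n, PHASE_REST, dtype=np.int8)
    envelope = np.zeros(n)
    loop_phase = np.zeros(n)
    amp_ml = np.zeros(n)
    amp_ap = np.zeros(n)
    wrist_ml = np.full(n, WRIST_SIDE_ML, dtype=float)
    boundaries_plate = []

    rest_frac = max(preset.rest_fraction - 2 * TRANSITION_FRAC, 0.0)
    for c in range(n_cycles):
        c0, c1 = int(t_starts[c]), int(t_starts[c + 1])
        nc = c1 - c0
        n_rest = int(round(rest_frac * nc))
        n_ramp = max(int(round(TRANSITION_FRAC * nc)), 2)
        n_manip = nc - n_rest - 2 * n_ramp
        i_pick = c0 + n_rest
        i_manip = i_pick + n_ramp
        i_rel = i_manip + n_manip
        labels[i_pick:i_manip] = PHASE_PICKUP
        labels[i_manip:i_rel] = PHASE_MANIP
        labels[i_rel:c1] = PHASE_RELEASE
        boundaries_plate.append(c1)

        # manipulation envelope with cosine edges over the transfers
        s_pick = _smoothstep(np.arange(n_ramp) / n_ramp)
        s_rel = _smoothstep(np.arange(c1 - i_rel) / max(c1 - i_rel, 1))
        envelope[i_pick:i_manip] = s_pick
        envelope[i_manip:i_rel] = 1.0
        envelope[i_rel:c1] = 1.0 - s_rel

        # one closed loop per manipulation phase
        phi = np.zeros(nc)
        span = i_rel - i_pick
        phi[i_pick - c0 : i_rel - c0] = np.linspace(0.0, 2 * np.pi, span, endpoint=False)
        phi[i_rel - c0 :] = 2 * np.pi
        loop_phase[c0:c1] = phi

        jit_ml, jit_ap = np.exp(preset.amp_jitter * rng.standard_normal(2))
        amp_ml[c0:c1] = 0.5 * preset.ml_range * jit_ml
        amp_ap[c0:c1] = 0.5 * preset.ap_range * jit_ap

        # wrist: rest at the side, left transfer, task plateau, rightward
        # return peaking at the object station (repetition completion)
        wiggle = 1.5 * np.sin(3.0 * phi[i_manip - c0 : i_rel - c0])
        wrist_ml[i_pick:i_manip] = WRIST_SIDE_ML - (WRIST_SIDE_ML - WRIST_TASK_ML) * s_pick
        wrist_ml[i_manip:i_rel] = WRIST_TASK_ML + wiggle
        peak_ml = WRIST_STATION_ML + WRIST_PEAK_BUMP
        # accelerating return so the completion peak is a sharp corner
        # (robust argmax under marker noise), then a linear settle
        n_rel = c1 - i_rel
        s_sharp = (np.arange(n_rel) / max(n_rel, 1)) ** 1.5
        wrist_ml[i_rel:c1] = WRIST_TASK_ML + (peak_ml - WRIST_TASK_ML) * s_sharp
        n_settle = min(max(n_ramp, 2), n - c1)
        if n_settle > 0:
            wrist_ml[c1 : c1 + n_settle] = peak_ml - (
                peak_ml - WRIST_SIDE_ML
            ) * (np.arange(n_settle) / n_settle)

    # --- ground-truth COP ----------------------------------------------
    scale = sway_scale
    loop_ml = amp_ml * scale * envelope * (
        np.cos(loop_phase) - 1.0 + 0.15 * (np.cos(3 * loop_phase) - 1.0)
    )
    loop_ap = amp_ap * scale * envelope * (
        np.sin(loop_phase) + 0.20 * np.sin(2 * loop_phase)
    )
    drift_ml = _lowpass_noise(rng, n, rate_plates, preset.drift_bw_hz,
                              preset.drift_cm * scale)
    drift_ap = _lowpass_noise(rng, n, rate_plates, preset.drift_bw_hz,
                              preset.drift_cm * scale)
    cop_ml = loop_ml + drift_ml
    cop_ap = loop_ap + drift_ap
    true_cop = CopTrajectory(ml=cop_ml, ap=cop_ap, rate_hz=rate_plates, meta=meta)

    # --- plate channels by exact inversion -----------------------------
    t = np.arange(n) / rate_plates
    weight_n = BODY_MASS_KG * GRAVITY
    share = 0.5 + 0.15 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    w_l = weight_n * share
    w_r = weight_n - w_l
    cop_l_x = cop_ml - (w_r / weight_n) * STANCE_WIDTH_CM
    cop_r_x = cop_ml + (w_l / weight_n) * STANCE_WIDTH_CM
    left = _plate_from_cop(cop_l_x, cop_ap, w_l, rng, rate_plates,
                           origin=(-PLATE_OFFSET_CM, 0.0), side="left")
    right = _plate_from_cop(cop_r_x, cop_ap, w_r, rng, rate_plates,
                            origin=(PLATE_OFFSET_CM, 0.0), side="right")

    # --- kinematic-rate outputs ----------------------------------------
    wrist_kin = wrist_ml[::k]
    if preset.drift_cm > 0:
        wrist_kin = wrist_kin + 0.03 * rng.standard_normal(wrist_kin.size)
    wrist_xyz = np.column_stack([
        wrist_kin,
        60.0 + 5.0 * envelope[::k],  # forward reach during manipulation
        100.0 + 3.0 * envelope[::k],  # working height
    ])
    wrist = MarkerTrajectory(xyz=wrist_xyz, rate_hz=rate_kin, label="right_wrist")
    boundaries_kin = np.array([min(b // k, wrist_kin.size - 1) for b in boundaries_plate])

    return SyntheticTrial(
        left=left,
        right=right,
        wrist=wrist,
        true_cop=true_cop,
        true_boundaries=boundaries_kin,
        phase_labels=labels[::k].copy(),
        preset=preset,
        meta=meta,
        seed=seed_int,
    )


def _plate_from_cop(
    cop_x_lab: np.ndarray,
    cop_y_lab: np.ndarray,
    fz: np.ndarray,
    rng: np.random.Generator,
    rate_hz: float,
    origin: tuple[float, float],
    side: str,
) -> PlateRecording:
    """Invert the plate-COP kinetics to emit raw 6-channel data."""
    n = cop_x_lab.size
    t = np.arange(n) / rate_hz
    fx = 4.0 * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi))
    fy = 4.0 * np.sin(2 * np.pi * 0.5 * t + rng.uniform(0, 2 * np.pi))
    h_m = SURFACE_OFFSET_CM / 100.0
    x_loc_m = (cop_x_lab - origin[0]) / 100.0
    y_loc_m = (cop_y_lab - origin[1]) / 100.0
    my = -(x_loc_m * fz) - fx * h_m
    mx = y_loc_m * fz + fy * h_m
    mz = 0.5 * np.sin(2 * np.pi * 0.3 * t)
    return PlateRecording(
        forces=np.column_stack([fx, fy, fz]),
        moments=np.column_stack([mx, my, mz]),
        rate_hz=rate_hz,
        origin_lab=origin,
        surface_offset=SURFACE_OFFSET_CM,
        side=side,
    )


@dataclass
class ParticipantEffects:
    """Per-participant random effects drawn once per cohort member."""

    sway_scale: float
    period_scale: float


def participant_effects(rng: np.random.Generator) -> ParticipantEffects:
    # mean-one log-normals so scales stay positive without biasing the
    # cohort mean; sigma=0.3 puts ~0.5-0.6 cm between-subject SD on the
    # group mean-distance, as seen in young adult cohorts
    return ParticipantEffects(
        sway_scale=float(np.exp(0.30 * rng.standard_normal() - 0.045)),
        period_scale=float(np.exp(0.08 * rng.standard_normal() - 0.0032)),
    )


def generate_cohort(
    n_participants: int = 14,
    presets: dict[str, ConditionPreset] | None = None,
    seed: int = 0,
    n_trials: int = 3,
    n_cycles: int = 5,
    rate_plates: float = 500.0,
    rate_kin: float = 250.0,
) -> Iterator[SyntheticTrial]:
    """Lazily yield the full cohort: participants x conditions x trials.

    Trials are yielded in participant-major order with deterministic
    per-trial seeds spawned from the cohort seed.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    presets = presets or DEFAULT_PRESETS
    root = np.random.SeedSequence(seed)
    part_seqs = root.spawn(n_participants)
    for p, pseq in enumerate(part_seqs):
        effects_rng = np.random.default_rng(pseq)
        eff = participant_effects(effects_rng)
        trial_seqs = pseq.spawn(len(presets) * n_trials)
        i = 0
        for cond in presets:
            for trial in range(n_trials):
                meta = TrialMeta(
                    participant=f"P{p + 1:02d}", condition=cond, trial=trial
                )
                yield generate_trial(
                    presets[cond],
                    trial_seqs[i],
                    meta=meta,
                    n_cycles=n_cycles,
                    rate_plates=rate_plates,
                    rate_kin=rate_kin,
                    sway_scale=eff.sway_scale,
                    period_scale=eff.period_scale,
                )
                i += 1
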