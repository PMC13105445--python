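"""Delimited-text readers and writers for recordings and results.

Plate and marker data travel as plain CSV/TSV with a header row (plate
columns Fx, Fy, Fz, Mx, My, Mz; marker columns X, Y, Z) plus a YAML
sidecar declaring rates, plate geometry, units and trial metadata::

    rates: {plates_hz: 500, kinematics_hz: 250}
    units: {force: N, moment: Nm, position: cm}
    plates:
      left:  {origin: [-10.0, 0.0], surface_offset: 4.0}
      right: {origin: [10.0, 0.0], surface_offset: 4.0}
    meta: {participant: P01, condition: Free, trial: 0}

Positions may be declared in mm (converted to cm on read) and moments
in Nmm (converted to N*m).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .types import CopTrajectory, CycleSet, MarkerTrajectory, PlateRecording, TrialMeta

PLATE_COLUMNS = ["Fx", "Fy", "Fz", "Mx", "My", "Mz"]
MARKER_COLUMNS = ["X", "Y", "Z"]

_POS_FACTORS = {"cm": 1.0, "mm": 0.1, "m": 100.0}
_MOM_FACTORS = {"Nm": 1.0, "Nmm": 1e-3}


def read_trial_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "rates" not in cfg or "plates" not in cfg:
        raise ValueError(f"trial config {path}: needs 'rates' and 'plates' sections")
    return cfg


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_plate_csv(path: str | Path, config: dict[str, Any], side: str) -> PlateRecording:
    """Read one plate's channels, applying the declared units and geometry."""
    df = _read_table(path, PLATE_COLUMNS)
    units = config.get("units", {})
    mom = _MOM_FACTORS[units.get("moment", "Nm")]
    pos = _POS_FACTORS[units.get("position", "cm")]
    geom = config["plates"][side]
    return PlateRecording(
        forces=df[["Fx", "Fy", "Fz"]].to_numpy(float),
        moments=df[["Mx", "My", "Mz"]].to_numpy(float) * mom,
        rate_hz=float(config["rates"]["plates_hz"]),
        origin_lab=tuple(np.asarray(geom["origin"], float) * pos),
        surface_offset=float(geom.get("surface_offset", 0.0)) * pos,
        side=side,
    )


def read_marker_csv(path: str | Path, config: dict[str, Any],
                    label: str = "right_wrist") -> MarkerTrajectory:
    df = _read_table(path, MARKER_COLUMNS)
    pos = _POS_FACTORS[config.get("units", {}).get("position", "cm")]
    return MarkerTrajectory(
        xyz=df[MARKER_COLUMNS].to_numpy(float) * pos,
        rate_hz=float(config["rates"]["kinematics_hz"]),
        label=label,
    )


def meta_from_config(config: dict[str, Any]) -> TrialMeta:
    m = config.get("meta", {})
    return TrialMeta(
        participant=str(m.get("participant", "P00")),
        condition=str(m.get("condition", "Free")),
        trial=int(m.get("trial", 0)),
    )


def write_cop_csv(cop: CopTrajectory, path: str | Path) -> None:
    t = np.arange(len(cop)) / cop.rate_hz
    pd.DataFrame(
        {"time_s": t, "ml_cm": cop.ml, "ap_cm": cop.ap, "valid": cop.valid.astype(int)}
    ).to_csv(path, index=False, float_format="%.6f")


def read_cop_csv(path: str | Path, rate_hz: float | None = None,
                 meta: TrialMeta | None = None) -> CopTrajectory:
    df = _read_table(path, ["time_s", "ml_cm", "ap_cm"])
    if rate_hz is None:
        dt = np.diff(df["time_s"].to_numpy(float))
        rate_hz = 1.0 / float(np.median(dt))
    valid = df["valid"].to_numpy(bool) if "valid" in df.columns else None
    return CopTrajectory(
        ml=df["ml_cm"].to_numpy(float),
        ap=df["ap_cm"].to_numpy(float),
        rate_hz=float(rate_hz),
        valid=valid,
        meta=meta or TrialMeta(),
    )


def write_cycles_csv(cycles: CycleSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cycle": range(len(cycles)),
            "start": [s for s, _ in cycles.intervals],
            "end": [e for _, e in cycles.intervals],
            "rate_hz": cycles.rate_hz,
        }
    ).to_csv(path, index=False)


def read_cycles_csv(path: str | Path) -> CycleSet:
    df = _read_table(path, ["start", "end"])
    rate = float(df["rate_hz"].iloc[0]) if "rate_hz" in df.columns else 250.0
    return CycleSet(
        intervals=[(int(s), int(e)) for s, e in zip(df["start"], df["end"])],
        rate_hz=rate,
    )


def read_phase_annotations(path: str | Path, rate_hz: float) -> CycleSet:
    """Manual phase annotations (cycle, start_s, end_s) override the heuristic."""
    df = _read_table(path, ["start_s", "end_s"])
    intervals = [
        (int(round(s * rate_hz)), int(round(e * rate_hz)))
        for s, e in zip(df["start_s"], df["end_s"])
    ]
    return CycleSet(intervals=intervals, rate_hz=rate_hz)


def write_trial_files(trial, out_dir: str | Path) -> dict[str, Path]:
    """Emit one synthetic trial as the CSV/YAML dialect the readers consume.

    Returns the paths written (left/right plates, wrist, config, ground
    truth COP and labels).
    """
    from .synth import SyntheticTrial  # local import to avoid a cycle

    assert isinstance(trial, SyntheticTrial)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{trial.meta.participant}_{trial.meta.condition}_T{trial.meta.trial}"
    paths: dict[str, Path] = {}

    for side, rec in (("left", trial.left), ("right", trial.right)):
        p = out / f"{stem}_{side}.csv"
        pd.DataFrame(
            np.column_stack([rec.forces, rec.moments]), columns=PLATE_COLUMNS
        ).to_csv(p, index=False, float_format="%.6f")
        paths[side] = p

    p = out / f"{stem}_wrist.csv"
    pd.DataFrame(trial.wrist.xyz, columns=MARKER_COLUMNS).to_csv(
        p, index=False, float_format="%.6f"
    )
    paths["wrist"] = p

    cfg = {
        "rates": {
            "plates_hz": float(trial.left.rate_hz),
            "kinematics_hz": float(trial.wrist.rate_hz),
        },
        "units": {"force": "N", "moment": "Nm", "position": "cm"},
        "plates": {
            side: {
                "origin": [float(v) for v in rec.origin_lab],
                "surface_offset": float(rec.surface_offset),
            }
            for side, rec in (("left", trial.left), ("right", trial.right))
        },
        "meta": {
            "participant": trial.meta.participant,
            "condition": trial.meta.condition,
            "trial": trial.meta.trial,
            "seed": trial.seed,
        },
    }
    p = out / f"{stem}.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    paths["config"] = p

    p = out / f"{stem}_truth.csv"
    pd.DataFrame(
        {
            "boundary_kin": pd.Series(trial.true_boundaries),
        }
    ).to_csv(p, index=False)
    paths["truth"] = p
    return paths


def write_cohort(trials, out_dir: str | Path) -> Path:
    """Write a cohort of synthetic trials plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        paths = write_trial_files(trial, out)
        rows.append(
            {
                "participant": trial.meta.participant,
                "condition": trial.meta.condition,
                "trial": trial.meta.trial,
                "left": paths["left"].name,
                "right": paths["right"].name,
                "wrist": paths["wrist"].name,
                "config": paths["config"].name,
                "truth": paths["truth"].name,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
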