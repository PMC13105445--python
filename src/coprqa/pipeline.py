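"""End-to-end orchestration: synth/ingest -> COP -> cycles -> metrics -> stats.

A run is fully described by a :class:`PipelineConfig` (serializable to
YAML); given the same config and seed the emitted CSVs are bitwise
reproducible. Per-trial failures are isolated: the offending trial goes
into an error ledger and the remainder of the cohort is processed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .plates import combine_cop, cop_from_plate, resample_cop
from .rqa import RqaConfig, rqa_frame, run_rqa
from .segmentation import segment_trial
from .stats import comparison_frame, compare_conditions
from .sway import SWAY_COLUMNS, aggregate, cycle_metrics
from .synth import DEFAULT_PRESETS, SyntheticTrial, generate_cohort
from .types import CopTrajectory, TrialMeta

log = logging.getLogger("coprqa")

RQA_METRICS = ("rec", "det", "ratio")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    out_dir: str = "coprqa_out"
    seed: int = 0
    synth: bool = True
    data_dir: str | None = None  # manifest directory when synth=False
    n_participants: int = 14
    n_trials: int = 3
    n_cycles: int = 5
    rate_plates: float = 500.0
    rate_kin: float = 250.0
    n_expected: int = 5
    prominence_frac: float = 0.10
    depth_frac: float = 0.8
    rqa: RqaConfig = field(default_factory=lambda: RqaConfig(downsample=10))
    stats_variant: str = "signed_rank"
    write_intermediates: bool = True
    make_figures: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"config {path}: expected a mapping")
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        if "rqa" in d and isinstance(d["rqa"], dict):
            d["rqa"] = RqaConfig(**d["rqa"])
        return cls(**d)


def cop_from_trial(trial: SyntheticTrial, to_hz: float | None = None) -> CopTrajectory:
    """Plate channels -> combined COP, decimated to the kinematic rate."""
    left = cop_from_plate(trial.left)
    right = cop_from_plate(trial.right)
    cop = combine_cop(left, right, meta=trial.meta)
    to_hz = to_hz or trial.wrist.rate_hz
    if cop.rate_hz != to_hz:
        cop = resample_cop(cop, to_hz)
    return cop


def process_trial(trial: SyntheticTrial, config: PipelineConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One trial through COP extraction, segmentation, sway and RQA."""
    cop = cop_from_trial(trial, to_hz=config.rate_kin)
    cycles = segment_trial(
        trial.wrist,
        n_expected=config.n_expected,
        prominence_frac=config.prominence_frac,
        depth_frac=config.depth_frac,
    )
    sway = cycle_metrics(cop, cycles)
    rqa_results = run_rqa(cop, cycles, config.rqa)
    return sway, rqa_frame(cop, rqa_results)


def _iter_trials(config: PipelineConfig) -> Iterable[SyntheticTrial]:
    if config.synth:
        yield from generate_cohort(
            n_participants=config.n_participants,
            presets=DEFAULT_PRESETS,
            seed=config.seed,
            n_trials=config.n_trials,
            n_cycles=config.n_cycles,
            rate_plates=config.rate_plates,
            rate_kin=config.rate_kin,
        )
        return
    if not config.data_dir:
        raise ValueError("synth=False requires data_dir with a manifest.csv")
    root = Path(config.data_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    for _, row in manifest.iterrows():
        cfg = cio.read_trial_config(root / row["config"])
        meta = cio.meta_from_config(cfg)
        left = cio.read_plate_csv(root / row["left"], cfg, "left")
        right = cio.read_plate_csv(root / row["right"], cfg, "right")
        wrist = cio.read_marker_csv(root / row["wrist"], cfg)
        yield SyntheticTrial(
            left=left, right=right, wrist=wrist,
            true_cop=CopTrajectory(
                ml=np.zeros(1), ap=np.zeros(1), rate_hz=left.rate_hz, meta=meta
            ),
            true_boundaries=np.array([], int),
            phase_labels=np.array([], np.int8),
            preset=DEFAULT_PRESETS.get(meta.condition, DEFAULT_PRESETS["Free"]),
            meta=meta, seed=int(cfg.get("meta", {}).get("seed", 0)),
        )


def aggregate_rqa(rqa_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial RQA -> per-participant-per-condition means, wide by component."""
    wide = rqa_trials.pivot_table(
        index=["participant", "condition", "trial"],
        columns="component", values=list(RQA_METRICS), aggfunc="mean",
    )
    wide.columns = [f"{metric}_{comp}" for metric, comp in wide.columns]
    return (
        wide.reset_index()
        .groupby(["participant", "condition"], sort=True)
        .mean(numeric_only=True)
        .reset_index()
        .drop(columns=["trial"])
    )


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full chain and write the results tree under out_dir.

    Returns a dict with the aggregated frames, the comparison table and
    the per-trial error ledger.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_snapshot.yaml")
    if config.write_intermediates:
        (out / "cop").mkdir(exist_ok=True)
        (out / "cycles").mkdir(exist_ok=True)

    sway_frames: list[pd.DataFrame] = []
    rqa_frames: list[pd.DataFrame] = []
    errors: list[dict[str, Any]] = []
    sample_trial: SyntheticTrial | None = None

    t0 = time.perf_counter()
    for trial in _iter_trials(config):
        key = f"{trial.meta.participant}/{trial.meta.condition}/T{trial.meta.trial}"
        try:
            cop = cop_from_trial(trial, to_hz=config.rate_kin)
            cycles = segment_trial(
                trial.wrist,
                n_expected=config.n_expected,
                prominence_frac=config.prominence_frac,
                depth_frac=config.depth_frac,
            )
            if config.write_intermediates:
                stem = key.replace("/", "_")
                cio.write_cop_csv(cop, out / "cop" / f"{stem}.csv")
                cio.write_cycles_csv(cycles, out / "cycles" / f"{stem}.csv")
            sway_frames.append(cycle_metrics(cop, cycles))
            rqa_frames.append(rqa_frame(cop, run_rqa(cop, cycles, config.rqa)))
            if sample_trial is None:
                sample_trial = trial
        except Exception as exc:  # noqa: BLE001 - isolation contract
            log.warning("trial %s failed: %s", key, exc)
            errors.append(
                {
                    "participant": trial.meta.participant,
                    "condition": trial.meta.condition,
                    "trial": trial.meta.trial,
                    "stage": type(exc).__name__,
                    "error": str(exc),
                }
            )
    log.info("processed cohort in %.1f s (%d failures)", time.perf_counter() - t0,
             len(errors))

    error_frame = pd.DataFrame(
        errors, columns=["participant", "condition", "trial", "stage", "error"]
    )
    error_frame.to_csv(out / "errors.csv", index=False)
    if not sway_frames:
        raise RuntimeError("no trial processed successfully; see errors.csv")

    sway_cycles = pd.concat(sway_frames, ignore_index=True)
    rqa_trials = pd.concat(rqa_frames, ignore_index=True)
    sway_agg = aggregate(sway_cycles)
    rqa_agg = aggregate_rqa(rqa_trials)

    sway_cycles.to_csv(out / "sway_cycles.csv", index=False, float_format="%.6f")
    sway_agg.to_csv(out / "sway.csv", index=False, float_format="%.6f")
    rqa_trials.to_csv(out / "rqa_trials.csv", index=False, float_format="%.6f")
    rqa_agg.to_csv(out / "rqa.csv", index=False, float_format="%.6f")

    comparisons = []
    for metric in SWAY_COLUMNS:
        comparisons.append(
            compare_conditions(sway_agg, metric, variant=config.stats_variant)
        )
    for col in rqa_agg.columns:
        if col in ("participant", "condition"):
            continue
        comparisons.append(
            compare_conditions(rqa_agg, col, variant=config.stats_variant)
        )
    stats_table = comparison_frame(comparisons)
    stats_table.to_csv(out / "stats.csv", index=False, float_format="%.6g")

    if config.make_figures and sample_trial is not None:
        from .figures import make_report

        make_report(out, sway_agg, rqa_agg, stats_table, sample_trial, config)

    return {
        "sway_cycles": sway_cycles,
        "sway": sway_agg,
        "rqa_trials": rqa_trials,
        "rqa": rqa_agg,
        "stats": stats_table,
        "errors": error_frame,
        "comparisons": comparisons,
    }
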