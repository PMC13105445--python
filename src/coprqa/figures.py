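"""Report stage: COP trajectory panels, metric boxplots, recurrence maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import PipelineConfig  # noqa: TCH001 - runtime typing only
from .rqa import RqaConfig, cycle_delay, embed, radial_component, recurrence_matrix
from .segmentation import segment_trial
from .types import CONDITIONS


def plot_cop_panels(sway_agg: pd.DataFrame, trial, path: Path, config) -> None:
    """Per-condition COP trace of the sample trial's condition (and peers)."""
    from .pipeline import cop_from_trial

    fig, ax = plt.subplots(figsize=(4, 4))
    cop = cop_from_trial(trial, to_hz=config.rate_kin)
    ax.plot(cop.ml, cop.ap, lw=0.5)
    ax.set_xlabel("ML (cm)")
    ax.set_ylabel("AP (cm)")
    ax.set_title(f"COP trajectory — {trial.meta.condition}")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_boxplots(agg: pd.DataFrame, metrics: list[str], stats: pd.DataFrame,
                  path: Path, title: str) -> None:
    metrics = [m for m in metrics if m in agg.columns]
    n = len(metrics)
    fig, axes = plt.subplots(1, n, figsize=(2.6 * n, 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        data = [
            agg.loc[agg["condition"] == c, metric].dropna() for c in CONDITIONS
        ]
        ax.boxplot(data, tick_labels=["F", "RF", "RP"])
        ax.set_title(metric, fontsize=9)
        rows = stats[(stats["metric"] == metric) & (stats["tier"] != "ns")]
        glyphs = ", ".join(f"{r.pair}: {r.tier}" for r in rows.itertuples())
        if glyphs:
            ax.set_xlabel(glyphs, fontsize=7)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_recurrence_map(trial, config, path: Path) -> None:
    from .pipeline import cop_from_trial

    cop = cop_from_trial(trial, to_hz=config.rate_kin)
    cycles = segment_trial(trial.wrist, n_expected=config.n_expected,
                           prominence_frac=config.prominence_frac,
                           depth_frac=config.depth_frac)
    keep = np.zeros(len(cop), dtype=bool)
    for s, e in cycles.intervals:
        keep[s:e] = True
    seg = cop.segment(0, len(cop))
    seg.valid = keep & cop.valid
    sig = radial_component(seg)[:: max(config.rqa.downsample, 1)]
    tau = max(1, round(cycle_delay(cycles) / max(config.rqa.downsample, 1)))
    states = embed(sig, config.rqa.m, tau)
    r = recurrence_matrix(states, config.rqa.epsilon,
                          config.rqa.epsilon_is_fraction, config.rqa.norm)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(r, origin="lower", cmap="binary", interpolation="nearest")
    ax.set_title(f"Recurrence map (radial) — {trial.meta.condition}")
    ax.set_xlabel("state index")
    ax.set_ylabel("state index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_report(out: Path, sway_agg: pd.DataFrame, rqa_agg: pd.DataFrame,
                stats_table: pd.DataFrame, sample_trial, config) -> None:
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    plot_cop_panels(sway_agg, sample_trial, fig_dir / "cop_trajectory.png", config)
    plot_boxplots(sway_agg, ["mdist_cm", "mvelo_cm_s", "area_ce_cm2", "area_sw_cm2_s"],
                  stats_table, fig_dir / "sway_boxplots.png", "Sway metrics")
    rqa_cols = [c for c in rqa_agg.columns if c not in ("participant", "condition")]
    plot_boxplots(rqa_agg, rqa_cols, stats_table, fig_dir / "rqa_boxplots.png",
                  "RQA metrics")
    plot_recurrence_map(sample_trial, config, fig_dir / "recurrence_map.png")

    lines = ["# coprqa run report", ""]
    lines.append("## Group means per condition (sway)")
    lines.append(
        sway_agg.groupby("condition").mean(numeric_only=True).round(3).to_string()
    )
    lines.append("")
    lines.append("## Group means per condition (RQA)")
    lines.append(
        rqa_agg.groupby("condition").mean(numeric_only=True).round(3).to_string()
    )
    lines.append("")
    lines.append("## Condition comparisons")
    lines.append(stats_table.round(4).to_string(index=False))
    lines.append("")
    lines.append("Figures: figures/*.png")
    (out / "report.md").write_text("\n".join(lines))
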