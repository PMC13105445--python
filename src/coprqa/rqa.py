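"""Recurrence quantification analysis of COP components.

The COP signal (radial, AP or ML component of the manipulation phases of
one trial) is delay-embedded into m-dimensional state vectors

    v_i = (s_i, s_{i+tau}, ..., s_{i+(m-1)tau}),

with the delay tau tied to the task: it is the average manipulation-cycle
length of the trial in samples, so recurrences are read on a cycle-based
time reference. The binary recurrence matrix

    R_ij = [ dist(v_i, v_j) <= eps ]

then yields three statistics over the admissible region |i - j| > theiler
(the identity line carries no dynamical information and is excluded):

* REC   — density of recurrent pairs among admissible pairs;
* DET   — fraction of those recurrent points lying on diagonal line
          segments of length >= l_min (predictability of the sway);
* RATIO — DET / REC, the degree to which recurrences are deterministic.

The radius eps may be given as an absolute distance in the signal's
units, or as a fraction of the attractor diameter (the maximal pairwise
state distance), the latter making REC/DET scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import CopTrajectory, CycleSet

Component = Literal["radial", "AP", "ML"]
COMPONENTS: tuple[Component, ...] = ("radial", "AP", "ML")


@dataclass
class RqaConfig:
    """Parameters of the embedding and of the recurrence statistics.

    epsilon is interpreted as a fraction of the maximal pairwise state
    distance when ``epsilon_is_fraction`` is true (default), otherwise as
    an absolute radius in cm. ``downsample`` decimates the analysed
    series by an integer factor before embedding (1 = none), trading
    recurrence-plot resolution for quadratic cost.
    """

    m: int = 2
    tau: int = 1
    epsilon: float = 0.10
    epsilon_is_fraction: bool = True
    l_min: int = 2
    theiler: int = 0
    norm: Literal["euclidean", "maximum"] = "euclidean"
    downsample: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")
        if self.norm not in ("euclidean", "maximum"):
            raise ValueError("norm must be 'euclidean' or 'maximum'")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


@dataclass
class RqaResult:
    """REC/DET/RATIO for one component of one trial."""

    rec: float
    det: float
    ratio: float
    component: Component
    config: RqaConfig
    n_states: int


def radial_component(segment: CopTrajectory) -> np.ndarray:
    """Radial COP excursion: distance from the centroid of the analysed series."""
    m = segment.valid
    ml = segment.ml[m]
    ap = segment.ap[m]
    return np.hypot(ml - ml.mean(), ap - ap.mean())


def cycle_delay(cycles: CycleSet) -> int:
    """Delay in samples: the trial's average manipulation-cycle length."""
    if len(cycles) == 0:
        raise ValueError("empty cycle set: cannot derive a delay")
    return max(1, int(round(float(cycles.lengths().mean()))))


def embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding into an (N - (m-1)*tau, m) state array."""
    s = np.asarray(series, dtype=float)
    n_states = s.shape[0] - (m - 1) * tau
    if n_states < 1:
        raise ValueError(
            f"series of length {s.shape[0]} too short for m={m}, tau={tau}: "
            f"need at least {(m - 1) * tau + 1} samples"
        )
    idx = np.arange(n_states)[:, None] + tau * np.arange(m)[None, :]
    return s[idx]


def recurrence_matrix(
    states: np.ndarray,
    epsilon: float,
    epsilon_is_fraction: bool = True,
    norm: str = "euclidean",
) -> np.ndarray:
    """Binary symmetric recurrence matrix of the embedded states."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] < 2:
        raise ValueError("need at least 2 states for a recurrence matrix")
    metric = "chebyshev" if norm == "maximum" else "euclidean"
    dist = pdist(states, metric=metric)
    eps_abs = epsilon
    if epsilon_is_fraction:
        diameter = float(dist.max())
        if diameter == 0.0:
            raise ValueError(
                "all states identical: fractional epsilon is undefined; "
                "use an absolute epsilon"
            )
        eps_abs = epsilon * diameter
    r = squareform(dist <= eps_abs).astype(bool)
    np.fill_diagonal(r, True)
    return r


def _admissible_mask(n: int, theiler: int) -> np.ndarray:
    i = np.arange(n)
    return np.abs(i[:, None] - i[None, :]) > theiler


def recurrence_rate(r: np.ndarray, theiler: int = 0) -> float:
    """Density of recurrent pairs with |i - j| > theiler."""
    mask = _admissible_mask(r.shape[0], theiler)
    n_adm = int(mask.sum())
    if n_adm == 0:
        raise ValueError("Theiler window excludes every pair")
    return float(np.count_nonzero(r & mask) / n_adm)


def determinism(r: np.ndarray, l_min: int = 2, theiler: int = 0) -> float:
    """Fraction of admissible recurrent points on diagonals of length >= l_min.

    Maximal runs of ones parallel to the main diagonal (outside the
    Theiler band) are histogrammed; DET is sum_{l >= l_min} l * P(l)
    divided by the total admissible recurrent-point count. NaN when
    there are no recurrent points.
    """
    n = r.shape[0]
    total = 0
    on_lines = 0
    for k in range(theiler + 1, n):
        diag = np.asarray(r.diagonal(k))
        total += 2 * int(np.count_nonzero(diag))  # symmetric: count both triangles
        for run in _run_lengths(diag):
            if run >= l_min:
                on_lines += 2 * run
    if total == 0:
        return float("nan")
    return on_lines / total


def _run_lengths(binary: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1D boolean array."""
    padded = np.concatenate([[0], binary.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def rqa_ratio(rec: float, det: float) -> float:
    """DET / REC; NaN when REC is zero (no recurrences to qualify)."""
    if not rec > 0:
        return float("nan")
    return det / rec


def rqa_from_series(series: np.ndarray, config: RqaConfig) -> tuple[float, float, float, int]:
    """Embed a scalar series and return (REC, DET, RATIO, n_states)."""
    s = np.asarray(series, dtype=float)
    if config.downsample > 1:
        s = s[:: config.downsample]
    tau = max(1, int(round(config.tau / config.downsample)))
    states = embed(s, config.m, tau)
    r = recurrence_matrix(
        states, config.epsilon, config.epsilon_is_fraction, config.norm
    )
    rec = recurrence_rate(r, config.theiler)
    det = determinism(r, config.l_min, config.theiler)
    return rec, det, rqa_ratio(rec, det), states.shape[0]


def run_rqa(
    cop: CopTrajectory, cycles: CycleSet, config: RqaConfig | None = None
) -> list[RqaResult]:
    """RQA of one trial on its radial, AP and ML COP components.

    Manipulation-phase samples are concatenated across the trial's
    cycles (single cycles are shorter than the cycle-based delay), the
    delay is set to the trial's average cycle length, and REC/DET/RATIO
    are computed per component.
    """
    config = config or RqaConfig()
    config = replace(config, tau=cycle_delay(cycles))
    keep = np.zeros(len(cop), dtype=bool)
    for start, end in cycles.intervals:
        keep[start:end] = True
    seg = CopTrajectory(
        ml=cop.ml[keep],
        ap=cop.ap[keep],
        rate_hz=cop.rate_hz,
        valid=cop.valid[keep],
        meta=cop.meta,
    )
    min_len = (config.m - 1) * config.tau + config.l_min
    if int(seg.valid.sum()) <= min_len:
        raise ValueError(
            f"concatenated manipulation series ({int(seg.valid.sum())} samples) "
            f"shorter than (m-1)*tau + l_min = {min_len}"
        )
    m = seg.valid
    signals: dict[Component, np.ndarray] = {
        "radial": radial_component(seg),
        "AP": seg.ap[m],
        "ML": seg.ml[m],
    }
    results = []
    for component, sig in signals.items():
        rec, det, ratio, n_states = rqa_from_series(sig, config)
        results.append(
            RqaResult(
                rec=rec, det=det, ratio=ratio, component=component,
                config=config, n_states=n_states,
            )
        )
    return results


def rqa_frame(cop: CopTrajectory, results: list[RqaResult]) -> pd.DataFrame:
    """Long-form frame of trial RQA results keyed like the sway output."""
    rows = [
        {
            "participant": cop.meta.participant,
            "condition": cop.meta.condition,
            "trial": cop.meta.trial,
            "component": res.component,
            "rec": res.rec,
            "det": res.det,
            "ratio": res.ratio,
            "n_states": res.n_states,
        }
        for res in results
    ]
    return pd.DataFrame(rows)
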