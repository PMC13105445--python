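"""Within-subject nonparametric comparison of the three task conditions.

The inferential chain for each metric: Shapiro-Wilk normality screen per
condition; if any condition departs from normality (the usual case for
sway measures), a Friedman omnibus test across the k=3 repeated
conditions; when the omnibus is significant at alpha=0.05, pairwise
Wilcoxon comparisons with effect sizes r = |Z| / sqrt(n) classified as
small (0.1-0.3), medium (0.3-0.5) or large (>0.5), and significance
tiers * / ** / *** at p < .05 / .01 / .001.

The pairwise test defaults to the paired signed-rank statistic with the
normal approximation and no continuity correction,

    W = sum of positive-difference ranks,
    Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24),

zero differences being dropped; a rank-sum (Mann-Whitney) variant is
available for completeness although the design is within-subject.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    w: float
    z: float
    p: float
    r: float
    magnitude: str
    tier: str


@dataclass
class ConditionComparison:
    """Friedman omnibus plus (gated) pairwise results for one metric."""

    metric: str
    n: int
    shapiro_p: dict[str, float]
    normal: bool
    friedman_chi2: float
    friedman_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return "ns"


def effect_magnitude(r: float) -> str:
    r = abs(r)
    if r > 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    if r >= 0.1:
        return "small"
    return "negligible"


def effect_size_r(z: float, n: int) -> float:
    """Effect size r = |Z| / sqrt(n), n = number of participants."""
    if n <= 0:
        raise ValueError("n must be positive")
    return abs(z) / np.sqrt(n)


def normality_gate(values_by_condition: dict[str, np.ndarray]) -> tuple[dict[str, float], bool]:
    """Shapiro-Wilk p per condition; False (non-normal) if any p < alpha.

    Degenerate samples (n < 3 or zero variance) force the nonparametric
    path with a warning.
    """
    pvals: dict[str, float] = {}
    normal = True
    for cond, vals in values_by_condition.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3 or np.ptp(vals) == 0:
            warnings.warn(
                f"condition {cond!r}: degenerate sample for Shapiro-Wilk; "
                "forcing nonparametric path",
                stacklevel=2,
            )
            pvals[cond] = float("nan")
            normal = False
            continue
        p = float(sps.shapiro(vals).pvalue)
        pvals[cond] = p
        if p < ALPHA:
            normal = False
    return pvals, normal


def friedman(table: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over an (n participants x k conditions) block table.

    Mid-ranks within each participant's row; chi-square reference with
    k-1 degrees of freedom. Rows with missing cells are excluded with a
    warning (complete-block design required).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 3:
        raise ValueError("need an (n, k>=3) table")
    complete = np.all(np.isfinite(table), axis=1)
    if not complete.all():
        warnings.warn(
            f"excluding {int((~complete).sum())} participant(s) with missing cells",
            stacklevel=2,
        )
        table = table[complete]
    if table.shape[0] < 2:
        raise ValueError("fewer than 2 complete blocks")
    with np.errstate(invalid="ignore"):
        res = sps.friedmanchisquare(*table.T)
    if not np.isfinite(res.statistic):
        # every block fully tied: no evidence of a condition effect
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(
    a: np.ndarray,
    b: np.ndarray,
    variant: str = "signed_rank",
) -> tuple[float, float, float]:
    """Pairwise condition comparison; returns (W, Z, two-sided p).

    ``signed_rank`` (default): paired Wilcoxon signed-rank with the
    normal approximation, no continuity correction; zero differences are
    dropped. ``rank_sum``: two-sample Wilcoxon rank-sum Z for reference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if variant == "rank_sum":
        res = sps.ranksums(a, b)
        return float("nan"), float(res.statistic), float(res.pvalue)
    if variant != "signed_rank":
        raise ValueError("variant must be 'signed_rank' or 'rank_sum'")
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; test undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w - mu) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return w, float(z), float(min(p, 1.0))


def compare_conditions(
    values: pd.DataFrame,
    metric: str,
    conditions: tuple[str, ...] = ("Free", "RF", "RP"),
    variant: str = "signed_rank",
) -> ConditionComparison:
    """Full inferential chain for one metric.

    ``values`` is long-form with columns participant, condition and the
    metric; one value per participant per condition (aggregate first).
    Pairwise comparisons are run only when the Friedman omnibus is
    significant at alpha=0.05.
    """
    wide = values.pivot_table(
        index="participant", columns="condition", values=metric, aggfunc="mean"
    ).reindex(columns=list(conditions))
    table = wide.to_numpy(dtype=float)
    by_cond = {c: table[:, i] for i, c in enumerate(conditions)}
    shapiro_p, normal = normality_gate(by_cond)
    chi2, p_omnibus = friedman(table)
    comparison = ConditionComparison(
        metric=metric,
        n=int(np.all(np.isfinite(table), axis=1).sum()),
        shapiro_p=shapiro_p,
        normal=normal,
        friedman_chi2=chi2,
        friedman_p=p_omnibus,
    )
    if p_omnibus < ALPHA:
        complete = np.all(np.isfinite(table), axis=1)
        for i, j in itertools.combinations(range(len(conditions)), 2):
            a = table[complete, i]
            b = table[complete, j]
            w, z, p = wilcoxon_paired(a, b, variant=variant)
            r = effect_size_r(z, a.size) if np.isfinite(z) else float("nan")
            comparison.pairwise.append(
                PairwiseResult(
                    pair=(conditions[i], conditions[j]),
                    w=w, z=z, p=p, r=r,
                    magnitude=effect_magnitude(r) if np.isfinite(r) else "undefined",
                    tier=significance_tier(p) if np.isfinite(p) else "ns",
                )
            )
    return comparison


def comparison_frame(comparisons: list[ConditionComparison]) -> pd.DataFrame:
    """Flatten comparisons into one row per metric x condition pair."""
    rows = []
    for comp in comparisons:
        if not comp.pairwise:
            rows.append(
                {
                    "metric": comp.metric, "n": comp.n,
                    "friedman_chi2": comp.friedman_chi2,
                    "friedman_p": comp.friedman_p,
                    "pair": "", "W": np.nan, "Z": np.nan, "p": np.nan,
                    "r": np.nan, "magnitude": "", "tier": "ns",
                }
            )
        for pw in comp.pairwise:
            rows.append(
                {
                    "metric": comp.metric, "n": comp.n,
                    "friedman_chi2": comp.friedman_chi2,
                    "friedman_p": comp.friedman_p,
                    "pair": f"{pw.pair[0]}-{pw.pair[1]}",
                    "W": pw.w, "Z": pw.z, "p": pw.p, "r": pw.r,
                    "magnitude": pw.magnitude, "tier": pw.tier,
                }
            )
    return pd.DataFrame(rows)
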