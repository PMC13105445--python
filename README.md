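# coprqa

Center-of-pressure (COP) posturography for human–robot collaborative
manipulation: from raw force-plate and motion-capture recordings to linear
sway metrics, recurrence quantification analysis (RQA), and within-subject
nonparametric statistics.

## Who this is for

Movement scientists and ergonomists assessing postural control while a
standing worker performs a cyclic manipulation task — alone or together with a
collaborative robot (cobot). The package covers the full measurement chain:

1. **COP extraction** — per-plate COP from 6-component force/moment channels,
   `COPx = (−My − Fx·h)/Fz`, `COPy = (Mx − Fy·h)/Fz`, combined across the two
   plates as the vertical-load-weighted average, decimated (zero-phase) from
   the force rate (500 Hz) to the kinematic rate (250 Hz).
2. **Cycle segmentation** — task repetitions from the right-wrist marker
   (completion = maximum rightward ML excursion); only manipulation phases
   enter the analysis, rest/pick-up/release are excluded.
3. **Linear sway metrics** per cycle — mean distance (cm), mean velocity
   (cm/s), 95 % confidence-ellipse area `π·5.991·√(λ₁λ₂)` (cm²), and sway
   area (cm²/s).
4. **RQA** per trial on the radial, AP and ML COP components — time-delay
   embedding with the delay set to the trial's average cycle length, then
   recurrence rate (REC), determinism (DET) and RATIO = DET/REC.
5. **Statistics** — Shapiro–Wilk gate, Friedman omnibus across the three
   conditions (Free / Robot-Free / Robot-Plane), gated pairwise Wilcoxon
   signed-rank comparisons with effect sizes `r = |Z|/√n` and */**/*** tiers.

A synthetic-data generator emits raw plate/marker recordings for a full
cohort (14 participants × 3 conditions × 3 trials × 5 repetitions) with
ground-truth COP, cycle boundaries and phase labels, so the entire pipeline is
testable end to end. The emitted plate channels invert the COP kinetics
exactly: re-extracting the COP reproduces the ground truth to < 1e−6 cm.

## Worked example

```python
import pandas as pd
from coprqa import DEFAULT_PRESETS, RqaConfig, generate_trial, run_rqa, segment_trial
from coprqa.pipeline import cop_from_trial
from coprqa.sway import cycle_metrics

trial = generate_trial(DEFAULT_PRESETS["RF"], seed=42)
cop = cop_from_trial(trial)           # plates -> total COP at 250 Hz
cycles = segment_trial(trial.wrist)   # 5 manipulation phases

sway = cycle_metrics(cop, cycles)
print(sway[["cycle", "mdist_cm", "mvelo_cm_s", "area_ce_cm2", "area_sw_cm2_s"]]
      .round(2).to_string(index=False))
for res in run_rqa(cop, cycles, RqaConfig(downsample=10)):
    print(f"{res.component:>6}: REC={res.rec:.3f}  DET={res.det:.3f}  RATIO={res.ratio:.2f}")
```

```
 cycle  mdist_cm  mvelo_cm_s  area_ce_cm2  area_sw_cm2_s
     0      2.16        2.58        34.81           2.05
     1      2.23        2.90        36.28           2.12
     2      2.51        3.09        44.44           3.19
     3      2.33        2.60        44.42           2.38
     4      2.66        3.41        61.96           3.51
radial: REC=0.099  DET=0.985  RATIO=9.92
    AP: REC=0.136  DET=0.994  RATIO=7.34
    ML: REC=0.120  DET=0.996  RATIO=8.31
```

Each row is one manipulation cycle of a robot-assisted trial: the COP wanders
on average ~2.2–2.7 cm from its centroid at ~2.6–3.4 cm/s. The RQA lines say
the sway is highly deterministic (DET ≈ 0.99: recurrent states sit on long
diagonal lines, i.e. whole stretches of the trajectory repeat across cycles)
while only ~10–14 % of state pairs recur at the 10 %-diameter radius.

Cohort-level inference (here a 14-participant synthetic cohort at desk-scale
sampling rates):

```python
from coprqa import generate_cohort
from coprqa.stats import compare_conditions
from coprqa.sway import aggregate

frames = [cycle_metrics(cop_from_trial(t), segment_trial(t.wrist))
          for t in generate_cohort(n_participants=14, seed=11,
                                   rate_plates=100, rate_kin=50)]
agg = aggregate(pd.concat(frames, ignore_index=True))
comp = compare_conditions(agg, "mdist_cm")
```

```
          mdist_cm       mvelo_cm_s
              mean   std       mean   std
condition
Free          1.72  0.39       2.65  0.58
RF            2.45  0.51       3.23  0.67
RP            2.32  0.47       3.12  0.64
Friedman chi2=28.0, p=8.32e-07
  Free vs RF   Z= 3.30  p=0.0010  r=0.88 (large) ***
  Free vs RP   Z= 3.30  p=0.0010  r=0.88 (large) ***
    RF vs RP   Z=-3.30  p=0.0010  r=0.88 (large) ***
```

Sway is larger under robotic assistance than in free manipulation, and with
every participant ordered the same way the signed-rank Z saturates at 3.30
(n = 14), i.e. the maximal effect size r = 0.88.

## Command line

Every stage is also a subcommand of `coprqa` (`synth`, `cop`, `segment`,
`sway`, `rqa`, `stats`), and `coprqa run --config pipeline.yaml` chains them
into a results tree (`sway.csv`, `rqa.csv`, `stats.csv`, figures, report) with
per-trial failure isolation and a config snapshot embedded in the output
directory. All intermediates are plain CSV/YAML and bitwise reproducible for a
fixed config and seed.

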