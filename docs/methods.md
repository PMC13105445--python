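# Methods

`coprqa` analyses postural control during cyclic bimanual manipulation at a
workbench, with or without a collaborating robot arm. This note documents the
measurement model, the defaults that matter, what the synthetic cohort does and
does not emulate, and the numerical choices that are genuinely open.

## From plate channels to the total COP

Each force plate reports the ground reaction force (Fx, Fy, Fz) and the moment
(Mx, My, Mz) about its own origin. With the origin a vertical distance *h*
below the top surface, the centre of pressure on the surface is

    COPx = (−My − Fx·h) / Fz        COPy = (Mx − Fy·h) / Fz

in plate coordinates, translated into a lab frame whose origin lies midway
between the two plates (ML = x, rightward positive; AP = y, forward positive;
outputs in cm). Samples with |Fz| < 20 N are flagged invalid instead of being
divided through: 20 N is a standard posturography guard against the COP ratio
blowing up when a foot unloads, and the exact value is uncritical because a
standing adult keeps an order of magnitude more load on at least one plate.

The total-body COP is the per-sample weighted average of the two plate COPs
with the instantaneous vertical forces (clamped at ≥ 0) as weights. This is the
physically correct combination — it is the point of application of the summed
vertical load — and it degrades gracefully: when one plate is unloaded or
invalid the total equals the other plate's COP, and only samples where both
plates fail are flagged invalid.

Force data (500 Hz) are decimated to the kinematic rate (250 Hz) with a
zero-phase 4th-order Butterworth low-pass at 0.4 × target rate before the
down-pick. Zero-phase (forward–backward) filtering matters here: a causal
filter's group delay would shift the COP against the wrist-derived cycle
intervals and bias the velocity metrics. Only integer decimation ratios are
supported; polyphase resampling is out of scope. No other filtering is applied.

## Cycle segmentation

Each repetition ends with the right hand returning the object to its station
on the participant's right, so repetition completions are local maxima of the
wrist-marker ML coordinate. Peak detection runs twice: a permissive pass
(prominence ≥ 10 % of the trial's ML range) establishes the typical inter-peak
spacing, and a second pass adds a minimum distance of half the median spacing.
The two-pass scheme suppresses jitter doublets without assuming a fixed cycle
duration — participants pace themselves freely.

Within each cycle (the span between consecutive completions, the first cycle
starting at sample 0), the manipulation phase is the interval where the wrist
ML coordinate is left of

    θ = rest_ml − 0.8 · (rest_ml − min_ml)

with rest_ml/min_ml the cycle's rightmost/leftmost wrist positions. The depth
factor 0.8 (configurable) was validated against the generator's ground-truth
phase labels: at default noise ≥ 95 % of the selected samples are true
manipulation samples and > 99 % of true manipulation samples are captured; the
residual contamination is the tail ends of the pick-up and release transfers,
whose COP behaviour is continuous with the manipulation phase. When manual
phase annotations exist they override the heuristic. Indices are 0-based and
intervals half-open.

## Linear sway metrics

Per manipulation cycle, on the (ML, AP) segment:

* **mean distance** (cm): mean radial distance from the segment's own centroid;
* **mean velocity** (cm/s): summed chord lengths over segment duration
  ((N−1)/rate); chords bridging an invalid sample are dropped from the sum
  rather than interpolated, so gaps never fabricate excursions;
* **95 % confidence-ellipse area** (cm²): π · χ²₂,₀.₉₅ · √(λ₁λ₂) with λᵢ the
  sample-covariance eigenvalues and χ²₂,₀.₉₅ = 5.991. The large-sample
  chi-square form is used rather than the small-sample F form: cycles hold
  hundreds of samples at 250 Hz, where the two differ by under 1 %. A
  rank-deficient covariance (perfectly collinear sway) yields area 0;
* **sway area** (cm²/s): shoelace accumulation (1/2T) Σ |xₙ₊₁yₙ − xₙyₙ₊₁| on
  centroid-centred coordinates — the area swept per unit time by the
  centroid-to-COP vector.

Centering uses the cycle's own centroid, consistent with per-cycle computation.
Cycle values are averaged per trial, then trial means per condition, giving one
value per participant × condition × metric for inference.

## Recurrence quantification

RQA runs on three scalar components of the trial's COP — radial (distance from
the centroid of the analysed series), AP, and ML — using the concatenated
manipulation phases of the trial. Concatenation is deliberate: the delay is
cycle-based (below), so a single cycle would be shorter than one delay.

The series is delay-embedded, v_i = (s_i, s_{i+τ}, …, s_{i+(m−1)τ}), with the
delay τ set to the trial's average manipulation-cycle length in samples
(rounded, minimum 1): recurrences are thereby read on a cycle-based time
reference, comparing states at homologous points of successive repetitions.
The recurrence matrix is R_ij = [‖v_i − v_j‖ ≤ ε] (Euclidean by default,
maximum norm available). Defaults, all configurable:

* **m = 2** — the lowest embedding dimension that unfolds a quasi-periodic
  loop; consistent with determinism values near 1 on this kind of signal;
* **ε = 10 % of the attractor diameter** (maximal pairwise state distance);
  the fraction-of-diameter convention makes REC/DET invariant to offset and
  scale of the input. An absolute radius in cm can be given instead. A
  degenerate series (zero diameter) rejects a fractional radius explicitly;
* **l_min = 2**, the shortest run counted as a deterministic line;
* **Theiler window = 0**, meaning only the identity line i = j is excluded:
  self-matches carry no dynamical information, so REC and DET are computed over
  off-diagonal admissible pairs (numerator and denominator alike).

REC is the density of recurrent admissible pairs; DET is Σ_{l≥l_min} l·P(l)
over the total admissible recurrent points, with P(l) the histogram of maximal
diagonal run lengths; RATIO = DET/REC. Note that DET of an all-recurrent plot
is slightly below 1 at finite n (the two length-1 corner diagonals can never
reach l_min) and approaches 1 as n grows — this is a property of the line-
histogram definition, not an implementation artefact.

Cost control: the recurrence matrix is quadratic in state count, so the
pipeline decimates the analysed series by an integer `downsample` factor
(default 10 in the full pipeline, i.e. 25 Hz analysis rate for 250 Hz input;
τ is rescaled accordingly). COP sway is band-limited well below the resulting
Nyquist rate, and REC/DET on decimated series were checked to be stable to the
factor on synthetic trials. The engine itself defaults to no decimation.

## Statistics

Per metric: Shapiro–Wilk per condition at α = .05; if any condition departs
from normality (the usual case — area-like metrics are strongly skewed) the
chain is nonparametric throughout. The omnibus is a Friedman test across the
k = 3 repeated conditions (mid-ranks, χ² reference with 2 df; participants
with missing cells are excluded from the block design). Only when the omnibus
is significant at α = .05 are the three pairwise comparisons run.

The pairwise test is the **paired Wilcoxon signed-rank** statistic with the
normal approximation and no continuity correction: zero differences dropped,
W = sum of positive-difference ranks,

    Z = (W − n(n+1)/4) / √(n(n+1)(2n+1)/24),

two-sided p, effect size r = |Z|/√n with n the number of participants, tiers
*, **, *** at p < .05/.01/.001 and magnitudes small/medium/large at
0.1–0.3/0.3–0.5/> 0.5. The within-subject design makes the paired test the
appropriate one; a two-sample rank-sum variant is exposed (`variant=
"rank_sum"`) for completeness. At n = 14 this arithmetic pins down two useful
reference values: uniformly positive differences give W = 105, Z = 3.296,
r = 0.88; flipping the single smallest-rank difference gives W = 104,
Z = 3.233, r = 0.86. No multiple-testing correction is applied beyond the
omnibus gate. Type-I calibration of both tests under simulated complete-block
nulls (n = 14) sits within [0.03, 0.07] at α = .05 in the test suite.

## Synthetic cohort

The generator emits raw recordings for 14 participants × 3 conditions (Free,
RF = robot free, RP = robot plane-constrained) × 3 trials × 5 repetitions —
the full study layout — so that every pipeline stage, including file ingest,
is testable without any recorded data.

Ground-truth COP per trial: one smooth closed loop per cycle in the (ML, AP)
plane (a harmonic-enriched ellipse, gated by a cosine-edged manipulation
envelope so the COP collapses to the stance baseline during rest), with
per-cycle log-normal amplitude jitter (σ = 0.12) and period jitter (σ = 0.06),
plus stationary low-pass Gaussian drift (2nd-order Butterworth at 1 Hz, RMS
0.45 cm) standing in for quiet-stance sway. Drift is band-limited stationary
noise rather than a random walk so per-cycle statistics are stable. Condition
presets differ in loop range: Free 3.2 cm in both axes; RF 5.9 cm AP × 3.0 cm
ML; RP 5.6 × 3.0. These constants were calibrated once so that desk-scale
cohorts land near group mean distances of 1.7 cm (Free) and 2.3–2.4 cm
(robot conditions) with ≈ 0.6 cm between-subject SD — the calibration targets
are the study conditions, the constants are ours. Participant-level random
effects are mean-one log-normals on sway scale (σ = 0.30) and cycle period
(σ = 0.08); cycle period defaults to 8 s, a realistic self-paced duration for
a six-step manipulation sequence, with 30 % of each cycle outside the
manipulation phase.

Plate channels are synthesised by exact inversion of the COP kinetics: the
body weight (71 kg) is split across the plates with a slowly oscillating load
share, per-plate COPs are placed so their load-weighted average is the ground
truth exactly, and moments are back-computed from the COP equation including
shear forces and the 4 cm surface offset. Extracting the COP from the emitted
channels therefore reproduces the truth to < 1e−6 cm, which pins down sign and
unit conventions across the whole ingest path. The wrist ML trajectory rests
at the participant's side (15 cm), transfers to the workpiece (0 cm), and
returns rightward to a sharp completion peak at the station (32 cm); the
sharp-cornered peak keeps the boundary argmax stable within ±2 samples under
marker noise. All randomness flows from one cohort seed via SeedSequence
spawning (cohort → participant → trial).

What the generator does **not** emulate: genuine human postural dynamics
(closed-loop balance control, intermittent corrections, long-range
correlations), robot-coupled interaction forces, anthropometric covariates,
fatigue or learning across trials, and any condition-specific *temporal*
structure beyond amplitude and timing — in particular the generator is not
calibrated to reproduce recorded REC/DET contrasts between conditions, nor
the ellipse-area-to-mean-distance ratio of real sway (a thin closed loop has
more area per unit mean distance than centre-concentrated real sway).
Passing recovery tests therefore shows that the pipeline detects injected
amplitude structure through the full measurement chain with correctly
calibrated inference — not that it would reproduce any particular recorded
effect on real data.

## Problem sizes and reproducibility

Cohort-level tests and recovery checks run at 100 Hz plate / 50 Hz kinematic
rates with the same cycle structure; the sampling rate only sets resolution,
not the sway geometry, and all rate-dependent steps (decimation, delays) scale
with it. Single-trial examples run at the native 500/250 Hz. Recovery rates
are estimated over 200 cohort seeds; type-I calibration over 10⁴ simulated
nulls. Pipeline outputs are plain CSV/YAML and are bitwise reproducible for a
fixed config and seed.

## Known limitations

* The manipulation-phase heuristic assumes the rest/grasp station is the
  wrist's rightward extreme; layouts that violate this need annotation files.
* DET saturates near 1 on strongly periodic signals, which compresses
  between-condition DET contrasts (RATIO then mostly tracks 1/REC).
* The fraction-of-diameter radius ties ε to the trial's own extremes; a single
  excursion outlier deflates REC. An absolute radius avoids this at the cost
  of scale dependence.
* Exact-period delays degenerate the m = 2 embedding of a pure sinusoid onto
  the diagonal; the cycle-averaged delay with natural period jitter avoids
  this in practice.
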