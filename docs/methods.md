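# Methods

This note documents the models, conventions and numerical choices behind
`racquetvr`, in the spirit of a simulator's model documentation: what is
simulated, what is measured, which knobs matter, and what the synthetic
data can and cannot show.

## World frame and units

Origin on the floor at the participant's prescribed starting position;
+z toward the front wall, +y up, +x toward the dominant hand. Metres,
seconds, degrees throughout; trial time starts at ball launch (t = 0).

## Ball physics

Flight is drag-free and spin-free: the only forces are gravity
(−9.8 m/s²) and an instantaneous vertical restitution at the bounce,
v⁺ = e·|v⁻| with e = 0.65 (normal) or 0.85 (bouncy). The launch solves the
stated constraints in closed form: from height h = 2 m, vertical speed at
the bounce pinned to −9 m/s gives v₀ = +√(81 − 2·9.8·2) ≈ 6.465 m/s
(upward root) and flight time (v₀ + 9)/9.8 ≈ 1.578 s. Post-bounce apex is
(e·9)²/(2·9.8): 1.7460 m normal, 2.9858 m bouncy.

The launch *point* is a documented convention: the task literature fixes
the launch height, the bounce point and the bounce-time speed but not
where balls originate. We launch from the front-wall plane (9 m from the
start, giving ≈3.49 m/s horizontal speed toward the player); the
alternative steep root (≈21 m/s) is selectable via `LaunchSpec(arc=...)`.
Events (bounce, arrival) are computed analytically and never snapped to
the sampling grid, so trajectories are exact at any sample rate.

## Trial-sequence design

Experimental blocks are 45 trials: five cued levels partitioning 36 trials
into lengths drawn from {6, 9, 12}, plus a fixed 9-trial cue-free catch
level (this reconciles the "five levels" and "six levels" readings of the
protocol: five *cued* levels, six in total). p(normal) per level comes
from {0.83, 0.67, 0.50} with consecutive levels always differing; the
catch level's underlying probability, never stated by the protocol, is
fixed at 0.67. Ball counts per level are quotas — round((1 − p)·length),
adjusted by at most ±1 per level so the block holds exactly 30 normal and
15 bouncy — rather than i.i.d. draws, because the original task used three
fixed pre-generated orderings. Control and cued blocks from one
(seed, sequence_id) pair share the identical ball ordering; only cue
annotations differ. The three canonical sequence ids map to fixed internal
seeds; the original deposited sequences are not embedded.

## The synthetic agent

The agent is deliberately the *minimal* behavioural model that produces
every measured effect direction; it is a testing instrument, not a claim
about mechanism.

* **Belief**: delta rule, b′ = b + α(outcome − b), b₀ = 1/3. Without a
  cue the agent acts on a discounted belief γ·b (hedging toward the
  familiar normal ball); with a cue, b_eff = w·cue + (1 − w)·γ·b.
* **Gaze**: smooth pursuit of the ball with band-limited noise; ~0.25 s
  before the bounce a two-step gaze shift (a 250 ms anticipatory sweep to
  a staging point 8° short of the target, then a 25 ms corrective
  saccade) lands on the predictive fixation, held ≥150 ms. Fixation
  pitch = pitch_bias + pitch_gain · E[apex | b_eff], with
  E[apex | b] = (1 − b)·1.746 + b·2.986 m. The two-step shift mirrors
  real interception gaze and keeps the 15 Hz filter's step ringing small
  relative to the fixation level. Per-block "session" pitch offsets model
  the per-condition eye-tracker recalibration.
* **Swing**: rest → minimum-jerk backswing to a pose whose head-to-hand
  azimuth *is* the intended ROM → 120 ms pause → minimum-jerk foreswing
  whose shared horizontal progress makes the hand path a straight line
  (so the azimuth decreases monotonically from the intended ROM), crossing
  the meeting plane at 80% progress with the requested peak forward
  velocity (peak = 1.875·A/T). The vertical axis completes exactly at the
  crossing so racquet height is settled at contact. The meeting plane sits
  0.75 m in front of the start, deepened per trial when needed to keep the
  swing ≥0.30 s (inside the 10 Hz filter band). ROM responds to
  uncertainty as rom_base − rom_uncertainty_slope · H₂(b_eff) plus a
  per-participant cued-trial shift (`cue_rom_shift`), clipped to
  [50°, 168°].
* **Interception**: the racquet is steered to the ball's arrival point
  plus Gaussian aim error (ε_x, ε_y); contact requires the error inside
  the racquet half-extents inflated by the ball radius
  (±0.3335 m, ±0.1835 m). Ground-truth contact is a fine analytic sweep of
  the same geometry the detector uses.
* **Dropout**: i.i.d. per-sample gaze invalidity (1%) plus an occasional
  contiguous gap (4% of trials, 40–180 ms), exercising the exclusion
  rules; ~2% of trials end up excluded, as intended.

### Cohort presets and calibration

`asd_like` and `nt_like` presets draw per-participant parameters from
truncated normals. Questionnaire totals match the study's Table of group
characteristics (AQ 35.86 ± 5.37 truncated at the clinical cut-off 26 vs
15.59 ± 7.96; IUS-S 38.86 ± 9.98 vs 27.00 ± 10.14). Interception is
calibrated through a latent per-participant target rate ~ Normal censored
at 100% — the censoring mass reproduces the observed ceiling subgroup —
whose latent mean is solved (Brent) so the censored mean equals the
printed group mean (87.75% / 97.22%); each rate is then inverted through
the contact envelope (per-axis probability √q via the Gaussian error
function) into aim-error SDs. Group differences in cue use are carried by
w (≈0.92 NT vs ≈0.08 ASD), belief discount γ (0.25 vs 0.85, making the
ASD-like agent act on volatile beliefs — higher, more variable pitch),
and `cue_rom_shift` (positive NT, negative ASD — the cued-block ROM
restriction). Magnitudes are set so condition differences match the
printed means ± SDs (pitch +1.96 ± 1.93° NT / +0.11 ± 2.75° ASD; ROM
+5.50 ± 13.68° NT / −6.50 ± 12.38° ASD). A consequence worth stating
plainly: at n = 22/group the pitch group-by-condition interaction has
analytic power ≈0.70–0.79 under these printed effect sizes, so replicate
detection rates near 70–75% are the faithful outcome, not a defect of the
pipelines. A `null` preset draws both groups from one population for
type-I calibration work.

All randomness descends from one master seed through named
`SeedSequence` substreams (design; one stream per participant), so
datasets are byte-reproducible and participants are independent.

### Two simulation routes

`iter_cohort`/`simulate_dataset` render full raw streams and are what the
pipelines consume. `simulate_metrics_cohort` runs the identical
trial-level behavioural model but emits the intended metrics directly,
skipping rendering and re-measurement; it exists for replicate-heavy
calibration studies (10,000-cohort type-I checks, 100-cohort power
checks) where rendering would be wasteful. The parameter-recovery tests
(noiseless agents: ROM <1°, peak velocity <2%, pitch <0.1°, contact flags
exact) are what licence treating the fast route as a stand-in.

## Pipelines

* Motion smoothing: dual-pass zero-phase Butterworth, order 2 per pass,
  10 Hz cutoff; velocities by central differences on the smoothed stream
  (one-sided at the ends).
* Foreswing onset: first sample of the last pre-offset run with forward
  velocity >0.2 m/s sustained ≥3 samples (~33 ms at 90 Hz); the threshold
  is a documented choice (none is stated by the protocol) and is exposed.
* Contact detection: poses linearly upsampled to 1 kHz so sub-sample
  crossings are not missed; closed boundary (touching counts). The stream
  schema carries no controller orientation, so the racquet box is
  axis-aligned, facing the wall.
* ROM reading: "angular deviation between headset and hand controller in
  the transverse plane" is implemented as facing-direction vs
  head-to-hand azimuthal angle; the alternative reading (total hand
  azimuth swept) is available via `rom_mode="hand_azimuth_range"`.
* Gaze: head-centred conversion (orientation interpolated to the gaze
  clock), 3-frame median then 2nd-order zero-phase Butterworth at 15 Hz,
  yaw unwrapped around ±180°; invalid samples are excluded from filter
  windows (per-segment filtering), never zero-filled.
* I-DT: dispersion = maximum pairwise separation (small-angle Euclidean
  on yaw/pitch) by default; the box measure
  (max−min)_yaw + (max−min)_pitch is selectable. Windows grow while
  dispersion ≤3°, maximal windows ≥100 ms are emitted, invalid samples
  break windows.
* Bounce fixation: fixations intersecting ±0.1 s around the bounce, ties
  broken by latest onset (the most recent predictive commitment);
  otherwise the latest fixation ending before the bounce, bounded at
  0.5 s lookback (unbounded lookback would select irrelevant early
  fixations). Onset is reported relative to launch.
* Exclusion: contiguous invalid gap >100 ms or >20% invalid samples,
  strict inequalities (boundary values retained).

## Statistics

Mixed 2×2 ANOVA by the classical split-plot decomposition: with two
levels per factor the between stratum reduces to subject means and the
within stratum to condition differences; unbalanced groups use unweighted
(type-III) marginal means. partial η² = SS_effect/(SS_effect + SS_error).
Normality routing follows the study's handling: an outcome whose any
group-by-condition cell fails Shapiro–Wilk (α = .05) gets Mann–Whitney /
Wilcoxon follow-ups and Spearman correlations; Levene (center = mean)
is reported per condition. Post-hoc p-values are Bonferroni-multiplied by
the family size (default family: 2 between-group + 2 within-group
comparisons), capped at 1. Two-tailed, α = .05.

Bayes factors: t-tests use the JZS default (Cauchy scale 0.707) by
numerical integration of the Zellner–Siow marginal likelihood; the
degenerate-evidence limit (null likelihood underflow) returns ∞.
Correlations re-express r as the one-predictor regression t and reuse the
JZS integral. ANOVA effects use the BIC approximation on the relevant
stratum (subject means for group; condition differences for condition and
interaction) — these will differ numerically from Monte-Carlo g-prior
ANOVA Bayes factors, and are labelled `bic_approx` in output.

A-priori power: smallest total N whose noncentral-F power reaches the
target, λ = f²·N for the fixed-effects families and the standard
repeated-measures boosts (correlation ρ, default 0.5) for the RM
families; N rounds up to a multiple of the group count. For f = 0.47,
α = .05, power = .80 every supported family needs ≤40 participants
(fixed-effects interaction: 38).

## Problem sizes and determinism

The replicate studies are sized for a single CPU: 10,000 null cohorts for
type-I calibration, 100 metrics-level cohorts for detection-rate checks,
and two full 22-agent stream-level cohorts for the interception-rate
reproduction (≈40 s each to simulate and process). `simulate → process →
analyze` is deterministic end to end: rerunning a config reproduces every
file byte for byte, and all tables carry a `schema_version` that readers
verify.

## What the synthetic data do not show

The generator emulates the *statistical structure* the analysis assumes —
stream rates, event timing, noise, dropout, group/condition contrasts —
not human motor control: no biomechanical arm model (bouncy-ball
interceptions can require implausibly high reaches), no head movement, no
saccade dynamics beyond the two-step shift, no learning across blocks
beyond the delta rule, and no cognitive model of intolerance of
uncertainty (the study found those trait correlations null). Passing
tests therefore validate the pipelines and the inferential layer, and the
direction and size of simulated group effects — they do not re-establish
the empirical findings themselves.
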