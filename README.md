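# racquetvr

A tested, reusable re-implementation of a virtual-reality racquetball
interception experiment used to study predictive sensorimotor control in
autistic and neurotypical adults. The package provides every stage of that
study as code: the volatile probabilistic trial sequences and explicit
probability cues, the projectile-and-bounce ball physics, a synthetic
participant generator that emits raw headset/controller (90 Hz) and gaze
(120 Hz) streams, the kinematic and gaze metric-extraction pipelines, and
the full group-by-condition statistical battery.

It is intended for researchers who want to prototype, validate or power
such interception paradigms — every pipeline stage is checked against an
independent oracle, and synthetic cohorts make the whole chain testable
without human data.

## The task and its measures

Participants intercept balls launched from 2 m height that bounce 3.5 m in
front of them with vertical speed fixed at −9 m/s at the bounce. Balls are
either *normal* (coefficient of restitution e = 0.65) or *bouncy*
(e = 0.85); pre-bounce flight is identical, so ball type is unknowable
until floor contact. The probability of a normal ball switches every 6, 9
or 12 trials between 0.83, 0.67 and 0.50. Each experimental block has 45
trials (30 normal / 15 bouncy) and ends with nine cue-free catch trials; in
the *cued* block, "hawkeye" and "bounceometer" cues announce each level's
bouncy likelihood (17% "low", 33% "medium", 50% "high").

From the raw streams the pipelines derive:

* **interception rate** — % of trials where the ball centre enters the
  0.6 × 0.3 × 0.01 m racquet box (inflated by the ball radius);
* **peak velocity** — max toward-target hand velocity during the
  *foreswing* (first forward racquet motion → contact, or the last sample
  with the ball still ahead on misses), after dual-pass zero-phase 10 Hz
  Butterworth smoothing;
* **ROM** — max transverse-plane angle between head facing and
  head-to-hand direction during the foreswing;
* **predictive bounce fixation** — gaze is converted to head-centred
  yaw/pitch, median+15 Hz Butterworth filtered, and segmented with a
  dispersion-threshold (I-DT) algorithm (≤3° for ≥100 ms); the fixation
  at/just before the bounce yields onset, duration, mean pitch and
  trial-to-trial pitch SD. Trials with >100 ms tracking loss or >20%
  missing samples are excluded.

Synthetic agents couple these behaviours to a delta-rule belief
b′ = b + α(outcome − b) about bouncy-ball probability, blended with the
explicit cue as b_eff = w·cue + (1 − w)·γ·b. Fixation pitch follows the
expected post-bounce apex under b_eff; ROM shrinks with outcome entropy;
aim error controls interception. Calibrated presets (`asd_like`,
`nt_like`) reproduce the study's group-level pattern.

## Worked example

```python
import numpy as np
from racquetvr import agent, design, gaze, kinematics, physics

block = design.generate_block(seed=42, sequence_id=1, block_kind="cued")
print("trials:", len(block.trials),
      "bouncy:", sum(t.ball_type == "bouncy" for t in block.trials))
print("levels:", [(lv.length, lv.p_normal) for lv in block.levels])
print("cue for level 0:", design.cue_for_level(block.levels[0].p_normal))

traj = physics.make_trajectory(elasticity=0.85)
print(f"bounce at t={traj.t_bounce:.4f} s, post-bounce apex={traj.post_bounce_apex:.4f} m")

params = agent.AgentParams.noiseless(rom_base=80.0, swing_peak_velocity_mean=4.0)
raw = agent.generate_trial(block.trials[0], traj, agent.BeliefState(0.5),
                           params, np.random.default_rng(0))
km = kinematics.process_trial(raw.motion, traj)
gm = gaze.process_trial(raw.gaze, raw.motion, t_bounce=traj.t_bounce)
print(f"intercepted={km.intercepted}, ROM={km.rom:.2f} deg, "
      f"peak velocity={km.peak_velocity:.2f} m/s")
print(f"bounce fixation: onset={gm.onset_rel_launch:.3f} s, "
      f"duration={gm.duration:.3f} s, pitch={gm.pitch:.2f} deg")
```

prints

```
trials: 45 bouncy: 15
levels: [(6, 0.5), (9, 0.83), (6, 0.67), (9, 0.83), (6, 0.5), (9, 0.67)]
cue for level 0: CueInfo(bouncy_pct=50, label='high', hawkeye_duration_s=10.0, bounceometer_lead_s=3.0)
bounce at t=1.5781 s, post-bounce apex=2.9858 m
intercepted=True, ROM=76.85 deg, peak velocity=3.98 m/s
bounce fixation: onset=1.358 s, duration=0.433 s, pitch=3.01 deg
```

The 45-trial block satisfies its quotas (30/15) with a final 9-trial catch
level; the bouncy ball's apex matches (0.85·9)²/(2·9.8) m; the measured
ROM is the set 80° minus the entropy adjustment for the 50% cue (the agent
"freezes" its swing under maximal outcome uncertainty); the fixation pitch
tracks the expected apex under the cue-blended belief.

Full cohorts run through the command-line interface:

```bash
racquetvr simulate --seed 1 --n-per-group 22 --out data/   # raw streams
racquetvr process data/                                    # metric tables
racquetvr analyze data/metrics                             # stats report
```

`analyze` writes a JSON/CSV/text report ordered like the study's results:
the baseline-vs-control manipulation check, seven mixed 2×2 ANOVAs
(group × condition) with partial η² and Bayes factors, Bonferroni
post-hocs routed to Mann–Whitney U when normality fails, and AQ/IUS trait
correlations.

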