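# Methods

This note documents the models, parameters and design choices behind
`teamcap`: what the simulator and agents assume, what the synthetic
cohorts can and cannot stand in for, and the numerical conventions the
measurement suite uses.

## Game model

The task is a discrete-time, constant-velocity arcade game on an
800×600-px frame. Two 40-px side panels carry the secondary
detection-response task (DRT), leaving a 720-px playable span. Paddles
(100 px wide) slide along a line at y = 560 at 400 px/s; balls travel
at constant speed (default 300 px/s) from the top edge at a launch
angle uniform within ±60° of vertical, reflect elastically off the side
walls, and are point-like with a 10-px collision radius. Coordinates
use the screen convention: origin top-left, y downward; all intervals
are half-open `[start, end)`.

A trial runs exactly `tick_rate × 45` frames (60 Hz → 2,700 frames).
Each frame: paddles move by `paddle_speed / tick_rate` in the commanded
direction (clamped to the playable span, never blocking each other);
balls advance by `velocity / tick_rate`; a descending ball crossing the
paddle line over a paddle's half-width (plus the ball radius) emits a
*hit* and reflects vertically; a ball crossing the bottom edge emits a
*miss*. In the separate condition a ball interacts only with the
same-colored paddle and passes through the other. Hits score +1 to the
team (collaborative) or the hitter (separate/competitive); when both
paddles overlap the crossing ball on the same frame, credit splits
0.5/0.5.

Ball-population rules keep the manipulated workload constant within a
trial: the nominal count (1/3/5/7 balls per processing unit for the
low/medium/high/very-high levels; the separate condition fields one set
per player, team conditions one shared set) is spawned at trial start;
a missed ball is replaced 1 s later; a ball that rebounds past the top
edge re-enters immediately as a fresh descent of the same ball id (its
hit has already been credited — with straight-line kinematics a
rebounded ball can never come back down on its own). Each *descent*
therefore terminates in exactly one hit or miss, except balls still in
flight at the final frame, which are censored and excluded from every
rate denominator (an unbiased miss-rate estimator; the engine asserts
`spawns = hits + misses + censored`).

Determinism: a trial is a pure function of (seed, config, policies).
Each ball carries its own random stream seeded at spawn, so one
player's ball trajectories are bit-identical regardless of what the
other player does — this is what makes the separate condition a true
solo measurement inside a dyadic session, and it is tested by swapping
partner policies under a fixed seed.

The DRT is modelled only as far as the exclusion rule needs: onsets at
uniform 3–5-s intervals, a 2.5-s response window, and per-policy
response probability (`drt_accuracy`, human surrogates only). DRT
events are logged, never analysed further.

## Agent models

All policies share one loop: re-decide every 5 frames (~83 ms), emit
−1/0/+1 paddle commands, and pass decisions through a reaction-delay
queue (default 150 ms). When deciding, a policy steers from the
position its paddle *will* occupy once queued decisions play out;
without that compensation a delayed bang-bang controller limit-cycles
around its aim point.

**Ideal observer (simple).** Extrapolates every eligible descending
ball to the paddle line analytically (wall reflections by unfolding)
and steers toward the intercept of the soonest-landing ball. An
optional `triage=True` mode restricts attention to balls still
reachable in time; it is off by default because the pure
minimum-time-to-interception chaser — not the triaging optimiser — is
what produces a human-like error profile across workloads (see
Calibration).

**Considerate observer.** Identical, except in the collaborative
condition balls whose intercept falls within 100 px of the partner's
paddle are deprioritised (taken only when nothing else is in the air).

**Human surrogate.** The noisy ideal observer plus two
condition-dependent strategy biases: `share_bias` (collaborative) is
the per-decision probability of restricting targets to the player's own
half of the span — workspace division; `monitor_weight` (competitive)
blends the aim point toward the opponent's paddle — monitoring, which
shrinks paddle separation and drags the player out of position. Both
default to 0, in which case the surrogate is bit-identical to the
simple observer. Cohort simulations enable `share_bias = 0.8,
monitor_weight = 0.35`, chosen as a plausibly strong expression of the
two strategies; the direction (not the magnitude) of the resulting
collaborative-vs-competitive efficiency difference is the claim the
test suite checks.

**Q-learning agent.** Tabular Q over (signed paddle→ball offset binned
at 40 px) × (time-to-floor binned at 0.25 s) × {left, none, right},
trained on solo trials with hits as +1 reward, α = 0.1, γ = 0.95, ε
linear 1 → 0.05, ties favouring "none". The default 5,000 training
episodes are far more than needed; the suite trains 150 episodes, which
already beats the untrained baseline by an order of magnitude.

**Noise model.** Three channels: Gaussian aim error (resampled when the
target changes), episodic attentional lapses (no action for a sustained
`lapse_duration_s`, triggered with `lapse_prob` per decision), and the
reaction delay. Lapses are episodic rather than single-epoch because an
83-ms freeze is recoverable at every workload and cannot produce the
strongly workload-dependent error pattern humans show; a ~0.5-s lapse
is harmless with one slow ball and frequently fatal with seven.

## Calibration

`calibrate_policy` fits a single noise scalar *s* that scales the aim
noise (15 px per unit) and lapse probability (0.065 per unit, 0.5-s
episodes) jointly, so that the solo miss rate hits 0.05 at the low
workload and 0.65 at the very-high workload (±0.02, 300 trials per
probe and workload). The solo miss rate is monotone in *s*, so a
bisection on the mean of the two target discrepancies converges; common
random numbers across probes keep the objective smooth. The base-scale
ratio, the no-triage default and the 300 px/s ball speed were chosen
together so that one scalar lands inside both target bands — with
reachability triage the agent saturates near 0.50–0.54 at seven balls
under any plausible geometry and the band is unreachable.

## Measurement conventions

- **Miss rate** `1 − hits/(hits+misses)`; empty denominators signal an
  undefined cell (excluded, never zero-filled). Counts pool across the
  three repeats of a cell before the ratio.
- **C(p) = p(A)·p(B) − p(AB)** with solo rates pooled per workload from
  the separate condition; team rates exist only for
  collaborative/competitive. The sign is stored exactly; |C| ≤ 0.01 is
  *labelled* "unlimited" because an exact zero is measure-zero under
  sampling noise.
- **Balls at 40%**: the unique cubic through the four (ball count,
  miss rate) points; smallest root inside the measured range (first
  attainment as load rises). No interior crossing → least-squares
  linear fallback, flagged `crossing_valid=False`. A flat profile
  exactly at the criterion returns the lowest measured workload.
- **HCS**: 1-s windows, 1-frame stride, lag 0, Pearson correlation of
  *first-differenced* positions (raw positions are inflated by shared
  drift); a frame is highly correlated if any covering window exceeds
  the 0.97 threshold; zero-variance windows never qualify. Window
  length, stride and threshold are exposed as parameters.
- **Exclusion**: a dyad is dropped if any human member has DRT accuracy
  < 0.5 or low-workload separate miss rate > 0.5 (strict inequalities:
  exactly 0.5/0.5 is retained); machine members never trigger
  exclusion; missing cells give a distinct "unevaluable" code.
- **Aggregation**: dyad-level means per cell; the separate condition
  collapses to one value per dyad (HH: mean of the two players; HM: the
  human alone, machine solo rates excluded). Contrasts report
  collaborative − competitive and HH − HM, paired within dyads or
  Welch-t between arms; omnibus mixed ANOVAs are delegated to pingouin.

## The UCIP-null generator

`simulate_ucip_null_cohort` builds dyads whose team outcome is, by
construction, the conjunction of two independent members' outcomes:
both members play solo trials, and the team misses a ball iff both
members missed theirs. Outcomes are paired by a seeded random
permutation — the members are independent, so any pairing is a valid
conjunction, and random pairing avoids aligning within-trial structure
(ball-index effects) that would bias the null. Under this mechanism
E[C(p)] = 0 at every workload. An efficiency loss is injected by
multiplying the odds of the conjunctive team miss rate
(`penalty_odds > 1`) and resampling extra misses, which drives C(p)
negative monotonically in the penalty.

## What the synthetic cohorts do and do not show

The surrogate dyads emulate the *structure* of the study conditions —
sessions of 3 counterbalanced blocks × 12 trials, four workloads ×3 in
random order per block, the exclusion pipeline, and the two behavioural
strategies — with calibrated, human-like solo error rates. They do not
emulate learning across blocks, fatigue, communication, individual
differences beyond the noise scalar, or the particular interaction
inefficiencies of real humans. Passing tests therefore demonstrate that
the measurement chain recovers known ground truth (the UCIP null,
injected penalties, direction of the collaborative advantage), not that
the synthetic world reproduces empirical effect sizes; the study's
deposited group statistics can only be reproduced by running the
analysis adapter over the deposited data themselves.

## Problem sizes

The suite uses 300 trials per workload for calibration and
monotonicity checks (matching the calibration protocol), 200 synthetic
dyads for the UCIP-null recovery, 100 paired trials for the monitoring
effect, and a 60-dyad surrogate cohort for the direction-of-effect
check; the Q agent trains 150 episodes. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands.

## Known limitations

- Ball kinematics are straight-line; the original game's trajectories,
  spawn schedule and exact ball counts at the upper workloads are not
  documented, so 5 and 7 continue the 1, 3 progression.
- The capacity analysis uses the accuracy form of the coefficient only;
  response-time-based (integrated-hazard) capacity is out of scope.
- DRT data exist only to drive the exclusion rule.
- The flat-CSV adapter assumes per-trial hit/miss counts and (for
  behaviour metrics) paddle trajectories; it maps columns, it does not
  infer undocumented schemas.
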