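# Methods

## The control model

The decoder is a memoryless linear map from an 8-channel RMS feature
vector to a 3-DoF position estimate, `y(t) = B(t) x(t)`, with one
independent coefficient row per DoF and no intercept: resting EMG has
(near-)zero RMS and must map to the rest position `(0,0,0)`, so an
intercept would only absorb baseline activation that the model treats
as signal.  Position control is assumed (the cursor *is* the decoder
output, not its integral), and all coupling between DoFs must be
resolved by the weights, since every row sees the same features.

Adaptation is normalised LMS.  The step is scale-free in EMG amplitude
— the effective gain `μ‖x‖²/(ε+‖x‖²)` is invariant to rescaling `x` —
which matters because RMS levels vary by an order of magnitude across
channels, users and fatigue states.  Defaults: `μ = 0.5` (middle of the
(0, 2) stability range: fast without noise amplification), `ε = 1e−6`
(guards silent windows; small enough to never bias an active window),
zero initial weights (symmetric and reproducible).  For `0 < μ < 2` the
error on a repeated sample contracts by `|1 − μ‖x‖²/(ε+‖x‖²)| < 1`
per step; on stationary noiseless linear data the sequential updates
converge to the normal-equations least-squares solution (verified
against `lstsq` in the tests).

### The transition guard

One deliberate departure from "update on every new feature": adaptation
pauses for `transition_guard` seconds (default 0.2 s, one full window)
after each prompt onset, while the cursor keeps refreshing.  Windows
that straddle a prompt boundary mix EMG generated for two different
targets, and because NLMS normalises by input power these inconsistent
windows get full-strength updates.  The worst case is the transition
into a rest prompt: 4–5 windows still carry the previous target's
decaying EMG but are labelled `(0,0,0)`, and each multiplies the
learned row by `(1 − μ)` along the active direction — a ×16 erasure per
rest prompt at the defaults, enough to destroy training outright.
Guarding one window length (about a human reaction time, during which a
subject would not have switched intent anyway) makes every update a
consistent feature/target pair.  An optional linear onset ramp of the
desired signal (`onset_ramp`, default off) is provided as a softer
alternative; the step-function desired signal is the default.

## Protocols

Targets live on the grid `{−1, 0, +1}³`: 1 rest + 6 one-DoF + 12
two-DoF + 8 three-DoF = 27.  A lap is the 6 one-DoF targets in seeded
pseudo-random order (Fisher–Yates via numpy's Generator), each followed
by a rest prompt.  Protocol I is five laps; Protocols II and III are
one lap plus the 20 combined targets (each followed by rest) in seeded
order, identical between II and III at the same seed.

Prompt durations are 3 s (targets) and 2 s (rests), configurable: long
enough that the NLMS loop converges within a prompt at `μ = 0.5`, short
enough that a Protocol II session lasts ≈ 4.3 min — plausible for a
human session and cheap to simulate.

In Protocol III the cursor is shown during the 20 combined targets
only.  Rest prompts stay blind by design: a feedback-correcting user at
rest pushes *against* the cursor (`intent = −g·cursor`), producing
corrective EMG labelled "rest", and the decoder then learns that its
own corrective patterns mean zero — in simulation this collapsed 3-DoF
test completion from ~0.33 to ~0.03.  Showing feedback only while a
target is active is also the natural reading of "feedback during the
combined targets".

## The acquisition test

All 27 targets in seeded order; 20 s per target; a hit is one
uninterrupted second inside the hit radius, completing within the 20 s.
Numerical conventions:

* **Hit radius** = 10% of the workspace *diagonal* (`2√3` for DoFs
  spanning [−1, 1]), ≈ 0.346.  The diagonal is the only single scalar
  that makes "10% Euclidean error in 3-D space" well defined for every
  target including rest; a per-axis normaliser is available as a config
  switch (`radius_normalizer="axis"`).
* **Dwell convention**: trajectory sample `i` sits at time `i·tick`
  (sample 0 is the carried-over cursor at trial start); a qualifying
  hold is a consecutive inside-run whose time span reaches the hold
  duration, i.e. 26 samples at the 40 ms tick.  Holds may not straddle
  the timeout.
* **Carry-over**: cursor and the EMG window buffer persist across
  trials (a continuous session, no teleport to centre); a reset switch
  exists.  Path-efficiency numerators therefore use each trial's actual
  starting position.
* **Clipping**: the cursor is clipped to ±1.5 per DoF so an untrained
  decoder cannot run off-workspace; the virtual user's corrected intent
  is clipped to the same bound.
* During the test the user *sees* the cursor (the task is a feedback
  task), so the proportional correction applies under every protocol;
  only the decoder is frozen.

## Metrics

CR = hits / trials.  PE = straight-line distance from the trial's
start to the target over the distance actually travelled, computed up
to the moment of the hit (full trajectory on misses), averaged over the
trials of a stratum that have a defined value.  PE is undefined when
the start coincides with the target (typically the rest trial after a
rest-adjacent trial) or when the cursor never moved, and is capped at
1.0 — on a miss with a nearly stationary cursor the ratio would
otherwise exceed 1 without meaning the path was efficient.  AR = total
entrances into the hit region over the number of hits, undefined (and
reported absent, never 0) when nothing was hit.  Strata: rest, 1-, 2-,
3-DoF, and overall; group comparisons across protocols use the Friedman
test from scipy on the per-user stratum values.

## The virtual user

What it emulates: EMG as amplitude-modulated zero-mean noise (the
standard surface-EMG envelope model) whose per-channel standard
deviation is a rectified linear synergy of the intent,
`a = max(0, S·d + baseline)`, so a window's expected RMS is ≈ `a` —
exactly the statistic the decoder consumes.  Synergies pair channels as
agonist/antagonist per DoF (loading +1/−1) with Gaussian crosstalk and
per-channel gain spread, redrawn until full column rank with condition
number < 10, so intent is decodable from RMS.  Under feedback the user
corrects proportionally, `intent = prompt + g(prompt − cursor)` with
`g = 0.5`, clipped to ±1.5.  Difficulty presets set the per-window RMS
jitter, crosstalk and baseline: easy (0.05/0.1/0.02), medium
(0.1/0.3/0.05), hard (0.2/0.5/0.1).

Two emission modes: `"gaussian"` (default) draws Gaussian samples, so a
40-sample window's RMS scatters ~11% (chi-distribution) around `a` even
with zero jitter; `"deterministic"` emits a zero-mean alternating-sign
carrier whose window RMS equals `a` exactly.  `make_ideal_user`
combines the deterministic carrier with a crosstalk-free synergy and
zero baseline: the noise-free, exactly invertible construction used for
parameter-recovery validation.

What it does **not** emulate — and what passing tests therefore do not
show about real use: motor-unit physiology (spikes, conduction
velocity, signal-dependent noise spectra), electrode shift, fatigue and
learning curves (a slow synergy drift hook exists, default off), human
reaction latency, or any richer visuomotor strategy than proportional
error correction.  Simulated cohort numbers are internally consistent
measurements of this generative model, not predictions of human
performance; only the *direction* of the protocol effect (co-adaptive,
combined-target training ≥ blind 1-DoF training on multi-DoF targets)
is expected to transfer qualitatively.

## Problem sizes

The test suite trains and tests single users at the nominal session
sizes (52–60 prompts, 27 test targets) and runs a 20-user paired cohort
for the protocol-ordering property; oracle checks use 600–5,000 sample
pairs, 1,000 random prediction cases and 1,000 random trajectories for
the hit detector.  `scripts/acceptance.py` simulates the 20-user cohort
under all three protocols (~1 min on one core).

## Known limitations

* The proportional feedback model makes co-adaptation helpful mainly
  through better coverage of the combined-target region and corrected
  operating points; it cannot reproduce strategy-level human learning,
  so between-protocol gaps are smaller than in human cohorts.
* Closed-loop sessions are logged but deliberately not replayable
  offline; only open-loop recordings retrain bit-identically.
* PE on missed trials mixes "never left the start" with "wandered far"
  under a single capped ratio; interpret stratum PE together with CR.
* The 27-target grid and the diagonal-normalised hit radius are fixed
  conventions of the task; other normalisers change CR levels (not
  orderings) and are exposed as configuration.
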