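# finloop

A hardware-free implementation of a closed-loop operant conditioning
platform for fish, aimed at behavioural researchers who want to prototype,
test, and analyse two-alternative forced-choice protocols — acquisition,
reversal, and trial-randomised colour discrimination — without a physical
rig.

In the real rig, a goldfish swims in a 60 × 30 cm Y-maze tank whose screen
end is split into two arms by an opaque divider; a monitor behind the screen
wall shows coloured circle stimuli, an overhead camera tracks the fish, and
pellet feeders deliver rewards. `finloop` reproduces the *software* core of
such a rig:

- **`finloop.tracking`** — the real-time video pipeline: crop → RGB-to-HSV →
  per-subject HSV threshold → median smoothing → centroid extraction, with
  ROI pixel-sum entry detection and a screen-probe luminance readout that
  encodes the task epoch in the tracking file.
- **`finloop.engine`** — the closed-loop trial state machine: ITI (black
  screen, behaviour has no consequences) → trial available (grey screen) →
  start-zone entry triggers stimulus onset → first choice-zone entry latches
  the choice → fixed outcome delay → pellet or omission → next ITI. Includes
  the pre-training protocols (choice-zone training, staged start-position
  training) and the main acquisition / reversal / colour-randomised presets.
- **`finloop.virtual_tank`** — a synthetic top-view video generator and a
  learning fish agent (Rescorla–Wagner values, softmax choice, noisy
  goal-directed swimming) that closes the loop entirely in software.
- **`finloop.io_logs`** — the platform's headerless CSV event list
  (`name,t,code`) and tracking file (`x,y,luminance`), plus a reader for the
  five-panel per-subject supplementary layout used for group statistics.
- **`finloop.analysis`** — trial reconstruction from event logs, choice
  proportions, initiation/response times, tercile splits, occupancy
  heatmaps, and the statistical battery: arcsine square-root transform
  (asin √p), one-sided one-sample *t* tests against 50 %, paired *t* tests,
  and one-way repeated-measures ANOVA.

## The model in brief

The simulated subject holds a value `V(c) ∈ [0, 1]` for each cue `c` (a side
or a stimulus colour). After each trial it updates the chosen cue by the
delta rule

    V ← V + α (λ − V),     λ = 1 if rewarded, 0 otherwise,

and chooses between the two offered cues with a softmax,

    P(left) = exp(β V_left) / (exp(β V_left) + exp(β V_right)),

where `α` is the learning rate and `β` the inverse temperature (β = 0 is an
indifferent chooser; large β is greedy). The agent perceives the task
symbolically (it reads the screen specification, not pixels); only the
tracker consumes rendered frames, so closed-loop tests exercise the
platform, not a model of fish vision.

## Worked example

Simulate a naive side-learning agent (α = 0.3, β = 5) on a 12-trial
acquisition session and summarise it from its own event log:

```bash
$ finloop simulate --phase acquisition --seed 7 --trials 12 \
      --beta 5 --alpha 0.3 --out demo
completed 12 trials; proportion correct = 0.750
logs written to demo

$ finloop analyze --events demo/events.csv
n_trials: 12
proportion_correct: 0.75
median_initiation_s: 5.045500000000004
median_response_s: 3.908999999999999
median_response_correct_s: 3.908999999999999
median_response_incorrect_s: 3.818999999999999
tercile_proportions: [0.25, 1.0, 1.0]
```

The tercile proportions (first/middle/last third of the session) show the
agent acquiring the side preference within the session: 25 % correct in the
first third, 100 % thereafter. Initiation time is the latency from trial
availability to start-zone entry; response time the latency from stimulus
onset to the choice-zone entry. The same `analyze` command accepts logs
recorded by a real rig in the same three-column format.

Group-level statistics from per-subject panels (a workbook or per-tab CSV
exports) are recomputed with:

```bash
finloop repro-fig3 --supplement path/to/panels
```

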