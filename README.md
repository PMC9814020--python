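# tracebench

Diagnostic classical-conditioning benchmarks for *online* multi-step
prediction, together with the standard baseline learners.

Animals readily learn to predict a distal outcome (an air puff to the eye)
from a cue (a tone) across a stimulus-free gap — trace conditioning.  For a
learning system this is a state-construction problem: the immediate
observation carries no signal during the gap, so the agent must summarize
its input history on its own.  `tracebench` provides three seeded
discrete-time generators that isolate facets of this problem:

* **trace conditioning** — one conditioned stimulus (CS), a stochastic
  inter-stimulus interval (ISI), an unconditioned stimulus (US) to be
  predicted, and free-running Poisson distractor channels: a pure temporal
  memory problem;
* **noisy patterning** — several simultaneous CSs of which only particular
  balanced configurations ("activation patterns") trigger the US, plus
  outcome noise and distractors: a nonlinear selection problem with no
  temporal gap;
* **trace patterning** — both at once.

The prediction target is the discounted return of the US channel
(Unicode: `G_t = Σ_k γ^k US_{t+k+1}`), with `γ = 1 − 1/E(ISI)` so the
prediction horizon matches the trial timing.  Agents predict online, every
step; accuracy is the mean squared return error (MSRE) against returns
recomputed retrospectively from the logged US stream.

Baselines included, all trained by semi-gradient temporal-difference
learning:

* linear TD(λ) over five fixed representations — presence bits,
  stimulating traces, tile-coded traces, Gaussian microstimuli, and an
  echo state network (fixed random reservoir with prediction feedback);
* vanilla RNN, LSTM, and GRU state constructors with a linear value head,
  trained online by truncated backprop through time (T-BPTT, stale boundary
  state, overlapping windows, update every step) or real-time recurrent
  learning (RTRL, forward influence matrix, stale-Jacobian protocol), with
  optional stimulating-trace input augmentation.

See `docs/methods.md` for the model details, defaults, and design choices.

## Worked example

A microstimulus TD(λ) agent on short-ISI trace conditioning
(`ISI ~ U(7,13)`, hence `γ = 0.9`), three seeded runs:

```yaml
# microstimulus.yaml
env:
  kind: trace_conditioning
  isi_range: [7, 13]
agent:
  kind: linear
  representation: microstimulus
  alpha: 0.0009765625
n_steps: 50000
n_runs: 3
seed_base: 0
```

```text
$ tracebench run microstimulus.yaml --outdir out --write-logs
MSRE 0.048496 (stderr 0.00020388427497551164, 3 runs x 50000 steps)

$ tracebench profile out/run000.csv --window -2 12
 offset  mean_prediction  mean_return  mean_us
     -2         0.115632     0.616819 0.000000
     -1         0.114603     0.685354 0.000000
      0         0.638398     0.761505 0.000000
      1         0.741806     0.846116 0.000000
      ...
      6         1.104596     1.432905 0.000000
      7         1.089643     1.397488 0.175166
      8         0.955560     1.200460 0.317073
      ...
451 trials averaged
```

Offset 0 is CS onset.  The learned prediction is near the bias level before
the cue, jumps at CS onset, climbs through the stimulus-free trace interval
as the microstimulus features unfold, and peaks just before the US arrives
(offsets 7–13 under the stochastic ISI) — the profile a well-trained
trace-conditioning predictor should show.  The mean return exceeds the mean
prediction before CS onset because the CS itself is unpredictable by
design.  Under the same protocol a presence-representation agent stays near
its bias weight throughout the gap and lands at roughly triple the MSRE.

The same CLI drives sweeps (`tracebench sweep config.yaml grid.yaml`) and
summary tabulation (`tracebench report out/`); everything is equally
accessible as a library (`tracebench.runner.run`, `sweep`,
`extract_profile`).

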