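# Methods

## The prediction problem

All three benchmarks are uncontrolled, partially observable discrete-time
dynamical systems.  At each step the agent sees a binary stimulus vector
`o_t` (CS channels, one US channel, distractor channels) and must emit a
scalar prediction `V_t` of the discounted return of the US channel,

    G_t = sum_{k>=0} gamma^k US_{t+k+1},        0 <= gamma < 1.

The discount is tied to the timing of the problem: `gamma = 1 - 1/E(ISI)`,
so the prediction horizon `1/(1-gamma)` matches the expected interval
between CS onset and US onset.  Returns are computed retrospectively from
the logged US stream by the backward recursion `G_t = US_{t+1} + gamma
G_{t+1}`; they are evaluation-only quantities and never visible to the
learner.  Performance is the mean squared return error (MSRE): the squared
gap between the online prediction and the return, averaged over steps, with
the final `ceil(log(tol)/log(gamma))` steps of every run masked out because
their returns are biased by the truncation of the tail (`tol = 1e-8` by
default; tightening it to `1e-12` changes no unmasked return by more than
1e-7).  We exclude nothing else — no warm-up period — so MSRE includes the
inter-trial intervals.

## The environments

**Trace conditioning.**  A single CS is shown for 4 steps; the US follows
ISI steps after CS onset and lasts 2 steps; the next trial starts ITI steps
after US onset.  ISI and ITI ranges are inclusive integer intervals read as
discrete uniform distributions (so `Unif(7,13)` has expectation exactly 10;
the standard difficulty settings are short `U(7,13)`, medium `U(14,26)`,
long `U(20,40)`, and ITI `U(80,120)`).  Ten free-running binary distractors
carry no information about the US: each inactive channel turns on with
probability `1/mean_interval` per step (mean intervals 10, 20, ..., 100) and
stays on for 4 steps, the simplest discrete-time realization of a Poisson
event process; onsets arriving while a channel is active are ignored, so
back-to-back episodes can merge in the bit stream.  Distractors run through
the ITI as well.

**Noisy patterning.**  `n` CSs and `m` trial-locked distractors are shown
simultaneously for 4 steps at trial start.  `k` activation patterns, drawn
once per environment without replacement from the balanced configurations
(exactly n/2 active CSs), define the outcome rule: the US fires (ISI fixed
at 4 steps, hence `gamma = 0.75`) iff the CS configuration matches a
pattern, XOR a per-trial noise flip with probability `noise_pct/100` (one
mechanism covering both false-negative and false-positive outcomes).  Half
of the trials present an activation pattern; the other half draw uniformly
from the complement of the activation set over all `2^n` configurations
(the composition of non-activating trials has no canonical definition;
uniform-over-the-complement is this package's choice).  Distractors are i.i.d. Bernoulli(0.5) per trial and co-occur with
the CSs; they do not appear during the ITI.  The ITI is anchored at the
scheduled US-onset time whether or not the US fires.  Difficulty presets
`easy` (6 CS / 4 patterns / 5 distractors / 5% noise), `medium` (8/8/10/10%,
the standard configuration and the default) and `hard` (10/16/20/15%) are
this package's own settings.

**Trace patterning** combines both: pattern-based outcomes, stochastic ISI,
and free-running Poisson distractors (defaults 8 CSs, 8 patterns, 10
distractors, 10% noise).

Trial annotations (trial id, phase, pattern membership, noise flip) are
emitted on a side channel used only for evaluation and profile extraction.
Every environment is exactly reproducible from its config and seed; the
activation patterns use an init stream separate from the trial stream.

## Fixed representations

All five constructors append a constant bias feature and treat every
channel identically (the US and distractors get traces and features exactly
like the CSs).

* **Presence** — the observation bits themselves.  During the trace
  interval only the bias is active, so the representation cannot support a
  rising prediction there; it serves as the failure baseline.
* **Stimulating traces** — per-channel memories `y` set to 1 at a rising
  edge of the channel and decaying as `y <- tau y` on every subsequent step,
  including while the stimulus stays on (onset-triggered, not
  level-triggered).  The default decay is tied to the problem timing,
  `tau = 1 - 1/E(ISI)`, reading the decay amount per step as `1/E(ISI)`;
  `trace_decay_from_expected_isi` also exposes a time-constant reading
  `tau = exp(-1/E(ISI))` because the two are easily conflated.
* **Tile-coded traces** — each trace discretized by `n_tilings` (default 2)
  tilings of `n_tiles` (default 8) tiles with deterministic, evenly spaced
  offsets `j/(n_tilings * n_tiles)`; exactly one tile per tiling is active
  (index `floor((y + offset) * n_tiles)`, clamped).  Hashing is pointless in
  a 1-D input space, so tiles are laid out explicitly.
* **Microstimulus** — trace-height-modulated Gaussians
  `y * exp(-(y - c_i)^2 / (2 sigma_t^2))` at centers `c_i = i/n_rbfs`
  (default 8 RBFs).  The width parameter (default 0.8) is expressed in units
  of the inter-center spacing, `sigma_t = sigma / n_rbfs`, the convention of
  the microstimulus literature.  Read instead in raw trace units, 0.8 makes
  the eight basis functions nearly collinear (each approximately equal to
  `y`), the features no longer unfold sequentially over the trial, and the
  learned prediction peaks early instead of just before the US — so the
  spacing-units reading is the default.
* **Echo state network** — `h <- tanh(W_in o + W h + W_fb V_{t-1})` with all
  three weight groups fixed at init: `W_in` and `W_fb` symmetric two-point
  (+/- input_scaling), `W` sparse (default density 0.1) and rescaled to a
  spectral radius below 1 (default 0.9, the echo-state condition).  The
  feedback input is the previous step's own prediction, keeping the
  construction causal.  Only the linear readout is ever trained.

## Linear TD(lambda)

The value estimate is `V_t = w^T x_t`.  Updates use the semi-gradient TD
error `delta_t = US_{t+1} + gamma V_{t+1} - V_t` with `V_{t+1}` evaluated
under the pre-update weights, and the accumulating eligibility trace
`z <- gamma lambda z + x_t` (`lambda = 0.9` for all fixed representations).
Two optimizers are provided: plain SGD (`w <- w + alpha delta z`, the
classic rule, used by the convergence oracles) and the default
adaptive-moment rule, which receives `-delta z` as the gradient surrogate
(bias-corrected moments, beta1 = 0.9, beta2 = 0.999, eps = 1e-8, one shared
step counter).  How moment estimates should interact with eligibility
traces has no canonical answer; feeding the trace-weighted semi-gradient to
the standard update is this package's choice, and the step size `alpha` is
the optimizer's learning rate in sweeps.

## Recurrent learners

Vanilla RNN, LSTM (forget-gate bias initialized to 1), and GRU cells with a
linear value head; all other weights start uniform on
`(-1/sqrt(n_hidden), 1/sqrt(n_hidden))`, the head at zero.  Targets are
semi-gradient TD(0) (`lambda = 0`), with the bootstrap term treated as a
constant.  Gradient clipping is off by default (a config option exists).

**T-BPTT.**  At each step the last `T` observations are re-unrolled from
the boundary hidden state `x_{t-T-1}` that was captured when it left the
window — stored stale, computed under the parameters current at that time,
and never recomputed.  The `T` per-step losses
`0.5 (US_{k+1} + gamma stopgrad(V_{k+1}) - V_k)^2` are summed (not
averaged) over the window, the newest bootstrap being the online `V_t`, and
one adaptive-moment update is applied to all parameters.  Updates fire on
every step once the buffer has filled (a `stride` option trades this
fidelity for speed).  The behavior state is always the incrementally
computed online state; window recomputation feeds gradients only.

**RTRL.**  A forward influence matrix `J_t = d state_t / d theta` (rows:
hidden state, plus the cell state for the LSTM; columns: all recurrent
parameters) is propagated as `J <- (dF/dstate) J + dF/dtheta` with the
local Jacobians evaluated during the forward pass at the current
parameters.  The value gradient is assembled as `w_out^T J_h` plus the
exact head gradients, and a TD(0) update is applied every step.  `J` is
never reset after an update — the stale-Jacobian protocol — so it tracks
sensitivity to the drifting parameter history.  With parameters frozen the
recursion is exact: the accumulated RTRL gradient equals full-unroll
backprop from the origin to machine precision, which is how the kernels are
tested.  Per-step cost grows as O(state_dim x n_params), i.e. quartically
in the hidden size for a fully connected cell.

**Stimulating-trace augmentation.**  Optionally the input is extended to
`[o_t ; y_t]` with one stimulating-trace bank per configured decay (default
`tau = 1 - 1/E(ISI)`, matching the fixed representations); the learner is
otherwise unchanged.  This hands the network the temporal memory it would
otherwise have to discover, which is why a T=1 window then suffices.

## Orchestration and seeding

Run `i` of an experiment uses seed `seed_base + i`; a `SeedSequence` derives
independent sub-streams for the environment and the learner init, and the
environment splits again into a pattern-init stream and a trial stream.
Sweeps enumerate the Cartesian grid in ascending order and keep the first
strictly best mean MSRE, so ties break toward the smallest hyperparameter
values.  Summaries embed the resolved config, its digest, and the seed
base; every reported number is recomputable from the per-step log CSV.

## Scaled study conditions

Full-scale runs (2M-5M steps, 30 runs, full sweep grids) are supported
through the same runner but the shipped studies use desk-scale conditions,
chosen once and stated here:

* Fixed-representation comparison: short-ISI trace conditioning, 200k
  steps, step sizes swept over {2^-6, 2^-8, 2^-10, 2^-12} with the
  lowest-MSRE setting selected per representation.
* Recurrent comparison: same problem, LSTM with 16 hidden units, 5 seeds,
  200k steps, Adam step size 2^-9 (selected by a coarse sweep under the
  same lowest-MSRE protocol; larger steps destabilize the T=10 window).
* Truncation-sensitivity curve: 8 hidden units, 120k steps, 5 seeds,
  T in {1, 5, 10, 20}.

At these scales the qualitative orderings reproduce: trace-based
representations roughly quarter the presence representation's MSRE;
T-BPTT with a window shorter than the trace interval is no better than
presence-level while T=10 bridges the gap; RTRL matches or beats the best
truncated window; and trace augmentation lets a T=1 window reach T=10
performance.

## What the generators do and do not emulate

The benchmarks are deliberately minimal: binary stimuli, trial-locked
timing, stationary statistics.  Passing the shipped studies shows that a
learner can bridge a stimulus-free gap, select relevant configurations
under noise, or both — it says nothing about continuous or high-dimensional
sensors, overlapping (delay-conditioning) stimulus arrangements,
action-conditional dynamics, or non-stationary environments, none of which
the generators model.  Distractor channels are independent of the outcome
by construction; real sensory streams rarely offer that guarantee.

## Numerical notes and limitations

* Returns are computed by a reverse IIR filter; the recursion identity
  holds to 1e-10 on generated streams.
* Tile indices clamp at the last tile so a trace of exactly 1 is valid;
  microstimulus features are Lipschitz in the trace with constant
  `1 + 1/(sigma_t sqrt(e))`.
* The ESN spectral radius is set by dense eigenvalue computation —
  adequate for reservoir sizes up to a few hundred.
* Non-finite TD errors or activations abort a run with a diagnostic rather
  than propagating NaNs into logs.
* The recurrent kernels are compiled with numba on first use; the first
  call in a fresh environment pays a one-time compilation cost.
* RTRL memory is O(state_dim x n_params) and becomes the binding constraint
  before compute does for hidden sizes beyond a few dozen.
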