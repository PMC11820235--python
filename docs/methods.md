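# Methods

## Task and noise model

Both environments are episodic deterministic MDPs with a single rewarded
terminal state. The agent's position is encoded as a one-hot vector
φ(s) over all observable cells; every observation the agent receives is
o = φ(s) + ε with ε ~ N(0, σ²I) drawn independently per step and per
coordinate. Noise enters *only* the observation: transitions and the
scalar reward are exact. One fresh percept is drawn per environment step;
the percept of s_{t+1} is used both in the learning update at time t and
for action selection at time t+1, mirroring a sensor that is read once per
step. A Gaussian block is consumed from the random stream even at σ = 0 so
that runs differing only in σ see identical exploration randomness.

Invalid moves (off the track, into a wall) leave the agent in place and
consume a step: the action set is the same everywhere and a blocked move
is a wasted step, the common grid-world convention. Entering the goal pays
reward 1 and terminates; hitting the step cap (100 steps in the 1D chain,
200 in the 2D arena) truncates the episode with reward 0. A goal entered
exactly on the cap step counts as success. The 2D arena indexes all 49
cells row-major; observations span wall cells too, so the observation is
49-dimensional while only 25 states are reachable. Start and goal are the
bottom-right and top-left navigable corners, 8 moves apart.

## Agents

All four agents share the ε-greedy policy (uniform exploration with
probability ε, uniform tie-breaking among greedy maxima otherwise) and the
per-episode schedule ε ← max(0.99 ε, 0.01), ε₁ = 1, which first hits its
floor at episode 460 (= ⌈log 0.01 / log 0.99⌉ + 1). All weights start at
zero; all learning rates default to 0.1 and γ to 0.95.

*Q / Q(λ).* Linear action values Q(o,a) = w_a·o with the one-step TD
target r + γ max_a′ Q(o′,a′). Q(λ) keeps an accumulating eligibility trace
shaped like the weights, with no trace cut on exploratory actions (naive
Q(λ)), since the source formulation gives only e ← γλe + φ.

*SF / PF.* One successor matrix per action, ψ_W(o,a) = W_a o, a shared
reward vector w_r, values ψ·w_r. The successor TD error is
δ_sf = o + γψ(o′,a*) − ψ(o,a) with a* the greedy next action (off-policy,
matching the Q target; an optional `next_action` argument supports
on-policy evaluation of a fixed policy instead). W_a moves by the outer
product α_W δ_sf ⊗ o (SF) or ⊗ e with the feature trace e ← γλe + o (PF).
w_r follows the delta rule w_r ← w_r + α_r (r − o′·w_r) o′.

*Terminal bootstrap.* Entering the goal is the only true terminal;
truncation at the cap still bootstraps. Q-style agents drop the bootstrap
at the terminal (target = r). SF/PF instead use ψ(terminal) := φ(terminal)
— the successor target at a goal transition is o + γo′ — so the goal state
occupies itself and nothing after. This is forced by the factorised value
form: the reward vector concentrates on the goal coordinate, so if the
goal's own feature never entered the occupancy estimate, ψ·w_r would
vanish identically and the SF/PF agents could not solve episodic tasks at
all. It also makes the fixed point of frozen-policy learning exactly
(I − γP_π)⁻¹ with the terminal row of P_π zeroed, which the tests exploit
as an analytic oracle.

## The percept interface (`observation_mode`)

How the noisy vector enters the update rules is genuinely underdetermined
by the formalism, and the two natural readings differ sharply under noise:

* **linear** — o replaces φ everywhere: values, TD targets, outer-product
  updates and traces all operate on the raw noisy vector (linear function
  approximation).
* **decoded** — the agent first self-localizes by maximum likelihood
  (for one-hot signal plus isotropic Gaussian noise this is argmax(o)) and
  feeds the exact one-hot of the estimate through the same rules, which
  thereby become the tabular algorithms; noise acts only through
  occasional mislocalization (≈0% of steps at σ = 0.05, ≈3% at 0.25,
  ≈45% at 0.5 in the 20-state chain).

Both interfaces are implemented for every agent as a percept transform in
front of unchanged update rules; they coincide exactly at σ = 0. The
package defaults are per-family: the value-based Q and Q(λ) agents use
`linear` (their defining equation takes the received observation as its
only state input), the map-based SF and PF agents use `decoded` (the
predictive-map account separates localization from valuation). Two
empirical findings, reproducible with this package, motivated the split:

1. With the `linear` interface, the 2D arena results are reproduced
   essentially exactly for *all eight* agent variants at all three noise
   levels — including the counterintuitive collapse of the λ = 0.9 agents
   at *low* noise and their partial recovery at moderate noise.
2. In the 1D chain, the `linear` interface makes every agent collapse for
   any σ > 0: noise destroys the exact-value ties whose random resolution
   is what keeps a 20-state chain explorable after ε anneals, a per-step
   weight shrinkage of order ασ² erases value structure between rare
   successes, and the max operator rectifies observation noise into
   self-reinforcing spurious preferences near the start wall. The
   `decoded` interface restores the 1D successor-feature robustness and
   the λ-sensitivity of PF, which is the regime of interest.

Limitations of the defaults: at σ = 0.5 in the 1D chain, 45% per-step
mislocalization corrupts the decoded map faster than it can be learned,
so our SF agent degrades more steeply between σ = 0.25 and σ = 0.5 than
the published 1D numbers, and decoded PF(λ=0.9) shows no fragility at
σ = 0.05 where the published 1D numbers do. No single interface we tested
reproduces every published 1D cell; the reference implementation for the
1D study was not available to consult.

## Experiment protocol and seeding

A trial trains a fresh agent for 3000 episodes; a condition (environment ×
agent × λ × σ) is replicated over independent trials — 100 in the full
design, 20 in the desk-scale profile used by the acceptance checks, which
the tests compensate for by widening the comparison band with √5 on
published SEMs. Trial seeds derive deterministically from (master seed,
condition id, trial index) through `numpy` seed sequences, so trials share
no state, execution order is irrelevant, and adding a condition never
perturbs another. ε is constant within an episode, decays between
episodes, and resets per trial; eligibility traces reset at every episode
start.

Per-step randomness follows a fixed layout (one Gaussian block per
observation, one uniform per action choice, one integer draw only when
exploring or when the greedy set is tied), shared bit-exactly by the two
execution engines: a readable numpy reference path and a numba-compiled
fast path used for full-scale runs (numba implements the same Mersenne
Twister and dispatches dot products to the same BLAS). Their equality over
whole trials, including final weights, is asserted in the suite.

## Statistics

Per-condition summaries report mean, SEM (sample SD over √n, flagged
undefined below n = 2), quartiles by linear interpolation of order
statistics, and the mean/SEM stability ratio (flagged, not infinite, when
SEM = 0). Episode-length curves use a 20-episode trailing moving average
whose partial initial windows average the available prefix; the
final-window statistic is the average length of the last 20 episodes.
Episode-outcome counts bin lengths into short (< 30 steps), intermediate,
and cap-length. Threshold first-passage statistics report the first
episode whose length is ≤ θ for θ ∈ {20, 40, 60}; trials that never attain
a threshold are censored at their last episode and the censored fraction
is reported alongside both the censored mean and the attained-only mean.
The analytic discounted occupancy M = (I − γP)⁻¹ of a fixed policy serves
as the convergence oracle for successor learning; for row-stochastic P its
rows sum to 1/(1−γ).

## Numerical notes and degenerate cases

Greedy selection is NaN-safe: if action values are all-NaN — which happens
when an off-default configuration genuinely diverges, e.g. linear-mode PF
with λ = 0.9 under strong noise, whose trace-amplified outer products
overflow — the policy falls back to a uniform draw so the trial completes
and records cap-length episodes rather than crashing. Ties in greedy
action selection are broken uniformly at random (exact float equality); in
the bootstrap's argmax the first maximum is taken, which is
deterministic and requires no randomness since equal maxima give equal
targets. The fast and reference engines mirror each other's operation
order exactly so both produce identical floats.

## What the generator does and does not emulate

The environments generate exactly the study conditions: deterministic
grids, isotropic Gaussian observation noise, noise-free rewards, fixed
hyperparameters. They do not model correlated or state-dependent sensor
noise, stochastic transitions, moving obstacles, or reward noise, so
passing results say nothing about those regimes; the 2D arena's small size
also means a random policy often stumbles into the goal within the
200-step cap, which inflates cumulative reward for *all* agents at high
noise and should be kept in mind when reading σ = 0.5 columns.
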