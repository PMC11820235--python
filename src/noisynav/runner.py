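"""Episode/trial/experiment orchestration with reproducible seeding.

The protocol: each *trial* trains a fresh agent for ``n_episodes`` episodes
(3000 in the full study), with epsilon starting at 1.0 and decaying once per
episode; a *condition* (environment x agent x sigma x lambda) is repeated
for ``n_trials`` independent trials (100 in the full study) whose seeds are
derived deterministically from a master seed, the condition id and the
trial index, so no trial shares randomness with any other and adding or
reordering conditions never perturbs existing results.

Two execution engines produce bit-identical trajectories:

``engine="python"``
    The readable reference path: :class:`~noisynav.agents` objects stepped
    through :func:`run_episode`, one numpy op per update term.

``engine="numba"`` (default)
    A jit-compiled kernel per agent family that replays exactly the same
    arithmetic and random-stream layout.  numba's legacy ``np.random``
    implements the same Mersenne Twister as ``numpy.random.RandomState``
    and its ``np.dot`` dispatches to the same BLAS, so the two engines
    agree to the last bit (this is asserted in the test suite).

Random-stream layout per trial (one RandomState seeded per trial): at each
episode start one ``dim``-long Gaussian block for the initial observation;
then per step one uniform (explore/exploit), one randint only if exploring
or if the greedy set is tied, and one ``dim``-long Gaussian block for the
next observation.  Gaussian blocks are drawn at every noise level,
including sigma = 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from numba import njit

from .agents import (
    AGENT_KINDS,
    DEFAULT_OBSERVATION_MODES,
    OBSERVATION_MODES,
    AgentParams,
    decay_epsilon,
    make_agent,
)
from .env import EnvState, GridSpec, chain_1d, env_step, grid_2d, observe

__all__ = [
    "ExperimentConfig",
    "EpisodeRecord",
    "TrialRecord",
    "derive_trial_seed",
    "run_episode",
    "run_trial",
    "run_experiment",
    "greedy_rollout",
]

ENV_BUILDERS = {"1d": chain_1d, "2d": grid_2d}


@dataclass(frozen=True)
class ExperimentConfig:
    """One experimental condition plus its replication settings."""

    env: str = "1d"  # "1d" | "2d"
    sigma: float = 0.0
    agent_kind: str = "sf"
    lam: float = 0.0
    n_trials: int = 100
    n_episodes: int = 3000
    master_seed: int = 0
    observation_mode: str = "default"  # "default" | "linear" | "decoded"
    params: AgentParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.env not in ENV_BUILDERS:
            raise ValueError(f"env must be one of {tuple(ENV_BUILDERS)}")
        if self.agent_kind not in AGENT_KINDS:
            raise ValueError(f"agent_kind must be one of {AGENT_KINDS}")
        if self.observation_mode not in ("default",) + OBSERVATION_MODES:
            raise ValueError(
                f"observation_mode must be 'default' or one of {OBSERVATION_MODES}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_trials < 1 or self.n_episodes < 1:
            raise ValueError("n_trials and n_episodes must be >= 1")
        if self.params is None:
            object.__setattr__(self, "params", AgentParams(lam=self.lam))
        elif self.params.lam != self.lam:
            object.__setattr__(self, "params", replace(self.params, lam=self.lam))

    @property
    def resolved_observation_mode(self) -> str:
        if self.observation_mode == "default":
            return DEFAULT_OBSERVATION_MODES[self.agent_kind]
        return self.observation_mode

    @property
    def condition_id(self) -> str:
        lam = f":lam={self.lam:g}" if self.agent_kind in ("q_lambda", "pf") else ""
        obs = ""
        if self.resolved_observation_mode != DEFAULT_OBSERVATION_MODES[self.agent_kind]:
            obs = f":obs={self.resolved_observation_mode}"
        return f"{self.env}:{self.agent_kind}{lam}{obs}:sigma={self.sigma:g}"

    def grid(self) -> GridSpec:
        return ENV_BUILDERS[self.env]()


@dataclass(frozen=True)
class EpisodeRecord:
    """Outcome of one episode: 1-based index, steps taken, terminal reward."""

    episode_index: int
    length: int
    reward: float


@dataclass
class TrialRecord:
    """Per-episode outcomes of one independent training run."""

    trial_index: int
    seed: int
    lengths: np.ndarray  # (n_episodes,) int64
    rewards: np.ndarray  # (n_episodes,) float64
    final_weights: dict = field(default_factory=dict, repr=False)

    @property
    def cumulative_reward(self) -> float:
        return float(self.rewards.sum())

    @property
    def n_episodes(self) -> int:
        return int(self.lengths.size)


def derive_trial_seed(master_seed: int, condition_id: str, trial_index: int) -> int:
    """Deterministic, collision-resistant per-trial seed (< 2**31)."""
    cond = zlib.crc32(condition_id.encode("utf8"))
    ss = np.random.SeedSequence([int(master_seed), cond, int(trial_index)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Reference engine
# ---------------------------------------------------------------------------


def run_episode(
    spec: GridSpec,
    agent,
    sigma: float,
    epsilon: float,
    rng: np.random.RandomState,
    episode_index: int = 1,
) -> EpisodeRecord:
    """observe -> act -> step -> learn until goal or step cap."""
    dim = spec.observation_dim
    state = EnvState(current=spec.start_index)
    o = observe(state.current, dim, sigma, rng)
    r = 0.0
    while not state.done:
        a = agent.act(o, epsilon, rng)
        state, r = env_step(spec, state, a)
        o_next = observe(state.current, dim, sigma, rng)
        terminal = state.current == spec.goal_index
        agent.learn(o, a, r, o_next, terminal)
        o = o_next
    return EpisodeRecord(episode_index, state.steps_taken, r)


def _run_trial_python(config: ExperimentConfig, trial_seed: int) -> tuple:
    spec = config.grid()
    rng = np.random.RandomState(trial_seed)
    agent = make_agent(
        config.agent_kind,
        config.params,
        spec.n_actions,
        spec.observation_dim,
        rng,
        observation_mode=config.resolved_observation_mode,
    )
    p = config.params
    eps = p.epsilon0
    lengths = np.empty(config.n_episodes, dtype=np.int64)
    rewards = np.empty(config.n_episodes, dtype=np.float64)
    for ep in range(config.n_episodes):
        agent.begin_episode()
        rec = run_episode(spec, agent, config.sigma, eps, rng, ep + 1)
        lengths[ep] = rec.length
        rewards[ep] = rec.reward
        eps = decay_epsilon(eps, p)
    if config.agent_kind in ("q", "q_lambda"):
        weights = {"weights": agent.weights}
    else:
        weights = {"W": agent.W, "w_r": agent.w_r}
    return lengths, rewards, weights


# ---------------------------------------------------------------------------
# Fast engine (numba kernels; same arithmetic, same stream)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _percept(o: np.ndarray, decode: int) -> np.ndarray:
    """Mirror of agents.decode_observation (identity in linear mode)."""
    if decode == 0:
        return o
    phi = np.zeros(o.size)
    phi[np.argmax(o)] = 1.0
    return phi


@njit(cache=False)
def _select_action(values: np.ndarray, epsilon: float) -> int:
    """Mirror of agents.epsilon_greedy on a precomputed value vector."""
    n = values.size
    if np.random.random_sample() < epsilon:
        return np.random.randint(n)
    for i in range(n):
        if np.isnan(values[i]):
            return np.random.randint(n)
    m = values[0]
    for i in range(1, n):
        if values[i] > m:
            m = values[i]
    ties = 0
    for i in range(n):
        if values[i] == m:
            ties += 1
    if ties == 1:
        for i in range(n):
            if values[i] == m:
                return i
    k = np.random.randint(ties)
    seen = 0
    for i in range(n):
        if values[i] == m:
            if seen == k:
                return i
            seen += 1
    return n - 1  # unreachable


@njit(cache=False)
def _trial_q_family(
    seed,
    next_state,
    start,
    goal,
    step_cap,
    n_episodes,
    alpha,
    gamma,
    lam,
    sigma,
    eps0,
    eps_decay,
    eps_floor,
    decode,
):
    np.random.seed(seed)
    dim, n_actions = next_state.shape
    W = np.zeros((n_actions, dim))
    e = np.zeros((n_actions, dim))
    lengths = np.empty(n_episodes, dtype=np.int64)
    rewards = np.empty(n_episodes, dtype=np.float64)
    values = np.empty(n_actions)
    eps = eps0
    for ep in range(n_episodes):
        e[:, :] = 0.0
        s = start
        steps = 0
        o = np.random.standard_normal(dim) * sigma
        o[s] += 1.0
        o = _percept(o, decode)
        r = 0.0
        done = False
        while not done:
            for ai in range(n_actions):
                values[ai] = np.dot(W[ai], o)
            a = _select_action(values, eps)
            s2 = next_state[s, a]
            steps += 1
            terminal = s2 == goal
            r = 1.0 if terminal else 0.0
            done = terminal or steps >= step_cap
            o2 = np.random.standard_normal(dim) * sigma
            o2[s2] += 1.0
            o2 = _percept(o2, decode)
            # naive Q(lambda): accumulate, update through the trace, decay
            e[a] += o
            q_sa = np.dot(W[a], o)
            if terminal:
                target = r
            else:
                best = -np.inf
                for ai in range(n_actions):
                    v = np.dot(W[ai], o2)
                    if v > best:
                        best = v
                target = r + gamma * best
            delta = target - q_sa
            W += (alpha * delta) * e
            e *= gamma * lam
            o = o2
            s = s2
        lengths[ep] = steps
        rewards[ep] = r
        eps = max(eps_decay * eps, eps_floor)
    return lengths, rewards, W


@njit(cache=False)
def _trial_sf_family(
    seed,
    next_state,
    start,
    goal,
    step_cap,
    n_episodes,
    alpha_W,
    alpha_r,
    gamma,
    lam,
    sigma,
    eps0,
    eps_decay,
    eps_floor,
    decode,
):
    np.random.seed(seed)
    dim, n_actions = next_state.shape
    W = np.zeros((n_actions, dim, dim))
    w_r = np.zeros(dim)
    e = np.zeros(dim)
    lengths = np.empty(n_episodes, dtype=np.int64)
    rewards = np.empty(n_episodes, dtype=np.float64)
    values = np.empty(n_actions)
    eps = eps0
    for ep in range(n_episodes):
        e[:] = 0.0
        s = start
        steps = 0
        o = np.random.standard_normal(dim) * sigma
        o[s] += 1.0
        o = _percept(o, decode)
        r = 0.0
        done = False
        while not done:
            for ai in range(n_actions):
                values[ai] = np.dot(np.dot(W[ai], o), w_r)
            a = _select_action(values, eps)
            s2 = next_state[s, a]
            steps += 1
            terminal = s2 == goal
            r = 1.0 if terminal else 0.0
            done = terminal or steps >= step_cap
            o2 = np.random.standard_normal(dim) * sigma
            o2[s2] += 1.0
            o2 = _percept(o2, decode)
            # predecessor-feature step (lam = 0 collapses to plain SF)
            e += o
            psi_t = np.dot(W[a], o)
            if terminal:
                boot = o2  # psi(terminal) := phi(terminal)
            else:
                best = -np.inf
                boot = o2  # overwritten on first iteration
                for ai in range(n_actions):
                    psi = np.dot(W[ai], o2)
                    v = np.dot(psi, w_r)
                    if v > best:
                        best = v
                        boot = psi
            delta = o + gamma * boot - psi_t
            W[a] += np.outer(alpha_W * delta, e)
            dr = r - np.dot(o2, w_r)
            w_r += (alpha_r * dr) * o2
            e *= gamma * lam
            o = o2
            s = s2
        lengths[ep] = steps
        rewards[ep] = r
        eps = max(eps_decay * eps, eps_floor)
    return lengths, rewards, W, w_r


def _run_trial_numba(config: ExperimentConfig, trial_seed: int) -> tuple:
    spec = config.grid()
    p = config.params
    lam = p.lam if config.agent_kind in ("q_lambda", "pf") else 0.0
    decode = 1 if config.resolved_observation_mode == "decoded" else 0
    args = (
        trial_seed,
        spec.next_state,
        spec.start_index,
        spec.goal_index,
        spec.step_cap,
        config.n_episodes,
    )
    tail = (config.sigma, p.epsilon0, p.epsilon_decay, p.epsilon_floor, decode)
    if config.agent_kind in ("q", "q_lambda"):
        lengths, rewards, W = _trial_q_family(*args, p.alpha, p.gamma, lam, *tail)
        return lengths, rewards, {"weights": W}
    lengths, rewards, W, w_r = _trial_sf_family(
        *args, p.alpha_W, p.alpha_r, p.gamma, lam, *tail
    )
    return lengths, rewards, {"W": W, "w_r": w_r}


# ---------------------------------------------------------------------------
# Trial / experiment drivers
# ---------------------------------------------------------------------------


def run_trial(
    config: ExperimentConfig,
    trial_seed: int | None = None,
    trial_index: int = 0,
    engine: str = "numba",
) -> TrialRecord:
    """Train one fresh agent for ``config.n_episodes`` episodes."""
    if trial_seed is None:
        trial_seed = derive_trial_seed(
            config.master_seed, config.condition_id, trial_index
        )
    if engine == "python":
        lengths, rewards, weights = _run_trial_python(config, trial_seed)
    elif engine == "numba":
        lengths, rewards, weights = _run_trial_numba(config, trial_seed)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return TrialRecord(trial_index, trial_seed, lengths, rewards, weights)


def run_experiment(
    config: ExperimentConfig, engine: str = "numba"
) -> list[TrialRecord]:
    """Run ``config.n_trials`` independent trials with derived seeds."""
    return [
        run_trial(config, trial_index=i, engine=engine)
        for i in range(config.n_trials)
    ]


def greedy_rollout(
    spec: GridSpec, agent, max_steps: int | None = None
) -> tuple[int, float]:
    """Noise-free, exploration-free rollout of the agent's current policy.

    Returns (steps taken, reward); used to probe whether a trained policy
    has converged to the shortest path.  Greedy ties are broken by the
    lowest action index so the probe consumes no randomness.
    """
    if max_steps is None:
        max_steps = spec.step_cap
    state = EnvState(current=spec.start_index)
    r = 0.0
    while not state.done and state.steps_taken < max_steps:
        values = agent.action_values(_one_hot_cached(spec, state.current))
        state, r = env_step(spec, state, int(np.argmax(values)))
    return state.steps_taken, r


def _one_hot_cached(spec: GridSpec, s: int) -> np.ndarray:
    o = np.zeros(spec.observation_dim)
    o[s] = 1.0
    return o


def weights_as_agent(config: ExperimentConfig, record: TrialRecord):
    """Rehydrate a trained agent object from a trial's final weights."""
    spec = config.grid()
    agent = make_agent(
        config.agent_kind,
        config.params,
        spec.n_actions,
        spec.observation_dim,
        observation_mode=config.resolved_observation_mode,
    )
    fw = record.final_weights
    if "weights" in fw:
        agent.weights[:] = fw["weights"]
    else:
        agent.W[:] = fw["W"]
        agent.w_r[:] = fw["w_r"]
    return agent


def iter_trial_frames(records: Iterable[TrialRecord]):
    """Yield (trial_index, episode_index, length, reward) tuples (tidy rows)."""
    for rec in records:
        for ep in range(rec.n_episodes):
            yield rec.trial_index, ep + 1, int(rec.lengths[ep]), float(rec.rewards[ep])
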