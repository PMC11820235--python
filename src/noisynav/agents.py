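"""The four learning agents: Q, Q(lambda), successor features, predecessor features.

All agents act on the raw (possibly noisy) observation vector through linear
function approximation; a noisy percept is never decoded back to a discrete
state.  With exact one-hot observations (sigma = 0) everything below reduces
to the familiar tabular algorithms.

Value forms
-----------
Q / Q(lambda)
    Q(o, a) = w_a . o with one weight vector per action.  The one-step TD
    error is delta = r + gamma * max_a' Q(o', a') - Q(o, a); Q(lambda)
    broadcasts it through an accumulating eligibility trace shaped like the
    weights (naive Q(lambda): exploratory actions do not cut the trace).

SF / PF
    The value function is decomposed into expected discounted feature
    occupancy and a reward vector: psi_W(o, a) = W_a o, V = psi . w_r.
    The successor TD error is the vector
    delta_sf = o + gamma * psi_W(o', a*) - psi_W(o, a), with a* the greedy
    next action, applied as an outer-product update to W_a.  The reward
    weights follow their own delta rule, w_r <- w_r + alpha_r (r - o'.w_r) o'.
    PF is SF with a feature eligibility trace e <- gamma*lambda*e + o that
    replaces o in the outer product, crediting predecessor features.

Exact reductions: PF with lambda = 0 reproduces SF, and Q(lambda) with
lambda = 0 reproduces Q, update-for-update on the same random stream.

Percept interfaces
------------------
How an agent turns the noisy observation o = phi(s) + eps into the phi it
feeds its update rules is a genuine degree of freedom, and the two natural
readings behave very differently under noise:

``observation_mode="linear"``
    o is used as-is everywhere phi appears: linear function approximation
    over the raw percept.  Noise then circulates through every update
    (values, TD targets, outer products, traces).

``observation_mode="decoded"``
    The agent first self-localizes by maximum likelihood -- for one-hot
    features plus isotropic Gaussian noise the ML position is simply
    argmax(o) -- and feeds the exact one-hot of that estimate to the same
    update rules, which thereby become the tabular algorithms; noise acts
    only through occasional mislocalization.

Defaults (``DEFAULT_OBSERVATION_MODES``): the value-based agents (Q,
Q(lambda)) read values straight off the percept (linear); the map-based
agents (SF, PF) localize before updating their predictive map (decoded).
At sigma = 0 the two modes coincide exactly.

Episode termination: entering the goal is the only true terminal.  Q-style
agents then drop the bootstrap (target = r).  SF/PF instead take the
terminal observation's own feature as the successor target,
psi(terminal) := phi(terminal), i.e. delta_sf = o + gamma * o' - psi(o, a);
the goal state occupies itself and nothing after.  Without the goal's
feature in the occupancy, psi . w_r would vanish identically (w_r
concentrates on the goal coordinate) and the SF/PF agents could not learn
episodic tasks at all.  Truncation at the step cap is not terminal: the
last update still bootstraps.

All updates mutate their weight arguments in place and also return them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AgentParams",
    "epsilon_greedy",
    "decay_epsilon",
    "epsilon_floor_episode",
    "q_update",
    "q_lambda_update",
    "sf_step",
    "pf_step",
    "QAgent",
    "QLambdaAgent",
    "SFAgent",
    "PFAgent",
    "make_agent",
    "AGENT_KINDS",
]

AGENT_KINDS = ("q", "q_lambda", "sf", "pf")

OBSERVATION_MODES = ("linear", "decoded")

#: percept interface each agent kind uses unless overridden
DEFAULT_OBSERVATION_MODES = {
    "q": "linear",
    "q_lambda": "linear",
    "sf": "decoded",
    "pf": "decoded",
}


def decode_observation(o: np.ndarray) -> np.ndarray:
    """Maximum-likelihood localization of a noisy one-hot observation.

    With o = phi(s) + eps, eps ~ N(0, sigma^2 I), the ML estimate of s is
    argmax(o); returns the exact one-hot of that estimate.
    """
    o = np.asarray(o)
    phi = np.zeros(o.shape[0])
    phi[int(np.argmax(o))] = 1.0
    return phi


@dataclass(frozen=True)
class AgentParams:
    """Learning hyperparameters shared by all agents.

    alpha       Q-value learning rate (Q family).
    alpha_W     feature-weight learning rate (SF/PF family).
    alpha_r     reward-weight learning rate (SF/PF family).
    gamma       discount factor.
    lam         eligibility-trace decay; ignored by Q and SF.
    epsilon0 / epsilon_decay / epsilon_floor
                exploration schedule: epsilon starts at epsilon0 and decays
                once per episode via max(epsilon_decay * eps, epsilon_floor).
    """

    alpha: float = 0.1
    alpha_W: float = 0.1
    alpha_r: float = 0.1
    gamma: float = 0.95
    lam: float = 0.0
    epsilon0: float = 1.0
    epsilon_decay: float = 0.99
    epsilon_floor: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_W", "alpha_r"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.gamma < 1:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if not 0 <= self.lam <= 1:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not 0 <= self.epsilon0 <= 1:
            raise ValueError("epsilon0 must be in [0, 1]")
        if not 0 < self.epsilon_decay <= 1:
            raise ValueError("epsilon_decay must be in (0, 1]")
        if not 0 <= self.epsilon_floor <= 1:
            raise ValueError("epsilon_floor must be in [0, 1]")


def epsilon_greedy(
    values: Sequence[float] | np.ndarray,
    epsilon: float,
    rng: np.random.RandomState,
) -> int:
    """Pick an action: random with probability epsilon, else greedy.

    Ties in the greedy set are broken uniformly at random (a tie draw is
    consumed only when there actually is a tie).  The exploration uniform
    is consumed on every call, so the stream position does not depend on
    epsilon.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if not 0 <= epsilon <= 1:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if rng.random_sample() < epsilon:
        return int(rng.randint(values.size))
    m = values.max()
    if np.isnan(m):
        # degenerate values (e.g. a diverged off-default configuration):
        # fall back to a uniform draw rather than crashing mid-trial
        return int(rng.randint(values.size))
    ties = np.flatnonzero(values == m)
    if ties.size == 1:
        return int(ties[0])
    return int(ties[rng.randint(ties.size)])


def decay_epsilon(epsilon_k: float, params: AgentParams) -> float:
    """One per-episode decay step: max(decay * eps, floor)."""
    if not 0 <= epsilon_k <= 1:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon_k}")
    return max(params.epsilon_decay * epsilon_k, params.epsilon_floor)


def epsilon_floor_episode(params: AgentParams = AgentParams()) -> int:
    """First (1-based) episode whose epsilon equals the floor exactly.

    With eps_1 = epsilon0 the schedule reads eps_k = epsilon0 * decay^(k-1)
    until the floor binds, so the first floored episode is
    ceil(log(floor/epsilon0) / log(decay)) + 1.
    """
    k = np.log(params.epsilon_floor / params.epsilon0) / np.log(params.epsilon_decay)
    return int(np.ceil(k)) + 1


# ---------------------------------------------------------------------------
# Q family
# ---------------------------------------------------------------------------


def _greedy_q(weights: np.ndarray, o: np.ndarray) -> float:
    best = -np.inf
    for a in range(weights.shape[0]):
        v = np.dot(weights[a], o)
        if v > best:
            best = v
    return best


def q_update(
    weights: np.ndarray,
    o: np.ndarray,
    a: int,
    r: float,
    o_next: np.ndarray,
    terminal: bool,
    params: AgentParams,
) -> np.ndarray:
    """One-step Q-learning update on linear action values (in place)."""
    _check_q_shapes(weights, o, o_next, a)
    q_sa = np.dot(weights[a], o)
    target = r if terminal else r + params.gamma * _greedy_q(weights, o_next)
    delta = target - q_sa
    weights[a] += (params.alpha * delta) * o
    return weights


def q_lambda_update(
    weights: np.ndarray,
    trace: np.ndarray,
    o: np.ndarray,
    a: int,
    r: float,
    o_next: np.ndarray,
    terminal: bool,
    params: AgentParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate credit, apply the TD error through the trace, decay (in place)."""
    _check_q_shapes(weights, o, o_next, a)
    if trace.shape != weights.shape:
        raise ValueError("trace must be shaped like the weights")
    trace[a] += o
    q_sa = np.dot(weights[a], o)
    target = r if terminal else r + params.gamma * _greedy_q(weights, o_next)
    delta = target - q_sa
    weights += (params.alpha * delta) * trace
    trace *= params.gamma * params.lam
    return weights, trace


def _check_q_shapes(weights, o, o_next, a):
    if weights.ndim != 2 or o.shape != (weights.shape[1],) or o_next.shape != o.shape:
        raise ValueError(
            f"shape mismatch: weights {weights.shape}, o {o.shape}, o_next {o_next.shape}"
        )
    if not 0 <= a < weights.shape[0]:
        raise ValueError(f"action {a} out of range")


# ---------------------------------------------------------------------------
# SF / PF family
# ---------------------------------------------------------------------------


def _greedy_psi(W: np.ndarray, w_r: np.ndarray, o: np.ndarray) -> np.ndarray:
    """psi of the greedy next action (first maximum wins; no randomness)."""
    best = -np.inf
    boot = None
    for a in range(W.shape[0]):
        psi = np.dot(W[a], o)
        v = np.dot(psi, w_r)
        if v > best:
            best = v
            boot = psi
    return boot


def sf_step(
    W: np.ndarray,
    w_r: np.ndarray,
    o: np.ndarray,
    a: int,
    r: float,
    o_next: np.ndarray,
    terminal: bool,
    params: AgentParams,
    next_action: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One successor-feature TD step (in place).

    The bootstrap uses the greedy next action (off-policy, mirroring the Q
    target); pass ``next_action`` to bootstrap on a prescribed action
    instead, e.g. to evaluate a fixed policy.
    """
    _check_sf_shapes(W, w_r, o, o_next, a)
    psi_t = np.dot(W[a], o)
    if terminal:
        boot = o_next  # psi(terminal) := phi(terminal)
    elif next_action is not None:
        boot = np.dot(W[next_action], o_next)
    else:
        boot = _greedy_psi(W, w_r, o_next)
    delta = o + params.gamma * boot - psi_t
    W[a] += np.outer(params.alpha_W * delta, o)
    dr = r - np.dot(o_next, w_r)
    w_r += (params.alpha_r * dr) * o_next
    return W, w_r


def pf_step(
    W: np.ndarray,
    w_r: np.ndarray,
    trace: np.ndarray,
    o: np.ndarray,
    a: int,
    r: float,
    o_next: np.ndarray,
    terminal: bool,
    params: AgentParams,
    next_action: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One predecessor-feature TD step (in place).

    Same TD error as :func:`sf_step` but the update column is the feature
    eligibility trace: e <- e + o before the update, e <- gamma*lambda*e
    after, so earlier observations keep receiving (decayed) credit.
    """
    _check_sf_shapes(W, w_r, o, o_next, a)
    if trace.shape != o.shape:
        raise ValueError("trace must be a feature-length vector")
    trace += o
    psi_t = np.dot(W[a], o)
    if terminal:
        boot = o_next
    elif next_action is not None:
        boot = np.dot(W[next_action], o_next)
    else:
        boot = _greedy_psi(W, w_r, o_next)
    delta = o + params.gamma * boot - psi_t
    W[a] += np.outer(params.alpha_W * delta, trace)
    dr = r - np.dot(o_next, w_r)
    w_r += (params.alpha_r * dr) * o_next
    trace *= params.gamma * params.lam
    return W, w_r, trace


def _check_sf_shapes(W, w_r, o, o_next, a):
    if W.ndim != 3 or W.shape[1] != W.shape[2]:
        raise ValueError(f"W must be (n_actions, dim, dim), got {W.shape}")
    dim = W.shape[1]
    if o.shape != (dim,) or o_next.shape != (dim,) or w_r.shape != (dim,):
        raise ValueError("observation / reward-weight length mismatch")
    if not 0 <= a < W.shape[0]:
        raise ValueError(f"action {a} out of range")


# ---------------------------------------------------------------------------
# Agent objects
# ---------------------------------------------------------------------------


class _AgentBase:
    """Shared plumbing: constructor, epsilon-greedy acting, episode reset."""

    def __init__(
        self,
        params: AgentParams,
        n_actions: int,
        observation_dim: int,
        rng: np.random.RandomState | None = None,
        observation_mode: str = "linear",
    ) -> None:
        if observation_mode not in OBSERVATION_MODES:
            raise ValueError(
                f"observation_mode must be one of {OBSERVATION_MODES}, "
                f"got {observation_mode!r}"
            )
        self.params = params
        self.n_actions = int(n_actions)
        self.observation_dim = int(observation_dim)
        self.observation_mode = observation_mode
        self.rng = rng if rng is not None else np.random.RandomState()

    def _percept(self, o: np.ndarray) -> np.ndarray:
        if self.observation_mode == "decoded":
            return decode_observation(o)
        return o

    def begin_episode(self) -> None:
        """Reset per-episode state (eligibility traces)."""

    def action_values(self, o: np.ndarray) -> np.ndarray:
        """Per-action values of (the percept of) observation ``o``."""
        return self._values(self._percept(o))

    def _values(self, phi: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def act(
        self, o: np.ndarray, epsilon: float, rng: np.random.RandomState | None = None
    ) -> int:
        return epsilon_greedy(self.action_values(o), epsilon, rng or self.rng)

    def learn(
        self, o: np.ndarray, a: int, r: float, o_next: np.ndarray, terminal: bool
    ) -> None:
        self._learn(self._percept(o), a, r, self._percept(o_next), terminal)

    def _learn(self, phi, a, r, phi_next, terminal) -> None:
        raise NotImplementedError


class QAgent(_AgentBase):
    """One-step Q learning with one value-weight vector per action."""

    def __init__(self, params, n_actions, observation_dim, rng=None,
                 observation_mode="linear"):
        super().__init__(params, n_actions, observation_dim, rng, observation_mode)
        self.weights = np.zeros((self.n_actions, self.observation_dim))

    def _values(self, phi):
        return np.array([np.dot(self.weights[a], phi) for a in range(self.n_actions)])

    def _learn(self, phi, a, r, phi_next, terminal):
        q_update(self.weights, phi, a, r, phi_next, terminal, self.params)


class QLambdaAgent(QAgent):
    """Naive Q(lambda) with an accumulating trace shaped like the weights."""

    def __init__(self, params, n_actions, observation_dim, rng=None,
                 observation_mode="linear"):
        super().__init__(params, n_actions, observation_dim, rng, observation_mode)
        self.trace = np.zeros_like(self.weights)

    def begin_episode(self):
        self.trace[:] = 0.0

    def _learn(self, phi, a, r, phi_next, terminal):
        q_lambda_update(
            self.weights, self.trace, phi, a, r, phi_next, terminal, self.params
        )


class SFAgent(_AgentBase):
    """Successor features with one weight matrix per action plus reward weights."""

    def __init__(self, params, n_actions, observation_dim, rng=None,
                 observation_mode="linear"):
        super().__init__(params, n_actions, observation_dim, rng, observation_mode)
        d = self.observation_dim
        self.W = np.zeros((self.n_actions, d, d))
        self.w_r = np.zeros(d)

    def successor_features(self, o: np.ndarray) -> np.ndarray:
        """psi_W(o, a) for every action, shape (n_actions, dim)."""
        phi = self._percept(o)
        return np.array([np.dot(self.W[a], phi) for a in range(self.n_actions)])

    def _values(self, phi):
        return np.array(
            [np.dot(np.dot(self.W[a], phi), self.w_r) for a in range(self.n_actions)]
        )

    def _learn(self, phi, a, r, phi_next, terminal):
        sf_step(self.W, self.w_r, phi, a, r, phi_next, terminal, self.params)


class PFAgent(SFAgent):
    """Predecessor features: SF plus a feature eligibility trace."""

    def __init__(self, params, n_actions, observation_dim, rng=None,
                 observation_mode="linear"):
        super().__init__(params, n_actions, observation_dim, rng, observation_mode)
        self.trace = np.zeros(self.observation_dim)

    def begin_episode(self):
        self.trace[:] = 0.0

    def _learn(self, phi, a, r, phi_next, terminal):
        pf_step(
            self.W, self.w_r, self.trace, phi, a, r, phi_next, terminal, self.params
        )


_AGENT_CLASSES = {
    "q": QAgent,
    "q_lambda": QLambdaAgent,
    "sf": SFAgent,
    "pf": PFAgent,
}


def make_agent(
    kind: str,
    params: AgentParams,
    n_actions: int,
    observation_dim: int,
    rng: np.random.RandomState | None = None,
    observation_mode: str | None = None,
) -> _AgentBase:
    """Construct an agent by kind name ("q", "q_lambda", "sf", "pf").

    ``observation_mode=None`` selects the kind's default percept interface
    (``DEFAULT_OBSERVATION_MODES``).  For the trace-free kinds ("q", "sf")
    lambda is forced to 0 so the reduction identities hold regardless of
    the lam carried in ``params``.
    """
    if kind not in _AGENT_CLASSES:
        raise ValueError(f"unknown agent kind {kind!r}; choose from {AGENT_KINDS}")
    if observation_mode is None:
        observation_mode = DEFAULT_OBSERVATION_MODES[kind]
    if kind in ("q", "sf") and params.lam != 0.0:
        params = replace(params, lam=0.0)
    return _AGENT_CLASSES[kind](
        params, n_actions, observation_dim, rng, observation_mode
    )
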