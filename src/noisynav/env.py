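"""Grid-world environments with noisy one-hot observations.

Two deterministic episodic MDPs are provided: a 20-state linear track
(``chain_1d``) and a 7x7 open arena whose border cells are walls, leaving a
5x5 navigable interior (``grid_2d``).  The agent's true position is encoded
as a one-hot vector phi(s); what the agent *receives* each step is a noisy
observation

    o_t = phi(s_t) + eps_t,   eps_t ~ N(0, sigma^2 I),

so all stochasticity in the world sits in the percept (sensor noise), never
in the transitions.  Reaching the goal pays reward 1 and ends the episode;
episodes are otherwise truncated at a fixed step cap.

These environments double as the study's data generator: every experiment
in this package draws its inputs from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

__all__ = [
    "GridSpec",
    "NoiseModel",
    "EnvState",
    "chain_1d",
    "grid_2d",
    "spec_from_config",
    "one_hot",
    "observe",
    "env_step",
    "shortest_path_length",
]


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic Gaussian observation noise with standard deviation ``sigma``."""

    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


@dataclass(frozen=True)
class GridSpec:
    """Immutable description of a grid world.

    ``next_state`` is the full deterministic transition table, shape
    ``(observation_dim, n_actions)``; invalid moves (off the track, into a
    wall or the boundary) map a state to itself, so the action set is the
    same everywhere and a blocked move still consumes a step.
    """

    layout_kind: str
    observation_dim: int
    n_states_navigable: int
    start_index: int
    goal_index: int
    actions: tuple[str, ...]
    step_cap: int
    next_state: np.ndarray = field(repr=False)
    wall_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ns = np.asarray(self.next_state, dtype=np.int64)
        object.__setattr__(self, "next_state", ns)
        if ns.shape != (self.observation_dim, len(self.actions)):
            raise ValueError(
                f"transition table shape {ns.shape} does not match "
                f"({self.observation_dim}, {len(self.actions)})"
            )
        for idx, name in ((self.start_index, "start"), (self.goal_index, "goal")):
            if not 0 <= idx < self.observation_dim:
                raise ValueError(f"{name} index {idx} out of range")
            if self.wall_mask is not None and self.wall_mask[idx]:
                raise ValueError(f"{name} index {idx} is a wall cell")
        if self.start_index == self.goal_index:
            raise ValueError("start and goal must differ")
        if self.step_cap < 1:
            raise ValueError("step_cap must be positive")

    @property
    def n_actions(self) -> int:
        return len(self.actions)


@dataclass
class EnvState:
    """Mutable per-episode position/step/termination bookkeeping."""

    current: int
    steps_taken: int = 0
    done: bool = False


def chain_1d(
    n_states: int = 20,
    start: int = 0,
    goal: int | None = None,
    step_cap: int = 100,
) -> GridSpec:
    """Linear track of ``n_states`` cells with actions (left, right).

    Defaults give the 20-state track: start at the leftmost cell, goal at
    the rightmost, 100-step cap.  Moving off either end leaves the agent in
    place.
    """
    if goal is None:
        goal = n_states - 1
    nxt = np.empty((n_states, 2), dtype=np.int64)
    nxt[:, 0] = np.maximum(np.arange(n_states) - 1, 0)  # left
    nxt[:, 1] = np.minimum(np.arange(n_states) + 1, n_states - 1)  # right
    return GridSpec(
        layout_kind="chain_1d",
        observation_dim=n_states,
        n_states_navigable=n_states,
        start_index=start,
        goal_index=goal,
        actions=("left", "right"),
        step_cap=step_cap,
        next_state=nxt,
    )


def grid_2d(side: int = 7, step_cap: int = 200) -> GridSpec:
    """``side`` x ``side`` arena whose border cells are walls.

    Observations span all ``side**2`` cells (walls included) while movement
    is confined to the interior, so with the default ``side=7`` the agent
    observes 49 cells but can occupy only 25.  States are indexed row-major
    over the full lattice.  Start is the bottom-right interior corner, goal
    the top-left interior corner (8 optimal moves apart by default).
    """
    if side < 3:
        raise ValueError("side must be at least 3 to leave a navigable interior")
    dim = side * side
    rows, cols = np.divmod(np.arange(dim), side)
    wall = (rows == 0) | (rows == side - 1) | (cols == 0) | (cols == side - 1)
    # actions: up, down, left, right (row-major lattice)
    deltas = ((-1, 0), (1, 0), (0, -1), (0, 1))
    nxt = np.empty((dim, 4), dtype=np.int64)
    for s in range(dim):
        r, c = divmod(s, side)
        for a, (dr, dc) in enumerate(deltas):
            r2, c2 = r + dr, c + dc
            t = r2 * side + c2
            if wall[s] or not (0 <= r2 < side and 0 <= c2 < side) or wall[t]:
                nxt[s, a] = s
            else:
                nxt[s, a] = t
    start = (side - 2) * side + (side - 2)  # bottom-right interior
    goal = side + 1  # top-left interior
    return GridSpec(
        layout_kind="grid_2d",
        observation_dim=dim,
        n_states_navigable=int((~wall).sum()),
        start_index=start,
        goal_index=goal,
        actions=("up", "down", "left", "right"),
        step_cap=step_cap,
        next_state=nxt,
        wall_mask=wall,
    )


def spec_from_config(config: Mapping) -> GridSpec:
    """Build a :class:`GridSpec` from a plain key-value mapping.

    Recognised keys: ``layout`` ("chain_1d" | "grid_2d"), ``size``
    (states for the chain, side length for the grid), ``start``, ``goal``,
    ``step_cap``.  Unspecified keys fall back to the layout defaults.
    """
    layout = config.get("layout", "chain_1d")
    if layout == "chain_1d":
        kwargs = {}
        if "size" in config:
            kwargs["n_states"] = int(config["size"])
        if "start" in config:
            kwargs["start"] = int(config["start"])
        if "goal" in config:
            kwargs["goal"] = int(config["goal"])
        if "step_cap" in config:
            kwargs["step_cap"] = int(config["step_cap"])
        return chain_1d(**kwargs)
    if layout == "grid_2d":
        kwargs = {}
        if "size" in config:
            kwargs["side"] = int(config["size"])
        if "step_cap" in config:
            kwargs["step_cap"] = int(config["step_cap"])
        return grid_2d(**kwargs)
    raise ValueError(f"unknown layout {layout!r}")


def one_hot(state: int, dim: int) -> np.ndarray:
    """One-hot feature vector phi(s) of length ``dim``."""
    if not 0 <= state < dim:
        raise ValueError(f"state {state} out of range [0, {dim})")
    phi = np.zeros(dim)
    phi[state] = 1.0
    return phi


def observe(
    state: int,
    dim: int,
    noise: NoiseModel | float,
    rng: np.random.RandomState,
) -> np.ndarray:
    """Draw the noisy percept o = phi(state) + eps, eps ~ N(0, sigma^2 I).

    A fresh ``dim``-long Gaussian draw is consumed on every call, including
    sigma = 0; this keeps the random stream identical across noise levels,
    so two runs differing only in sigma see the same exploration draws.
    """
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    o = rng.standard_normal(dim) * sigma
    o[_check_state(state, dim)] += 1.0
    return o


def _check_state(state: int, dim: int) -> int:
    if not 0 <= state < dim:
        raise ValueError(f"state {state} out of range [0, {dim})")
    return state


class EpisodeFinishedError(RuntimeError):
    """Raised when stepping an environment whose episode already ended."""


def env_step(
    spec: GridSpec, state: EnvState, action: int
) -> tuple[EnvState, float]:
    """Advance one step; returns the successor state and the reward (0 or 1).

    Transitions are deterministic.  Reward 1 is paid exactly on the
    transition that enters the goal, which also terminates the episode; a
    goal entered on the cap-th step still counts as success (goal takes
    precedence over truncation).
    """
    if state.done:
        raise EpisodeFinishedError("episode already finished; reset before stepping")
    if not 0 <= action < spec.n_actions:
        raise ValueError(f"action {action} out of range [0, {spec.n_actions})")
    nxt = int(spec.next_state[state.current, action])
    steps = state.steps_taken + 1
    reached = nxt == spec.goal_index
    done = reached or steps >= spec.step_cap
    return EnvState(current=nxt, steps_taken=steps, done=done), float(reached)


def shortest_path_length(
    spec: GridSpec, source: int | None = None, target: int | None = None
) -> int:
    """Breadth-first-search distance (in moves) between two states.

    Defaults to start -> goal; ``source == target`` gives 0.
    """
    source = spec.start_index if source is None else source
    target = spec.goal_index if target is None else target
    g = nx.DiGraph()
    g.add_nodes_from(range(spec.observation_dim))
    for s in range(spec.observation_dim):
        for a in range(spec.n_actions):
            t = int(spec.next_state[s, a])
            if t != s:
                g.add_edge(s, t)
    try:
        return int(nx.shortest_path_length(g, source=source, target=target))
    except nx.NetworkXNoPath as exc:
        raise ValueError("goal is unreachable from start") from exc
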