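"""Summary statistics for the noisy-navigation experiments.

Everything the study reports is computed here: per-condition cumulative
reward summaries (mean, SEM, quartiles, mean/SEM stability ratio),
20-episode moving averages of episode length, counts of short (< 30 step)
and cap-length episodes, first-passage episodes for length thresholds, and
the analytic discounted-occupancy matrix (I - gamma P)^-1 that serves as
the convergence oracle for successor-feature learning.

Conventions (the source experiments leave these open):

* quartiles use linear interpolation between order statistics;
* SEM is the ddof-1 sample SD over sqrt(n); undefined (NaN, flagged) for
  n < 2, and the mean/SEM ratio is likewise flagged rather than infinite
  when SEM = 0;
* moving-average windows at the start of a series use the available
  prefix, so the smoothed curve has the same length as the raw one;
* a trial that never attains a length threshold is censored at its last
  episode index and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryRow",
    "ThresholdParams",
    "ThresholdResult",
    "EpisodeBins",
    "moving_average",
    "summarize",
    "summary_table",
    "final_window_length",
    "count_episode_bins",
    "first_threshold_episode",
    "cumulative_reward",
    "analytic_successor",
]

SHORT_EPISODE_STEPS = 30  # "efficient" episodes finish in fewer steps than this
MOVING_AVERAGE_WINDOW = 20


@dataclass(frozen=True)
class SummaryRow:
    """Distribution summary of one value per trial."""

    mean: float
    sem: float  # NaN when n < 2
    q25: float
    q50: float
    q75: float
    mean_sem_ratio: float  # NaN when undefined (SEM zero or unavailable)
    n: int

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.mean_sem_ratio)


@dataclass(frozen=True)
class ThresholdParams:
    """Episode-length threshold theta, in steps (the study uses 20/40/60)."""

    theta: int

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError("theta must be a positive step count")


class ThresholdResult(NamedTuple):
    episode: int  # 1-based; censoring value when not attained
    attained: bool


class EpisodeBins(NamedTuple):
    short: int  # length < SHORT_EPISODE_STEPS
    mid: int
    maxed: int  # length == cap


def moving_average(series: Sequence[float], window: int = MOVING_AVERAGE_WINDOW) -> np.ndarray:
    """Trailing moving average; early elements average the available prefix."""
    arr = np.asarray(series, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("series must be non-empty")
    if window < 1:
        raise ValueError("window must be >= 1")
    return (
        pd.Series(arr).rolling(window, min_periods=1).mean().to_numpy()
    )


def summarize(values: Sequence[float]) -> SummaryRow:
    """Mean, SEM, quartiles and mean/SEM ratio of one value per trial."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    mean = float(arr.mean())
    sem = float(sps.sem(arr, ddof=1)) if arr.size >= 2 else float("nan")
    q25, q50, q75 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    ratio = mean / sem if np.isfinite(sem) and sem > 0 else float("nan")
    return SummaryRow(mean, sem, q25, q50, q75, float(ratio), int(arr.size))


def summary_table(values_by_condition: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One summary row per condition, mirroring the study's table layout."""
    rows = []
    for cond, values in values_by_condition.items():
        s = summarize(values)
        rows.append(
            {
                "condition": cond,
                "mean": s.mean,
                "sem": s.sem,
                "25%": s.q25,
                "50%": s.q50,
                "75%": s.q75,
                "mean/sem": s.mean_sem_ratio,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def final_window_length(
    lengths: Sequence[float], window: int = MOVING_AVERAGE_WINDOW
) -> float:
    """Moving-average episode length at the final episode (last ``window`` mean)."""
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size < window:
        raise ValueError(f"need at least {window} episodes, got {arr.size}")
    return float(arr[-window:].mean())


def count_episode_bins(
    lengths: Sequence[int], cap: int, short: int = SHORT_EPISODE_STEPS
) -> EpisodeBins:
    """Counts of short (< ``short`` steps), intermediate, and cap-length episodes."""
    arr = np.asarray(lengths)
    if arr.size and (arr.min() < 1 or arr.max() > cap):
        raise ValueError(f"episode lengths must lie in [1, {cap}]")
    n_short = int((arr < short).sum())
    n_maxed = int((arr == cap).sum())
    return EpisodeBins(n_short, int(arr.size) - n_short - n_maxed, n_maxed)


def first_threshold_episode(
    lengths: Sequence[int], theta: int | ThresholdParams
) -> ThresholdResult:
    """1-based index of the first episode with length <= theta.

    Never-attaining series are censored at their final episode index
    (``attained=False``) rather than dropped, so condition means remain
    averages over all trials.
    """
    th = theta.theta if isinstance(theta, ThresholdParams) else int(theta)
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise ValueError("lengths must be non-empty")
    hits = np.flatnonzero(arr <= th)
    if hits.size == 0:
        return ThresholdResult(int(arr.size), False)
    return ThresholdResult(int(hits[0]) + 1, True)


def cumulative_reward(rewards: Sequence[float]) -> tuple[np.ndarray, float]:
    """Running-sum curve and final total of per-episode rewards."""
    arr = np.asarray(rewards, dtype=np.float64)
    curve = np.cumsum(arr)
    return curve, float(curve[-1]) if arr.size else 0.0


def analytic_successor(P: np.ndarray, gamma: float) -> np.ndarray:
    """Discounted occupancy M = (I - gamma P)^-1 of a fixed policy.

    ``P`` is the policy's state-transition matrix.  Row-stochastic P gives
    row sums 1/(1-gamma); an episodic chain is represented by zeroing the
    terminal state's outgoing row (the terminal then occupies only itself),
    which is the fixed point of successor-feature TD learning under the
    psi(terminal) = phi(terminal) convention.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    return np.linalg.inv(np.eye(P.shape[0]) - gamma * P)


def trials_summary_frame(
    lengths_by_trial: Iterable[Sequence[int]],
    rewards_by_trial: Iterable[Sequence[float]],
    cap: int,
    thetas: Sequence[int] = (20, 40, 60),
) -> pd.DataFrame:
    """Per-trial scalar metrics used throughout the study's tables.

    Columns: cumulative_reward, final_window_length, short/mid/maxed episode
    counts, and first_theta{t} first-passage episodes (censored, with a
    matching attained_theta{t} flag).
    """
    rows = []
    for lengths, rewards in zip(lengths_by_trial, rewards_by_trial):
        row = {
            "cumulative_reward": float(np.sum(rewards)),
            "final_window_length": final_window_length(lengths),
        }
        bins = count_episode_bins(lengths, cap)
        row.update(
            {"short_episodes": bins.short, "mid_episodes": bins.mid, "maxed_episodes": bins.maxed}
        )
        for th in thetas:
            res = first_threshold_episode(lengths, th)
            row[f"first_theta{th}"] = res.episode
            row[f"attained_theta{th}"] = res.attained
        rows.append(row)
    return pd.DataFrame(rows)
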