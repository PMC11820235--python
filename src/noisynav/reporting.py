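"""Condition sweeps, on-disk results, and table regeneration.

A sweep runs a list of :class:`~noisynav.runner.ExperimentConfig`
conditions, writing for each a tidy per-episode CSV
(``episodes_<condition>.csv`` with columns condition, trial, episode,
length, reward), plus summary tables and a ``metadata.json`` echoing every
parameter and derived trial seed.  ``make_report`` rebuilds all summary
tables purely from the stored per-episode CSVs — no simulation is rerun —
so reports are a pure function of the stored records and can be
regenerated after deleting or archiving conditions (gaps are flagged, not
silently ignored).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .runner import ExperimentConfig, TrialRecord, run_experiment
from .stats import summary_table, trials_summary_frame

__all__ = [
    "SweepManifest",
    "paper_conditions",
    "run_sweep",
    "make_report",
    "plot_learning_curves",
]

log = logging.getLogger("noisynav")

PAPER_SIGMAS = (0.05, 0.25, 0.5)
PAPER_LAMBDAS = (0.7, 0.8, 0.9)
THRESHOLDS = (20, 40, 60)


def paper_conditions(
    env: str,
    n_trials: int = 100,
    n_episodes: int = 3000,
    master_seed: int = 0,
    sigmas: Sequence[float] = PAPER_SIGMAS,
    lambdas: Sequence[float] = PAPER_LAMBDAS,
) -> list[ExperimentConfig]:
    """The study's full agent grid for one environment.

    Eight agent variants (Q; Q(lambda) and PF(lambda) for each lambda; SF)
    crossed with the noise levels: 24 conditions per environment at the
    default three sigmas.
    """
    variants: list[tuple[str, float]] = [("q", 0.0)]
    variants += [("q_lambda", lam) for lam in lambdas]
    variants += [("sf", 0.0)]
    variants += [("pf", lam) for lam in lambdas]
    return [
        ExperimentConfig(
            env=env,
            sigma=sigma,
            agent_kind=kind,
            lam=lam,
            n_trials=n_trials,
            n_episodes=n_episodes,
            master_seed=master_seed,
        )
        for sigma in sigmas
        for kind, lam in variants
    ]


@dataclass(frozen=True)
class SweepManifest:
    """A list of conditions plus where to put their outputs."""

    configs: tuple[ExperimentConfig, ...]
    out_dir: Path
    engine: str = "numba"

    def __post_init__(self) -> None:
        object.__setattr__(self, "configs", tuple(self.configs))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        ids = [c.condition_id for c in self.configs]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate condition ids in manifest: {sorted(dupes)}")


def _slug(condition_id: str) -> str:
    return condition_id.replace(":", "_").replace("=", "-").replace(".", "p")


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _episode_frame(config: ExperimentConfig, records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        n = rec.n_episodes
        rows.append(
            pd.DataFrame(
                {
                    "condition": config.condition_id,
                    "trial": rec.trial_index,
                    "episode": np.arange(1, n + 1),
                    "length": rec.lengths,
                    "reward": rec.rewards,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_sweep(manifest: SweepManifest) -> dict[str, pd.DataFrame]:
    """Run every condition in the manifest and write all artifacts.

    Returns the summary tables also written to disk.  Conditions are
    validated up front (the manifest constructor) so an invalid entry is
    rejected before any simulation starts.
    """
    out = manifest.out_dir
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"package_version": __version__, "engine": manifest.engine, "conditions": []}
    frames: dict[str, pd.DataFrame] = {}
    for i, config in enumerate(manifest.configs):
        log.info(
            "condition %d/%d: %s", i + 1, len(manifest.configs), config.condition_id
        )
        records = run_experiment(config, engine=manifest.engine)
        df = _episode_frame(config, records)
        _atomic_write(df, out / f"episodes_{_slug(config.condition_id)}.csv")
        frames[config.condition_id] = df
        meta["conditions"].append(
            {
                "condition_id": config.condition_id,
                "env": config.env,
                "agent_kind": config.agent_kind,
                "lam": config.lam,
                "sigma": config.sigma,
                "observation_mode": config.resolved_observation_mode,
                "n_trials": config.n_trials,
                "n_episodes": config.n_episodes,
                "master_seed": config.master_seed,
                "step_cap": config.grid().step_cap,
                "trial_seeds": [rec.seed for rec in records],
            }
        )
    tmp = out / "metadata.json.tmp"
    tmp.write_text(json.dumps(meta, indent=2))
    os.replace(tmp, out / "metadata.json")
    if not frames:
        return {}
    tables = _tables_from_frames(frames, {c["condition_id"]: c for c in meta["conditions"]})
    for name, table in tables.items():
        _atomic_write(table, out / f"summary_{name}.csv")
    return tables


def _tables_from_frames(
    frames: dict[str, pd.DataFrame], meta_by_id: dict[str, dict]
) -> dict[str, pd.DataFrame]:
    cumulative: dict[str, np.ndarray] = {}
    final_len: dict[str, np.ndarray] = {}
    per_trial_rows = []
    threshold_rows = []
    for cond, df in frames.items():
        cap = meta_by_id[cond]["step_cap"]
        lengths = [g["length"].to_numpy() for _, g in df.groupby("trial", sort=True)]
        rewards = [g["reward"].to_numpy() for _, g in df.groupby("trial", sort=True)]
        pt = trials_summary_frame(lengths, rewards, cap, THRESHOLDS)
        pt.insert(0, "condition", cond)
        per_trial_rows.append(pt)
        cumulative[cond] = pt["cumulative_reward"].to_numpy()
        final_len[cond] = pt["final_window_length"].to_numpy()
        for th in THRESHOLDS:
            first = pt[f"first_theta{th}"].to_numpy(dtype=float)
            attained = pt[f"attained_theta{th}"].to_numpy(dtype=bool)
            threshold_rows.append(
                {
                    "condition": cond,
                    "theta": th,
                    "mean_first_episode": float(first.mean()),
                    "sem_first_episode": float(
                        first.std(ddof=1) / np.sqrt(first.size)
                    )
                    if first.size > 1
                    else float("nan"),
                    "censored_fraction": float((~attained).mean()),
                    "mean_first_episode_attained_only": float(
                        first[attained].mean()
                    )
                    if attained.any()
                    else float("nan"),
                }
            )
    per_trial = pd.concat(per_trial_rows, ignore_index=True)
    bins = (
        per_trial.groupby("condition", sort=False)[
            ["short_episodes", "mid_episodes", "maxed_episodes"]
        ]
        .agg(["mean", "sem"])
        .reset_index()
    )
    bins.columns = ["condition"] + [f"{a}_{b}" for a, b in bins.columns[1:]]
    return {
        "cumulative_reward": summary_table(cumulative),
        "final_window_length": summary_table(final_len),
        "episode_bins": bins,
        "thresholds": pd.DataFrame(threshold_rows),
        "per_trial": per_trial,
    }


def make_report(results_dir: str | Path) -> dict:
    """Regenerate all summary tables from stored per-episode CSVs only.

    Returns ``{"tables": {...}, "missing": [...]}``; conditions listed in
    the metadata whose episode CSVs have gone missing are reported in
    ``missing`` (and logged) instead of failing silently or aborting.
    """
    results_dir = Path(results_dir)
    meta_path = results_dir / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json in {results_dir}")
    meta = json.loads(meta_path.read_text())
    frames: dict[str, pd.DataFrame] = {}
    missing: list[str] = []
    meta_by_id = {}
    for cond_meta in meta["conditions"]:
        cond = cond_meta["condition_id"]
        path = results_dir / f"episodes_{_slug(cond)}.csv"
        if not path.exists():
            log.warning("missing episode records for condition %s (%s)", cond, path)
            missing.append(cond)
            continue
        frames[cond] = pd.read_csv(path)
        meta_by_id[cond] = cond_meta
    tables = _tables_from_frames(frames, meta_by_id) if frames else {}
    return {"tables": tables, "missing": missing}


def plot_learning_curves(
    results_dir: str | Path, out_path: str | Path | None = None, window: int = 20
):
    """Mean moving-averaged episode-length curves with SEM bands per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    meta = json.loads((results_dir / "metadata.json").read_text())
    fig, ax = plt.subplots(figsize=(8, 5))
    for cond_meta in meta["conditions"]:
        cond = cond_meta["condition_id"]
        path = results_dir / f"episodes_{_slug(cond)}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        wide = df.pivot(index="episode", columns="trial", values="length")
        smooth = wide.rolling(window, min_periods=1).mean()
        mean = smooth.mean(axis=1)
        sem = smooth.std(axis=1, ddof=1) / np.sqrt(smooth.shape[1])
        ax.plot(mean.index, mean, label=cond, lw=1)
        ax.fill_between(mean.index, mean - sem, mean + sem, alpha=0.2)
    ax.set_xlabel("episode")
    ax.set_ylabel(f"episode length ({window}-episode moving average)")
    ax.legend(fontsize=6)
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return Path(out_path)
    return fig
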