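"""Descriptive statistics on evolutionary runs: gene trajectories and trends.

The unit of analysis is the per-generation population median of the
deviation-from-symmetry (DS) and orientation (ORI) genes. A participant's
two runs are averaged element-wise; a condition is summarized by the mean
trajectory ± SEM across participants, each participant's DS change
(generation-1 median minus the mean of the final five generations' medians,
sign flipped so negative means evolution toward symmetry), and ordinary
least-squares linear trends over the first and second halves of the
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    ExperimentConfig,
    RunResult,
    replicate_condition,
)

__all__ = [
    "Trajectory",
    "ConditionSummary",
    "median_trajectory",
    "average_runs",
    "ds_change",
    "linear_trend",
    "summarize_condition",
    "plot_condition",
    "calibrate_null_slopes",
]


@dataclass
class Trajectory:
    """Per-generation median DS and ORI for one run (or run average)."""

    ds: np.ndarray
    ori: np.ndarray
    label: str = ""

    def __len__(self) -> int:
        return len(self.ds)


@dataclass
class ConditionSummary:
    label: str
    n_participants: int
    generations: np.ndarray  # 1-based indices
    mean_ds: np.ndarray
    sem_ds: np.ndarray
    mean_ori: np.ndarray
    sem_ori: np.ndarray
    ds_changes: np.ndarray  # per participant, deg (negative = toward symmetry)
    first_half_slopes: np.ndarray  # per participant, deg/generation (DS)
    second_half_slopes: np.ndarray
    participant_trajectories: list[Trajectory] = field(default_factory=list)


def median_trajectory(run: RunResult) -> Trajectory:
    """Median over all 48 members' genes, per generation (mean-of-middle-pair)."""
    ds = np.array(
        [np.median([m.chromosome.ds for m in rec.members]) for rec in run.records]
    )
    ori = np.array(
        [np.median([m.chromosome.ori for m in rec.members]) for rec in run.records]
    )
    return Trajectory(ds=ds, ori=ori, label=f"run{run.run_index}")


def average_runs(t1: Trajectory, t2: Trajectory) -> Trajectory:
    """Element-wise mean of two equal-length trajectories."""
    if len(t1) != len(t2):
        raise ValueError(f"trajectory lengths differ: {len(t1)} vs {len(t2)}")
    return Trajectory(
        ds=(t1.ds + t2.ds) / 2.0,
        ori=(t1.ori + t2.ori) / 2.0,
        label=f"mean({t1.label},{t2.label})",
    )


def ds_change(t: Trajectory) -> float:
    """Mean of the final five generations' median DS minus generation 1's.

    Negative values indicate evolution toward symmetry.
    """
    if len(t) < 6:
        raise ValueError(f"need >= 6 generations, got {len(t)}")
    return float(np.mean(t.ds[-5:]) - t.ds[0])


def linear_trend(
    t: Trajectory, gen_range: tuple[int, int], gene: str = "ds"
) -> tuple[float, float]:
    """OLS slope (deg/generation) and two-sided p over 1-based generations
    ``gen_range[0]..gen_range[1]`` inclusive."""
    lo, hi = gen_range
    if hi - lo + 1 < 3 or lo < 1 or hi > len(t):
        raise ValueError(f"degenerate generation range {gen_range} for length {len(t)}")
    y = getattr(t, gene)[lo - 1 : hi]
    x = np.arange(lo, hi + 1, dtype=float)
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def participant_trajectory(runs: list[RunResult]) -> Trajectory:
    """One participant's trajectory: the element-wise mean across their runs."""
    trajs = [median_trajectory(r) for r in runs]
    out = trajs[0]
    for t in trajs[1:]:
        out = average_runs(out, t)
    return out


def summarize_condition(
    results: list[list[RunResult]], label: str = ""
) -> ConditionSummary:
    """Condition-level summary over participants (each a list of runs)."""
    if len(results) < 2:
        raise ValueError("need >= 2 participants to summarize a condition")
    trajs = [participant_trajectory(runs) for runs in results]
    n_gen = len(trajs[0])
    ds_mat = np.vstack([t.ds for t in trajs])
    ori_mat = np.vstack([t.ori for t in trajs])
    half = n_gen // 2
    return ConditionSummary(
        label=label,
        n_participants=len(trajs),
        generations=np.arange(1, n_gen + 1),
        mean_ds=ds_mat.mean(axis=0),
        sem_ds=ds_mat.std(axis=0, ddof=1) / np.sqrt(len(trajs)),
        mean_ori=ori_mat.mean(axis=0),
        sem_ori=ori_mat.std(axis=0, ddof=1) / np.sqrt(len(trajs)),
        ds_changes=np.array([ds_change(t) for t in trajs]),
        first_half_slopes=np.array(
            [linear_trend(t, (1, half))[0] for t in trajs]
        ),
        second_half_slopes=np.array(
            [linear_trend(t, (half + 1, n_gen))[0] for t in trajs]
        ),
        participant_trajectories=trajs,
    )


def summary_to_frame(summary: ConditionSummary) -> pd.DataFrame:
    """Tidy export: one row per participant x generation."""
    rows = []
    for p, t in enumerate(summary.participant_trajectories):
        for g in range(len(t)):
            rows.append(
                {
                    "condition": summary.label,
                    "participant": p,
                    "generation": g + 1,
                    "median_ds": t.ds[g],
                    "median_ori": t.ori[g],
                }
            )
    return pd.DataFrame(rows)


def calibrate_null_slopes(
    n_participants: int = 100,
    master_seed: int = 987654321,
    gen_range: tuple[int, int] | None = None,
    gene: str = "ds",
    config: ExperimentConfig | None = None,
) -> np.ndarray:
    """Per-participant trend slopes under the drift-only control condition.

    Runs extra no-observer participants and returns the distribution of OLS
    slopes of the run-averaged median trajectory over ``gen_range``; the
    spread calibrates what 'no trend' means for this algorithm's intrinsic
    genetic drift.
    """
    results = replicate_condition(
        "control", participants=n_participants, master_seed=master_seed, config=config
    )
    trajs = [participant_trajectory(runs) for runs in results]
    if gen_range is None:
        gen_range = (1, len(trajs[0]))
    return np.array([linear_trend(t, gen_range, gene=gene)[0] for t in trajs])


def plot_condition(summary: ConditionSummary, path_prefix) -> list[Path]:
    """Write the mean ± SEM gene-trajectory plot and the per-participant
    DS-change bar chart; returns the created file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    g = summary.generations
    for ax, mean, sem, name, lim in (
        (axes[0], summary.mean_ds, summary.sem_ds, "median DS (deg)", (0, 4.25)),
        (axes[1], summary.mean_ori, summary.sem_ori, "median ORI (deg)", (0, 90)),
    ):
        ax.errorbar(g, mean, yerr=sem, marker="o", ms=3, capsize=2)
        ax.set_xlabel("generation")
        ax.set_ylabel(name)
        ax.set_ylim(*lim)
        ax.set_title(summary.label)
    fig.tight_layout()
    p = prefix.with_name(prefix.name + "_trajectory.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    order = np.argsort(summary.ds_changes)
    ax.bar(np.arange(summary.n_participants), summary.ds_changes[order])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("participant (sorted)")
    ax.set_ylabel("DS change (deg)")
    ax.set_title(f"{summary.label}: generation 1 vs final five")
    fig.tight_layout()
    p = prefix.with_name(prefix.name + "_ds_change.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
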