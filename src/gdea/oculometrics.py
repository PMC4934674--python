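"""From gaze samples to fitness: I-DT fixations, AOI metrics, scores, estimates.

Fixation detection is the dispersion-threshold (I-DT) algorithm: a window is
grown while its spatial dispersion ``(max x - min x) + (max y - min y)`` stays
within twice the configured radius; windows shorter than the minimum duration
are discarded. Fixations are assigned to the circular stimulus areas of
interest, and each stimulus receives a fitness score in [0, 1] combining its
dwell-time share, first-fixation rank and revisit share. Genotypes never
shown to the observer get fitness interpolated from the presented ones by
inverse-squared-distance (Shepard) weighting in normalized gene space.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .genome import Chromosome, DS_BOUNDS, ORI_BOUNDS
from .observer import GazeStream
from .stimulus import DISK_RADIUS, TrialLayout

__all__ = [
    "Fixation",
    "AoiMetrics",
    "FitnessWeights",
    "EstimationError",
    "detect_fixations_idt",
    "assign_aoi",
    "score_trial",
    "estimate_fitness",
    "fixations_to_csv",
]


class EstimationError(ValueError):
    """Fitness estimation needs at least one presented, scored member."""


@dataclass
class Fixation:
    onset_ms: float
    offset_ms: float
    x: float  # centroid, screen deg
    y: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class AoiMetrics:
    """Per-stimulus oculomotor bookkeeping for one four-stimulus trial."""

    dwell_ms: list[float]
    first_fix_rank: list[int | None]  # 1..4 in order of first entry, None if unvisited
    revisits: list[int]  # re-entries after fixating a different AOI


@dataclass
class FitnessWeights:
    """Non-negative weights (summing to 1) for dwell, first-fixation and revisit terms."""

    w_dwell: float = 0.6
    w_first: float = 0.2
    w_revisit: float = 0.2

    def __post_init__(self) -> None:
        w = (self.w_dwell, self.w_first, self.w_revisit)
        if any(v < 0 for v in w):
            raise ValueError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(w)}")


def _valid_runs(valid: np.ndarray):
    """Maximal runs of consecutive valid samples, as (start, stop) slices."""
    if len(valid) == 0:
        return
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [len(valid)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if valid[a]:
            yield int(a), int(b)


def detect_fixations_idt(
    stream: GazeStream, radius: float = 0.5, min_dur_ms: float = 100.0
) -> list[Fixation]:
    """Greedy dispersion-threshold fixation detection.

    ``radius`` is the gaze-position radius about the centroid, so the window
    dispersion span ``(max dx + max dy)`` may reach ``2 * radius``. Invalid
    samples split the stream; emitted fixations are non-overlapping, time
    ordered, and at least ``min_dur_ms`` long.
    """
    thresh = 2.0 * radius
    out: list[Fixation] = []
    for a, b in _valid_runs(stream.valid):
        t = stream.t[a:b]
        x = stream.x[a:b]
        y = stream.y[a:b]
        n = b - a
        i = 0
        while i < n:
            # smallest window from i spanning the minimum duration
            j = i + int(np.searchsorted(t[i:], t[i] + min_dur_ms - 1e-9))
            if j >= n:
                break
            xs, ys = x[i : j + 1], y[i : j + 1]
            xmin, xmax = xs.min(), xs.max()
            ymin, ymax = ys.min(), ys.max()
            if (xmax - xmin) + (ymax - ymin) <= thresh:
                while j + 1 < n:
                    nx, ny = x[j + 1], y[j + 1]
                    xmin2, xmax2 = min(xmin, nx), max(xmax, nx)
                    ymin2, ymax2 = min(ymin, ny), max(ymax, ny)
                    if (xmax2 - xmin2) + (ymax2 - ymin2) > thresh:
                        break
                    xmin, xmax, ymin, ymax = xmin2, xmax2, ymin2, ymax2
                    j += 1
                out.append(
                    Fixation(
                        onset_ms=float(t[i]),
                        offset_ms=float(t[j]),
                        x=float(x[i : j + 1].mean()),
                        y=float(y[i : j + 1].mean()),
                    )
                )
                i = j + 1
            else:
                i += 1
    return out


def assign_aoi(fixations: list[Fixation], layout: TrialLayout) -> AoiMetrics:
    """Assign fixations to the disk AOIs containing their centroids.

    Fixations outside every disk are discarded. A revisit is a re-entry into
    an AOI after at least one fixation on a different AOI.
    """
    centers = np.asarray(layout.disk_centers)
    n_aoi = len(centers)
    dwell = [0.0] * n_aoi
    first_rank: list[int | None] = [None] * n_aoi
    revisits = [0] * n_aoi
    rank = 0
    prev_aoi: int | None = None
    for fx in fixations:
        d = np.linalg.norm(centers - np.array([fx.x, fx.y]), axis=1)
        hit = int(np.argmin(d))
        if d[hit] > DISK_RADIUS:
            continue
        dwell[hit] += fx.duration_ms
        if first_rank[hit] is None:
            rank += 1
            first_rank[hit] = rank
        elif prev_aoi is not None and prev_aoi != hit:
            revisits[hit] += 1
        prev_aoi = hit
    return AoiMetrics(dwell_ms=dwell, first_fix_rank=first_rank, revisits=revisits)


def score_trial(
    metrics: AoiMetrics, weights: FitnessWeights = FitnessWeights()
) -> list[float]:
    """Fitness in [0, 1] per stimulus: attention directed toward each image.

    ``score_i = w_dwell * dwell_i / total_dwell + w_first * (5 - rank_i) / 4
    + w_revisit * revisits_i / max_revisits``; unvisited AOIs contribute no
    first-fixation bonus, the revisit term is zero when nothing was
    revisited, and a trial with no fixations at all scores four zeros.
    """
    n = len(metrics.dwell_ms)
    total_dwell = sum(metrics.dwell_ms)
    if total_dwell <= 0:
        return [0.0] * n
    max_rev = max(metrics.revisits)
    scores = []
    for i in range(n):
        s = weights.w_dwell * metrics.dwell_ms[i] / total_dwell
        if metrics.first_fix_rank[i] is not None:
            s += weights.w_first * (5 - metrics.first_fix_rank[i]) / 4.0
        if max_rev > 0:
            s += weights.w_revisit * metrics.revisits[i] / max_rev
        scores.append(float(np.clip(s, 0.0, 1.0)))
    return scores


def _embed(chromosomes: list[Chromosome]) -> np.ndarray:
    """Normalized genotype coordinates (ds/4.25, ori/90); the ±1 gene is excluded."""
    return np.array(
        [[c.ds / DS_BOUNDS[1], c.ori / ORI_BOUNDS[1]] for c in chromosomes]
    )


def estimate_fitness(
    presented: list[tuple[Chromosome, float]],
    unpresented: list[Chromosome],
    method: str = "shepard",
    eps: float = 1e-6,
) -> list[float]:
    """Interpolate fitness for genotypes never shown to the observer.

    ``shepard`` (default): inverse-squared-distance weighted mean of the
    presented fitness values in normalized gene space, with a small distance
    floor; a genotype coinciding with a presented one returns that fitness
    exactly. ``linear``: a global least-squares plane fitness ~ (ds, ori),
    kept for sensitivity analysis. Either way the estimates are clipped to
    the presented min/max, so the step interpolates and never extrapolates.
    """
    if not presented:
        raise EstimationError("no presented members to estimate from")
    if not unpresented:
        return []
    anchors = _embed([c for c, _ in presented])
    values = np.array([f for _, f in presented])
    queries = _embed(unpresented)
    lo, hi = float(values.min()), float(values.max())
    if method == "shepard":
        d = np.linalg.norm(queries[:, None, :] - anchors[None, :, :], axis=-1)
        est = np.empty(len(queries))
        exact = d < 1e-12
        for k in range(len(queries)):
            if exact[k].any():
                est[k] = values[exact[k]].mean()
            else:
                w = 1.0 / np.maximum(d[k], eps) ** 2
                est[k] = float(np.average(values, weights=w))
    elif method == "linear":
        design = np.column_stack([np.ones(len(anchors)), anchors])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        est = np.column_stack([np.ones(len(queries)), queries]) @ coef
    else:
        raise ValueError(f"unknown estimation method {method!r}")
    return [float(v) for v in np.clip(est, lo, hi)]


def fixations_to_csv(
    fixations: list[Fixation], layout: TrialLayout, path
) -> None:
    """Export fixations with their AOI index (-1 outside all disks)."""
    centers = np.asarray(layout.disk_centers)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_ms", "offset_ms", "x_deg", "y_deg", "aoi_index"])
        for fx in fixations:
            d = np.linalg.norm(centers - np.array([fx.x, fx.y]), axis=1)
            hit = int(np.argmin(d))
            aoi = hit if d[hit] <= DISK_RADIUS else -1
            writer.writerow([repr(fx.onset_ms), repr(fx.offset_ms), repr(fx.x), repr(fx.y), aoi])
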