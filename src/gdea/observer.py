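"""Simulated observers: synthetic 120 Hz gaze streams for a four-stimulus trial.

Three viewing policies stand in for the human instruction groups:

* ``symmetry`` — scan the four disks in random order, form a noisy internal
  estimate of each pattern's deviation from symmetry, then fixate the
  apparent minimum until the trial ends.
* ``preference`` — after the same scan, allocate the remaining dwell time
  across disks in proportion to a softmax of a tolerance-thresholded utility:
  patterns within ``tolerance`` degrees of perfect symmetry are equally
  liked, worse ones are penalized linearly.
* ``freeview`` — dwell is allocated uniformly at random among disks,
  independent of the stimuli.

The control condition (``none``) generates no gaze at all. Fixation
locations carry Gaussian jitter around the disk centre, samples within a
fixation carry a small ocular tremor, and transitions between disks are
linearly interpolated saccade samples, so the dispersion-based fixation
filter downstream is exercised on realistic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import StimulusPattern, TrialLayout

__all__ = [
    "SAMPLE_RATE_HZ",
    "SAMPLE_DT_MS",
    "GazeStream",
    "ObserverPolicy",
    "NoGazeError",
    "GazeFileError",
    "perceive_ds",
    "simulate_trial_gaze",
    "read_gaze_file",
]

SAMPLE_RATE_HZ = 120.0
SAMPLE_DT_MS = 1000.0 / SAMPLE_RATE_HZ

#: within-fixation ocular tremor (deg, sd per axis); small enough that a
#: steady fixation never trips the 0.5 deg dispersion radius
TREMOR_SIGMA = 0.02

_POLICY_KINDS = ("symmetry", "preference", "freeview", "none")


class NoGazeError(RuntimeError):
    """Gaze simulation was requested for the no-observer control policy."""


class GazeFileError(ValueError):
    """A recorded gaze file could not be parsed."""


@dataclass
class GazeStream:
    """Timestamped gaze samples; synthetic streams are uniform at 120 Hz."""

    t: np.ndarray  # ms from stimulus onset
    x: np.ndarray  # screen deg
    y: np.ndarray
    valid: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass
class ObserverPolicy:
    """Viewing-policy parameters.

    ``perceptual_noise_sigma`` is the sd (deg) of the observer's internal
    estimate of a pattern's deviation from symmetry, modelling the limits of
    symmetry discrimination; ``tolerance`` (preference only) is the deviation
    below which patterns are equally liked.
    """

    kind: str = "symmetry"
    perceptual_noise_sigma: float = 0.2
    tolerance: float = 0.5
    softmax_temperature: float = 0.25
    scan_dwell_ms: float = 400.0
    fixation_jitter_sigma: float = 0.15
    saccade_duration_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in _POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.perceptual_noise_sigma < 0 or self.fixation_jitter_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be > 0")


def perceive_ds(
    p: StimulusPattern, sigma: float, rng: np.random.Generator
) -> float:
    """Noisy internal estimate of a pattern's deviation-from-symmetry gene value."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    ds = p.source_chromosome.ds if p.source_chromosome is not None else 0.0
    return max(0.0, float(ds + rng.normal(0.0, sigma))) if sigma > 0 else float(ds)


def _dwell(policy: ObserverPolicy, rng: np.random.Generator) -> float:
    # per-inspection dwell; mildly variable, floored well above the fixation minimum
    return float(max(150.0, rng.normal(policy.scan_dwell_ms, 0.15 * policy.scan_dwell_ms)))


def _plan_fixations(
    layout: TrialLayout,
    policy: ObserverPolicy,
    rng: np.random.Generator,
    duration_ms: float,
) -> list[tuple[int, float]]:
    """Sequence of (disk index, dwell ms) the observer intends to execute."""
    order = list(rng.permutation(4))
    estimates = np.array(
        [perceive_ds(p, policy.perceptual_noise_sigma, rng) for p in layout.patterns]
    )
    scan = [(int(i), _dwell(policy, rng)) for i in order]

    if policy.kind == "freeview":
        plan: list[tuple[int, float]] = []
        budget = duration_ms
        while budget > 0:
            i = int(rng.integers(4))
            d = _dwell(policy, rng)
            plan.append((i, d))
            budget -= d + policy.saccade_duration_ms
        return plan

    scan_cost = sum(d for _, d in scan) + 4 * policy.saccade_duration_ms
    remaining = max(0.0, duration_ms - scan_cost)

    if policy.kind == "symmetry":
        target = int(np.argmin(estimates))
        plan = list(scan)
        budget = remaining
        while budget > 0:
            d = float(rng.uniform(250.0, 500.0))
            plan.append((target, d))
            budget -= d
        return plan

    if policy.kind == "preference":
        utility = -np.maximum(0.0, estimates - policy.tolerance)
        z = utility / policy.softmax_temperature
        weights = np.exp(z - z.max())
        shares = weights / weights.sum()
        chunks: list[tuple[int, float]] = []
        for i in range(4):
            alloc = remaining * shares[i]
            while alloc > 0:
                d = min(alloc, _dwell(policy, rng))
                if d > 50.0:
                    chunks.append((i, float(d)))
                alloc -= d
        rng.shuffle(chunks)
        return scan + chunks

    raise NoGazeError("the control policy generates no gaze")


def simulate_trial_gaze(
    layout: TrialLayout,
    policy: ObserverPolicy,
    rng: np.random.Generator,
    duration_ms: float = 5000.0,
) -> GazeStream:
    """Synthesize one trial's gaze at 120 Hz under the given viewing policy.

    The gaze starts at screen centre (the pre-trial fixation cross) and then
    follows the policy's fixation plan, with linear saccade interpolation
    between successive fixation locations.
    """
    if policy.kind == "none":
        raise NoGazeError("the control policy generates no gaze")
    plan = _plan_fixations(layout, policy, rng, duration_ms)

    # timeline of (is_saccade, p_from, p_to, t_start, t_end)
    segments: list[tuple[bool, np.ndarray, np.ndarray, float, float]] = []
    cursor = 0.0
    pos = np.zeros(2)  # screen centre
    for disk, dwell in plan:
        loc = layout.disk_centers[disk] + rng.normal(
            0.0, policy.fixation_jitter_sigma, size=2
        )
        if not np.allclose(loc, pos):
            segments.append(
                (True, pos, loc, cursor, cursor + policy.saccade_duration_ms)
            )
            cursor += policy.saccade_duration_ms
        segments.append((False, loc, loc, cursor, cursor + dwell))
        cursor += dwell
        pos = loc
        if cursor >= duration_ms:
            break
    if cursor < duration_ms:  # hold the last fixation to the end of the trial
        last = segments[-1]
        segments[-1] = (last[0], last[1], last[2], last[3], duration_ms)

    n = int(round(duration_ms / SAMPLE_DT_MS))
    t = np.arange(n) * SAMPLE_DT_MS
    xy = np.zeros((n, 2))
    starts = np.array([s[3] for s in segments])
    seg_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(segments) - 1)
    for k, (is_sac, p_from, p_to, t0, t1) in enumerate(segments):
        mask = seg_idx == k
        if not mask.any():
            continue
        if is_sac:
            frac = (t[mask] - t0) / (t1 - t0)
            xy[mask] = p_from + np.clip(frac, 0, 1)[:, None] * (p_to - p_from)
        else:
            tremor = rng.normal(0.0, TREMOR_SIGMA, size=(int(mask.sum()), 2))
            xy[mask] = p_to + tremor
    return GazeStream(t=t, x=xy[:, 0], y=xy[:, 1], valid=np.ones(n, dtype=bool))


def read_gaze_file(path) -> GazeStream:
    """Read a recorded gaze stream from a delimited text file.

    Expected header ``t_ms,x_deg,y_deg`` (comma- or whitespace-delimited).
    Rows with empty coordinate fields become invalid samples; non-numeric
    fields raise :class:`GazeFileError` naming the offending line.
    """
    t: list[float] = []
    x: list[float] = []
    y: list[float] = []
    valid: list[bool] = []
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise GazeFileError(f"{path}: empty file, expected header t_ms,x_deg,y_deg")
        delim = "," if "," in first else None
        header = [c.strip() for c in (first.split(delim) if delim else first.split())]
        if header[:3] != ["t_ms", "x_deg", "y_deg"]:
            raise GazeFileError(f"{path}: bad header {header!r}, expected t_ms,x_deg,y_deg")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = [c.strip() for c in (line.split(delim) if delim else line.split())]
            if len(cells) < 3:
                raise GazeFileError(f"{path}, line {lineno}: expected 3 fields, got {len(cells)}")
            try:
                ti = float(cells[0])
            except ValueError:
                raise GazeFileError(f"{path}, line {lineno}: non-numeric t_ms {cells[0]!r}") from None
            if cells[1] == "" or cells[2] == "":
                t.append(ti); x.append(np.nan); y.append(np.nan); valid.append(False)
                continue
            try:
                xi, yi = float(cells[1]), float(cells[2])
            except ValueError:
                raise GazeFileError(f"{path}, line {lineno}: non-numeric coordinate") from None
            t.append(ti); x.append(xi); y.append(yi); valid.append(True)
    return GazeStream(
        t=np.asarray(t, dtype=float),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        valid=np.asarray(valid, dtype=bool),
    )
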