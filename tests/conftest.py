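import numpy as np
import pytest

from gdea.genome import Chromosome, Individual, Population
from gdea.stimulus import QUADRANT_CENTERS, TrialLayout, realize_phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def scored_population(fitnesses, rng, ds=None):
    """A population with prescribed fitness values (genes random unless given)."""
    members = []
    for k, f in enumerate(fitnesses):
        c = Chromosome(
            ds=float(ds[k]) if ds is not None else float(rng.uniform(0, 4.25)),
            ori=float(rng.uniform(0, 90)),
            bina=int(rng.choice((-1, 1))),
        )
        members.append(Individual(c, fitness=float(f), provenance="presented"))
    return Population(members=members, generation_index=1)


def nominal_layout(chromosomes, rng):
    """Trial layout at exact quadrant centres (no jitter), for deterministic AOI tests."""
    patterns = [realize_phenotype(c, rng) for c in chromosomes]
    return TrialLayout(
        patterns=patterns, disk_centers=np.asarray(QUADRANT_CENTERS, dtype=float)
    )


def idt_oracle(stream, radius=0.5, min_dur_ms=100.0):
    """Brute-force dispersion-threshold reference: for each start sample, the
    maximal window whose dispersion span stays within 2*radius; the first
    start whose maximal window spans the minimum duration emits a fixation.

    Independent of the production implementation; O(n^2), for tests only.
    """
    thresh = 2.0 * radius
    out = []
    valid = stream.valid
    n = len(stream.t)
    a = 0
    while a < n:
        if not valid[a]:
            a += 1
            continue
        b = a
        while b + 1 < n and valid[b + 1]:
            b += 1
        t, x, y = stream.t[a : b + 1], stream.x[a : b + 1], stream.y[a : b + 1]
        m = b + 1 - a
        i = 0
        while i < m:
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            j = i
            while j + 1 < m:
                nx, ny = x[j + 1], y[j + 1]
                if (max(xmax, nx) - min(xmin, nx)) + (max(ymax, ny) - min(ymin, ny)) > thresh:
                    break
                xmin, xmax = min(xmin, nx), max(xmax, nx)
                ymin, ymax = min(ymin, ny), max(ymax, ny)
                j += 1
            if t[j] - t[i] >= min_dur_ms - 1e-9:
                out.append(
                    (float(t[i]), float(t[j]), float(x[i : j + 1].mean()), float(y[i : j + 1].mean()))
                )
                i = j + 1
            else:
                i += 1
        a = b + 1
    return out


def random_gaze_stream(rng, n_events=8, invalid_gaps=True):
    """Synthetic stream stressing the fixation filter: noisy clusters of random
    duration (some below the minimum), saccade transitions, optional dropouts."""
    from gdea.observer import SAMPLE_DT_MS, GazeStream

    t_cursor = 0.0
    ts, xs, ys, vs = [], [], [], []
    pos = rng.uniform(-10, 10, 2)
    for _ in range(n_events):
        target = rng.uniform(-12, 12, 2)
        for frac in np.linspace(0, 1, rng.integers(2, 6)):
            ts.append(t_cursor)
            p = pos + frac * (target - pos)
            xs.append(p[0]); ys.append(p[1]); vs.append(True)
            t_cursor += SAMPLE_DT_MS
        pos = target
        dur = float(rng.uniform(30, 500))
        sigma = float(rng.uniform(0.01, 0.35))
        for _ in range(int(dur / SAMPLE_DT_MS)):
            ts.append(t_cursor)
            xs.append(pos[0] + rng.normal(0, sigma))
            ys.append(pos[1] + rng.normal(0, sigma))
            vs.append(True)
            t_cursor += SAMPLE_DT_MS
        if invalid_gaps and rng.uniform() < 0.3:
            for _ in range(rng.integers(1, 10)):
                ts.append(t_cursor)
                xs.append(np.nan); ys.append(np.nan); vs.append(False)
                t_cursor += SAMPLE_DT_MS
    return GazeStream(
        t=np.array(ts), x=np.array(xs), y=np.array(ys), valid=np.array(vs, dtype=bool)
    )
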