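"""Genotype-to-phenotype translation: mirrored 12-dot patterns in an 8.5 deg disk.

A phenotype starts from a perfectly mirror-symmetric template: six dot centres
are placed uniformly at random on one side of the symmetry axis and reflected
to the other side, with one dot of each of six diameters (0.9 to 1.5 deg in
even steps) per side. The deviation-from-symmetry gene then displaces every
dot by exactly ``ds`` degrees in an independent random direction, resampling
directions (and, as a last resort, shrinking the displacement) whenever a dot
would leave the disk or cross the visible midline.

Coordinates are degrees of visual angle with the origin at screen centre,
x rightward and y upward; the y-axis flip happens only at rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from scipy.optimize import linear_sum_assignment

from .genome import Chromosome, axis_angle

__all__ = [
    "DISK_DIAMETER",
    "DOT_DIAMETERS",
    "SCREEN_WIDTH_DEG",
    "SCREEN_RESOLUTION",
    "PX_PER_DEG",
    "QUADRANT_CENTERS",
    "JITTER_MAX",
    "DotTemplate",
    "StimulusPattern",
    "TrialLayout",
    "ConstraintFailureError",
    "InvalidTrialError",
    "make_template",
    "apply_ds",
    "realize_phenotype",
    "layout_trial",
    "measured_asymmetry",
    "reflect_about_axis",
    "rasterize",
]

DISK_DIAMETER = 8.5  # deg; a quarter of the 34 deg screen width
DISK_RADIUS = DISK_DIAMETER / 2.0
#: six evenly spaced dot diameters, endpoints included (step 0.12 deg)
DOT_DIAMETERS = tuple(np.linspace(0.9, 1.5, 6))
SCREEN_WIDTH_DEG = 34.0
SCREEN_RESOLUTION = (1024, 768)
PX_PER_DEG = SCREEN_RESOLUTION[0] / SCREEN_WIDTH_DEG
#: nominal quadrant centres (deg); chosen so four 8.5 deg disks fit a 4:3 screen
QUADRANT_CENTERS = ((-8.5, 6.0), (8.5, 6.0), (-8.5, -6.0), (8.5, -6.0))
JITTER_MAX = 0.33  # deg, per axis

_EPS = 1e-9

# stimulus grey levels (8-bit): background, disk, dots, midline
_BG_GREY = 0
_DISK_GREY = 64
_DOT_GREY = 128
_LINE_GREY = 0


class ConstraintFailureError(RuntimeError):
    """No feasible displacement found for a dot (should be unreachable for ds <= 4.25)."""


class InvalidTrialError(ValueError):
    """A trial layout needs exactly four stimulus patterns."""


def _axis_direction(angle_deg: float) -> np.ndarray:
    """Unit vector along the symmetry axis; angle measured from vertical."""
    a = np.deg2rad(angle_deg)
    return np.array([np.sin(a), np.cos(a)])


def _axis_normal(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), -np.sin(a)])


def reflect_about_axis(points: np.ndarray, angle_deg: float) -> np.ndarray:
    """Mirror points about the axis line through the origin at ``angle_deg`` from vertical."""
    d = _axis_direction(angle_deg)
    m = 2.0 * np.outer(d, d) - np.eye(2)
    return points @ m.T


@dataclass
class DotTemplate:
    """Perfectly symmetric 12-dot arrangement: dots ``i`` and ``i+6`` mirror each other."""

    dot_centers: np.ndarray  # (12, 2) deg, disk-local
    dot_diameters: np.ndarray  # (12,) deg
    axis_angle: float  # signed deg from vertical
    sides: np.ndarray = field(default=None)  # (12,) ±1, sign of axis-normal coordinate

    def __post_init__(self) -> None:
        if self.sides is None:
            n = _axis_normal(self.axis_angle)
            self.sides = np.sign(self.dot_centers @ n).astype(int)


@dataclass
class StimulusPattern:
    """A realized phenotype: displaced dot centres inside the disk."""

    dot_centers: np.ndarray  # (12, 2) deg, disk-local
    dot_diameters: np.ndarray  # (12,) deg
    axis_angle: float
    disk_diameter: float = DISK_DIAMETER
    source_chromosome: Chromosome | None = None
    sides: np.ndarray | None = None


@dataclass
class TrialLayout:
    """Four stimuli, one per screen quadrant, with per-disk positional jitter."""

    patterns: list[StimulusPattern]
    disk_centers: np.ndarray  # (4, 2) screen deg
    screen_width_deg: float = SCREEN_WIDTH_DEG
    screen_resolution: tuple[int, int] = SCREEN_RESOLUTION


def _sample_half_disk(margin: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform point in the canonical (axis = y) half-disk with both margins respected.

    Feasible region: |p| <= DISK_RADIUS - margin and p_x >= margin, so the
    whole dot stays inside the disk and does not cross the midline.
    """
    rmax = DISK_RADIUS - margin
    while True:
        cand = rng.uniform((-rmax, -rmax), (rmax, rmax), size=(32, 2))
        ok = (np.einsum("ij,ij->i", cand, cand) <= rmax * rmax) & (cand[:, 0] >= margin)
        if ok.any():
            return cand[np.argmax(ok)]


def make_template(axis_angle_deg: float, rng: np.random.Generator) -> DotTemplate:
    """Random symmetric template: 6 free dots on one side, mirrored to the other.

    Dot ``i`` (side +1) has diameter ``DOT_DIAMETERS[i]`` and dot ``i+6`` is
    its mirror image, so each side carries one dot of every size.
    """
    if abs(axis_angle_deg) > 90.0 + _EPS:
        raise ValueError(f"|axis angle| {axis_angle_deg} > 90")
    radii = np.asarray(DOT_DIAMETERS) / 2.0
    free = np.stack([_sample_half_disk(r, rng) for r in radii])
    canonical = np.vstack([free, free * np.array([-1.0, 1.0])])
    a = np.deg2rad(axis_angle_deg)
    rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    centers = canonical @ rot.T
    diameters = np.concatenate([DOT_DIAMETERS, DOT_DIAMETERS])
    sides = np.array([1] * 6 + [-1] * 6)
    return DotTemplate(
        dot_centers=centers,
        dot_diameters=diameters,
        axis_angle=axis_angle_deg,
        sides=sides,
    )


def _max_step(p0: np.ndarray, u: np.ndarray, rmax: float, side: int, normal: np.ndarray, line_margin: float) -> float:
    """Largest t >= 0 with p0 + t*u inside the disk of radius rmax and on the right side."""
    # disk: |p0 + t u|^2 <= rmax^2, |u| = 1
    b = p0 @ u
    c = p0 @ p0 - rmax * rmax
    disc = b * b - c
    if disc < 0:
        return 0.0
    t_disk = -b + np.sqrt(disc)
    # half-plane: side * (p0 + t u) . n >= line_margin
    a0 = side * (p0 @ normal)
    au = side * (u @ normal)
    if au >= 0:
        t_line = np.inf
    else:
        t_line = (line_margin - a0) / au
    return float(max(0.0, min(t_disk, t_line)))


def apply_ds(
    template: DotTemplate,
    ds: float,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> StimulusPattern:
    """Displace every template dot by exactly ``ds`` deg in a random direction.

    Directions violating the disk or midline constraint are resampled up to
    ``max_resample`` times; if none succeeds, the displacement for that dot is
    shrunk to the largest feasible step along the best of a batch of random
    directions (preserving the distance semantics as closely as possible).
    """
    if not (0.0 <= ds <= 4.25):
        raise ValueError(f"ds={ds} outside [0, 4.25]")
    normal = _axis_normal(template.axis_angle)
    radii = template.dot_diameters / 2.0
    centers = template.dot_centers.copy()
    if ds > 0.0:
        for i in range(12):
            p0 = centers[i]
            r = radii[i]
            rmax = DISK_RADIUS - r
            side = int(template.sides[i])
            angles = rng.uniform(0.0, 2.0 * np.pi, size=max_resample)
            dirs = np.column_stack([np.cos(angles), np.sin(angles)])
            cand = p0 + ds * dirs
            ok = (np.einsum("ij,ij->i", cand, cand) <= rmax * rmax + _EPS) & (
                side * (cand @ normal) >= r - _EPS
            )
            if ok.any():
                centers[i] = cand[np.argmax(ok)]
                continue
            # shrink: best feasible step over the same direction batch
            steps = np.array(
                [_max_step(p0, u, rmax, side, normal, r) for u in dirs]
            )
            t = float(steps.max())
            if t <= 0.0:
                raise ConstraintFailureError(
                    f"dot {i}: no feasible displacement for ds={ds}"
                )
            centers[i] = p0 + min(ds, t) * dirs[int(steps.argmax())]
    return StimulusPattern(
        dot_centers=centers,
        dot_diameters=template.dot_diameters.copy(),
        axis_angle=template.axis_angle,
        source_chromosome=None,
        sides=template.sides.copy(),
    )


def realize_phenotype(c: Chromosome, rng: np.random.Generator) -> StimulusPattern:
    """Fresh random template at the chromosome's axis angle, then DS displacement.

    The template is re-randomized on every call, so two realizations of the
    same chromosome practically never coincide.
    """
    template = make_template(axis_angle(c), rng)
    pattern = apply_ds(template, c.ds, rng)
    pattern.source_chromosome = c
    return pattern


def layout_trial(
    patterns: list[StimulusPattern], rng: np.random.Generator
) -> TrialLayout:
    """Place four stimuli at jittered quadrant centres (jitter <= 0.33 deg per axis)."""
    if len(patterns) != 4:
        raise InvalidTrialError(f"need exactly 4 patterns, got {len(patterns)}")
    jitter = rng.uniform(-JITTER_MAX, JITTER_MAX, size=(4, 2))
    centers = np.asarray(QUADRANT_CENTERS, dtype=float) + jitter
    return TrialLayout(patterns=list(patterns), disk_centers=centers)


def measured_asymmetry(p: StimulusPattern) -> float:
    """Phenotype-level deviation from mirror symmetry, in degrees.

    Reflects the dot centres about the axis, optimally pairs original and
    reflected dots of equal diameter (Hungarian assignment per size class),
    and returns half the mean pair distance. Zero iff the pattern is a
    perfect mirror image of itself.
    """
    reflected = reflect_about_axis(p.dot_centers, p.axis_angle)
    total = 0.0
    for d in np.unique(p.dot_diameters):
        idx = np.flatnonzero(p.dot_diameters == d)
        cost = np.linalg.norm(
            p.dot_centers[idx][:, None, :] - reflected[idx][None, :, :], axis=-1
        )
        rows, cols = linear_sum_assignment(cost)
        total += cost[rows, cols].sum()
    return total / len(p.dot_centers) / 2.0


def _deg_to_px(xy: np.ndarray, px_per_deg: float, size: tuple[int, int]) -> np.ndarray:
    w, h = size
    return np.column_stack(
        [xy[:, 0] * px_per_deg + w / 2.0, h / 2.0 - xy[:, 1] * px_per_deg]
    )


def rasterize(
    layout: TrialLayout, px_per_deg: float = PX_PER_DEG, path: str | None = None
) -> Image.Image:
    """Render a trial to an image: black field, dark-grey disks, mid-grey dots.

    Each disk shows a visible black midline along its symmetry axis. No
    anti-aliasing, so the image contains only the stimulus grey levels.
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be > 0")
    w = int(round(SCREEN_WIDTH_DEG * px_per_deg))
    h = int(round(w * SCREEN_RESOLUTION[1] / SCREEN_RESOLUTION[0]))
    img = Image.new("L", (w, h), _BG_GREY)
    draw = ImageDraw.Draw(img)
    for pattern, center in zip(layout.patterns, layout.disk_centers):
        cpx = _deg_to_px(center[None, :], px_per_deg, (w, h))[0]
        r = DISK_RADIUS * px_per_deg
        draw.ellipse([cpx[0] - r, cpx[1] - r, cpx[0] + r, cpx[1] + r], fill=_DISK_GREY)
        dots_px = _deg_to_px(pattern.dot_centers + center, px_per_deg, (w, h))
        for (x, y), diam in zip(dots_px, pattern.dot_diameters):
            dr = diam / 2.0 * px_per_deg
            draw.ellipse([x - dr, y - dr, x + dr, y + dr], fill=_DOT_GREY)
        d = _axis_direction(pattern.axis_angle) * np.array([1.0, -1.0])  # y-flip
        p1 = cpx + d * r
        p2 = cpx - d * r
        draw.line([tuple(p1), tuple(p2)], fill=_LINE_GREY, width=2)
    if path is not None:
        img.save(path)
    return img
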