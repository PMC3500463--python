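"""Motion-defined figure-ground random-dot stimuli and trial schedules.

Three stimulus kinds share an identical region geometry (a small inner
square nested in a square frame, embedded in the background) and differ only
in how the dots of each region move:

* ``homogenous`` -- all three regions drift coherently in one direction;
* ``frame``      -- the frame region moves orthogonally to background and
  inner region (which share a direction), so a hollow frame segregates;
* ``stack``      -- all three regions move in pairwise different directions,
  so a stack of two surfaces segregates.

Dots are single black/white pixels (fair coin per pixel). On each screen
refresh every region's dots translate one displacement step along the
region's direction; dots never cross their region border, and the vacated
trailing-border pixels are refilled with fresh fair coin flips. Because the
region partition is applied to all three kinds alike, the expected flicker
from (dis)appearing dots and the marginal motion energy per direction are
identical across kinds, and stack and frame differ from each other only in
the number of segregating surfaces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STIMULUS_KINDS = ("stack", "frame", "homogenous")
TMS_CONDITIONS = ("none", "early", "intermediate", "late")

#: the 12 cells of the stimulus x TMS-window design
TRIAL_TYPES = tuple((k, c) for k in STIMULUS_KINDS for c in TMS_CONDITIONS)

_REGIONS = ("background", "frame", "inner")
_REGION_CODE = {"background": 0, "frame": 1, "inner": 2}


class GeometryError(ValueError):
    """A stimulus region does not fit on the screen."""


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and dynamics of the random-dot display.

    Pixel extents are the operative values; the ``*_deg`` fields carry the
    nominal sizes in degrees of visual angle (at 0.64 deg/cm viewing
    geometry) as metadata and are not enforced against the pixel values.

    Parameters
    ----------
    screen_size : (width, height) in pixels.
    refresh_rate : display refresh in Hz; two refreshes make the motion.
    frame_extent_px, inner_extent_px : side lengths of the nested squares.
    offset_px : (x, y) of the figure centre relative to screen centre,
        x positive rightward, y positive downward (the figure sits in the
        lower-left visual quadrant with the default negative x, positive y).
    dot_black_prob : probability that a pixel is black (0.5 = balanced).
    directions : the four motion angles in degrees, 90 deg apart.
    displacement : pixels moved per refresh (0 allowed as a degenerate,
        static configuration for audits).
    n_motion_frames : number of displaced refreshes per stimulus.
    """

    screen_size: tuple[int, int] = (1024, 768)
    refresh_rate: float = 60.0
    frame_extent_px: int = 150
    inner_extent_px: int = 112
    offset_px: tuple[int, int] = (-180, 180)
    dot_black_prob: float = 0.5
    directions: tuple[int, ...] = (45, 135, 225, 315)
    displacement: int = 1
    n_motion_frames: int = 2
    background_extent_deg: float = 17.99
    frame_extent_deg: float = 3.23
    inner_extent_deg: float = 2.42
    offset_deg: tuple[float, float] = (7.7, 10.64)
    luminance_cd_m2: float = 24.8

    def __post_init__(self) -> None:
        w, h = self.screen_size
        if w <= 0 or h <= 0:
            raise GeometryError(f"screen_size must be positive, got {self.screen_size}")
        if not (0 < self.inner_extent_px < self.frame_extent_px):
            raise GeometryError(
                "region extents must nest: 0 < inner_extent_px "
                f"({self.inner_extent_px}) < frame_extent_px ({self.frame_extent_px})"
            )
        if self.frame_extent_px >= min(w, h):
            raise GeometryError(
                f"frame_extent_px ({self.frame_extent_px}) does not fit on "
                f"screen {self.screen_size}"
            )
        if len(self.directions) != 4 or len(set(self.directions)) != 4:
            raise ValueError("directions must be 4 distinct angles")
        ds = sorted(d % 360 for d in self.directions)
        if any((b - a) % 360 != 90 for a, b in zip(ds, ds[1:])):
            raise ValueError(f"directions must be 90 degrees apart, got {self.directions}")
        if self.displacement < 0:
            raise ValueError("displacement must be >= 0")
        if not 0.0 <= self.dot_black_prob <= 1.0:
            raise ValueError("dot_black_prob must be a probability")

    @property
    def duration_ms(self) -> float:
        """Nominal stimulus duration: motion refreshes at the refresh rate."""
        return 1000.0 * self.n_motion_frames / self.refresh_rate

    def scaled(self, factor: float) -> "StimulusParams":
        """Proportionally scaled-down geometry (for Monte-Carlo audits)."""
        w, h = self.screen_size
        ox, oy = self.offset_px
        return dataclasses.replace(
            self,
            screen_size=(max(8, round(w * factor)), max(8, round(h * factor))),
            frame_extent_px=max(4, round(self.frame_extent_px * factor)),
            inner_extent_px=max(2, round(self.inner_extent_px * factor)),
            offset_px=(round(ox * factor), round(oy * factor)),
        )


@dataclass(frozen=True)
class RegionMasks:
    """Partition of the screen into background / frame / inner regions.

    ``labels`` is a (height, width) uint8 array with codes 0 = background,
    1 = frame, 2 = inner. The geometry is shared verbatim between stack and
    frame stimuli; only the direction assignment differs.
    """

    labels: np.ndarray

    def region(self, name: str) -> np.ndarray:
        return self.labels == _REGION_CODE[name]

    @property
    def border_pixels(self) -> np.ndarray:
        """Boolean mask of pixels adjacent (8-neighbourhood) to another region."""
        lab = self.labels
        border = np.zeros_like(lab, dtype=bool)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                shifted = _shift2d(lab, dr, dc, fill=255)
                border |= (shifted != lab) & (shifted != 255)
        return border

    def areas(self) -> dict[str, int]:
        return {r: int(np.sum(self.labels == c)) for r, c in _REGION_CODE.items()}


@dataclass(frozen=True)
class DirectionAssignment:
    """Motion direction (degrees) of each region for one trial."""

    background: int
    frame: int
    inner: int

    def as_dict(self) -> dict[str, int]:
        return {"background": self.background, "frame": self.frame, "inner": self.inner}


@dataclass(frozen=True)
class StimulusMovie:
    """A single stimulus presentation.

    ``frames`` has shape (2 + n_motion_frames, height, width) of uint8
    {0 = white, 1 = black}: a pre-stimulus static frame, the displaced
    motion frames, and one post-stimulus static frame (the continuous
    static display before/after is a hold of the first/last frame).
    """

    frames: np.ndarray
    masks: RegionMasks
    assignment: DirectionAssignment
    kind: str
    seed: int
    params: StimulusParams

    @property
    def motion_frames(self) -> np.ndarray:
        return self.frames[1:-1]


def make_region_masks(params: StimulusParams) -> RegionMasks:
    """Build the three nested concentric-square region masks.

    Raises
    ------
    GeometryError
        If the frame square does not fit on screen at the configured offset.
    """
    w, h = params.screen_size
    cx = w // 2 + params.offset_px[0]
    cy = h // 2 + params.offset_px[1]
    labels = np.zeros((h, w), dtype=np.uint8)
    for name, extent, code in (
        ("frame_extent_px", params.frame_extent_px, 1),
        ("inner_extent_px", params.inner_extent_px, 2),
    ):
        half = extent // 2
        r0, r1 = cy - half, cy - half + extent
        c0, c1 = cx - half, cx - half + extent
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise GeometryError(
                f"{name}={extent} at offset {params.offset_px} exceeds the "
                f"screen {params.screen_size}"
            )
        labels[r0:r1, c0:c1] = code
    return RegionMasks(labels=labels)


def assign_directions(kind: str, params: StimulusParams, rng: np.random.Generator) -> DirectionAssignment:
    """Draw one trial's per-region directions.

    Regions that share a border always move orthogonally (+/-90 deg); for
    the stack this forces inner opposite to background (they share no
    border, so 180 deg between them is allowed). Each region's marginal
    direction distribution is uniform over the four angles for every kind,
    which is what balances motion energy across kinds.
    """
    dirs = params.directions
    background = int(rng.choice(dirs))
    if kind == "homogenous":
        return DirectionAssignment(background, background, background)
    sign = 90 if rng.random() < 0.5 else -90
    frame_dir = (background + sign) % 360
    if kind == "frame":
        return DirectionAssignment(background, frame_dir, background)
    if kind == "stack":
        inner = (background + 180) % 360
        return DirectionAssignment(background, frame_dir, inner)
    raise ValueError(f"unknown stimulus kind {kind!r}; expected one of {STIMULUS_KINDS}")


def _shift2d(a: np.ndarray, d_row: int, d_col: int, fill=0) -> np.ndarray:
    """Shift a 2-D array by (d_row, d_col) without wrap-around."""
    out = np.full_like(a, fill)
    h, w = a.shape
    rs = slice(max(d_row, 0), h + min(d_row, 0))
    cs = slice(max(d_col, 0), w + min(d_col, 0))
    rsrc = slice(max(-d_row, 0), h + min(-d_row, 0))
    csrc = slice(max(-d_col, 0), w + min(-d_col, 0))
    out[rs, cs] = a[rsrc, csrc]
    return out


def direction_step(angle_deg: int, displacement: int) -> tuple[int, int]:
    """Per-refresh (d_row, d_col) pixel step for a diagonal motion angle.

    Screen rows grow downward, so 45 deg (up-right) is (-1, +1).
    """
    a = np.deg2rad(angle_deg % 360)
    d_col = int(np.sign(round(np.cos(a) * 2))) * displacement
    d_row = -int(np.sign(round(np.sin(a) * 2))) * displacement
    return d_row, d_col


def refill_mask(masks: RegionMasks, assignment: DirectionAssignment, displacement: int) -> np.ndarray:
    """Pixels refilled with fresh dots on one refresh (trailing borders).

    Depends only on geometry and directions, not on dot values; identical in
    expectation across stimulus kinds because geometry is shared and every
    region's direction is marginally uniform.
    """
    refill = np.zeros_like(masks.labels, dtype=bool)
    for region in _REGIONS:
        m = masks.region(region)
        d_row, d_col = direction_step(assignment.as_dict()[region], displacement)
        src_ok = _shift2d(m, d_row, d_col, fill=False)
        refill |= m & ~src_ok
    return refill


def _step_frame(
    frame: np.ndarray,
    masks: RegionMasks,
    assignment: DirectionAssignment,
    params: StimulusParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the dot field by one refresh: per-region coherent translation."""
    new = np.empty_like(frame)
    for region in _REGIONS:
        m = masks.region(region)
        d_row, d_col = direction_step(assignment.as_dict()[region], params.displacement)
        moved = _shift2d(frame, d_row, d_col)
        src_ok = _shift2d(m, d_row, d_col, fill=False)
        keep = m & src_ok
        new[keep] = moved[keep]
        fresh = m & ~src_ok
        n_fresh = int(fresh.sum())
        if n_fresh:
            new[fresh] = (rng.random(n_fresh) < params.dot_black_prob).astype(np.uint8)
    return new


def generate_stimulus(kind: str, params: StimulusParams, seed: int) -> StimulusMovie:
    """Generate one stimulus movie; bit-identical for equal (kind, params, seed)."""
    if kind not in STIMULUS_KINDS:
        raise ValueError(f"unknown stimulus kind {kind!r}; expected one of {STIMULUS_KINDS}")
    masks = make_region_masks(params)
    rng = np.random.default_rng(seed)
    assignment = assign_directions(kind, params, rng)
    h, w = masks.labels.shape
    first = (rng.random((h, w)) < params.dot_black_prob).astype(np.uint8)
    frames = [first]
    for _ in range(params.n_motion_frames):
        frames.append(_step_frame(frames[-1], masks, assignment, params, rng))
    frames.append(frames[-1].copy())  # dots remain in position after offset
    return StimulusMovie(
        frames=np.stack(frames),
        masks=masks,
        assignment=assignment,
        kind=kind,
        seed=int(seed),
        params=params,
    )


def generate_movies(kind: str, params: StimulusParams, n: int, seed: int) -> Iterable[StimulusMovie]:
    """Lazily generate ``n`` movies with per-movie seeds spawned from ``seed``."""
    for s in spawn_seeds(seed, n, key=kind):
        yield generate_stimulus(kind, params, s)


def spawn_seeds(seed: int, n: int, key: str | int | tuple = 0) -> np.ndarray:
    """Derive ``n`` child seeds (< 2**31) from a root seed and a stream key."""
    if isinstance(key, str):
        key = tuple(key.encode())
    elif isinstance(key, int):
        key = (key,)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))
    return (ss.generate_state(n, dtype=np.uint64) % (2**31)).astype(np.int64)


def motion_energy_summary(movies: Iterable[StimulusMovie]) -> pd.DataFrame:
    """Per-kind, per-direction displaced-pixel counts aggregated over movies.

    Each motion refresh contributes every region pixel to the region's
    direction. Returns a tidy frame with columns ``kind``, ``direction``,
    ``count``, ``share`` and ``n_movies``; shares within a kind sum to 1.
    """
    counts: dict[tuple[str, int], int] = {}
    n_movies: dict[str, int] = {}
    any_movie = False
    for mv in movies:
        any_movie = True
        n_movies[mv.kind] = n_movies.get(mv.kind, 0) + 1
        areas = mv.masks.areas()
        for region in _REGIONS:
            d = mv.assignment.as_dict()[region] % 360
            key = (mv.kind, d)
            counts[key] = counts.get(key, 0) + areas[region] * mv.params.n_motion_frames
    if not any_movie:
        raise ValueError("motion_energy_summary requires at least one movie")
    rows = []
    for kind in n_movies:
        total = sum(c for (k, _), c in counts.items() if k == kind)
        for d in (45, 135, 225, 315):
            c = counts.get((kind, d), 0)
            rows.append(
                {"kind": kind, "direction": d, "count": c,
                 "share": c / total if total else np.nan, "n_movies": n_movies[kind]}
            )
    return pd.DataFrame(rows)


def flicker_audit(movies: Iterable[StimulusMovie]) -> pd.DataFrame:
    """Mean changed-pixel counts between consecutive frames, split by cause.

    ``border_refill`` counts changes at trailing-border pixels refilled with
    fresh dots; ``interior`` counts changes at translated pixels. Counts are
    means per refresh transition per movie. By construction the expected
    border refill is equal across kinds (shared geometry, uniform marginal
    directions), which is the flicker-balance property audited here.
    """
    agg: dict[str, dict[str, float]] = {}
    for mv in movies:
        entry = agg.setdefault(mv.kind, {"border_refill": 0.0, "interior": 0.0, "n_transitions": 0})
        refill = refill_mask(mv.masks, mv.assignment, mv.params.displacement)
        seq = mv.frames[: 1 + mv.params.n_motion_frames]  # static -> motion steps
        for prev, nxt in zip(seq, seq[1:]):
            changed = prev != nxt
            entry["border_refill"] += float(np.sum(changed & refill))
            entry["interior"] += float(np.sum(changed & ~refill))
            entry["n_transitions"] += 1
    rows = []
    for kind, e in agg.items():
        n = max(e["n_transitions"], 1)
        rows.append(
            {"kind": kind,
             "mean_border_refill": e["border_refill"] / n,
             "mean_interior": e["interior"] / n,
             "n_transitions": e["n_transitions"]}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialSchedule:
    """Randomized, block-balanced trial order of the 3 x 4 design.

    ``table`` columns: ``block``, ``trial`` (within block), ``kind``,
    ``tms``, ``seed`` (per-trial stimulus seed). Within every block each of
    the 12 trial types occurs equally often.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_blocks(self) -> int:
        return int(self.table["block"].nunique())

    def type_counts(self) -> pd.DataFrame:
        return self.table.groupby(["kind", "tms"], sort=True).size().rename("count").reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialSchedule":
        df = pd.read_csv(path)
        required = {"block", "trial", "kind", "tms", "seed"}
        if not required.issubset(df.columns):
            raise ValueError(f"schedule CSV must have columns {sorted(required)}")
        return cls(table=df)


def build_schedule(n_blocks: int, trials_per_block: int, seed: int) -> TrialSchedule:
    """Build the randomized block schedule.

    Every block holds ``trials_per_block / 12`` repeats of each of the 12
    stimulus x TMS trial types in shuffled order; 25 blocks of 96 trials
    give the full session set of 200 trials per type.
    """
    if trials_per_block % len(TRIAL_TYPES) != 0:
        raise ValueError(
            f"trials_per_block ({trials_per_block}) must be divisible by {len(TRIAL_TYPES)}"
        )
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    reps = trials_per_block // len(TRIAL_TYPES)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(ord("s"),)))
    trial_seeds = spawn_seeds(seed, n_blocks * trials_per_block, key="trialseeds")
    rows = []
    i = 0
    for b in range(n_blocks):
        types = list(TRIAL_TYPES) * reps
        order = rng.permutation(len(types))
        for t, j in enumerate(order):
            kind, cond = types[j]
            rows.append(
                {"block": b, "trial": t, "kind": kind, "tms": cond, "seed": int(trial_seeds[i])}
            )
            i += 1
    return TrialSchedule(table=pd.DataFrame(rows))
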