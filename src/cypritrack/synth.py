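"""Ground-truth-labelled synthetic cyprid trajectories and rendered frames.

The generator emulates what a fixed overhead camera sees: a bright static
arena with up to a few dozen dark elliptical animals. Motion is scripted per
behaviour so ground truth is unambiguous:

* **swimming** — fast ballistic motion with a persistent, slightly noisy
  heading (reflecting off arena walls);
* **wide search** — dwell-step-dwell walking with near-constant step length
  (a fixed fraction of the body length) and small heading noise;
* **close search** — the same stepped walking interrupted every 1-3 steps by
  a pivot: the animal rotates about its leading terminal point by 45-70
  degrees, reproducing the abrupt anchored direction changes of tortuous
  exploration;
* **inspection** — the trailing terminal point stays pinned while the body
  oscillates sinusoidally about it.

Behaviour transitions occur exactly at scripted times; one integer seed
drives all randomness, so trajectory tables are bit-reproducible. Rendering
rasterises each animal as a hard-edged filled ellipse (no anti-aliasing, so
segment sizes are deterministic) and optionally adds Gaussian pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.draw import ellipse as draw_ellipse

__all__ = ["Phase", "BehaviourScript", "ArenaSpec", "generate_trajectory",
           "render_frames", "rasterize_ellipse", "write_sequence"]


@dataclass(frozen=True)
class Phase:
    behaviour: str        # swimming | wide_search | close_search | inspection
    duration_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("phase duration must be > 0")


@dataclass
class BehaviourScript:
    phases: list[Phase]

    @classmethod
    def from_dict(cls, d: dict) -> "BehaviourScript":
        return cls(phases=[Phase(p["behaviour"], float(p["duration_s"]),
                                 dict(p.get("params", {}))) for p in d["phases"]])

    @classmethod
    def load(cls, path: str | Path) -> "BehaviourScript":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ArenaSpec:
    """Imaging geometry of the synthetic arena.

    The default 33 fps matches the acquisition rate the behavioural
    thresholds were tuned at; blob semi-axes give a body boundary well above
    the five-pixel minimum the segmentation assumes.
    """

    width: int = 200
    height: int = 200
    background: float = 200.0
    blob_intensity: float = 60.0
    a: float = 9.0           # semimajor, px
    b: float = 4.0           # semiminor, px
    noise_sd: float = 2.0
    frame_rate: float = 33.0

    def __post_init__(self):
        if self.blob_intensity >= self.background:
            raise ValueError("blob must be darker than the background")

    @property
    def cl(self) -> float:
        """Cyprid body length: the full major axis."""
        return 2.0 * self.a


# ---------------------------------------------------------------------------
# Trajectory generation


def _unit(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([math.cos(t), math.sin(t)])


class _Walker:
    """Internal state machine emitting per-frame (x, y, theta)."""

    def __init__(self, arena: ArenaSpec, rng: np.random.Generator,
                 start_xy, heading_deg: float):
        self.arena = arena
        self.rng = rng
        self.pos = np.array(start_xy, dtype=float)
        self.heading = float(heading_deg)
        self.margin = 2.0 * arena.a + 4.0

    def _steer_inside(self) -> None:
        """Point the heading at the arena centre when too close to a wall."""
        w, h, m = self.arena.width, self.arena.height, self.margin
        if not (m <= self.pos[0] <= w - m and m <= self.pos[1] <= h - m):
            cx, cy = w / 2.0, h / 2.0
            self.heading = math.degrees(math.atan2(cy - self.pos[1], cx - self.pos[0]))
            self.heading += float(self.rng.uniform(-15, 15))

    def swim(self, n: int, speed: float, heading_sd: float):
        w, h, m = self.arena.width, self.arena.height, self.margin
        for _ in range(n):
            self.heading += float(self.rng.normal(0.0, heading_sd))
            step = speed * _unit(self.heading)
            nxt = self.pos + step
            if not (m <= nxt[0] <= w - m):
                self.heading = 180.0 - self.heading
            if not (m <= nxt[1] <= h - m):
                self.heading = -self.heading
            self.pos = self.pos + speed * _unit(self.heading)
            yield (*self.pos, self.heading)

    def dwell(self, n: int, jitter: float):
        for _ in range(n):
            p = self.pos + self.rng.normal(0.0, jitter, size=2)
            yield (*p, self.heading)

    def step(self, n_frames: int, length: float):
        self._steer_inside()
        target = self.pos + length * _unit(self.heading)
        for k in range(1, n_frames + 1):
            p = self.pos + (target - self.pos) * k / n_frames
            yield (*p, self.heading)
        self.pos = target

    def pivot(self, n_frames: int, delta_deg: float):
        """Rotate about the leading terminal point TP1 (the front anchor)."""
        anchor = self.pos + self.arena.a * _unit(self.heading)
        h0 = self.heading
        for k in range(1, n_frames + 1):
            h = h0 + delta_deg * k / n_frames
            p = anchor - self.arena.a * _unit(h)
            yield (*p, h)
        self.heading = h0 + delta_deg
        self.pos = anchor - self.arena.a * _unit(self.heading)

    def oscillate(self, n: int, amplitude_deg: float, period_frames: float,
                  jitter: float):
        """Pin the trailing terminal point TP2 and swing the body about it."""
        pin = self.pos - self.arena.a * _unit(self.heading)
        h0 = self.heading
        for k in range(n):
            h = h0 + amplitude_deg * math.sin(2.0 * math.pi * k / period_frames)
            p = pin + self.arena.a * _unit(h) + self.rng.normal(0.0, jitter, size=2)
            yield (*p, h)
        self.heading = h0
        self.pos = pin + self.arena.a * _unit(self.heading)


_DEFAULTS = {
    "swimming": dict(speed=6.0, heading_sd=3.0),
    "wide_search": dict(step_factor=0.85, dwell_frames=20, step_frames=3,
                        heading_sd=8.0, jitter=0.2),
    "close_search": dict(step_factor=0.85, dwell_frames=18, step_frames=3,
                         pivot_frames=25, turn_min=45.0, turn_max=70.0,
                         max_steps_between_turns=3, jitter=0.2),
    "inspection": dict(amplitude_deg=30.0, period_s=3.0, jitter=0.1),
}


def generate_trajectory(
    script: BehaviourScript,
    arena: ArenaSpec,
    seed: int,
    start_xy: tuple[float, float] | None = None,
    heading_deg: float | None = None,
) -> pd.DataFrame:
    """Emit one animal's frame-by-frame ground truth for a behaviour script.

    Returns a table (frame, xc, yc, theta_deg, behaviour); deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    if start_xy is None:
        m = 2.0 * arena.a + 6.0
        start_xy = (float(rng.uniform(m, arena.width - m)),
                    float(rng.uniform(m, arena.height - m)))
    if heading_deg is None:
        heading_deg = float(rng.uniform(0.0, 360.0))
    walker = _Walker(arena, rng, start_xy, heading_deg)

    rows: list[tuple] = []
    frame = 0

    def take(gen, n: int, label: str) -> int:
        nonlocal frame
        count = 0
        for x, y, h in gen:
            rows.append((frame, x, y, h, label))
            frame += 1
            count += 1
            if count >= n:
                break
        return count

    for phase in script.phases:
        p = {**_DEFAULTS[phase.behaviour], **phase.params}
        n = int(round(phase.duration_s * arena.frame_rate))
        if phase.behaviour == "swimming":
            take(walker.swim(n, p["speed"], p["heading_sd"]), n, "swimming")
        elif phase.behaviour == "wide_search":
            left = n
            step_len = p["step_factor"] * arena.cl
            while left > 0:
                left -= take(walker.dwell(min(p["dwell_frames"], left), p["jitter"]),
                             left, "wide_search")
                if left <= 0:
                    break
                walker.heading += float(rng.normal(0.0, p["heading_sd"]))
                left -= take(walker.step(p["step_frames"], step_len), left, "wide_search")
        elif phase.behaviour == "close_search":
            left = n
            step_len = p["step_factor"] * arena.cl
            while left > 0:
                delta = float(rng.uniform(p["turn_min"], p["turn_max"]))
                delta *= 1.0 if rng.random() < 0.5 else -1.0
                left -= take(walker.pivot(p["pivot_frames"], delta), left, "close_search")
                k = int(rng.integers(1, p["max_steps_between_turns"] + 1))
                for _ in range(k):
                    if left <= 0:
                        break
                    left -= take(walker.dwell(min(p["dwell_frames"], left), p["jitter"]),
                                 left, "close_search")
                    if left <= 0:
                        break
                    left -= take(walker.step(p["step_frames"], step_len), left,
                                 "close_search")
        elif phase.behaviour == "inspection":
            period = p["period_s"] * arena.frame_rate
            take(walker.oscillate(n, p["amplitude_deg"], period, p["jitter"]),
                 n, "inspection")
        else:
            raise ValueError(f"unknown behaviour {phase.behaviour!r}")

    return pd.DataFrame(rows, columns=["frame", "xc", "yc", "theta_deg", "behaviour"])


def crossing_trajectories(
    arena: ArenaSpec,
    angle_deg: float,
    speed: float = 3.0,
    n_frames: int = 60,
    heading_deg: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two straight swimmers whose paths cross at the arena centre.

    Both animals pass through the centre at the sequence midpoint, their
    headings separated by ``angle_deg``; the arena must be large enough to
    hold the full paths (checked). Used to exercise merge/split identity
    resolution with known ground truth.
    """
    half = speed * n_frames / 2.0
    margin = 2.0 * arena.a + 2.0
    if half + margin > min(arena.width, arena.height) / 2.0:
        raise ValueError("arena too small for the requested crossing paths")
    c = np.array([arena.width / 2.0, arena.height / 2.0])
    out = []
    for h in (heading_deg, heading_deg + angle_deg):
        u = _unit(h)
        rows = [(f, *(c + (f - n_frames / 2.0) * speed * u), h % 360.0, "swimming")
                for f in range(n_frames)]
        out.append(pd.DataFrame(rows, columns=["frame", "xc", "yc", "theta_deg",
                                               "behaviour"]))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Rendering


def rasterize_ellipse(xc: float, yc: float, a: float, b: float, theta_deg: float,
                      shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Integer (rows, cols) of a filled rotated ellipse.

    The rotation sign is chosen so that the drawn blob's second-moment
    orientation equals ``theta_deg`` in image convention (x right, y down).
    """
    return draw_ellipse(yc, xc, b, a, shape=shape,
                        rotation=-math.radians(theta_deg))


def render_frames(
    trajectories: list[pd.DataFrame],
    arena: ArenaSpec,
    seed: int = 0,
) -> list[np.ndarray]:
    """Rasterise trajectories into an 8-bit grayscale frame sequence.

    Overlapping animals naturally fuse into a single dark blob. Frames cover
    0..max frame; an animal absent from a frame simply is not drawn.
    """
    rng = np.random.default_rng(seed)
    n_frames = 1 + max(int(t["frame"].max()) for t in trajectories)
    by_frame: list[list[tuple]] = [[] for _ in range(n_frames)]
    for traj in trajectories:
        for row in traj.itertuples(index=False):
            by_frame[int(row.frame)].append((row.xc, row.yc, row.theta_deg))
    shape = (arena.height, arena.width)
    frames = []
    for f in range(n_frames):
        img = np.full(shape, arena.background, dtype=np.float64)
        for xc, yc, theta in by_frame[f]:
            rr, cc = rasterize_ellipse(xc, yc, arena.a, arena.b, theta, shape)
            img[rr, cc] = arena.blob_intensity
        if arena.noise_sd > 0:
            img = img + rng.normal(0.0, arena.noise_sd, size=shape)
        frames.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return frames


def write_sequence(frames: list[np.ndarray], out_dir: str | Path,
                   truth: pd.DataFrame | None = None) -> None:
    """Write frames as numbered PNGs plus an optional ground-truth CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(frames))))
    for i, img in enumerate(frames):
        iio.imwrite(out / f"frame_{i:0{width}d}.png", img)
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
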