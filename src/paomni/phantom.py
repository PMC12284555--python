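"""Random optical-absorption phantoms: disks and vessel-like segments.

A :class:`PhantomScene` is a reproducible description of absorbers in the
normalized [-1, 1]^2 field of view.  Scenes emulate the content of
vascular / forearm photoacoustic images at desk scale: a few bright
disk-shaped absorbers plus elongated vessel segments.  Scene sampling is
two-level: a *group* ("patient") seed fixes a base anatomy which all
items of the group share, and a per-item seed jitters it, so grouped
train/validation/test splits are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = ["Disk", "VesselSegment", "PhantomScene", "random_scene", "group_scene"]

# absorbers are confined to this radius so every primitive stays inside
# the field of view even after per-item jitter
_FOV_LIMIT = 0.78


@dataclass(frozen=True)
class Disk:
    center: tuple[float, float]
    radius: float
    amplitude: float


@dataclass(frozen=True)
class VesselSegment:
    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float
    amplitude: float


@dataclass(frozen=True)
class PhantomScene:
    """Absorber layout plus the grid it rasterizes onto."""

    absorbers: tuple = field(repr=False)
    grid_size: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.grid_size
        if h < 4 or w < 4:
            raise ValueError(f"degenerate grid {self.grid_size}")
        for a in self.absorbers:
            if a.amplitude <= 0:
                raise ValueError("absorber amplitudes must be positive")
            pts = [a.center] if isinstance(a, Disk) else [a.p0, a.p1]
            for x, y in pts:
                if abs(x) > 1 or abs(y) > 1:
                    raise ValueError("absorber outside the field of view")

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of pixel centers, y-axis up."""
        h, w = self.grid_size
        xs = -1.0 + (2.0 * (np.arange(w) + 0.5)) / w
        ys = 1.0 - (2.0 * (np.arange(h) + 0.5)) / h
        return np.meshgrid(xs, ys)

    def rasterize(self) -> np.ndarray:
        """Render the scene to an H x W absorption map in [0, 1].

        Primitive amplitudes add; edges are softened over one pixel to
        avoid aliasing.  An empty scene renders to all zeros.
        """
        h, w = self.grid_size
        px = 2.0 / max(h, w)
        x, y = self.pixel_grid()
        img = np.zeros((h, w), dtype=np.float64)
        for a in self.absorbers:
            if isinstance(a, Disk):
                d = np.hypot(x - a.center[0], y - a.center[1]) - a.radius
            else:
                d = _segment_distance(x, y, a.p0, a.p1) - a.width / 2.0
            img += a.amplitude * np.clip(0.5 - d / px, 0.0, 1.0)
        peak = img.max()
        if peak > 0:
            img /= peak
        return img


def _segment_distance(x, y, p0, p1):
    """Distance from each grid point to the segment p0-p1."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    l2 = vx * vx + vy * vy
    if l2 == 0:
        return np.hypot(x - p0[0], y - p0[1])
    t = np.clip(((x - p0[0]) * vx + (y - p0[1]) * vy) / l2, 0.0, 1.0)
    return np.hypot(x - (p0[0] + t * vx), y - (p0[1] + t * vy))


def _sample_absorbers(rng: np.random.Generator) -> list:
    absorbers: list = []
    for _ in range(rng.integers(2, 6)):
        r = rng.uniform(0.04, 0.14)
        c = rng.uniform(-_FOV_LIMIT + r, _FOV_LIMIT - r, size=2)
        absorbers.append(Disk(center=(c[0], c[1]), radius=r, amplitude=rng.uniform(0.4, 1.0)))
    for _ in range(rng.integers(1, 4)):
        p0 = rng.uniform(-_FOV_LIMIT, _FOV_LIMIT, size=2)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.3, 0.9)
        p1 = np.clip(p0 + length * np.array([np.cos(ang), np.sin(ang)]), -_FOV_LIMIT, _FOV_LIMIT)
        absorbers.append(
            VesselSegment(
                p0=(p0[0], p0[1]), p1=(p1[0], p1[1]),
                width=rng.uniform(0.02, 0.07), amplitude=rng.uniform(0.3, 0.9),
            )
        )
    return absorbers


def random_scene(seed: int, grid_size: tuple[int, int] = (64, 64)) -> PhantomScene:
    """A fully random scene; identical seed reproduces an identical scene."""
    rng = np.random.default_rng(seed)
    return PhantomScene(absorbers=tuple(_sample_absorbers(rng)), grid_size=grid_size, seed=int(seed))


def _jitter(a, rng: np.random.Generator, scale: float = 0.04,
            amp_lo: float = 0.85, amp_hi: float = 1.15):
    dx, dy = rng.uniform(-scale, scale, size=2)
    amp = float(np.clip(a.amplitude * rng.uniform(amp_lo, amp_hi), 0.05, 1.0))

    def move(p):
        return (float(np.clip(p[0] + dx, -_FOV_LIMIT, _FOV_LIMIT)),
                float(np.clip(p[1] + dy, -_FOV_LIMIT, _FOV_LIMIT)))

    if isinstance(a, Disk):
        return Disk(center=move(a.center), radius=a.radius, amplitude=amp)
    return VesselSegment(p0=move(a.p0), p1=move(a.p1), width=a.width, amplitude=amp)


def group_scene(family_seed: int, group_seed: int, item_seed: int,
                grid_size: tuple[int, int] = (64, 64)) -> PhantomScene:
    """Scene for one item of a group, with a two-level anatomy hierarchy.

    ``family_seed`` fixes the base anatomy of a whole dataset (the organ
    / preparation being imaged: all subjects of one cohort resemble each
    other, the way volunteer forearms do); ``group_seed`` applies a
    moderate subject-level deformation (a synthetic "patient"); and
    ``item_seed`` adds small positional and amplitude jitter (repeat
    slices / acquisitions of that subject).
    """
    base = _sample_absorbers(np.random.default_rng(family_seed))
    grng = np.random.default_rng((int(family_seed) << 16) ^ (int(group_seed) + 1))
    subject = [_jitter(a, grng, scale=0.12, amp_lo=0.7, amp_hi=1.3) for a in base]
    irng = np.random.default_rng((int(group_seed) << 20) ^ int(item_seed))
    jittered = tuple(_jitter(a, irng, scale=0.03) for a in subject)
    return PhantomScene(absorbers=jittered, grid_size=grid_size, seed=int(item_seed))
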