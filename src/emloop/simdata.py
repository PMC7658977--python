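"""Synthetic cryo-EM data with known ground truth.

Real feedback-loop experiments run on micrograph movies that are not
publicly deposited, so this module generates stand-ins with the
statistical structure the pipeline assumes: dose-fractionated movies with
global per-frame drift and additive Gaussian noise, a mixture of particle
shape classes with controllable abundances (emulating a two-conformation
specimen where the targeted state is the rare one), high-intensity
contamination blobs, and filamentous specimens rendered as constant-width
ridges along polylines.

No contrast transfer function is simulated: the feedback loop operates on
picked coordinates and class-average labels, none of which depend on CTF
oscillations, and CTF estimation is an external-adapter concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import Box, Micrograph, MovieStack

__all__ = [
    "ParticleClassSpec",
    "SimConfig",
    "MicrographTruth",
    "GroundTruth",
    "make_template",
    "default_class_specs",
    "generate_dataset",
    "render_micrograph",
    "render_filaments",
    "sample_polylines",
    "corrupt_picks",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Particle templates
# ---------------------------------------------------------------------------

def make_template(kind: str, diameter: int, side: Optional[int] = None) -> np.ndarray:
    """Build a smooth, radially asymmetric particle template.

    Parameters
    ----------
    kind:
        One of ``"disc"`` (soft-edged solid disc with an off-center lobe),
        ``"ring"`` (annulus with an off-center lobe), ``"dumbbell"``
        (two merged discs).  The shapes have clearly different radial
        profiles so distinct classes are separable by rotation-invariant
        features.
    diameter:
        Particle diameter in pixels (>= 4).
    side:
        Template side length; defaults to an odd value slightly larger
        than the diameter.
    """
    if diameter < 4:
        raise ConfigurationError(f"diameter must be >= 4 px, got {diameter}")
    if side is None:
        side = int(diameter) + (int(diameter) // 4) * 2 + 1
    if side < diameter:
        raise ConfigurationError("template side must be >= diameter")
    r = diameter / 2.0
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    d = np.hypot(xx - c, yy - c)

    def soft_disc(dist, radius, edge):
        return 0.5 * (1.0 - np.tanh((dist - radius) / edge))

    edge = max(1.0, r / 6.0)
    if kind == "disc":
        body = soft_disc(d, r, edge)
        lobe_d = np.hypot(xx - (c + 0.4 * r), yy - c)
        body = body + 0.5 * np.exp(-(lobe_d / (0.3 * r)) ** 2)
    elif kind == "ring":
        body = soft_disc(d, r, edge) - 0.9 * soft_disc(d, 0.55 * r, edge)
        lobe_d = np.hypot(xx - c, yy - (c - 0.75 * r))
        body = body + 0.4 * np.exp(-(lobe_d / (0.3 * r)) ** 2)
    elif kind == "dumbbell":
        d1 = np.hypot(xx - (c - 0.45 * r), yy - c)
        d2 = np.hypot(xx - (c + 0.45 * r), yy - (c + 0.2 * r))
        body = soft_disc(d1, 0.5 * r, edge) + soft_disc(d2, 0.4 * r, edge)
    else:
        raise ConfigurationError(f"unknown template kind {kind!r}")
    body = body.astype(np.float32)
    peak = float(body.max())
    if peak > 0:
        body /= peak
    return body


@dataclass(frozen=True)
class ParticleClassSpec:
    """One particle shape class in the simulated mixture."""

    class_id: str
    template: np.ndarray
    diameter: int
    abundance: float

    def __post_init__(self) -> None:
        t = np.asarray(self.template, dtype=np.float32)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ConfigurationError("template must be a square 2D array")
        if self.diameter < 4:
            raise ConfigurationError("diameter must be >= 4 px")
        if t.shape[0] < self.diameter:
            raise ConfigurationError("template side must be >= diameter")
        if not (0.0 <= self.abundance <= 1.0):
            raise ConfigurationError("abundance must lie in [0, 1]")
        object.__setattr__(self, "template", t)


def default_class_specs(
    abundances: Sequence[float] = (0.81, 0.19),
    diameter: int = 24,
    kinds: Sequence[str] = ("disc", "ring"),
    class_ids: Optional[Sequence[str]] = None,
) -> list[ParticleClassSpec]:
    """Built-in two-class mixture.

    The defaults emulate a specimen with a common conformation (81%) and
    a rare, targeted one (19%), rendered as visually distinct shapes.
    """
    if class_ids is None:
        class_ids = [f"class_{k}" for k in kinds]
    specs = [
        ParticleClassSpec(cid, make_template(kind, diameter), diameter, ab)
        for cid, kind, ab in zip(class_ids, kinds, abundances)
    ]
    _check_abundances(specs)
    return specs


def _check_abundances(specs: Sequence[ParticleClassSpec]) -> None:
    total = sum(s.abundance for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"class abundances must sum to 1 (got {total:.12f})"
        )


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic acquisition.

    ``noise_sigma`` sets the additive Gaussian noise per frame relative to
    a template peak amplitude of 1; the per-frame noise level therefore
    directly controls SNR, which is a free parameter of the simulation.
    """

    image_size: tuple[int, int] = (360, 360)
    n_frames: int = 1
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.25
    particles_per_micrograph: int = 25
    contamination_rate: float = 0.5
    filament_mode: bool = False
    filament_width: int = 12
    filaments_per_micrograph: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.particles_per_micrograph < 0 or self.contamination_rate < 0:
            raise ConfigurationError("counts must be >= 0")


@dataclass
class MicrographTruth:
    """Ground truth for one micrograph."""

    micrograph_id: str
    particles: list[tuple[float, float, str]] = field(default_factory=list)
    contaminants: list[tuple[float, float, float]] = field(default_factory=list)
    polylines: list[np.ndarray] = field(default_factory=list)

    def boxes(self, box_size: int) -> list[Box]:
        """Truth particle centers as Box records with confidence 1."""
        return [
            Box(x, y, box_size, 1.0, micrograph_id=self.micrograph_id)
            for x, y, _cid in self.particles
        ]

    def class_of(self, x: float, y: float, tol: float = 1e-6) -> Optional[str]:
        for px, py, cid in self.particles:
            if abs(px - x) <= tol and abs(py - y) <= tol:
                return cid
        return None


@dataclass
class GroundTruth:
    """Per-micrograph truth for a generated dataset, keyed by id."""

    micrographs: dict[str, MicrographTruth] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.micrographs)

    def __getitem__(self, mic_id: str) -> MicrographTruth:
        return self.micrographs[mic_id]

    def __iter__(self):
        return iter(self.micrographs.values())


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_patch(image: np.ndarray, patch: np.ndarray, cx: float, cy: float,
               amplitude: float = 1.0) -> None:
    """Add ``patch`` centered at (cx, cy) with subpixel placement.

    The patch is shifted by the fractional part via linear interpolation;
    portions falling outside the image are clipped.
    """
    side = patch.shape[0]
    half = (side - 1) / 2.0
    x0f, y0f = cx - half, cy - half
    ix0, iy0 = int(math.floor(x0f)), int(math.floor(y0f))
    fx, fy = x0f - ix0, y0f - iy0
    if fx or fy:
        shifted = ndimage.shift(patch, (fy, fx), order=1, mode="constant",
                                cval=0.0, prefilter=False)
        # shifting pushes content down/right; allow one extra row/col
        padded = np.zeros((side + 1, side + 1), dtype=patch.dtype)
        padded[:side, :side] = shifted
        patch = padded
        side += 1
    h, w = image.shape
    sy0, sy1 = max(0, iy0), min(h, iy0 + side)
    sx0, sx1 = max(0, ix0), min(w, ix0 + side)
    if sy0 >= sy1 or sx0 >= sx1:
        return
    py0, px0 = sy0 - iy0, sx0 - ix0
    image[sy0:sy1, sx0:sx1] += amplitude * patch[py0:py0 + (sy1 - sy0),
                                                 px0:px0 + (sx1 - sx0)]


def _contamination_patch(radius: float) -> np.ndarray:
    side = int(2 * radius) + 5
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    d = np.hypot(xx - c, yy - c)
    return (0.5 * (1.0 - np.tanh((d - radius) / max(1.0, radius / 5.0)))
            ).astype(np.float32)


def render_micrograph(
    truth: MicrographTruth,
    config: SimConfig,
    class_specs: Sequence[ParticleClassSpec],
    rng: Optional[np.random.Generator] = None,
) -> MovieStack:
    """Render one movie from its ground-truth entry.

    Frame ``f`` contains every particle template centered at its truth
    position plus the cumulative drift ``f * drift_per_frame``, plus
    i.i.d. Gaussian noise per frame.  Particles drifting off the frame
    are clipped, never an error.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec_by_id = {s.class_id: s for s in class_specs}
    h, w = config.image_size
    dx, dy = config.drift_per_frame
    frames = np.zeros((config.n_frames, h, w), dtype=np.float32)
    for f in range(config.n_frames):
        img = frames[f]
        ox, oy = f * dx, f * dy
        for (x, y, cid) in truth.particles:
            spec = spec_by_id[cid]
            _add_patch(img, spec.template, x + ox, y + oy)
        for (x, y, r) in truth.contaminants:
            _add_patch(img, _contamination_patch(r), x + ox, y + oy,
                       amplitude=1.5)
        for line in truth.polylines:
            _draw_ridge(img, line + np.array([ox, oy]), config.filament_width)
        if config.noise_sigma > 0:
            img += rng.normal(0.0, config.noise_sigma, size=img.shape
                              ).astype(np.float32)
    return MovieStack(frames, micrograph_id=truth.micrograph_id)


def _draw_ridge(image: np.ndarray, polyline: np.ndarray, width: int,
                amplitude: float = 1.0) -> None:
    """Add a flat-top intensity ridge of the given width along a polyline."""
    h, w = image.shape
    mask = np.ones((h, w), dtype=bool)
    pts = np.asarray(polyline, dtype=float)
    # rasterize centerline densely, then take a distance transform
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        n = int(max(abs(x1 - x0), abs(y1 - y0)) * 2) + 2
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        ii = np.round(ys).astype(int)
        jj = np.round(xs).astype(int)
        keep = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
        mask[ii[keep], jj[keep]] = False
    dist = ndimage.distance_transform_edt(mask)
    half = width / 2.0
    ridge = 0.5 * (1.0 - np.tanh((dist - half) / 1.0))
    image += (amplitude * ridge).astype(np.float32)


def render_filaments(
    polylines: Sequence[np.ndarray],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Micrograph:
    """Render a single micrograph containing filament ridges plus noise."""
    if not config.filament_mode:
        raise ConfigurationError("filament rendering requires filament_mode")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    img = np.zeros((h, w), dtype=np.float32)
    for line in polylines:
        _draw_ridge(img, np.asarray(line, dtype=float), config.filament_width)
    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape
                          ).astype(np.float32)
    return Micrograph(img)


def sample_polylines(config: SimConfig, n: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Random straight filament centerlines crossing the field of view."""
    h, w = config.image_size
    margin = config.filament_width
    lines = []
    for _ in range(n):
        x0 = rng.uniform(margin, w - margin)
        y0 = rng.uniform(margin, h - margin)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.5, 0.9) * min(h, w)
        dx, dy = math.cos(angle), math.sin(angle)
        p0 = np.array([x0 - dx * length / 2, y0 - dy * length / 2])
        p1 = np.array([x0 + dx * length / 2, y0 + dy * length / 2])
        lines.append(np.vstack([p0, p1]))
    return lines


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SimConfig,
    n_micrographs: int,
    class_specs: Optional[Sequence[ParticleClassSpec]] = None,
) -> tuple[list[MovieStack], GroundTruth]:
    """Generate movies and ground truth for ``n_micrographs`` micrographs.

    Particle classes are drawn per particle with the configured
    abundances; centers are uniform with a margin of half the class
    diameter from every edge.  Contamination blob counts are Poisson with
    mean ``contamination_rate``.  Output is bit-for-bit reproducible for
    a fixed ``(config, seed)``.
    """
    if n_micrographs < 0:
        raise ConfigurationError("n_micrographs must be >= 0")
    if class_specs is None:
        class_specs = default_class_specs()
    _check_abundances(class_specs)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(max(n_micrographs, 1))
    h, w = config.image_size
    abundances = np.array([s.abundance for s in class_specs])
    movies: list[MovieStack] = []
    truth = GroundTruth()
    for i in range(n_micrographs):
        rng = np.random.default_rng(children[i])
        mic_id = f"mic_{i:04d}"
        entry = MicrographTruth(mic_id)
        if config.filament_mode:
            entry.polylines = sample_polylines(
                config, config.filaments_per_micrograph, rng)
        else:
            # excluded volume: solid particles cannot overlap, so centers
            # are rejected closer than ~one diameter to an earlier center
            placed: list[tuple[float, float]] = []
            for _ in range(config.particles_per_micrograph):
                k = int(rng.choice(len(class_specs), p=abundances))
                spec = class_specs[k]
                m = 0.5 * spec.diameter
                min_sep = 0.9 * spec.diameter
                for _attempt in range(100):
                    x = rng.uniform(m, w - 1 - m)
                    y = rng.uniform(m, h - 1 - m)
                    if all((x - px) ** 2 + (y - py) ** 2 >= min_sep ** 2
                           for px, py in placed):
                        placed.append((x, y))
                        entry.particles.append((x, y, spec.class_id))
                        break
            mean_diam = float(np.mean([s.diameter for s in class_specs]))
            for _ in range(rng.poisson(config.contamination_rate)):
                r = rng.uniform(1.0, 2.0) * mean_diam  # 2-4x diameter across
                entry.contaminants.append(
                    (rng.uniform(0, w - 1), rng.uniform(0, h - 1), r))
        movies.append(render_micrograph(entry, config, class_specs, rng))
        truth.micrographs[mic_id] = entry
    return movies, truth


def corrupt_picks(
    boxes: Sequence[Box],
    fraction: float,
    image_size: tuple[int, int],
    seed: int,
) -> list[Box]:
    """Replace ``ceil(fraction * n)`` boxes with random in-image positions.

    Emulates a deliberately crippled round-1 picking model: the replaced
    boxes keep their confidence and size but land at uniformly random
    coordinates.  The remaining boxes are returned unchanged, in the
    original order.  Deterministic per seed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    boxes = list(boxes)
    n = len(boxes)
    n_replace = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_replace, replace=False) if n_replace else []
    h, w = image_size
    out = list(boxes)
    for i in idx:
        out[i] = boxes[i].with_center(rng.uniform(0, w - 1),
                                      rng.uniform(0, h - 1))
    return out
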