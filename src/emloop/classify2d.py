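"""Batch accumulation and capacity-constrained 2D class averaging.

The classifier is a deterministic, CPU-cheap stand-in honoring the
contract of capacity-limited 2D classification as used on-the-fly:
classes are kept between a minimum and maximum member count, particles
that do not fit a stable class are rejected into an "unaccounted" set,
and class averages are member means after coarse translational
alignment.  Features are rotation- and translation-tolerant (radial
intensity profile plus radially averaged Fourier magnitudes), and
assignment is balanced k-means with a hard per-class capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import Box, Micrograph

__all__ = [
    "ParticleImage",
    "BatchAccumulator",
    "ClassAverage",
    "ClassifyResult",
    "window_particles",
    "accumulate",
    "classify",
]


@dataclass
class ParticleImage:
    """One windowed, normalized particle patch with its provenance box."""

    patch: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        if self.patch.ndim != 2 or self.patch.shape[0] != self.patch.shape[1]:
            raise ValueError("particle patch must be square")


def window_particles(micrograph: Micrograph, boxes: Sequence[Box],
                     box_size: int) -> list[ParticleImage]:
    """Extract square windows centered on each box.

    Boxes whose window would extend beyond the micrograph are discarded.
    Patches are normalized to zero mean and unit variance.
    """
    h, w = micrograph.image.shape
    if box_size > min(h, w):
        raise ValueError("box_size exceeds micrograph dimensions")
    half = box_size // 2
    out: list[ParticleImage] = []
    for b in boxes:
        x0 = int(round(b.center_x)) - half
        y0 = int(round(b.center_y)) - half
        if x0 < 0 or y0 < 0 or x0 + box_size > w or y0 + box_size > h:
            continue
        patch = micrograph.image[y0:y0 + box_size, x0:x0 + box_size]
        patch = patch.astype(np.float64)
        patch = patch - patch.mean()
        sd = patch.std()
        if sd > 0:
            patch = patch / sd
        out.append(ParticleImage(patch, b))
    return out


# ---------------------------------------------------------------------------
# Batch accumulation
# ---------------------------------------------------------------------------

@dataclass
class BatchAccumulator:
    """Collects particles until a batch worth classifying has built up.

    When the pending count reaches ``batch_size``, *all* pending
    particles are flushed as one batch — batches may therefore exceed
    the nominal size, but classification never starts on fewer.
    """

    batch_size: int = 20000
    pending: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def accumulate(acc: BatchAccumulator,
               new_particles: Sequence) -> tuple[BatchAccumulator, list[list]]:
    """Add particles, flushing whenever the pending count reaches the
    batch size.  Arrival order is preserved.  Returns the (mutated)
    accumulator and the list of flushed batches (possibly empty)."""
    flushed: list[list] = []
    acc.pending.extend(new_particles)
    if len(acc.pending) >= acc.batch_size:
        flushed.append(acc.pending)
        acc.pending = []
    return acc, flushed


def flush_remainder(acc: BatchAccumulator) -> list[list]:
    """Force out whatever is pending (end of a finite dataset/round)."""
    if not acc.pending:
        return []
    batch = acc.pending
    acc.pending = []
    return [batch]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassAverage:
    """A 2D class mean with its member list.

    ``member_shifts`` holds the integer (dx, dy) translation applied to
    each member during alignment to the class centroid; subtracting a
    member's shift from its box center re-centers the pick on the
    particle, the way alignment parameters from 2D classification are
    used to refine coordinates downstream.
    """

    mean_image: np.ndarray
    member_ids: list[int]
    member_shifts: list[tuple[int, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClassifyResult:
    """Partition of a batch into classes and unaccounted particles."""

    classes: list[ClassAverage]
    unaccounted: list[int]

    @property
    def accounted(self) -> list[int]:
        return [i for c in self.classes for i in c.member_ids]


def _radial_bins(side: int) -> np.ndarray:
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(xx - c, yy - c)
    return np.minimum(r.astype(int), side // 2)


def _features(patches: np.ndarray) -> np.ndarray:
    """Radial mean profile + radially averaged Fourier magnitudes."""
    n, side, _ = patches.shape
    bins = _radial_bins(side).ravel()
    nbins = bins.max() + 1
    counts = np.bincount(bins, minlength=nbins)
    flat = patches.reshape(n, -1)
    radial = np.stack([np.bincount(bins, weights=f, minlength=nbins) / counts
                       for f in flat])
    spectra = np.abs(np.fft.fftshift(np.fft.fft2(patches), axes=(1, 2)))
    sflat = spectra.reshape(n, -1)
    fradial = np.stack([np.bincount(bins, weights=f, minlength=nbins) / counts
                        for f in sflat])
    fradial = fradial / (np.linalg.norm(fradial, axis=1, keepdims=True) + 1e-12)
    return np.hstack([radial, fradial])


def _capacity_assign(dist: np.ndarray, cap: int) -> np.ndarray:
    """Greedy best-fit assignment with a hard per-class capacity.

    Particles are processed in order of how much they would lose by not
    getting their closest class (largest margin first), each taking the
    nearest class with remaining capacity.
    """
    n, k = dist.shape
    order = np.argsort(dist.min(axis=1) - dist.mean(axis=1))
    remaining = np.full(k, cap)
    assign = np.full(n, -1)
    for i in order:
        for j in np.argsort(dist[i]):
            if remaining[j] > 0:
                assign[i] = j
                remaining[j] -= 1
                break
    return assign


def _integer_shift(patch: np.ndarray, reference: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) registering patch onto reference via FFT correlation."""
    c = np.fft.ifft2(np.fft.fft2(reference) * np.conj(np.fft.fft2(patch))).real
    dy, dx = np.unravel_index(np.argmax(c), c.shape)
    h, w = patch.shape
    if dy > h // 2:
        dy -= h
    if dx > w // 2:
        dx -= w
    return int(dy), int(dx)


def _aligned_mean(
    patches: np.ndarray, n_passes: int = 2,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Member mean after coarse translational alignment to the centroid.

    Returns the aligned mean and the per-member (dx, dy) shifts of the
    final pass.
    """
    mean = patches.mean(axis=0)
    shifts: list[tuple[int, int]] = [(0, 0)] * len(patches)
    for _ in range(n_passes):
        aligned = []
        shifts = []
        for p in patches:
            dy, dx = _integer_shift(p, mean)
            shifts.append((dx, dy))
            aligned.append(np.roll(np.roll(p, dy, axis=0), dx, axis=1))
        mean = np.mean(aligned, axis=0)
    return mean, shifts


def classify(
    batch: Sequence[ParticleImage],
    class_size_range: tuple[int, int] = (60, 100),
    seed: int = 0,
    n_iterations: int = 20,
) -> ClassifyResult:
    """Partition a batch into capacity-constrained 2D classes.

    The number of classes attempted is ``max(1, round(N / mean(range)))``
    so classes land inside the configured size range; no class may
    exceed the maximum size, and classes ending below the minimum are
    dissolved into the unaccounted set.  Deterministic per seed.
    """
    min_s, max_s = class_size_range
    if not (0 < min_s <= max_s):
        raise ValueError("class size range must satisfy 0 < min <= max")
    n = len(batch)
    if n == 0:
        raise ValueError("classification requires a non-empty batch")
    if n < min_s:
        return ClassifyResult([], list(range(n)))
    patches = np.stack([p.patch for p in batch])
    feats = _features(patches)
    k = max(1, round(n / ((min_s + max_s) / 2.0)))
    rng = np.random.default_rng(seed)
    centers = feats[rng.choice(n, size=k, replace=False)]
    assign = np.full(n, -1)
    for _ in range(n_iterations):
        dist = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = _capacity_assign(dist, max_s)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = feats[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    classes: list[ClassAverage] = []
    unaccounted: list[int] = []
    for j in range(k):
        member_ids = np.flatnonzero(assign == j).tolist()
        if len(member_ids) < min_s:
            unaccounted.extend(member_ids)
            continue
        mean_img, shifts = _aligned_mean(patches[member_ids])
        classes.append(ClassAverage(mean_img, member_ids, shifts))
    unaccounted.extend(np.flatnonzero(assign == -1).tolist())
    return ClassifyResult(classes, sorted(unaccounted))
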