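"""Trainable particle picking, evaluation, and threshold optimization.

The reference picker is a template-correlation detector that behaves like
a learned picker at desk scale: training windows labeled particles,
clusters them into a small set of normalized templates, and fits a
logistic calibration that maps per-template normalized cross-correlation
scores at a location to a confidence in [0, 1].  Candidate locations are
local correlation maxima; duplicates are removed by non-maximum
suppression; the picking threshold is applied to the calibrated
confidence.

Re-trained models keep a reference to their predecessor and blend
confidences with exponential forgetting (momentum).  This mirrors the
incremental fine-tuning dynamics of a neural picker across feedback
rounds: the model adapts gradually toward the most recent training set
rather than jumping to it, which is what produces the round-over-round
improvement curves the feedback loop is built to exploit.

Filamentous specimens are traced rather than picked: a ridge skeleton is
extracted, split at crossings, and resampled into segment boxes at a
fixed box distance; short traces and segments near crossings are
discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template, peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import skeletonize
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .types import Box, FilamentTrace, Micrograph

__all__ = [
    "StateError",
    "TrainingError",
    "FilamentParams",
    "MatchResult",
    "PickerModel",
    "fbeta",
    "match_boxes",
    "train_picker",
    "pick",
    "optimize_threshold",
    "trace_filaments",
    "THRESHOLD_GRID",
]

_TEMPLATE_GRID = 32          # clustering resolution for training patches
_NMS_IOU = 0.3               # duplicate-suppression overlap
_CANDIDATE_NCC_FLOOR = 0.08  # raw correlation gate for candidate peaks

# The post-feedback threshold search evaluates exactly this grid.
THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)


class StateError(RuntimeError):
    """Raised when an untrained model is asked to operate."""


class TrainingError(ValueError):
    """Raised when a training set cannot produce a model."""


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def fbeta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta score; beta=2 weights recall twice as much as precision.

    Returns 0 for the degenerate precision = recall = 0 case.
    """
    if precision == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    denom = b2 * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * precision * recall / denom


@dataclass
class MatchResult:
    """One-to-one greedy matching between picks and reference boxes."""

    pairs: list[tuple[int, int]]
    unmatched_picks: list[int]
    unmatched_refs: list[int]

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fp(self) -> int:
        return len(self.unmatched_picks)

    @property
    def n_fn(self) -> int:
        return len(self.unmatched_refs)

    @property
    def precision(self) -> float:
        total = self.n_tp + self.n_fp
        return self.n_tp / total if total else 0.0

    @property
    def recall(self) -> float:
        total = self.n_tp + self.n_fn
        return self.n_tp / total if total else 0.0


def match_boxes(
    picked: Sequence[Box],
    reference: Sequence[Box],
    criterion: Optional[float] = None,
) -> MatchResult:
    """Greedily match picks to references by descending pick confidence.

    A pair matches iff the Euclidean center distance is at most
    ``criterion`` (default: half the pick's box size — the standard
    center-distance criterion of picker evaluation).  Matching is
    one-to-one; each pick takes the nearest still-unmatched reference.
    """
    order = sorted(range(len(picked)),
                   key=lambda i: (-picked[i].confidence, i))
    ref_xy = np.array([[r.center_x, r.center_y] for r in reference]
                      ) if reference else np.empty((0, 2))
    available = np.ones(len(reference), dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched_picks: list[int] = []
    for i in order:
        p = picked[i]
        max_d = criterion if criterion is not None else 0.5 * p.box_size
        if not available.any():
            unmatched_picks.append(i)
            continue
        d = np.hypot(ref_xy[:, 0] - p.center_x, ref_xy[:, 1] - p.center_y)
        d[~available] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_d:
            pairs.append((i, j))
            available[j] = False
        else:
            unmatched_picks.append(i)
    unmatched_refs = [j for j in range(len(reference)) if available[j]]
    return MatchResult(pairs, sorted(unmatched_picks), unmatched_refs)


# ---------------------------------------------------------------------------
# Picker model
# ---------------------------------------------------------------------------

def _normalize_patch(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(np.float64)
    p = p - p.mean()
    n = np.linalg.norm(p)
    return p / n if n > 0 else p


def _extract_patch(image: np.ndarray, cx: float, cy: float,
                   size: int) -> Optional[np.ndarray]:
    h, w = image.shape
    half = size // 2
    x0, y0 = int(round(cx)) - half, int(round(cy)) - half
    if x0 < 0 or y0 < 0 or x0 + size > w or y0 + size > h:
        return None
    return image[y0:y0 + size, x0:x0 + size]


def _zncc_at(image: np.ndarray, templates: np.ndarray,
             coords: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of each template at each (x, y).

    Matches the definition used by :func:`skimage.feature.match_template`
    so scores computed at isolated locations live on the same scale as
    the full correlation maps used during candidate detection.
    """
    k, size, _ = templates.shape
    norm_t = np.stack([_normalize_patch(t).ravel() for t in templates])
    out = np.zeros((len(coords), k))
    for i, (cx, cy) in enumerate(coords):
        patch = _extract_patch(image, cx, cy, size)
        if patch is None:
            continue
        out[i] = norm_t @ _normalize_patch(patch).ravel()
    return out


def _local_std_map(image: np.ndarray, size: int) -> np.ndarray:
    """Sliding-window standard deviation, normalized by the global SD.

    Particles raise the local contrast above the noise floor, so this
    complements correlation: noise maxima correlate moderately but show
    no contrast excess.
    """
    mean = ndimage.uniform_filter(image, size, mode="reflect")
    mean_sq = ndimage.uniform_filter(image * image, size, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    global_sd = image.std()
    return np.sqrt(var) / (global_sd if global_sd > 0 else 1.0)


def _features_at_coords(image: np.ndarray, templates: np.ndarray,
                        anchor_size: int,
                        coords: np.ndarray) -> np.ndarray:
    """Calibration features at (x, y): per-template ZNCC + local contrast."""
    ncc = _zncc_at(image, templates, coords)
    std_map = _local_std_map(image, anchor_size)
    h, w = image.shape
    ii = np.clip(np.round(coords[:, 1]).astype(int), 0, h - 1)
    jj = np.clip(np.round(coords[:, 0]).astype(int), 0, w - 1)
    return np.hstack([ncc, std_map[ii, jj][:, None]])


@dataclass
class PickerModel:
    """Trained picker state: templates + confidence calibration.

    ``prev`` points at the model of the previous feedback round; the
    confidence reported at a location is
    ``blend * own_score + (1 - blend) * prev_confidence``, evaluated
    recursively, so older rounds decay geometrically.
    """

    templates: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0)))
    coef: np.ndarray = field(default_factory=lambda: np.empty(0))
    intercept: float = 0.0
    anchor_size: int = 0
    round_tag: str = "1"
    blend: float = 0.5
    prev: Optional["PickerModel"] = None
    n_train_micrographs: int = 0
    n_train_boxes: int = 0

    @property
    def trained(self) -> bool:
        return self.templates.size > 0 and self.coef.size > 0

    # -- scoring ----------------------------------------------------------

    def _own_scores(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def confidence_at(self, image: np.ndarray,
                      coords: np.ndarray) -> np.ndarray:
        """Blended confidence at (x, y) locations on a micrograph image."""
        if not self.trained:
            raise StateError("picker model is not trained")
        if len(coords) == 0:
            return np.empty(0)
        own = self._own_scores(_features_at_coords(
            image, self.templates, self.anchor_size, coords))
        if self.prev is None:
            return own
        return self.blend * own + (1.0 - self.blend) * \
            self.prev.confidence_at(image, coords)

    def correlation_maps(self, image: np.ndarray) -> np.ndarray:
        """(k, h, w) normalized cross-correlation map per template."""
        return np.stack([
            match_template(image.astype(np.float64), t, pad_input=True)
            for t in self.templates
        ])

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Serialize the model chain to a single ``.npz`` file."""
        chain, m = [], self
        while m is not None:
            chain.append(m)
            m = m.prev
        payload = {"format_version": np.array([1]),
                   "n_levels": np.array([len(chain)])}
        for i, mm in enumerate(chain):
            payload[f"m{i}_templates"] = mm.templates
            payload[f"m{i}_coef"] = mm.coef
            payload[f"m{i}_meta"] = np.array(
                [mm.intercept, mm.anchor_size, mm.blend,
                 mm.n_train_micrographs, mm.n_train_boxes])
            payload[f"m{i}_tag"] = np.array([mm.round_tag])
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "PickerModel":
        with np.load(path, allow_pickle=False) as data:
            n = int(data["n_levels"][0])
            prev: Optional[PickerModel] = None
            for i in reversed(range(n)):
                meta = data[f"m{i}_meta"]
                prev = cls(
                    templates=data[f"m{i}_templates"],
                    coef=data[f"m{i}_coef"],
                    intercept=float(meta[0]),
                    anchor_size=int(meta[1]),
                    blend=float(meta[2]),
                    prev=prev,
                    n_train_micrographs=int(meta[3]),
                    n_train_boxes=int(meta[4]),
                    round_tag=str(data[f"m{i}_tag"][0]),
                )
        return prev  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_picker(
    labeled: Sequence[tuple[Micrograph, Sequence[Box]]],
    max_micrographs: int = 50,
    max_particles: int = 20000,
    seed: int = 0,
    anchor_size: Optional[int] = None,
    k_templates: int = 4,
    round_tag: str = "1",
    prev_model: Optional[PickerModel] = None,
    blend: float = 0.5,
) -> PickerModel:
    """Train a picker from labeled micrographs.

    At most ``max_micrographs`` micrographs and ``max_particles`` boxes
    are used, sampled without replacement under ``seed`` — training on a
    single data set saturates quickly, so larger training sets only cost
    time.  The anchor size defaults to the median labeled box size
    (i.e., the estimated particle diameter).
    """
    labeled = [(m, list(b)) for m, b in labeled if len(b) > 0]
    if not labeled or sum(len(b) for _, b in labeled) == 0:
        raise TrainingError("training requires at least one labeled box")
    rng = np.random.default_rng(seed)
    if len(labeled) > max_micrographs:
        idx = rng.choice(len(labeled), size=max_micrographs, replace=False)
        labeled = [labeled[i] for i in sorted(idx)]
    n_boxes = sum(len(b) for _, b in labeled)
    if n_boxes > max_particles:
        keep = np.zeros(n_boxes, dtype=bool)
        keep[rng.choice(n_boxes, size=max_particles, replace=False)] = True
        out, pos = [], 0
        for mic, boxes in labeled:
            sel = [b for j, b in enumerate(boxes) if keep[pos + j]]
            pos += len(boxes)
            out.append((mic, sel))
        labeled = [(m, b) for m, b in out if b]
        n_boxes = max_particles
    if anchor_size is None:
        anchor_size = int(np.median(
            [b.box_size for _, boxes in labeled for b in boxes]))
    anchor_size = max(9, anchor_size)
    # odd anchor keeps the correlation-map pixel grid aligned with
    # window extraction (an even template centers between pixels)
    anchor_size |= 1

    # -- templates: windowed, downsampled, normalized, clustered ----------
    patches = []
    for mic, boxes in labeled:
        for b in boxes:
            patch = _extract_patch(mic.image, b.center_x, b.center_y,
                                   anchor_size)
            if patch is not None:
                patches.append(resize(patch.astype(np.float64),
                                      (_TEMPLATE_GRID, _TEMPLATE_GRID),
                                      anti_aliasing=True))
    if not patches:
        raise TrainingError("no labeled box lies fully inside a micrograph")
    feats = np.stack([_normalize_patch(p).ravel() for p in patches])
    k = min(k_templates, len(patches))
    km = KMeans(n_clusters=k, random_state=int(rng.integers(2**31)),
                n_init=4).fit(feats)
    templates = np.stack([
        _normalize_patch(resize(c.reshape(_TEMPLATE_GRID, _TEMPLATE_GRID),
                                (anchor_size, anchor_size),
                                anti_aliasing=True))
        for c in km.cluster_centers_
    ])

    model = PickerModel(templates=templates, anchor_size=anchor_size,
                        round_tag=round_tag, blend=blend, prev=prev_model,
                        n_train_micrographs=len(labeled),
                        n_train_boxes=sum(len(b) for _, b in labeled))
    _fit_calibration(model, labeled, rng)
    return model


def _fit_calibration(model: PickerModel,
                     labeled: Sequence[tuple[Micrograph, Sequence[Box]]],
                     rng: np.random.Generator,
                     max_calibration_mics: int = 50) -> None:
    """Fit the logistic map from correlation features to confidence.

    Positives are the training locations.  Negatives are uniformly
    random locations plus "hard" candidate peaks far from any training
    box (contamination, other specimens, noise maxima).  Hard negatives
    are capped at the number of positives so that a sparsely labeled
    micrograph — where most true particles are unlabeled — cannot invert
    the calibration.
    """
    pos_feats, hard_feats, rand_feats = [], [], []
    subset = labeled[:max_calibration_mics]
    for mic, boxes in subset:
        image = mic.image.astype(np.float64)
        maps = model.correlation_maps(image)
        std_map = _local_std_map(image, model.anchor_size)
        max_map = maps.max(axis=0)
        h, w = image.shape

        def feats_at(ii, jj):
            return np.hstack([maps[:, ii, jj].T, std_map[ii, jj][:, None]])

        pos_xy = np.array([[b.center_x, b.center_y] for b in boxes])
        ii = np.clip(np.round(pos_xy[:, 1]).astype(int), 0, h - 1)
        jj = np.clip(np.round(pos_xy[:, 0]).astype(int), 0, w - 1)
        pos_feats.append(feats_at(ii, jj))
        peaks = peak_local_max(max_map,
                               min_distance=max(1, model.anchor_size // 3),
                               threshold_abs=_CANDIDATE_NCC_FLOOR)
        if len(peaks):
            d = np.hypot(peaks[:, 1][:, None] - pos_xy[None, :, 0],
                         peaks[:, 0][:, None] - pos_xy[None, :, 1])
            far = d.min(axis=1) > model.anchor_size
            hp = peaks[far]
            hard_feats.append(feats_at(hp[:, 0], hp[:, 1]))
        n_rand = max(4, len(boxes))
        rand_feats.append(feats_at(rng.integers(0, h, size=n_rand),
                                   rng.integers(0, w, size=n_rand)))
    pos = np.vstack(pos_feats)
    hard = np.vstack(hard_feats) if hard_feats else np.empty((0, pos.shape[1]))
    rand = np.vstack(rand_feats)
    if len(hard) > 2 * len(pos):
        hard = hard[rng.choice(len(hard), size=2 * len(pos), replace=False)]
    if len(rand) > len(pos):
        rand = rand[rng.choice(len(rand), size=len(pos), replace=False)]
    X = np.vstack([pos, hard, rand])
    y = np.concatenate([np.ones(len(pos)),
                        np.zeros(len(hard) + len(rand))])
    # light regularization: the feature scale is ~[0, 1] and the classes
    # are near-separable on clean data, so the calibration must be able
    # to saturate — an over-regularized fit leaves rejected locations
    # with mid-range confidences that a permissive threshold accepts
    clf = LogisticRegression(C=10.0, max_iter=500).fit(X, y)
    model.coef = clf.coef_[0].copy()
    model.intercept = float(clf.intercept_[0])


# ---------------------------------------------------------------------------
# Picking
# ---------------------------------------------------------------------------

def _nms(boxes: list[Box], iou_max: float = _NMS_IOU) -> list[Box]:
    """Suppress overlapping boxes, keeping the higher-confidence one."""
    order = sorted(range(len(boxes)),
                   key=lambda i: (-boxes[i].confidence, i))
    kept: list[Box] = []
    for i in order:
        b = boxes[i]
        ok = True
        for k in kept:
            s = 0.5 * (b.box_size + k.box_size)
            ix = max(0.0, s - abs(b.center_x - k.center_x))
            iy = max(0.0, s - abs(b.center_y - k.center_y))
            ix = min(ix, b.box_size, k.box_size)
            iy = min(iy, b.box_size, k.box_size)
            inter = ix * iy
            union = b.box_size**2 + k.box_size**2 - inter
            if union > 0 and inter / union > iou_max:
                ok = False
                break
        if ok:
            kept.append(b)
    return kept


def pick(micrograph: Micrograph, model: PickerModel,
         threshold: float) -> list[Box]:
    """Pick particles from one micrograph.

    Candidate locations are local maxima of the per-template correlation
    maps; the calibrated (blended) confidence is computed per candidate;
    duplicates are removed by non-maximum suppression (IoU > 0.3); every
    returned box has confidence >= ``threshold``.  Deterministic for
    fixed inputs.
    """
    if not model.trained:
        raise StateError("picker model is not trained")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    image = micrograph.image.astype(np.float64)
    maps = model.correlation_maps(image)
    max_map = maps.max(axis=0)
    peaks = peak_local_max(max_map,
                           min_distance=max(1, model.anchor_size // 3),
                           threshold_abs=_CANDIDATE_NCC_FLOOR)
    if len(peaks) == 0:
        return []
    std_map = _local_std_map(image, model.anchor_size)
    features = np.hstack([maps[:, peaks[:, 0], peaks[:, 1]].T,
                          std_map[peaks[:, 0], peaks[:, 1]][:, None]])
    own = model._own_scores(features)
    if model.prev is not None:
        coords = peaks[:, ::-1].astype(float)  # (x, y)
        prev_conf = model.prev.confidence_at(image, coords)
        conf = model.blend * own + (1.0 - model.blend) * prev_conf
    else:
        conf = own
    boxes = [
        Box(float(x), float(y), model.anchor_size, float(np.clip(c, 0, 1)),
            micrograph_id=micrograph.micrograph_id)
        for (y, x), c in zip(peaks, conf)
    ]
    kept = _nms(boxes)
    return [b for b in kept if b.confidence >= threshold]


# ---------------------------------------------------------------------------
# Threshold optimization
# ---------------------------------------------------------------------------

def optimize_threshold(
    model: PickerModel,
    micrographs: Sequence[Micrograph],
    reference_boxes: Sequence[Sequence[Box]],
    beta: float = 2.0,
    pick_fn: Callable[[Micrograph, PickerModel, float], list[Box]] = None,
) -> tuple[float, pd.DataFrame]:
    """Post-feedback picking-threshold grid search.

    A fixed subset of micrographs is picked once at threshold 0; the
    confidence threshold is then varied over the grid 0.00, 0.01, ...,
    1.00 and the threshold maximizing the micro-averaged F-beta score
    (counts pooled over the subset) is returned, ties broken toward the
    smallest threshold.  Also returns the full per-threshold table.
    """
    if len(micrographs) == 0:
        raise ValueError("threshold optimization requires a non-empty subset")
    if len(micrographs) != len(reference_boxes):
        raise ValueError("one reference box list per micrograph is required")
    if pick_fn is None:
        pick_fn = pick
    base_picks = [pick_fn(m, model, 0.0) for m in micrographs]
    rows = []
    for t in THRESHOLD_GRID:
        tp = fp = fn = 0
        for picks, refs in zip(base_picks, reference_boxes):
            filtered = [b for b in picks if b.confidence >= t]
            res = match_boxes(filtered, refs)
            tp += res.n_tp
            fp += res.n_fp
            fn += res.n_fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append((float(t), tp, fp, fn, precision, recall,
                     fbeta(precision, recall, beta)))
    table = pd.DataFrame(rows, columns=["threshold", "tp", "fp", "fn",
                                        "precision", "recall", "fbeta"])
    best = float(table.loc[table["fbeta"].idxmax(), "threshold"])
    return best, table


# ---------------------------------------------------------------------------
# Filament tracing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentParams:
    """Tracing parameters: ridge width, segment spacing, minimum length."""

    filament_width: int = 100
    box_distance: int = 25
    min_segments: int = 6

    def __post_init__(self) -> None:
        if self.box_distance <= 0:
            raise ValueError("box_distance must be positive")
        if self.min_segments < 1:
            raise ValueError("min_segments must be >= 1")
        if self.filament_width <= 0:
            raise ValueError("filament_width must be positive")


def _ordered_path(component: np.ndarray) -> list[tuple[int, int]]:
    """Order a branchless skeleton component into a pixel chain."""
    pixels = set(map(tuple, component))
    nbrs = {}
    for (r, c) in pixels:
        nbrs[(r, c)] = [(r + dr, c + dc)
                        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr or dc) and (r + dr, c + dc) in pixels]
    endpoints = sorted(p for p, n in nbrs.items() if len(n) <= 1)
    start = endpoints[0] if endpoints else min(pixels)
    path, visited = [start], {start}
    current = start
    while True:
        nxt = [p for p in nbrs[current] if p not in visited]
        if not nxt:
            break
        current = sorted(nxt)[0]
        path.append(current)
        visited.add(current)
    return path


def trace_filaments(
    micrograph: Micrograph,
    model: Optional[PickerModel],
    params: FilamentParams,
    threshold: float = 0.3,
) -> tuple[list[FilamentTrace], list[Box]]:
    """Trace filaments and emit segment boxes along each centerline.

    The ridge map is thresholded and skeletonized; skeleton branch
    points mark filament crossings and split the skeleton into
    branchless traces.  Each trace is resampled at ``box_distance``
    spacing along its arc length; traces with fewer than
    ``min_segments`` segments are discarded, and segments within one
    ``filament_width`` of a crossing point are removed.  Segment
    confidence is the normalized ridge strength at the segment center;
    the picking threshold applies to the trace-mean confidence.

    Returns the retained traces and the flat list of their segment boxes.
    """
    image = micrograph.image.astype(np.float64)
    sm = gaussian(image, sigma=2.0)
    lo, hi = float(sm.min()), float(sm.max())
    if hi - lo < 1e-9:
        return [], []
    thr = threshold_otsu(sm)
    mask = sm > thr
    skel = skeletonize(mask)
    if not skel.any():
        return [], []
    neighbor_count = ndimage.convolve(skel.astype(int), np.ones((3, 3)),
                                      mode="constant") - skel.astype(int)
    branch = skel & (neighbor_count > 2)
    crossings: list[tuple[float, float]] = []
    if branch.any():
        lbl, n = ndimage.label(branch, structure=np.ones((3, 3)))
        for (r, c) in ndimage.center_of_mass(branch, lbl, range(1, n + 1)):
            crossings.append((float(c), float(r)))  # (x, y)
        skel = skel & ~ndimage.binary_dilation(branch, np.ones((3, 3)))
    lbl, n_comp = ndimage.label(skel, structure=np.ones((3, 3)))
    denom = hi - thr if hi > thr else 1.0
    traces: list[FilamentTrace] = []
    fid = 0
    for comp_id in range(1, n_comp + 1):
        comp = np.argwhere(lbl == comp_id)
        if len(comp) < 2:
            continue
        path = np.array(_ordered_path(comp), dtype=float)  # (r, c)
        steps = np.hypot(np.diff(path[:, 0]), np.diff(path[:, 1]))
        arclen = np.concatenate([[0.0], np.cumsum(steps)])
        total = arclen[-1]
        n_seg = int(total // params.box_distance) + 1
        if n_seg < params.min_segments:
            continue
        s = np.arange(n_seg) * params.box_distance
        ys = np.interp(s, arclen, path[:, 0])
        xs = np.interp(s, arclen, path[:, 1])
        segments = []
        for k, (x, y) in enumerate(zip(xs, ys)):
            near_crossing = any(
                math.hypot(x - cx, y - cy) <= params.filament_width
                for cx, cy in crossings)
            if near_crossing:
                continue
            conf = float(np.clip(
                (sm[int(round(y)), int(round(x))] - thr) / denom, 0.0, 1.0))
            segments.append(Box(float(x), float(y), params.filament_width,
                                conf, micrograph_id=micrograph.micrograph_id,
                                filament_id=fid, segment_index=k))
        if not segments:
            continue
        trace = FilamentTrace(fid, tuple(segments),
                              tuple(zip(xs.tolist(), ys.tolist())))
        if trace.confidence >= threshold:
            traces.append(trace)
            fid += 1
    boxes = [s for t in traces for s in t.segments]
    return traces, boxes
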