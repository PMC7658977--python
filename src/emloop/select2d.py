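"""Good/bad 2D class-average selection.

A trainable binary selector over class averages, playing the role a
CNN-based selector plays in the full-scale pipeline: it decides which
classes (and hence which particles) continue into 3D processing, and —
crucially for subpopulation targeting — it can be trained so that sharp
classes of an *unwanted* species are labeled bad, steering the picker
re-training toward the wanted one.

The reference model is a regularized logistic classifier over five
hand-crafted class-average features that separate sharp structured
averages from noise and contamination averages on synthetic data:
contrast, edge energy, low/high radial power ratio, member count, and
intensity-centroid offset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .classify2d import ClassAverage

__all__ = [
    "SelectorModel",
    "LabeledClass",
    "SelectorStateError",
    "train_selector",
    "select",
    "class_features",
]

GOOD, BAD = "good", "bad"


class SelectorStateError(RuntimeError):
    """Raised when an untrained selector is asked to label classes."""


class SelectorTrainingError(ValueError):
    """Raised for degenerate training label sets."""


@dataclass(frozen=True)
class LabeledClass:
    """A class average with a manual (or truth-derived) good/bad label."""

    average: ClassAverage
    label: str

    def __post_init__(self) -> None:
        if self.label not in (GOOD, BAD):
            raise ValueError(f"label must be '{GOOD}' or '{BAD}'")


_N_PROFILE_BINS = 8


def class_features(avg: ClassAverage) -> np.ndarray:
    """Feature description of one class average.

    Five quality features (contrast, edge energy, low/high radial power
    ratio, member count, centroid offset) separate structured averages
    from noise and contamination; a normalized radial intensity profile
    adds shape discrimination, so the selector can also be trained to
    prefer one particle species over another (subpopulation targeting).
    """
    img = avg.mean_image.astype(np.float64)
    side = img.shape[0]
    contrast = img.std()
    gy, gx = np.gradient(img)
    edge_energy = np.hypot(gx, gy).mean()
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(xx - c, yy - c)
    low = spectrum[(r > 0) & (r <= side / 8)].sum()
    high = spectrum[(r > side / 8) & (r <= side / 2)].sum()
    power_ratio = low / (high + 1e-12)
    shifted = img - img.min()
    total = shifted.sum()
    if total > 0:
        cy, cx = ndimage.center_of_mass(shifted)
        centroid_offset = float(np.hypot(cx - c, cy - c)) / side
    else:
        centroid_offset = 0.0
    # shape block: radial mean profile, scale-normalized
    bins = np.minimum((r / (side / 2) * _N_PROFILE_BINS).astype(int),
                      _N_PROFILE_BINS - 1)
    profile = np.array([img[bins == b].mean() for b in range(_N_PROFILE_BINS)])
    norm = np.linalg.norm(profile)
    if norm > 0:
        profile = profile / norm
    return np.concatenate([[contrast, edge_energy, power_ratio,
                            float(avg.size), centroid_offset], profile])


@dataclass
class SelectorModel:
    """Trained selector: standardized logistic weights + label counts."""

    coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    n_good: int
    n_bad: int
    format_version: int = 1

    @property
    def trained(self) -> bool:
        return self.coef.size > 0

    def good_confidence(self, averages: Sequence[ClassAverage]) -> np.ndarray:
        if not self.trained:
            raise SelectorStateError("selector model is not trained")
        X = np.stack([class_features(a) for a in averages])
        X = (X - self.feature_mean) / self.feature_std
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format_version": self.format_version,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "n_good": self.n_good,
            "n_bad": self.n_bad,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SelectorModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coef=np.array(payload["coef"]),
            intercept=float(payload["intercept"]),
            feature_mean=np.array(payload["feature_mean"]),
            feature_std=np.array(payload["feature_std"]),
            n_good=int(payload["n_good"]),
            n_bad=int(payload["n_bad"]),
            format_version=int(payload["format_version"]),
        )


def train_selector(labeled: Sequence[LabeledClass],
                   seed: int = 0) -> SelectorModel:
    """Train the selector from labeled class averages.

    Requires at least 5 examples per label; below 20 per label a warning
    (not an error) is emitted — around 40 roughly balanced examples is
    the point where selection becomes reliable.
    """
    n_good = sum(1 for lc in labeled if lc.label == GOOD)
    n_bad = len(labeled) - n_good
    if n_good == 0 or n_bad == 0:
        raise SelectorTrainingError(
            "training requires both good and bad examples")
    if n_good < 5 or n_bad < 5:
        raise SelectorTrainingError(
            f"need >= 5 examples per label (got {n_good} good, {n_bad} bad)")
    if n_good < 20 or n_bad < 20:
        warnings.warn(
            f"selector trained on few examples ({n_good} good, {n_bad} bad); "
            "about 20 per label is recommended", UserWarning, stacklevel=2)
    X = np.stack([class_features(lc.average) for lc in labeled])
    y = np.array([1.0 if lc.label == GOOD else 0.0 for lc in labeled])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    clf = LogisticRegression(C=1.0, max_iter=1000,
                             random_state=seed).fit(Xs, y)
    return SelectorModel(coef=clf.coef_[0].copy(),
                         intercept=float(clf.intercept_[0]),
                         feature_mean=mean, feature_std=std,
                         n_good=n_good, n_bad=n_bad)


def select(
    averages: Sequence[ClassAverage],
    model: SelectorModel,
    confidence_threshold: float = 0.1,
) -> list[tuple[str, float]]:
    """Label each class average good or bad.

    A class is good iff its good-confidence is at least
    ``confidence_threshold``; the permissive default of 0.1 accepts any
    class the model does not actively reject.  Deterministic.
    """
    if not averages:
        return []
    conf = model.good_confidence(averages)
    return [(GOOD if c >= confidence_threshold else BAD, float(c))
            for c in conf]
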