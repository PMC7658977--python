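"""Reference study protocols for the feedback loop.

Two end-to-end experiments exercise the loop the way its full-scale
counterparts are exercised on real data:

* **Recovery** — a single-specimen dataset whose round-1 picks are 90%
  randomized, simulating a picking model with no usable knowledge of
  the specimen.  Success means the re-trained picker approaches the
  quality of a picker trained directly on ground truth.

* **Steering** — a two-conformation mixture (81% / 19%) in which the
  selector is trained to accept only the rare species, so the loop
  teaches the picker to reject the abundant one.  Success means the
  minority's share of picks grows over the rounds while its absolute
  recall holds steady.

Both protocols also build their class selector the way practitioners
do: by labeling an initial set of 2D class averages (here labeled from
ground truth instead of by eye), including class averages of randomized
picks so the selector has seen representative junk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import classify2d, picking, select2d, simdata
from .feedback import FeedbackConfig, FeedbackResult, RoundReport, evaluate_models, run_feedback
from .picking import PickerModel, fbeta, match_boxes, pick, train_picker
from .select2d import LabeledClass, SelectorModel, train_selector
from .simdata import GroundTruth, SimConfig, corrupt_picks
from .types import Box, Micrograph

__all__ = [
    "truth_class_of_box",
    "build_truth_selector",
    "heldout_scores",
    "RecoveryResult",
    "SteeringResult",
    "recovery_experiment",
    "steering_experiment",
]

# matching radius (px) used when attributing a pick to a truth particle
_ATTRIBUTION_RADIUS = 12.0


def truth_class_of_box(truth: GroundTruth, box: Box,
                       radius: float = _ATTRIBUTION_RADIUS) -> Optional[str]:
    """Class id of the truth particle a box sits on, or None for junk."""
    entry = truth[box.micrograph_id]
    best, best_d2 = None, radius * radius
    for x, y, cid in entry.particles:
        d2 = (box.center_x - x) ** 2 + (box.center_y - y) ** 2
        if d2 <= best_d2:
            best_d2, best = d2, cid
    return best


def _labeled_classes_from_picks(
    mics: Sequence[Micrograph],
    truth: GroundTruth,
    model: PickerModel,
    good_classes: Sequence[str],
    box_size: int,
    class_size_range: tuple[int, int],
    seed: int,
    corrupt_fraction: float = 0.0,
    only_bad: bool = False,
) -> list[LabeledClass]:
    parts: list[classify2d.ParticleImage] = []
    for i, mic in enumerate(mics):
        picks = pick(mic, model, 0.1)
        if corrupt_fraction > 0:
            picks = corrupt_picks(picks, corrupt_fraction, mic.image.shape,
                                  seed=seed * 1000 + i)
        parts += classify2d.window_particles(mic, picks, box_size)
    result = classify2d.classify(parts, class_size_range, seed=seed)
    labeled = []
    for cls in result.classes:
        member_classes = [truth_class_of_box(truth, parts[i].box)
                          for i in cls.member_ids]
        frac_target = np.mean([c in good_classes for c in member_classes])
        label = select2d.GOOD if frac_target >= 0.5 else select2d.BAD
        if only_bad and label == select2d.GOOD:
            continue
        labeled.append(LabeledClass(cls, label))
    return labeled


def build_truth_selector(
    mics: Sequence[Micrograph],
    truth: GroundTruth,
    model: PickerModel,
    good_classes: Sequence[str],
    box_size: int = 32,
    class_size_range: tuple[int, int] = (20, 40),
    seed: int = 0,
    corrupt_fraction: float = 0.9,
    corrupt_only_bad: bool = False,
) -> SelectorModel:
    """Train a selector from truth-labeled 2D class averages.

    Mirrors the practical workflow of labeling the first produced class
    averages: classes of clean picks provide good (target-species) and
    bad (other-species) examples, and classes built from partially
    randomized picks contribute representative junk — the selector must
    have seen the kind of averages a degraded picking model produces,
    or it cannot police the loop.
    """
    labeled = []
    if corrupt_fraction > 0:
        labeled += _labeled_classes_from_picks(
            mics, truth, model, good_classes, box_size, class_size_range,
            seed, corrupt_fraction=corrupt_fraction,
            only_bad=corrupt_only_bad)
    labeled += _labeled_classes_from_picks(
        mics, truth, model, good_classes, box_size, class_size_range,
        seed + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return train_selector(labeled, seed=seed)


def heldout_scores(
    model: PickerModel,
    threshold: float,
    mics: Sequence[Micrograph],
    truth: GroundTruth,
    box_size: int,
) -> tuple[float, float, float]:
    """Pooled (precision, recall, F2) of a model on held-out micrographs."""
    tp = fp = fn = 0
    for mic in mics:
        refs = truth[mic.micrograph_id].boxes(box_size)
        res = match_boxes(pick(mic, model, threshold), refs)
        tp += res.n_tp
        fp += res.n_fp
        fn += res.n_fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, fbeta(precision, recall)


# ---------------------------------------------------------------------------
# Recovery protocol
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    feedback: FeedbackResult
    f2_feedback: float
    f2_supervised: float
    precision_feedback: float
    recall_feedback: float

    @property
    def f2_ratio(self) -> float:
        return self.f2_feedback / self.f2_supervised if self.f2_supervised else 0.0


def recovery_experiment(
    seed: int = 2,
    n_micrographs: int = 70,
    n_loop: int = 60,
    particles_per_micrograph: int = 25,
    diameter: int = 24,
    box_size: int = 32,
    corrupt_fraction: float = 0.9,
) -> RecoveryResult:
    """Feedback recovery from 90%-randomized round-1 picks.

    A one-class dataset is picked by a decently initialized model whose
    round-1 picks are then corrupted; after five re-training rounds the
    final model (at its grid-searched threshold) is compared on held-out
    micrographs against a picker trained directly on the full ground
    truth (evaluated at the permissive default threshold).
    """
    specs = simdata.default_class_specs(abundances=(1.0,), kinds=("disc",),
                                        diameter=diameter)
    cfg = SimConfig(seed=seed, particles_per_micrograph=particles_per_micrograph)
    movies, truth = simdata.generate_dataset(cfg, n_micrographs, specs)
    mics = [Micrograph(m.frames[0], micrograph_id=m.micrograph_id)
            for m in movies]
    loop_mics, held = mics[:n_loop], mics[n_loop:]
    init = train_picker(
        [(m, truth[m.micrograph_id].boxes(diameter)) for m in loop_mics[:10]],
        seed=0)
    selector = build_truth_selector(loop_mics[:30], truth, init,
                                    good_classes=("class_disc",),
                                    box_size=box_size, seed=11)
    config = FeedbackConfig(batch_size=2000, class_size_range=(20, 40),
                            extract_box_size=box_size,
                            round1_corrupt_fraction=corrupt_fraction,
                            seed=seed + 1)
    result = run_feedback(loop_mics, init, selector, config)
    supervised = train_picker(
        [(m, truth[m.micrograph_id].boxes(diameter)) for m in loop_mics],
        seed=0)
    p_fb, r_fb, f2_fb = heldout_scores(result.final_model,
                                       result.final_threshold,
                                       held, truth, diameter)
    _, _, f2_sup = heldout_scores(supervised, 0.1, held, truth, diameter)
    return RecoveryResult(result, f2_fb, f2_sup, p_fb, r_fb)


# ---------------------------------------------------------------------------
# Steering protocol
# ---------------------------------------------------------------------------

@dataclass
class SteeringResult:
    feedback: FeedbackResult
    minority_shares: list[float]        # one per round model, rounds 1..6
    evaluation: list[RoundReport]       # fixed-subset table rows
    minority_recalls: list[float]       # minority picks recovered per round

    @property
    def share_gain(self) -> float:
        """Round-6 minority share over round-2 minority share."""
        if len(self.minority_shares) < 2 or self.minority_shares[1] == 0:
            return float("inf")
        return self.minority_shares[-1] / self.minority_shares[1]


def steering_experiment(
    seed: int = 4,
    n_micrographs: int = 60,
    particles_per_micrograph: int = 25,
    abundances: tuple[float, float] = (0.81, 0.19),
    diameter: int = 24,
    box_size: int = 32,
    n_eval_mics: int = 20,
) -> SteeringResult:
    """Subpopulation targeting on a two-conformation mixture.

    The selector accepts only minority-species classes; the loop then
    re-trains the picker on minority particles alone.  Per-round models
    re-pick a fixed subset to measure the minority's share among picks
    attributable to a truth particle, the minority's absolute recall,
    and the per-round evaluation table.
    """
    specs = simdata.default_class_specs(abundances=abundances,
                                        kinds=("disc", "ring"),
                                        diameter=diameter)
    cfg = SimConfig(seed=seed, particles_per_micrograph=particles_per_micrograph)
    movies, truth = simdata.generate_dataset(cfg, n_micrographs, specs)
    mics = [Micrograph(m.frames[0], micrograph_id=m.micrograph_id)
            for m in movies]
    init = train_picker(
        [(m, truth[m.micrograph_id].boxes(diameter)) for m in mics[:10]],
        seed=0)
    selector = build_truth_selector(mics, truth, init,
                                    good_classes=("class_ring",),
                                    box_size=box_size,
                                    class_size_range=(15, 25),
                                    seed=7, corrupt_fraction=1.0,
                                    corrupt_only_bad=True)
    config = FeedbackConfig(batch_size=2000, class_size_range=(20, 40),
                            extract_box_size=box_size, seed=seed + 1)
    result = run_feedback(mics, init, selector, config)

    subset = mics[:n_eval_mics]
    shares, recalls = [], []
    n_minority_truth = sum(
        sum(1 for *_xy, cid in truth[m.micrograph_id].particles
            if cid == "class_ring") for m in subset)
    for model in result.models:
        n_min = n_attr = 0
        minority_hit: set[tuple[str, int]] = set()
        for mic in subset:
            entry = truth[mic.micrograph_id]
            for b in pick(mic, model, config.feedback_pick_threshold):
                cid = truth_class_of_box(truth, b)
                if cid is None:
                    continue
                n_attr += 1
                if cid == "class_ring":
                    n_min += 1
                    for pi, (x, y, c) in enumerate(entry.particles):
                        if (c == "class_ring" and
                                (b.center_x - x) ** 2 + (b.center_y - y) ** 2
                                <= _ATTRIBUTION_RADIUS ** 2):
                            minority_hit.add((mic.micrograph_id, pi))
        shares.append(n_min / n_attr if n_attr else 0.0)
        recalls.append(len(minority_hit) / n_minority_truth
                       if n_minority_truth else 0.0)
    evaluation = evaluate_models(subset, result.models,
                                 result.final_threshold, selector, config)
    return SteeringResult(result, shares, evaluation, recalls)
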