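"""The picker re-training feedback loop and its evaluation.

One feedback round picks every available micrograph at a permissive
threshold (0.1 by default), accumulates the picks into classification
batches, runs capacity-constrained 2D classification, labels the class
averages good or bad with the selector, and re-trains the picker on the
particles that landed in good classes (at most 50 micrographs and
20,000 particles).  The loop iterates a fixed five times — enough for
convergence — and then finalizes the picking threshold, either by an
F2-maximizing grid search or at a fixed value (filaments).

Per-round statistics mirror the fixed-subset evaluation tables of
feedback-loop experiments: good classes, good particles, picks per
micrograph, and the relative amount of good picks.  Round 1 is the
initial model; rounds 2..6 are the models produced by the five
re-trainings; the final thresholded run is labeled "6 + T x.xx".

3D processing itself is out of scope; the loop emits trigger events —
one ab initio trigger when 200 good classes have accumulated, one
refinement trigger per 40,000 accumulated good particles — that
external adapters may consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import classify2d, picking, select2d
from .classify2d import BatchAccumulator, ParticleImage, accumulate, flush_remainder
from .formats_io import write_mrc
from .picking import PickerModel, optimize_threshold, pick, train_picker
from .select2d import SelectorModel
from .simdata import corrupt_picks
from .types import Box, Micrograph

__all__ = [
    "FeedbackConfig",
    "RoundReport",
    "FeedbackState",
    "FeedbackResult",
    "FeedbackHalted",
    "TriggerEvent",
    "run_feedback",
    "build_training_set",
    "relative_good_stat",
    "evaluate_models",
    "check_triggers",
    "assemble_stack",
]


class FeedbackHalted(RuntimeError):
    """A round produced zero good particles; silent continuation would
    re-train the picker on nothing and poison every later round, so the
    loop halts and surfaces its diagnostic state instead."""

    def __init__(self, message: str, state: "FeedbackState"):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class FeedbackConfig:
    """All tunables of the loop, at their standard defaults."""

    n_rounds: int = 5
    batch_size: int = 20000
    train_mics_max: int = 50
    train_particles_max: int = 20000
    feedback_pick_threshold: float = 0.1
    selector_threshold: float = 0.1
    final_threshold_mode: str = "grid_search"   # or "fixed"
    fixed_final_threshold: float = 0.3
    ab_initio_min_good_classes: int = 200
    refine_batch_particles: int = 40000
    class_size_range: tuple[int, int] = (60, 100)
    extract_box_size: Optional[int] = None      # default: picker anchor size
    round1_corrupt_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        for t in (self.feedback_pick_threshold, self.selector_threshold,
                  self.fixed_final_threshold):
            if not (0.0 <= t <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")
        if min(self.batch_size, self.train_mics_max,
               self.train_particles_max, self.ab_initio_min_good_classes,
               self.refine_batch_particles) < 1:
            raise ValueError("all counts must be positive")
        if self.final_threshold_mode not in ("grid_search", "fixed"):
            raise ValueError("final_threshold_mode must be "
                             "'grid_search' or 'fixed'")


@dataclass
class RoundReport:
    """Per-round evaluation row (good classes, good particles, picks)."""

    round_label: str
    good_classes: int
    good_particles: int
    picks_per_mic: float
    good_picks_per_mic: float
    relative_good: float

    def as_dict(self) -> dict:
        return dict(round_label=self.round_label,
                    good_classes=self.good_classes,
                    good_particles=self.good_particles,
                    picks_per_mic=self.picks_per_mic,
                    good_picks_per_mic=self.good_picks_per_mic,
                    relative_good=self.relative_good)


@dataclass
class TriggerEvent:
    """A downstream 3D processing trigger."""

    kind: str                       # "ab_initio" | "refine_batch"
    count: int                      # good-class count or batch index
    stack_ref: Optional[str] = None


@dataclass
class FeedbackState:
    """Mutable loop state: counters are cumulative across rounds."""

    current_model: Optional[PickerModel] = None
    round_index: int = 1
    cumulative_good_classes: int = 0
    cumulative_good_particles: int = 0
    ab_initio_fired: bool = False
    refine_batches_fired: int = 0
    history: list[RoundReport] = field(default_factory=list)
    events: list[TriggerEvent] = field(default_factory=list)


@dataclass
class FeedbackResult:
    final_model: PickerModel
    final_threshold: Optional[float]
    history: list[RoundReport]
    models: list[PickerModel]       # round 1 .. round n_rounds+1
    state: FeedbackState
    threshold_table: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def relative_good_stat(good_particles: int, picks_per_mic: float,
                       n_mics: int) -> float:
    """Relative amount of good picks on a fixed subset.

    ``good_particles / (picks_per_mic * n_mics)``, rounded half-up to
    two decimals — the bold per-round quality column of the evaluation
    tables.
    """
    denom = picks_per_mic * n_mics
    if denom <= 0:
        raise ValueError("picks_per_mic * n_mics must be positive")
    value = Decimal(good_particles) / Decimal(str(denom))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

def build_training_set(
    good_boxes_by_mic: dict[str, list[Box]],
    max_mics: int = 50,
    max_particles: int = 20000,
    seed: int = 0,
) -> dict[str, list[Box]]:
    """Sample the re-training subset from the good-class picks.

    Micrographs holding at least one good box are sampled uniformly
    without replacement up to ``max_mics``; the particle cap is applied
    afterwards by dropping whole micrographs, last-sampled first, until
    the total is within ``max_particles``.
    """
    eligible = sorted(m for m, boxes in good_boxes_by_mic.items() if boxes)
    if not eligible:
        raise ValueError("training-set assembly requires at least one good box")
    rng = np.random.default_rng(seed)
    order = [eligible[i] for i in
             rng.permutation(len(eligible))[:max_mics]]
    total = 0
    kept: list[str] = []
    for mic_id in order:
        kept.append(mic_id)
        total += len(good_boxes_by_mic[mic_id])
    while kept and total > max_particles:
        total -= len(good_boxes_by_mic[kept.pop()])
    return {m: list(good_boxes_by_mic[m]) for m in kept}


# ---------------------------------------------------------------------------
# One processing pass (shared by the loop and the evaluation)
# ---------------------------------------------------------------------------

def _process_round(
    micrographs: Sequence[Micrograph],
    model: PickerModel,
    selector: SelectorModel,
    config: FeedbackConfig,
    threshold: float,
    round_label: str,
    seed: int,
    corrupt_fraction: float = 0.0,
) -> tuple[RoundReport, dict[str, list[Box]], int]:
    """Pick -> window -> accumulate -> classify -> select on a mic set.

    Returns the round report, the good boxes grouped by micrograph, and
    the number of classified batches.
    """
    box_size = config.extract_box_size or model.anchor_size
    picks_by_mic: dict[str, list[Box]] = {}
    for i, mic in enumerate(micrographs):
        picks = pick(mic, model, threshold)
        if corrupt_fraction > 0:
            picks = corrupt_picks(picks, corrupt_fraction,
                                  (mic.image.shape[0], mic.image.shape[1]),
                                  seed=seed * 100003 + i)
        picks_by_mic[mic.micrograph_id] = picks
    total_picks = sum(len(p) for p in picks_by_mic.values())

    acc = BatchAccumulator(batch_size=config.batch_size)
    batches: list[list[ParticleImage]] = []
    for mic in micrographs:
        particles = classify2d.window_particles(
            mic, picks_by_mic[mic.micrograph_id], box_size)
        _, flushed = accumulate(acc, particles)
        batches.extend(flushed)
    batches.extend(flush_remainder(acc))

    good_classes = 0
    good_boxes_by_mic: dict[str, list[Box]] = {}
    good_particles = 0
    for bi, batch in enumerate(batches):
        if not batch:
            continue
        result = classify2d.classify(batch, config.class_size_range,
                                     seed=seed + bi)
        labels = select2d.select(result.classes, selector,
                                 config.selector_threshold)
        for cls, (label, _conf) in zip(result.classes, labels):
            if label != select2d.GOOD:
                continue
            good_classes += 1
            good_particles += cls.size
            shifts = cls.member_shifts or [(0, 0)] * cls.size
            for pid, (sx, sy) in zip(cls.member_ids, shifts):
                b = batch[pid].box
                # the alignment shift re-centers the pick on the particle
                b = b.with_center(b.center_x - sx, b.center_y - sy)
                good_boxes_by_mic.setdefault(b.micrograph_id, []).append(b)
    # re-centered duplicates of one particle collapse onto ~the same
    # coordinate; keep one box per particle (duplicate removal after
    # alignment-offset re-centering, as done before re-extraction)
    for mid, boxes in good_boxes_by_mic.items():
        kept: list[Box] = []
        min_sep2 = (0.5 * (config.extract_box_size or model.anchor_size)) ** 2
        for b in sorted(boxes, key=lambda b: -b.confidence):
            if all((b.center_x - k.center_x) ** 2 +
                   (b.center_y - k.center_y) ** 2 >= min_sep2 for k in kept):
                kept.append(b)
        good_boxes_by_mic[mid] = kept

    n_mics = len(micrographs)
    picks_per_mic = total_picks / n_mics if n_mics else 0.0
    good_per_mic = good_particles / n_mics if n_mics else 0.0
    relative = (relative_good_stat(good_particles, picks_per_mic, n_mics)
                if total_picks > 0 else 0.0)
    report = RoundReport(round_label, good_classes, good_particles,
                         picks_per_mic, good_per_mic, relative)
    return report, good_boxes_by_mic, len(batches)


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------

def run_feedback(
    micrographs: Sequence[Micrograph],
    initial_model: PickerModel,
    selector: SelectorModel,
    config: FeedbackConfig = FeedbackConfig(),
) -> FeedbackResult:
    """Run the full feedback loop on a set of micrographs.

    Executes exactly ``config.n_rounds`` re-training cycles, then
    finalizes the picking threshold.  With
    ``config.round1_corrupt_fraction`` set, that fraction of the round-1
    picks is replaced by random coordinates before classification —
    the stress protocol that simulates a picker with no usable prior
    knowledge of the specimen.  Fully deterministic per config seed.

    Raises :class:`FeedbackHalted` if a round yields zero good
    particles.
    """
    state = FeedbackState(current_model=initial_model)
    models = [initial_model]
    model = initial_model
    if config.n_rounds == 0:
        return FeedbackResult(initial_model, None, [], models, state)
    for r in range(1, config.n_rounds + 1):
        state.round_index = r
        state.current_model = model
        report, good_boxes_by_mic, _ = _process_round(
            micrographs, model, selector, config,
            threshold=config.feedback_pick_threshold,
            round_label=str(r), seed=config.seed + 7919 * r,
            corrupt_fraction=(config.round1_corrupt_fraction
                              if r == 1 else 0.0),
        )
        state.history.append(report)
        state.events.extend(check_triggers(
            state, report.good_classes, report.good_particles,
            config.ab_initio_min_good_classes,
            config.refine_batch_particles))
        if report.good_particles == 0:
            raise FeedbackHalted(
                f"round {r} produced zero good particles; re-training "
                "would be degenerate — check the selector model and the "
                "picking threshold", state)
        training = build_training_set(
            good_boxes_by_mic, config.train_mics_max,
            config.train_particles_max, seed=config.seed + 104729 * r)
        mic_by_id = {m.micrograph_id: m for m in micrographs}
        labeled = [(mic_by_id[mid], boxes)
                   for mid, boxes in sorted(training.items())]
        model = train_picker(
            labeled, config.train_mics_max, config.train_particles_max,
            seed=config.seed + 15485863 * r,
            anchor_size=initial_model.anchor_size,
            round_tag=str(r + 1), prev_model=model)
        models.append(model)
    state.round_index = config.n_rounds + 1
    state.current_model = model

    threshold_table = None
    if config.final_threshold_mode == "fixed":
        final_threshold = config.fixed_final_threshold
    else:
        # the good picks of the final round act as the reference set
        final_report, final_good, _ = _process_round(
            micrographs, model, selector, config,
            threshold=config.feedback_pick_threshold,
            round_label="final", seed=config.seed + 7919 * (config.n_rounds + 1))
        refs = [final_good.get(m.micrograph_id, []) for m in micrographs]
        final_threshold, threshold_table = optimize_threshold(
            model, micrographs, refs)
    return FeedbackResult(model, final_threshold, state.history, models,
                          state, threshold_table)


# ---------------------------------------------------------------------------
# Fixed-subset evaluation (the per-round tables)
# ---------------------------------------------------------------------------

def evaluate_models(
    fixed_subset: Sequence[Micrograph],
    models: Sequence[PickerModel],
    final_threshold: float,
    selector: SelectorModel,
    config: FeedbackConfig = FeedbackConfig(),
) -> list[RoundReport]:
    """Re-pick a fixed micrograph subset with every round's model.

    Rounds 1..n run at the permissive feedback threshold; one extra run
    uses the final model at the optimized threshold and is labeled
    ``"n + T x.xx"``.  Each run proceeds through classification and
    selection so the reports are comparable across rounds.
    """
    reports: list[RoundReport] = []
    for i, model in enumerate(models, start=1):
        report, _, _ = _process_round(
            fixed_subset, model, selector, config,
            threshold=config.feedback_pick_threshold,
            round_label=str(i), seed=config.seed + 31 * i)
        reports.append(report)
    label = f"{len(models)} + T {final_threshold:.2f}"
    report, _, _ = _process_round(
        fixed_subset, models[-1], selector, config,
        threshold=final_threshold, round_label=label,
        seed=config.seed + 31 * (len(models) + 1))
    reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# Triggers and stack assembly
# ---------------------------------------------------------------------------

def check_triggers(state: FeedbackState, new_good_classes: int,
                   new_good_particles: int,
                   min_good_classes: int = 200,
                   refine_batch_particles: int = 40000) -> list[TriggerEvent]:
    """Update cumulative counters and emit any due 3D triggers.

    The ab initio trigger fires once, when the cumulative good-class
    count first reaches ``min_good_classes`` (200 by default); one
    refinement trigger fires per completed block of
    ``refine_batch_particles`` good particles (40,000 by default).
    """
    if new_good_classes < 0 or new_good_particles < 0:
        raise ValueError("trigger counters must be non-negative")
    events: list[TriggerEvent] = []
    state.cumulative_good_classes += new_good_classes
    state.cumulative_good_particles += new_good_particles
    if (not state.ab_initio_fired
            and state.cumulative_good_classes >= min_good_classes):
        state.ab_initio_fired = True
        events.append(TriggerEvent("ab_initio",
                                   state.cumulative_good_classes))
    due = state.cumulative_good_particles // refine_batch_particles
    while state.refine_batches_fired < due:
        state.refine_batches_fired += 1
        events.append(TriggerEvent("refine_batch",
                                   state.refine_batches_fired))
    return events


def assemble_stack(
    particles: Sequence[ParticleImage],
    class_ids: Sequence[Union[int, str]],
    out_stem: Union[str, Path],
    pixel_size: float = 1.0,
) -> tuple[Path, Path]:
    """Write the good-particle stack plus its provenance manifest.

    Produces ``<stem>.mrcs`` (one section per particle, stable order)
    and ``<stem>.tsv`` with columns particle_id, micrograph_id,
    center_x, center_y, class_id.  Duplicate provenance entries are
    rejected.
    """
    if len(particles) == 0:
        raise ValueError("stack assembly requires at least one particle")
    if len(particles) != len(class_ids):
        raise ValueError("one class id per particle is required")
    seen = set()
    rows = []
    for i, (p, cid) in enumerate(zip(particles, class_ids)):
        key = (p.box.micrograph_id, p.box.center_x, p.box.center_y)
        if key in seen:
            raise ValueError(f"duplicate provenance entry: {key}")
        seen.add(key)
        rows.append((i, p.box.micrograph_id, p.box.center_x,
                     p.box.center_y, cid))
    out_stem = Path(out_stem)
    stack_path = out_stem.with_suffix(".mrcs")
    manifest_path = out_stem.with_suffix(".tsv")
    stack = np.stack([p.patch for p in particles]).astype(np.float32)
    write_mrc(stack, pixel_size, stack_path)
    pd.DataFrame(rows, columns=["particle_id", "micrograph_id", "center_x",
                                "center_y", "class_id"]
                 ).to_csv(manifest_path, sep="\t", index=False)
    return stack_path, manifest_path
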