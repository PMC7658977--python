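"""Stage/queue orchestration, drift alignment, and quality gates.

Every processing stage owns a first-in-first-out queue and a worker
pool; a worker takes a task, runs the stage handler, and forwards the
result to the downstream stage's queue.  Stages declared as GPU
resources additionally acquire a slot token from a shared pool before
running, so the number of concurrent GPU tasks never exceeds the
configured capacity — the desk-scale version of avoiding GPU memory
oversubscription.  Failed tasks are retried twice, then quarantined
with the error recorded; a handler exception never aborts the session.

Drift alignment is a compact stand-in for beam-induced motion
correction: integer inter-frame shifts estimated by cross-correlation
against a running average, a shift-compensated frame sum, and the mean
shift per frame as the reported metric.
"""

from __future__ import annotations

import json
import queue
import threading
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import Micrograph, MovieStack

__all__ = [
    "Task",
    "StageSpec",
    "GpuSlotPool",
    "RangeRule",
    "PipelineReport",
    "run_pipeline",
    "align_frames",
    "flag_out_of_range",
]


@dataclass
class Task:
    """One unit of work traveling through the stage graph."""

    task_id: int
    payload: Any
    stage: str = ""
    attempts: int = 0
    status: str = "pending"     # pending|running|done|failed|quarantined
    error: Optional[str] = None


@dataclass(frozen=True)
class StageSpec:
    """A stage: name, resource class, handler, and downstream stage."""

    name: str
    handler: Callable[[Any], Any]
    resource: str = "cpu"           # "cpu" | "gpu"
    downstream: Optional[str] = None

    def __post_init__(self) -> None:
        if self.resource not in ("cpu", "gpu"):
            raise ValueError("resource must be 'cpu' or 'gpu'")


class GpuSlotPool:
    """Token pool limiting concurrent GPU tasks; records peak usage."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("gpu capacity must be >= 1")
        self.capacity = capacity
        self._sem = threading.Semaphore(capacity)
        self._lock = threading.Lock()
        self._holders = 0
        self.max_observed = 0

    def __enter__(self) -> "GpuSlotPool":
        self._sem.acquire()
        with self._lock:
            self._holders += 1
            self.max_observed = max(self.max_observed, self._holders)
        return self

    def __exit__(self, *exc) -> None:
        with self._lock:
            self._holders -= 1
        self._sem.release()


@dataclass
class PipelineReport:
    """Outcome of a pipeline run."""

    completed: list[Task] = field(default_factory=list)
    quarantined: list[Task] = field(default_factory=list)
    max_gpu_concurrency: int = 0
    results: dict[int, Any] = field(default_factory=dict)


def _validate_stage_graph(stages: Sequence[StageSpec]) -> None:
    if not stages:
        raise ValueError("at least one stage is required")
    by_name = {s.name: s for s in stages}
    if len(by_name) != len(stages):
        raise ValueError("stage names must be unique")
    # acyclicity: following downstream links must terminate
    for s in stages:
        seen, cur = {s.name}, s.downstream
        while cur is not None:
            if cur not in by_name:
                raise ValueError(f"unknown downstream stage {cur!r}")
            if cur in seen:
                raise ValueError("stage graph must be acyclic")
            seen.add(cur)
            cur = by_name[cur].downstream


def run_pipeline(
    stages: Sequence[StageSpec],
    inputs: Sequence[Any],
    gpu_capacity: int = 2,
    workers_per_stage: int = 2,
    max_retries: int = 2,
    quarantine_dir: Optional[Union[str, Path]] = None,
) -> PipelineReport:
    """Run every input through the stage chain.

    Each input is processed by each stage exactly once, in stage order;
    GPU stages never exceed ``gpu_capacity`` concurrent executions.
    A failing task is retried up to ``max_retries`` times and then
    quarantined with its error; when ``quarantine_dir`` is given, a
    JSON error record per quarantined task is written under
    ``<quarantine_dir>/FAILED/``.
    """
    stages = list(stages)
    _validate_stage_graph(stages)
    by_name = {s.name: s for s in stages}
    first = stages[0].name
    pool = GpuSlotPool(gpu_capacity)
    queues: dict[str, queue.Queue] = {s.name: queue.Queue() for s in stages}
    report = PipelineReport()
    report_lock = threading.Lock()
    remaining = len(inputs)
    done_event = threading.Event()
    if remaining == 0:
        done_event.set()

    def _finish_one() -> None:
        nonlocal remaining
        with report_lock:
            remaining -= 1
            if remaining == 0:
                done_event.set()

    def _quarantine(task: Task, exc_text: str) -> None:
        task.status = "quarantined"
        task.error = exc_text
        with report_lock:
            report.quarantined.append(task)
        if quarantine_dir is not None:
            fail_dir = Path(quarantine_dir) / "FAILED"
            fail_dir.mkdir(parents=True, exist_ok=True)
            record = {"task_id": task.task_id, "stage": task.stage,
                      "attempts": task.attempts, "error": exc_text}
            (fail_dir / f"task_{task.task_id}.json").write_text(
                json.dumps(record, indent=1))
        _finish_one()

    def _worker(spec: StageSpec) -> None:
        q = queues[spec.name]
        while True:
            task = q.get()
            if task is None:
                q.task_done()
                return
            task.stage = spec.name
            task.status = "running"
            try:
                if spec.resource == "gpu":
                    with pool:
                        result = spec.handler(task.payload)
                else:
                    result = spec.handler(task.payload)
            except Exception:
                task.attempts += 1
                if task.attempts > max_retries:
                    _quarantine(task, traceback.format_exc(limit=3))
                else:
                    task.status = "failed"
                    q.put(task)
                q.task_done()
                continue
            task.payload = result
            task.attempts = 0
            if spec.downstream is None:
                task.status = "done"
                with report_lock:
                    report.completed.append(task)
                    report.results[task.task_id] = result
                _finish_one()
            else:
                task.status = "pending"
                queues[spec.downstream].put(task)
            q.task_done()

    threads = []
    for spec in stages:
        for _ in range(max(1, workers_per_stage)):
            t = threading.Thread(target=_worker, args=(spec,), daemon=True)
            t.start()
            threads.append(t)
    for i, payload in enumerate(inputs):
        queues[first].put(Task(task_id=i, payload=payload))
    done_event.wait()
    for spec in stages:
        for _ in range(max(1, workers_per_stage)):
            queues[spec.name].put(None)
    for t in threads:
        t.join()
    report.max_gpu_concurrency = pool.max_observed
    report.completed.sort(key=lambda t: t.task_id)
    report.quarantined.sort(key=lambda t: t.task_id)
    return report


# ---------------------------------------------------------------------------
# Drift alignment
# ---------------------------------------------------------------------------

def _xcorr_shift(reference: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer (dx, dy) such that frame ≈ reference shifted by (dx, dy)."""
    c = np.fft.ifft2(np.fft.fft2(frame) * np.conj(np.fft.fft2(reference))).real
    dy, dx = np.unravel_index(np.argmax(c), c.shape)
    h, w = frame.shape
    if dy > h // 2:
        dy -= h
    if dx > w // 2:
        dx -= w
    return int(dx), int(dy)


def align_frames(
    movie: MovieStack,
) -> tuple[Micrograph, list[tuple[int, int]], float]:
    """Estimate per-frame drift and build the compensated frame sum.

    Each frame's integer shift is estimated by cross-correlation
    against the running average of the already-aligned frames; the sum
    image is the shift-compensated frame sum.  The reported metric is
    the mean Euclidean shift between consecutive frames.
    """
    frames = movie.frames.astype(np.float64)
    n = frames.shape[0]
    if n == 1:
        return (Micrograph(frames[0], movie.pixel_size, movie.micrograph_id),
                [(0, 0)], 0.0)
    shifts: list[tuple[int, int]] = [(0, 0)]
    aligned_sum = frames[0].copy()
    for f in range(1, n):
        running_avg = aligned_sum / f
        dx, dy = _xcorr_shift(running_avg, frames[f])
        shifts.append((dx, dy))
        aligned_sum += np.roll(np.roll(frames[f], -dy, axis=0), -dx, axis=1)
    diffs = [np.hypot(shifts[i + 1][0] - shifts[i][0],
                      shifts[i + 1][1] - shifts[i][1])
             for i in range(n - 1)]
    mean_shift = float(np.mean(diffs))
    return (Micrograph(aligned_sum.astype(np.float32), movie.pixel_size,
                       movie.micrograph_id),
            shifts, mean_shift)


# ---------------------------------------------------------------------------
# Out-of-range flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeRule:
    """A per-metric acceptance window for micrograph quality gating."""

    metric: str
    min: float
    max: float
    action: str = "flag"        # "flag" | "discard"

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError("rule min must be <= max")
        if self.action not in ("flag", "discard"):
            raise ValueError("action must be 'flag' or 'discard'")


def flag_out_of_range(
    metrics: pd.DataFrame,
    rules: Sequence[RangeRule],
    id_column: str = "micrograph_id",
) -> tuple[list, dict]:
    """Partition micrographs into kept and flagged by the range rules.

    A micrograph is flagged if *any* rule is violated; the returned
    mapping lists every violated rule's metric per flagged id.  An
    unknown metric in a rule is a configuration error.
    """
    for rule in rules:
        if rule.metric not in metrics.columns:
            raise KeyError(f"rule references unknown metric {rule.metric!r}")
    ids = (metrics[id_column] if id_column in metrics.columns
           else metrics.index).tolist()
    flagged: dict = {}
    for rule in rules:
        values = metrics[rule.metric].to_numpy()
        bad = (values < rule.min) | (values > rule.max)
        for mid in np.asarray(ids, dtype=object)[bad]:
            flagged.setdefault(mid, []).append(rule.metric)
    kept = [m for m in ids if m not in flagged]
    return kept, flagged
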