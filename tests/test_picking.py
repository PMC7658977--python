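"""Picker training, picking, matching, F-beta, threshold search, and
filament tracing contracts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emloop import simdata
from emloop.picking import (
    FilamentParams,
    PickerModel,
    StateError,
    THRESHOLD_GRID,
    TrainingError,
    fbeta,
    match_boxes,
    optimize_threshold,
    pick,
    trace_filaments,
    train_picker,
)
from emloop.types import Box, Micrograph


class TestFbeta:
    @pytest.mark.parametrize("p,r,beta,expected", [
        (1.0, 1.0, 2.0, 1.0),
        (0.5, 1.0, 2.0, 5 * 0.5 * 1.0 / (4 * 0.5 + 1.0)),  # 0.8333...
        (0.0, 0.0, 2.0, 0.0),
        (1.0, 0.0, 2.0, 0.0),
        (0.25, 0.25, 2.0, 0.25),        # equals recall when P == R
        (0.5, 0.5, 1.0, 0.5),
    ])
    def test_closed_form(self, p, r, beta, expected):
        assert fbeta(p, r, beta) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(p=st.floats(0, 1), r=st.floats(0, 1))
    def test_bounded_by_one(self, p, r):
        assert 0.0 <= fbeta(p, r) <= 1.0


def _brute_force_max_matching(picks, refs, criterion):
    """Oracle: maximum one-to-one matching size by exhaustive search."""
    ok = [[np.hypot(p.center_x - r.center_x, p.center_y - r.center_y)
           <= criterion for r in refs] for p in picks]
    best = 0
    idx_r = range(len(refs))
    for k in range(min(len(picks), len(refs)), 0, -1):
        for ps in itertools.combinations(range(len(picks)), k):
            for rs in itertools.permutations(idx_r, k):
                if all(ok[p][r] for p, r in zip(ps, rs)):
                    return k
    return best


class TestMatchBoxes:
    def _box(self, x, y, conf=1.0):
        return Box(float(x), float(y), 24, conf)

    def test_identical_lists_are_perfect(self):
        boxes = [self._box(10, 10), self._box(50, 80), self._box(200, 30)]
        res = match_boxes(boxes, boxes)
        assert res.precision == 1.0 and res.recall == 1.0
        assert res.n_fp == res.n_fn == 0

    def test_extra_far_pick_costs_precision_only(self):
        refs = [self._box(10, 10), self._box(50, 80), self._box(200, 30)]
        picks = refs + [self._box(300, 300)]
        res = match_boxes(picks, refs)
        assert res.precision == pytest.approx(3 / 4)
        assert res.recall == 1.0
        # greedy result matches the exhaustive maximum matching
        assert res.n_tp == _brute_force_max_matching(picks, refs, 12.0)

    def test_empty_picks(self):
        refs = [self._box(i * 30, i * 30) for i in range(5)]
        res = match_boxes([], refs)
        assert res.precision == 0.0 and res.recall == 0.0
        assert res.n_fn == 5

    def test_greedy_equals_brute_force_on_crowded_case(self):
        rng = np.random.default_rng(0)
        refs = [self._box(x, y) for x, y in rng.uniform(0, 100, (4, 2))]
        picks = [self._box(x, y, c) for (x, y), c in
                 zip(rng.uniform(0, 100, (5, 2)), rng.uniform(0, 1, 5))]
        res = match_boxes(picks, refs)
        assert res.n_tp == _brute_force_max_matching(picks, refs, 12.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = [self._box(x, y) for x, y in rng.uniform(0, 200, (6, 2))]
        b = [self._box(x, y) for x, y in rng.uniform(0, 200, (9, 2))]
        ab = match_boxes(a, b)
        ba = match_boxes(b, a)
        assert ab.precision == pytest.approx(ba.recall)
        assert ab.recall == pytest.approx(ba.precision)


class TestTrainPicker:
    def test_zero_boxes_is_a_training_error(self, one_class_dataset):
        mics, _, _, _ = one_class_dataset
        with pytest.raises(TrainingError):
            train_picker([(mics[0], [])])

    def test_micrograph_cap(self, one_class_dataset):
        mics, truth, specs, _ = one_class_dataset
        labeled = [(m, truth[m.micrograph_id].boxes(specs[0].diameter))
                   for m in mics]
        many = labeled * 3                      # 90 labeled micrographs
        model = train_picker(many, max_micrographs=50, seed=0)
        assert model.n_train_micrographs == 50
        few = train_picker(labeled[:10], max_micrographs=50, seed=0)
        assert few.n_train_micrographs == 10

    def test_particle_cap(self, one_class_dataset):
        mics, truth, specs, _ = one_class_dataset
        boxes = truth[mics[0].micrograph_id].boxes(specs[0].diameter)
        # 25 micrographs x 500 boxes = 12,500; cap at 10,000
        labeled = [(m, boxes * 20) for m in mics[:25]]
        model = train_picker(labeled, max_particles=10000, seed=0)
        assert model.n_train_boxes == 10000

    def test_determinism(self, one_class_dataset):
        mics, truth, specs, _ = one_class_dataset
        labeled = [(m, truth[m.micrograph_id].boxes(specs[0].diameter))
                   for m in mics[:8]]
        m1 = train_picker(labeled, seed=3)
        m2 = train_picker(labeled, seed=3)
        assert np.array_equal(m1.templates, m2.templates)
        assert np.array_equal(m1.coef, m2.coef)
        assert m1.intercept == m2.intercept


class TestPick:
    def test_untrained_model_raises(self, one_class_dataset):
        mics, _, _, _ = one_class_dataset
        with pytest.raises(StateError):
            pick(mics[0], PickerModel(), 0.1)

    def test_threshold_one_on_pure_noise(self, trained_picker):
        rng = np.random.default_rng(6)
        noise = Micrograph(rng.normal(0, 0.25, (360, 360)), micrograph_id="n")
        boxes = pick(noise, trained_picker, 1.0)
        assert all(b.confidence >= 1.0 for b in boxes)

    def test_threshold_monotonicity_superset(self, one_class_dataset,
                                             trained_picker):
        mics, _, _, _ = one_class_dataset
        low = {(b.center_x, b.center_y)
               for b in pick(mics[25], trained_picker, 0.0)}
        high = {(b.center_x, b.center_y)
                for b in pick(mics[25], trained_picker, 0.5)}
        assert high <= low

    def test_confidences_respect_threshold(self, one_class_dataset,
                                           trained_picker):
        mics, _, _, _ = one_class_dataset
        assert all(b.confidence >= 0.3
                   for b in pick(mics[26], trained_picker, 0.3))

    def test_noise_free_recall(self):
        specs = simdata.default_class_specs(abundances=(1.0,),
                                            kinds=("disc",))
        cfg = simdata.SimConfig(seed=11, particles_per_micrograph=20,
                                noise_sigma=0.0, contamination_rate=0.0)
        movies, truth = simdata.generate_dataset(cfg, 12, specs)
        mics = [Micrograph(m.frames[0], micrograph_id=m.micrograph_id)
                for m in movies]
        model = train_picker(
            [(m, truth[m.micrograph_id].boxes(24)) for m in mics[:8]],
            seed=0)
        res_all = [match_boxes(pick(m, model, 0.1),
                               truth[m.micrograph_id].boxes(24))
                   for m in mics[8:]]
        recall = (sum(r.n_tp for r in res_all)
                  / sum(r.n_tp + r.n_fn for r in res_all))
        assert recall >= 0.95

    def test_deterministic(self, one_class_dataset, trained_picker):
        mics, _, _, _ = one_class_dataset
        a = pick(mics[27], trained_picker, 0.1)
        b = pick(mics[27], trained_picker, 0.1)
        assert a == b

    def test_held_out_f2_at_optimized_threshold(self, one_class_dataset,
                                                trained_picker):
        """Parameter-recovery check: a picker trained on ground truth
        reaches F2 >= 0.9 on held-out micrographs at its optimized
        threshold."""
        mics, truth, specs, _ = one_class_dataset
        held = mics[20:]
        refs = [truth[m.micrograph_id].boxes(specs[0].diameter)
                for m in held]
        best, table = optimize_threshold(trained_picker, held, refs)
        assert table.loc[table["threshold"] == best, "fbeta"].iloc[0] >= 0.9


class TestOptimizeThreshold:
    def test_grid_has_101_points(self, one_class_dataset, trained_picker):
        mics, truth, specs, _ = one_class_dataset
        refs = [truth[m.micrograph_id].boxes(specs[0].diameter)
                for m in mics[:3]]
        _, table = optimize_threshold(trained_picker, mics[:3], refs)
        assert len(table) == 101
        assert np.allclose(table["threshold"].to_numpy(), THRESHOLD_GRID)

    def test_equals_brute_force_argmax(self, one_class_dataset,
                                       trained_picker):
        mics, truth, specs, _ = one_class_dataset
        subset = mics[20:24]
        refs = [truth[m.micrograph_id].boxes(specs[0].diameter)
                for m in subset]
        best, table = optimize_threshold(trained_picker, subset, refs)
        # independent recomputation at every grid point
        base = [pick(m, trained_picker, 0.0) for m in subset]
        best_f2, best_t = -1.0, None
        for t in THRESHOLD_GRID:
            tp = fp = fn = 0
            for picks, ref in zip(base, refs):
                r = match_boxes([b for b in picks if b.confidence >= t], ref)
                tp, fp, fn = tp + r.n_tp, fp + r.n_fp, fn + r.n_fn
            p = tp / (tp + fp) if tp + fp else 0.0
            rc = tp / (tp + fn) if tp + fn else 0.0
            f2 = fbeta(p, rc)
            if f2 > best_f2:
                best_f2, best_t = f2, t
        assert best == pytest.approx(best_t)
        assert table["fbeta"].max() == pytest.approx(best_f2)

    def test_scripted_confidences(self):
        """Confidence 1.0 at every true particle, <= 0.2 for decoys:
        the optimum lies above 0.20 with a perfect F2."""
        refs = [Box(20.0 * (i + 1), 50.0, 16, 1.0) for i in range(5)]
        decoys = [Box(20.0 * (i + 1), 150.0, 16, 0.08 + 0.03 * i)
                  for i in range(5)]           # confidences up to 0.20

        def scripted_pick(mic, model, threshold):
            return [b for b in refs + decoys if b.confidence >= threshold]

        mic = Micrograph(np.zeros((200, 200)), micrograph_id="s")
        best, table = optimize_threshold(
            PickerModel(), [mic], [refs], pick_fn=scripted_pick)
        assert 0.20 < best <= 1.00
        assert table.loc[table["threshold"] == best, "fbeta"].iloc[0] == 1.0

    def test_invariant_to_micrograph_order(self, one_class_dataset,
                                           trained_picker):
        mics, truth, specs, _ = one_class_dataset
        subset = mics[20:24]
        refs = [truth[m.micrograph_id].boxes(specs[0].diameter)
                for m in subset]
        b1, _ = optimize_threshold(trained_picker, subset, refs)
        b2, _ = optimize_threshold(trained_picker, subset[::-1], refs[::-1])
        assert b1 == b2

    def test_empty_subset_is_an_error(self, trained_picker):
        with pytest.raises(ValueError):
            optimize_threshold(trained_picker, [], [])


FILAMENT_CFG = simdata.SimConfig(image_size=(400, 400), filament_mode=True,
                                 filament_width=12, noise_sigma=0.25, seed=0)
FILAMENT_PARAMS = FilamentParams(filament_width=12, box_distance=25,
                                 min_segments=6)


class TestTraceFilaments:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            FilamentParams(box_distance=0)
        with pytest.raises(ValueError):
            FilamentParams(min_segments=0)

    def test_straight_filament_segment_count_and_spacing(self):
        line = np.array([[50.0, 200.0], [210.0, 200.0]])    # length 160
        mic = simdata.render_filaments([line], FILAMENT_CFG)
        traces, boxes = trace_filaments(mic, None, FILAMENT_PARAMS, 0.3)
        assert len(traces) == 1
        assert 6 <= traces[0].n_segments <= 7       # ~ floor(L/d) + 1
        seg = traces[0].segments
        gaps = [np.hypot(seg[i + 1].center_x - seg[i].center_x,
                         seg[i + 1].center_y - seg[i].center_y)
                for i in range(len(seg) - 1)]
        assert all(abs(g - 25.0) <= 1.0 for g in gaps)
        assert all(b.filament_id is not None and b.segment_index is not None
                   for b in boxes)

    def test_short_filament_discarded(self):
        line = np.array([[50.0, 100.0], [150.0, 100.0]])    # length 100
        mic = simdata.render_filaments([line], FILAMENT_CFG)
        traces, boxes = trace_filaments(mic, None, FILAMENT_PARAMS, 0.3)
        assert traces == [] and boxes == []

    def test_no_segment_near_crossing(self):
        l1 = np.array([[40.0, 60.0], [360.0, 340.0]])
        l2 = np.array([[40.0, 340.0], [360.0, 60.0]])
        mic = simdata.render_filaments([l1, l2], FILAMENT_CFG)
        _, boxes = trace_filaments(mic, None, FILAMENT_PARAMS, 0.3)
        assert boxes
        ix, iy = 200.0, 200.0           # geometric intersection
        for b in boxes:
            assert np.hypot(b.center_x - ix, b.center_y - iy) > 12.0

    def test_trace_threshold_filters_whole_traces(self):
        line = np.array([[50.0, 200.0], [350.0, 200.0]])
        mic = simdata.render_filaments([line], FILAMENT_CFG)
        lo, _ = trace_filaments(mic, None, FILAMENT_PARAMS, 0.0)
        hi, _ = trace_filaments(mic, None, FILAMENT_PARAMS, 1.0)
        assert len(lo) >= 1 and hi == []


class TestModelSerialization:
    def test_save_load_preserves_picks(self, tmp_path, one_class_dataset,
                                       trained_picker):
        mics, truth, specs, _ = one_class_dataset
        # build a two-level chain to exercise chain serialization
        labeled = [(m, truth[m.micrograph_id].boxes(specs[0].diameter))
                   for m in mics[:5]]
        chained = train_picker(labeled, seed=1, round_tag="2",
                               prev_model=trained_picker,
                               anchor_size=trained_picker.anchor_size)
        path = tmp_path / "model.npz"
        chained.save(path)
        loaded = PickerModel.load(path)
        assert loaded.round_tag == "2" and loaded.prev is not None
        assert pick(mics[25], loaded, 0.1) == pick(mics[25], chained, 0.1)
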