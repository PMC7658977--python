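"""Feedback-loop orchestration: the relative-good statistic, training-set
assembly, triggers, stack assembly, and loop behavior."""

import numpy as np
import pandas as pd
import pytest

from emloop import feedback as fb
from emloop.classify2d import ParticleImage
from emloop.feedback import (
    FeedbackConfig,
    FeedbackHalted,
    FeedbackState,
    TriggerEvent,
    assemble_stack,
    build_training_set,
    check_triggers,
    relative_good_stat,
    run_feedback,
)
from emloop.formats_io import read_mrc
from emloop.select2d import SelectorModel
from emloop.types import Box


class TestRelativeGoodStat:
    @pytest.mark.parametrize("good,ppm,n_mics,expected", [
        (32513, 132, 500, 0.49),    # TRPC4 evaluation, round 4
        (12595, 130, 500, 0.19),    # Tc holotoxin evaluation, round 1
        (38946, 515, 100, 0.76),    # actomyosin, final thresholded run
        (0, 50, 100, 0.00),
    ])
    def test_table_cells(self, good, ppm, n_mics, expected):
        assert relative_good_stat(good, ppm, n_mics) == expected

    def test_rounds_half_up(self):
        # 0.125 rounds up to 0.13, not banker's 0.12
        assert relative_good_stat(125, 10, 100) == 0.13

    def test_zero_picks_is_an_error(self):
        with pytest.raises(ValueError):
            relative_good_stat(10, 0, 500)


class TestBuildTrainingSet:
    def _grouped(self, n_mics, boxes_per_mic):
        return {f"m{i:03d}": [Box(10.0 + j, 10.0, 24) for j in
                              range(boxes_per_mic)]
                for i in range(n_mics)}

    def test_micrograph_cap(self):
        out = build_training_set(self._grouped(120, 5), max_mics=50,
                                 max_particles=20000, seed=0)
        assert len(out) == 50

    def test_cap_not_binding(self):
        out = build_training_set(self._grouped(5, 5), max_mics=50,
                                 max_particles=20000, seed=0)
        assert len(out) == 5

    def test_particle_cap_truncates_whole_micrographs(self):
        out = build_training_set(self._grouped(50, 500), max_mics=50,
                                 max_particles=20000, seed=0)
        total = sum(len(b) for b in out.values())
        assert total <= 20000
        assert total == 20000               # 40 whole micrographs x 500

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_training_set({}, 50, 20000, 0)

    def test_deterministic(self):
        grouped = self._grouped(80, 10)
        a = build_training_set(grouped, 50, 20000, seed=3)
        b = build_training_set(grouped, 50, 20000, seed=3)
        assert sorted(a) == sorted(b)


class TestCheckTriggers:
    def test_ab_initio_fires_exactly_at_200(self):
        state = FeedbackState()
        assert check_triggers(state, 199, 0) == []
        events = check_triggers(state, 1, 0)
        assert [e.kind for e in events] == ["ab_initio"]
        # never again
        assert check_triggers(state, 500, 0) == []

    def test_refine_batches_per_40k(self):
        state = FeedbackState()
        events = check_triggers(state, 0, 80000)
        assert [e.kind for e in events] == ["refine_batch", "refine_batch"]
        assert [e.count for e in events] == [1, 2]
        assert check_triggers(state, 0, 39999) == []
        assert [e.kind for e in check_triggers(state, 0, 1)] == \
            ["refine_batch"]

    def test_zero_counters_no_events(self):
        state = FeedbackState()
        assert check_triggers(state, 0, 0) == []

    def test_negative_counters_rejected(self):
        with pytest.raises(ValueError):
            check_triggers(FeedbackState(), -1, 0)


class TestAssembleStack:
    def _particles(self, n):
        rng = np.random.default_rng(0)
        return [ParticleImage(rng.normal(size=(16, 16)),
                              Box(float(10 + i), 20.0, 16, 1.0, f"m{i % 7}"))
                for i in range(n)]

    def test_stack_and_manifest(self, tmp_path):
        parts = self._particles(100)
        stack_path, manifest_path = assemble_stack(
            parts, [i % 3 for i in range(100)], tmp_path / "good")
        stack, _ = read_mrc(stack_path)
        assert stack.shape == (100, 16, 16)
        manifest = pd.read_csv(manifest_path, sep="\t")
        assert len(manifest) == 100
        assert list(manifest.columns) == ["particle_id", "micrograph_id",
                                          "center_x", "center_y", "class_id"]

    def test_duplicate_provenance_rejected(self, tmp_path):
        parts = self._particles(5)
        parts.append(parts[0])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_stack(parts, [0] * 6, tmp_path / "dup")

    def test_manifest_joins_back_to_boxes(self, tmp_path):
        parts = self._particles(40)
        _, manifest_path = assemble_stack(parts, [0] * 40, tmp_path / "j")
        manifest = pd.read_csv(manifest_path, sep="\t")
        for _, row in manifest.iterrows():
            p = parts[int(row.particle_id)]
            assert p.box.micrograph_id == row.micrograph_id
            assert p.box.center_x == row.center_x
            assert p.box.center_y == row.center_y


class TestRunFeedback:
    def test_zero_rounds_returns_input_model(self, trained_picker,
                                             one_class_dataset):
        mics, _, _, _ = one_class_dataset
        dummy_selector = SelectorModel(
            coef=np.ones(1), intercept=0.0, feature_mean=np.zeros(1),
            feature_std=np.ones(1), n_good=1, n_bad=1)
        result = run_feedback(mics[:5], trained_picker, dummy_selector,
                              FeedbackConfig(n_rounds=0))
        assert result.final_model is trained_picker
        assert result.history == [] and result.final_threshold is None

    def test_zero_good_particles_halts_with_diagnostic(
            self, trained_picker, one_class_dataset):
        mics, _, _, _ = one_class_dataset

        class RejectAll(SelectorModel):
            def good_confidence(self, averages):
                return np.zeros(len(averages))

        selector = RejectAll(coef=np.ones(1), intercept=0.0,
                             feature_mean=np.zeros(1),
                             feature_std=np.ones(1), n_good=1, n_bad=1)
        config = FeedbackConfig(batch_size=500, class_size_range=(20, 40),
                                extract_box_size=32, seed=0)
        with pytest.raises(FeedbackHalted) as excinfo:
            run_feedback(mics[:10], trained_picker, selector, config)
        assert excinfo.value.state.round_index == 1
        assert excinfo.value.state.history[-1].good_particles == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FeedbackConfig(n_rounds=-1)
        with pytest.raises(ValueError):
            FeedbackConfig(feedback_pick_threshold=1.5)
        with pytest.raises(ValueError):
            FeedbackConfig(final_threshold_mode="sometimes")


class TestRecoveryLoopProperties:
    """Deeper checks on the shared recovery run."""

    def test_runs_exactly_five_rounds(self, recovery_run):
        assert len(recovery_run.feedback.history) == 5
        assert [r.round_label for r in recovery_run.feedback.history] == \
            ["1", "2", "3", "4", "5"]
        assert len(recovery_run.feedback.models) == 6
        assert [m.round_tag for m in recovery_run.feedback.models] == \
            ["1", "2", "3", "4", "5", "6"]

    def test_good_particles_never_exceed_picks(self, recovery_run):
        n_loop_mics = 60
        for report in recovery_run.feedback.history:
            assert report.good_particles <= \
                report.picks_per_mic * n_loop_mics + 1e-9
            assert 0.0 <= report.relative_good <= 1.0

    def test_final_threshold_from_grid(self, recovery_run):
        t = recovery_run.feedback.final_threshold
        assert 0.0 <= t <= 1.0
        assert round(t * 100) == pytest.approx(t * 100)
        assert recovery_run.feedback.threshold_table is not None
        assert len(recovery_run.feedback.threshold_table) == 101

    def test_retraining_maintains_heldout_quality(self, recovery_run):
        """Re-training on loop survivors keeps held-out F2 high: the
        final model retains at least 90% of the first re-trained model's
        score and stays above 0.8 absolute.  (The initial model here is
        strong — only its picks were corrupted — so the loop's job is to
        keep quality while its training signal purifies.)"""
        from emloop import simdata
        from emloop.protocols import heldout_scores
        specs = simdata.default_class_specs(abundances=(1.0,),
                                            kinds=("disc",))
        cfg = simdata.SimConfig(seed=2, particles_per_micrograph=25)
        movies, truth = simdata.generate_dataset(cfg, 70, specs)
        from emloop.types import Micrograph
        held = [Micrograph(m.frames[0], micrograph_id=m.micrograph_id)
                for m in movies[60:]]
        models = recovery_run.feedback.models
        _, _, f2_round2 = heldout_scores(models[1], 0.1, held, truth, 24)
        _, _, f2_round6 = heldout_scores(models[5], 0.1, held, truth, 24)
        assert f2_round6 >= 0.9 * f2_round2
        assert f2_round6 >= 0.8


class TestSteeringLoopProperties:
    def test_minority_recall_stable_while_share_grows(self, steering_run):
        recalls = steering_run.minority_recalls
        assert all(r >= 0.9 for r in recalls)
        assert steering_run.minority_shares[-1] > \
            steering_run.minority_shares[1]

    def test_evaluation_has_seven_rows(self, steering_run):
        labels = [r.round_label for r in steering_run.evaluation]
        assert labels[:6] == ["1", "2", "3", "4", "5", "6"]
        assert labels[6].startswith("6 + T ")

    def test_total_picks_do_not_balloon(self, steering_run):
        """Targeting a subpopulation trims the pick stream rather than
        growing it: final-round picks stay within 10% of round 2."""
        rows = steering_run.evaluation
        assert rows[5].picks_per_mic <= rows[1].picks_per_mic * 1.1
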