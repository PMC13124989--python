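"""Trial execution: perception, route arbitration and motor readout."""

import numpy as np
import pytest

from apraxim.agent import efe_table, observe_gesture, plan_response, run_trial
from apraxim.core import Categorical, expected_free_energy, floor_log
from apraxim.tasks import TaskKind, enrich_observations, make_task
from oracles import random_prior


class TestObserveGesture:
    def test_noiseless_recognition_recovers_sequence_and_concept(self, noiseless_model):
        rng = np.random.default_rng(0)
        perception = observe_gesture(noiseless_model, "hammering", rng)
        rep = noiseless_model.repertoire
        assert perception.q_sequence.label_of_mode() == "hammering"
        assert perception.q_sequence.probs.max() > 0.999
        assert perception.q_concept.label_of_mode() == "hammer"
        true = [rep.segment_index(s) for s in rep.sequences["hammering"]]
        assert [int(np.argmax(s)) for s in perception.smoothed_segments] == true

    def test_upper_beliefs_change_only_at_timescale_boundary(self, model):
        rng = np.random.default_rng(5)
        perception = observe_gesture(model, "waving", rng)
        beliefs = perception.l2_beliefs
        # initial prior plus one entry per fast step; the sequence belief
        # holds its prior until the slow-step boundary after the last step
        assert len(beliefs) == 1 + model.understanding.timescale
        for held in beliefs[:-1]:
            np.testing.assert_array_equal(held, beliefs[0])
        assert not np.array_equal(beliefs[-1], beliefs[0])

    def test_smoothing_corrects_single_misperceived_step(self, model):
        # find a trial whose raw observation is wrong at one position and
        # check that the smoothed belief still names the true segment
        rep = model.repertoire
        true = [rep.segment_index(s) for s in rep.sequences["meaningless_2"]]
        for seed in range(400):
            rng = np.random.default_rng(seed)
            p = observe_gesture(model, "meaningless_2", rng)
            obs = p.observations["kinematic"]
            wrong = [t for t in range(3) if obs[t] != true[t]]
            if len(wrong) == 1 and p.q_sequence.label_of_mode() == "meaningless_2":
                smoothed_modes = [int(np.argmax(s)) for s in p.smoothed_segments]
                assert smoothed_modes == true
                return
        pytest.fail("no single-error trial found in 400 seeds")


class TestEfeTable:
    def test_matches_generic_expected_free_energy(self, rng):
        n_seg, horizon = 5, 3
        B = np.zeros((n_seg, n_seg, n_seg))
        for a in range(n_seg):
            B[a, a, :] = 1.0
        A = np.eye(n_seg)
        C_rows = floor_log(np.stack([random_prior(rng, n_seg) for _ in range(horizon)]))
        policies = rng.integers(0, n_seg, size=(40, horizon))
        table = efe_table(policies, A, C_rows)
        belief = Categorical(random_prior(rng, n_seg))
        for row, policy in enumerate(policies):
            g = expected_free_energy(policy, belief, B, A, C_rows)
            assert table[row] == pytest.approx(g, abs=1e-10)


class TestPlanResponse:
    def test_lexical_drive_reproduces_recognized_sequence(self, model):
        rep = model.repertoire
        drive = Categorical.delta(rep.sequence_index("saluting"),
                                  len(rep.sequence_labels), rep.sequence_labels)
        actions, post, w = plan_response(model, drive, None, np.random.default_rng(2))
        assert w > 0.99
        assert tuple(rep.segments[a] for a in actions) == rep.sequences["saluting"]

    def test_direct_route_reproduces_observed_segments(self, model):
        rep = model.repertoire
        drive = Categorical.delta(rep.sequence_index("meaningless_1"),
                                  len(rep.sequence_labels), rep.sequence_labels)
        target = [rep.segment_index(s) for s in rep.sequences["meaningless_1"]]
        prefs = [np.eye(len(rep.segments))[k] * 0.99 + 0.01 / 8 for k in target]
        prefs = [p / p.sum() for p in prefs]
        actions, post, w = plan_response(model, drive, prefs, np.random.default_rng(3))
        assert w < 0.01  # meaningless drive leaves the lexical gate shut
        assert actions == target


class TestRunTrial:
    def test_noiseless_imitation_is_exact(self, noiseless_model):
        rep = noiseless_model.repertoire
        for label, kind in (("hammering", TaskKind.IMITATE_FAMILIAR),
                            ("meaningless_1", TaskKind.IMITATE_MEANINGLESS)):
            task = make_task(kind, label, rep)
            for seed in range(20):
                trace = run_trial(noiseless_model, task, np.random.default_rng(seed))
                assert trace.correct
                assert trace.response == rep.sequences[label]

    def test_recognition_response_is_concept_label(self, noiseless_model):
        task = make_task(TaskKind.RECOGNIZE_FAMILIAR, "waving",
                         noiseless_model.repertoire)
        trace = run_trial(noiseless_model, task, np.random.default_rng(0))
        assert trace.response == "wave"
        assert trace.correct

    def test_verbal_command_produces_commanded_gesture(self, noiseless_model):
        rep = noiseless_model.repertoire
        task = make_task(TaskKind.EXECUTE_VERBAL_COMMAND, "salute", rep)
        trace = run_trial(noiseless_model, task, np.random.default_rng(1))
        assert trace.response == rep.sequences["saluting"]

    def test_tool_use_with_enrichment_succeeds(self, noiseless_model):
        rep = noiseless_model.repertoire
        task = enrich_observations(make_task(TaskKind.USE_REAL_TOOL, "hammering", rep))
        trace = run_trial(noiseless_model, task, np.random.default_rng(4))
        assert trace.correct
        assert set(trace.observations) == {"tactile", "auditory", "visual_consequence"}

    def test_familiarity_discrimination_reads_sequence_posterior(self, noiseless_model):
        rep = noiseless_model.repertoire
        familiar = make_task(TaskKind.DISCRIMINATE_FAMILIARITY, "hammering", rep)
        novel = make_task(TaskKind.DISCRIMINATE_FAMILIARITY, "meaningless_1", rep)
        assert run_trial(noiseless_model, familiar,
                         np.random.default_rng(0)).response == "meaningful"
        assert run_trial(noiseless_model, novel,
                         np.random.default_rng(0)).response == "meaningless"

    def test_trials_reproducible_under_fixed_seed(self, model):
        task = make_task(TaskKind.IMITATE_FAMILIAR, "hammering", model.repertoire)
        t1 = run_trial(model, task, np.random.default_rng(77))
        t2 = run_trial(model, task, np.random.default_rng(77))
        assert t1.actions == t2.actions
        assert t1.response == t2.response
        np.testing.assert_array_equal(t1.q_sequence.probs, t2.q_sequence.probs)
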