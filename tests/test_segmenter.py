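import dataclasses

import numpy as np
import pytest

from mitovo2.io import NA, START, Trace
from mitovo2.segmenter import (SEARCH_SPACE, BiLstmSegmenter, ModelConfig,
                               make_windows, normalize, train, tune,
                               window_offsets, windows_from_cohort)
from mitovo2.synthetic import CohortConfig, generate_cohort, generate_subject


class TestNormalize:
    def test_symmetric_triplet(self):
        out = normalize(np.array([50.0, 60.0, 70.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])  # sample sd = 10
        assert out.mean() == pytest.approx(0.0, abs=1e-15)

    def test_idempotent_up_to_reestimation(self, rng):
        x = rng.normal(size=500)
        once = normalize(x)
        np.testing.assert_allclose(normalize(once), once, atol=1e-12)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize(np.full(100, 60.0))


def brute_force_offsets(n, window=250, step=10):
    """Enumeration oracle: all offsets o with o+window <= n at the stride,
    plus a clamped tail window covering the final samples."""
    if n <= window:
        return [0]
    offs = [o for o in range(0, n - window + 1) if o % step == 0]
    if offs[-1] + window < n:
        offs.append(n - window)
    return offs


class TestMakeWindows:
    @pytest.mark.parametrize("n, expected", [
        (260, 2),    # offsets 0 and 10
        (250, 1),
        (505, None),  # checked against the enumeration oracle
    ])
    def test_window_counts(self, n, expected, rng):
        oracle = brute_force_offsets(n)
        if expected is not None:
            assert len(oracle) == expected
        trace = Trace("t", rng.normal(60, 5, n))
        ws = make_windows(trace)
        assert list(ws.offsets) == oracle

    def test_windows_reproduce_trace_slices(self, rng):
        vals = rng.normal(60, 5, 505)
        trace = Trace("t", vals)
        norm = normalize(vals)
        ws = make_windows(trace)
        for k, o in enumerate(ws.offsets):
            np.testing.assert_array_equal(ws.X[k, :, 0], norm[o: o + 250])

    def test_short_trace_padded_with_na_targets(self, rng):
        vals = rng.normal(60, 5, 120)
        trace = Trace("t", vals)
        ws = make_windows(trace)
        assert len(ws) == 1
        assert ws.weight[0, :120].all() and not ws.weight[0, 120:].any()
        assert (ws.y[0, 120:] == NA).all()
        np.testing.assert_array_equal(ws.X[0, 120:, 0], ws.X[0, 119, 0])


class TestConfig:
    def test_defaults_are_the_tuned_values(self):
        cfg = ModelConfig()
        assert (cfg.hidden_units, cfg.initial_learn_rate, cfg.max_epochs,
                cfg.mini_batch_size) == (55, 0.0137, 3, 80)
        cfg.validate_in_search_box()

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="max_epochs"):
            ModelConfig(max_epochs=0).validate()

    def test_out_of_box_rejected_for_search(self):
        with pytest.raises(ValueError, match="outside search range"):
            ModelConfig(hidden_units=40).validate_in_search_box()


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortConfig(n_subjects=3, seed=31,
                                        measurements_per_subject=3))


class TestTraining:
    def test_seeded_retraining_reproduces_predictions(self, small_cohort):
        traces = [c[0] for c in small_cohort]
        labels = [c[1] for c in small_cohort]
        cfg = ModelConfig(max_epochs=1, seed=8)
        ws = windows_from_cohort(traces, labels)
        m1 = train(ws, cfg)
        m2 = train(ws, cfg)
        probe = traces[0]
        assert m1.predict(probe) == m2.predict(probe)

    def test_predict_is_deterministic(self, trained_model, small_cohort):
        probe = small_cohort[0][0]
        assert trained_model.predict(probe) == trained_model.predict(probe)

    def test_probabilities_sum_to_one_over_full_trace(self, trained_model,
                                                      small_cohort):
        probs = trained_model.predict_proba(small_cohort[0][0])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_flat_trace_is_all_na(self, trained_model, rng):
        flat = Trace("flat", 60.0 + rng.normal(0, 1.5, 400))
        pred = trained_model.predict(flat)
        assert not pred.codes.any()

    def test_detects_measurement_onsets_near_true_starts(self, trained_model):
        """Raw (pre-cleanup) detection: the onset of each predicted activity
        run falls within +/-5 samples of a true start for at least 2 of 3
        measurements."""
        trace, _, truth = generate_subject(
            CohortConfig(measurements_per_subject=3), 555)
        pred = trained_model.predict(trace).codes
        active = pred != NA
        onsets = [i for i in np.flatnonzero(active)
                  if i == 0 or not active[i - 1]]
        hits = sum(any(abs(int(o) - g.start_index) <= 5 for o in onsets)
                   for g in truth)
        assert hits >= 2

    def test_checkpoint_roundtrip(self, trained_model, tmp_path,
                                  small_cohort):
        path = tmp_path / "model.ckpt.npz"
        trained_model.save(path)
        loaded = BiLstmSegmenter.load(path)
        probe = small_cohort[0][0]
        assert loaded.predict(probe) == trained_model.predict(probe)

    def test_sklearn_param_interface(self):
        model = BiLstmSegmenter(hidden_units=60)
        assert model.get_params()["hidden_units"] == 60
        model.set_params(max_epochs=2)
        assert model.max_epochs == 2


class TestTune:
    def test_budget_one_returns_single_evaluated_config(self, small_cohort):
        pairs = [(c[0], c[1]) for c in small_cohort]
        space = {"max_epochs": (2, 2), "hidden_units": (50, 52)}
        best, trials = tune(pairs, budget_trials=1, seed=0, search_space=space)
        assert len(trials) == 1
        assert trials[0]["config"] == dataclasses.asdict(best)

    def test_search_stays_in_box_and_is_seeded(self, small_cohort):
        pairs = [(c[0], c[1]) for c in small_cohort]
        space = {"max_epochs": (2, 2)}
        b1, t1 = tune(pairs, budget_trials=2, seed=4, search_space=space)
        b2, t2 = tune(pairs, budget_trials=2, seed=4, search_space=space)
        assert b1 == b2
        for rec in t1:
            cfg = rec["config"]
            for name, (lo, hi) in SEARCH_SPACE.items():
                assert lo <= cfg[name] <= hi

    def test_bad_budget_and_space(self, small_cohort):
        pairs = [(c[0], c[1]) for c in small_cohort]
        with pytest.raises(ValueError):
            tune(pairs, budget_trials=0)
        with pytest.raises(ValueError, match="outside"):
            tune(pairs, 1, search_space={"hidden_units": (10, 80)})
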