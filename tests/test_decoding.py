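"""One-vs-rest linear-SVM decoding: normalization, training, classification,
cross-validated window decoding, and AUC profiling."""

import numpy as np
import pytest

from amygdecode import data_model as dm
from amygdecode import decoding, synthetic
from amygdecode.data_model import EXPRESSIONS
from amygdecode.decoding import (
    ClassifierEnsemble,
    classify,
    decode_window,
    normalize_responses,
    pairwise_auc_profile,
    train_ovr,
)


class TestNormalization:
    def test_worked_example(self):
        counts = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        out = normalize_responses(counts, counts)
        np.testing.assert_allclose(out[:, 0], [0, 0.25, 0.5, 0.75, 1])

    def test_zero_reference_maps_to_zero(self):
        train = np.zeros((4, 2))
        apply_to = np.ones((3, 2))
        np.testing.assert_array_equal(normalize_responses(train, apply_to), 0.0)

    def test_constant_nonzero_maps_to_one(self):
        counts = np.full((3, 1), 5.0)
        np.testing.assert_allclose(normalize_responses(counts, counts), 1.0)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(10, 4)).astype(float)
        once = normalize_responses(counts, counts)
        twice = normalize_responses(once, once)
        np.testing.assert_allclose(once, twice)


def toy_separable_set():
    """Two neurons; neuron 0 fires only for open_mouth, neuron 1 only for
    neutral.  9 samples (3 per class), linearly separable."""
    x, labels = [], []
    for expr in EXPRESSIONS:
        for _ in range(3):
            if expr == "open_mouth":
                x.append([1.0, 0.0])
            elif expr == "neutral":
                x.append([0.0, 1.0])
            else:
                x.append([0.0, 0.0])
            labels.append(expr)
    return np.array(x), np.array(labels)


class TestTrainAndClassify:
    def test_separable_toy_set_classified_perfectly(self):
        x, labels = toy_separable_set()
        ens = train_ovr(x, labels)
        pred = classify(ens, x)
        assert np.all(pred == labels)
        f_open = ens.decision_values(x)[:, 0]
        assert np.all(np.sign(f_open[labels == "open_mouth"]) > 0) or np.all(
            f_open[labels == "open_mouth"] > f_open[labels != "open_mouth"].max()
        )

    def test_duplication_invariance(self):
        # at the default small cost every sample is a bounded support vector,
        # so duplication rescales the (soft-margin) hyperplane but leaves all
        # predictions unchanged; at a cost large enough to reach the
        # hard-margin solution the hyperplane itself is duplication-invariant
        x, labels = toy_separable_set()
        ens1 = train_ovr(x, labels)
        ens2 = train_ovr(np.vstack([x, x]), np.concatenate([labels, labels]))
        assert np.all(classify(ens1, x) == classify(ens2, x))
        hard1 = train_ovr(x, labels, cost=100.0)
        hard2 = train_ovr(np.vstack([x, x]), np.concatenate([labels, labels]), cost=100.0)
        np.testing.assert_allclose(hard1.weights, hard2.weights, atol=1e-4)

    def test_missing_class_rejected(self):
        x, labels = toy_separable_set()
        keep = labels != "pout_lips"
        with pytest.raises(ValueError, match="pout_lips"):
            train_ovr(x[keep], labels[keep])

    def test_identical_samples_mixed_labels_tie(self):
        x = np.ones((9, 2))
        labels = np.array(sorted(EXPRESSIONS * 3))
        ens = train_ovr(x, labels)
        f = ens.decision_values(x[:1])
        assert np.ptp(f) < 1e-6  # degenerate geometry: decision values tie

    def test_argmax_and_tie_break(self):
        ens = ClassifierEnsemble(weights=np.eye(3), offsets=np.zeros(3), center=0.0)
        assert classify(ens, np.array([[2.0, -1.0, -1.0]]))[0] == "open_mouth"
        # exact tie between open_mouth and neutral -> fixed order wins
        assert classify(ens, np.array([[0.5, 0.5, -1.0]]))[0] == "open_mouth"

    def test_dimension_mismatch_rejected(self):
        ens = ClassifierEnsemble(weights=np.eye(3), offsets=np.zeros(3), center=0.0)
        with pytest.raises(ValueError):
            ens.decision_values(np.ones((1, 5)))


class TestDecodeWindow:
    def test_split_bookkeeping_72_train_18_test(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        spec = dm.WindowSpec()
        res = decode_window(ds, 55.0, spec, n_reps=2, seed=0)
        assert res.n_train == 72
        assert res.n_test == 18

    def test_incomplete_neuron_excluded(self, catalog):
        cfg = synthetic.PopulationConfig(
            n_positive=0, n_negative=0, n_nonselective=4, n_trials=10, seed=0
        )
        ds = synthetic.simulate_population(config=cfg)
        ds.neurons[0].trials = ds.neurons[0].trials[:-1]  # 9 trials on one image
        res = decode_window(ds, 0.0, dm.WindowSpec(), n_reps=1, seed=0)
        assert res.neuron_ids.size == 3

    def test_label_shuffled_accuracy_near_chance(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        res = decode_window(ds, 55.0, dm.WindowSpec(), n_reps=60, seed=1, shuffle_labels=True)
        se = res.overall.std(ddof=1) / np.sqrt(res.overall.size)
        assert abs(res.mean_overall - 1 / 3) < 3.5 * max(se, 0.01)

    def test_early_window_open_mouth_best(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        res = decode_window(ds, 60.0, dm.WindowSpec(), n_reps=25, seed=2)
        per = res.mean_per_class
        k = EXPRESSIONS.index("open_mouth")
        assert per[k] > max(per[i] for i in range(3) if i != k)

    def test_scale_invariance_of_accuracy(self, small_preset_dataset):
        # multiplying all of a neuron's spike times... instead, scale counts:
        # normalization maps per-neuron scale out, so doubling every count of
        # a neuron (noiseless surrogate via duplicated spikes) keeps accuracy
        ds, _ = small_preset_dataset
        spec = dm.WindowSpec()
        res1 = decode_window(ds, 60.0, spec, n_reps=5, seed=3)
        # surrogate: duplicate each spike (count doubling) for half the neurons
        import copy

        ds2 = copy.deepcopy(ds)
        for n in ds2.neurons[:10]:
            for t in n.trials:
                doubled = np.sort(np.concatenate([t.spike_times, t.spike_times + 1e-4]))
                t.spike_times = doubled
        res2 = decode_window(ds2, 60.0, spec, n_reps=5, seed=3)
        np.testing.assert_allclose(res1.overall, res2.overall, atol=1e-12)


class TestAucProfile:
    def test_single_rep_auc_degenerate(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        spec = dm.WindowSpec(step=1, center_min=60, center_max=60)
        tc = decoding.decode_timecourse(ds, spec, n_reps=1, seed=4, with_chance=False)
        aucs = pairwise_auc_profile(tc, 60.0)
        assert all(v in (0.5, 1.0) for v in aucs.values())

    def test_open_mouth_pairs_dominate_at_early_peak(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        spec = dm.WindowSpec(step=1, center_min=60, center_max=60)
        tc = decoding.decode_timecourse(ds, spec, n_reps=40, seed=5, with_chance=False)
        aucs = pairwise_auc_profile(tc, 60.0)
        assert aucs[("open_mouth", "neutral")] > aucs[("neutral", "pout_lips")]
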