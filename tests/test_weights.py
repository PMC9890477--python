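"""Weight-sign grouping, weighted-sum time courses, and group latency."""

import numpy as np
import pytest

from amygdecode import data_model as dm
from amygdecode import decoding, synthetic, weights
from amygdecode.weights import WeightRecord


@pytest.fixture(scope="module")
def preset_with_weights():
    cfg = synthetic.PopulationConfig(
        n_positive=8, n_negative=8, n_nonselective=4, n_trials=10, seed=55
    )
    ds = synthetic.simulate_population(config=cfg)
    res = decoding.decode_window(ds, 60.0, dm.WindowSpec(), n_reps=20, seed=9, store_weights=True)
    return ds, cfg, res


class TestExtractWeights:
    def test_requires_stored_weights(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        res = decoding.decode_window(ds, 60.0, dm.WindowSpec(), n_reps=2, seed=0)
        with pytest.raises(ValueError):
            weights.extract_weights(res)

    def test_sign_groups_recover_generator_groups(self, preset_with_weights):
        ds, cfg, res = preset_with_weights
        recs = weights.extract_weights(res)
        membership = synthetic.group_membership(cfg)
        hits = sum(
            1
            for r in recs
            if membership[r.neuron_id] in ("positive", "negative")
            and r.group == membership[r.neuron_id]
        )
        assert hits >= 14  # of 16 signal neurons

    def test_zero_weight_excluded(self):
        res = decoding.DecodeWindowResult(
            center=55.0,
            overall=np.array([1.0]),
            per_class=np.ones((1, 3)),
            neuron_ids=np.array([1, 2]),
            weights_open_mouth=np.array([[0.0, 0.5]]),
        )
        recs = weights.extract_weights(res)
        assert recs[0].group == "excluded_zero"
        assert recs[1].group == "positive"

    def test_never_subsampled_neuron_warns(self):
        res = decoding.DecodeWindowResult(
            center=55.0,
            overall=np.array([1.0]),
            per_class=np.ones((1, 3)),
            neuron_ids=np.array([1, 2]),
            weights_open_mouth=np.array([[np.nan, 0.5]]),
        )
        with pytest.warns(UserWarning, match="never subsampled"):
            recs = weights.extract_weights(res)
        assert len(recs) == 1


class TestWeightedSum:
    def test_zero_weights_give_flat_zero_series(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        recs = [WeightRecord(n.neuron_id, 0.0, "positive") for n in ds.neurons[:5]]
        # force nonzero group membership with zero weights
        recs = [WeightRecord(r.neuron_id, 0.0, "positive") for r in recs]
        spec = dm.WindowSpec(step=100)
        _, series = weights.weighted_sum_timecourse(ds, recs, "positive", spec)
        np.testing.assert_allclose(series, 0.0)

    def test_linearity_in_weights(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        spec = dm.WindowSpec(step=100)
        recs1 = [WeightRecord(n.neuron_id, 0.5, "positive") for n in ds.neurons[:5]]
        recs2 = [WeightRecord(n.neuron_id, 1.5, "positive") for n in ds.neurons[:5]]
        _, s1 = weights.weighted_sum_timecourse(ds, recs1, "positive", spec)
        _, s2 = weights.weighted_sum_timecourse(ds, recs2, "positive", spec)
        np.testing.assert_allclose(3 * s1, s2, rtol=1e-10)

    def test_empty_group_rejected(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        with pytest.raises(ValueError):
            weights.weighted_sum_timecourse(ds, [], "positive", dm.WindowSpec(step=100))

    def test_positive_group_prefers_open_mouth_early(self, preset_with_weights):
        ds, cfg, res = preset_with_weights
        recs = weights.extract_weights(res)
        spec = dm.WindowSpec(step=5, center_min=40, center_max=80)
        centers, series = weights.weighted_sum_timecourse(ds, recs, "positive", spec)
        k = dm.EXPRESSIONS.index("open_mouth")
        others = [i for i in range(3) if i != k]
        assert series[:, k].mean() > series[:, others].mean()


class TestGroupFrAndLatency:
    def test_constant_rate_group_flat_series(self, small_null_dataset):
        recs = [WeightRecord(n.neuron_id, 1.0, "positive") for n in small_null_dataset.neurons]
        spec = dm.WindowSpec(step=50)
        _, series = weights.group_mean_fr_timecourse(small_null_dataset, recs, "positive", spec)
        assert abs(series.mean() - 10.0) < 1.0
        assert series.std() < 2.0

    def test_alpha_one_gives_first_center(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        recs = [WeightRecord(n.neuron_id, 1.0, "positive") for n in ds.neurons[:8]]
        spec = dm.WindowSpec(step=50)
        lat = weights.group_latency(ds, recs, "positive", spec, alpha=1.0)
        assert lat.latency == spec.centers[0]

    def test_small_group_rejected(self, small_preset_dataset):
        ds, _ = small_preset_dataset
        recs = [WeightRecord(n.neuron_id, 1.0, "positive") for n in ds.neurons[:3]]
        with pytest.raises(ValueError):
            weights.group_latency(ds, recs, "positive", dm.WindowSpec(step=50))

    def test_positive_latency_precedes_negative(self, preset_with_weights):
        ds, cfg, res = preset_with_weights
        recs = weights.extract_weights(res)
        spec = dm.WindowSpec(step=3, center_min=0, center_max=200)
        lat_pos = weights.group_latency(ds, recs, "positive", spec, sustained_ms=15)
        lat_neg = weights.group_latency(ds, recs, "negative", spec, sustained_ms=15)
        assert lat_pos.latency is not None and lat_neg.latency is not None
        assert lat_pos.latency < lat_neg.latency


class TestWeightResponseCorrelation:
    def test_preference_mode_positive_correlation(self, preset_with_weights):
        ds, cfg, res = preset_with_weights
        recs = weights.extract_weights(res)
        corr = weights.weight_response_correlation(recs, ds, 60.0, dm.WindowSpec(), "preference")
        assert corr.rs > 0.5

    def test_excitation_mode_positive_correlation(self, preset_with_weights):
        ds, cfg, res = preset_with_weights
        recs = weights.extract_weights(res)
        corr = weights.weight_response_correlation(recs, ds, 60.0, dm.WindowSpec(), "excitation")
        assert corr.rs > 0.3
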