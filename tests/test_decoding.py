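import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1sparse import decoding as dec
from v1sparse.core import ResponseTensor
from conftest import random_tensor
from oracles import centroid_oracle, cv_accuracy_oracle, predict_oracle, top_only_oracle


class TestCentroids:
    def test_mean_of_identical_trials(self, rng):
        m = rng.random((6, 4))
        t = ResponseTensor(values=np.stack([rng.random((6, 4)), m, m]))
        model = dec.train_centroids(t, 0)
        assert model.C == pytest.approx(m)

    def test_arithmetic(self, rng):
        m = rng.random((5, 3))
        t = ResponseTensor(values=np.stack([rng.random((5, 3)), np.zeros((5, 3)), 2 * m]))
        assert dec.train_centroids(t, 0).C == pytest.approx(m)

    def test_matches_loop_oracle(self, rng):
        t = random_tensor(rng, R=4, S=6, N=5)
        for held in range(4):
            assert dec.train_centroids(t, held).C == pytest.approx(
                centroid_oracle(t.values, held)
            )

    def test_single_trial_rejected(self, rng):
        t = ResponseTensor(values=rng.random((1, 4, 3)))
        with pytest.raises(ValueError):
            dec.train_centroids(t, 0)


class TestPredict:
    def test_exact_row_match(self, rng):
        C = rng.random((10, 6))
        model = dec.CentroidModel(C=C, held_out_trial=0)
        assert dec.predict(C[7], model) == 7

    def test_tie_breaks_to_smallest_index(self):
        C = np.array([[5.0, 5.0], [0.0, 2.0], [0.0, 0.0], [0.0, 2.0]])
        model = dec.CentroidModel(C=C, held_out_trial=0)
        # query equidistant from rows 1 and 3
        assert dec.predict(np.array([0.0, 1.0]), model) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_argmin(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.random((8, 5))
        x = rng.random(5)
        model = dec.CentroidModel(C=C, held_out_trial=0)
        assert dec.predict(x, model) == predict_oracle(x, C)
        assert dec.predict_batch(x[None], model)[0] == predict_oracle(x, C)


class TestCrossValidation:
    def test_identical_trials_are_perfect(self, rng):
        m = rng.random((12, 6))
        t = ResponseTensor(values=np.stack([m, m, m]))
        assert dec.cross_validated_accuracy(t) == 1.0

    def test_uninformative_data_is_chance(self, rng):
        S = 300
        t = ResponseTensor(values=np.abs(rng.standard_normal((3, S, 20))))
        acc = dec.cross_validated_accuracy(t)
        se = np.sqrt((1 / S) * (1 - 1 / S) / (3 * S))
        assert abs(acc - 1 / S) <= 3 * se

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_end_to_end_loop(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tensor(rng, R=3, S=10, N=5)
        assert dec.cross_validated_accuracy(t) == pytest.approx(
            cv_accuracy_oracle(t.values), abs=1e-12
        )


class TestThresholding:
    def test_p100_keeps_everything(self, rng):
        t = random_tensor(rng)
        out = dec.threshold_responses(t, 100.0, "top_only")
        assert (out.values == t.values).all()

    def test_p0_zeroes_everything(self, rng):
        t = random_tensor(rng)
        out = dec.threshold_responses(t, 0.0, "top_only")
        assert (out.values == 0).all()

    def test_sort_and_count_oracle_distinct_values(self):
        # 10 distinct pooled values, top 20% -> exactly the 2 largest survive
        vals = np.arange(10, dtype=float).reshape(1, 5, 2) + 1
        t = ResponseTensor(values=vals)
        out = dec.threshold_responses(t, 20.0, "top_only")
        assert out.values == pytest.approx(top_only_oracle(vals, 20.0))
        assert np.count_nonzero(out.values) == 2
        assert set(out.values[out.values > 0]) == {9.0, 10.0}

    @pytest.mark.parametrize("mode", ["absolute", "relative", "relative_per_neuron"])
    @pytest.mark.parametrize("p", [0.0, 7.5, 30.0, 100.0])
    def test_complementarity(self, rng, mode, p):
        # every input entry survives in exactly one of top_only/top_excluded
        t = random_tensor(rng, R=3, S=6, N=5)
        only = dec.threshold_responses(t, p, "top_only", mode=mode).values
        excl = dec.threshold_responses(t, p, "top_excluded", mode=mode).values
        assert (only + excl) == pytest.approx(t.values)
        nz = t.values != 0
        assert not ((only != 0) & (excl != 0)).any()
        assert ((only[nz] != 0) | (excl[nz] != 0)).all()

    def test_exact_count_kept_with_ties(self, rng):
        # tied values at the cut: stable tie-breaking keeps the exact count
        vals = np.ones((2, 5, 3))
        t = ResponseTensor(values=vals)
        out = dec.threshold_responses(t, 50.0, "top_only")
        assert np.count_nonzero(out.values) == 15

    def test_relative_mode_ranks_by_peak_normalized(self):
        # neuron 0 peaks at 10, neuron 1 at 1: a response of 0.9 on neuron 1
        # (90% of peak) outranks 5.0 on neuron 0 (50% of peak)
        vals = np.array([[[10.0, 1.0], [5.0, 0.9]]])  # 1 trial, 2 stim, 2 neurons
        t = ResponseTensor(values=vals)
        out = dec.threshold_responses(t, 75.0, "top_only", mode="relative")
        assert out.values[0, 1, 0] == 0.0  # the 50%-of-peak entry was dropped
        assert out.values[0, 1, 1] == 0.9

    def test_invalid_p(self, rng):
        with pytest.raises(ValueError):
            dec.threshold_responses(random_tensor(rng), 101.0, "top_only")


class TestDecodingCurve:
    def test_default_grid_is_canonical(self):
        assert len(dec.DEFAULT_PERCENTAGES) == 29
        assert dec.DEFAULT_PERCENTAGES[:5] == [0.0, 0.1, 0.2, 0.3, 0.4]
        assert dec.DEFAULT_PERCENTAGES[-5:] == [60.0, 70.0, 80.0, 90.0, 99.0]

    def test_endpoints_reproduce_full_accuracy(self, rng):
        t = random_tensor(rng, R=3, S=20, N=10)
        full = dec.cross_validated_accuracy(t)
        only = dec.decoding_curve(t, [100.0], keep="top_only")
        excl = dec.decoding_curve(t, [0.0], keep="top_excluded")
        assert only.accuracy[0] == full == only.full_accuracy
        assert excl.accuracy[0] == full

    def test_strong_entries_carry_identity(self):
        # noiseless one-hot tuning: keeping any p that retains the strong
        # entries decodes perfectly
        from v1sparse import synthetic as syn

        tm = syn.generate_tuning_matrix(30, 30, 1, weak_scale=0.01, seed=5)
        t, _ = syn.generate_response_tensor(tm, 3, 0.0, seed=5)
        curve = dec.decoding_curve(t, [5.0, 50.0], keep="top_only")
        assert curve.accuracy == [1.0, 1.0]

    def test_accuracies_bounded(self, desk_tensor):
        tensor, _ = desk_tensor
        curve = dec.decoding_curve(tensor, [0.5, 10.0], keep="top_excluded")
        assert all(0.0 <= a <= 1.0 for a in curve.accuracy)
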