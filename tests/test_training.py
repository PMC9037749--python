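"""Losses, sample weighting, masking gradients, and training contracts."""

import numpy as np
import pytest

from weakbeat import autodiff as ad
from weakbeat import model_core as mc
from weakbeat import preprocess as pp
from weakbeat import training as tr
from weakbeat.autodiff import Tensor
from weakbeat.io_formats import BeatAnnotation
from weakbeat.model_core import GlobalPrediction, LocalPrediction
from weakbeat.synthetic_ecg import SynthSpec, generate_dataset, generate_record


def make_prepared(n=6, seed=0, mix=(0.2, 0.2, 0.1, 0.5)):
    records = generate_dataset(n, mix, seed)
    return [tr.prepare_record(pp.preprocess_record(r)) for r in records]


class TestWeakLoss:
    def test_perfect_prediction_near_zero(self):
        gp = GlobalPrediction({"N": 1 - 1e-9, "S": 1 - 1e-9, "V": 1 - 1e-9})
        assert tr.weak_loss(gp, {"N", "S", "V"}) < 1e-5

    def test_uniform_scores_ln2(self):
        gp = GlobalPrediction({"N": 0.5, "S": 0.5, "V": 0.5})
        assert tr.weak_loss(gp, {"N"}) == pytest.approx(np.log(2), abs=1e-9)
        assert tr.weak_loss(gp, {"S", "V"}) == pytest.approx(np.log(2), abs=1e-9)

    def test_direct_formula_example(self):
        gp = GlobalPrediction({"N": 0.9, "S": 0.1, "V": 0.2})
        expected = -(np.log(0.9) + np.log(0.9) + np.log(0.8)) / 3
        assert tr.weak_loss(gp, {"N"}) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1446, abs=1e-4)

    def test_nonnegative(self, rng):
        for _ in range(50):
            scores = dict(zip("NSV", rng.random(3)))
            labels = set(np.array(list("NSV"))[rng.random(3) < 0.5])
            assert tr.weak_loss(GlobalPrediction(scores), labels) >= 0


class TestSampleWeight:
    @pytest.mark.parametrize("labels,expected", [
        ({"S", "N"}, 2.0), ({"V"}, 2.0), ({"V", "N"}, 2.0),
        ({"S", "V", "N"}, 4.0), ({"S", "V"}, 4.0),
        ({"N"}, 0.1), (set(), 0.1), ({"N", "SVTA"}, 0.1),
    ])
    def test_truth_table(self, labels, expected):
        assert tr.sample_weight(labels) == expected

    def test_all_subsets_of_aami_classes(self):
        import itertools
        for subset in itertools.chain.from_iterable(
                itertools.combinations("NSV", k) for k in range(4)):
            s = set(subset)
            w = tr.sample_weight(s)
            n_ect = len(s & {"S", "V"})
            assert w == {0: 0.1, 1: 2.0, 2: 4.0}[n_ect]


class TestSupervisedLoss:
    def _local(self, rows):
        return LocalPrediction(np.asarray(rows, dtype=float))

    def test_confident_correct_near_zero(self):
        probs = np.full((10, 3), 1e-9)
        probs[[2, 7], [0, 2]] = 1 - 2e-9
        beats = BeatAnnotation([2, 7], ["N", "V"])
        assert tr.supervised_loss(self._local(probs), beats) < 1e-6

    def test_uniform_is_ln3(self):
        probs = np.full((20, 3), 1 / 3)
        beats = BeatAnnotation([3, 9, 15], ["N", "S", "V"])
        assert tr.supervised_loss(self._local(probs), beats) == pytest.approx(np.log(3))

    def test_two_beat_example(self):
        probs = np.full((10, 3), 0.1)
        probs[2] = [0.7, 0.2, 0.1]
        probs[6] = [0.5, 0.3, 0.2]
        beats = BeatAnnotation([2, 6], ["N", "V"])
        expected = -(np.log(0.7) + np.log(0.2)) / 2
        assert tr.supervised_loss(self._local(probs), beats) == pytest.approx(expected)
        assert expected == pytest.approx(0.9831, abs=1e-4)

    def test_excluded_beats_skipped(self):
        probs = np.full((10, 3), 1 / 3)
        beats = BeatAnnotation([2, 6], ["F", "Q"])
        with pytest.warns(UserWarning):
            assert tr.supervised_loss(self._local(probs), beats) == 0.0


class TestMaskingGradient:
    """With MGMP the weak loss must ignore every non-R-peak sample."""

    def test_gradient_zero_off_peaks_and_fd_check(self, float64_engine):
        rng = np.random.default_rng(1)
        n = 2500
        peaks = np.arange(40, n - 40, 97)
        probs_data = rng.random((1, n, 3))
        probs_data /= probs_data.sum(-1, keepdims=True)
        peak_mask = np.zeros((1, n), dtype=bool)
        peak_mask[0, peaks] = True
        valid = np.ones((1, n), dtype=bool)
        targets = np.array([[1.0, 1.0, 0.0]])
        weights = np.array([2.0])

        probs = ad.Parameter(probs_data)
        scores = mc.aggregate_graph(probs, "MGMP", peak_mask, valid, 5.0)
        loss = tr.weak_loss_graph(scores, targets, weights)
        loss.backward()
        grad = probs.grad[0]
        off_peak = np.ones(n, dtype=bool)
        off_peak[peaks] = False
        assert np.abs(grad[off_peak]).max() == 0.0
        assert np.abs(grad[peaks]).max() > 0  # signal does reach the peaks

        # finite-difference confirmation at a handful of non-peak samples
        def loss_value():
            s = mc.aggregate_graph(Tensor(probs_data), "MGMP", peak_mask, valid, 5.0)
            return float(tr.weak_loss_graph(s, targets, weights).data)

        base = loss_value()
        for idx in (0, 500, 1234, 2400):
            for c in range(3):
                old = probs_data[0, idx, c]
                probs_data[0, idx, c] = old + 1e-4
                assert loss_value() == pytest.approx(base, abs=1e-12)
                probs_data[0, idx, c] = old

    def test_gap_gradient_reaches_all_samples(self, float64_engine):
        rng = np.random.default_rng(2)
        probs = ad.Parameter(rng.random((1, 50, 3)))
        peak_mask = np.zeros((1, 50), dtype=bool)
        peak_mask[0, [10, 30]] = True
        valid = np.ones((1, 50), dtype=bool)
        loss = tr.weak_loss_graph(
            mc.aggregate_graph(probs, "GAP", peak_mask, valid),
            np.array([[1.0, 0.0, 0.0]]), np.array([1.0]))
        loss.backward()
        assert (np.abs(probs.grad).sum(axis=-1) > 0).all()


class TestWeightedLossIdentity:
    def test_unit_weights_equal_unweighted(self, rng):
        scores = ad.Tensor(rng.random((4, 3)))
        targets = (rng.random((4, 3)) < 0.5).astype(float)
        weighted = tr.weak_loss_graph(scores, targets, np.ones(4))
        per_rec = [tr.weak_loss(GlobalPrediction(dict(zip("NSV", scores.data[i]))),
                                {c for j, c in enumerate("NSV") if targets[i, j]})
                   for i in range(4)]
        assert float(weighted.data) == pytest.approx(np.mean(per_rec), abs=1e-5)


class TestTrainingContracts:
    def _model(self, seed=0):
        return mc.BeatDetector(mc.BackboneConfig(n_blocks=2, kernels=6), seed=seed)

    def test_loss_decreases_on_toy_records(self):
        prepped = make_prepared(8, seed=3)
        model = self._model()
        cfg = tr.TrainConfig(max_epochs=4, batch_size=4, lr=0.01, seed=0)
        _, hist = tr.train_weak(model, prepped, prepped, cfg)
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_early_stop_after_patience(self, monkeypatch):
        prepped = make_prepared(4, seed=4)
        model = self._model()
        monkeypatch.setattr(tr, "_mean_f1", lambda *a, **k: (0.5, {"N": 0.5, "S": 0.5, "V": 0.5}))
        cfg = tr.TrainConfig(max_epochs=50, patience=1, batch_size=4, seed=0)
        _, hist = tr.train_weak(model, prepped, prepped, cfg)
        assert len(hist) == 2  # first epoch improves over -inf, second stops

    def test_seeded_determinism(self):
        prepped = make_prepared(6, seed=5)
        outs = []
        for _ in range(2):
            model = self._model(seed=7)
            cfg = tr.TrainConfig(max_epochs=2, batch_size=4, seed=11)
            model, _ = tr.train_weak(model, prepped, prepped, cfg)
            outs.append([p.data.copy() for p in model.params()])
        for a, b in zip(*outs):
            np.testing.assert_array_equal(a, b)

    def test_pretrain_zero_epochs_is_identity(self):
        prepped = make_prepared(4, seed=6)
        model = self._model()
        before = [p.data.copy() for p in model.params()]
        tr.pretrain_supervised(model, prepped, epochs=0)
        for a, p in zip(before, model.params()):
            np.testing.assert_array_equal(a, p.data)

    def test_pretraining_fits_separable_beats(self):
        # ventricular beats are morphologically separable; supervised
        # pre-training alone must learn them on its own training data
        prepped = make_prepared(10, seed=8, mix=(0.0, 0.5, 0.0, 0.5))
        model = self._model()
        cfg = tr.TrainConfig(batch_size=4, lr=0.01, seed=0)
        tr.pretrain_supervised(model, prepped, epochs=30, cfg=cfg)
        truth, pred, _ = tr.beat_predictions(model, prepped)
        from weakbeat import evaluation as ev
        f1_v = ev.rates(ev.confusion(pred, truth, "V"))[4]
        assert f1_v > 0.9

    def test_two_stage_reduces_to_weak_without_fine_records(self):
        prepped = make_prepared(4, seed=9)
        a = self._model(seed=3)
        cfg = tr.TrainConfig(max_epochs=2, batch_size=4, seed=5)
        a, _ = tr.two_stage_train(a, [], prepped, prepped, cfg)
        b = self._model(seed=3)
        b, _ = tr.train_weak(b, prepped, prepped, cfg)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            tr.train_weak(self._model(), [], [], tr.TrainConfig())


class TestPrepareRecord:
    def test_padding_alignment(self):
        rec = generate_record(SynthSpec(seed=2, duration=12.0, rhythm="sinus"))
        rec = pp.preprocess_record(rec)
        prep = tr.prepare_record(rec, pad_length=20.0)
        assert len(prep.signal) == 2500
        assert prep.knowledge.shape == (2500, 2)
        assert prep.valid_n == 1500
        np.testing.assert_array_equal(prep.knowledge[1500:], 0.0)
        np.testing.assert_array_equal(prep.signal[1500:], 0.0)
        assert prep.peak_indices.max() < 1500

    def test_requires_beats(self):
        rec = generate_record(SynthSpec(seed=2))
        rec.beats = None
        with pytest.raises(ValueError):
            tr.prepare_record(rec)
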