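import numpy as np
import pytest
from sklearn.base import clone

from cpcca import (
    CCAClassifier,
    CPCCAClassifier,
    CPCCAModel,
    EEGEpoch,
    PSDAClassifier,
    ValidationError,
    cca_classify,
    cpcca_classify,
    cpcca_train,
    make_bank,
    psda_classify,
)
from cpcca.simulate import SimConfig, generate_dataset

from conftest import PAPER_FREQS

CHANNELS = ("O1", "O2", "P7", "P8")


def tone_epoch(f, fs=128.0, n=640, phases=(0.0, 0.7, 1.4, 2.1), amp=1.0):
    t = np.arange(1, n + 1) / fs
    data = np.stack([amp * np.sin(2 * np.pi * f * t + p) for p in phases])
    return EEGEpoch(data, fs, CHANNELS)


class TestCCAClassify:
    def test_noiseless_tone_recognized_with_unit_score(self):
        bank = make_bank(PAPER_FREQS, 4, 128.0, 640)
        res = cca_classify(tone_epoch(10.0), bank)
        assert res.predicted_hz == 10.0
        assert res.scores[10.0] == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_accuracy_consistent_with_chance(self):
        # 50 unlabeled noise epochs scored against 6.67 Hz as the "true"
        # class: hits should fall inside the 95% binomial band around 0.2
        rng = np.random.default_rng(7)
        bank = make_bank(PAPER_FREQS, 4, 128.0, 640)
        hits = sum(
            cca_classify(
                EEGEpoch(rng.standard_normal((4, 640)), 128.0, CHANNELS), bank
            ).predicted_hz
            == 6.67
            for _ in range(50)
        )
        assert 5 <= hits <= 16  # binom.interval(0.95, 50, 0.2)

    def test_deterministic_across_windows(self):
        ep = tone_epoch(7.5)
        for w in (128, 640):
            bank = make_bank(PAPER_FREQS, 4, 128.0, w)
            a = cca_classify(ep, bank, w)
            b = cca_classify(ep, bank, w)
            assert a.scores == b.scores and a.predicted_hz == b.predicted_hz

    def test_bank_window_mismatch_rejected(self):
        bank = make_bank(PAPER_FREQS, 4, 128.0, 640)
        with pytest.raises(ValidationError, match="bank"):
            cca_classify(tone_epoch(10.0), bank, window_samples=128)


class TestPSDAClassify:
    def test_noiseless_tone_recognized(self):
        res = psda_classify(tone_epoch(12.0), PAPER_FREQS)
        assert res.predicted_hz == 12.0

    def test_equal_amplitude_tie_resolves_to_lowest_frequency(self):
        t = np.arange(1, 257) / 128.0
        sig = np.sin(2 * np.pi * 7.5 * t) + np.sin(2 * np.pi * 10.0 * t)
        ep = EEGEpoch(np.tile(sig, (4, 1)), 128.0, CHANNELS)
        res = psda_classify(ep, PAPER_FREQS, 256, bin_tolerance_hz=0.025)
        assert res.scores[7.5] == pytest.approx(res.scores[10.0], rel=1e-9)
        assert res.predicted_hz == 7.5

    def test_subsecond_window_rejected(self):
        with pytest.raises(ValidationError, match="1 s"):
            psda_classify(tone_epoch(10.0), PAPER_FREQS, window_samples=64)

    def test_too_small_bin_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="resolution"):
            psda_classify(
                tone_epoch(10.0), PAPER_FREQS, bin_tolerance_hz=0.001
            )


class TestCPCCATrain:
    def test_identical_noiseless_trials_recover_the_tone(self):
        cfg = SimConfig(seed=0, snr_db=np.inf, phase_jitter_sd=0.0,
                        n_trials_per_class=5)
        ds = generate_dataset(cfg)
        model = cpcca_train(ds)
        ep = ds.epochs_for(10.0)[0]
        for ci, c in enumerate(CHANNELS):
            r = np.corrcoef(model.optimal_refs[(c, 10.0)], ep.data[ci])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_single_trial_reference_equals_the_trial(self):
        ds = generate_dataset(SimConfig(seed=3, n_trials_per_class=1))
        model = cpcca_train(ds)
        ep = ds.epochs_for(10.0)[0]
        r = np.corrcoef(model.optimal_refs[("O1", 10.0)], ep.data[0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_references_stored_normalized(self, tiny_dataset):
        model = cpcca_train(tiny_dataset)
        for ref in model.optimal_refs.values():
            assert np.mean(ref) == pytest.approx(0.0, abs=1e-9)
            assert np.std(ref, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_missing_channel_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError, match="Oz"):
            cpcca_train(tiny_dataset, channel_labels=["O1", "Oz"])

    def test_class_without_trials_rejected(self):
        est = CPCCAClassifier(frequencies=PAPER_FREQS)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 4, 128))
        y = [6.67, 6.67, 7.5, 7.5]  # three classes unseen
        with pytest.raises(ValidationError, match="no training trials"):
            est.fit(X, y)


@pytest.fixture(scope="module")
def model(tiny_dataset):
    return cpcca_train(tiny_dataset)


class TestCPCCAClassify:
    def test_self_match_saturates_all_channels(self, model):
        data = np.stack([model.optimal_refs[(c, 7.5)] for c in model.channel_labels])
        ep = EEGEpoch(data, 128.0, model.channel_labels)
        res = cpcca_classify(ep, model)
        assert res.predicted_hz == 7.5
        assert res.scores[7.5] == pytest.approx(4.0, abs=1e-9)

    def test_score_bounds(self, model, tiny_dataset):
        res = cpcca_classify(tiny_dataset.epochs[0], model)
        assert all(0.0 <= v <= 1.0 for v in res.per_channel_scores.values())
        assert all(0.0 <= v <= 4.0 for v in res.scores.values())

    def test_per_channel_scaling_invariance(self, model, tiny_dataset):
        ep = tiny_dataset.epochs[3]
        scaled = EEGEpoch(
            ep.data * np.array([[0.1], [3.0], [42.0], [0.55]]),
            ep.fs, ep.channel_labels, ep.stimulus_hz, ep.trial_index,
        )
        a, b = cpcca_classify(ep, model), cpcca_classify(scaled, model)
        assert a.predicted_hz == b.predicted_hz
        for f in a.scores:
            assert a.scores[f] == pytest.approx(b.scores[f], abs=1e-10)

    def test_window_exceeding_reference_rejected(self, tiny_dataset):
        model = cpcca_train(tiny_dataset, window_samples=256)
        with pytest.raises(ValidationError, match="exceeds"):
            cpcca_classify(tiny_dataset.epochs[0], model, window_samples=512)

    def test_prediction_always_in_stimulus_set(self, model, moderate_dataset):
        for ep in moderate_dataset.epochs[:10]:
            res = cpcca_classify(ep, model, window_samples=128)
            assert res.predicted_hz in PAPER_FREQS


class TestModelPersistence:
    def test_round_trip(self, tiny_dataset, tmp_path):
        model = cpcca_train(tiny_dataset)
        model.save(tmp_path / "m.json")
        back = CPCCAModel.load(tmp_path / "m.json")
        assert back.stimulus_set == model.stimulus_set
        assert back.channel_labels == model.channel_labels
        assert back.n_train_trials == model.n_train_trials
        for key in model.optimal_refs:
            np.testing.assert_allclose(
                back.optimal_refs[key], model.optimal_refs[key], atol=1e-12
            )
        ep = tiny_dataset.epochs[0]
        assert (
            cpcca_classify(ep, back).predicted_hz
            == cpcca_classify(ep, model).predicted_hz
        )

    def test_reject_foreign_file(self, tmp_path):
        (tmp_path / "x.json").write_text('{"format": "other"}')
        with pytest.raises(ValidationError):
            CPCCAModel.load(tmp_path / "x.json")


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = CPCCAClassifier(fs=128.0, frequencies=PAPER_FREQS, n_harmonics=2)
        est2 = clone(est)
        assert est2.get_params()["n_harmonics"] == 2
        est2.set_params(window_seconds=1.0)
        assert est2.window_seconds == 1.0

    def test_fit_predict_shapes(self, tiny_dataset):
        X, y = tiny_dataset.arrays()
        est = CPCCAClassifier(fs=128.0).fit(X, y)
        assert est.references_.shape == (4, 5, 640)
        assert est.n_train_trials_ == (3, 3, 3, 3, 3)
        pred = est.predict(X)
        assert pred.shape == (15,)
        assert set(pred) <= set(PAPER_FREQS)

    def test_estimators_agree_with_functional_wrappers(self, tiny_dataset):
        X, y = tiny_dataset.arrays()
        bank = make_bank(PAPER_FREQS, 4, 128.0, 640)
        est = CCAClassifier(fs=128.0, frequencies=PAPER_FREQS).fit()
        pred = est.predict(X[:5])
        for ep, p in zip(tiny_dataset.epochs[:5], pred):
            assert cca_classify(ep, bank).predicted_hz == p
        est = PSDAClassifier(fs=128.0, frequencies=PAPER_FREQS).fit()
        pred = est.predict(X[:5])
        for ep, p in zip(tiny_dataset.epochs[:5], pred):
            assert psda_classify(ep, PAPER_FREQS).predicted_hz == p
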