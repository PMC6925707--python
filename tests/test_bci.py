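"""Filtering, features, r-squared maps, LDA consensus and session scoring."""

import numpy as np
import pandas as pd
import pytest

from neuroarm.bci import (
    CHANNELS_10_20,
    ConsensusClassifier,
    EEGRecording,
    Epoch,
    FeatureDef,
    PairwiseLDA,
    band_power,
    bandpass_filter,
    classify_epoch,
    decide_from_features,
    epochs_from_events,
    laplacian_filter,
    load_recording,
    make_subepochs,
    notch_filter,
    preprocess,
    r2_from_powers,
    r2_map,
    save_recording,
    score_session,
    select_features,
    train_pairwise,
)

FS = 1000.0


def sine_epoch(freq, amp=1.0, dur=4.0, label="rest", channel="C3"):
    t = np.arange(int(dur * FS)) / FS
    data = np.zeros((len(CHANNELS_10_20), len(t)))
    data[CHANNELS_10_20.index(channel)] = amp * np.sin(2 * np.pi * freq * t)
    return Epoch(data, label, fs=FS)


def recording_with_events(data, events=None):
    ev = pd.DataFrame(events or [], columns=["onset_s", "duration_s", "label"])
    return EEGRecording(data, FS, list(CHANNELS_10_20), ev)


class TestFiltering:
    def test_laplacian_kills_common_signal(self):
        data = np.ones((len(CHANNELS_10_20), 100)) * 7.3
        out = laplacian_filter(data, CHANNELS_10_20)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_notch_attenuates_60hz_by_30db(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)
        y = notch_filter(x, 60.0, FS)
        core = slice(int(FS), int(3 * FS))  # avoid edge transients
        atten = 20 * np.log10(np.abs(y[core]).max() / np.abs(x[core]).max())
        assert atten < -30.0

    def test_mu_band_passes_10hz_within_5pct(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_filter(x, (8.0, 13.0), FS)
        core = slice(int(FS), int(3 * FS))
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        rec = recording_with_events(np.zeros((19, 100)))
        with pytest.raises(ValueError, match="band"):
            preprocess(rec, band=(1.0, 600.0))

    def test_zero_phase_impulse_unshifted(self):
        x = np.zeros(4000)
        x[2000] = 1.0
        y = bandpass_filter(x, (1.0, 40.0), FS)
        assert abs(int(np.argmax(y)) - 2000) <= 1


class TestEpoching:
    def test_subepoch_count_derived_from_window_and_stride(self):
        ep = sine_epoch(10.0)
        subs = make_subepochs(ep, window=2.0, stride=0.0625)
        assert len(subs) == 33  # floor((4-2)/0.0625) + 1
        assert all(s.data.shape[1] == 2000 for s in subs)

    def test_window_equal_to_epoch_gives_one(self):
        assert len(make_subepochs(sine_epoch(10.0), window=4.0, stride=0.5)) == 1

    def test_nonpositive_stride_rejected(self):
        with pytest.raises(ValueError):
            make_subepochs(sine_epoch(10.0), window=2.0, stride=0.0)

    def test_epochs_from_events_respects_labels_and_bounds(self):
        data = np.zeros((19, int(30 * FS)))
        rec = recording_with_events(data, [
            {"onset_s": 1.0, "duration_s": 4.0, "label": "LHIM"},
            {"onset_s": 10.0, "duration_s": 4.0, "label": "cue"},
            {"onset_s": 28.0, "duration_s": 4.0, "label": "RHIM"},  # truncated
        ])
        eps = epochs_from_events(rec)
        assert [e.label for e in eps] == ["LHIM"]


class TestBandPower:
    def test_unit_sine_power_is_half(self):
        ep = sine_epoch(10.0, amp=1.0)
        assert band_power(ep, FeatureDef("C3", 8.0, 13.0)) == pytest.approx(0.5, rel=0.05)

    def test_zero_signal_zero_power(self):
        ep = sine_epoch(10.0, amp=0.0)
        assert band_power(ep, FeatureDef("C3", 8.0, 13.0)) == pytest.approx(0.0, abs=1e-15)

    def test_power_is_quadratic_in_amplitude(self):
        p1 = band_power(sine_epoch(10.0, 1.0), FeatureDef("C3", 8.0, 13.0))
        p2 = band_power(sine_epoch(10.0, 2.0), FeatureDef("C3", 8.0, 13.0))
        assert p2 == pytest.approx(4 * p1, rel=1e-6)

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            sine_epoch(10.0).channel("XX")


class TestR2:
    def test_perfect_separation_gives_one(self):
        powers = np.array([[[1.0]], [[1.0]], [[1.0]],
                           [[9.0]], [[9.0]], [[9.0]]])
        r2 = r2_from_powers(powers, ["a"] * 3 + ["b"] * 3, ("a", "b"))
        assert r2[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_distributions_near_zero(self, rng):
        powers = rng.uniform(1, 2, (40, 3, 5))
        labels = ["a", "b"] * 20
        r2 = r2_from_powers(powers, labels, ("a", "b"))
        assert r2.mean() < 0.05

    def test_matches_bruteforce_pearson_squared(self, rng):
        powers = rng.uniform(0, 5, (12, 2, 3))
        labels = ["a"] * 6 + ["b"] * 6
        r2 = r2_from_powers(powers, labels, ("a", "b"))
        y = np.array([0.0] * 6 + [1.0] * 6)
        for c in range(2):
            for b in range(3):
                expected = np.corrcoef(powers[:, c, b], y)[0, 1] ** 2
                assert r2[c, b] == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        powers = rng.uniform(0, 5, (20, 2, 3))
        labels = ["a", "b"] * 10
        r2a = r2_from_powers(powers, labels, ("a", "b"))
        r2b = r2_from_powers(3.7 * powers + 11.0, labels, ("a", "b"))
        assert np.allclose(r2a, r2b, atol=1e-12)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            r2_from_powers(np.ones((3, 1, 1)), ["a", "a", "b"], ("a", "b"))

    def test_r2_map_shape_on_synthetic_epochs(self):
        eps = ([sine_epoch(10.0, 2.0, label="a")] * 3
               + [sine_epoch(10.0, 0.5, label="b")] * 3)
        m = r2_map(eps, ("a", "b"))
        assert m.shape == (19, 34)
        assert m.min() >= 0.0 and m.max() <= 1.0 + 1e-12


class TestSelectFeatures:
    def make_map(self):
        m = np.zeros((19, 34))
        return m

    def test_single_maximal_cell(self):
        m = self.make_map()
        m[CHANNELS_10_20.index("C4"), 5] = 0.9  # bin 11-13 Hz
        feats = select_features(m, k=1)
        assert feats == [FeatureDef("C4", 11.0, 13.0)]

    def test_adjacent_bins_merge(self):
        m = self.make_map()
        c3 = CHANNELS_10_20.index("C3")
        m[c3, 4] = 0.9  # 9-11
        m[c3, 5] = 0.8  # 11-13
        feats = select_features(m, k=2)
        assert feats == [FeatureDef("C3", 9.0, 13.0)]

    def test_deterministic_tie_break_by_channel_then_frequency(self):
        m = self.make_map()
        m[2, 7] = m[1, 9] = m[1, 3] = 0.5
        feats = select_features(m, k=2)
        assert feats == [FeatureDef(CHANNELS_10_20[1], 7.0, 9.0),
                         FeatureDef(CHANNELS_10_20[1], 19.0, 21.0)]

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            select_features(self.make_map(), k=19 * 34 + 1)


class TestLDA:
    def test_separated_clouds_train_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        clf = train_pairwise(X, y, ("a", "b"))
        assert clf.decide(X) == list(y)

    def test_weights_match_closed_form(self):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [1.5, 1.5],
                      [4.0, 4.0], [5.0, 4.5], [4.5, 5.0], [5.5, 5.5]])
        y = ["a"] * 4 + ["b"] * 4
        clf = train_pairwise(X, y, ("a", "b"))
        X0, X1 = X[:4], X[4:]
        mu0, mu1 = X0.mean(0), X1.mean(0)
        S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (len(X) - 2)
        w = np.linalg.solve(S, mu1 - mu0)
        assert np.allclose(clf.w, w, atol=1e-9)
        assert clf.b == pytest.approx(-w @ (mu0 + mu1) / 2, abs=1e-9)

    def test_matches_sklearn_direction(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal(0, 1.0, (40, 3)), rng.normal(1.0, 1.0, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        ours = train_pairwise(X, [str(v) for v in y], ("0", "1"))
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        cos = (ours.w @ ref.coef_[0]) / (
            np.linalg.norm(ours.w) * np.linalg.norm(ref.coef_[0]))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_identical_means_near_chance(self, rng):
        X = rng.normal(0, 1, (200, 2))
        y = ["a"] * 100 + ["b"] * 100
        clf = train_pairwise(X, y, ("a", "b"))
        acc = np.mean([d == t for d, t in zip(clf.decide(X), y)])
        assert 0.35 < acc < 0.65

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            train_pairwise(np.zeros((4, 2)), ["a"] * 4, ("a", "b"))

    def test_singular_covariance_handled_by_shrinkage(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        clf = train_pairwise(X, ["a", "a", "b", "b"], ("a", "b"))
        assert np.all(np.isfinite(clf.w))


def fixed_consensus(outputs):
    """A consensus classifier whose pairwise models give fixed answers."""
    feats = [FeatureDef("C3", 8.0, 13.0)]
    disc = {}
    for pair, out in outputs.items():
        w = np.zeros(1)
        b = 1.0 if out == pair[1] else -1.0
        disc[pair] = PairwiseLDA(pair, w, b)
    return ConsensusClassifier(feats, disc)


class TestConsensus:
    def test_two_of_three_agreement(self):
        clf = fixed_consensus({("LHIM", "RHIM"): "LHIM",
                               ("LHIM", "rest"): "LHIM",
                               ("RHIM", "rest"): "rest"})
        assert decide_from_features(clf, np.zeros((5, 1))) == "LHIM"

    def test_three_way_disagreement_rejects(self):
        clf = fixed_consensus({("LHIM", "RHIM"): "LHIM",
                               ("LHIM", "rest"): "rest",
                               ("RHIM", "rest"): "RHIM"})
        assert decide_from_features(clf, np.zeros((5, 1))) == "reject"

    def test_subepoch_mode_and_permutation_invariance(self, rng):
        w = np.array([1.0])
        clf = ConsensusClassifier([FeatureDef("C3", 8.0, 13.0)], {
            ("LHIM", "RHIM"): PairwiseLDA(("LHIM", "RHIM"), w, 0.0),
            ("LHIM", "rest"): PairwiseLDA(("LHIM", "rest"), w, 0.0),
            ("RHIM", "rest"): PairwiseLDA(("RHIM", "rest"), w, 0.0),
        })
        # features [1,1,3,3,3] (signs): mode over subepochs decides
        F = np.array([[-1.0], [-1.0], [1.0], [1.0], [1.0]])
        lab = decide_from_features(clf, F)
        perm = F[rng.permutation(len(F))]
        assert decide_from_features(clf, perm) == lab

    def test_pairwise_tie_goes_to_first_listed_class(self):
        w = np.array([1.0])
        p = PairwiseLDA(("LHIM", "RHIM"), w, 0.0)
        assert p.decide(np.array([[0.0]])) == ["LHIM"]

    def test_classifier_json_roundtrip(self):
        clf = fixed_consensus({("LHIM", "RHIM"): "LHIM",
                               ("LHIM", "rest"): "LHIM",
                               ("RHIM", "rest"): "rest"})
        clf2 = ConsensusClassifier.from_json_dict(clf.to_json_dict())
        assert decide_from_features(clf2, np.zeros((3, 1))) == "LHIM"

    def test_short_epoch_rejected(self):
        clf = fixed_consensus({("LHIM", "RHIM"): "LHIM",
                               ("LHIM", "rest"): "LHIM",
                               ("RHIM", "rest"): "rest"})
        short = Epoch(np.zeros((19, 500)), "rest", fs=FS)
        with pytest.raises(ValueError, match="window"):
            classify_epoch(clf, short)


class TestScoring:
    def test_goal_selection_coincidences(self):
        intended = ["LHIM"] * 9 + ["RHIM"] * 6
        decided = ["LHIM"] * 9 + ["LHIM"] * 6
        assert score_session(intended, decided, "uncued_gs") == pytest.approx(60.0)

    def test_cued_all_correct(self):
        assert score_session(["rest"] * 5, ["rest"] * 5, "cued") == 100.0

    def test_uncued_pc_uses_step_outcomes(self):
        ctx = ([{"reduced_distance": True, "completed_needed_axis_change": False}] * 4
               + [{"reduced_distance": False, "completed_needed_axis_change": False}] * 16)
        assert score_session(["x"] * 20, ["x"] * 20, "uncued_pc", ctx) == pytest.approx(20.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_session(["a"], ["a", "b"], "cued")


def test_recording_io_roundtrip(tmp_path, rng):
    data = rng.normal(0, 1, (19, 500))
    ev = pd.DataFrame([{"onset_s": 0.1, "duration_s": 0.2, "label": "LHIM"}])
    rec = EEGRecording(data, FS, list(CHANNELS_10_20), ev)
    save_recording(rec, tmp_path / "rec")
    back = load_recording(tmp_path / "rec")
    assert np.allclose(back.data, data, atol=1e-4)
    assert back.fs == FS
    assert list(back.events["label"]) == ["LHIM"]


def test_montage_validation():
    with pytest.raises(ValueError, match="montage"):
        EEGRecording(np.zeros((3, 10)), FS, ["A", "B", "C"])
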