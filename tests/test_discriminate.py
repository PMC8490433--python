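"""Frequency split, noise features, SVC classification, decision regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage, signal

import nanokin as nk
from nanokin.errors import ConfigurationError, TrivialModelWarning
from nanokin.schemes import StateNoise, TelegraphNoise

from conftest import make_acq

FS = 25_000.0


def butter_gain_squared(f, fc=100.0, order=4):
    """Zero-phase (forward-backward) Butterworth amplitude response."""
    return 1.0 / (1.0 + (f / fc) ** (2 * order))


class TestFrequencySplit:
    def test_dc_trace_passes_entirely_to_low_pass(self):
        x = np.full(20_000, 137.0)
        sp = nk.frequency_split(x, 100.0, sampling_rate=FS)
        assert np.max(np.abs(sp.high_pass)) < 1e-9 * 137.0
        np.testing.assert_allclose(sp.low_pass, x, rtol=1e-9)

    def test_additivity_is_exact(self):
        rng = np.random.default_rng(0)
        x = 120.0 + rng.normal(0, 3, 100_000)
        sp = nk.frequency_split(x, 100.0, sampling_rate=FS)
        assert np.array_equal(sp.low_pass + sp.high_pass, x)

    @pytest.mark.parametrize("f", [10.0, 50.0, 100.0, 300.0])
    def test_sinusoid_gain_matches_analytic_butterworth(self, f):
        t = np.arange(100_000) / FS
        x = np.sin(2 * np.pi * f * t)
        sp = nk.frequency_split(x, 100.0, order=4, sampling_rate=FS)
        measured = np.sqrt(2) * np.std(sp.low_pass[20_000:80_000])
        expected = butter_gain_squared(f)
        assert measured == pytest.approx(expected, rel=5e-3, abs=5e-4)

    def test_low_frequency_sinusoid_retained(self):
        t = np.arange(100_000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        sp = nk.frequency_split(x, 100.0, order=4, sampling_rate=FS)
        amp = np.sqrt(2) * np.std(sp.low_pass[20_000:80_000])
        assert amp >= 0.999

    def test_white_noise_variance_partition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 100_000)
        sp = nk.frequency_split(x, 100.0, sampling_rate=FS)
        var_sum = np.var(sp.low_pass) + np.var(sp.high_pass)
        assert var_sum == pytest.approx(np.var(x), rel=0.02)
        # hp SD against the actual filter's integrated response
        sos = signal.butter(4, 100.0, btype="low", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=8192, fs=FS)
        expected_ratio = np.sqrt(np.mean(np.abs(1 - np.abs(h) ** 2) ** 2))
        assert np.std(sp.high_pass) / 2.0 == pytest.approx(expected_ratio, rel=0.02)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            nk.frequency_split(np.zeros(1000), 13_000.0, sampling_rate=FS)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_additivity_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 200) + rng.normal(0, rng.uniform(0.1, 10), 4096)
        sp = nk.frequency_split(x, 100.0, sampling_rate=FS)
        np.testing.assert_array_equal(sp.low_pass + sp.high_pass, x)


class TestFeatures:
    def test_noiseless_event_has_zero_features(self, two_state, quiet_noise):
        acq = make_acq(2.0, corner=None)
        trace = nk.simulate_trace(two_state, 0.0, quiet_noise, acq, seed=2)
        ev = nk.EventRecord(start=10_000, end=30_000, t_off=0.8, t_on=np.nan)
        table = nk.EventTable([ev], nk.BaselineEstimate(120.0, 0.0), FS)
        sp = nk.frequency_split(trace)
        feats = nk.extract_features(sp, table)
        assert feats[0].lp_sd < 1e-6 and feats[0].hp_sd < 1e-6

    def test_white_noise_event_concentrates_in_high_pass(self):
        rng = np.random.default_rng(3)
        sigma = 3.0
        x = 100.0 + rng.normal(0, sigma, 200_000)
        trace = nk.SimulatedTrace(samples=x, acquisition=make_acq(8.0, corner=None))
        ev = nk.EventRecord(start=1000, end=199_000, t_off=7.9, t_on=np.nan)
        table = nk.EventTable([ev], nk.BaselineEstimate(100.0, sigma), FS)
        feats = nk.extract_features(nk.frequency_split(trace), table)
        # white-noise bandwidth partition: hp keeps ~99.6% of the SD
        assert feats[0].hp_sd == pytest.approx(0.996 * sigma, rel=0.01)
        assert feats[0].lp_sd < 0.15 * sigma

    def test_slow_telegraph_inflates_lp_only(self, two_state):
        # a <=20 Hz bound-state flicker shows up in the low-pass SD while
        # barely moving the high-pass SD (epinephrine-vs-isoprenaline logic)
        acq = make_acq(40.0, corner=None)
        base = nk.NoiseModel(baseline_sd=1.0)
        flicker = nk.NoiseModel(
            baseline_sd=1.0,
            state_noise={
                "bound": StateNoise(telegraph=TelegraphNoise(10.0, 10.0, 10.0))
            },
        )
        quiet_tr = nk.simulate_trace(two_state, 1e-3, base, acq, seed=4)
        flick_tr = nk.simulate_trace(two_state, 1e-3, flicker, acq, seed=4)
        baseline = nk.BaselineEstimate(120.0, 1.0)
        fq = nk.extract_features(
            nk.frequency_split(quiet_tr),
            nk.detect_events(quiet_tr, baseline, -60.0),
        )
        ff = nk.extract_features(
            nk.frequency_split(flick_tr),
            nk.detect_events(flick_tr, baseline, -60.0),
        )
        long_q = [f for f in fq if f.event_id >= 0]
        lp_q = np.median([f.lp_sd for f in long_q])
        lp_f = np.median([f.hp_sd * 0 + f.lp_sd for f in ff])
        hp_q = np.median([f.hp_sd for f in fq])
        hp_f = np.median([f.hp_sd for f in ff])
        assert lp_f > 3 * lp_q
        assert abs(hp_f - hp_q) < 0.05 * hp_q + 0.2


def make_clusters(rng, centroids, n_per_class, sd=1.0):
    X, y = [], []
    for label, (cx, cy) in centroids.items():
        pts = np.column_stack(
            [rng.normal(cx, sd, n_per_class), rng.normal(cy, sd, n_per_class)]
        )
        X.append(np.abs(pts))
        y.extend([label] * n_per_class)
    return np.vstack(X), np.array(y)


CENTROIDS = {"a": (2.0, 2.0), "b": (10.0, 2.0), "c": (2.0, 10.0)}  # 8 = 6+ SDs apart


class TestClassifier:
    def test_single_class_predicts_that_class(self):
        rng = np.random.default_rng(5)
        X = rng.normal(5, 1, size=(40, 2))
        with pytest.warns(TrivialModelWarning):
            clf = nk.train_classifier(X, ["only"] * 40)
        assert list(clf.predict(X[:5])) == ["only"] * 5

    def test_well_separated_classes_high_holdout_accuracy(self):
        from sklearn.model_selection import train_test_split

        rng = np.random.default_rng(6)
        X, y = make_clusters(rng, CENTROIDS, 300)
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.3, stratify=y, random_state=0
        )
        clf = nk.train_classifier(Xtr, ytr, seed=0)
        cm = nk.confusion_matrix(yte, clf.predict(Xte))
        assert cm.overall_accuracy >= 0.99

    def test_retraining_is_deterministic(self):
        rng = np.random.default_rng(7)
        X, y = make_clusters(rng, CENTROIDS, 50)
        a = nk.train_classifier(X, y, seed=1)
        b = nk.train_classifier(X, y, seed=1)
        np.testing.assert_array_equal(a.support_vectors_, b.support_vectors_)
        grid = np.column_stack([np.linspace(0, 12, 100), np.linspace(0, 12, 100)])
        np.testing.assert_array_equal(a.predict(grid), b.predict(grid))

    def test_centroid_is_classified_as_its_class(self):
        rng = np.random.default_rng(8)
        X, y = make_clusters(rng, CENTROIDS, 100)
        clf = nk.train_classifier(X, y, seed=0)
        for label, c in CENTROIDS.items():
            assert clf.predict(np.array([c]))[0] == label

    def test_empty_feature_list_gives_empty_labels(self):
        rng = np.random.default_rng(9)
        X, y = make_clusters(rng, CENTROIDS, 20)
        clf = nk.train_classifier(X, y, seed=0)
        assert clf.predict(np.empty((0, 2))).size == 0

    def test_prediction_invariant_to_unit_rescaling(self):
        # pA -> nA rescaling of both axes leaves z-scored predictions alone
        rng = np.random.default_rng(10)
        X, y = make_clusters(rng, CENTROIDS, 60)
        a = nk.train_classifier(X, y, seed=2)
        b = nk.train_classifier(X * 1e-3, y, seed=2)
        probe = make_clusters(np.random.default_rng(11), CENTROIDS, 30)[0]
        np.testing.assert_array_equal(a.predict(probe), b.predict(probe * 1e-3))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(12)
        X, y = make_clusters(rng, CENTROIDS, 30)
        clf = nk.train_classifier(X, y, seed=3)
        clf.save(tmp_path / "model.joblib")
        clf2 = nk.EventClassifier.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(clf.predict(X), clf2.predict(X))
        assert clf.training_hash_ == clf2.training_hash_

    def test_mixture_simulation_per_class_recall(self):
        # end to end: mixture trace -> detection -> split features -> SVC
        from sklearn.model_selection import train_test_split

        i_p = 120.0
        schemes = {
            "quiet": nk.two_state_scheme(i_p, 80.0, 1e4, 3.0),
            "flicker": nk.two_state_scheme(i_p, 80.0, 1e4, 3.0),
            "hiss": nk.two_state_scheme(i_p, 80.0, 1e4, 3.0),
        }
        noise = nk.NoiseModel(
            baseline_sd=1.5,
            state_noise={
                "bound:flicker": StateNoise(telegraph=TelegraphNoise(12.0, 40.0, 40.0)),
                "bound:hiss": StateNoise(broadband_sd=8.0),
            },
        )
        acq = make_acq(150.0)
        trace, labels = nk.simulate_mixture(
            schemes, {"quiet": 1 / 3, "flicker": 1 / 3, "hiss": 1 / 3},
            1e-3, noise, acq, seed=13,
        )
        baseline = nk.BaselineEstimate(i_p, 0.6)
        table = nk.detect_events(trace, baseline, -40.0)
        truth = trace.truth.events("baseline")
        # align detected events to truth labels by midpoint containment
        fs = acq.sampling_rate
        aligned = []
        for ev in table:
            mid = 0.5 * (ev.start + ev.end) / fs
            lab = next(
                (s.state.split(":", 1)[1] for s in truth if s.t_start <= mid < s.t_end),
                None,
            )
            aligned.append(lab)
        feats = nk.extract_features(nk.frequency_split(trace), table, trace=trace)
        # events shorter than the split-filter guard cannot carry clean
        # frequency-split features; they are flagged and excluded here
        keep = [
            i
            for i, lab in enumerate(aligned)
            if lab is not None and "short_for_guard" not in feats[i].extras
        ]
        X = np.array([[feats[i].lp_sd, feats[i].hp_sd] for i in keep])
        y = np.array([aligned[i] for i in keep])
        assert min(np.bincount(np.unique(y, return_inverse=True)[1])) >= 60
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.3, stratify=y, random_state=1
        )
        cm = nk.confusion_matrix(yte, nk.train_classifier(Xtr, ytr, seed=0).predict(Xte))
        assert (cm.per_class_accuracy >= 0.95).all()


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = nk.confusion_matrix(["a", "b", "c"], ["a", "b", "c"])
        assert np.trace(cm.counts.to_numpy()) == 3
        assert cm.overall_accuracy == 1.0
        assert (cm.per_class_accuracy == 1.0).all()

    def test_small_enumeration(self):
        cm = nk.confusion_matrix(["A", "A", "B"], ["A", "B", "B"])
        np.testing.assert_array_equal(cm.counts.to_numpy(), [[1, 1], [0, 1]])
        assert cm.overall_accuracy == pytest.approx(2 / 3)

    def test_unseen_label_appears_as_zero_row(self):
        cm = nk.confusion_matrix(["a", "a"], ["a", "c"])
        assert list(cm.counts.index) == ["a", "c"]
        assert cm.counts.loc["c"].sum() == 0

    def test_row_sums_equal_class_counts_random_property(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            n = rng.integers(1, 50)
            truth = rng.choice(list("xyz"), n)
            pred = rng.choice(list("xyz"), n)
            cm = nk.confusion_matrix(truth, pred)
            for lab in cm.counts.index:
                assert cm.counts.loc[lab].sum() == np.sum(truth == lab)


class TestDecisionGrid:
    def test_linear_two_class_boundary_is_straight(self):
        rng = np.random.default_rng(15)
        X, y = make_clusters(rng, {"lo": (2.0, 2.0), "hi": (10.0, 10.0)}, 200)
        clf = nk.train_classifier(X, y, seed=0, kernel="linear")
        lp, hp, labels = nk.decision_boundary_grid(clf, (0, 12), (0, 12), 200)
        # boundary cells: horizontal transitions between the two labels
        pts = []
        for i in range(200):
            flips = np.flatnonzero(labels[i, 1:] != labels[i, :-1])
            for j in flips:
                pts.append((lp[j], hp[i]))
        pts = np.array(pts)
        assert len(pts) > 50
        slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
        resid = np.abs(pts[:, 1] - (slope * pts[:, 0] + intercept))
        cell = 12.0 / 199
        assert np.max(resid) < 2 * cell

    def test_three_separable_classes_give_three_connected_regions(self):
        rng = np.random.default_rng(16)
        X, y = make_clusters(rng, CENTROIDS, 200)
        clf = nk.train_classifier(X, y, seed=0, kernel="linear")
        _, _, labels = nk.decision_boundary_grid(clf, (0, 12), (0, 12), 150)
        assert len(np.unique(labels)) == 3
        for lab in np.unique(labels):
            _, n_components = ndimage.label(labels == lab)
            assert n_components == 1

    def test_labels_stable_far_from_boundary_across_resolutions(self):
        rng = np.random.default_rng(17)
        X, y = make_clusters(rng, CENTROIDS, 100)
        clf = nk.train_classifier(X, y, seed=0)
        for label, c in CENTROIDS.items():
            for res in (50, 101, 200):
                lp, hp, labels = nk.decision_boundary_grid(clf, (0, 12), (0, 12), res)
                i = int(np.argmin(np.abs(hp - c[1])))
                j = int(np.argmin(np.abs(lp - c[0])))
                assert labels[i, j] == label

    def test_training_points_match_their_grid_cells(self):
        rng = np.random.default_rng(18)
        X, y = make_clusters(rng, CENTROIDS, 100)
        clf = nk.train_classifier(X, y, seed=0)
        pred = clf.predict(X)
        assert (pred == y).mean() >= 0.99
        lp, hp, labels = nk.decision_boundary_grid(clf, (0, 14), (0, 14), 300)
        agree = 0
        for (px, py), lab in zip(X, pred):
            i = int(np.argmin(np.abs(hp - py)))
            j = int(np.argmin(np.abs(lp - px)))
            agree += labels[i, j] == lab
        assert agree / len(X) >= 0.99

    def test_degenerate_range_rejected(self):
        rng = np.random.default_rng(19)
        X, y = make_clusters(rng, CENTROIDS, 20)
        clf = nk.train_classifier(X, y, seed=0)
        with pytest.raises(ConfigurationError):
            nk.decision_boundary_grid(clf, (5, 5), (0, 1), 10)
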