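"""Behavioural-mode features, ward clustering, elbow, KNN and ethograms."""

import numpy as np
import pytest

from cionetho import (
    CANONICAL_MODE_NAMES,
    MISSING,
    FeatureMatrix,
    ModeModel,
    ModeRegime,
    SimConfig,
    build_features,
    classify,
    cluster_modes,
    concat_features,
    elbow_select,
    generate_cohort,
    lag_kinematics,
    mode_distribution,
    name_modes,
)

from conftest import straight_line


def three_regime_features(n_per=2000, seed=0):
    """Well-separated 3-blob feature set with ground-truth labels."""
    rng = np.random.default_rng(seed)
    centres = np.array([[100.0, 0.0, 0.0], [800.0, 0.0, 0.0], [1600.0, 0.0, 0.0]])
    sig = np.array([8.0, 15.0, 2.0])
    X = np.vstack(
        [rng.normal(c, sig, size=(n_per, 3)) for c in centres]
    )
    truth = np.repeat(np.arange(3), n_per)
    perm = rng.permutation(len(X))
    X, truth = X[perm], truth[perm]
    fm = FeatureMatrix(
        X=X,
        valid=np.ones(len(X), dtype=bool),
        animal_ids=np.full(len(X), "a", dtype=object),
        frames=np.arange(len(X)),
    )
    return fm, truth


class TestBuildFeatures:
    def test_constant_line_rows_equal(self):
        kin = lag_kinematics(straight_line(600.0, n=400))
        fm = build_features(kin, animal_id="a")
        rows = fm.X[fm.valid]
        np.testing.assert_allclose(rows[:, 0], 600.0, rtol=1e-9)
        np.testing.assert_allclose(rows[:, 1], 0.0, atol=1e-9)
        np.testing.assert_allclose(rows[:, 2], 0.0, atol=1e-9)

    def test_edges_invalid(self):
        kin = lag_kinematics(straight_line(600.0, n=400))
        fm = build_features(kin)
        assert not fm.valid[:25].any()
        assert not fm.valid[-25:].any()

    def test_window_mean_matches_brute_force(self, rng):
        n = 1000
        kin = lag_kinematics(straight_line(600.0, n=n))
        kin.rho[:] = rng.normal(500, 100, n)
        kin.accel[:] = rng.normal(0, 50, n)
        kin.turn[:] = rng.normal(0, 0.5, n)
        kin.valid_mask[:] = True
        fm = build_features(kin)
        t = 300
        for j, arr in enumerate((kin.rho, kin.accel, kin.turn)):
            assert fm.X[t, j] == pytest.approx(arr[t - 25 : t + 26].mean(), rel=1e-9)

    def test_short_trace_rejected(self):
        kin = lag_kinematics(straight_line(600.0, n=40))
        with pytest.raises(ValueError):
            build_features(kin)


class TestElbowSelect:
    def test_constructed_sharp_knee(self):
        ks = np.arange(2, 15)
        wcd = np.where(ks <= 4, 100.0 - 30.0 * (ks - 2), 40.0 - 0.5 * (ks - 4))
        assert elbow_select((ks, wcd)) == 4

    def test_straight_line_degenerate(self):
        ks = np.arange(2, 10)
        with pytest.warns(UserWarning, match="straight-line|flat"):
            assert elbow_select((ks, 100.0 - 5.0 * ks)) == 3

    def test_matches_brute_force_knee_scan(self, rng):
        # independent oracle: scan every interior split of the log-drop
        # sequence and score it with scipy's pooled two-sample t statistic
        from scipy import stats as sps

        ks = np.arange(2, 21)
        decays = np.sort(rng.uniform(0.1, 20.0, len(ks)))[::-1]
        wcd = np.cumsum(decays[::-1])[::-1]
        drops = np.log(wcd[:-1] - wcd[1:])
        best, best_k = -np.inf, None
        for i in range(1, len(drops)):
            if i == 1:
                # single-point head: plain standardised mean difference
                tail = drops[1:]
                sp = tail.std(ddof=1)
                t = (drops[0] - tail.mean()) / (sp * np.sqrt(1 + 1 / len(tail)))
            else:
                t = sps.ttest_ind(drops[:i], drops[i:], equal_var=True).statistic
            if t > best:
                best, best_k = t, ks[i]
        assert elbow_select((ks, wcd)) == best_k

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            elbow_select((np.array([2, 3]), np.array([5.0, 1.0])))


class TestClusterModes:
    def test_three_separable_regimes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        fm, truth = three_regime_features()
        model = cluster_modes(fm, subsample=4000, seed=1)
        assert model.k == 3
        ethos = classify(model, fm)
        labels = ethos["a"].labels
        name_to_idx = {v: k for k, v in model.mode_names.items()}
        pred = np.array([name_to_idx[m] for m in labels])
        assert adjusted_rand_score(truth, pred) >= 0.95

    def test_holdout_knn_accuracy(self):
        fm, truth = three_regime_features(seed=3)
        train = FeatureMatrix(
            X=fm.X[:4000], valid=fm.valid[:4000],
            animal_ids=fm.animal_ids[:4000], frames=fm.frames[:4000],
        )
        model = cluster_modes(train, subsample=4000, seed=1)
        held = FeatureMatrix(
            X=fm.X[4000:], valid=fm.valid[4000:],
            animal_ids=fm.animal_ids[4000:], frames=np.arange(len(fm.X) - 4000),
        )
        ethos = classify(model, held)
        name_to_idx = {v: k for k, v in model.mode_names.items()}
        pred = np.array([name_to_idx[m] for m in ethos["a"].labels])
        # clusters are speed-ordered, so indices align with truth blobs
        assert (pred == truth[4000:]).mean() >= 0.95

    def test_training_self_classification_exact_with_1nn(self):
        fm, _ = three_regime_features(n_per=500, seed=5)
        model = cluster_modes(fm, subsample=1500, seed=2, k_nn=1)
        pred = model.classifier.predict(model.training_X)
        assert (pred == model.training_labels).all()

    def test_too_few_valid_rows_rejected(self):
        fm, _ = three_regime_features(n_per=5)
        with pytest.raises(ValueError):
            cluster_modes(fm, k_range=range(2, 21))

    def test_scaler_standardizes_training_subsample(self):
        fm, _ = three_regime_features(seed=2)
        model = cluster_modes(fm, subsample=3000, seed=0, standardize=True)
        assert np.allclose(model.training_X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(model.training_X.std(axis=0), 1.0, atol=1e-9)

    def test_json_round_trip(self, tmp_path):
        fm, _ = three_regime_features(n_per=300, seed=4)
        model = cluster_modes(fm, subsample=900, seed=0)
        model.to_json(tmp_path / "model.json")
        back = ModeModel.from_json(tmp_path / "model.json")
        assert back.k == model.k
        np.testing.assert_allclose(back.centres_raw, model.centres_raw)
        e1 = classify(model, fm)["a"].labels
        e2 = classify(back, fm)["a"].labels
        assert (e1 == e2).all()


class TestNamingAndEthograms:
    def test_eleven_clusters_get_canonical_names(self):
        fm, _ = three_regime_features(n_per=200, seed=6)
        model = cluster_modes(fm, subsample=600, seed=0)
        model.k = 11  # naming depends only on the count
        names = name_modes(model)
        assert names[0] == "Inactive 1"
        assert names[10] == "Fast swimming 2"
        assert tuple(names[i] for i in range(11)) == CANONICAL_MODE_NAMES

    def test_generic_names_ordered_by_speed(self):
        fm, _ = three_regime_features(seed=7)
        model = cluster_modes(fm, subsample=3000, seed=0)
        assert [model.mode_names[i] for i in range(3)] == [
            "mode_01", "mode_02", "mode_03",
        ]
        assert np.all(np.diff(model.centres_raw[:, 0]) > 0)

    def test_all_invalid_features_give_all_missing(self):
        fm, _ = three_regime_features(n_per=300, seed=8)
        model = cluster_modes(fm, subsample=900, seed=0)
        fm2 = FeatureMatrix(
            X=np.full((50, 3), np.nan),
            valid=np.zeros(50, dtype=bool),
            animal_ids=np.full(50, "z", dtype=object),
            frames=np.arange(50),
        )
        ethos = classify(model, fm2)
        assert (ethos["z"].labels == MISSING).all()

    def test_dimension_mismatch_rejected(self):
        fm, _ = three_regime_features(n_per=300, seed=9)
        model = cluster_modes(fm, subsample=900, seed=0)
        bad = FeatureMatrix.__new__(FeatureMatrix)
        bad.X = np.zeros((5, 2))
        bad.valid = np.ones(5, dtype=bool)
        bad.animal_ids = np.full(5, "a", dtype=object)
        bad.frames = np.arange(5)
        with pytest.raises(ValueError):
            classify(model, bad)

    def test_mode_distribution_fractions(self):
        from cionetho.modes import Ethogram

        e1 = Ethogram("a", np.array(["x"] * 80 + [MISSING] * 20, dtype=object))
        e2 = Ethogram("b", np.array(["x"] * 30 + ["y"] * 70, dtype=object))
        dist = mode_distribution({"g1": [e1], "g2": [e2]})
        assert dist.fractions.loc["x", "g1"] == pytest.approx(1.0)
        assert dist.fractions.loc["y", "g2"] == pytest.approx(0.7)
        np.testing.assert_allclose(dist.fractions.sum(axis=0), 1.0)

    def test_empty_group_rejected(self):
        from cionetho.modes import Ethogram

        e = Ethogram("a", np.array([MISSING] * 10, dtype=object))
        with pytest.raises(ValueError):
            mode_distribution({"g": [e]})

    def test_fast_boosted_cohort_has_more_fast_modes(self):
        cfg = SimConfig(duration=60.0, seed=31)
        base = generate_cohort(4, cfg, id_prefix="base")
        boosted = generate_cohort(
            4, cfg,
            overrides={"occupancy_boost": {"Fast swimming 1": 6.0, "Fast swimming 2": 6.0}},
            id_prefix="boost",
        )
        feats = []
        for lab in base + boosted:
            feats.append(
                build_features(
                    lag_kinematics(lab.trajectory), animal_id=lab.trajectory.animal_id
                )
            )
        F = concat_features(feats)
        model = cluster_modes(F, subsample=15000, seed=0, k_range=range(2, 13))
        ethos = classify(model, F)
        groups = {
            "base": [ethos[l.trajectory.animal_id] for l in base],
            "boost": [ethos[l.trajectory.animal_id] for l in boosted],
        }
        dist = mode_distribution(groups)
        # mass in the fastest third of modes rises under the boost
        fast = dist.fractions.index[-(model.k // 3):]
        assert dist.fractions.loc[fast, "boost"].sum() > dist.fractions.loc[fast, "base"].sum()
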