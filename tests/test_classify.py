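"""Least-squares SVM, LOOCV AUC, nested configuration selection, permutation null."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from dfncflow.classify import (
    FeatureSet,
    adjust_features,
    bootstrap_null,
    build_features,
    enumerate_configs,
    loocv_auc,
    nested_selection,
    train_ls_svm,
)
from dfncflow import dfnc
from dfncflow.synthgen import SynthConfig, generate_cohort


def _covariates(rng, n):
    return pd.DataFrame({
        "gender": rng.integers(0, 2, size=n),
        "age": rng.normal(28, 9, size=n),
        "TRN": np.abs(rng.normal(0.1, 0.03, size=n)),
        "ROT": np.abs(rng.normal(0.002, 0.0005, size=n)),
        "spk": rng.poisson(2, size=n).astype(float),
    })


def _separable_features(rng, n_per_class=10, dim=4, gap=4.0):
    x = np.vstack([
        rng.normal(-gap / 2, 0.5, size=(n_per_class, dim)),
        rng.normal(gap / 2, 0.5, size=(n_per_class, dim)),
    ])
    y = np.repeat([0, 1], n_per_class)
    return FeatureSet(x, y)


class TestAdjustFeatures:
    def test_covariate_free_features_only_mean_centered(self, rng):
        cov = _covariates(rng, 200)
        x = np.tile(np.arange(200.0)[:, None] % 2, (1, 3))
        fs = FeatureSet(x, rng.integers(0, 2, size=200))
        out = adjust_features(fs, cov)
        # residualizing on unrelated covariates leaves structure intact
        assert np.corrcoef(out.features[:, 0], x[:, 0])[0, 1] > 0.9

    def test_age_driven_feature_removed(self, rng):
        cov = _covariates(rng, 40)
        x = 3.0 * cov["age"].to_numpy()[:, None]
        fs = FeatureSet(x, rng.integers(0, 2, size=40))
        out = adjust_features(fs, cov)
        assert np.max(np.abs(out.features)) < 1e-8

    def test_diagnosis_separation_survives_age_removal(self, rng):
        cov = _covariates(rng, 60)
        y = rng.integers(0, 2, size=60)
        x = (2.0 * y + 0.5 * cov["age"].to_numpy())[:, None]
        out = adjust_features(FeatureSet(x, y), cov)
        gap = out.features[y == 1].mean() - out.features[y == 0].mean()
        assert gap == pytest.approx(2.0, abs=0.3)


class TestLsSvm:
    def test_two_point_problem_matches_hand_solved_kkt_system(self):
        # x = -1 (label 0), x = +1 (label 1), C = 0.01:
        # the KKT system forces alpha1 = alpha2 = a with 52 a - b = 1 and
        # 52 a + b = 1, hence b = 0, a = 1/52, w = 2a = 1/26.
        x = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = train_ls_svm(x, y, C=0.01)
        a_mat = np.array([
            [0.0, -1.0, 1.0],
            [-1.0, 1.0 + 50.0, 1.0],
            [1.0, 1.0, 1.0 + 50.0],
        ])
        sol = np.linalg.solve(a_mat, [0.0, 1.0, 1.0])
        assert model.bias == pytest.approx(sol[0], abs=1e-6)
        np.testing.assert_allclose(model.alpha, sol[1:], atol=1e-6)
        assert model.weights[0] == pytest.approx(1.0 / 26.0, abs=1e-6)

    def test_separable_clusters_classified_correctly(self, rng):
        fs = _separable_features(rng)
        model = train_ls_svm(fs.features, fs.labels)
        signs = np.sign(model.decision(fs.features))
        np.testing.assert_array_equal(signs, np.where(fs.labels == 1, 1, -1))

    def test_mirror_symmetric_data_has_zero_bias(self, rng):
        x = rng.standard_normal((10, 3))
        features = np.vstack([x, -x])
        y = np.repeat([0, 1], 10)
        model = train_ls_svm(features, y)
        assert model.bias == pytest.approx(0.0, abs=1e-10)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_ls_svm(rng.standard_normal((5, 2)), np.zeros(5))


class TestLoocv:
    def test_separable_groups_reach_auc_one(self, rng):
        fs = _separable_features(rng)
        assert loocv_auc(fs).auc == 1.0

    def test_permuted_labels_center_at_half(self):
        aucs = []
        for seed in range(100):
            rng = np.random.default_rng(700 + seed)
            x = rng.standard_normal((32, 4))
            y = rng.permutation(np.repeat([0, 1], 16))
            aucs.append(loocv_auc(FeatureSet(x, y)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_auc_invariant_under_monotone_transform_of_decisions(self, rng):
        fs = _separable_features(rng, gap=1.0)
        res = loocv_auc(fs)
        transformed = np.tanh(3.0 * res.decisions) + 5.0
        assert roc_auc_score(fs.labels, transformed) == pytest.approx(res.auc)


class TestEnumerateConfigs:
    def test_paper_factor_grid_yields_108(self):
        configs = enumerate_configs()
        assert len(configs) == 108
        assert len({c.config_id for c in configs}) == 108

    def test_single_values_yield_one(self):
        assert len(enumerate_configs(("PA",), (3.0,), (70,), (30,))) == 1

    def test_two_by_two_yields_four(self):
        assert len(enumerate_configs(("PA", "PB"), (3.0, 4.0), (70,), (30,))) == 4

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configs(pipelines=())


def _config_sets(rng, n=12, n_configs=8, informative=()):
    y = np.repeat([0, 1], n // 2)
    sets = {}
    for c in range(n_configs):
        if c in informative:
            x = y[:, None] * 3.0 + rng.normal(0, 0.5, size=(n, 3))
        else:
            x = rng.standard_normal((n, 3))
        sets[f"cfg{c}"] = FeatureSet(x, y, config_id=f"cfg{c}")
    return sets, y


class TestNestedSelection:
    def test_grid_dimensions_12_subjects_8_configs(self, rng):
        sets, _ = _config_sets(rng)
        res = nested_selection(sets)
        assert res.auc_grid.shape == (12, 8)
        assert res.auc_grid.size == 96
        assert sum(res.selection_counts.values()) == 12

    def test_dominant_config_always_selected(self, rng):
        # uninformative configurations carry constant features, so their inner
        # AUC is exactly 0.5 and the separable one strictly dominates
        y = np.repeat([0, 1], 6)
        sets = {}
        for c in range(8):
            if c == 5:
                x = y[:, None] * 3.0 + rng.normal(0, 0.2, size=(12, 3))
            else:
                x = np.zeros((12, 3))
            sets[f"cfg{c}"] = FeatureSet(x, y, config_id=f"cfg{c}")
        res = nested_selection(sets)
        assert res.selection_counts["cfg5"] == 12
        assert res.auc == pytest.approx(loocv_auc(sets["cfg5"]).auc)

    def test_identical_configs_resolve_ties_to_first(self, rng):
        x = rng.standard_normal((10, 3))
        y = np.repeat([0, 1], 5)
        sets = {f"cfg{c}": FeatureSet(x.copy(), y) for c in range(3)}
        res = nested_selection(sets)
        assert set(res.winners) == {"cfg0"}
        assert res.auc == pytest.approx(loocv_auc(sets["cfg0"]).auc)

    def test_no_leakage_from_held_out_subject(self, rng):
        """Perturbing a held-out subject's features never changes which
        configuration the inner loop picks for it."""
        sets, _ = _config_sets(rng, n=8, n_configs=3, informative=(1,))
        res = nested_selection(sets)
        for i in (0, 3, 7):
            perturbed = {
                name: FeatureSet(fs.features.copy(), fs.labels)
                for name, fs in sets.items()
            }
            for fs in perturbed.values():
                fs.features[i] += 100.0
            res2 = nested_selection(perturbed)
            assert res2.winners[i] == res.winners[i]
            np.testing.assert_allclose(res2.auc_grid[i], res.auc_grid[i])

    def test_mismatched_labels_rejected(self, rng):
        sets, y = _config_sets(rng, n=8, n_configs=2)
        sets["cfg1"] = FeatureSet(sets["cfg1"].features, 1 - y)
        with pytest.raises(ValueError):
            nested_selection(sets)


class TestBootstrapNull:
    def test_constant_grid_flags_nothing(self):
        grid = np.full((10, 4), 0.5)
        out = bootstrap_null(grid, B=200, method="resample", seed=0)
        assert not out["significant"].any()

    def test_dominant_config_flagged_under_permutation_null(self, rng):
        sets, y = _config_sets(rng, n=16, n_configs=4, informative=(2,))
        res = nested_selection(sets)
        out = bootstrap_null(res.auc_grid, sets, B=100, seed=1)
        assert out["significant"][2]
        assert out["significant"].sum() == 1

    def test_null_data_flag_rate_near_alpha(self):
        """Calibration: pure-noise configurations should be flagged at roughly
        the nominal 5% rate of the 95th-percentile threshold."""
        flags = total = 0
        for seed in range(8):
            rng = np.random.default_rng(900 + seed)
            sets, _ = _config_sets(rng, n=12, n_configs=5)
            res = nested_selection(sets)
            out = bootstrap_null(res.auc_grid, sets, B=100, seed=seed)
            flags += int(out["significant"].sum())
            total += 5
        assert flags / total < 0.2

    def test_low_b_warns(self, rng):
        grid = np.full((5, 2), 0.5)
        with pytest.warns(UserWarning, match="low"):
            bootstrap_null(grid, B=50, method="resample", seed=0)


class TestBuildFeatures:
    def test_missing_state_imputed_to_cohort_mean(self, rng):
        sm = rng.standard_normal((5, 2, 3))
        sm[0, 1, :] = np.nan
        fs = build_features(sm, labels=np.array([0, 0, 1, 1, 1]))
        expected = np.nanmean(sm.reshape(5, -1), axis=0)[3:]
        np.testing.assert_allclose(fs.features[0, 3:], expected)
        assert fs.imputed[0, 3:].all()

    def test_occupancy_appended_when_requested(self, rng):
        sm = rng.standard_normal((4, 2, 3))
        occ = rng.dirichlet([2, 2], size=4) * 100
        fs = build_features(sm, np.array([0, 1, 0, 1]), occupancy_pct=occ)
        assert fs.features.shape == (4, 8)


def test_auc_trend_non_increasing_with_window_size():
    """With short-dwell planted states, longer windows blur the state dynamics,
    so the group-contrast AUC should not improve as the window grows
    (trend over seeds, on features built from the truth time courses)."""
    mean_auc = {15: [], 30: [], 45: []}
    for seed in range(10):
        cfg = SynthConfig(n_pairs=10, n_frames=150, dwell_mean_tr=6.0,
                          occupancy_by_group={"HC": (0.3, 0.7), "mTBI": (0.7, 0.3)},
                          seed=1000 + seed)
        cohort = generate_cohort(cfg)
        labels = np.array([1 if s.group == "mTBI" else 0 for s in cohort.subjects])
        tcs = [cohort.truth.source_tcs[s.subject_id] for s in cohort.subjects]
        for window in mean_auc:
            taper = dfnc.make_taper(window, 3.0)
            ws = [dfnc.windowed_correlation(tc, taper) for tc in tcs]
            sm = dfnc.cluster_states(ws, k=2, restarts=2, seed=seed)
            means = dfnc.subject_state_means(ws, sm)
            occ = dfnc.occupancy(sm, [s.group for s in cohort.subjects])
            fs = build_features(means, labels, occupancy_pct=occ.percentages)
            mean_auc[window].append(loocv_auc(fs).auc)
    m15, m30, m45 = (np.mean(mean_auc[w]) for w in (15, 30, 45))
    assert m15 >= m30 - 0.02
    assert m30 >= m45 - 0.02
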