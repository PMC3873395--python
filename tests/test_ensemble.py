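"""Score normalization, weighted-sum fusion, one-vs-all AUC, and CV hygiene."""

import numpy as np
import pytest

from cooctex import (
    CvPlan,
    FusionRule,
    ScorePanel,
    auc_ova,
    decision_scores,
    fuse,
    normalize_panel,
    panel_specs,
    train_scorer,
)
from cooctex.ensemble import COMPOSITE_METHODS
from conftest import auc_concordance_oracle


class TestNormalizePanel:
    def test_column_z_scores_with_population_std(self):
        p = normalize_panel(ScorePanel(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(p.scores[:, 0], [-1.22474487, 0.0, 1.22474487])

    def test_constant_column_maps_to_zeros(self):
        p = normalize_panel(ScorePanel(np.full((5, 2), 3.14)))
        assert np.all(p.scores == 0)

    def test_idempotence(self, rng):
        s = rng.normal(size=(20, 3))
        once = normalize_panel(ScorePanel(s))
        twice = normalize_panel(once)
        np.testing.assert_allclose(once.scores, twice.scores, atol=1e-12)

    def test_normalized_columns_have_unit_moments(self, rng):
        p = normalize_panel(ScorePanel(rng.normal(2.0, 5.0, size=(50, 4))))
        np.testing.assert_allclose(p.scores.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(p.scores.std(axis=0), 1.0, atol=1e-8)


class TestFuse:
    def test_unit_weights_on_identical_panels_scale_linearly(self, rng):
        s = rng.normal(size=(10, 2))
        panels = [ScorePanel(s.copy()) for _ in range(3)]
        fused = fuse(panels, [1, 1, 1])
        np.testing.assert_allclose(fused.scores, 3 * s)

    def test_weighted_sum_definition(self, rng):
        a, b = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        fused = fuse([ScorePanel(a), ScorePanel(b)], [2, 1])
        np.testing.assert_allclose(fused.scores, 2 * a + b)

    def test_weight_scaling_leaves_auc_invariant(self, rng):
        labels = rng.integers(0, 2, size=40)
        a = rng.normal(size=(40, 2)) + labels[:, None] * [[-1, 1]]
        b = rng.normal(size=(40, 2)) + labels[:, None] * [[-1, 1]]
        f1 = fuse([ScorePanel(a), ScorePanel(b)], [2, 1])
        f2 = fuse([ScorePanel(a), ScorePanel(b)], [20, 10])
        assert auc_ova(f1.scores, labels) == auc_ova(f2.scores, labels)

    def test_sum_rule_preserves_informative_channels(self, rng):
        # two independently noisy but informative score channels: fusing
        # should not fall notably below the best single channel
        n = 500
        labels = rng.integers(0, 2, size=n)
        signal = labels * 2.0 - 1.0
        panels = []
        for _ in range(2):
            s = signal + rng.normal(scale=1.5, size=n)
            panels.append(normalize_panel(ScorePanel(np.column_stack([-s, s]))))
        best = max(auc_ova(p.scores, labels) for p in panels)
        fused = fuse(panels, [1, 1])
        assert auc_ova(fused.scores, labels) >= best - 0.02

    def test_misaligned_panels_rejected(self):
        with pytest.raises(ValueError):
            fuse([ScorePanel(np.zeros((3, 2))), ScorePanel(np.zeros((4, 2)))], [1, 1])

    def test_fusion_rule_validates_weights(self):
        with pytest.raises(ValueError):
            FusionRule((("a", -1.0),))


class TestAucOva:
    def test_perfect_ordering(self):
        scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        labels = np.array([1, 1, 0, 0])
        assert auc_ova(scores, labels) == 1.0

    def test_hand_counted_concordant_pairs(self):
        # positive scores 0.9, 0.3 vs negative 0.8, 0.2: 3 of 4 pairs concordant
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 0, 1, 0])
        panel = np.column_stack([-scores, scores])
        assert auc_ova(panel, labels) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        scores = np.ones((6, 2))
        labels = np.array([0, 1, 0, 1, 0, 1])
        assert auc_ova(scores, labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_matches_concordance_oracle(self, rng, n_classes):
        n = 50
        labels = rng.integers(0, n_classes, size=n)
        scores = rng.normal(size=(n, n_classes))
        scores[np.arange(n), labels] += rng.normal(scale=1.0, size=n)
        assert auc_ova(scores, labels) == pytest.approx(
            auc_concordance_oracle(scores, labels), abs=1e-12
        )


class TestTrainScorer:
    def _separable(self, rng, n=60):
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5))
        X[:, 0] += labels * 10.0
        return X, labels

    def test_separable_data_reaches_perfect_training_auc(self, rng):
        X, y = self._separable(rng)
        model = train_scorer(X, y, random_state=0)
        assert auc_ova(decision_scores(model, X), y) == 1.0

    def test_permuted_labels_give_chance_level_auc(self, rng):
        n = 200
        X = rng.normal(size=(n, 5))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        tr, te = np.arange(0, n, 2), np.arange(1, n, 2)
        model = train_scorer(X[tr], y[tr], random_state=0)
        auc = auc_ova(decision_scores(model, X[te]), y[te])
        assert 0.3 <= auc <= 0.7

    def test_selection_depends_on_training_data_only(self, rng):
        X, y = self._separable(rng)
        m1 = train_scorer(X, y, random_state=3)
        m2 = train_scorer(X, y, random_state=3)
        assert m1.get_params()["svm__kernel"] == m2.get_params()["svm__kernel"]
        assert m1.get_params()["svm__C"] == m2.get_params()["svm__C"]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_scorer(rng.normal(size=(10, 3)), np.zeros(10))

    def test_nan_features_rejected_with_descriptor_name(self, rng):
        X = rng.normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="har_whole"):
            train_scorer(X, np.repeat([0, 1], 5), descriptor="har_whole")


class TestPanelSpecs:
    def test_hrsub_is_whole_plus_quadrants_with_printed_weights(self):
        specs = panel_specs("HRsub")
        assert len(specs) == 5
        assert specs[0].window is None and specs[0].weight == 4.0
        assert all(s.weight == 1.0 for s in specs[1:])

    def test_hrsca_has_fifteen_panels_weighted_by_scale(self):
        specs = panel_specs("HRsca")
        assert len(specs) == 15
        assert sum(1 for s in specs if s.scale == 0 and s.weight == 4.0) == 5
        assert sum(1 for s in specs if s.scale > 0 and s.weight == 1.0) == 10

    def test_shsub_uses_thirteen_windows_with_half_weights(self):
        specs = panel_specs("SHsub")
        assert len(specs) == 13
        assert [s.weight for s in specs[:5]] == [1.0] * 5
        assert [s.weight for s in specs[5:]] == [0.5] * 8

    def test_composite_presets(self):
        assert COMPOSITE_METHODS["SUM2"] == (("HRsca", 1.0), ("GRsca", 1.0))
        assert COMPOSITE_METHODS["WS2"] == (("HRsca", 2.0), ("GRsca", 1.0))
        assert COMPOSITE_METHODS["W2"] == (("SUM2", 2.0), ("SHsca", 1.0))
        assert COMPOSITE_METHODS["W3"] == (("SUM2", 3.0), ("SHsca", 1.0))


class TestCvPlan:
    def test_folds_partition_and_stratify(self):
        labels = np.repeat([0, 1, 2], 20)
        plan = CvPlan(5, seed=11)
        splits = plan.splits(labels)
        assert len(splits) == 5
        all_test = np.concatenate([te for _, te in splits])
        assert sorted(all_test) == list(range(60))
        for tr, _ in splits:
            assert set(labels[tr]) == {0, 1, 2}

    def test_seeded_splits_reproducible(self):
        labels = np.repeat([0, 1], 25)
        a = CvPlan(5, seed=4).splits(labels)
        b = CvPlan(5, seed=4).splits(labels)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)
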