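"""Fisher scoring, the gradient proxy, and layer selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import softmax as sp_softmax

from probefuse import (ProbeHead, SyntheticSpec, classical_fisher_score,
                       fisher_proxy, generate_episode, layer_scores,
                       linear_probe_eval, linear_probe_sweep, probe_backbone,
                       select_layers, selection_frequencies)
from probefuse.fisher import ZERO_VARIANCE_SENTINEL


class TestClassicalFisherScore:
    def test_two_class_worked_example(self):
        # class means 1 and 5, global mean 3, population variances 1 each:
        # numerator 2*(1-3)^2 + 2*(5-3)^2 = 16, denominator 2*1 + 2*1 = 4
        feats = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = [0, 0, 1, 1]
        np.testing.assert_allclose(classical_fisher_score(feats, labels),
                                   [4.0])

    def test_identical_class_means_score_zero(self):
        feats = np.array([[1.0], [3.0], [1.0], [3.0]])
        scores = classical_fisher_score(feats, [0, 0, 1, 1])
        np.testing.assert_allclose(scores, [0.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classical_fisher_score(np.ones((3, 2)), [1, 1, 1])

    def test_zero_variance_dimension_gets_sentinel(self):
        feats = np.array([[0.0], [0.0], [1.0], [1.0]])
        with pytest.warns(UserWarning, match="zero within-class variance"):
            scores = classical_fisher_score(feats, [0, 0, 1, 1])
        assert scores[0] == ZERO_VARIANCE_SENTINEL


def proxy_finite_difference(feats, labels, head, h=1e-3):
    """Independent oracle: central differences of the per-sample CE loss."""
    def loss_of(f, y):
        logits = head.weight @ f + head.bias
        return -np.log(sp_softmax(logits)[y])

    n, d = feats.shape
    sqnorms = np.zeros(n)
    for i in range(n):
        grad = np.zeros(d)
        for j in range(d):
            up, down = feats[i].copy(), feats[i].copy()
            up[j] += h
            down[j] -= h
            grad[j] = (loss_of(up, labels[i]) - loss_of(down, labels[i])) / (2 * h)
        sqnorms[i] = (grad**2).sum()
    return np.array([sqnorms[labels == c].mean()
                     for c in range(head.n_classes)])


class TestFisherProxy:
    def test_zero_head_gives_zero_proxies(self):
        head = ProbeHead(weight=np.zeros((3, 4)), bias=np.zeros(3))
        feats = np.random.default_rng(0).normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1, 2, 2])
        np.testing.assert_allclose(fisher_proxy(feats, labels, head),
                                   np.zeros(3), atol=1e-15)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_finite_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d, c = 8, 5, 3
        feats = rng.normal(size=(n, d))
        labels = np.concatenate([np.arange(c), rng.integers(0, c, n - c)])
        head = ProbeHead.create(d, c, seed=seed + 100)
        got = fisher_proxy(feats, labels, head)
        expected = proxy_finite_difference(feats, labels, head)
        np.testing.assert_allclose(got, expected, rtol=1e-4)

    def test_duplicating_class_samples_leaves_proxy_unchanged(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1, 2, 2])
        head = ProbeHead.create(4, 3, seed=0)
        base = fisher_proxy(feats, labels, head)
        doubled = fisher_proxy(np.vstack([feats, feats[:2]]),
                               np.concatenate([labels, [0, 0]]), head)
        np.testing.assert_allclose(doubled, base, atol=1e-12)

    def test_absent_class_flagged_nan(self):
        head = ProbeHead.create(4, 3, seed=0)
        feats = np.random.default_rng(0).normal(size=(4, 4))
        with pytest.warns(UserWarning, match="absent"):
            proxies = fisher_proxy(feats, np.array([0, 0, 1, 1]), head)
        assert np.isnan(proxies[2]) and not np.isnan(proxies[:2]).any()

    def test_class_relabeling_permutes_proxies_max_invariant(self):
        # renaming classes (and the head rows with them) permutes the
        # per-class proxies, so the layer score max_c F_c is invariant
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(9, 6))
        labels = np.repeat([0, 1, 2], 3)
        head = ProbeHead.create(6, 3, seed=1)
        base = fisher_proxy(feats, labels, head)
        perm = np.array([2, 0, 1])
        renamed_head = ProbeHead(weight=head.weight[np.argsort(perm)],
                                 bias=head.bias[np.argsort(perm)])
        permuted = fisher_proxy(feats, perm[labels], renamed_head)
        np.testing.assert_allclose(permuted[perm], base, atol=1e-12)
        np.testing.assert_allclose(np.nanmax(permuted), np.nanmax(base),
                                   atol=1e-12)


class TestLayerScores:
    def test_score_is_max_over_classes(self):
        table = layer_scores({1: [1.0, 3.0], 2: [2.0, 0.5]})
        np.testing.assert_allclose(table.raw_scores, [3.0, 2.0])

    def test_max_dominates_mean(self):
        rng = np.random.default_rng(0)
        proxies = {l: rng.uniform(0, 5, size=4) for l in range(1, 7)}
        table = layer_scores(proxies)
        means = np.array([np.mean(proxies[l]) for l in range(1, 7)])
        assert (table.raw_scores >= means - 1e-12).all()

    def test_z_scores_hand_example(self):
        table = layer_scores({1: [1.0], 2: [2.0], 3: [3.0]})
        np.testing.assert_allclose(table.normalized,
                                   [-1.2247, 0.0, 1.2247], atol=1e-3)

    def test_z_score_population_moments(self):
        rng = np.random.default_rng(1)
        table = layer_scores({l: rng.uniform(0, 2, 3) for l in range(1, 9)})
        assert abs(table.normalized.mean()) < 1e-9
        assert abs(table.normalized.std() - 1.0) < 1e-6

    def test_single_layer_degenerates_to_zero(self):
        table = layer_scores({1: [5.0, 2.0]})
        np.testing.assert_allclose(table.normalized, [0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            layer_scores({})


class TestSelectLayers:
    def test_top_k_by_score(self):
        table = layer_scores({1: [0.1], 2: [0.9], 3: [0.5]})
        assert select_layers(table, 2).selected == [2, 3]

    def test_k_equals_l_selects_all(self):
        table = layer_scores({1: [0.1], 2: [0.9], 3: [0.5]})
        assert sorted(select_layers(table, 3).selected) == [1, 2, 3]

    def test_ties_break_to_lower_index(self):
        table = layer_scores({1: [1.0], 2: [1.0], 3: [1.0]})
        assert select_layers(table, 2).selected == [1, 2]

    def test_k_too_large_rejected(self):
        table = layer_scores({1: [1.0], 2: [2.0]})
        with pytest.raises(ValueError):
            select_layers(table, 3)


class TestProbeBackbone:
    def test_deterministic(self, small_backbone, texture_episode):
        a = probe_backbone(small_backbone, texture_episode, 3, seed=5)
        b = probe_backbone(small_backbone, texture_episode, 3, seed=5)
        assert a.selected == b.selected
        np.testing.assert_array_equal(a.table.raw_scores, b.table.raw_scores)

    def test_single_class_support_rejected(self, small_backbone):
        images = np.zeros((4, 1, 32, 32))
        with pytest.raises(ValueError):
            probe_backbone(small_backbone, (images, np.zeros(4, dtype=int)), 2)

    def test_backbone_weights_untouched(self, small_backbone, texture_episode):
        before = small_backbone.state_snapshot()
        probe_backbone(small_backbone, texture_episode, 3, seed=0)
        after = small_backbone.state_snapshot()
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)

    def test_selects_requested_count(self, small_backbone, texture_episode):
        result = probe_backbone(small_backbone, texture_episode, 4, seed=1)
        assert len(result.selected) == 4
        assert all(1 <= l <= 6 for l in result.selected)


class TestLinearProbe:
    def test_separable_features_reach_perfect_auroc(self, small_backbone,
                                                    planted):
        record = linear_probe_eval(small_backbone, planted.episode,
                                   planted.layer)
        assert record["auroc"] > 0.9

    def test_sweep_returns_one_record_per_layer(self, small_backbone,
                                                texture_episode):
        records = linear_probe_sweep(small_backbone, texture_episode)
        assert [r["layer"] for r in records] == [1, 2, 3, 4, 5, 6]

    def test_random_labels_near_chance(self, small_backbone):
        # labels independent of the images: AUROC within the permutation band
        spec = SyntheticSpec(n_way=2, k_shot=10, n_query=60, margin=0.0,
                             seed=3)
        episode = generate_episode(spec)
        record = linear_probe_eval(small_backbone, episode, 3)
        assert 0.35 <= record["auroc"] <= 0.65


class TestScoreProperties:
    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=16),
           st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_selection_invariant_to_positive_scaling(self, raws, factor):
        """Rescaling all raw scores by a positive factor preserves the
        selection order (z-scoring is affine)."""
        base = layer_scores({i + 1: [v] for i, v in enumerate(raws)})
        scaled = layer_scores({i + 1: [v * factor]
                               for i, v in enumerate(raws)})
        k = max(1, len(raws) // 2)
        assert (select_layers(base, k).selected
                == select_layers(scaled, k).selected)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_selected_scores_dominate_unselected(self, raws):
        table = layer_scores({i + 1: [v] for i, v in enumerate(raws)})
        k = max(1, len(raws) // 2)
        chosen = select_layers(table, k).selected
        rest = set(range(1, len(raws) + 1)) - set(chosen)
        if rest:
            worst_chosen = min(table.normalized[l - 1] for l in chosen)
            best_rest = max(table.normalized[l - 1] for l in rest)
            assert worst_chosen >= best_rest


class TestSelectionFrequencies:
    def test_empty_list_all_zero(self):
        np.testing.assert_array_equal(selection_frequencies([], 6),
                                      np.zeros(6))

    def test_single_result(self):
        counts = selection_frequencies([[2, 5, 6]], 6)
        np.testing.assert_array_equal(counts, [0, 1, 0, 0, 1, 1])

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        sels = [list(rng.choice(6, size=3, replace=False) + 1)
                for _ in range(100)]
        assert selection_frequencies(sels, 6).sum() == 300
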