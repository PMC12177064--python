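"""rh-SiRF discovery: iterated forests, signed paths, mining, selection."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from mica import discovery
from mica.containers import MicaError

HIGH, LOW = discovery.HIGH, discovery.LOW


def _signal_data(n=200, p=30, seed=0, pair=False):
    """One (or two, AND-style) strongly predictive binary-presence taxa."""
    rng = np.random.default_rng(seed)
    X = rng.gamma(1, 1, (n, p)) * (rng.random((n, p)) < 0.5)
    if pair:
        y = 2.0 * ((X[:, 0] > 0) & (X[:, 1] > 0)) + rng.normal(0, 0.3, n)
    else:
        y = 2.0 * (X[:, 0] > 0) + rng.normal(0, 0.3, n)
    return X, y


def _small_cfg(**kw):
    defaults = dict(n_repeats=20, n_bootstraps=25, seed=0)
    defaults.update(kw)
    return discovery.RhSirfConfig(**defaults)


class TestFitIrf:
    def test_weights_sum_to_one_every_iteration(self):
        X, y = _signal_data()
        forest = discovery.fit_irf(X, y, _small_cfg(irf_iterations=3))
        for w in forest.weight_history:
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)

    def test_signal_weight_grows_and_beats_uniform(self):
        X, y = _signal_data(seed=3)
        forest = discovery.fit_irf(X, y, _small_cfg(irf_iterations=3))
        w0 = [w[0] for w in forest.weight_history]
        assert w0[-1] > w0[0]
        assert w0[-1] > 3.0 / X.shape[1]  # clearly above the uniform weight

    def test_same_seed_same_forest_digest(self):
        X, y = _signal_data()
        cfg = _small_cfg()
        f1 = discovery.fit_irf(X, y, cfg)
        f2 = discovery.fit_irf(X, y, cfg)
        assert f1.digest() == f2.digest()

    def test_constant_outcome_rejected(self):
        X, _ = _signal_data()
        with pytest.raises(MicaError):
            discovery.fit_irf(X, np.ones(len(X)), _small_cfg())


def _forest_from_tree(X_local, y, fmap, **tree_kw):
    tree = DecisionTreeRegressor(random_state=0, **tree_kw)
    tree.fit(X_local, y)
    return discovery.Forest([tree], [np.asarray(fmap)], np.ones(len(fmap)) / len(fmap))


class TestSignedPaths:
    def test_depth_one_stump(self):
        # single split on (global) taxon 7 -> exactly {(7,low)}, {(7,high)}
        x = np.linspace(0, 1, 20)[:, None]
        y = (x[:, 0] > 0.5).astype(float)
        forest = _forest_from_tree(x, y, [7], max_depth=1)
        paths = {fs for fs, _ in discovery.extract_signed_paths(forest)}
        assert paths == {frozenset({(7, LOW)}), frozenset({(7, HIGH)})}

    def test_depth_two_sets_bounded(self):
        rng = np.random.default_rng(1)
        X = rng.random((100, 3))
        y = X[:, 0] + X[:, 1]
        forest = _forest_from_tree(X, y, [0, 1, 2], max_depth=2)
        for fs, _ in discovery.extract_signed_paths(forest):
            assert 1 <= len(fs) <= 2

    def test_hand_built_tree_parse(self):
        # force the split structure: root on feature 0, then feature 1 on the
        # high side only (y = 1 only when both exceed 0.5)
        X = np.array([[0.2, 0.2], [0.2, 0.8], [0.8, 0.2], [0.8, 0.8]] * 10, dtype=float)
        y = (X[:, 0] > 0.5).astype(float) + ((X[:, 0] > 0.5) & (X[:, 1] > 0.5))
        forest = _forest_from_tree(X, y, [5, 9], max_depth=2, min_samples_leaf=5)
        paths = {fs for fs, _ in discovery.extract_signed_paths(forest)}
        assert frozenset({(5, LOW)}) in paths
        assert frozenset({(5, HIGH), (9, LOW)}) in paths
        assert frozenset({(5, HIGH), (9, HIGH)}) in paths

    def test_leaf_weights_sum_to_root_samples(self):
        X, y = _signal_data(n=150)
        forest = discovery.fit_irf(X, y, _small_cfg(n_bootstraps=5))
        paths = discovery.extract_signed_paths(forest)
        assert sum(w for _, w in paths) == pytest.approx(150 * 5)


class TestMining:
    def test_anti_monotone_support(self):
        X, y = _signal_data(pair=True, seed=2)
        forest = discovery.fit_irf(X, y, _small_cfg())
        paths = discovery.extract_signed_paths(forest)
        cfg = _small_cfg(support_floor=0.0)
        mined = {m.features: m.frequency for m in discovery.mine_cooccurrences(paths, cfg)}
        for feats, freq in mined.items():
            for sub in feats:
                smaller = frozenset(feats - {sub})
                if smaller:
                    assert mined[smaller] >= freq - 1e-12

    def test_single_path_frequencies_are_binary(self):
        x = np.ones((10, 1))  # constant feature: no split possible -> one leaf
        forest = _forest_from_tree(x, np.arange(10.0), [0], max_depth=1)
        paths = discovery.extract_signed_paths(forest)
        assert len(paths) == 1

    def test_planted_and_interaction_ranks_top(self):
        X, y = _signal_data(n=300, seed=4, pair=True)
        forest = discovery.fit_irf(X, y, _small_cfg(irf_iterations=3))
        mined = discovery.mine_cooccurrences(
            discovery.extract_signed_paths(forest), _small_cfg(support_floor=0.01))
        pairs = sorted((m for m in mined if len(m) == 2),
                       key=lambda m: -m.frequency)
        top2 = {m.taxa for m in pairs[:2]}
        assert frozenset({0, 1}) in top2

    def test_frequencies_in_unit_interval(self):
        X, y = _signal_data()
        forest = discovery.fit_irf(X, y, _small_cfg())
        mined = discovery.mine_cooccurrences(
            discovery.extract_signed_paths(forest), _small_cfg())
        assert all(0 <= m.frequency <= 1 for m in mined)


class TestRepeatedHoldout:
    def test_stability_bounds_and_reproducibility(self):
        X, y = _signal_data(n=120, p=20, seed=5)
        cfg = _small_cfg(n_repeats=10)
        r1 = discovery.stability_analysis(X, y, cfg)
        r2 = discovery.stability_analysis(X, y, cfg)
        assert [s.features for s in r1.itemsets] == [s.features for s in r2.itemsets]
        assert [s.stability for s in r1.itemsets] == [s.stability for s in r2.itemsets]
        assert all(0 <= s.stability <= 1 for s in r1.itemsets)

    def test_planted_pair_recovered(self):
        X, y = _signal_data(n=250, p=30, seed=6, pair=True)
        report = discovery.stability_analysis(X, y, _small_cfg(n_repeats=30))
        assert report.taxon_sets[0].taxa == frozenset({0, 1})
        assert report.taxon_sets[0].stability >= 0.8

    def test_too_small_to_partition(self):
        X, y = _signal_data(n=8)
        with pytest.raises(MicaError):
            discovery.stability_analysis(X[:8], y[:8], _small_cfg())

    def test_permuted_outcome_reduces_stability(self):
        # null calibration property: permuting y cannot make the planted
        # pair MORE stable
        X, y = _signal_data(n=250, p=30, seed=7, pair=True)
        cfg = _small_cfg(n_repeats=20)
        obs = discovery.stability_analysis(X, y, cfg)
        rng = np.random.default_rng(0)
        perm = discovery.stability_analysis(X, rng.permutation(y), cfg)
        key = frozenset({0, 1})
        s_obs = next((s.stability for s in obs.taxon_sets if s.taxa == key), 0.0)
        s_null = next((s.stability for s in perm.taxon_sets if s.taxa == key), 0.0)
        assert s_null <= s_obs


def _itemset(taxa, stability, sign=HIGH, frequency=0.3):
    return discovery.SignedItemset(frozenset((j, sign) for j in taxa),
                                   frequency=frequency, stability=stability)


class TestClosedLoopSelection:
    def test_triangle_of_pairs_becomes_one_clique(self):
        items = [_itemset((0, 1), 0.9), _itemset((1, 2), 0.8), _itemset((0, 2), 0.7)]
        cliques = discovery.select_cliques_closed_loop(items)
        assert [c.members for c in cliques] == [(0, 1, 2)]

    def test_single_pair_is_a_two_node_loop(self):
        cliques = discovery.select_cliques_closed_loop([_itemset((3, 5), 0.9)])
        assert [c.members for c in cliques] == [(3, 5)]

    def test_open_chain_is_pruned(self):
        items = [_itemset((0, 1), 0.9), _itemset((1, 2), 0.8)]
        cliques = discovery.select_cliques_closed_loop(items)
        assert [c.members for c in cliques] == [(0, 1)]

    def test_below_threshold_ignored(self):
        cliques = discovery.select_cliques_closed_loop([_itemset((0, 1), 0.3)])
        assert cliques == []

    def test_empty_input(self):
        assert discovery.select_cliques_closed_loop([]) == []

    def test_taxon_sets_accepted_directly(self):
        sets = [discovery.TaxonSet(frozenset({2, 4}), 0.2, 0.9)]
        assert [c.members for c in discovery.select_cliques_closed_loop(sets)] == [(2, 4)]
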