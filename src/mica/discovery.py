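"""Stage 1: signed iterative random-forest clique discovery (rh-SiRF).

The discovery engine mines small combinations of taxa whose joint
high/low abundance is predictive of the transformed cognitive-risk
outcome:

1. **Iterative random forest** (:func:`fit_irf`). A forest of regression
   trees is grown on bootstrap resamples; each tree sees a random feature
   subset drawn, in the first iteration, uniformly, and in later
   iterations with probability proportional to the previous iteration's
   impurity-based feature importances. Iterating concentrates splits on
   the stable predictive taxa.
2. **Signed path parsing** (:func:`extract_signed_paths`). Every
   root-to-leaf decision path yields a set of (taxon, sign) features:
   ``high`` if the path takes the "greater-than" branch at that taxon's
   split, ``low`` otherwise; a taxon split twice on one path keeps the
   deepest (most specific) sign.
3. **Co-occurrence mining** (:func:`mine_cooccurrences`). Signed itemsets
   up to a maximum size are counted across paths, weighted by leaf sample
   count; support is anti-monotone in itemset size by construction.
4. **Repeated-holdout stability** (:func:`repeated_holdout_stability`).
   The fit-and-mine cycle is repeated on random train/test partitions; an
   itemset's stability is the fraction of repeats in which it re-appears
   above the support floor. True signal recurs; noise does not.
5. **Closed-loop selection** (:func:`select_cliques_closed_loop`). Top
   itemsets are accepted greedily while the accepted taxon co-occurrence
   graph stays a union of closed loops; each resulting connected
   component becomes one candidate clique.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .containers import ConfigError, MicaError

HIGH = "high"
LOW = "low"

SignedFeature = tuple[int, str]  # (taxon index, "high"|"low")


@dataclass
class SignedItemset:
    """A set of signed taxa with its mining statistics."""

    features: frozenset[SignedFeature]
    frequency: float = 0.0  # weighted fraction of paths containing it, within one forest
    stability: float = 0.0  # fraction of repeated holdouts recovering it

    @property
    def taxa(self) -> frozenset[int]:
        return frozenset(j for j, _ in self.features)

    @property
    def high_taxa(self) -> frozenset[int]:
        return frozenset(j for j, s in self.features if s == HIGH)

    def sort_key(self) -> tuple:
        # descending stability, then frequency; lexicographic features for total order
        return (-self.stability, -self.frequency, sorted(self.features))

    @property
    def graph_taxa(self) -> frozenset[int]:
        """Taxa contributing edges to the closed-loop co-occurrence graph."""
        return self.high_taxa

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class TaxonSet:
    """A sign-collapsed co-occurring taxon set with union stability.

    The clique indicator counts *present* members, for which the side of
    the abundance split carries no extra information: a path conditioning
    on joint absence identifies the same membership as one conditioning on
    joint presence. Stability here is therefore the fraction of repeats in
    which ANY sign pattern over these taxa was recovered.
    """

    taxa: frozenset[int]
    frequency: float = 0.0
    stability: float = 0.0

    @property
    def graph_taxa(self) -> frozenset[int]:
        return self.taxa

    def sort_key(self) -> tuple:
        return (-self.stability, -self.frequency, sorted(self.taxa))

    def __len__(self) -> int:
        return len(self.taxa)


@dataclass
class RhSirfConfig:
    """Knobs of the repeated-holdout signed iterative random forest.

    The reference procedure uses 1000 repeated holdouts with 250
    bootstrapped trees per forest on a 60/40 train/test partition;
    ``n_repeats``/``n_bootstraps`` scale that down for desk-sized runs
    while leaving the stability estimates unbiased (they change only
    within binomial Monte-Carlo error).
    """

    n_repeats: int = 1000
    n_bootstraps: int = 250  # trees per forest, one bootstrap resample each
    train_fraction: float = 0.60
    irf_iterations: int = 4
    max_depth: int = 4
    feature_fraction: float = 0.10  # per-node split-candidate fraction of the multiset
    min_leaf: int = 4
    max_itemset_size: int = 4
    support_floor: float = 0.02
    stability_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0,1)")
        for name in ("n_repeats", "n_bootstraps", "irf_iterations", "max_depth",
                     "max_itemset_size", "min_leaf"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.feature_fraction <= 1:
            raise ConfigError("feature_fraction must lie in (0,1]")


@dataclass
class Forest:
    """A fitted iterative forest: trees with their global feature maps."""

    trees: list[DecisionTreeRegressor]
    feature_maps: list[np.ndarray]  # per tree: local feature idx -> global taxon idx
    weights: np.ndarray  # final normalized feature importances
    weight_history: list[np.ndarray] = field(default_factory=list)

    def digest(self) -> str:
        """Stable structural fingerprint, for determinism checks."""
        h = hashlib.sha256()
        for tree, fmap in zip(self.trees, self.feature_maps):
            t = tree.tree_
            h.update(fmap.tobytes())
            h.update(t.feature.tobytes())
            h.update(np.round(t.threshold, 12).tobytes())
            h.update(t.n_node_samples.tobytes())
        return h.hexdigest()


def _fit_one_forest(X: np.ndarray, y: np.ndarray, probs: np.ndarray,
                    cfg: RhSirfConfig, rng: np.random.Generator) -> Forest:
    """One forest with split candidates sampled ∝ ``probs``.

    Weighted split-candidate sampling is realized by handing each tree a
    feature *multiset* of size p drawn with replacement ∝ probs and
    letting the tree subsample ``feature_fraction`` of those columns at
    every node: a feature with weight w then enters a node's candidate
    set with probability ≈ 1 − (1 − w)^(p·feature_fraction), the weighted
    analogue of ordinary mtry.
    """
    n, p = X.shape
    m = max(2, min(p, int(round(cfg.feature_fraction * p))))
    trees, fmaps = [], []
    importance = np.zeros(p)
    for _ in range(cfg.n_bootstraps):
        rows = rng.integers(0, n, size=n)
        fmap = np.sort(rng.choice(p, size=p, replace=True, p=probs))
        tree = DecisionTreeRegressor(
            max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_leaf,
            max_features=m,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[np.ix_(rows, fmap)], y[rows])
        trees.append(tree)
        fmaps.append(fmap)
        imp = tree.tree_.compute_feature_importances(normalize=False)
        np.add.at(importance, fmap, imp)
    importance = np.clip(importance, 0.0, None)  # guard fp rounding in impurity sums
    total = importance.sum()
    weights = importance / total if total > 0 else np.full(p, 1.0 / p)
    return Forest(trees, fmaps, weights)


def fit_irf(X: np.ndarray, y: np.ndarray, cfg: RhSirfConfig,
            rng: np.random.Generator | None = None) -> Forest:
    """Iteratively reweighted random forest.

    Iteration 1 samples each tree's candidate-feature subset uniformly;
    every later iteration samples features proportional to the previous
    iteration's normalized impurity importances (features with zero weight
    drop out). The returned forest is the final iteration's, carrying the
    weight history of all iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise MicaError("X and y are not aligned")
    if np.all(y == y[0]):
        raise MicaError("outcome is constant; nothing to fit")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = X.shape[1]
    probs = np.full(p, 1.0 / p)
    history = []
    forest = None
    for _ in range(cfg.irf_iterations):
        forest = _fit_one_forest(X, y, probs, cfg, rng)
        history.append(forest.weights.copy())
        probs = forest.weights
    forest.weight_history = history
    return forest


def extract_signed_paths(forest: Forest) -> list[tuple[frozenset[SignedFeature], float]]:
    """One signed feature set per root-to-leaf path, weighted by leaf samples.

    sklearn trees send ``x <= threshold`` left, so the left branch carries
    sign ``low`` and the right branch ``high``. A taxon appearing at
    several depths on one path keeps the sign of its deepest split.
    """
    out: list[tuple[frozenset[SignedFeature], float]] = []
    for tree, fmap in zip(forest.trees, forest.feature_maps):
        t = tree.tree_
        stack: list[tuple[int, list[tuple[int, str]]]] = [(0, [])]
        while stack:
            node, signs = stack.pop()
            if t.children_left[node] == -1:  # leaf
                latest: dict[int, str] = {}
                for taxon, sign in signs:  # later entries are deeper: overwrite
                    latest[taxon] = sign
                out.append((frozenset(latest.items()), float(t.n_node_samples[node])))
                continue
            taxon = int(fmap[t.feature[node]])
            stack.append((t.children_left[node], signs + [(taxon, LOW)]))
            stack.append((t.children_right[node], signs + [(taxon, HIGH)]))
    return out


def mine_cooccurrences(paths: list[tuple[frozenset[SignedFeature], float]],
                       cfg: RhSirfConfig) -> list[SignedItemset]:
    """Count signed itemsets across weighted paths.

    The support of an itemset is the weighted fraction of paths containing
    it; itemsets at or above ``cfg.support_floor`` are returned. Support is
    anti-monotone: any superset of an itemset is contained in a subset of
    its paths.
    """
    if not paths:
        raise MicaError("no decision paths to mine")
    total = sum(w for _, w in paths)
    counts: dict[frozenset[SignedFeature], float] = {}
    for features, w in paths:
        feats = sorted(features)
        kmax = min(len(feats), cfg.max_itemset_size)
        for size in range(1, kmax + 1):
            for combo in combinations(feats, size):
                key = frozenset(combo)
                counts[key] = counts.get(key, 0.0) + w
    floor = cfg.support_floor * total
    return [SignedItemset(k, frequency=v / total)
            for k, v in counts.items() if v >= floor]


def _holdout_indices(n: int, train_fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    n_train = int(round(train_fraction * n))
    if n_train < 8 or n - n_train < 2:
        raise MicaError(f"n={n} too small to partition at train_fraction={train_fraction}")
    perm = rng.permutation(n)
    return perm[:n_train]


@dataclass
class StabilityReport:
    """Output of the repeated-holdout stage: signed and sign-collapsed views."""

    itemsets: list[SignedItemset]
    taxon_sets: list[TaxonSet]


def stability_analysis(X: np.ndarray, y: np.ndarray,
                       cfg: RhSirfConfig) -> StabilityReport:
    """Stability of mined itemsets over repeated random holdouts.

    Each repeat draws a fresh ``train_fraction`` partition, fits the
    iterative forest on the training part (``n_bootstraps`` bootstrap
    resamples feeding its trees), and mines co-occurrences. An itemset's
    stability is the fraction of repeats in which it was recovered above
    the support floor. Alongside the signed itemsets, sign-collapsed
    :class:`TaxonSet` stabilities (recovery of any sign pattern over the
    same taxa, sizes ≥ 2) are reported; clique selection operates on
    those. Both lists are sorted by stability, ties broken by mean
    within-forest frequency, then lexicographic order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    master = np.random.default_rng(cfg.seed)
    hits: dict[frozenset[SignedFeature], int] = {}
    freq_sum: dict[frozenset[SignedFeature], float] = {}
    u_hits: dict[frozenset[int], int] = {}
    u_freq: dict[frozenset[int], float] = {}
    for _ in range(cfg.n_repeats):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        train = _holdout_indices(len(y), cfg.train_fraction, rng)
        if np.all(y[train] == y[train][0]):
            continue  # degenerate holdout; counts as a non-recovery for every itemset
        forest = fit_irf(X[train], y[train], cfg, rng=rng)
        mined = mine_cooccurrences(extract_signed_paths(forest), cfg)
        seen: dict[frozenset[int], float] = {}
        for itemset in mined:
            hits[itemset.features] = hits.get(itemset.features, 0) + 1
            freq_sum[itemset.features] = freq_sum.get(itemset.features, 0.0) + itemset.frequency
            if len(itemset) >= 2:
                t = itemset.taxa
                seen[t] = max(seen.get(t, 0.0), itemset.frequency)
        for t, f in seen.items():
            u_hits[t] = u_hits.get(t, 0) + 1
            u_freq[t] = u_freq.get(t, 0.0) + f
    itemsets = [
        SignedItemset(k, frequency=freq_sum[k] / hits[k], stability=hits[k] / cfg.n_repeats)
        for k in hits
    ]
    itemsets.sort(key=SignedItemset.sort_key)
    taxon_sets = [
        TaxonSet(t, frequency=u_freq[t] / u_hits[t], stability=u_hits[t] / cfg.n_repeats)
        for t in u_hits
    ]
    taxon_sets.sort(key=TaxonSet.sort_key)
    return StabilityReport(itemsets, taxon_sets)


def repeated_holdout_stability(X: np.ndarray, y: np.ndarray,
                               cfg: RhSirfConfig) -> list[SignedItemset]:
    """Signed-itemset stabilities over repeated holdouts (see :func:`stability_analysis`)."""
    return stability_analysis(X, y, cfg).itemsets


@dataclass
class CliqueDefinition:
    """A selected clique: taxa whose joint presence defines the indicator."""

    members: tuple[int, ...]  # global taxon indices, sorted
    name: str = ""
    low_members: tuple[int, ...] = ()  # low-signed taxa reported but not in the indicator

    def __post_init__(self) -> None:
        self.members = tuple(sorted(self.members))
        if len(self.members) < 2:
            raise ConfigError("a clique needs at least 2 members")


def select_cliques_closed_loop(itemsets: list[SignedItemset],
                               stability_threshold: float = 0.5,
                               max_cliques: int | None = None) -> list[CliqueDefinition]:
    """Greedy closed-loop selection of top itemsets into cliques.

    Candidate itemsets (size ≥ 2, stability ≥ threshold, ≥ 2 high-signed
    members) each contribute the pairwise edges among their high-signed
    taxa. The accepted set is the largest rank-prefix-respecting subset
    whose union graph is a union of *closed loops*: every connected
    component is either a single edge (a closed 2-node loop) or has every
    node on a cycle. Concretely, all candidates are taken and the
    lowest-ranked one is eliminated until closure holds, so cycles
    assembled from several pairwise itemsets (e.g. a triangle of pairs)
    survive, while a dangling chain extension is dropped. Each final
    connected component becomes one clique. ``max_cliques`` optionally
    keeps only the top-ranked components.
    """
    candidates = [
        s for s in sorted(itemsets, key=lambda s: s.sort_key())
        if len(s) >= 2 and s.stability >= stability_threshold and len(s.graph_taxa) >= 2
    ]
    while candidates:
        g = nx.Graph()
        for s in candidates:
            g.add_edges_from(combinations(sorted(s.graph_taxa), 2))
        if _all_components_closed(g):
            break
        candidates.pop()
    else:
        g = nx.Graph()
    accepted_low: set[int] = set().union(*[s.taxa - s.graph_taxa for s in candidates]) \
        if candidates else set()
    cliques = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)):
        members = tuple(sorted(comp))
        cliques.append(CliqueDefinition(
            members=members,
            name="clique_" + "_".join(str(j) for j in members),
            low_members=tuple(sorted(accepted_low & set(members))),
        ))
    if max_cliques is not None:
        # rank components by the best stability of an accepted itemset inside them
        def comp_rank(c: CliqueDefinition) -> tuple:
            best = min(
                (s.sort_key() for s in candidates if s.graph_taxa <= set(c.members)),
                default=((0.0,)),
            )
            return best
        cliques.sort(key=comp_rank)
        cliques = cliques[:max_cliques]
    return cliques


def _all_components_closed(g: nx.Graph) -> bool:
    """Every component is a single edge or has all nodes on cycles."""
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 1:
            continue
        # a node lies on a cycle iff it belongs to a biconnected component with >= 2 edges
        on_cycle: set = set()
        for bicomp in nx.biconnected_components(sub):
            if len(bicomp) >= 3:
                on_cycle |= bicomp
        if set(comp) - on_cycle:
            return False
    return True
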