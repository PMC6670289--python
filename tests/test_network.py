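"""Ensemble association network: scores, null, stability, Brown, graphs."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import chi2, kstest

from mycoflow.network import (EnsembleAssociationNetwork, bootstrap_stability,
                              browns_merge, network_summary, pairwise_scores,
                              permutation_null, select_candidates)


def _lognormal_rows(rng, p, n, scale=1.0):
    return np.exp(rng.normal(0, scale, size=(p, n)))


class TestPairwiseScores:
    def test_identical_rows_are_perfectly_associated(self, rng):
        row = rng.uniform(1, 10, 20)
        X = np.vstack([row, row, rng.uniform(1, 10, 20)])
        s = pairwise_scores(X)
        assert s["pearson"][0, 1] == pytest.approx(1.0)
        assert s["spearman"][0, 1] == pytest.approx(1.0)
        assert s["bray_curtis"][0, 1] == pytest.approx(0.0, abs=1e-12)
        assert s["kld"][0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_reversed_ranks_give_spearman_minus_one(self):
        X = np.vstack([np.arange(1.0, 13.0), np.arange(12.0, 0.0, -1.0),
                       np.ones(12) + np.arange(12) % 2])
        s = pairwise_scores(X)
        assert s["spearman"][0, 1] == pytest.approx(-1.0)

    def test_constant_row_flagged_as_zero_correlation(self):
        X = np.vstack([np.ones(15), np.arange(15.0) + 1])
        s = pairwise_scores(X)
        assert s["pearson"][0, 1] == 0.0

    def test_mi_of_independent_rows_shrinks_with_n(self, rng):
        # mean MI over 100 independent pairs at n = 500 stays tiny
        vals = []
        for _ in range(100):
            X = _lognormal_rows(rng, 2, 500)
            vals.append(pairwise_scores(X)["mutual_information"][0, 1])
        assert np.mean(vals) < 0.05

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_scores(_lognormal_rows(rng, 3, 5))


class TestPermutationNull:
    def test_null_p_values_approximately_uniform(self):
        # independent replicates (pairs sharing rows are correlated and
        # would distort a KS check); each replicate is one null pair
        ps = {m: [] for m in ("spearman", "pearson", "bray_curtis",
                              "kld", "mutual_information")}
        for seed in range(150):
            g = np.random.default_rng(seed)
            X = _lognormal_rows(g, 2, 30)
            null = permutation_null(X, n_permutations=49, seed=seed + 10_000)
            for m in ps:
                ps[m].append(null.p_values[m][0, 1])
        for m, v in ps.items():
            v = np.asarray(v)
            assert kstest(v, "uniform").statistic < 0.15, m
            assert 0.0 <= (v <= 0.05).mean() <= 0.12, m

    def test_perfect_pair_reaches_floor_p(self, rng):
        row = rng.uniform(1, 5, 30)
        X = np.vstack([row, row * 2.0, _lognormal_rows(rng, 1, 30)[0]])
        null = permutation_null(X, n_permutations=99, seed=0)
        assert null.p_values["pearson"][0, 1] == pytest.approx(1 / 100)
        assert null.directions["pearson"][0, 1] == 1

    def test_row_shuffle_preserves_marginals(self, rng):
        X = _lognormal_rows(rng, 4, 25)
        null = permutation_null(X, n_permutations=25, seed=2)
        # every null Bray-Curtis score is computed from rows with the
        # same per-row multiset, so scores stay within the feasible
        # range set by the marginals (never 1 when supports must overlap)
        assert np.isfinite(null.null_scores["bray_curtis"]).all()
        assert null.null_mean["bray_curtis"][0, 1] > 0

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_null(_lognormal_rows(rng, 3, 15), n_permutations=5)


class TestBrownsMerge:
    def test_single_p_returned_unchanged(self):
        assert browns_merge([0.037]) == pytest.approx(0.037)

    def test_independent_case_equals_fisher_closed_form(self):
        # k = 2, p = (0.1, 0.1): X = 9.2103, chi2_4 sf = (1 + X/2) e^{-X/2}
        merged = browns_merge([0.1, 0.1])
        X = -2 * np.log(0.1) * 2
        fisher = (1 + X / 2) * np.exp(-X / 2)
        assert merged == pytest.approx(fisher, abs=1e-12)
        assert merged == pytest.approx(0.0561, abs=5e-4)

    def test_zero_covariance_equals_fisher_for_any_k(self, rng):
        for k in (2, 3, 5):
            p = rng.uniform(0.01, 0.99, k)
            fisher = chi2.sf(-2 * np.log(p).sum(), 2 * k)
            assert browns_merge(p, covariances=np.zeros((k, k))) == \
                pytest.approx(fisher, abs=1e-9)

    def test_perfect_dependence_collapses_to_single_p(self):
        # duplicated method: cov(-2 ln p_i, -2 ln p_j) = 4 -> c = 2, df = 2
        cov = np.full((2, 2), 4.0)
        for p in (0.9, 0.3, 0.02):
            assert browns_merge([p, p], covariances=cov) == \
                pytest.approx(p, abs=1e-6)

    def test_zero_p_requires_clamp(self):
        with pytest.raises(ValueError):
            browns_merge([0.0, 0.5])
        assert browns_merge([0.0, 0.5], clamp=0.01) > 0


class TestBootstrapStability:
    def test_noise_free_strong_pair_is_stable(self, rng):
        row = np.linspace(1, 30, 30)
        X = np.vstack([row, row * 1.5, _lognormal_rows(rng, 4, 30)])
        null = permutation_null(X, n_permutations=49, seed=3)
        cand = select_candidates(null, alpha=0.05, min_methods=2)
        assert ((cand["i"] == 0) & (cand["j"] == 1)).any()
        stable = bootstrap_stability(X, cand, null, n_bootstrap=50, seed=4)
        idx = cand.index[(cand["i"] == 0) & (cand["j"] == 1)][0]
        assert stable[idx]

    def test_single_outlier_association_removed(self, rng):
        # two heterogeneous rows, independent except one shared spike
        n = 30
        a = np.exp(rng.normal(0, 1, n))
        b = np.exp(rng.normal(0, 1, n))
        a[0] = b[0] = 500.0
        X = np.vstack([a, b, _lognormal_rows(rng, 4, n)])
        null = permutation_null(X, n_permutations=99, seed=5)
        cand = select_candidates(null, alpha=0.05, min_methods=2)
        mask = (cand["i"] == 0) & (cand["j"] == 1)
        if mask.any():
            stable = bootstrap_stability(X, cand, null, n_bootstrap=100,
                                         seed=6)
            assert not stable[cand.index[mask][0]]

    def test_minimum_bootstrap_iterations_enforced(self, rng):
        X = _lognormal_rows(rng, 3, 15)
        null = permutation_null(X, n_permutations=25, seed=1)
        cand = select_candidates(null, alpha=0.5, min_methods=1)
        with pytest.raises(ValueError):
            bootstrap_stability(X, cand, null, n_bootstrap=5)


def brute_force_clustering(G: nx.Graph) -> float:
    """Independent oracle: triangle counting over all node triples."""
    vals = []
    for node in G.nodes:
        nbrs = list(G.neighbors(node))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        closed = sum(1 for u, v in itertools.combinations(nbrs, 2)
                     if G.has_edge(u, v))
        vals.append(closed / (k * (k - 1) / 2))
    return float(np.mean(vals)) if vals else 0.0


class TestNetworkSummary:
    def test_complete_graph_clustering_one(self):
        assert network_summary(nx.complete_graph(4))[
            "clustering_coefficient"] == pytest.approx(1.0)

    def test_star_clustering_zero(self):
        assert network_summary(nx.star_graph(4))[
            "clustering_coefficient"] == pytest.approx(0.0)

    def test_path_graph_single_component_no_triangles(self):
        s = network_summary(nx.path_graph(3))
        assert s["clustering_coefficient"] == 0.0
        assert s["n_components"] == 1

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)),
                                    seed=int(rng.integers(1 << 30)))
            assert network_summary(G)["clustering_coefficient"] == \
                pytest.approx(brute_force_clustering(G), abs=1e-12)

    def test_exclusion_counts_and_sign_tallies(self):
        G = nx.Graph()
        G.add_edge("a", "b", sign=1)
        G.add_edge("a", "c", sign=-1)
        G.add_edge("d", "e", sign=-1)
        s = network_summary(G)
        assert s["n_positive"] == 1 and s["n_negative"] == 2
        assert s["exclusion_count"]["a"] == 1
        assert s["n_components"] == 2


class TestEnsembleEstimator:
    def test_lower_q_threshold_never_adds_edges(self, rng):
        from mycoflow.synthetic import make_coupled_pairs_dataset
        counts, _ = make_coupled_pairs_dataset(n_pos=4, n_neg=2,
                                               n_background=8,
                                               n_samples=40, seed=3)
        X = counts.to_numpy().astype(float).T
        loose = EnsembleAssociationNetwork(n_permutations=49, n_bootstrap=30,
                                           q_threshold=0.1, random_state=0)
        strict = EnsembleAssociationNetwork(n_permutations=49, n_bootstrap=30,
                                            q_threshold=0.01, random_state=0)
        loose.fit(X, otu_ids=list(counts.index))
        strict.fit(X, otu_ids=list(counts.index))
        loose_edges = set(map(frozenset, loose.graph_.edges()))
        strict_edges = set(map(frozenset, strict.graph_.edges()))
        assert strict_edges <= loose_edges

    def test_null_data_edge_count_within_fdr_band(self, rng):
        # mean detected edges over seeds stays near q * tested pairs
        counts = []
        n_pairs = 15 * 14 // 2
        for seed in range(20):
            g = np.random.default_rng(seed + 100)
            X = _lognormal_rows(g, 15, 30).T
            est = EnsembleAssociationNetwork(n_permutations=49,
                                             n_bootstrap=30,
                                             random_state=seed)
            est.fit(X)
            counts.append(est.graph_.number_of_edges())
        assert np.mean(counts) <= 0.05 * n_pairs * 1.5
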