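"""Diversity metrics and permutation statistics.

Brute-force enumeration oracles and scikit-bio cross-checks back the
in-package ANOSIM and PCoA implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.ordination import pcoa as skbio_pcoa

from mycoflow.diversity import (anosim, bh_adjust, bray_curtis,
                                kruskal_wallis, nonparametric_two_sample_t,
                                observed_species, pcoa, shannon)


class TestAlpha:
    @pytest.mark.parametrize("counts, expected", [
        ((5, 5), 1.0), ((10,), 0.0), ((1, 1, 1, 1), 2.0)])
    def test_shannon_base2_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    def test_shannon_rejects_all_zero(self):
        with pytest.raises(ValueError):
            shannon((0, 0))

    @pytest.mark.parametrize("counts, expected", [
        ((0, 0, 3), 1), ((0, 0), 0), ((1, 1, 1), 3)])
    def test_observed_species(self, counts, expected):
        assert observed_species(counts) == expected


class TestBrayCurtis:
    def test_hand_value_and_metric_properties(self):
        values = pd.DataFrame({"u": [6, 2], "v": [2, 2], "w": [0, 5]},
                              index=["t1", "t2"])
        dm = bray_curtis(values)
        assert dm["u", "v"] == pytest.approx(1 / 3)  # 1 - 2*4/12
        assert dm["u", "u"] == 0.0
        d = dm.data
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()

    def test_disjoint_supports_give_one(self):
        values = pd.DataFrame({"u": [3, 0], "v": [0, 7]})
        assert bray_curtis(values)["u", "v"] == pytest.approx(1.0)

    def test_zero_total_sample_named_in_error(self):
        values = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(values)


class TestPcoa:
    def test_euclidean_input_recovered_exactly(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(6)])
        coords, eigvals = pcoa(dm)
        rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rec, dm.data, atol=1e-9)

    def test_collinear_points_have_one_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords, eigvals = pcoa(DistanceMatrix(d, ids=list("abc")))
        # second and later eigenvalues vanish; the first axis is the line
        assert eigvals[1] == pytest.approx(0.0, abs=1e-9)
        axis = coords["PC1"].to_numpy()
        assert np.allclose(sorted(np.abs(np.diff(sorted(axis)))), [1, 1])

    def test_matches_skbio_eigenvalues(self, rng):
        pts = rng.normal(size=(7, 3))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(7)])
        _, eigvals = pcoa(dm)
        ref = skbio_pcoa(dm, method="eigh")
        assert np.allclose(sorted(eigvals[eigvals > 1e-9]),
                           sorted(ref.eigvals[ref.eigvals > 1e-9]), atol=1e-9)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["a", "b"])
        with pytest.raises(ValueError):
            pcoa(dm)


def _enumerate_anosim_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p for ANOSIM by full enumeration of distinct
    label arrangements (add-one convention over non-identity perms to
    mirror the Monte-Carlo estimator's support)."""
    n = len(labels)
    condensed = squareform(d, checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    M = ranks.size

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return ((ranks[~within].mean() - ranks[within].mean()) / (M / 2))

    observed = r_stat(labels)
    stats = [r_stat(np.array(perm)) for perm in
             set(itertools.permutations(labels))]
    return sum(s >= observed - 1e-12 for s in stats) / len(stats)


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        # two tight groups far apart: every between > every within
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(6)])
        res = anosim(dm, ["a"] * 3 + ["b"] * 3, permutations=999, seed=0)
        assert res.statistic == pytest.approx(1.0)
        # the original split recurs under label permutation with
        # probability 2 / C(6,3) = 0.1, which floors the attainable p
        assert res.p_value == pytest.approx(0.1, abs=0.04)

    def test_matches_skbio_statistic(self, rng):
        pts = rng.normal(size=(9, 3))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(9)])
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        mine = anosim(dm, labels, permutations=99, seed=0)
        ref = skbio_anosim(dm, grouping=labels, permutations=0)
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_monte_carlo_p_matches_full_enumeration(self, rng):
        pts = rng.normal(size=(5, 2))
        d = squareform(pdist(pts))
        labels = np.array(["a", "a", "b", "b", "b"])
        exact = _enumerate_anosim_p(d, labels)
        dm = DistanceMatrix(d, ids=list("vwxyz"))
        B = 4999
        res = anosim(dm, labels, permutations=B, seed=3)
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(res.p_value - exact) < 4 * se + 2 / B

    def test_r_in_range_and_rank_invariance(self, rng):
        pts = rng.normal(size=(8, 2))
        d = squareform(pdist(pts))
        labels = ["a"] * 4 + ["b"] * 4
        dm1 = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        dm2 = DistanceMatrix(np.sqrt(d), ids=[f"s{i}" for i in range(8)])
        r1 = anosim(dm1, labels, permutations=49, seed=1).statistic
        r2 = anosim(dm2, labels, permutations=49, seed=1).statistic
        assert -1 <= r1 <= 1
        assert r1 == pytest.approx(r2)  # monotone-transform invariant

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(squareform(pdist(np.arange(4)[:, None])),
                            ids=list("abcd"))
        with pytest.raises(ValueError):
            anosim(dm, ["x", "x", "x", "y"], permutations=9, seed=0)


class TestKruskalWallis:
    def test_hand_rank_arithmetic(self):
        res = kruskal_wallis([[1, 2], [3, 4]], permutations=99, seed=0)
        assert res.statistic == pytest.approx(2.4)

    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[2, 2], [2, 2]], permutations=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_permutation_p_matches_enumeration_n6(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 6.0, 3.0]
        pooled = np.array(a + b)
        ranks = rankdata(pooled)
        n = 6

        def h_stat(idx):
            ra, rb = ranks[list(idx)], ranks[[i for i in range(n)
                                              if i not in idx]]
            return 12 / (n * (n + 1)) * (
                3 * (ra.mean() - 3.5) ** 2 + 3 * (rb.mean() - 3.5) ** 2)

        obs = h_stat((0, 1, 2))
        stats = [h_stat(c) for c in itertools.combinations(range(n), 3)]
        exact = sum(s >= obs - 1e-12 for s in stats) / len(stats)
        res = kruskal_wallis([a, b], permutations=9999, seed=5)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p_value - exact) < 4 * se + 1e-3

    def test_h_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=5).tolist() for _ in range(3)]
        h1 = kruskal_wallis(groups, permutations=9, seed=0).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups],
                            permutations=9, seed=0).statistic
        assert h1 == pytest.approx(h2)


class TestNonparametricT:
    def test_extreme_separation_hits_floor(self):
        # only the 2 of C(6,3) = 20 splits reproducing the original
        # grouping reach |t_obs|, so enumeration puts the floor at 0.1
        res = nonparametric_two_sample_t([1, 2, 3], [101, 102, 103],
                                         permutations=999, seed=0)
        assert res.p_value == pytest.approx(2 / 20, abs=0.04)

    def test_identical_multisets_give_large_p(self):
        ps = [nonparametric_two_sample_t([1, 2, 3, 4], [4, 3, 2, 1],
                                         permutations=499, seed=s).p_value
              for s in range(5)]
        assert min(ps) >= 0.9

    def test_permutation_p_matches_enumeration_3_plus_3(self):
        a, b = np.array([0.3, 1.2, 0.8]), np.array([1.9, 2.4, 1.1])
        pooled = np.concatenate([a, b])

        def welch(x, y):
            vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
            return (x.mean() - y.mean()) / np.sqrt(vx + vy)

        obs = abs(welch(a, b))
        stats = []
        for idx in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in idx]
            stats.append(abs(welch(pooled[list(idx)], pooled[rest])))
        exact = sum(s >= obs - 1e-12 for s in stats) / len(stats)
        res = nonparametric_two_sample_t(a, b, permutations=9999, seed=2)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p_value - exact) < 4 * se + 1e-3


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_never_decreases_and_capped(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
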