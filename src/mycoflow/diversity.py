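"""Alpha/beta diversity and permutation-based community statistics.

Covers the descriptive and inferential statistics used on normalized
OTU tables: Shannon entropy and observed species for alpha diversity,
Bray-Curtis dissimilarity and principal coordinates analysis for beta
diversity, and permutation tests (ANOSIM, Kruskal-Wallis, nonparametric
two-sample t) with Benjamini-Hochberg correction.

Distance matrices are held in scikit-bio's :class:`~skbio.DistanceMatrix`
(ids travel with the matrix).  Permutation p-values use the add-one
convention p = (b + 1) / (B + 1), so p >= 1/(B+1) always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, rankdata, ttest_ind
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """Outcome of a permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str
    adjusted_p: float | None = None
    extras: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


def _perm_p(b: int, B: int) -> float:
    return (b + 1) / (B + 1)


# -- alpha diversity -------------------------------------------------------

def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_base p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_species(counts) -> int:
    """Number of taxa with count >= 1 (Sobs)."""
    return int((np.asarray(counts, dtype=float) >= 1).sum())


# -- beta diversity --------------------------------------------------------

def bray_curtis(values: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (columns).

    d(u, v) = 1 - 2 sum_t min(u_t, v_t) / (sum u + sum v), in [0, 1].
    """
    X = values.to_numpy(dtype=float).T
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = [values.columns[i] for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"zero-total samples: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(c) for c in values.columns])


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and returns coordinates for
    the positive eigenvalues only; the full eigenvalue vector (negatives
    included, no correction) is returned alongside for inspection.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return frame, eigvals


# -- permutation tests -----------------------------------------------------

def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    M = ranks.size
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (M / 2.0))


def anosim(dm: DistanceMatrix, groups, permutations: int = 999,
           seed: int | None = None) -> TestResult:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances and mid-ranks for ties; the p-value
    permutes group labels.  R is 1 when every between-group distance
    exceeds every within-group distance and near 0 under exchangeability.
    """
    labels = np.asarray(pd.Series(list(groups)).to_numpy())
    n = len(dm.ids)
    if labels.shape[0] != n:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("at least two groups required")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with a single sample: {small}")
    condensed = squareform(dm.data, checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    observed = _anosim_r(ranks, labels[iu] == labels[ju])
    rng = np.random.default_rng(seed)
    # batch label permutations: (B, M) within-pair masks
    codes = pd.factorize(labels)[0]
    perms = np.argsort(rng.random((permutations, n)), axis=1)
    L = codes[perms]
    within = L[:, iu] == L[:, ju]
    M = ranks.size
    n_within = within.sum(axis=1)
    sum_within = (ranks[None, :] * within).sum(axis=1)
    r_w = sum_within / n_within
    r_b = (ranks.sum() - sum_within) / (M - n_within)
    null_r = (r_b - r_w) / (M / 2.0)
    b = int((null_r >= observed - 1e-12).sum())
    return TestResult(observed, _perm_p(b, permutations), permutations, "anosim")


def kruskal_wallis(groups: list, permutations: int = 999,
                   seed: int | None = None) -> TestResult:
    """Kruskal-Wallis H with Monte-Carlo permutation p.

    H uses mid-ranks and the standard tie correction (via
    scipy.stats.kruskal); the reported p-value comes from group-label
    permutations, with the asymptotic chi-square p kept in ``extras``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("total n must be >= 3")
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, permutations, "kruskal_wallis",
                          extras={"chi2_p": 1.0})
    H_obs, chi2_p = kruskal(*groups)
    sizes = [g.size for g in groups]
    ranks = rankdata(pooled)
    n = pooled.size
    # tie correction shared by every permutation (ranks are fixed)
    _, t = np.unique(pooled, return_counts=True)
    tie = 1.0 - (t ** 3 - t).sum() / (n ** 3 - n)
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    perms = ranks[np.argsort(rng.random((permutations, n)), axis=1)]
    h_null = np.zeros(permutations)
    for i, s in enumerate(sizes):
        seg = perms[:, bounds[i]:bounds[i + 1]].mean(axis=1)
        h_null += s * (seg - (n + 1) / 2.0) ** 2
    h_null *= 12.0 / (n * (n + 1)) / tie
    b = int((h_null >= H_obs - 1e-12).sum())
    return TestResult(float(H_obs), _perm_p(b, permutations), permutations,
                      "kruskal_wallis", extras={"chi2_p": float(chi2_p)})


def nonparametric_two_sample_t(a, b, permutations: int = 999,
                               seed: int | None = None) -> TestResult:
    """Two-sided permutation test on the Welch t statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, permutations, "nonparametric_t")
    t_obs = ttest_ind(a, b, equal_var=False).statistic
    if np.isnan(t_obs):  # zero variance in both groups, unequal means
        t_obs = np.inf if a.mean() != b.mean() else 0.0
    rng = np.random.default_rng(seed)
    na, nb = a.size, b.size
    perms = pooled[np.argsort(rng.random((permutations, pooled.size)), axis=1)]
    ga, gb = perms[:, :na], perms[:, na:]
    va = ga.var(axis=1, ddof=1) / na
    vb = gb.var(axis=1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = (ga.mean(axis=1) - gb.mean(axis=1)) / denom
    t_null = np.nan_to_num(t_null, nan=0.0)
    count = int((np.abs(t_null) >= abs(t_obs) - 1e-12).sum())
    return TestResult(float(t_obs), _perm_p(count, permutations), permutations,
                      "nonparametric_t")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def alpha_diversity_frame(values: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon and observed-species table from a counts frame."""
    rows = {}
    for sample in values.columns:
        col = values[sample].to_numpy()
        rows[sample] = {"shannon": shannon(col, base=base),
                        "observed_species": observed_species(col)}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame
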