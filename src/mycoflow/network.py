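"""Ensemble co-occurrence / mutual-exclusion network inference.

Associations between OTU abundance profiles are scored with five
measures — Spearman and Pearson correlation, Bray-Curtis and
(symmetrized) Kullback-Leibler dissimilarity, and mutual information —
and tested against a permutation null built by independently shuffling
each OTU's row across samples.  Candidate edges (permutation p <= 0.05
in at least two measures agreeing in direction) pass through a bootstrap
stability filter (resampling samples with replacement; an edge is
unstable for a measure when the null expectation falls inside the
central 95% bootstrap interval or its direction flips in more than 5%
of replicates).  The per-measure p-values of each surviving edge are
merged with Brown's method (a moment-matched scaled chi-square that
generalizes Fisher's combination to dependent tests), corrected with
Benjamini-Hochberg, and the resulting signed graph is clustered into
connected components.

Directions: correlations carry their sign; dissimilarities and mutual
information are signless and receive a direction only relative to the
null — an observed score below the null mean indicates co-occurrence,
above it mutual exclusion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, rankdata
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .diversity import bh_adjust

logger = logging.getLogger(__name__)

METHODS = ("spearman", "pearson", "bray_curtis", "kld", "mutual_information")
CORRELATIONS = ("spearman", "pearson")


# -- pairwise scores -------------------------------------------------------

def _safe_corr(rows: np.ndarray) -> np.ndarray:
    constant = rows.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rows)
    c = np.nan_to_num(c, nan=0.0)
    c[constant, :] = 0.0
    c[:, constant] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def _mi_bins(rows: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization of each row into n_bins codes."""
    n = rows.shape[1]
    order = rankdata(rows, axis=1, method="ordinal") - 1
    return (order * n_bins // n).astype(np.int64)


def _pairwise_mi(bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Mutual information (bits) between all row pairs of a discretized
    matrix, with the Miller-Madow bias correction
    (K_x - 1)(K_y - 1) / (2 n ln 2) subtracted so independent rows score
    near zero instead of carrying the plug-in estimator's positive bias.
    """
    P, n = bins.shape
    marg = np.stack([np.bincount(b, minlength=n_bins) for b in bins]) / n
    occupied = (marg > 0).sum(axis=1)
    out = np.zeros((P, P))
    for i in range(P):
        bi = bins[i] * n_bins
        for j in range(i + 1, P):
            joint = np.bincount(bi + bins[j], minlength=n_bins * n_bins) / n
            pij = joint.reshape(n_bins, n_bins)
            outer = marg[i][:, None] * marg[j][None, :]
            mask = pij > 0
            mi = (pij[mask] * np.log2(pij[mask] / outer[mask])).sum()
            # the corrected estimator may dip slightly below zero for
            # independent rows; keep it unclipped so null comparisons
            # are not distorted by a point mass at 0
            mi -= (occupied[i] - 1) * (occupied[j] - 1) / (2.0 * n * np.log(2))
            out[i, j] = out[j, i] = mi
    return out


def _sym_kld(rows: np.ndarray, pseudocount: float) -> np.ndarray:
    """Symmetrized KL divergence between rows normalized to distributions."""
    q = rows + pseudocount
    q = q / q.sum(axis=1, keepdims=True)
    logq = np.log(q)
    h = (q * logq).sum(axis=1)  # -entropy per row
    cross = q @ logq.T
    kl = h[:, None] - cross
    return 0.5 * (kl + kl.T)


def pairwise_scores(values: pd.DataFrame | np.ndarray,
                    methods=METHODS, pseudocount: float = 1e-6
                    ) -> dict[str, np.ndarray]:
    """Score every OTU pair under each measure.

    ``values`` is OTUs x samples.  Correlations act on the value rows;
    Bray-Curtis and KLD act on per-sample-normalized rows (relative
    abundances, plus a pseudocount for KLD); mutual information acts on
    equal-frequency-discretized rows with floor(n^(1/3)) bins and the
    Miller-Madow bias correction.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[1] < 10:
        raise ValueError("network inference needs at least 10 samples")
    colsums = X.sum(axis=0)
    colsums[colsums == 0] = 1.0
    R = X / colsums  # per-sample relative abundances
    # cube-root bin growth keeps joint cells populated (sqrt(n) bins put
    # ~1 sample per cell and the plug-in MI never approaches zero under
    # independence, even bias-corrected)
    n_bins = max(2, int(np.cbrt(X.shape[1])))
    out: dict[str, np.ndarray] = {}
    for m in methods:
        if m == "pearson":
            out[m] = _safe_corr(X)
        elif m == "spearman":
            out[m] = _safe_corr(rankdata(X, axis=1))
        elif m == "bray_curtis":
            out[m] = np.nan_to_num(squareform(pdist(R, metric="braycurtis")),
                                   nan=1.0)
        elif m == "kld":
            out[m] = _sym_kld(R, pseudocount)
        elif m == "mutual_information":
            out[m] = _pairwise_mi(_mi_bins(X, n_bins), n_bins)
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


# -- permutation null ------------------------------------------------------

@dataclass
class PermutationNull:
    """Observed scores, null score stacks, p-values and directions."""

    observed: dict[str, np.ndarray]
    null_scores: dict[str, np.ndarray]       # (B, P, P)
    p_values: dict[str, np.ndarray]          # (P, P)
    directions: dict[str, np.ndarray]        # (P, P) in {-1, 0, +1}
    null_mean: dict[str, np.ndarray]
    n_permutations: int


def _shuffle_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = rng.permutation(X[i])
    return out


def permutation_null(values: pd.DataFrame | np.ndarray,
                     n_permutations: int = 100, seed: int | None = None,
                     methods=METHODS) -> PermutationNull:
    """Per-pair, per-method permutation p-values by row shuffling.

    Each permutation independently shuffles every OTU row across samples
    (marginals preserved) and rescores all pairs.  Two-sided
    extremeness: |r| for correlations, distance from the null mean for
    dissimilarities and MI; p = (b + 1) / (B + 1).
    """
    if n_permutations < 20:
        raise ValueError("at least 20 permutations required")
    X = np.asarray(values, dtype=float)
    observed = pairwise_scores(X, methods=methods)
    rng = np.random.default_rng(seed)
    P = X.shape[0]
    null_scores = {m: np.empty((n_permutations, P, P), dtype=np.float32)
                   for m in methods}
    for b in range(n_permutations):
        perm_scores = pairwise_scores(_shuffle_rows(X, rng), methods=methods)
        for m in methods:
            null_scores[m][b] = perm_scores[m]
    p_values, directions, null_mean = {}, {}, {}
    for m in methods:
        obs = observed[m]
        nulls = null_scores[m].astype(float)
        mean = nulls.mean(axis=0)
        null_mean[m] = mean
        if m in CORRELATIONS:
            b_count = (np.abs(nulls) >= np.abs(obs) - 1e-12).sum(axis=0)
            direction = np.sign(obs).astype(int)
            direction[obs == 0] = 0
        else:
            dev = np.abs(obs - mean)
            b_count = (np.abs(nulls - mean) >= dev - 1e-12).sum(axis=0)
            direction = np.where(obs < mean, 1, -1)  # closer than null = co-occur
            direction[np.abs(obs - mean) == 0] = 0
        p = (b_count + 1) / (n_permutations + 1)
        np.fill_diagonal(p, 1.0)
        np.fill_diagonal(direction, 0)
        p_values[m] = p
        directions[m] = direction
    return PermutationNull(observed, null_scores, p_values, directions,
                           null_mean, n_permutations)


# -- candidate selection and bootstrap stability ---------------------------

def select_candidates(null: PermutationNull, alpha: float = 0.05,
                      min_methods: int = 2) -> pd.DataFrame:
    """Edges with p <= alpha in >= min_methods measures of one direction.

    Returns a frame indexed by (i, j) pairs with the supporting methods
    and the consensus direction among supporters.
    """
    methods = list(null.p_values)
    P = next(iter(null.p_values.values())).shape[0]
    rows = []
    for i, j in itertools.combinations(range(P), 2):
        support_pos = [m for m in methods
                       if null.p_values[m][i, j] <= alpha
                       and null.directions[m][i, j] > 0]
        support_neg = [m for m in methods
                       if null.p_values[m][i, j] <= alpha
                       and null.directions[m][i, j] < 0]
        for sign, support in ((1, support_pos), (-1, support_neg)):
            if len(support) >= min_methods:
                rows.append({"i": i, "j": j, "sign": sign,
                             "supporting": tuple(support)})
    frame = pd.DataFrame(rows, columns=["i", "j", "sign", "supporting"])
    if not frame.empty:
        # a pair significant in both directions is contradictory: drop it
        dup = frame.duplicated(subset=["i", "j"], keep=False)
        if dup.any():
            logger.info("dropping %d direction-contradictory pairs",
                        dup.sum() // 2)
            frame = frame[~dup]
    return frame.reset_index(drop=True)


def bootstrap_stability(values, candidates: pd.DataFrame,
                        null: PermutationNull, n_bootstrap: int = 100,
                        seed: int | None = None,
                        methods=METHODS) -> np.ndarray:
    """Stability flags for candidate edges under sample resampling.

    For each bootstrap replicate the samples (columns) are resampled
    with replacement and every method rescored.  An edge is unstable for
    a method when the permutation-null mean lies inside the central 95%
    bootstrap interval of the score, or when the direction implied by
    the replicate flips in more than 5% of replicates.  An edge is
    removed when unstable in a majority of its supporting methods.
    """
    if n_bootstrap < 20:
        raise ValueError("at least 20 bootstrap iterations required")
    X = np.asarray(values, dtype=float)
    if candidates.empty:
        return np.zeros(0, dtype=bool)
    rng = np.random.default_rng(seed)
    boot = {m: np.empty((n_bootstrap, len(candidates)), dtype=float)
            for m in methods}
    ii = candidates["i"].to_numpy()
    jj = candidates["j"].to_numpy()
    for b in range(n_bootstrap):
        cols = rng.integers(0, X.shape[1], X.shape[1])
        scores = pairwise_scores(X[:, cols], methods=methods)
        for m in methods:
            boot[m][b] = scores[m][ii, jj]
    stable = np.zeros(len(candidates), dtype=bool)
    for e, row in candidates.iterrows():
        i, j = int(row["i"]), int(row["j"])
        votes = []
        for m in row["supporting"]:
            scores_b = boot[m][:, e]
            lo, hi = np.percentile(scores_b, [2.5, 97.5])
            null_ref = 0.0 if m in CORRELATIONS else null.null_mean[m][i, j]
            inside = lo <= null_ref <= hi
            if m in CORRELATIONS:
                obs_side = np.sign(null.observed[m][i, j])
                flips = np.mean(np.sign(scores_b) != obs_side)
            else:
                obs_side = np.sign(null.observed[m][i, j] - null_ref)
                flips = np.mean(np.sign(scores_b - null_ref) != obs_side)
            votes.append(not inside and flips <= 0.05)
        stable[e] = sum(votes) * 2 > len(votes)
    return stable


# -- Brown's method --------------------------------------------------------

def browns_merge(p_values, covariances: np.ndarray | None = None,
                 null_p: np.ndarray | None = None,
                 clamp: float | None = None) -> float:
    """Combine k dependent p-values with Brown's method.

    X = -2 sum ln p_i has E[X] = 2k and Var[X] = 4k + 2 sum_{i<j}
    cov(-2 ln p_i, -2 ln p_j); X/c with c = Var/(2E) is referred to a
    chi-square with df = 2 E^2 / Var.  With zero covariance this is
    exactly Fisher's method.

    ``covariances`` may supply the k x k covariance matrix of the
    -2 ln p_i directly (only the off-diagonal is used); otherwise it is
    estimated empirically from ``null_p`` (replicates x k p-values drawn
    under the null).  Zero p-values are clamped to ``clamp`` (required
    if any p == 0).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("at least one p-value required")
    if np.any(p <= 0):
        if clamp is None:
            raise ValueError("zero p-value; supply clamp=1/(B+1)")
        logger.info("clamping %d zero p-values to %g", (p <= 0).sum(), clamp)
        p = np.maximum(p, clamp)
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    X = float(-2.0 * np.log(p).sum())
    if k == 1:
        return float(p[0])
    E = 2.0 * k
    cov_sum = 0.0
    if covariances is not None:
        cov = np.asarray(covariances, dtype=float)
        cov_sum = float(np.triu(cov, k=1).sum())
    elif null_p is not None:
        y = -2.0 * np.log(np.clip(np.asarray(null_p, dtype=float), 1e-12, 1.0))
        cov = np.cov(y, rowvar=False)
        cov_sum = float(np.triu(cov, k=1).sum())
    var = 4.0 * k + 2.0 * cov_sum
    var = max(var, 1e-9)
    c = var / (2.0 * E)
    df = 2.0 * E ** 2 / var
    return float(chi2.sf(X / c, df))


def _null_p_replicates(null: PermutationNull, i: int, j: int,
                       methods) -> np.ndarray:
    """Empirical p-value of each null replicate's score, per method.

    Each null score is ranked within its own null distribution with the
    same extremeness rule used for the observed score, giving the
    (discrete-uniform) p-value replicates Brown's covariance needs.
    """
    B = null.n_permutations
    cols = []
    for m in methods:
        scores = null.null_scores[m][:, i, j].astype(float)
        if m in CORRELATIONS:
            extremeness = np.abs(scores)
        else:
            extremeness = np.abs(scores - scores.mean())
        ranks = rankdata(-extremeness, method="max")
        cols.append(ranks / B)
    return np.column_stack(cols)


# -- graph assembly --------------------------------------------------------

def build_network(values, candidates: pd.DataFrame, stable: np.ndarray,
                  null: PermutationNull, otu_ids: list[str],
                  q_threshold: float = 0.05,
                  taxonomy: pd.Series | None = None,
                  environments: pd.Series | None = None) -> nx.Graph:
    """Assemble the final signed graph from candidates and stability flags.

    Merges each candidate's per-method p-values with Brown's method
    (covariances from the null replicates), applies Benjamini-Hochberg
    across candidates, and keeps stable edges with q <= q_threshold.
    Node attributes carry mean relative abundance (overall and per
    environment when sample environments are given), a phylum label
    parsed from taxonomy, and the component index.
    """
    X = np.asarray(values, dtype=float)
    G = nx.Graph()
    methods = list(null.p_values)
    clamp = 1.0 / (null.n_permutations + 1)
    if not candidates.empty:
        merged = np.empty(len(candidates))
        for e, row in candidates.iterrows():
            i, j = int(row["i"]), int(row["j"])
            p_vec = np.array([null.p_values[m][i, j] for m in methods])
            merged[e] = browns_merge(
                p_vec, null_p=_null_p_replicates(null, i, j, methods),
                clamp=clamp)
        merged = np.clip(merged, clamp, 1.0)
        q = bh_adjust(merged)
    else:
        merged = np.zeros(0)
        q = np.zeros(0)
    colsums = X.sum(axis=0)
    colsums[colsums == 0] = 1.0
    rel = X / colsums
    for e, row in candidates.iterrows():
        if not stable[e] or q[e] > q_threshold:
            continue
        i, j = int(row["i"]), int(row["j"])
        a, b = otu_ids[i], otu_ids[j]
        if a > b:
            a, b = b, a
        G.add_edge(a, b, sign=int(row["sign"]),
                   merged_p=float(merged[e]), q=float(q[e]),
                   supporting=",".join(row["supporting"]),
                   scores={m: float(null.observed[m][i, j]) for m in methods})
    for node in G.nodes:
        idx = otu_ids.index(node)
        G.nodes[node]["mean_rel_abundance"] = float(rel[idx].mean())
        if environments is not None:
            env = np.asarray(environments)
            for label in dict.fromkeys(env):
                G.nodes[node][f"mean_rel_abundance_{label}"] = float(
                    rel[idx, env == label].mean())
        if taxonomy is not None and node in taxonomy.index:
            phylum = [tok.strip() for tok in str(taxonomy[node]).split(";")
                      if tok.strip().startswith("p__")]
            G.nodes[node]["phylum"] = phylum[0][3:] if phylum else "unknown"
    for ci, comp in enumerate(sorted(nx.connected_components(G),
                                     key=len, reverse=True)):
        for node in comp:
            G.nodes[node]["component"] = ci
    return G


def network_summary(G: nx.Graph) -> dict:
    """Headline statistics of a signed association graph.

    The clustering coefficient is the sign-blind mean of local
    coefficients with degree < 2 nodes contributing 0; components are
    connected components of the undirected, unsigned graph.
    """
    n_nodes = G.number_of_nodes()
    n_edges = G.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in G.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = sum(1 for s in signs if s < 0)
    components = list(nx.connected_components(G))
    exclusions = {
        n: sum(1 for _, _, d in G.edges(n, data=True) if d.get("sign", 1) < 0)
        for n in G.nodes
    }
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "clustering_coefficient": (nx.average_clustering(G, count_zeros=True)
                                   if n_nodes else 0.0),
        "n_components": len(components),
        "mean_component_size": (n_nodes / len(components) if components
                                else 0.0),
        "degree": dict(G.degree()),
        "exclusion_count": exclusions,
    }


class EnsembleAssociationNetwork(BaseEstimator):
    """End-to-end ensemble network inference as a fit-shaped estimator.

    ``fit(X)`` takes samples x taxa values (already normalized and
    prevalence-filtered upstream) and populates ``graph_``, ``edges_``
    and ``summary_``.
    """

    def __init__(self, n_permutations: int = 100, n_bootstrap: int = 100,
                 alpha_candidate: float = 0.05, min_methods: int = 2,
                 q_threshold: float = 0.05, methods=METHODS,
                 random_state: int | None = None):
        self.n_permutations = n_permutations
        self.n_bootstrap = n_bootstrap
        self.alpha_candidate = alpha_candidate
        self.min_methods = min_methods
        self.q_threshold = q_threshold
        self.methods = methods
        self.random_state = random_state

    def fit(self, X, y=None, otu_ids=None, taxonomy=None, environments=None):
        X = np.asarray(X, dtype=float).T  # to taxa x samples
        if otu_ids is None:
            otu_ids = [f"OTU{i}" for i in range(X.shape[0])]
        rng = np.random.default_rng(self.random_state)
        null = permutation_null(X, self.n_permutations,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                methods=self.methods)
        candidates = select_candidates(null, self.alpha_candidate,
                                       self.min_methods)
        stable = bootstrap_stability(X, candidates, null, self.n_bootstrap,
                                     seed=int(rng.integers(2 ** 31 - 1)),
                                     methods=self.methods)
        self.null_ = null
        self.candidates_ = candidates
        self.stable_ = stable
        self.graph_ = build_network(X, candidates, stable, null,
                                    list(otu_ids), self.q_threshold,
                                    taxonomy=taxonomy,
                                    environments=environments)
        self.summary_ = network_summary(self.graph_)
        self.edges_ = pd.DataFrame(
            [{"otu_a": a, "otu_b": b, **{k: v for k, v in d.items()
                                         if k != "scores"}}
             for a, b, d in self.graph_.edges(data=True)])
        return self

    def write_outputs(self, directory, header_lines=()):
        """GraphML, edge/node TSVs and a summary JSON."""
        check_is_fitted(self, "graph_")
        import json
        from pathlib import Path

        from .otu import _write_tsv
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        G = self.graph_.copy()
        for _, _, d in G.edges(data=True):
            d.pop("scores", None)
        nx.write_graphml(G, directory / "network.graphml")
        if not self.edges_.empty:
            _write_tsv(self.edges_.set_index("otu_a"),
                       directory / "edges.tsv", header_lines,
                       index_label="otu_a")
        nodes = pd.DataFrame.from_dict(dict(G.nodes(data=True)),
                                       orient="index")
        if not nodes.empty:
            _write_tsv(nodes, directory / "nodes.tsv", header_lines,
                       index_label="otu_id")
        summary = {k: v for k, v in self.summary_.items()
                   if k not in ("degree", "exclusion_count")}
        with open(directory / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
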