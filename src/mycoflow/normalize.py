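"""Normalization and filtering of OTU count tables.

Estimator classes follow the scikit-learn transformer protocol and
operate on arrays of shape (n_samples, n_taxa); the module-level
functions wrap them for :class:`~mycoflow.otu.OtuTable` inputs (OTUs x
samples, the field's usual table orientation).

Implemented steps:

* rarefaction — without-replacement subsampling of every sample's reads
  to a common depth (default 1,000 reads), the classical normalization
  for alpha diversity;
* cumulative sum scaling (CSS) — each sample's counts divided by the sum
  of its counts up to a chosen quantile of the nonzero count
  distribution, then multiplied by a fixed scaling constant;
* prevalence and overall-relative-abundance filters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .otu import NormalizedTable, OtuTable, OtuTableError

logger = logging.getLogger(__name__)


class Rarefier(BaseEstimator, TransformerMixin):
    """Rarefy integer count rows to an even depth without replacement.

    Each retained sample is an exact without-replacement subsample of its
    reads summing to ``depth`` (multivariate hypergeometric draw).
    Samples whose total is below ``depth`` are dropped; fitted attribute
    ``kept_idx_`` records which input rows survive.

    Parameters
    ----------
    depth : int, default=1000
        Target number of reads per sample.
    random_state : int or None
        Seed; identical seeds give identical subsamples.
    """

    def __init__(self, depth: int = 1000, random_state: int | None = None):
        self.depth = depth
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.int64)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        totals = X.sum(axis=1)
        self.kept_idx_ = np.nonzero(totals >= self.depth)[0]
        if self.kept_idx_.size == 0:
            raise OtuTableError("no samples at requested depth")
        if self.kept_idx_.size < X.shape[0]:
            logger.warning("rarefaction drops %d of %d samples below depth %d",
                           X.shape[0] - self.kept_idx_.size, X.shape[0], self.depth)
        return self

    def transform(self, X):
        check_is_fitted(self, "kept_idx_")
        X = check_array(X, dtype=np.int64)
        rng = np.random.default_rng(self.random_state)
        out = np.empty((self.kept_idx_.size, X.shape[1]), dtype=np.int64)
        for i, idx in enumerate(self.kept_idx_):
            row = X[idx]
            if row.sum() == self.depth:
                out[i] = row
            else:
                out[i] = rng.multivariate_hypergeometric(row, self.depth)
        return out


class CSSNormalizer(BaseEstimator, TransformerMixin):
    """Cumulative sum scaling of count rows.

    For sample j, the scale factor ``s_j`` is the sum of counts that are
    less than or equal to the chosen quantile of the sample's *nonzero*
    count distribution (inclusive linear interpolation).  Output values
    are ``count / s_j * scaling_constant``.

    ``quantile="adaptive"`` walks a 0.05-step grid upward and stops at
    the first point where the median scale factor across samples changes
    by less than 10% relative to the previous grid point.

    Fitted attributes: ``quantile_`` (the quantile used) and
    ``scale_factors_`` (per retained sample).
    """

    def __init__(self, quantile: float | str = 0.5,
                 scaling_constant: float = 1000.0):
        self.quantile = quantile
        self.scaling_constant = scaling_constant

    @staticmethod
    def _factors(X: np.ndarray, q: float) -> np.ndarray:
        s = np.empty(X.shape[0])
        for j, row in enumerate(X):
            nz = row[row > 0]
            if nz.size == 0:
                raise OtuTableError(f"sample at row {j} has no nonzero counts")
            cutoff = np.quantile(nz, q)
            s[j] = row[row <= cutoff].sum()
        return s

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.scaling_constant <= 0:
            raise ValueError("scaling_constant must be positive")
        if self.quantile == "adaptive":
            grid = np.arange(0.05, 1.0, 0.05)
            prev = None
            chosen = grid[-1]
            for q in grid:
                med = np.median(self._factors(X, q))
                if prev is not None and prev > 0 and abs(med - prev) / prev < 0.10:
                    chosen = q
                    break
                prev = med
            self.quantile_ = float(chosen)
        else:
            q = float(self.quantile)
            if not 0.0 < q < 1.0:
                raise ValueError("quantile must lie in (0, 1)")
            self.quantile_ = q
        self.scale_factors_ = self._factors(X, self.quantile_)
        zero = self.scale_factors_ == 0
        if zero.any():
            raise OtuTableError(
                f"zero CSS scale factor for sample rows {np.nonzero(zero)[0].tolist()}")
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_factors_")
        X = check_array(X, dtype=float)
        return X / self.scale_factors_[:, None] * self.scaling_constant


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Keep taxa detected (count >= 1) in at least ``min_samples`` samples."""

    def __init__(self, min_samples: int = 20):
        self.min_samples = min_samples

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        prevalence = (X > 0).sum(axis=0)
        self.support_ = prevalence >= self.min_samples
        if not self.support_.any():
            logger.warning("prevalence filter removed every taxon")
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=float)
        return X[:, self.support_]


class AbundanceFilter(BaseEstimator, TransformerMixin):
    """Keep taxa whose overall relative abundance meets a threshold.

    Overall relative abundance = taxon total / grand total; the boundary
    is inclusive, so a taxon at exactly the threshold is retained.
    """

    def __init__(self, min_rel_abundance: float = 0.001):
        self.min_rel_abundance = min_rel_abundance

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if not 0.0 <= self.min_rel_abundance < 1.0:
            raise ValueError("min_rel_abundance must lie in [0, 1)")
        grand = X.sum()
        rel = X.sum(axis=0) / grand if grand > 0 else np.zeros(X.shape[1])
        self.support_ = rel >= self.min_rel_abundance
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=float)
        return X[:, self.support_]


# -- OtuTable-level wrappers ----------------------------------------------

def rarefy(table: OtuTable, depth: int = 1000,
           seed: int | None = None) -> NormalizedTable:
    """Rarefy an :class:`OtuTable` to an even depth (default 1,000 reads)."""
    est = Rarefier(depth=depth, random_state=seed)
    X = table.counts.to_numpy().T
    out = est.fit(X).transform(X)
    kept = [table.sample_ids[i] for i in est.kept_idx_]
    values = pd.DataFrame(out.T, index=table.otu_ids, columns=kept)
    return NormalizedTable(values, "rarefied",
                           {"depth": depth, "seed": seed},
                           metadata=table.metadata.loc[kept])


def css_normalize(table: OtuTable, quantile: float | str = 0.5,
                  scaling_constant: float = 1000.0) -> NormalizedTable:
    """CSS-normalize an :class:`OtuTable`."""
    est = CSSNormalizer(quantile=quantile, scaling_constant=scaling_constant)
    X = table.counts.to_numpy(dtype=float).T
    out = est.fit(X).transform(X)
    values = pd.DataFrame(out.T, index=table.otu_ids, columns=table.sample_ids)
    return NormalizedTable(values, "css",
                           {"quantile": est.quantile_,
                            "scaling_constant": scaling_constant,
                            "scale_factors": est.scale_factors_.tolist()},
                           metadata=table.metadata)


def relative_abundance(table: OtuTable) -> NormalizedTable:
    """Per-sample relative abundances (columns sum to 1)."""
    v = table.counts.to_numpy(dtype=float)
    values = pd.DataFrame(v / v.sum(axis=0, keepdims=True),
                          index=table.otu_ids, columns=table.sample_ids)
    return NormalizedTable(values, "relative", {}, metadata=table.metadata)


def filter_prevalence(table: OtuTable, min_samples: int = 20) -> OtuTable:
    """Keep OTUs present in at least ``min_samples`` samples (order kept)."""
    est = PrevalenceFilter(min_samples=min_samples)
    est.fit(table.counts.to_numpy().T)
    kept = [o for o, keep in zip(table.otu_ids, est.support_) if keep]
    return table.subset_otus(kept)


def filter_abundance(table: OtuTable, min_rel_abundance: float = 0.001) -> OtuTable:
    """Keep OTUs at or above an overall relative-abundance threshold."""
    est = AbundanceFilter(min_rel_abundance=min_rel_abundance)
    est.fit(table.counts.to_numpy(dtype=float).T)
    kept = [o for o, keep in zip(table.otu_ids, est.support_) if keep]
    return table.subset_otus(kept)
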