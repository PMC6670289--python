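"""OTU count tables: data model, TSV I/O, and shared-OTU membership summaries.

The central container is :class:`OtuTable`, an integer count matrix
(OTUs x samples) with per-sample metadata (environment, vineyard, time
point, replicate) and optional taxonomy strings per OTU.  Tables are
backed by pandas and validated on construction: counts must be
non-negative integers, identifiers unique, every sample must carry an
environment label, and all-zero samples are rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("environment", "vineyard", "timepoint", "replicate")


class OtuTableError(ValueError):
    """Raised when an OTU table violates its invariants."""


def percent_of(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` out of ``total`` rounded to ``decimals``.

    Used by membership summaries so that reported percentages share one
    rounding convention (round-half-to-even, as numpy does).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * count / total, decimals))


@dataclass
class OtuTable:
    """Validated OTU count table with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, index = OTU ids,
        columns = sample ids.
    metadata
        DataFrame indexed by sample id with at least an ``environment``
        column; ``vineyard``, ``timepoint`` and ``replicate`` are kept if
        present.
    taxonomy
        Optional Series of semicolon-ranked lineage strings per OTU.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series | None = None
    #: allow columns that became all-zero through OTU filtering (flagged,
    #: not rejected); fresh tables read from disk keep the strict check.
    allow_empty_samples: bool = False

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate OTU ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise OtuTableError("counts must be numeric")
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise OtuTableError(
                f"negative count at OTU {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        if not np.allclose(values, np.round(values)):
            raise OtuTableError("counts must be integers")
        self.counts = counts.astype(np.int64)
        zero = self.counts.sum(axis=0) == 0
        if self.counts.shape[0] > 0 and zero.any():
            if self.allow_empty_samples:
                logger.warning("all-zero samples flagged: %s",
                               list(self.counts.columns[zero]))
            else:
                raise OtuTableError(
                    f"all-zero samples not allowed: {list(self.counts.columns[zero])}"
                )
        if "environment" not in self.metadata.columns:
            raise OtuTableError("metadata must contain an 'environment' column")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise OtuTableError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.metadata.index if s not in self.counts.columns]
        if extra:
            logger.warning("dropping metadata-only samples: %s", extra)
        self.metadata = self.metadata.loc[list(self.counts.columns)].copy()
        if self.metadata["environment"].isna().any():
            bad = self.metadata.index[self.metadata["environment"].isna()].tolist()
            raise OtuTableError(f"samples without environment label: {bad}")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    # -- convenience accessors -------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def environments(self) -> list[str]:
        """Environment labels in first-appearance order."""
        return list(dict.fromkeys(self.metadata["environment"]))

    def samples_in(self, environment: str) -> list[str]:
        mask = self.metadata["environment"] == environment
        return list(self.metadata.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        counts = self.counts[list(sample_ids)]
        return OtuTable(counts, self.metadata.loc[list(sample_ids)], self.taxonomy)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        tax = self.taxonomy.loc[list(otu_ids)] if self.taxonomy is not None else None
        return OtuTable(self.counts.loc[list(otu_ids)], self.metadata, tax,
                        allow_empty_samples=True)


@dataclass
class NormalizedTable:
    """Real-valued table produced by a normalization step.

    ``method`` is one of ``{"rarefied", "css", "relative"}``;
    ``parameters`` records depth/quantile/scaling constant and the seed
    used, so a table is reproducible from its provenance alone.
    """

    values: pd.DataFrame
    method: str
    parameters: dict = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0):
            raise OtuTableError("normalized values must be non-negative")
        if self.method == "rarefied":
            depth = self.parameters.get("depth")
            sums = v.sum(axis=0)
            if depth is not None and not np.all(sums == depth):
                raise OtuTableError("rarefied columns must sum exactly to depth")
        elif self.method == "relative":
            if not np.allclose(v.sum(axis=0), 1.0, atol=1e-9):
                raise OtuTableError("relative columns must sum to 1")
        elif self.method == "css":
            factors = self.parameters.get("scale_factors")
            if factors is not None and np.any(np.asarray(factors) <= 0):
                raise OtuTableError("CSS scale factors must be positive")
        else:
            raise OtuTableError(f"unknown normalization method {self.method!r}")


# -- I/O ------------------------------------------------------------------

def read_otu_table(table_path: str | Path, metadata_path: str | Path) -> OtuTable:
    """Read a tab-separated OTU table and its sample metadata.

    The table has OTU ids in the first column, one numeric column per
    sample, and optionally a trailing ``taxonomy`` column.  The metadata
    file has one row per sample with at least ``sample_id`` and
    ``environment`` columns.  Samples present in the table but absent
    from the metadata raise an error; metadata-only samples are dropped
    with a warning.
    """
    raw = pd.read_csv(table_path, sep="\t", index_col=0, comment="#")
    taxonomy = None
    if raw.columns.size and str(raw.columns[-1]).lower() == "taxonomy":
        taxonomy = raw.iloc[:, -1].astype(str)
        raw = raw.iloc[:, :-1]
    try:
        counts = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        # locate the offending cell for the error message
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad][0]
                raise OtuTableError(
                    f"malformed numeric cell at OTU {row!r}, sample {col!r}"
                ) from exc
        raise
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in meta.columns:
        raise OtuTableError("metadata must contain a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        dupes = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
        raise OtuTableError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.set_index("sample_id")
    return OtuTable(counts, meta, taxonomy)


def write_otu_table(table: OtuTable, table_path: str | Path,
                    metadata_path: str | Path,
                    header_lines: Iterable[str] = ()) -> None:
    """Write a table and metadata as TSV; inverse of :func:`read_otu_table`."""
    out = table.counts.copy()
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    _write_tsv(out, table_path, header_lines, index_label="otu_id")
    meta = table.metadata.copy()
    _write_tsv(meta, metadata_path, header_lines, index_label="sample_id")


def _write_tsv(frame: pd.DataFrame, path: str | Path,
               header_lines: Iterable[str] = (), index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index_label=index_label)


# -- shared-OTU membership -------------------------------------------------

@dataclass
class SharedOtuSummary:
    """Counts of OTUs present in exactly each non-empty subset of groups."""

    subset_counts: dict[frozenset, int]
    group_totals: dict[str, int]
    n_otus: int

    def percent(self, subset: Iterable[str], decimals: int = 1) -> float:
        return percent_of(self.subset_counts.get(frozenset(subset), 0),
                          self.n_otus, decimals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, count in sorted(self.subset_counts.items(),
                                    key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            rows.append({
                "groups": "&".join(sorted(subset)),
                "n_otus": count,
                "percent": percent_of(count, self.n_otus),
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "n_otus": self.n_otus,
            "group_totals": self.group_totals,
            "subsets": [
                {"groups": sorted(s), "n_otus": c,
                 "percent": percent_of(c, self.n_otus)}
                for s, c in self.subset_counts.items()
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def shared_otu_summary(table: OtuTable,
                       grouping: str | Mapping[str, str] = "environment"
                       ) -> SharedOtuSummary:
    """Membership of OTUs across groups of samples (shared/unique breakdown).

    For every non-empty subset of groups, counts the OTUs detected
    (count >= 1 in at least one sample) in exactly that subset.  With
    ``grouping="environment"`` this reproduces the shared/unique OTU
    breakdown among air and plant-organ communities.
    """
    if isinstance(grouping, str):
        if grouping not in table.metadata.columns:
            raise OtuTableError(f"unknown grouping column {grouping!r}")
        labels = table.metadata[grouping]
    else:
        missing = [s for s in table.sample_ids if s not in grouping]
        if missing:
            raise OtuTableError(f"samples without group label: {missing}")
        labels = pd.Series({s: grouping[s] for s in table.sample_ids})
    groups = list(dict.fromkeys(labels))
    if len(groups) < 1:
        raise OtuTableError("at least one group required")
    present = {}
    for g in groups:
        cols = [s for s in table.sample_ids if labels[s] == g]
        present[g] = (table.counts[cols].to_numpy() > 0).any(axis=1)
    membership = np.stack([present[g] for g in groups])  # groups x otus
    detected = membership.any(axis=0)
    subset_counts: dict[frozenset, int] = {}
    keys = [frozenset(g for gi, g in enumerate(groups) if membership[gi, j])
            for j in np.nonzero(detected)[0]]
    for key in keys:
        subset_counts[key] = subset_counts.get(key, 0) + 1
    group_totals = {g: int(present[g].sum()) for g in groups}
    return SharedOtuSummary(subset_counts, group_totals, int(detected.sum()))
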