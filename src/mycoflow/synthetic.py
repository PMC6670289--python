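"""Synthetic phyllosphere communities with known source-attribution truth.

The generator emulates an amplicon survey of fungal communities on grape
organs (leaves, flowers, fruit) and in vineyard air: four environments,
a few hundred taxa, heavily uneven compositions, and sequencing depths
in the 10^3-10^4 range with Dirichlet-multinomial overdispersion.

Each environment has a base composition; a sink environment's samples
are drawn from the convex combination of the source environments' base
compositions given by its mixing row, plus a reserved-block Unknown
pool, so the attribution truth is planted explicitly and recoverable.
A note on the closed-system variant (every environment mixed at once)
and why it is not statistically identifiable is in docs/methods.md.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .otu import OtuTable, read_otu_table, write_otu_table

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"

#: Published estimated source fractions of fungal communities among
#: vineyard air and grape organs (rows = sinks, read along the row;
#: each row lists the fraction of that community attributed to each
#: other environment plus an unexplained Unknown component).  Printed
#: rows can sum to 1.01 due to rounding; they are kept verbatim here and
#: renormalized only where a model requires exact simplex rows.
VINEYARD_ATTRIBUTION: dict[str, dict[str, float]] = {
    "air":    {"fruit": 0.54, "leaf": 0.30, "flower": 0.08, UNKNOWN: 0.08},
    "fruit":  {"air": 0.35, "leaf": 0.47, "flower": 0.17, UNKNOWN: 0.01},
    "leaf":   {"air": 0.15, "fruit": 0.32, "flower": 0.52, UNKNOWN: 0.02},
    "flower": {"air": 0.04, "fruit": 0.12, "leaf": 0.81, UNKNOWN: 0.04},
}


@dataclass
class CommunityModel:
    """Generative truth for a multi-environment OTU table.

    Attributes
    ----------
    environments : list of str
        Ordered environment labels.
    base_composition : DataFrame (environments x taxa)
        Per-environment taxon probability vectors; each sample of an
        environment is drawn around its row.
    mixing : DataFrame (environments x environments + Unknown)
        Truth attribution: row e gives the fraction of environment e's
        community contributed by each other environment and by the
        Unknown pool.  Rows sum to 1; the diagonal is 0 unless
        self-mixing is deliberately modeled.
    unknown_composition : DataFrame (environments x taxa)
        Per-environment exogenous pool compositions (disjoint taxon
        blocks by default) backing the Unknown column.
    dispersion : float
        Overdispersion theta >= 0; 0 gives multinomial counts, otherwise
        Dirichlet-multinomial with concentration composition / theta.
    depth : int or (mean, sigma) tuple
        Fixed per-sample read total, or log-normal parameters.
    n_samples : dict env -> int
        Samples per environment.
    seed : int
        Master seed for all randomness in :func:`simulate`.
    """

    environments: list[str]
    base_composition: pd.DataFrame
    mixing: pd.DataFrame
    unknown_composition: pd.DataFrame
    dispersion: float = 0.01
    depth: int | tuple[float, float] = 2000
    n_samples: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    #: environments whose samples are drawn directly from their base
    #: composition instead of their mixing row (they act as pure
    #: sources; see make_paper_like_model for why this matters).
    source_only: frozenset = frozenset()

    def __post_init__(self) -> None:
        comp = self.base_composition.to_numpy()
        if self.base_composition.shape[1] < 2:
            raise ValueError("n_taxa must be >= 2")
        if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("base compositions must sum to 1")
        if not np.allclose(self.mixing.to_numpy().sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("mixing rows must sum to 1")
        if not np.allclose(self.unknown_composition.to_numpy().sum(axis=1), 1.0,
                           atol=1e-9):
            raise ValueError("unknown compositions must sum to 1")

    @property
    def n_taxa(self) -> int:
        return self.base_composition.shape[1]

    def effective_composition(self, env: str) -> np.ndarray:
        """Sink composition: sum_v mixing[env][v] * base_v + unknown term.

        Environments in ``source_only`` return their base composition.
        """
        if env in self.source_only:
            return self.base_composition.loc[env].to_numpy().copy()
        row = self.mixing.loc[env]
        comp = np.zeros(self.n_taxa)
        for v in self.environments:
            w = row.get(v, 0.0)
            if v != env and w:
                comp += w * self.base_composition.loc[v].to_numpy()
            elif v == env and w:  # explicit self-mixing (identity models)
                comp += w * self.base_composition.loc[v].to_numpy()
        comp += row[UNKNOWN] * self.unknown_composition.loc[env].to_numpy()
        return comp


@dataclass
class SyntheticDataset:
    """A simulated OTU table together with its generative truth."""

    table: OtuTable
    truth: CommunityModel
    realized_mixing: pd.DataFrame  # per-sample realized source fractions


def vineyard_mixing_matrix() -> pd.DataFrame:
    """The published attribution truth with rows renormalized to sum 1.

    Printed rows can sum to 1.01 because the source cells are rounded;
    the generative truth must be an exact simplex row.
    """
    envs = ["air", "fruit", "leaf", "flower"]
    mix = pd.DataFrame(0.0, index=envs, columns=envs + [UNKNOWN])
    for e in envs:
        row = VINEYARD_ATTRIBUTION[e]
        total = sum(row.values())
        for src, val in row.items():
            mix.loc[e, src] = val / total
    return mix


def make_paper_like_model(seed: int = 0, n_taxa: int = 300,
                          n_samples_per_env: int = 10,
                          depth: int | tuple[float, float] = 2000,
                          dispersion: float = 0.01,
                          concentration: float = 0.05,
                          sink_env: str | None = None) -> CommunityModel:
    """Four-environment vineyard model carrying the published mixing truth.

    Base compositions are independent symmetric-Dirichlet draws
    (concentration 0.05 per taxon — heavily uneven, a few dominant taxa)
    over a shared named-taxon region; each environment additionally owns
    a disjoint reserved block carrying its exogenous Unknown pool, so
    the Unknown fraction is identifiable.

    ``sink_env`` selects the well-posed parameter-recovery layout: that
    environment's samples follow its mixing row (a convex combination of
    the *other* environments' base compositions plus its Unknown pool)
    while the other environments are sampled directly from their own
    base compositions and act as pure sources.  With ``sink_env=None``
    every environment's samples follow its mixing row simultaneously; in
    that closed system the published matrix cannot be recovered by
    rotation source tracking, because sources are then themselves
    mixtures that contain none of their own base signal (see
    docs/methods.md for the identifiability analysis).
    """
    envs = ["air", "fruit", "leaf", "flower"]
    rng = np.random.default_rng(seed)
    k = len(envs)
    # reserve the tail of the taxon axis for the exogenous pools
    n_unknown = max(k, int(round(0.2 * n_taxa)))
    n_named = n_taxa - n_unknown
    block = n_unknown // k
    base = np.zeros((k, n_taxa))
    psi = np.zeros((k, n_taxa))
    for i in range(k):
        base[i, :n_named] = rng.dirichlet(np.full(n_named, concentration))
        start = n_named + i * block
        stop = n_named + (i + 1) * block if i < k - 1 else n_taxa
        psi[i, start:stop] = rng.dirichlet(np.full(stop - start, concentration))
    taxa = [f"OTU_{t:04d}" for t in range(n_taxa)]
    source_only = (frozenset(e for e in envs if e != sink_env)
                   if sink_env is not None else frozenset())
    return CommunityModel(
        environments=envs,
        base_composition=pd.DataFrame(base, index=envs, columns=taxa),
        mixing=vineyard_mixing_matrix(),
        unknown_composition=pd.DataFrame(psi, index=envs, columns=taxa),
        dispersion=dispersion,
        depth=depth,
        n_samples={e: n_samples_per_env for e in envs},
        seed=seed,
        source_only=source_only,
    )


def make_independent_model(base_composition: pd.DataFrame,
                           mixing: pd.DataFrame,
                           unknown_composition: pd.DataFrame | None = None,
                           dispersion: float = 0.0,
                           depth: int | tuple[float, float] = 2000,
                           n_samples: dict[str, int] | None = None,
                           seed: int = 0) -> CommunityModel:
    """Model with caller-supplied compositions (self-mixing allowed).

    Useful for controlled experiments, e.g. identity mixing where every
    environment is drawn from its own base composition.
    """
    envs = list(base_composition.index)
    if unknown_composition is None:
        unknown_composition = pd.DataFrame(
            np.full((len(envs), base_composition.shape[1]),
                    1.0 / base_composition.shape[1]),
            index=envs, columns=base_composition.columns)
    mixing = mixing.copy()
    if UNKNOWN not in mixing.columns:
        mixing[UNKNOWN] = 0.0
    # an all-zero row marks a pure source environment: its samples are
    # drawn from its own base composition
    source_only = frozenset(
        e for e in envs
        if e in mixing.index and mixing.loc[e].sum() == 0)
    for e in source_only:
        mixing.loc[e, e] = 1.0
    return CommunityModel(envs, base_composition, mixing, unknown_composition,
                          dispersion=dispersion, depth=depth,
                          n_samples=n_samples or {e: 10 for e in envs},
                          seed=seed, source_only=source_only)


def simulate(model: CommunityModel) -> SyntheticDataset:
    """Draw an OTU table from a :class:`CommunityModel`.

    Each sample of environment e has expected composition
    ``model.effective_composition(e)``; counts are multinomial at the
    sample's depth, or Dirichlet-multinomial with concentration
    composition / theta when ``dispersion`` theta > 0.  Deterministic
    given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    taxa = list(model.base_composition.columns)
    counts = {}
    meta_rows = {}
    realized = {}
    vineyards = ["V1", "V2"]
    timepoints = ["Jun", "Jul", "Aug", "Sep", "Oct"]
    for env in model.environments:
        comp = model.effective_composition(env)
        n = model.n_samples.get(env, 0)
        for r in range(n):
            if isinstance(model.depth, tuple):
                mean, sigma = model.depth
                depth = int(np.round(rng.lognormal(np.log(mean), sigma)))
            else:
                depth = int(model.depth)
            if depth <= 0:
                raise ValueError("sample depth must be positive")
            if model.dispersion > 0:
                alpha = np.where(comp > 0, comp / model.dispersion, 0.0)
                p = np.zeros_like(comp)
                pos = alpha > 0
                p[pos] = rng.dirichlet(alpha[pos])
            else:
                p = comp
            sid = f"{env}_{r:02d}"
            counts[sid] = rng.multinomial(depth, p)
            meta_rows[sid] = {
                "environment": env,
                "vineyard": vineyards[r % len(vineyards)],
                "timepoint": timepoints[r % len(timepoints)],
                "replicate": str(r),
            }
            realized[sid] = model.mixing.loc[env].to_dict()
    counts_df = pd.DataFrame(counts, index=taxa)
    meta_df = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta_df.index.name = "sample_id"
    taxonomy = pd.Series(
        {t: f"k__Fungi;p__Placeholder;g__Genus{i % 40}"
         for i, t in enumerate(taxa)})
    table = OtuTable(counts_df, meta_df, taxonomy)
    realized_df = pd.DataFrame.from_dict(realized, orient="index")
    return SyntheticDataset(table, model, realized_df)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write table.tsv, metadata.tsv and truth.json; round-trips via
    :func:`mycoflow.otu.read_otu_table`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": directory / "table.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    write_otu_table(dataset.table, paths["table"], paths["metadata"])
    truth = {
        "environments": dataset.truth.environments,
        "mixing": {e: dataset.truth.mixing.loc[e].to_dict()
                   for e in dataset.truth.environments},
        "dispersion": dataset.truth.dispersion,
        "depth": dataset.truth.depth if not isinstance(dataset.truth.depth, tuple)
        else list(dataset.truth.depth),
        "n_samples": dataset.truth.n_samples,
        "seed": dataset.truth.seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths


def read_fixture(directory: str | Path) -> tuple[OtuTable, dict]:
    """Read a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    table = read_otu_table(directory / "table.tsv", directory / "metadata.tsv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return table, truth


def make_coupled_pairs_dataset(n_pos: int = 10, n_neg: int = 5,
                               n_background: int = 20, n_samples: int = 60,
                               depth: int = 5000, rho: float = 0.8,
                               seed: int = 0):
    """Count table with planted co-occurring and mutually exclusive pairs.

    Latent per-taxon log-abundances follow a Gaussian copula: each
    planted pair shares correlation ``+rho`` (co-occurrence) or ``-rho``
    (exclusion); background taxa are independent.  Log-abundances are
    exponentiated into relative abundances and counts drawn multinomially
    per sample, reproducing the compositional noise real tables carry.

    Returns ``(counts DataFrame taxa x samples, planted edge list)`` with
    each planted edge a ``(taxon_a, taxon_b, sign)`` tuple.
    """
    rng = np.random.default_rng(seed)
    n_taxa = 2 * (n_pos + n_neg) + n_background
    z = rng.standard_normal((n_samples, n_taxa))
    edges = []
    col = 0
    for i in range(n_pos + n_neg):
        sign = 1 if i < n_pos else -1
        a, b = col, col + 1
        shared = rng.standard_normal(n_samples)
        s, e = np.sqrt(rho), np.sqrt(1.0 - rho)
        z[:, a] = s * shared + e * rng.standard_normal(n_samples)
        z[:, b] = sign * s * shared + e * rng.standard_normal(n_samples)
        edges.append((f"T{a:03d}", f"T{b:03d}", sign))
        col += 2
    mu = rng.normal(0.0, 1.0, n_taxa)
    abund = np.exp(mu[None, :] + 1.0 * z)
    probs = abund / abund.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs]).T
    taxa = [f"T{t:03d}" for t in range(n_taxa)]
    samples = [f"S{s:02d}" for s in range(n_samples)]
    return pd.DataFrame(counts, index=taxa, columns=samples), edges
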