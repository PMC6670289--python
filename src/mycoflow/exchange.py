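"""Pairwise community exchange statistic and the index of conservation.

Given an attribution matrix f (rows = sink environments, columns =
source environments + Unknown), the round-trip exchange fraction for an
unordered pair of environments is

    z(A, B) = f[A][B] * f[B][A]

— the fraction of A's community that came from B times the fraction of
B's community that came from A, read as the share of a community that
leaves for the partner environment and returns.  Summing z over all
partners of an environment gives its index of conservation: the total
fraction of that community that cycles back through the other
environments, with higher values indicating a more stable, shared
community.  The Unknown column has no reciprocal row and is excluded.

All computation is at full precision; rounding happens only in the
display layer (percentages, round-half-to-even, one decimal by default
or nearest integer for values >= 10 when ``mixed_style`` rounding is
selected).

z is a product of two *estimated* fractions; it is reported as defined,
with no claim that true round-trip movement of taxa is identifiable
from it.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .otu import _write_tsv
from .sourcetracker import UNKNOWN, AttributionMatrix


def pair_exchange(f: AttributionMatrix, a: str, b: str) -> float:
    """z(a, b) = f[a][b] * f[b][a], full precision."""
    if a == b:
        raise ValueError("exchange is defined for two distinct environments")
    return f.fraction(a, b) * f.fraction(b, a)


def conservation_index(f: AttributionMatrix, env: str) -> float:
    """Sum of z(env, B) over every other named environment B."""
    if env not in f.environments:
        raise KeyError(f"unknown environment {env!r}")
    return float(sum(pair_exchange(f, env, b)
                     for b in f.environments if b != env))


def display_percent(value: float, mixed_style: bool = False,
                    decimals: int = 1) -> float:
    """Percentage for display: one decimal, or nearest integer when the
    value is >= 10% and ``mixed_style`` is on."""
    pct = 100.0 * value
    if mixed_style and pct >= 10:
        return float(np.round(pct, 0))
    return float(np.round(pct, decimals))


@dataclass
class ExchangeReport:
    """All pairwise z values and per-environment conservation indices."""

    z: pd.DataFrame                 # symmetric, NaN diagonal, full precision
    conservation: pd.Series         # per environment, full precision
    mixed_style: bool = False
    provenance: dict = field(default_factory=dict)

    def z_percent(self, a: str, b: str) -> float:
        return display_percent(self.z.loc[a, b], self.mixed_style)

    def conservation_percent(self, env: str) -> float:
        return display_percent(self.conservation[env], self.mixed_style)

    def pair_frame(self) -> pd.DataFrame:
        rows = []
        envs = list(self.z.index)
        for a, b in itertools.combinations(envs, 2):
            rows.append({"env_a": a, "env_b": b,
                         "z": self.z.loc[a, b],
                         "z_percent": self.z_percent(a, b)})
        return pd.DataFrame(rows)

    def conservation_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "environment": list(self.conservation.index),
            "index": self.conservation.to_numpy(),
            "index_percent": [self.conservation_percent(e)
                              for e in self.conservation.index],
        })

    def write(self, directory: str | Path, header_lines=()) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"pairs": directory / "exchange_pairs.tsv",
                 "conservation": directory / "conservation.tsv",
                 "json": directory / "exchange.json"}
        _write_tsv(self.pair_frame().set_index("env_a"), paths["pairs"],
                   header_lines, index_label="env_a")
        _write_tsv(self.conservation_frame().set_index("environment"),
                   paths["conservation"], header_lines,
                   index_label="environment")
        payload = {
            "z": {a: {b: (None if np.isnan(v) else float(v))
                      for b, v in self.z.loc[a].items()}
                  for a in self.z.index},
            "conservation": {e: float(v)
                             for e, v in self.conservation.items()},
            "note": ("z = f[A][B]*f[B][A] is a product of estimated "
                     "fractions; round-trip movement itself is not "
                     "identified"),
            **self.provenance,
        }
        with open(paths["json"], "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return paths


def exchange_report(f: AttributionMatrix, mixed_style: bool = False
                    ) -> ExchangeReport:
    """Compute every pairwise z and every conservation index."""
    envs = [e for e in f.environments if e != UNKNOWN]
    if len(envs) < 2:
        raise ValueError("at least two environments required")
    z = pd.DataFrame(np.nan, index=envs, columns=envs)
    for a, b in itertools.combinations(envs, 2):
        val = pair_exchange(f, a, b)
        z.loc[a, b] = z.loc[b, a] = val
    conservation = pd.Series({e: conservation_index(f, e) for e in envs})
    return ExchangeReport(z, conservation, mixed_style=mixed_style)
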