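"""Core in-memory container: the taxon x sample count table.

A :class:`CountTable` holds nonnegative integer amplicon counts for a set of
taxa across a set of samples, where each sample is identified by a
(condition, fraction-or-bin, replicate) key. Fractions are integer gradient
fraction indices (1 = bottom = densest); bins are named pools of fractions
("light", "middle", "heavy"). Taxon lineages (phylum ... species) ride along
in a separate frame so rank-level aggregation has something to chew on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["CountTable", "make_sample_id", "LINEAGE_RANKS"]

#: Canonical lineage ranks, most inclusive first.
LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus", "species")

CONDITIONS = ("labeled", "control")


def make_sample_id(condition: str, unit: str | int, replicate: str | int) -> str:
    """Stable sample identifier, e.g. ``labeled:F04:r1`` or ``control:heavy:r2``."""
    if isinstance(unit, (int, np.integer)):
        unit = f"F{int(unit):02d}"
    return f"{condition}:{unit}:r{replicate}"


@dataclass
class CountTable:
    """Taxa x samples integer counts plus per-sample metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Rows indexed by taxon id, columns by sample id; nonnegative integers.
    samples : pandas.DataFrame
        Indexed by sample id, with columns ``condition`` (labeled/control),
        ``fraction`` (nullable integer index), ``bin`` (nullable string) and
        ``replicate``.
    lineages : pandas.DataFrame or None
        Indexed by taxon id with a subset of :data:`LINEAGE_RANKS` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lineages: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if c.columns.duplicated().any():
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integral")
        missing = set(c.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"samples metadata lacks required column {col!r}")

    # -- accessors -------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def select(
        self,
        condition: str | None = None,
        bin: str | None = None,
        fraction: int | None = None,
    ) -> "CountTable":
        """Subset samples by metadata; taxa are kept as-is."""
        meta = self.samples.loc[self.counts.columns]
        keep = pd.Series(True, index=meta.index)
        if condition is not None:
            keep &= meta["condition"] == condition
        if bin is not None:
            if "bin" not in meta.columns:
                raise ValueError("table has no bin annotations")
            keep &= meta["bin"] == bin
        if fraction is not None:
            if "fraction" not in meta.columns:
                raise ValueError("table has no fraction annotations")
            keep &= meta["fraction"] == fraction
        ids = meta.index[keep]
        return CountTable(
            counts=self.counts[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            lineages=self.lineages,
        )

    def depth(self) -> pd.Series:
        """Total counts per sample."""
        return self.counts.sum(axis=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountTable({self.counts.shape[0]} taxa x "
            f"{self.counts.shape[1]} samples)"
        )


def concat_tables(tables: Iterable[CountTable]) -> CountTable:
    """Concatenate tables sample-wise over a shared taxon universe (union, 0-filled)."""
    tables = list(tables)
    counts = pd.concat([t.counts for t in tables], axis=1).fillna(0).astype(int)
    samples = pd.concat([t.samples for t in tables], axis=0)
    lineages = next((t.lineages for t in tables if t.lineages is not None), None)
    return CountTable(counts=counts, samples=samples, lineages=lineages)
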