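"""Alpha-diversity summaries and rank-level aggregation for count tables.

Richness (observed taxa), Shannon and Gini-Simpson indices, Faith's
phylogenetic diversity against a user tree, exact (hypergeometric)
rarefaction curves, and phylum-style rank aggregation. Index computations
delegate to scikit-bio; the analytic rarefaction expectation and the rank
roll-up are implemented here.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import TreeNode
from skbio.diversity import alpha as _alpha

from .containers import CountTable

__all__ = [
    "observed_richness",
    "shannon",
    "simpson",
    "rarefaction_curve",
    "faith_pd",
    "aggregate_by_rank",
    "diversity_report",
]


def _as_counts(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return arr


def observed_richness(counts: Sequence[float]) -> int:
    """Number of taxa with a nonzero count."""
    return int(np.count_nonzero(_as_counts(counts)))


def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy -sum p ln p, natural log by default (pass base=2 for bits)."""
    arr = _as_counts(counts)
    if not arr.sum() > 0:
        raise ValueError("empty sample")
    return float(_alpha.shannon(arr, base=base if base is not None else np.e))


def simpson(
    counts: Sequence[float],
    variant: Literal["gini", "dominance", "inverse"] = "gini",
) -> float:
    """Simpson-family index; the default is Gini-Simpson 1 - sum(p^2).

    ``variant="dominance"`` returns the raw sum(p^2) and ``"inverse"`` its
    reciprocal, for tables reported under those conventions.
    """
    arr = _as_counts(counts)
    total = arr.sum()
    if not total > 0:
        raise ValueError("empty sample")
    d = float(np.sum((arr / total) ** 2))
    if variant == "gini":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown variant {variant!r}")


def rarefaction_curve(
    counts: Sequence[float],
    depths: Sequence[int],
    mode: Literal["analytic", "resample"] = "analytic",
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected richness at the given subsampling depths.

    ``analytic`` uses the exact hypergeometric expectation
    ``E[S_d] = sum_i [1 - C(N - n_i, d) / C(N, d)]`` (computed through log
    binomial coefficients for stability); ``resample`` averages richness over
    ``reps`` random without-replacement subsamples. Returns a frame with
    ``depth`` and ``expected_richness`` columns.
    """
    arr = _as_counts(counts).astype(np.int64)
    total = int(arr.sum())
    rows = []
    for d in depths:
        d = int(d)
        if d > total:
            raise ValueError(f"depth {d} exceeds total count {total}")
        if mode == "analytic":
            nz = arr[arr > 0]
            # log C(N - n_i, d) - log C(N, d); taxa with N - n_i < d are
            # guaranteed present in every subsample
            can_miss = (total - nz) >= d
            log_miss = np.full(nz.shape, -np.inf)
            m = total - nz[can_miss]
            log_miss[can_miss] = (
                gammaln(m + 1) - gammaln(d + 1) - gammaln(m - d + 1)
                - (gammaln(total + 1) - gammaln(d + 1) - gammaln(total - d + 1))
            )
            expected = float(np.sum(1.0 - np.exp(log_miss)))
        elif mode == "resample":
            rng = np.random.default_rng(seed)
            rich = np.empty(reps)
            for r in range(reps):
                sub = rng.multivariate_hypergeometric(arr, d)
                rich[r] = np.count_nonzero(sub)
            expected = float(rich.mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"depth": d, "expected_richness": expected})
    return pd.DataFrame(rows)


def faith_pd(counts: Sequence[float], taxa: Sequence[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: branch length spanning the observed tips.

    Every taxon with a nonzero count must be a tip of ``tree``; absentees are
    listed in the error.
    """
    arr = _as_counts(counts)
    observed = [t for t, c in zip(taxa, arr) if c > 0]
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(observed) - tips)
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing}")
    return float(_alpha.faith_pd(arr, taxa=list(taxa), tree=tree))


def aggregate_by_rank(ct: CountTable, rank: str = "phylum") -> pd.DataFrame:
    """Proportion table rank-label x sample; unresolved lineages pool into "Other".

    Proportions sum to 1 per sample (multiply by 100 for a percent table).
    """
    if ct.lineages is None:
        raise ValueError("count table has no lineage annotations")
    if rank not in ct.lineages.columns:
        raise ValueError(
            f"rank {rank!r} absent from the lineage schema {list(ct.lineages.columns)}"
        )
    labels = ct.lineages[rank].reindex(ct.counts.index)
    labels = labels.where(labels.notna() & (labels != ""), "Other")
    grouped = ct.counts.groupby(labels.rename(rank)).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with no counts: {empty}")
    out = grouped / totals
    # keep "Other" last, as percent tables conventionally print it
    if "Other" in out.index:
        order = [r for r in out.index if r != "Other"] + ["Other"]
        out = out.loc[order]
    return out


def diversity_report(
    ct: CountTable,
    tree: TreeNode | None = None,
    rarefaction_depths: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-sample richness/diversity table (observed, Shannon, Gini-Simpson, PD).

    Shannon is natural-log. ``pd`` is filled only when a tree is supplied.
    Rarefaction expectations, if requested, appear as ``rarefied_<depth>``
    columns (depths beyond a sample's total are left missing).
    """
    rows = {}
    for sid in ct.sample_ids:
        counts = ct.counts[sid].to_numpy()
        row = {
            "observed": observed_richness(counts),
            "shannon": shannon(counts),
            "simpson": simpson(counts),
        }
        if tree is not None:
            row["pd"] = faith_pd(counts, ct.taxa, tree)
        if rarefaction_depths:
            total = counts.sum()
            for d in rarefaction_depths:
                if d <= total:
                    rc = rarefaction_curve(counts, [d])
                    row[f"rarefied_{d}"] = rc["expected_richness"].iloc[0]
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
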