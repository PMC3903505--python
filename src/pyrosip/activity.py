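"""Per-taxon metabolic-activity inference from binned SIP count tables.

The headline statistic: a taxon's *activity score* is its mean relative
abundance in the heavy fraction of the 13C-labeled sample minus that in the
heavy fraction of the unlabeled control, in percentage points. Taxa whose DNA
took up label migrate into the heavy fractions of the labeled gradient only,
so a positive, significant score marks a metabolically active taxon.

Significance follows the METASTATS design (White, Nagarajan & Pop 2009): a
two-sample t-statistic on replicate-level proportions, with its null
distribution built by permuting condition labels and, by default, pooling the
permuted statistics across taxa — with triplicates a single taxon admits only
20 distinct label assignments (two-sided minimum p = 0.1), so cross-feature
pooling is what makes p < 0.05 reachable at all. Sparse taxa fall back to
Fisher's exact test on the pooled 2x2 table.

Classification: *active* (positive score, significant), *less active*
(not active, but the taxon's own across-bin profile peaks in the middle bin
under labeling and not in the control — partial label uptake, the
Enterococcus pattern), otherwise *inactive*.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import group_assignments, t_for_splits
from .containers import CountTable

__all__ = [
    "relative_abundance",
    "replicate_proportions",
    "activity_score",
    "nonparametric_test",
    "peak_bins",
    "classify_activity",
    "activity_table",
    "activity_matrix",
]

CLASSES = ("active", "less_active", "inactive")


def relative_abundance(ct: CountTable, sample_id: str) -> pd.Series:
    """Per-taxon proportions in one sample; zero-count taxa get exactly 0."""
    if sample_id not in ct.counts.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    col = ct.counts[sample_id]
    total = col.sum()
    if not total > 0:
        raise ValueError(f"sample {sample_id!r} is empty")
    return col / total


def replicate_proportions(ct: CountTable, condition: str, bin: str = "heavy") -> pd.DataFrame:
    """Taxa x replicates proportion matrix for one condition and bin."""
    sub = ct.select(condition=condition, bin=bin)
    if not sub.sample_ids:
        raise ValueError(f"no {bin!r}-bin samples for condition {condition!r}")
    props = {sid: relative_abundance(sub, sid) for sid in sub.sample_ids}
    return pd.DataFrame(props)


def activity_score(ct: CountTable, bin: str = "heavy") -> pd.Series:
    """Activity score per taxon, percentage points.

    score(X) = 100 * [mean relabund(X | heavy, labeled)
                      - mean relabund(X | heavy, control)].
    Replicates are converted to proportions *before* averaging, so unequal
    sequencing depths never bias the score. Scores close under the
    composition: they sum to 0 over taxa.
    """
    p_lab = replicate_proportions(ct, "labeled", bin).mean(axis=1)
    p_ctl = replicate_proportions(ct, "control", bin).mean(axis=1)
    return 100.0 * (p_lab - p_ctl)


def nonparametric_test(
    ct: CountTable,
    n_permutations: int = 1000,
    seed: int = 0,
    sparse_threshold: int = 8,
    bin: str = "heavy",
    pool_null: bool = True,
    max_exact: int = 10_000,
) -> pd.DataFrame:
    """METASTATS-style per-taxon two-sided p-values in the heavy bin.

    For each taxon, a Welch t-statistic is computed on replicate-level
    proportions (labeled vs control); the null is formed by permuting
    condition labels — all distinct assignments are enumerated when there are
    at most ``max_exact``, otherwise ``n_permutations`` random shuffles are
    drawn. With ``pool_null=True`` (default, following METASTATS) permuted
    statistics are pooled across taxa, so small replicate numbers still admit
    small p-values; with ``pool_null=False`` each taxon is compared only to
    its own permutation distribution (3 vs 3 then bottoms out at p = 0.1).

    Taxa whose count pooled over all replicates and both conditions is below
    ``sparse_threshold`` are instead tested by Fisher's exact test on the
    2x2 table (taxon vs all others, labeled vs control, counts pooled).

    Returns a frame indexed by taxon with columns ``t``, ``p_value`` and
    ``method``; p-values are in (0, 1].
    """
    props_lab = replicate_proportions(ct, "labeled", bin)
    props_ctl = replicate_proportions(ct, "control", bin)
    n1, n2 = props_lab.shape[1], props_ctl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            "need at least 2 replicates per condition for the permutation test; "
            "with single replicates use activity_score alone"
        )
    counts_lab = ct.select(condition="labeled", bin=bin).counts.sum(axis=1)
    counts_ctl = ct.select(condition="control", bin=bin).counts.sum(axis=1)
    pooled = counts_lab + counts_ctl
    sparse = pooled < sparse_threshold

    taxa = list(ct.counts.index)
    values = np.hstack([props_lab.to_numpy(), props_ctl.to_numpy()])  # (F, n1+n2)
    # observed statistic through the same split machinery as the null, so
    # the identity assignment ties with itself exactly
    identity = np.zeros((1, n1 + n2), dtype=bool)
    identity[0, :n1] = True
    t_obs = t_for_splits(values, identity)[:, 0]

    rng = np.random.default_rng(seed)
    masks, exact = group_assignments(n1, n2, max_exact=max_exact,
                                     n_random=n_permutations, rng=rng)
    dense_idx = np.flatnonzero(~sparse.to_numpy())
    p = np.ones(len(taxa))
    if dense_idx.size:
        t_null = t_for_splits(values[dense_idx], masks)  # (Fd, S)
        abs_null = np.abs(t_null)
        # relative slack absorbs summation-order roundoff between the
        # observed statistic and its mirror splits
        abs_obs = np.abs(t_obs[dense_idx]) * (1.0 - 1e-9)
        if pool_null:
            flat = np.sort(abs_null.ravel())
            total = flat.size
            # count of null stats >= observed, via right-edge search
            ge = total - np.searchsorted(flat, abs_obs, side="left")
            p[dense_idx] = ge / total
        else:
            p[dense_idx] = (abs_null >= abs_obs[:, None]).mean(axis=1)
    # permutation p of 0 cannot occur when the identity split is enumerated,
    # but guard the sampled path so p stays in (0, 1]
    p = np.maximum(p, 1.0 / (masks.shape[0] * max(len(taxa), 1) + 1))

    method = np.where(sparse, "fisher_exact", "permutation")
    n_lab_total = int(counts_lab.sum())
    n_ctl_total = int(counts_ctl.sum())
    for i in np.flatnonzero(sparse.to_numpy()):
        table = [
            [int(counts_lab.iloc[i]), n_lab_total - int(counts_lab.iloc[i])],
            [int(counts_ctl.iloc[i]), n_ctl_total - int(counts_ctl.iloc[i])],
        ]
        p[i] = stats.fisher_exact(table, alternative="two-sided").pvalue

    return pd.DataFrame({"t": t_obs, "p_value": p, "method": method}, index=taxa)


def peak_bins(ct: CountTable, bin_order: tuple[str, ...] = ("light", "middle", "heavy")) -> pd.DataFrame:
    """Which bin each taxon's own abundance profile peaks in, per condition.

    The profile is the taxon's relative abundance per bin (replicate-averaged),
    renormalized within the taxon so conditions are comparable. Ties break
    toward the heavier bin (last in ``bin_order``), the conservative direction
    for the less-active call.
    """
    meta = ct.samples.loc[ct.counts.columns]
    bins = [b for b in bin_order if b in set(meta["bin"].dropna())]
    if not bins:
        raise ValueError("count table has no binned samples")
    out = {}
    for cond in sorted(meta["condition"].unique()):
        profile = pd.DataFrame(
            {b: replicate_proportions(ct, cond, b).mean(axis=1) for b in bins}
        )
        # within-taxon normalization is monotone, argmax unaffected; keep the
        # renormalized profile semantics by guarding all-zero rows
        arr = profile.to_numpy()
        idx = np.where(
            arr.sum(axis=1) > 0,
            arr.shape[1] - 1 - np.argmax(arr[:, ::-1], axis=1),  # last argmax
            -1,
        )
        out[cond] = [bins[i] if i >= 0 else "" for i in idx]
    return pd.DataFrame(out, index=ct.counts.index)


def classify_activity(
    scores: pd.Series,
    p_values: pd.Series,
    peaks: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Three-way activity call per taxon.

    active      — score > 0 and p < alpha (significantly label-enriched);
    less_active — not active, but the within-taxon profile peaks in the
                  middle bin under labeling and not in the control;
    inactive    — everything else.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    idx = scores.index
    if not (idx.equals(p_values.index) and idx.equals(peaks.index)):
        raise ValueError("scores, p_values and peaks must be aligned on taxa")
    active = (scores > 0) & (p_values < alpha)
    middle_shift = (peaks.get("labeled") == "middle") & (peaks.get("control") != "middle")
    cls = np.where(active, "active", np.where(middle_shift, "less_active", "inactive"))
    return pd.Series(cls, index=idx, name="activity_class")


def activity_table(
    ct: CountTable,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    sparse_threshold: int = 8,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full per-taxon activity results on a binned count table.

    Columns: ``score_pct_points``, ``p_value``, ``q_value`` (only if ``fdr``),
    ``activity_class``, ``peak_bin_labeled``, ``peak_bin_control`` and any
    lineage ranks available. No multiple-testing correction is applied by
    default (calls use the raw p at ``alpha``); ``fdr=True`` adds
    Benjamini-Hochberg q-values and bases the calls on them instead.
    """
    scores = activity_score(ct)
    test = nonparametric_test(ct, n_permutations=n_permutations, seed=seed,
                              sparse_threshold=sparse_threshold)
    peaks = peak_bins(ct)
    p = test["p_value"]
    out = pd.DataFrame({
        "score_pct_points": scores,
        "p_value": p,
        "test_method": test["method"],
        "peak_bin_labeled": peaks.get("labeled"),
        "peak_bin_control": peaks.get("control"),
    })
    if fdr:
        out["q_value"] = pd.Series(
            stats.false_discovery_control(p.to_numpy(), method="bh"), index=p.index
        )
        p = out["q_value"]
    out["activity_class"] = classify_activity(scores, p, peaks, alpha=alpha)
    if ct.lineages is not None:
        out = out.join(ct.lineages, how="left")
    out.index.name = "taxon"
    return out


def activity_matrix(
    results: Mapping[str, pd.DataFrame],
    abundances: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Long-format (stage, taxon) matrix of abundance and activity.

    ``results`` maps a stage name (e.g. "early", "late") to an
    :func:`activity_table` frame; ``abundances`` maps the stage to the
    control-community relative abundance per taxon (conventionally the
    light-bin control profile). Stages are joined over the union of taxa;
    a taxon absent from a stage contributes zeros, not missing values.
    """
    if set(results) != set(abundances):
        raise ValueError("results and abundances must cover the same stages")
    taxa: list[str] = []
    for stage in results:
        for t in list(results[stage].index) + list(abundances[stage].index):
            if t not in taxa:
                taxa.append(t)
    rows = []
    for stage in results:
        res = results[stage]
        ab = abundances[stage]
        for t in taxa:
            rows.append({
                "stage": stage,
                "taxon": t,
                "abundance": float(ab.get(t, 0.0)),
                "activity_score_pct_points": float(
                    res["score_pct_points"].get(t, 0.0)
                ),
                "activity_class": str(res["activity_class"].get(t, "inactive")),
            })
    return pd.DataFrame(rows)
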