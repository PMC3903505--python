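"""Activity scoring, permutation testing and three-way classification."""

import numpy as np
import pandas as pd
import pytest

from pyrosip import activity as act
from pyrosip.containers import CountTable


def build_table(heavy_labeled, heavy_control, extra_bins=None, taxa=None):
    """Binned table from per-replicate heavy-bin count lists (taxa x reps)."""
    heavy_labeled = np.asarray(heavy_labeled)
    heavy_control = np.asarray(heavy_control)
    n_taxa = heavy_labeled.shape[0]
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    cols, rows = {}, []

    def add(cond, bin_, mat):
        for rep in range(mat.shape[1]):
            sid = f"{cond}:{bin_}:r{rep + 1}"
            cols[sid] = mat[:, rep]
            rows.append({"sample_id": sid, "condition": cond, "bin": bin_,
                         "fraction": pd.NA, "replicate": rep + 1})

    add("labeled", "heavy", heavy_labeled)
    add("control", "heavy", heavy_control)
    for (cond, bin_), mat in (extra_bins or {}).items():
        add(cond, bin_, np.asarray(mat))
    return CountTable(counts=pd.DataFrame(cols, index=taxa),
                      samples=pd.DataFrame(rows).set_index("sample_id"))


class TestRelativeAbundance:
    def test_worked_proportions(self):
        ct = build_table([[17200], [16400], [66400]], [[1], [1], [1]])
        p = act.relative_abundance(ct, "labeled:heavy:r1")
        assert np.allclose(p, [0.172, 0.164, 0.664])

    def test_single_taxon(self):
        ct = build_table([[100]], [[50]])
        assert act.relative_abundance(ct, "labeled:heavy:r1").iloc[0] == 1.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        ct = build_table(rng.integers(1, 100, (6, 2)), rng.integers(1, 100, (6, 2)))
        for sid in ct.sample_ids:
            assert act.relative_abundance(ct, sid).sum() == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        ct = build_table([[0], [1]], [[1], [1]])
        ct.counts["labeled:heavy:r1"] = 0
        with pytest.raises(ValueError):
            act.relative_abundance(ct, "labeled:heavy:r1")


class TestActivityScore:
    def test_identical_compositions_score_zero(self):
        ct = build_table([[30, 30], [70, 70]], [[30, 30], [70, 70]])
        assert np.allclose(act.activity_score(ct), 0.0)

    def test_thirty_vs_five_percent(self):
        ct = build_table([[30], [70]], [[5], [95]])
        scores = act.activity_score(ct)
        assert scores.iloc[0] == pytest.approx(25.0)

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(1)
        ct = build_table(rng.integers(1, 500, (8, 3)), rng.integers(1, 500, (8, 3)))
        assert act.activity_score(ct).sum() == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        lab, ctl = rng.integers(1, 500, (5, 3)), rng.integers(1, 500, (5, 3))
        a = act.activity_score(build_table(lab, ctl))
        b = act.activity_score(build_table(ctl, lab))
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_missing_heavy_bin_rejected(self):
        ct = build_table([[1], [2]], [[1], [2]])
        only_labeled = ct.select(condition="labeled")
        with pytest.raises(ValueError):
            act.activity_score(only_labeled)

    def test_unequal_depths_handled_via_proportions(self):
        # same compositions at very different depths must score zero
        ct = build_table([[100, 1000], [300, 3000]], [[10, 10000], [30, 30000]])
        assert np.allclose(act.activity_score(ct), 0.0, atol=1e-12)


class TestNonparametricTest:
    def test_permutation_invariant_data_p_one(self):
        ct = build_table([[5, 5, 5], [7, 7, 7]], [[5, 5, 5], [7, 7, 7]])
        res = act.nonparametric_test(ct, sparse_threshold=0)
        assert (res["p_value"] == 1.0).all()

    def test_three_vs_three_separation_enumerated_minimum(self):
        # per-feature null (no pooling): 20 distinct splits, two extremes
        lab = [[100, 110, 120], [900, 890, 880]]
        ctl = [[10, 11, 12], [990, 989, 988]]
        ct = build_table(lab, ctl)
        res = act.nonparametric_test(ct, pool_null=False, sparse_threshold=0)
        assert res.loc["t0", "p_value"] == pytest.approx(0.1)

    def test_pooled_null_reaches_below_alpha(self):
        # one strongly shifted taxon among many null ones: the cross-feature
        # null admits p < 0.05 even with triplicates
        rng = np.random.default_rng(3)
        n_taxa = 20
        lab = rng.poisson(100, (n_taxa, 3))
        ctl = rng.poisson(100, (n_taxa, 3))
        lab[0] = [2000, 2100, 1900]
        ct = build_table(lab, ctl)
        res = act.nonparametric_test(ct, seed=0)
        assert res.loc["t0", "p_value"] < 0.05

    def test_single_replicate_rejected(self):
        ct = build_table([[5], [7]], [[5], [7]])
        with pytest.raises(ValueError, match="replicate"):
            act.nonparametric_test(ct)

    def test_sparse_taxa_use_exact_test(self):
        lab = [[1000, 1100, 900], [2, 1, 0]]
        ctl = [[1000, 900, 1100], [0, 0, 1]]
        ct = build_table(lab, ctl)
        res = act.nonparametric_test(ct, sparse_threshold=8)
        assert res.loc["t1", "method"] == "fisher_exact"
        assert res.loc["t0", "method"] == "permutation"
        assert 0 < res.loc["t1", "p_value"] <= 1

    def test_null_calibration_small(self):
        # multinomial null: rejection rate near alpha (sharper check is the
        # acceptance suite's 1000-experiment version)
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(15))
        rejections, n_tests = 0, 0
        for _ in range(120):
            lab = rng.multinomial(3000, p, size=3).T
            ctl = rng.multinomial(3000, p, size=3).T
            res = act.nonparametric_test(build_table(lab, ctl), seed=1)
            rejections += int((res["p_value"] < 0.05).sum())
            n_tests += len(res)
        assert 0.02 < rejections / n_tests < 0.08


class TestClassification:
    def test_positive_significant_is_active(self):
        idx = pd.Index(["x"])
        cls = act.classify_activity(
            pd.Series([12.0], index=idx),
            pd.Series([0.01], index=idx),
            pd.DataFrame({"labeled": ["heavy"], "control": ["light"]}, index=idx),
        )
        assert cls.loc["x"] == "active"

    def test_zero_scores_inactive(self):
        idx = pd.Index(["x", "y"])
        cls = act.classify_activity(
            pd.Series([0.0, 0.0], index=idx),
            pd.Series([1.0, 1.0], index=idx),
            pd.DataFrame({"labeled": ["light", "light"],
                          "control": ["light", "light"]}, index=idx),
        )
        assert (cls == "inactive").all()

    def test_middle_peak_pattern_is_less_active(self):
        # the Enterococcus pattern: abundant everywhere, but its own profile
        # peaks mid-gradient only under labeling (partial 13C uptake)
        extra = {
            ("labeled", "middle"): [[60], [20]],
            ("labeled", "light"): [[20], [40]],
            ("control", "middle"): [[20], [20]],
            ("control", "light"): [[60], [40]],
        }
        ct = build_table([[20], [40]], [[20], [40]], extra_bins=extra)
        peaks = act.peak_bins(ct)
        assert peaks.loc["t0", "labeled"] == "middle"
        assert peaks.loc["t0", "control"] == "light"
        cls = act.classify_activity(
            pd.Series([0.0, 0.0], index=ct.counts.index),
            pd.Series([0.5, 0.5], index=ct.counts.index),
            peaks,
        )
        assert cls.loc["t0"] == "less_active"
        assert cls.loc["t1"] == "inactive"

    def test_significant_negative_score_is_not_active(self):
        idx = pd.Index(["x"])
        cls = act.classify_activity(
            pd.Series([-8.0], index=idx),
            pd.Series([0.001], index=idx),
            pd.DataFrame({"labeled": ["light"], "control": ["heavy"]}, index=idx),
        )
        assert cls.loc["x"] == "inactive"


class TestActivityTableAndMatrix:
    def _results(self, seed=0):
        rng = np.random.default_rng(seed)
        lab = rng.poisson([[900], [100], [500]], (3, 3))
        ctl = rng.poisson([[100], [900], [500]], (3, 3))
        extra = {
            ("labeled", "light"): rng.poisson(300, (3, 3)),
            ("control", "light"): rng.poisson(300, (3, 3)),
            ("labeled", "middle"): rng.poisson(300, (3, 3)),
            ("control", "middle"): rng.poisson(300, (3, 3)),
        }
        return build_table(lab, ctl, extra_bins=extra)

    def test_table_columns_and_consistency(self):
        ct = self._results()
        table = act.activity_table(ct, seed=1)
        assert {"score_pct_points", "p_value", "activity_class",
                "peak_bin_labeled", "peak_bin_control"} <= set(table.columns)
        pd.testing.assert_series_equal(
            table["score_pct_points"], act.activity_score(ct),
            check_names=False,
        )

    def test_matrix_cross_checks_against_sources(self):
        ct = self._results()
        table = act.activity_table(ct, seed=1)
        light = act.replicate_proportions(ct, "control", "light").mean(axis=1)
        mat = act.activity_matrix({"early": table}, {"early": light})
        row = mat[(mat.stage == "early") & (mat.taxon == "t0")].iloc[0]
        assert row["activity_score_pct_points"] == pytest.approx(
            table.loc["t0", "score_pct_points"]
        )
        assert row["abundance"] == pytest.approx(light.loc["t0"])

    def test_matrix_absent_taxon_gets_zeros(self):
        ct = self._results()
        table = act.activity_table(ct, seed=1)
        light = act.replicate_proportions(ct, "control", "light").mean(axis=1)
        small = table.iloc[:1]
        mat = act.activity_matrix(
            {"early": table, "late": small},
            {"early": light, "late": light.iloc[:1]},
        )
        late_t2 = mat[(mat.stage == "late") & (mat.taxon == "t2")].iloc[0]
        assert late_t2["abundance"] == 0.0
        assert late_t2["activity_score_pct_points"] == 0.0
        assert late_t2["activity_class"] == "inactive"

    def test_single_stage_single_taxon_shape(self):
        ct = build_table([[10, 12, 11]], [[9, 10, 11]])
        table = act.activity_table(ct, seed=0)
        mat = act.activity_matrix(
            {"only": table}, {"only": pd.Series({"t0": 1.0})}
        )
        assert len(mat) == 1 and set(mat.columns) >= {"abundance",
                                                      "activity_score_pct_points"}

    def test_fdr_option_adds_q_values(self):
        ct = self._results()
        table = act.activity_table(ct, seed=1, fdr=True)
        assert "q_value" in table.columns
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()
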