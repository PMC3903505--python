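"""Forward-simulator tests: labeling arithmetic, banding physics, sampling."""

import numpy as np
import pandas as pd
import pytest

from pyrosip import isotope as iso
from pyrosip import sipsim as sim


def uniform_community(n=4, **kw):
    kw.setdefault("host_dna_fraction", 0.3)
    kw.setdefault("background_fraction", 0.05)
    return sim.generate_community(n, abundance_model="uniform", seed=1, **kw)


class TestGenerateCommunity:
    def test_single_taxon_gets_everything(self):
        c = sim.generate_community(1, seed=0)
        assert c.taxa[0].base_abundance == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ["uniform", "lognormal"])
    def test_abundances_close(self, model):
        c = sim.generate_community(25, abundance_model=model, seed=3)
        assert sum(t.base_abundance for t in c.taxa) == pytest.approx(1.0, abs=1e-9)
        assert len({t.id for t in c.taxa}) == 25

    def test_same_seed_identical(self):
        a = sim.generate_community(10, seed=42)
        b = sim.generate_community(10, seed=42)
        assert a.taxa == b.taxa

    def test_gc_respects_bounds(self):
        c = sim.generate_community(50, gc_bounds=(0.4, 0.5), seed=5)
        assert all(0.4 <= t.gc <= 0.5 for t in c.taxa)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sim.generate_community(0, seed=1)
        with pytest.raises(ValueError):
            sim.generate_community(3, gc_bounds=(0.7, 0.3), seed=1)


class TestApplyLabeling:
    def test_zero_turnover_is_control(self):
        c = uniform_community()
        lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.0))
        for pools in lab.pools.values():
            assert len(pools) == 1
            assert pools[0].af == lab.natural_af

    def test_full_replacement(self):
        c = uniform_community()
        lab = sim.apply_labeling(
            c, sim.LabelingScenario(substrate_af=0.99, turnover=1.0, assimilation=1.0)
        )
        for pools in lab.pools.values():
            assert len(pools) == 1
            assert pools[0].af == pytest.approx(0.99)

    def test_new_pool_atom_fraction_arithmetic(self):
        c = uniform_community()
        lab = sim.apply_labeling(
            c,
            sim.LabelingScenario(substrate_af=0.99, turnover=0.5, assimilation=0.8),
            natural_af=0.0111,
        )
        for pools in lab.pools.values():
            new = pools[1]
            assert new.af == pytest.approx(0.0111 + 0.8 * (0.99 - 0.0111), rel=1e-12)
            assert new.af == pytest.approx(0.79422, rel=1e-12)

    def test_mass_conserved_and_split_by_turnover(self):
        c = uniform_community()
        lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.25))
        for pools in lab.pools.values():
            old, new = pools
            assert new.mass / (old.mass + new.mass) == pytest.approx(0.25)
        assert lab.total_mass() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            sim.LabelingScenario(turnover=1.5)
        with pytest.raises(ValueError):
            sim.LabelingScenario(substrate_af=-0.1)


class TestBuoyantDensity:
    def test_unlabeled_closed_form(self):
        nat = sim.natural_atom_fraction()
        assert sim.pool_buoyant_density(0.41, nat) == pytest.approx(
            1.660 + 0.098 * 0.41, rel=1e-12
        )
        assert sim.pool_buoyant_density(0.41, nat) == pytest.approx(1.70018)

    def test_full_label_adds_configured_shift(self):
        nat = sim.natural_atom_fraction()
        bd_un = sim.pool_buoyant_density(0.5, nat)
        bd_full = sim.pool_buoyant_density(0.5, 1.0)
        assert bd_full - bd_un == pytest.approx(0.036, rel=1e-9)

    def test_natural_af_gives_zero_shift_term(self):
        nat = sim.natural_atom_fraction()
        assert sim.pool_buoyant_density(0.3, nat) == pytest.approx(
            1.660 + 0.098 * 0.3, rel=1e-12
        )


class TestRunGradient:
    def test_mass_conserved(self):
        c = uniform_community(6)
        lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.4))
        _, matrix = sim.run_gradient(lab)
        assert matrix.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)

    def test_band_centers_on_pool_density(self):
        # a single-taxon, host-free community with BD 1.700 must peak in the
        # fraction whose window contains 1.700
        taxon = sim.Taxon(id="x", gc=(1.700 - 1.660) / 0.098, base_abundance=1.0)
        c = sim.CommunityProfile([taxon], host_dna_fraction=0.0, background_fraction=0.0)
        lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.0))
        cfg = sim.GradientConfig()
        _, matrix = sim.run_gradient(lab, cfg)
        upper, lower = cfg.window_edges()
        modal = int(matrix.loc["x"].idxmax()) - 1
        assert lower[modal] <= 1.700 <= upper[modal]

    def test_fraction_densities_linear_and_decreasing(self):
        c = uniform_community()
        lab = sim.apply_labeling(c, sim.LabelingScenario())
        fs, _ = sim.run_gradient(lab)
        d = fs.densities
        assert d[0] == pytest.approx(1.761)
        assert d[-1] == pytest.approx(1.688)
        assert np.allclose(np.diff(d), np.diff(d)[0])

    def test_agrees_with_molecule_level_monte_carlo(self):
        c = sim.generate_community(8, seed=9, host_dna_fraction=0.4,
                                   background_fraction=0.06)
        lab = sim.apply_labeling(
            c, sim.LabelingScenario(turnover={"otu1": 0.7, "otu2": 0.5}, substrate_af=0.99)
        )
        _, matrix = sim.run_gradient(lab)
        analytic = matrix.to_numpy().sum(axis=0)
        mc = sim.monte_carlo_gradient(lab, n_molecules=100_000, seed=2)
        tv = 0.5 * np.abs(analytic / analytic.sum() - mc).sum()
        assert tv < 0.02

    def test_full_label_shift_visible_in_modal_fraction(self):
        # fully labeled, fully turned-over taxon shifts by ~full_label_shift
        taxon = sim.Taxon(id="x", gc=0.5, base_abundance=1.0)
        c = sim.CommunityProfile([taxon], host_dna_fraction=0.0, background_fraction=0.0)
        cfg = sim.GradientConfig()
        un = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.0))
        fu = sim.apply_labeling(
            c, sim.LabelingScenario(turnover=1.0, assimilation=1.0, substrate_af=1.0)
        )
        _, m_un = sim.run_gradient(un, cfg)
        _, m_fu = sim.run_gradient(fu, cfg)
        d = cfg.fraction_densities()
        bd_un = d[int(m_un.loc["x"].idxmax()) - 1]
        bd_fu = d[int(m_fu.loc["x"].idxmax()) - 1]
        width = abs(d[1] - d[0])
        assert bd_fu - bd_un == pytest.approx(cfg.full_label_shift, abs=width)


class TestSampleReads:
    def _matrix(self, n=3):
        c = uniform_community(n)
        lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.3))
        _, matrix = sim.run_gradient(lab)
        return matrix

    def test_row_sums_equal_depth(self):
        ct = sim.sample_reads(self._matrix(), depth=500, n_replicates=2, seed=4)
        assert (ct.depth() == 500).all()

    def test_single_taxon_gets_all_reads(self):
        taxon = sim.Taxon(id="only", gc=0.5, base_abundance=1.0)
        # background keeps every fraction amplifiable; it is community DNA,
        # so the single taxon still owns every read
        c = sim.CommunityProfile([taxon], host_dna_fraction=0.2, background_fraction=0.05)
        lab = sim.apply_labeling(c, sim.LabelingScenario())
        _, matrix = sim.run_gradient(lab)
        ct = sim.sample_reads(matrix, depth=100, n_replicates=1, seed=0)
        assert (ct.counts.loc["only"] == 100).all()

    def test_host_row_excluded(self):
        ct = sim.sample_reads(self._matrix(), depth=100, seed=0)
        assert sim.HOST_ROW not in ct.counts.index

    def test_empirical_frequencies_converge(self):
        matrix = self._matrix(4)
        frac = 6
        masses = matrix.drop(index=sim.HOST_ROW)[frac]
        p = (masses / masses.sum()).to_numpy()
        depth = 1_000_000
        ct = sim.sample_reads(matrix[[frac]], depth=depth, n_replicates=1, seed=8)
        obs = ct.counts.iloc[:, 0].to_numpy() / depth
        se = np.sqrt(p * (1 - p) / depth)
        assert np.all(np.abs(obs - p) <= 3 * se + 1e-12)

    def test_zero_mass_fraction_named_in_error(self):
        matrix = self._matrix()
        matrix.loc[matrix.index != sim.HOST_ROW, 3] = 0.0
        with pytest.raises(ValueError, match="3"):
            sim.sample_reads(matrix, depth=10, seed=0)

    def test_determinism_under_seed(self):
        m = self._matrix()
        a = sim.sample_reads(m, depth=200, n_replicates=3, seed=5)
        b = sim.sample_reads(m, depth=200, n_replicates=3, seed=5)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestSimulateIrms:
    def test_unlabeled_reads_baseline(self):
        c = uniform_community()
        lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=0.0))
        m = sim.simulate_irms(lab, noise_sd=0.0)
        assert m.delta == pytest.approx(-30.7, abs=1e-9)

    def test_matches_per_pool_bookkeeping(self):
        c = uniform_community()
        lab = sim.apply_labeling(
            c, sim.LabelingScenario(substrate_af=0.99, turnover=0.2, assimilation=1.0)
        )
        m = sim.simulate_irms(lab, noise_sd=0.0)
        # independent bookkeeping: mass-weighted atom fraction over all pools
        masses, afs = [], []
        for pools in lab.pools.values():
            for p in pools:
                masses.append(p.mass)
                afs.append(p.af)
        masses += [lab.host_pool.mass, lab.background_mass]
        afs += [lab.host_pool.af, lab.natural_af]
        bulk = np.average(afs, weights=masses)
        base = iso.atom_fraction_from_delta(-30.7)
        expect = iso.delta_from_atom_fraction(base + bulk - lab.natural_af)
        assert m.delta == pytest.approx(expect, rel=1e-12)

    def test_enrichment_increases_delta(self):
        c = uniform_community()
        deltas = []
        for turn in (0.0, 0.1, 0.2, 0.4):
            lab = sim.apply_labeling(c, sim.LabelingScenario(turnover=turn))
            deltas.append(sim.simulate_irms(lab, noise_sd=0.0).delta)
        assert np.all(np.diff(deltas) > 0)


class TestTruth:
    def test_roundtrip(self, tmp_path):
        c = uniform_community()
        scenario = sim.LabelingScenario(turnover={"otu1": 0.6}, substrate_af=0.99)
        path = tmp_path / "truth.json"
        written = sim.write_truth(c, scenario, path)
        read = sim.read_truth(path)
        assert read == written
        assert read["schema"] == sim.TRUTH_SCHEMA

    def test_taxa_match_community(self, tmp_path):
        c = uniform_community(5)
        doc = sim.write_truth(c, sim.LabelingScenario(), tmp_path / "t.json")
        assert {t["id"] for t in doc["taxa"]} == {t.id for t in c.taxa}

    def test_labeled_flag_tracks_turnover(self, tmp_path):
        c = uniform_community(3)
        doc = sim.write_truth(
            c, sim.LabelingScenario(turnover={"otu1": 0.5}), tmp_path / "t.json"
        )
        flags = {t["id"]: t["labeled"] for t in doc["taxa"]}
        assert flags == {"otu1": True, "otu2": False, "otu3": False}


class TestExperimentDeterminism:
    def test_zero_turnover_matches_control_arm(self):
        from pyrosip.scenarios import demo_community

        c = demo_community()
        exp = sim.simulate_experiment(
            c, sim.LabelingScenario(turnover=0.0), depth=300, n_replicates=2, seed=3
        )
        # with no label anywhere the two arms band identically
        pd.testing.assert_frame_equal(exp.control_mass, exp.labeled_mass)

    def test_same_seed_same_counts(self):
        from pyrosip.scenarios import demo_community, demo_scenario

        c = demo_community()
        a = sim.simulate_experiment(c, demo_scenario("48h"), depth=300, seed=6)
        b = sim.simulate_experiment(c, demo_scenario("48h"), depth=300, seed=6)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
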