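"""FFT insertion engine: kernels, oracle equivalence, averaging."""

import math

import numpy as np
import pytest

from crowdxfer import (COULOMB_KCAL, GridSpec, InsertionMaps, Molecule,
                       PotentialParams, SampleAverages, SpherePacking,
                       aggregate, build_insertion_maps, direct_insertion_maps,
                       insertion_averages, pairwise_energy,
                       replace_with_molecules, run_transfer,
                       single_interaction_mu)
from crowdxfer.constants import kbt
from crowdxfer.crowder_box import CrowderConfiguration


def one_atom_config(box, pos, radius=2.0, lj_a=0.0, lj_b=0.0, charge=0.0):
    mol = Molecule("c", ["C"], [[0.0, 0.0, 0.0]], [radius], [lj_a], [lj_b],
                   [charge])
    p = SpherePacking(box, np.array([pos], dtype=float), radius, 0)
    return replace_with_molecules(p, mol, clash_threshold=0.1, seed=0)


class TestPairwiseEnergy:
    def test_lj_zero_at_contact_distance(self, make_atom):
        # A/r^12 = B/r^6 at r = (A/B)^(1/6)
        a, b = 1.0e4, 1.0
        r0 = (a / b) ** (1.0 / 6.0)
        cfg = one_atom_config(60.0, [30.0, 30, 30], lj_a=a, lj_b=b)
        test = make_atom(2.0, lj_a=a, lj_b=b, pos=(30.0 + r0, 30, 30))
        e, clash = pairwise_energy(test, cfg, PotentialParams(scale_nonpolar=1.0))
        assert e == pytest.approx(0.0, abs=1e-12)
        assert not clash

    def test_debye_huckel_closed_form(self, make_atom):
        # unit charges, infinite screening length, r = 332.06 A
        params = PotentialParams(scale_elec=1.0, debye=1e12)
        cfg = one_atom_config(1000.0, [100.0, 100, 100], charge=1.0)
        test = make_atom(2.0, charge=1.0, pos=(100.0 + COULOMB_KCAL, 100, 100))
        e, _ = pairwise_energy(test, cfg, params, soft_terms=("electrostatic",))
        assert e == pytest.approx(1.0 / 78.4, rel=1e-6)

    def test_clash_flag_below_hard_core_contact(self, make_atom):
        cfg = one_atom_config(60.0, [30.0, 30, 30], radius=2.0)
        test = make_atom(2.0, pos=(33.5, 30, 30))  # contact = 4.0
        _, clash = pairwise_energy(test, cfg)
        assert clash
        _, clash2 = pairwise_energy(make_atom(2.0, pos=(34.5, 30, 30)), cfg)
        assert not clash2


class TestBuildInsertionMaps:
    def test_empty_configuration_all_free(self, make_atom):
        cfg = one_atom_config(24.0, [12.0, 12, 12])
        cfg.translations = np.zeros((0, 3))
        cfg.atom_coords = np.zeros((0, 3))
        cfg.rotations = []
        grid = GridSpec(24.0, 40)
        maps = build_insertion_maps(make_atom(2.0), cfg, grid)
        assert maps.n_free == maps.n_total
        assert np.all(maps.u_soft == 0.0)

    def test_single_sphere_pair_free_fraction(self, make_atom):
        """One hard sphere crowder and a point-like probe: the clash-free
        fraction equals 1 - (4/3) pi d^3 / V up to a voxel shell."""
        box, rc, rt = 24.0, 2.0, 1.0
        cfg = one_atom_config(box, [12.0, 12, 12], radius=rc)
        grid = GridSpec(box, 96)
        maps = build_insertion_maps(make_atom(rt), cfg, grid,
                                    PotentialParams(scale_nonpolar=0.0,
                                                    scale_elec=0.0))
        d = rc + rt
        expected = 1.0 - (4.0 / 3.0) * math.pi * d ** 3 / box ** 3
        shell = 4.0 * math.pi * d ** 2 * grid.spacing / box ** 3
        assert abs(maps.clash_free_fraction - expected) < 2 * shell

    @pytest.mark.parametrize("seed", [0, 1])
    def test_fft_equals_direct_oracle(self, mini_system, params, seed):
        from crowdxfer import random_orientation
        cfg = mini_system.configurations[0.08][0]
        grid = GridSpec(mini_system.box_side, 48)
        test = random_orientation(mini_system.test, seed)
        m_fft = build_insertion_maps(test, cfg, grid, params)
        m_dir = direct_insertion_maps(test, cfg, grid, params)
        assert np.array_equal(m_fft.clash_free, m_dir.clash_free)
        diff = np.abs(m_fft.u_soft - m_dir.u_soft)
        assert (diff / np.maximum(1.0, np.abs(m_dir.u_soft))).max() < 1e-6


class TestInsertionAverages:
    def _maps(self, clash_free, u):
        return InsertionMaps(clash_free, u, clash_free.size,
                             int(clash_free.sum()))

    def test_all_free_zero_energy(self, params):
        cf = np.ones((4, 4, 4), dtype=bool)
        s = insertion_averages(self._maps(cf, np.zeros_like(cf, float)), params)
        assert (s.bf_int, s.bf_st, s.bf_soft) == (1.0, 1.0, 1.0)

    def test_half_clashed(self, params):
        cf = np.zeros((4, 4, 4), dtype=bool)
        cf[:2] = True
        s = insertion_averages(self._maps(cf, np.zeros_like(cf, float)), params)
        assert (s.bf_int, s.bf_st, s.bf_soft) == (0.5, 0.5, 1.0)

    def test_product_identity_random_field(self, params):
        rng = np.random.default_rng(0)
        cf = rng.random((8, 8, 8)) > 0.3
        u = np.where(cf, rng.normal(0, 0.5, (8, 8, 8)), 0.0)
        s = insertion_averages(self._maps(cf, u), params)
        assert s.bf_int == pytest.approx(s.bf_st * s.bf_soft, rel=1e-13)

    def test_fully_clashed_sample_flagged(self, params):
        cf = np.zeros((4, 4, 4), dtype=bool)
        s = insertion_averages(self._maps(cf, np.zeros_like(cf, float)), params)
        assert s.fully_clashed and s.bf_int == 0.0 and math.isnan(s.bf_soft)


class TestAggregate:
    def test_fully_clashed_correction_from_printed_counts(self, params):
        """2,914 usable of 5,000 samples gives a +0.320 kcal/mol shift at
        298 K."""
        samples = [SampleAverages(1.0, 1.0, 1.0, False)] * 2914 \
            + [SampleAverages(0.0, 0.0, float("nan"), True)] * 2086
        res = aggregate(samples, params, n_boot=10)
        expected = -kbt(298.0) * math.log(2914 / 5000)
        assert res.correction == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.320, abs=2e-3)
        assert res.dmu == pytest.approx(expected)
        assert res.n_fully_clashed == 2086

    def test_identical_samples_reduce_to_single(self, params):
        s = SampleAverages(0.36, 0.6, 0.6, False)
        res = aggregate([s] * 50, params, n_boot=10)
        kT = params.kbt
        assert res.dmu == pytest.approx(-kT * math.log(0.36), rel=1e-12)
        assert res.dmu == pytest.approx(res.dmu_ev + res.dmu_sa, rel=1e-9)

    def test_lognormal_mean_matches_independent_formula(self, params):
        rng = np.random.default_rng(1)
        bf = rng.lognormal(-1.0, 0.4, 5000)
        samples = [SampleAverages(b, 1.0, b, False) for b in bf]
        res = aggregate(samples, params, n_boot=10)
        # one-line independent recomputation
        expected = -params.kbt * math.log(bf.sum() / len(bf))
        assert res.dmu == pytest.approx(expected, rel=1e-12)

    def test_all_clashed_sentinel(self, params):
        samples = [SampleAverages(0.0, 0.0, float("nan"), True)] * 4
        res = aggregate(samples, params)
        assert math.isinf(res.dmu)


class TestRunTransfer:
    def test_degenerate_loop_equals_single_sample(self, mini_system, params):
        from crowdxfer import random_orientation
        cfg = mini_system.configurations[0.08][0]
        grid = GridSpec(mini_system.box_side, 48)
        res = run_transfer(mini_system.test, [cfg], 1, grid, params, seed=9)
        # replicate the single sample by hand with the same seed path
        ss = np.random.SeedSequence(9)
        rng = np.random.default_rng(ss.spawn(1)[0])
        oriented = random_orientation(mini_system.test, rng)
        maps = build_insertion_maps(oriented, cfg, grid, params)
        s = insertion_averages(maps, params)
        assert res.dmu == pytest.approx(-params.kbt * math.log(s.bf_int),
                                        rel=1e-12)

    def test_hard_core_only_has_zero_soft_component(self, mini_system,
                                                    hardcore_params):
        cfg = mini_system.configurations[0.08][0]
        grid = GridSpec(mini_system.box_side, 48)
        res = run_transfer(mini_system.test, [cfg], 3, grid, hardcore_params,
                           seed=2)
        assert res.dmu_sa == pytest.approx(0.0, abs=1e-12)
        assert res.dmu == pytest.approx(res.dmu_ev, rel=1e-12)
        assert res.dmu_ev > 0

    def test_fft_and_direct_paths_agree_end_to_end(self, mini_system, params):
        cfgs = mini_system.configurations[0.08]
        grid = GridSpec(mini_system.box_side, 48)
        res_fft = run_transfer(mini_system.test, cfgs, 2, grid, params, seed=4)
        res_dir = run_transfer(mini_system.test, cfgs, 2, grid, params, seed=4,
                               use_fft=False)
        assert res_fft.dmu == pytest.approx(res_dir.dmu, abs=1e-6)
        assert res_fft.dmu_ev == pytest.approx(res_dir.dmu_ev, abs=1e-9)
        assert res_fft.dmu_sa == pytest.approx(res_dir.dmu_sa, abs=1e-6)

    def test_soft_scaling_zero_matches_hardcore_bitwise(self, mini_system,
                                                        hardcore_params):
        cfg = mini_system.configurations[0.08][0]
        grid = GridSpec(mini_system.box_side, 48)
        res = run_transfer(mini_system.test, [cfg], 2, grid, hardcore_params,
                           seed=6)
        res2 = run_transfer(mini_system.test, [cfg], 2, grid,
                            PotentialParams(scale_nonpolar=0.0, scale_elec=0.0),
                            seed=6)
        assert res.dmu_ev == res2.dmu_ev


class TestSingleInteraction:
    def test_zero_charges_give_zero_electrostatic_mu(self, mini_system):
        from crowdxfer import Molecule
        t = mini_system.test
        neutral = Molecule("n", t.labels, t.coords, t.radii, t.lj_a, t.lj_b,
                           np.zeros(len(t)))
        cfg = mini_system.configurations[0.08][0]
        grid = GridSpec(mini_system.box_side, 48)
        mu = single_interaction_mu(neutral, [cfg], 2, grid,
                                   which="electrostatic", seed=1)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_components_reported_not_additive(self, mini_system, params):
        """dmu_na + dmu_elec need not equal dmu_sa (correlated terms)."""
        cfg = mini_system.configurations[0.15][0]
        grid = GridSpec(mini_system.box_side, 48)
        mu_na = single_interaction_mu(mini_system.test, [cfg], 2, grid, params,
                                      which="nonpolar", seed=1)
        mu_el = single_interaction_mu(mini_system.test, [cfg], 2, grid, params,
                                      which="electrostatic", seed=1)
        res = run_transfer(mini_system.test, [cfg], 2, grid, params, seed=1)
        for v in (mu_na, mu_el, res.dmu_sa):
            assert math.isfinite(v)
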