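import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import magsense as ms
from magsense.constants import MU0
from magsense.errors import DomainError, SingularityError
from magsense.interactions import default_wca_params, dipolar_fields

from _oracles import dipole_pair_energy_oracle, finite_difference_forces


class TestPairDipoleEnergy:
    def test_head_to_tail_closed_form(self, moment_20nm):
        m, r = moment_20nm, 50e-9
        e = ms.pair_dipole_energy([m, 0, 0], [m, 0, 0], [r, 0, 0])
        assert e == pytest.approx(-MU0 * m**2 / (2 * np.pi * r**3), rel=1e-12)

    def test_side_by_side_parallel(self, moment_20nm):
        m, r = moment_20nm, 50e-9
        e = ms.pair_dipole_energy([0, 0, m], [0, 0, m], [r, 0, 0])
        assert e == pytest.approx(+MU0 * m**2 / (4 * np.pi * r**3), rel=1e-12)

    def test_zero_moment(self, moment_20nm):
        e = ms.pair_dipole_energy([moment_20nm, 0, 0], [0, 0, 0],
                                  [30e-9, 0, 0])
        assert e == 0.0

    def test_coincident_particles_raise(self, moment_20nm):
        with pytest.raises(SingularityError):
            ms.pair_dipole_energy([moment_20nm, 0, 0], [moment_20nm, 0, 0],
                                  [0, 0, 0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_exchange_symmetry(self, seed):
        g = np.random.default_rng(seed)
        m1, m2 = g.normal(size=(2, 3)) * 1e-18
        r = g.normal(size=3) * 1e-7
        if np.linalg.norm(r) < 1e-9:
            return
        assert ms.pair_dipole_energy(m1, m2, r) == pytest.approx(
            ms.pair_dipole_energy(m2, m1, -r), rel=1e-12)

    def test_matches_substitution_oracle(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(size=(2, 3)) * 1e-18
            r = rng.normal(size=3) * 1e-7
            assert ms.pair_dipole_energy(m1, m2, r) == pytest.approx(
                dipole_pair_energy_oracle(m1, m2, r), rel=1e-12)


class TestDipolarField:
    def test_head_to_tail_field(self, pair_factory, moment_20nm):
        ens = pair_factory(50e-9, orientations=[[1, 0, 0], [1, 0, 0]])
        B = ms.dipolar_field(ens, 0)
        expected = MU0 * moment_20nm / (2 * np.pi * (50e-9) ** 3)
        assert B[0] == pytest.approx(expected, rel=1e-12)
        assert abs(B[1]) < 1e-18 and abs(B[2]) < 1e-18

    def test_single_particle_zero_field(self):
        ens = ms.generate_random_ensemble(1, (100e-9, 100e-9), seed=0)
        np.testing.assert_array_equal(ms.dipolar_field(ens, 0), 0.0)

    def test_field_energy_consistency(self):
        # H_DD = -1/2 sum_i m_i . B_i must equal the pairwise sum
        ens = ms.generate_random_ensemble(10, (300e-9, 300e-9), seed=5)
        B = dipolar_fields(ens)
        e_field = -0.5 * float((ens.moments * B).sum())
        e_pairs = sum(
            ms.pair_dipole_energy(ens.moments[i], ens.moments[j],
                                  ens.positions[i] - ens.positions[j])
            for i in range(ens.n) for j in range(i + 1, ens.n)
        )
        assert e_field == pytest.approx(e_pairs, rel=1e-12)

    def test_bad_index(self, small_ensemble):
        with pytest.raises(DomainError):
            ms.dipolar_field(small_ensemble, 99)


class TestWCA:
    def test_zero_at_cutoff(self):
        p = ms.WCAParams(epsilon=1e-20, sigma=20e-9)
        assert ms.wca_energy(p.cutoff, p) == 0.0
        assert ms.wca_energy(10 * p.sigma, p) == 0.0

    def test_epsilon_at_sigma(self):
        p = ms.WCAParams(epsilon=3e-21, sigma=20e-9)
        assert ms.wca_energy(p.sigma, p) == pytest.approx(p.epsilon,
                                                          rel=1e-12)

    def test_cutoff_is_fixed(self):
        p = ms.WCAParams(epsilon=1.0, sigma=2.0)
        assert p.cutoff == pytest.approx(2 ** (1 / 6) * 2.0, rel=1e-15)

    def test_continuity_at_cutoff(self):
        p = ms.WCAParams(epsilon=1e-20, sigma=20e-9)
        below = ms.wca_energy(p.cutoff * (1 - 1e-9), p)
        assert abs(below) < 1e-7 * p.epsilon

    def test_domain_error(self):
        p = ms.WCAParams(epsilon=1.0, sigma=1.0)
        with pytest.raises(DomainError):
            ms.wca_energy(0.0, p)

    def test_bad_params(self):
        with pytest.raises(DomainError):
            ms.WCAParams(epsilon=-1.0, sigma=1.0)


class TestPairForces:
    def test_newton_third_law_pair(self, pair_factory):
        ens = pair_factory(30e-9, seed=3)
        F = ms.pair_forces(ens)
        np.testing.assert_allclose(F[0], -F[1], rtol=1e-12)

    def test_head_to_tail_attraction_magnitude(self, pair_factory,
                                               moment_20nm):
        r = 60e-9  # beyond the WCA cutoff
        ens = pair_factory(r, orientations=[[1, 0, 0], [1, 0, 0]])
        F = ms.pair_forces(ens)
        expected = 3 * MU0 * moment_20nm**2 / (2 * np.pi * r**4)
        # particle 0 sits at lower x: the force on it points to +x
        assert F[0, 0] == pytest.approx(expected, rel=1e-12)
        assert np.linalg.norm(F[0]) == pytest.approx(expected, rel=1e-12)

    def test_matches_finite_difference(self):
        ens = ms.generate_random_ensemble(8, (300e-9, 300e-9), seed=11,
                                          motion_dim=3)
        wca = default_wca_params(ens)
        F = ms.pair_forces(ens, wca)

        def energy(pos):
            e = ens.with_(positions=pos)
            b = ms.total_energy(e, params=wca)
            return b.dipolar + b.wca

        F_fd = finite_difference_forces(energy, ens.positions, h=1e-12)
        scale = np.abs(F).max()
        np.testing.assert_allclose(F, F_fd, atol=1e-6 * scale)

    def test_global_force_balance(self):
        for seed in (0, 1, 2):
            ens = ms.generate_random_ensemble(15, (300e-9, 300e-9),
                                              seed=seed)
            F = ms.pair_forces(ens)
            assert np.abs(F.sum(axis=0)).max() <= 1e-12 * np.abs(F).max()

    def test_wca_force_continuous_at_cutoff(self, moment_20nm):
        # beyond-cutoff pair with zero moments: no force at all
        d = 20e-9
        pos = np.array([[0, 0, 0], [2 ** (1 / 6) * d * 1.0000001, 0, 0]])
        ens = ms.NanoparticleEnsemble(
            positions=pos + 1e-7, diameters=np.full(2, d),
            moments=np.zeros((2, 3)), box=[1e-6] * 3, Ms=0.0, motion_dim=3)
        F = ms.pair_forces(ens, ms.WCAParams(epsilon=1e-20, sigma=d))
        assert np.abs(F).max() == 0.0


class TestTotalEnergy:
    def test_single_particle_all_zero(self):
        ens = ms.generate_random_ensemble(1, (100e-9, 100e-9), seed=0)
        e = ms.total_energy(ens)
        assert e.dipolar == e.wca == e.zeeman == e.total == 0.0

    def test_zeeman_single_moment(self, moment_20nm):
        ens = ms.generate_random_ensemble(1, (100e-9, 100e-9), seed=0)
        ens.moments = np.array([[0.0, 0.0, moment_20nm]])
        e = ms.total_energy(ens, B_ext=[0, 0, 0.05])
        assert e.zeeman == pytest.approx(-moment_20nm * 0.05, rel=1e-12)

    def test_two_head_to_tail_beyond_cutoff(self, pair_factory, moment_20nm):
        r = 60e-9
        ens = pair_factory(r, orientations=[[1, 0, 0], [1, 0, 0]])
        e = ms.total_energy(ens)
        assert e.wca == 0.0
        assert e.total == pytest.approx(
            -MU0 * moment_20nm**2 / (2 * np.pi * r**3), rel=1e-12)

    def test_total_is_exact_sum(self, small_ensemble):
        e = ms.total_energy(small_ensemble, B_ext=[0.01, 0, 0])
        assert e.total == e.dipolar + e.wca + e.zeeman
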