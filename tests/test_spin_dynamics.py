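import numpy as np
import pytest

import magsense as ms
from magsense.constants import MU0
from magsense.errors import DomainError
from magsense.spin_dynamics import (
    ConstantField,
    DemagProtocol,
    FieldSweep,
    SDParams,
    Trajectory,
    demagnetize,
    magnetization_curve,
    relax,
    sd_integrate,
)

from _oracles import brute_force_ground_state


def single_macrospin(direction, moment=None):
    m = moment if moment is not None else ms.moment_magnitude(20e-9, 1.446e6)
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    return ms.NanoparticleEnsemble(
        positions=np.array([[50e-9, 50e-9, 50e-9]]),
        diameters=np.array([20e-9]),
        moments=m * v[None, :],
        box=[100e-9] * 3, motion_dim=3,
    )


class TestSDIntegrate:
    def test_damped_alignment_into_field(self):
        ens = single_macrospin([1, 0, 0])  # 90 degrees from B
        traj = sd_integrate(ens, ConstantField((0, 0, 0.05)),
                            SDParams(alpha=0.1, dt=1e-13), n_steps=60_000)
        mhat = traj.final_ensemble.moments[0]
        mhat = mhat / np.linalg.norm(mhat)
        assert mhat[2] > 0.999

    def test_moment_magnitude_conserved(self, pair_factory):
        ens = pair_factory(25e-9, seed=5)
        mags0 = ens.moment_magnitudes.copy()
        traj = sd_integrate(ens, ConstantField((0, 0, 0.02)),
                            SDParams(alpha=0.1, dt=1e-13), n_steps=5000,
                            record_every=500)
        for snap in traj.moments:
            np.testing.assert_allclose(np.linalg.norm(snap, axis=1), mags0,
                                       rtol=1e-10)

    def test_conservative_precession_energy(self):
        # alpha = 0, T = 0, constant B: Zeeman energy is conserved
        ens = single_macrospin([1, 0, 1])
        p = SDParams(alpha=0.0, dt=1e-13)
        traj = sd_integrate(ens, ConstantField((0, 0, 0.01)), p,
                            n_steps=10_000, record_every=1000)
        e = np.array([b.total for b in traj.energies])
        assert np.abs(e - e[0]).max() <= 1e-6 * np.abs(e[0])

    def test_two_contact_particles_ground_state(self, pair_factory,
                                                moment_20nm):
        r = 20e-9
        ens = pair_factory(r, seed=9)
        traj = sd_integrate(ens, ConstantField(),
                            SDParams(alpha=0.5, dt=2e-13), n_steps=20_000)
        e_target = -MU0 * moment_20nm**2 / (2 * np.pi * r**3)
        assert traj.energies[-1].dipolar == pytest.approx(e_target, rel=0.01)
        mhat = traj.final_ensemble.moments
        mhat = mhat / np.linalg.norm(mhat, axis=1, keepdims=True)
        # head-to-tail along the pair axis (x)
        assert abs(mhat[0, 0]) > 0.999
        assert mhat[0] @ mhat[1] > 0.999

    def test_deterministic_given_seed(self, pair_factory):
        ens = pair_factory(30e-9, seed=2)
        ens = ens.with_(temperature=50.0)
        p = SDParams(alpha=0.1, dt=1e-13, seed=77)
        a = sd_integrate(ens, ConstantField(), p, n_steps=500)
        b = sd_integrate(ens, ConstantField(), p, n_steps=500)
        np.testing.assert_array_equal(a.final_ensemble.moments,
                                      b.final_ensemble.moments)

    def test_invalid_steps(self, small_ensemble):
        with pytest.raises(DomainError):
            sd_integrate(small_ensemble, ConstantField(), SDParams(), 0)


class TestRelax:
    def test_single_particle_untouched(self):
        ens = single_macrospin([0, 1, 0])
        res = relax(ens, SDParams(alpha=0.5, dt=1e-13), window=200,
                    max_windows=5)
        assert res.energy.dipolar == 0.0
        mhat = res.ensemble.moments[0] / np.linalg.norm(
            res.ensemble.moments[0])
        assert mhat @ np.array([0, 1, 0]) > 0.999999

    def test_energy_non_increasing_between_windows(self, fast_sd):
        ens = ms.generate_random_ensemble(12, (250e-9, 250e-9), seed=8)
        energies = []
        work = ens
        for _ in range(6):
            res = relax(work, fast_sd, tol=1e-30, window=400, max_windows=1)
            work = res.ensemble
            energies.append(res.energy.total)
        e = np.array(energies)
        assert np.all(np.diff(e) <= 1e-9 * np.abs(e[:-1]))

    def test_collinear_three_matches_brute_force(self, fast_sd, moment_20nm):
        d = 20e-9
        pos = np.array([[100e-9, 100e-9, 0], [100e-9 + d, 100e-9, 0],
                        [100e-9 + 2 * d, 100e-9, 0]])
        e_bf = brute_force_ground_state(pos[:, :2] - pos[0, :2], moment_20nm,
                                        coarse_deg=1.0)
        best = np.inf
        for seed in range(6):
            g = np.random.default_rng(seed)
            v = g.normal(size=(3, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            ens = ms.NanoparticleEnsemble(
                positions=pos + 50e-9, diameters=np.full(3, d),
                moments=moment_20nm * v, box=[400e-9] * 3, motion_dim=3)
            res = relax(ens, fast_sd, tol=1e-26, window=1000, max_windows=60)
            best = min(best, res.energy.dipolar)
        assert best == pytest.approx(e_bf, rel=0.01)
        # ground state of the chain: all moments along the line
        mhat = res.ensemble.moments / moment_20nm

    def test_unconverged_flag(self, small_ensemble):
        res = relax(small_ensemble, SDParams(alpha=0.1, dt=1e-14),
                    tol=1e-40, window=50, max_windows=2)
        assert not res.converged

    def test_requires_positive_damping(self, small_ensemble):
        with pytest.raises(DomainError):
            relax(small_ensemble, SDParams(alpha=0.0, dt=1e-13))


class TestDemagnetize:
    def test_energy_not_increased(self, fast_sd):
        ens = ms.generate_random_ensemble(24, (250e-9, 250e-9), seed=4)
        e0 = ms.total_energy(ens).dipolar
        res = demagnetize(ens, DemagProtocol(duration=2e-9),
                          SDParams(alpha=0.5, dt=2e-13))
        assert res.energy.dipolar <= e0

    def test_zero_field_equals_relax(self, fast_sd):
        ens = ms.generate_random_ensemble(8, (250e-9, 250e-9), seed=6)
        a = demagnetize(ens, DemagProtocol(B0=0.0), fast_sd)
        b = relax(ens, fast_sd)
        np.testing.assert_allclose(a.ensemble.moments, b.ensemble.moments,
                                   rtol=1e-10)

    def test_protocol_validation(self):
        with pytest.raises(DomainError):
            DemagProtocol(B0=-0.01)
        with pytest.raises(DomainError):
            DemagProtocol(duration=0.0)

    def test_field_series_shape_and_envelope(self):
        proto = DemagProtocol(B0=0.05, duration=1e-7)
        s = proto.series(1e-12, 100_000)
        mags = np.linalg.norm(s, axis=1)
        assert s.shape == (100_000, 3)
        assert mags.max() <= 0.05 + 1e-12
        assert mags[-100:].max() < 0.005  # damped to ~zero at the end


class TestMagnetizationCurve:
    def test_single_macrospin_saturates(self, fast_sd):
        ens = single_macrospin([0, 1, 0])
        sweep = FieldSweep(B_max=0.1, n_steps=5, axis=(1, 0, 0), mode="half")
        B, m = magnetization_curve(ens, sweep, fast_sd,
                                   steps_per_field=4000)
        assert m[0] == pytest.approx(1.0, abs=1e-3)
        assert m[-1] == pytest.approx(-1.0, abs=1e-3)

    def test_loop_shape_contract(self, fast_sd):
        ens = single_macrospin([1, 0, 0])
        sweep = FieldSweep(B_max=0.05, n_steps=5, mode="loop")
        B, m = magnetization_curve(ens, sweep, fast_sd, steps_per_field=500)
        assert len(B) == len(m) == 2 * 5 - 1
        np.testing.assert_allclose(B, sweep.field_values())
        assert np.all(np.abs(m) <= 1 + 1e-9)

    def test_relaxed_many_particle_zero_field_not_saturated(self, fast_sd):
        ens = ms.generate_random_ensemble(16, (200e-9, 200e-9), seed=13)
        res = relax(ens, fast_sd, window=1000, max_windows=30)
        mag = np.linalg.norm(res.ensemble.reduced_magnetization())
        assert mag < 1.0


class TestTrajectoryInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            Trajectory(times=np.arange(3, dtype=float),
                       moments=np.zeros((2, 1, 3)),
                       energies=[], magnetization=np.zeros((3, 3)))

    def test_reduced_magnetization_bounded(self, pair_factory):
        ens = pair_factory(30e-9, seed=1)
        traj = sd_integrate(ens, ConstantField((0, 0, 0.05)),
                            SDParams(alpha=0.3, dt=1e-13), n_steps=2000,
                            record_every=100)
        norms = np.linalg.norm(traj.magnetization, axis=1)
        assert np.all(norms <= 1 + 1e-9)
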