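"""Leap-frog integration, thermostat, snapshot sampling, production runs."""

import numpy as np
import pytest

from eimsim.chem_data import Molecule, atomic_mass
from eimsim.constants import KE_CONV
from eimsim.fragments import kinetic_energy
from eimsim.md import (
    MDState,
    equilibrate_nvt,
    leapfrog_step,
    run_production,
    sample_snapshots,
)
from eimsim.providers import Provider
from eimsim.ionization import MOSpectrum


class ZeroForceProvider(Provider):
    def energy_gradient(self, mol, electronic_temperature=300.0):
        return 0.0, np.zeros_like(mol.coords)

    def mo_spectrum(self, mol):
        n = mol.n_atoms
        return MOSpectrum(np.array([-10.0]), np.full((1, n), 2.0 / n))

    def vertical_ip(self, mol):
        return 10.0


class HarmonicProvider(Provider):
    """Isotropic harmonic well k/2 * |r|^2 acting on every atom."""

    def __init__(self, k=5.0):  # eV/Å^2
        self.k = k

    def energy_gradient(self, mol, electronic_temperature=300.0):
        e = 0.5 * self.k * float(np.sum(mol.coords**2))
        return e, self.k * mol.coords

    def mo_spectrum(self, mol):
        raise NotImplementedError

    def vertical_ip(self, mol):
        return 10.0


def single_atom(sym="H", x=0.0, vx=0.0):
    return Molecule([sym], np.array([[x, 0.0, 0.0]]),
                    np.array([[vx, 0.0, 0.0]]))


class TestLeapfrog:
    def test_free_particle_advances_exactly(self):
        mol = single_atom(vx=0.02)
        state = MDState(mol)
        new = leapfrog_step(state, ZeroForceProvider(), dt=0.5)
        assert new.mol.coords[0, 0] == pytest.approx(0.01, abs=1e-15)
        assert new.mol.velocities[0, 0] == 0.02
        assert new.time == 0.5

    def test_harmonic_period(self):
        # period T = 2π sqrt(m/k); amplitude 0.1 Å
        k = 5.0
        m = atomic_mass("H")
        period = 2.0 * np.pi * np.sqrt(m * KE_CONV / k)
        dt = period / 1000.0
        provider = HarmonicProvider(k)
        state = MDState(single_atom(x=0.1))
        crossings = []
        prev_x = state.mol.coords[0, 0]
        for step in range(2500):
            state = leapfrog_step(state, provider, dt)
            x = state.mol.coords[0, 0]
            if prev_x < 0 <= x:  # upward zero crossing
                frac = -prev_x / (x - prev_x)
                crossings.append((step + frac) * dt)
            prev_x = x
        assert len(crossings) >= 2
        measured = crossings[-1] - crossings[0]
        n_periods = round(measured / period)
        assert measured / n_periods == pytest.approx(period, rel=1e-3)

    def test_nve_energy_drift_bound_diatomic(self, hf_diatomic):
        mol, provider = hf_diatomic
        mol = mol.copy()
        mol.coords[1, 0] += 0.02  # small stretch
        e0, _ = provider.energy_gradient(mol)
        state = MDState(mol, 0.0, kinetic_energy(mol), e0)
        energies = []
        for _ in range(10_000):
            state = leapfrog_step(state, provider, dt=0.5)
            energies.append(state.total_energy)
        drift = abs(np.mean(energies[-100:]) - np.mean(energies[:100]))
        assert drift < 1e-4

    def test_momentum_conserved(self, hf_diatomic):
        mol, provider = hf_diatomic
        mol = mol.copy()
        mol.coords[1, 0] += 0.05
        mol.velocities[:] = [[0.001, 0.0, 0.0], [0.002, 0.001, 0.0]]
        masses = mol.masses
        p0 = (masses[:, None] * mol.velocities).sum(axis=0)
        state = MDState(mol)
        for _ in range(500):
            state = leapfrog_step(state, provider, dt=0.5)
        p1 = (state.mol.masses[:, None] * state.mol.velocities).sum(axis=0)
        assert np.allclose(p1, p0, atol=1e-9)


class TestEquilibration:
    def test_holds_set_point(self, weak_dimer):
        mol, provider = weak_dimer.molecule(), weak_dimer.provider()
        temps: list[float] = []
        equilibrate_nvt(mol, provider, 500.0, 4000.0, seed=5,
                        temperature_history=temps)
        final_third = temps[len(temps) * 2 // 3 :]
        assert np.mean(final_third) == pytest.approx(500.0, rel=0.10)

    def test_zero_duration_only_initializes_velocities(self, hf_diatomic):
        mol, provider = hf_diatomic
        state = equilibrate_nvt(mol, provider, 300.0, 0.0, seed=3)
        assert np.allclose(state.mol.coords, mol.coords)
        assert not np.allclose(state.mol.velocities, 0.0)

    def test_same_seed_same_trajectory(self, hf_diatomic):
        mol, provider = hf_diatomic
        a = equilibrate_nvt(mol, provider, 300.0, 200.0, seed=11)
        b = equilibrate_nvt(mol, provider, 300.0, 200.0, seed=11)
        assert np.array_equal(a.mol.coords, b.mol.coords)
        assert np.array_equal(a.mol.velocities, b.mol.velocities)


class TestSnapshotSampling:
    def test_counts_times_and_determinism(self, hf_diatomic):
        mol, provider = hf_diatomic
        state0 = equilibrate_nvt(mol, provider, 300.0, 100.0, seed=1)
        snaps = sample_snapshots(
            {"duration": 200.0, "n": 20}, state0, provider, seed=9
        )
        times = [s.time for s in snaps]
        assert len(snaps) == 20
        assert times == sorted(times) and len(set(times)) == 20
        again = sample_snapshots(
            {"duration": 200.0, "n": 20}, state0, provider, seed=9
        )
        assert [s.time for s in again] == times

    def test_single_snapshot_and_overdraw_error(self, hf_diatomic):
        mol, provider = hf_diatomic
        state0 = MDState(mol.copy())
        assert len(sample_snapshots({"duration": 10.0, "n": 1}, state0, provider)) == 1
        with pytest.raises(ValueError):
            sample_snapshots({"duration": 5.0, "n": 100}, state0, provider)


class TestProductionRun:
    def test_no_iee_no_fragmentation(self, weak_dimer):
        mol, provider = weak_dimer.molecule(), weak_dimer.provider()
        state = equilibrate_nvt(mol, provider, 300.0, 500.0, seed=2)
        res = run_production(state, provider, iee=0.0, ionized_mo=2,
                             max_time=1000.0, seed=3)
        assert res.terminated_by == "no_fragmentation_timeout"
        assert len(res.fragment_records) == 1
        assert res.fragment_records[0].formula.hill() == "CH4O"
        assert res.fragment_records[0].statistical_charge == 1.0

    def test_forced_dissociation_gives_designed_fragments(self, weak_dimer):
        mol, provider = weak_dimer.molecule(), weak_dimer.provider()
        state = equilibrate_nvt(mol, provider, 500.0, 1000.0, seed=4)
        res = run_production(state, provider, iee=weak_dimer.suggested_iee,
                             ionized_mo=2, max_time=4000.0, seed=5)
        formulas = sorted(r.formula.hill() for r in res.fragment_records)
        assert formulas == sorted(weak_dimer.expected_fragments)

    def test_charges_sum_to_one(self, weak_dimer, chain3):
        for fix, mo in ((weak_dimer, 2), (chain3, 1)):
            mol, provider = fix.molecule(), fix.provider()
            state = equilibrate_nvt(mol, provider, 500.0, 1000.0, seed=6)
            for seed in (7, 8):
                res = run_production(state, provider, iee=fix.suggested_iee,
                                     ionized_mo=mo, max_time=3000.0, seed=seed)
                assert res.success
                total = sum(r.statistical_charge for r in res.fragment_records)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_atom_conservation_across_records(self, chain3):
        mol, provider = chain3.molecule(), chain3.provider()
        state = equilibrate_nvt(mol, provider, 500.0, 1000.0, seed=9)
        res = run_production(state, provider, iee=chain3.suggested_iee,
                             ionized_mo=1, max_time=3000.0, seed=10)
        merged: dict[str, int] = {}
        for rec in res.fragment_records:
            for sym, n in rec.formula.counts.items():
                merged[sym] = merged.get(sym, 0) + n
        assert merged == {"C": 1, "N": 1, "O": 1, "F": 1}

    def test_determinism_under_seed(self, weak_dimer):
        mol, provider = weak_dimer.molecule(), weak_dimer.provider()
        state = equilibrate_nvt(mol, provider, 500.0, 500.0, seed=20)
        runs = [
            run_production(state, provider, iee=6.0, ionized_mo=2,
                           max_time=2000.0, seed=21)
            for _ in range(2)
        ]
        a, b = runs
        assert a.n_steps == b.n_steps and a.terminated_by == b.terminated_by
        assert [r.formula.hill() for r in a.fragment_records] == [
            r.formula.hill() for r in b.fragment_records
        ]
        assert [r.statistical_charge for r in a.fragment_records] == [
            r.statistical_charge for r in b.fragment_records
        ]

    def test_provider_failure_is_counted_not_raised(self, weak_dimer):
        class FailingProvider(ZeroForceProvider):
            def energy_gradient(self, mol, electronic_temperature=300.0):
                from eimsim.providers import ProviderError

                raise ProviderError("SCF blew up")

        mol = weak_dimer.molecule()
        state = MDState(mol)
        res = run_production(state, FailingProvider(), iee=1.0, ionized_mo=0,
                             max_time=100.0, seed=1)
        assert res.terminated_by == "provider_failure"
        assert not res.success
        assert res.fragment_records == []
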