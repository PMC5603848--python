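"""Boltzmann charge partitioning and cascade charge conservation."""

import numpy as np
import pytest
import sympy

from eimsim.chem_data import Molecule, formula_of
from eimsim.charges import assign_and_select, charge_assignment, statistical_weights
from eimsim.constants import K_B
from eimsim.fragments import FragmentRecord


def record(n_atoms=2, ip=10.0, temperature=2000.0, depth=1):
    syms = ["C"] * n_atoms
    coords = np.arange(3 * n_atoms, dtype=float).reshape(n_atoms, 3) * 2.0
    mol = Molecule(syms, coords, np.zeros((n_atoms, 3)))
    return FragmentRecord(mol, formula_of(mol), ip, temperature, 0.0, depth)


class TestStatisticalWeights:
    def test_equal_ips_split_evenly(self):
        assert np.allclose(statistical_weights([9.0, 9.0], 3000.0), [0.5, 0.5])

    def test_normalized_for_any_input(self, rng):
        for _ in range(50):
            ips = rng.uniform(5.0, 15.0, rng.integers(1, 8))
            t = rng.uniform(10.0, 10_000.0)
            assert statistical_weights(ips, t).sum() == pytest.approx(1.0, abs=1e-12)

    def test_against_arbitrary_precision_boltzmann(self):
        # independent oracle: sympy exact exponentials at 50 digits
        ips, t_av = [8.0, 9.0], 5000.0
        kbt = sympy.Float(K_B, 50) * sympy.Integer(5000)
        terms = [sympy.exp(-sympy.Float(ip, 50) / kbt) for ip in ips]
        total = sum(terms)
        expected = [float(term / total) for term in terms]
        got = statistical_weights(ips, t_av)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_temperature_limit_and_ties(self):
        with pytest.warns(UserWarning):
            w = statistical_weights([7.0, 9.0, 7.0], 0.0)
        assert np.allclose(w, [0.5, 0.0, 0.5])

    def test_shift_invariance(self, rng):
        ips = rng.uniform(6.0, 14.0, 5)
        w0 = statistical_weights(ips, 4000.0)
        w1 = statistical_weights(ips + 100.0, 4000.0)
        assert np.allclose(w0, w1, atol=1e-12)

    def test_lowering_ip_never_lowers_weight(self, rng):
        ips = list(rng.uniform(8.0, 12.0, 4))
        w0 = statistical_weights(ips, 3000.0)
        lowered = list(ips)
        lowered[2] -= 1.0
        w1 = statistical_weights(lowered, 3000.0)
        assert w1[2] >= w0[2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            statistical_weights([], 1000.0)

    def test_selected_index_is_argmax_lowest_on_tie(self):
        assign = charge_assignment([9.0, 8.0, 8.0], 3000.0)
        assert assign.selected_index == 1


class TestAssignAndSelect:
    def test_single_fragment_survives_with_parent_weight(self):
        rec = record(n_atoms=3)
        stored, nxt = assign_and_select([rec], parent_weight=0.8)
        assert nxt is rec
        assert rec.statistical_charge == pytest.approx(0.8)
        assert stored == []

    def test_two_level_cascade_hand_multiplication(self):
        # stage 1 weights 0.7/0.3, stage 2 weights 0.6/0.4 => survivor 0.42
        a, b = record(ip=8.0, temperature=1.0), record(ip=8.0, temperature=1.0)
        stored1, nxt1 = assign_and_select([a, b], 1.0)
        # force the designed weights directly to exercise the bookkeeping rule
        nxt1.statistical_charge = 0.7
        stored1[0].statistical_charge = 0.3
        c, d = record(ip=8.0), record(n_atoms=1, ip=9.5)
        t_av = np.mean([c.temperature, d.temperature])
        w = statistical_weights([c.vertical_ip, d.vertical_ip], t_av)
        stored2, nxt2 = assign_and_select([c, d], nxt1.statistical_charge)
        assert nxt2.statistical_charge == pytest.approx(0.7 * w[0])
        total = (stored1[0].statistical_charge
                 + sum(r.statistical_charge for r in stored2)
                 + nxt2.statistical_charge)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_atom_terminates_cascade(self):
        atom = record(n_atoms=1, ip=7.0)
        mol2 = record(n_atoms=2, ip=12.0)
        stored, nxt = assign_and_select([atom, mol2], 1.0)
        assert nxt is None  # argmax fragment is a lone atom: nothing to propagate
        assert len(stored) == 2

    def test_depth_cap_terminates(self):
        deep = record(n_atoms=4, ip=7.0, depth=6)
        other = record(n_atoms=2, ip=12.0, depth=6)
        stored, nxt = assign_and_select([deep, other], 0.5, depth_cap=6)
        assert nxt is None
        assert sum(r.statistical_charge for r in stored) == pytest.approx(0.5)

    def test_stored_charges_bounded_by_parent_weight(self, rng):
        recs = [record(ip=float(ip)) for ip in rng.uniform(7, 13, 5)]
        stored, nxt = assign_and_select(recs, 0.37)
        for r in recs:
            assert r.statistical_charge <= 0.37 + 1e-12


def brute_force_cascade(weights_per_level):
    """Recursive oracle: total stored charge for a cascade with the given
    per-level weight vectors (survivor continues with index 0's weight)."""

    def go(parent, levels):
        if not levels:
            return parent
        w = levels[0]
        stored = parent * sum(w[1:])
        return stored + go(parent * w[0], levels[1:])

    return go(1.0, weights_per_level)


class TestCascadeConservation:
    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_cascade_trees_conserve_charge(self, seed):
        rng = np.random.default_rng(seed)
        depth = int(rng.integers(1, 6))
        parent_weight = 1.0
        total_stored = 0.0
        level_weights = []
        for level in range(1, depth + 1):
            n_frag = int(rng.integers(2, 5))
            recs = [
                record(
                    n_atoms=int(rng.integers(2, 4)),
                    ip=float(rng.uniform(7, 13)),
                    temperature=float(rng.uniform(500, 6000)),
                    depth=level,
                )
                for _ in range(n_frag)
            ]
            stored, nxt = assign_and_select(recs, parent_weight)
            w = statistical_weights(
                [r.vertical_ip for r in recs],
                float(np.mean([r.temperature for r in recs])),
            )
            order = [int(np.argmax(w))] + [
                i for i in range(n_frag) if i != int(np.argmax(w))
            ]
            level_weights.append([w[i] for i in order])
            total_stored += sum(r.statistical_charge for r in stored)
            if nxt is None:
                break
            parent_weight = nxt.statistical_charge
        else:
            total_stored += parent_weight  # survivor recorded at the end
        assert total_stored == pytest.approx(
            brute_force_cascade(level_weights[: len(level_weights)]), abs=1e-9
        )
        assert total_stored == pytest.approx(1.0, abs=1e-9)
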