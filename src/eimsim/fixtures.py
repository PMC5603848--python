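"""Designed toy molecules with analytically predictable fragmentation.

Each fixture bundles a geometry, surrogate-PES parameters, a mock orbital
spectrum and a vertical-IP table, chosen so the energetics dictate what the
full protocol must produce: which bond breaks, which fragment keeps the
charge, how deep the cascade goes. They make every stage of the simulator
testable at desk scale; they are not models of real molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_data import Formula, Molecule, covalent_radius, formula_of, parse_xyz, write_xyz
from .providers import MockMOConfig, PairMorse, SurrogatePESParams, SurrogateProvider

__all__ = [
    "FixtureSpec",
    "make_weak_bond_dimer",
    "make_cascade_chain",
    "list_fixtures",
    "get_fixture",
    "demo_xyz",
]


@dataclass(eq=False)
class FixtureSpec:
    name: str
    xyz: str
    pes_params: SurrogatePESParams
    mo_config: MockMOConfig
    ip_table: dict[str, float]
    ip_fallback: float
    expected_fragments: list[str]  # canonical Hill formulas
    suggested_iee: float  # eV, comfortably above the designed weak bond

    def molecule(self) -> Molecule:
        return parse_xyz(self.xyz)

    def provider(self) -> SurrogateProvider:
        return SurrogateProvider(
            self.molecule(),
            self.pes_params,
            self.mo_config,
            self.ip_table,
            self.ip_fallback,
        )

    def __post_init__(self) -> None:
        parent = formula_of(self.molecule())
        total: dict[str, int] = {}
        for hill in self.expected_fragments:
            for sym, n in Formula.from_string(hill).counts.items():
                total[sym] = total.get(sym, 0) + n
        if total != dict(parent.counts):
            raise ValueError(
                f"{self.name}: expected fragments {self.expected_fragments} do not "
                f"sum to the parent formula {parent.hill()}"
            )


def _tetrahedral_frame(bond: float) -> np.ndarray:
    """Three unit directions at 109.47° from +x, for sp3-like substituents."""
    base = np.array(
        [
            [-1.0 / 3.0, 2.0 * np.sqrt(2.0) / 3.0, 0.0],
            [-1.0 / 3.0, -np.sqrt(2.0) / 3.0, np.sqrt(2.0 / 3.0)],
            [-1.0 / 3.0, -np.sqrt(2.0) / 3.0, -np.sqrt(2.0 / 3.0)],
        ]
    )
    return bond * base


def make_weak_bond_dimer(
    de_strong: float = 6.0, de_weak: float = 1.0
) -> FixtureSpec:
    """Two strongly bound moieties joined by one weak bond.

    A methanol-shaped CH3–OH skeleton: the C–O bridge carries the weak Morse
    well, every X–H bond the strong one. Heating above ``de_weak`` cleaves the
    bridge into CH3 and OH; the IP table (7 vs 11 eV) then routes essentially
    all the statistical charge onto the methyl moiety.
    """
    if not de_weak < de_strong:
        raise ValueError("need de_weak < de_strong")
    r_ch = covalent_radius("C") + covalent_radius("H")
    r_co = covalent_radius("C") + covalent_radius("O")
    r_oh = covalent_radius("O") + covalent_radius("H")
    c = np.zeros(3)
    o = np.array([r_co, 0.0, 0.0])
    hs = _tetrahedral_frame(r_ch)  # three H on carbon, pointing away from O
    oh_dir = np.array([np.cos(np.deg2rad(70.0)), np.sin(np.deg2rad(70.0)), 0.0])
    h_on_o = o + r_oh * oh_dir
    coords = np.vstack([c, hs[0], hs[1], hs[2], o, h_on_o])
    symbols = ["C", "H", "H", "H", "O", "H"]
    mol = Molecule(symbols, coords, np.zeros((6, 3)))
    xyz = write_xyz(mol, comment="weak-bond dimer fixture")
    params = SurrogatePESParams(
        default_well_depth=de_strong,
        default_width=1.8,
        pair_overrides={
            frozenset(("C", "O")): PairMorse(de_weak, 1.8),
            frozenset(("C", "H")): PairMorse(de_strong, 1.8),
            frozenset(("O", "H")): PairMorse(de_strong, 1.8),
        },
        charge_softening=0.2,
    )
    # HOMO localized on the C–O bridge so the initial kick lands on the weak bond
    mo = MockMOConfig(
        orbital_energies=[-15.0, -14.6, -10.0],
        populations=[
            [1.0 / 3.0] * 6,
            [1.0 / 3.0] * 6,
            [0.90, 0.03, 0.03, 0.03, 0.95, 0.06],
        ],
    )
    ip_table = {"CH3": 7.0, "OH": 11.0, "CH4O": 9.5}
    return FixtureSpec(
        name="weak_bond_dimer",
        xyz=xyz,
        pes_params=params,
        mo_config=mo,
        ip_table=ip_table,
        ip_fallback=10.0,
        expected_fragments=["CH3", "HO"],
        suggested_iee=6.0,
    )


_CHAIN_ELEMENTS = ["C", "N", "O", "F", "S", "Cl", "P", "B"]


def make_cascade_chain(n_links: int = 3) -> FixtureSpec:
    """A linear chain whose bonds strengthen toward the head.

    The terminal bond is weakest, so heating peels atoms off the tail one at a
    time; the IP table makes the large remainder the charge carrier at every
    event, forcing at least two cascade levels.
    """
    if n_links < 2:
        raise ValueError("need n_links >= 2")
    if n_links + 1 > len(_CHAIN_ELEMENTS):
        raise ValueError(f"at most {len(_CHAIN_ELEMENTS) - 1} links supported")
    symbols = _CHAIN_ELEMENTS[: n_links + 1]
    xs = [0.0]
    for a, b in zip(symbols, symbols[1:]):
        xs.append(xs[-1] + covalent_radius(a) + covalent_radius(b))
    coords = np.array([[x, 0.0, 0.0] for x in xs])
    mol = Molecule(symbols, coords, np.zeros((len(symbols), 3)))
    xyz = write_xyz(mol, comment="cascade chain fixture")
    # bond k joins atoms k and k+1; strength decays toward the tail
    overrides = {}
    de_tail = 0.6
    growth = 2.5
    for k, (a, b) in enumerate(zip(symbols, symbols[1:])):
        d_e = min(de_tail * growth ** (n_links - 1 - k), 8.0)
        overrides[frozenset((a, b))] = PairMorse(d_e, 1.8)
    params = SurrogatePESParams(
        pair_overrides=overrides, charge_softening=0.2
    )
    n = len(symbols)
    # HOMO weighted toward the weak tail end
    tail_weight = np.linspace(0.5, 1.5, n)
    tail_weight *= 2.0 / tail_weight.sum()
    mo = MockMOConfig(
        orbital_energies=[-14.0, -10.0],
        populations=[[2.0 / n] * n, list(tail_weight)],
    )
    # larger contiguous head fragments get lower IPs, single atoms the highest
    ip_table: dict[str, float] = {}
    for size in range(1, n + 1):
        hill = formula_of(
            Molecule(symbols[:size], coords[:size], np.zeros((size, 3)))
        ).hill()
        ip_table[hill] = 13.0 - 1.2 * size
    for sym in symbols:
        ip_table.setdefault(sym, 13.5)
    expected = [formula_of(Molecule(symbols[:-2], coords[:-2], np.zeros((n - 2, 3)))).hill()]
    expected += [symbols[-2], symbols[-1]]
    return FixtureSpec(
        name=f"cascade_chain_{n_links}",
        xyz=xyz,
        pes_params=params,
        mo_config=mo,
        ip_table=ip_table,
        ip_fallback=13.0,
        expected_fragments=expected,
        suggested_iee=6.0,
    )


_FACTORIES = {
    "weak_bond_dimer": make_weak_bond_dimer,
    "cascade_chain": make_cascade_chain,
}


def list_fixtures() -> list[str]:
    return sorted(_FACTORIES)


def get_fixture(name: str, **kwargs) -> FixtureSpec:
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from None
    return factory(**kwargs)


def demo_xyz(name: str) -> str:
    """Demo XYZ inputs for use with an external quantum-chemistry backend.

    Synthetic idealized geometries (crown S8, tetrahedral methane) — starting
    points for a real backend's optimizer, not refined structures.
    """
    if name == "s8":
        # D4d crown: ring radius and pucker giving ~2.05 Å S–S bonds
        r_ring, pucker = 2.24, 0.49
        coords = []
        for k in range(8):
            ang = 2.0 * np.pi * k / 8.0
            coords.append(
                [r_ring * np.cos(ang), r_ring * np.sin(ang), pucker * (-1) ** k]
            )
        mol = Molecule(["S"] * 8, np.array(coords), np.zeros((8, 3)))
        return write_xyz(mol, comment="synthetic crown S8 demo input")
    if name == "methane":
        r = 1.09
        dirs = np.vstack([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                          [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)
        coords = np.vstack([[0.0, 0.0, 0.0], r * dirs])
        mol = Molecule(["C", "H", "H", "H", "H"], coords, np.zeros((5, 3)))
        return write_xyz(mol, comment="synthetic tetrahedral methane demo input")
    raise KeyError(f"unknown demo geometry {name!r}")
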