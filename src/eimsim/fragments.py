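"""Geometric bond detection, fragment extraction and fragment temperature.

Bonds are detected from interatomic distances against scaled covalent-radius
sums; fragments are the connected components of that graph. The fragment
temperature is the *internal* kinetic temperature: center-of-mass translation
is always removed, rigid rotation is removed for three or more atoms, and the
remaining kinetic energy is divided over the vibrational degrees of freedom
(3N−6 nonlinear, 3N−5 linear, and a single-mode convention for diatomics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chem_data import Formula, Molecule, covalent_radius
from .constants import KE_CONV, K_B

__all__ = [
    "BondGraph",
    "FragmentRecord",
    "detect_bonds",
    "split_fragments",
    "split_indices",
    "kinetic_energy",
    "fragment_temperature",
]

#: default scale on the covalent-radius sum for calling two atoms bonded
DEFAULT_BOND_SCALE = 1.2


@dataclass
class BondGraph:
    """Symmetric adjacency over atom indices plus the detection scale used."""

    n_atoms: int
    edges: set[frozenset[int]] = field(default_factory=set)
    detection_scale: float = DEFAULT_BOND_SCALE

    def add(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-edges are not allowed")
        self.edges.add(frozenset((i, j)))

    def bonded(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.edges

    def components(self) -> list[list[int]]:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(tuple(e) for e in self.edges)
        return [sorted(c) for c in nx.connected_components(g)]


@dataclass(eq=False)
class FragmentRecord:
    """A detached fragment with the quantities the charge model needs."""

    mol: Molecule
    formula: Formula
    vertical_ip: float  # eV
    temperature: float  # K
    statistical_charge: float
    cascade_depth: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistical_charge <= 1.0 + 1e-12:
            raise ValueError("statistical charge outside [0, 1]")
        if self.temperature < 0:
            raise ValueError("negative temperature")


def detect_bonds(mol: Molecule, k: float = DEFAULT_BOND_SCALE) -> BondGraph:
    """Edge (i, j) iff distance(i, j) < k * (R_i + R_j), R covalent radii."""
    radii = np.array([covalent_radius(s) for s in mol.symbols])
    g = BondGraph(mol.n_atoms, detection_scale=k)
    if mol.n_atoms < 2:
        return g
    diff = mol.coords[:, None, :] - mol.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cutoff = k * (radii[:, None] + radii[None, :])
    ii, jj = np.where((dist < cutoff) & np.tri(mol.n_atoms, k=-1, dtype=bool).T)
    for i, j in zip(ii, jj):
        g.add(int(i), int(j))
    return g


def split_indices(mol: Molecule, g: BondGraph) -> list[list[int]]:
    """Connected-component atom index lists, sorted by smallest member."""
    return sorted(g.components(), key=lambda c: c[0])


def split_fragments(mol: Molecule, g: BondGraph) -> list[Molecule]:
    """Connected components as molecules, carrying coordinates and velocities."""
    return [mol.subset(c) for c in split_indices(mol, g)]


def kinetic_energy(mol: Molecule) -> float:
    """Total nuclear kinetic energy in eV."""
    return 0.5 * KE_CONV * float(np.sum(mol.masses * np.sum(mol.velocities**2, axis=1)))


def _is_linear(coords: np.ndarray, tol: float = 1e-6) -> bool:
    if len(coords) < 3:
        return True
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] < tol * max(s[0], 1.0))


def internal_velocities(mol: Molecule) -> np.ndarray:
    """Velocities with COM translation removed, and rigid rotation for N >= 3."""
    m = mol.masses
    v = mol.velocities - np.average(mol.velocities, axis=0, weights=m)
    if mol.n_atoms < 3:
        return v
    com = np.average(mol.coords, axis=0, weights=m)
    r = mol.coords - com
    # angular momentum and inertia tensor about the COM
    ang_mom = np.sum(m[:, None] * np.cross(r, v), axis=0)
    inertia = np.zeros((3, 3))
    for mi, ri in zip(m, r):
        inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    omega = np.linalg.pinv(inertia, rcond=1e-10) @ ang_mom
    return v - np.cross(omega, r)


def vibrational_dof(mol: Molecule) -> int:
    n = mol.n_atoms
    if n <= 2:
        return 1  # single-mode convention for atoms/diatomics
    return 3 * n - 5 if _is_linear(mol.coords) else 3 * n - 6


def fragment_temperature(frag: Molecule) -> float:
    """Internal kinetic temperature in K: T = 2 E_int / (n_dof k_B)."""
    if frag.n_atoms < 1:
        raise ValueError("empty fragment")
    v_int = internal_velocities(frag)
    e_int = 0.5 * KE_CONV * float(np.sum(frag.masses * np.sum(v_int**2, axis=1)))
    return 2.0 * e_int / (vibrational_dof(frag) * K_B)
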