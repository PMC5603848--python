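"""Electronic-structure providers: the contract plus desk-scale built-ins.

A *provider* supplies the three services the simulation protocol consumes:

* ``energy_gradient(mol, electronic_temperature)`` — potential energy (eV) and
  nuclear gradient (eV/Å) on the current charge state's surface;
* ``mo_spectrum(mol)`` — occupied-orbital energies and per-orbital per-atom
  Mulliken populations;
* ``vertical_ip(mol)`` — vertical ionization potential (eV) at the frozen
  geometry.

The built-in :class:`SurrogateProvider` is a reactive pairwise potential
(Morse bonds over a topology frozen at construction, plus a short-range
exponential repulsion between all pairs) with a configurable mock orbital
spectrum and a table-driven vertical-IP service. It exists so the full
protocol is testable with analytically predictable fixtures; quantitative
spectra of real molecules require an external quantum-chemistry backend via
:class:`ExternalEngineAdapter`.
"""

from __future__ import annotations

import subprocess
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem_data import Formula, Molecule, covalent_radius, formula_of, write_xyz
from .fragments import BondGraph, detect_bonds, DEFAULT_BOND_SCALE
from .ionization import MOSpectrum

__all__ = [
    "ProviderError",
    "Provider",
    "PairMorse",
    "SurrogatePESParams",
    "surrogate_energy_gradient",
    "MockMOConfig",
    "mock_mo_spectrum",
    "heuristic_vertical_ip",
    "SurrogateProvider",
    "ExternalEngineAdapter",
]


class ProviderError(RuntimeError):
    """An electronic-structure call failed; production runs count this as lost."""


class Provider(ABC):
    """Abstract provider contract. The electronic temperature (K) is part of
    the call signature; backends that ignore it must document that."""

    @abstractmethod
    def energy_gradient(
        self, mol: Molecule, electronic_temperature: float = 300.0
    ) -> tuple[float, np.ndarray]: ...

    @abstractmethod
    def mo_spectrum(self, mol: Molecule) -> MOSpectrum: ...

    @abstractmethod
    def vertical_ip(self, mol: Molecule) -> float: ...

    def subset(self, indices: Sequence[int]) -> "Provider":
        """Provider restricted to a fragment's atoms (cascade propagation).

        Default: the provider is geometry-agnostic and returns itself.
        """
        return self


@dataclass(frozen=True)
class PairMorse:
    """Morse parameters for one element pair; r_e defaults to the covalent-radius sum."""

    well_depth: float  # D_e, eV
    width: float  # a, 1/Å
    r_e: float | None = None  # Å

    def __post_init__(self) -> None:
        if self.well_depth <= 0 or self.width <= 0:
            raise ValueError("well_depth and width must be positive")
        if self.r_e is not None and self.r_e <= 0:
            raise ValueError("r_e must be positive")


@dataclass
class SurrogatePESParams:
    """Parameters of the surrogate reactive PES.

    ``pair_overrides`` maps frozensets of element symbols (or a single-symbol
    frozenset for homonuclear pairs) to :class:`PairMorse`; unlisted pairs use
    the defaults. On a charged surface every well depth is multiplied by
    ``1 − charge_softening`` in the attractive region only, so the cation
    surface is everywhere at or above the neutral one — ionization weakens
    binding without creating spurious short-range attraction.
    """

    default_well_depth: float = 4.0  # eV
    default_width: float = 1.8  # 1/Å
    pair_overrides: dict[frozenset, PairMorse] = field(default_factory=dict)
    charge_softening: float = 0.2
    rep_strength: float = 10.0  # eV
    rep_range: float = 0.08  # Å

    def __post_init__(self) -> None:
        if not 0.0 <= self.charge_softening < 1.0:
            raise ValueError("charge_softening must be in [0, 1)")
        if self.default_well_depth <= 0 or self.default_width <= 0:
            raise ValueError("default Morse parameters must be positive")
        self.pair_overrides = {
            frozenset(k): v for k, v in self.pair_overrides.items()
        }

    def lookup(self, sym_i: str, sym_j: str) -> tuple[float, float, float]:
        """(D_e, a, r_e) for an element pair."""
        pm = self.pair_overrides.get(frozenset((sym_i, sym_j)))
        if pm is None:
            d_e, a, r_e = self.default_well_depth, self.default_width, None
        else:
            d_e, a, r_e = pm.well_depth, pm.width, pm.r_e
        if r_e is None:
            r_e = covalent_radius(sym_i) + covalent_radius(sym_j)
        return d_e, a, r_e


def surrogate_energy_gradient(
    mol: Molecule,
    params: SurrogatePESParams,
    topology: BondGraph | None = None,
) -> tuple[float, np.ndarray]:
    """Energy (eV) and analytic gradient (eV/Å) of the surrogate PES.

    Morse terms act only along ``topology`` edges (detected from the current
    geometry if not given); an exponential repulsion acts between all pairs.
    For a charged molecule the attractive (negative-energy) part of each Morse
    term is scaled by ``1 − charge_softening``; the scaled and unscaled
    branches join continuously at the zero crossing (the gradient has a small
    kink there, deep inside the repulsive wall).
    """
    if mol.n_atoms < 1:
        raise ValueError("need at least one atom")
    if topology is None:
        topology = detect_bonds(mol)
    soften = params.charge_softening if mol.charge != 0 else 0.0
    energy = 0.0
    grad = np.zeros_like(mol.coords)
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            rij = mol.coords[j] - mol.coords[i]
            r = float(np.linalg.norm(rij))
            if r < 1e-6:
                raise ValueError(f"atoms {i} and {j} overlap (r = {r:.2e} Å)")
            u = rij / r
            # short-range repulsion, all pairs
            e_rep = params.rep_strength * np.exp(-r / params.rep_range)
            de_rep = -e_rep / params.rep_range
            energy += e_rep
            grad[i] -= de_rep * u
            grad[j] += de_rep * u
            if topology.bonded(i, j):
                d_e, a, r_e = params.lookup(mol.symbols[i], mol.symbols[j])
                ex = np.exp(-a * (r - r_e))
                m = d_e * ((1.0 - ex) ** 2 - 1.0)
                dm = 2.0 * d_e * a * (1.0 - ex) * ex
                if soften > 0.0 and m < 0.0:
                    m *= 1.0 - soften
                    dm *= 1.0 - soften
                energy += m
                grad[i] -= dm * u
                grad[j] += dm * u
    return float(energy), grad


@dataclass
class MockMOConfig:
    """Static orbital spectrum for the mock MO provider."""

    orbital_energies: Sequence[float]
    populations: Sequence[Sequence[float]]
    normalization: float = 2.0


def mock_mo_spectrum(config: MockMOConfig) -> MOSpectrum:
    """Build an MOSpectrum from an explicit configuration.

    All listed orbitals are occupied, so the HOMO ordinal is their count;
    each orbital's atom populations must sum to the declared normalization.
    """
    return MOSpectrum(
        np.asarray(config.orbital_energies, dtype=float),
        np.asarray(config.populations, dtype=float),
        normalization=config.normalization,
    )


def heuristic_vertical_ip(
    f: Formula, table: Mapping[str, float], fallback: float
) -> float:
    """Table lookup of a vertical IP by canonical formula, else the fallback."""
    canonical = {
        Formula.from_string(k).hill(): v for k, v in table.items()
    }
    return float(canonical.get(f.hill(), fallback))


class SurrogateProvider(Provider):
    """Bundled desk-scale provider: surrogate PES + mock MOs + IP table.

    The Morse bond topology is frozen from the reference geometry at
    construction, so the surrogate cannot re-bond atoms that drift close
    during a trajectory; fragmentation on this surface is therefore
    analytically predictable from the designed bond strengths. The electronic
    temperature argument is accepted and ignored (the surrogate has no
    electronic structure); it is forwarded verbatim by the external adapter.
    """

    def __init__(
        self,
        reference: Molecule,
        pes_params: SurrogatePESParams | None = None,
        mo_config: MockMOConfig | None = None,
        ip_table: Mapping[str, float] | None = None,
        ip_fallback: float = 10.0,
        bond_scale: float = DEFAULT_BOND_SCALE,
        topology: BondGraph | None = None,
    ) -> None:
        self.params = pes_params or SurrogatePESParams()
        self.topology = topology if topology is not None else detect_bonds(
            reference, bond_scale
        )
        self.mo_config = mo_config
        self.ip_table = dict(ip_table or {})
        self.ip_fallback = ip_fallback
        self.bond_scale = bond_scale
        self.n_atoms = reference.n_atoms

    def energy_gradient(
        self, mol: Molecule, electronic_temperature: float = 300.0
    ) -> tuple[float, np.ndarray]:
        return surrogate_energy_gradient(mol, self.params, self.topology)

    def mo_spectrum(self, mol: Molecule) -> MOSpectrum:
        if self.mo_config is None:
            raise ProviderError("surrogate provider has no MO configuration")
        spec = mock_mo_spectrum(self.mo_config)
        if spec.n_atoms != mol.n_atoms:
            raise ProviderError(
                f"MO configuration is for {spec.n_atoms} atoms, molecule has "
                f"{mol.n_atoms}"
            )
        return spec

    def vertical_ip(self, mol: Molecule) -> float:
        return heuristic_vertical_ip(formula_of(mol), self.ip_table, self.ip_fallback)

    def subset(self, indices: Sequence[int]) -> "SurrogateProvider":
        idx = list(indices)
        pos = {atom: k for k, atom in enumerate(idx)}
        sub = BondGraph(len(idx), detection_scale=self.topology.detection_scale)
        for edge in self.topology.edges:
            i, j = tuple(edge)
            if i in pos and j in pos:
                sub.add(pos[i], pos[j])
        clone = SurrogateProvider.__new__(SurrogateProvider)
        clone.params = self.params
        clone.topology = sub
        clone.mo_config = None  # MO spectrum only defined for the parent
        clone.ip_table = self.ip_table
        clone.ip_fallback = self.ip_fallback
        clone.bond_scale = self.bond_scale
        clone.n_atoms = len(idx)
        return clone


class ExternalEngineAdapter(Provider):
    """Subprocess contract for a real quantum-chemistry backend.

    The adapter writes the molecule as XYZ (with ``charge=`` / ``mult=``
    tokens on the comment line) plus a control line
    ``# etemp=<K> task=<energy_gradient|mo_spectrum|vertical_ip>`` appended as
    a trailing comment, invokes ``command <input file>``, and parses a keyed
    plain-text reply on stdout::

        energy <eV>
        gradient
        <gx> <gy> <gz>        (one line per atom, eV/Å)
        orbitals <n_occupied>
        <epsilon_eV>          (one line per orbital, ascending)
        populations
        <p_atom1> ... <p_atomN>   (one line per orbital)
        ip <eV>

    Only the keys relevant to the requested task need to be present. Any
    nonzero exit status or malformed reply raises :class:`ProviderError`.
    This adapter is not exercised by the default test suite; it documents the
    integration surface for tight-binding or DFT engines.
    """

    def __init__(self, command: Sequence[str], workdir: str = ".") -> None:
        self.command = list(command)
        self.workdir = workdir

    def _call(self, mol: Molecule, task: str, etemp: float) -> dict:
        import tempfile, os

        text = write_xyz(mol, comment=f"task={task}") + f"# etemp={etemp}\n"
        with tempfile.NamedTemporaryFile(
            "w", suffix=".xyz", dir=self.workdir, delete=False
        ) as fh:
            fh.write(text)
            path = fh.name
        try:
            proc = subprocess.run(
                [*self.command, path], capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise ProviderError(
                    f"external engine failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip()[:500]}"
                )
            return self._parse(proc.stdout, mol.n_atoms)
        finally:
            os.unlink(path)

    @staticmethod
    def _parse(text: str, n_atoms: int) -> dict:
        out: dict = {}
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        i = 0
        try:
            while i < len(lines):
                key = lines[i].split()[0]
                if key == "energy":
                    out["energy"] = float(lines[i].split()[1])
                    i += 1
                elif key == "gradient":
                    block = lines[i + 1 : i + 1 + n_atoms]
                    out["gradient"] = np.array(
                        [[float(x) for x in ln.split()[:3]] for ln in block]
                    )
                    i += 1 + n_atoms
                elif key == "orbitals":
                    n_occ = int(lines[i].split()[1])
                    eps = [float(lines[i + 1 + k]) for k in range(n_occ)]
                    out["orbital_energies"] = np.array(eps)
                    out["n_occupied"] = n_occ
                    i += 1 + n_occ
                elif key == "populations":
                    n_occ = out["n_occupied"]
                    block = lines[i + 1 : i + 1 + n_occ]
                    out["populations"] = np.array(
                        [[float(x) for x in ln.split()] for ln in block]
                    )
                    i += 1 + n_occ
                elif key == "ip":
                    out["ip"] = float(lines[i].split()[1])
                    i += 1
                else:
                    i += 1
        except (IndexError, ValueError) as exc:
            raise ProviderError(f"malformed engine reply: {exc}") from exc
        return out

    def energy_gradient(
        self, mol: Molecule, electronic_temperature: float = 300.0
    ) -> tuple[float, np.ndarray]:
        out = self._call(mol, "energy_gradient", electronic_temperature)
        if "energy" not in out or "gradient" not in out:
            raise ProviderError("engine reply missing energy/gradient")
        return out["energy"], out["gradient"]

    def mo_spectrum(self, mol: Molecule) -> MOSpectrum:
        out = self._call(mol, "mo_spectrum", 300.0)
        if "orbital_energies" not in out or "populations" not in out:
            raise ProviderError("engine reply missing orbital data")
        return MOSpectrum(out["orbital_energies"], out["populations"])

    def vertical_ip(self, mol: Molecule) -> float:
        out = self._call(mol, "vertical_ip", 300.0)
        if "ip" not in out:
            raise ProviderError("engine reply missing ip")
        return out["ip"]
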