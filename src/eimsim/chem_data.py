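"""Element/isotope reference data, formula arithmetic and XYZ I/O.

The element table (symbols, covalent radii, isotope masses and natural
abundances) ships with the package as a plain-text TSV and is loaded once at
import. Mass-spectral m/z labels follow the usual low-resolution convention:
the *nominal* mass is the sum of the mass numbers of each element's most
abundant isotope, and a fragment is assumed singly charged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Element",
    "Formula",
    "Molecule",
    "ELEMENTS",
    "atomic_mass",
    "covalent_radius",
    "parse_xyz",
    "write_xyz",
    "formula_of",
    "nominal_mz",
    "isotope_pattern",
    "XYZParseError",
]


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; message names the offending line."""


@dataclass(frozen=True)
class Element:
    symbol: str
    atomic_number: int
    covalent_radius: float  # Å
    isotopes: tuple[tuple[int, float, float], ...]  # (mass_number, exact_mass u, abundance)

    def __post_init__(self) -> None:
        total = sum(a for _, _, a in self.isotopes)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.symbol}: isotope abundances sum to {total}, not 1")
        if self.covalent_radius <= 0:
            raise ValueError(f"{self.symbol}: non-positive covalent radius")
        if list(self.isotopes) != sorted(self.isotopes):
            raise ValueError(f"{self.symbol}: isotopes not sorted by mass number")

    @property
    def most_abundant(self) -> tuple[int, float, float]:
        return max(self.isotopes, key=lambda iso: iso[2])

    @property
    def standard_mass(self) -> float:
        """Abundance-weighted atomic mass (u)."""
        return sum(m * a for _, m, a in self.isotopes)


def _load_elements() -> dict[str, Element]:
    rows: dict[str, list[tuple[int, float, float]]] = {}
    meta: dict[str, tuple[int, float]] = {}
    text = resources.files("eimsim.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, z, radius, mass_number, exact_mass, abundance = line.split("\t")
        rows.setdefault(sym, []).append(
            (int(mass_number), float(exact_mass), float(abundance))
        )
        meta[sym] = (int(z), float(radius))
    out = {}
    for sym, isos in rows.items():
        z, radius = meta[sym]
        out[sym] = Element(sym, z, radius, tuple(sorted(isos)))
    return out


ELEMENTS: dict[str, Element] = _load_elements()


def _element(symbol: str) -> Element:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}") from None


def atomic_mass(symbol: str) -> float:
    """Standard (abundance-weighted) atomic mass in u — the MD mass."""
    return _element(symbol).standard_mass


def covalent_radius(symbol: str) -> float:
    return _element(symbol).covalent_radius


_HILL_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition plus net charge.

    ``counts`` maps element symbols to positive integers. The canonical string
    uses Hill order (C, then H, then other elements alphabetically; plain
    alphabetical when no carbon is present).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        frozen = dict(self.counts)
        for sym, n in frozen.items():
            if n < 1 or n != int(n):
                raise ValueError(f"count for {sym} must be a positive integer, got {n}")
        object.__setattr__(self, "counts", frozen)

    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "Formula":
        """Parse e.g. ``"C6H5"`` or ``"C4H4O2Cu"`` into a Formula."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _HILL_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts, charge)

    def hill(self) -> str:
        """Canonical Hill-order formula string (ignores charge)."""
        syms = sorted(self.counts)
        ordered: list[str] = []
        if "C" in self.counts:
            ordered.append("C")
            if "H" in self.counts:
                ordered.append("H")
            ordered.extend(s for s in syms if s not in ("C", "H"))
        else:
            ordered = syms
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in ordered
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return Formula(counts, self.charge + other.charge)


@dataclass(eq=False)
class Molecule:
    """Nuclear state used by the MD engine: geometry, velocities, charge, spin."""

    symbols: list[str]
    coords: np.ndarray  # (N, 3) Å
    velocities: np.ndarray  # (N, 3) Å/fs
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(
            len(self.symbols), 3
        )
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for sym in self.symbols:
            _element(sym)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(s) for s in self.symbols])

    def copy(self) -> "Molecule":
        return Molecule(
            list(self.symbols),
            self.coords.copy(),
            self.velocities.copy(),
            self.charge,
            self.multiplicity,
        )

    def subset(self, indices: Iterable[int]) -> "Molecule":
        idx = list(indices)
        return Molecule(
            [self.symbols[i] for i in idx],
            self.coords[idx],
            self.velocities[idx],
            self.charge,
            self.multiplicity,
        )


_COMMENT_TOKEN = re.compile(r"(charge|mult)\s*=\s*([+-]?\d+)")


def parse_xyz(text: str) -> Molecule:
    """Parse a standard XYZ block into a :class:`Molecule`.

    Line 1 is the atom count, line 2 a free comment (optionally carrying
    ``charge=<int>`` and ``mult=<int>`` tokens), then one ``symbol x y z`` per
    atom. Velocities are zero-initialized.
    """
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ text (line 1)")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise XYZParseError(f"line 1: cannot read atom count from {lines[0]!r}")
    if len(lines) < n + 2:
        raise XYZParseError(
            f"declared {n} atoms but only {max(len(lines) - 2, 0)} atom lines present"
        )
    comment = lines[1] if len(lines) > 1 else ""
    charge, mult = 0, 1
    for key, val in _COMMENT_TOKEN.findall(comment):
        if key == "charge":
            charge = int(val)
        else:
            mult = int(val)
    symbols: list[str] = []
    coords: list[list[float]] = []
    for i, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {i}: expected 'symbol x y z', got {line!r}")
        sym = parts[0]
        if sym not in ELEMENTS:
            raise XYZParseError(f"line {i}: unknown element symbol {sym!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"line {i}: non-numeric coordinate in {line!r}")
        symbols.append(sym)
        coords.append(xyz)
    # trailing non-blank atom-like lines beyond the declared count are an error
    extra = [ln for ln in lines[2 + n :] if ln.strip()]
    if extra:
        raise XYZParseError(
            f"declared {n} atoms but found {n + len(extra)} atom lines"
        )
    return Molecule(symbols, np.array(coords), np.zeros((n, 3)), charge, mult)


def write_xyz(mol: Molecule, comment: str = "") -> str:
    """Serialize a Molecule to the standard XYZ dialect (velocities dropped)."""
    tokens = f"charge={mol.charge} mult={mol.multiplicity}"
    head = f"{comment} {tokens}".strip() if comment else tokens
    lines = [str(mol.n_atoms), head]
    for sym, (x, y, z) in zip(mol.symbols, mol.coords):
        lines.append(f"{sym:<2s} {x:20.12f} {y:20.12f} {z:20.12f}")
    return "\n".join(lines) + "\n"


def formula_of(mol: Molecule) -> Formula:
    counts: dict[str, int] = {}
    for sym in mol.symbols:
        counts[sym] = counts.get(sym, 0) + 1
    return Formula(counts, mol.charge)


def nominal_mz(f: Formula) -> int:
    """Nominal m/z: sum of most-abundant-isotope mass numbers, singly charged."""
    return sum(n * _element(sym).most_abundant[0] for sym, n in f.counts.items())


def isotope_pattern(
    f: Formula, prune_threshold: float = 0.0
) -> list[tuple[int, float]]:
    """Unit-mass isotopologue distribution of a formula.

    Iterative convolution atom by atom on the integer mass-number grid, pruning
    isotopologues whose abundance falls below ``prune_threshold`` relative to
    the most abundant one. With ``prune_threshold=0`` the returned abundances
    sum to 1 (exact convolution). Sorted by m/z.
    """
    if not 0 <= prune_threshold < 1:
        raise ValueError("prune_threshold must be in [0, 1)")
    dist: dict[int, float] = {0: 1.0}
    for sym, count in f.counts.items():
        isos = _element(sym).isotopes
        for _ in range(count):
            new: dict[int, float] = {}
            for mz, p in dist.items():
                for mass_number, _, abundance in isos:
                    if abundance == 0.0:
                        continue
                    key = mz + mass_number
                    new[key] = new.get(key, 0.0) + p * abundance
            if prune_threshold > 0 and new:
                cutoff = prune_threshold * max(new.values())
                new = {mz: p for mz, p in new.items() if p >= cutoff}
            dist = new
    return sorted(dist.items())
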