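"""Spectrum assembly: accumulate fragment charges, convolve natural isotope
patterns onto the unit-mass grid, normalize to the base peak, and exchange
spectra as MSP or JCAMP-DX text.

The statistical charges of a given fragment formula, summed over the ensemble
of production runs, are its raw intensity. Natural isotope abundances are
applied in this post-simulation step (the dynamics always uses standard
atomic masses), and intensities are reported as percent of the base peak —
the universal low-resolution EI-MS convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .chem_data import Formula, isotope_pattern
from .fragments import FragmentRecord

__all__ = [
    "Spectrum",
    "accumulate",
    "convolve_and_bin",
    "write_msp",
    "read_msp",
    "write_jcamp",
    "read_jcamp",
    "cosine_similarity",
    "plot_head_to_tail",
]


@dataclass(eq=False)
class Spectrum:
    """Stick spectrum: (m/z, relative intensity in % of base peak).

    ``provenance`` maps each m/z to the contributing fragment formulas with
    their summed raw statistical charge, so every stick can be traced back to
    the dynamics that produced it.
    """

    sticks: list[tuple[int, float]] = field(default_factory=list)
    provenance: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.sticks]
        if mzs != sorted(set(mzs)):
            raise ValueError("sticks must be strictly increasing in m/z")
        if self.sticks:
            heights = [h for _, h in self.sticks]
            if not all(0.0 < h <= 100.0 + 1e-9 for h in heights):
                raise ValueError("intensities must lie in (0, 100]")
            if abs(max(heights) - 100.0) > 1e-9:
                raise ValueError("base peak must be normalized to 100")

    @property
    def base_peak(self) -> int:
        return max(self.sticks, key=lambda s: s[1])[0]

    def intensity_at(self, mz: int) -> float:
        for m, h in self.sticks:
            if m == mz:
                return h
        return 0.0


def accumulate(records: Iterable[FragmentRecord]) -> dict[str, float]:
    """Sum statistical charges grouped by canonical (Hill) formula."""
    totals: dict[str, float] = {}
    for rec in records:
        key = rec.formula.hill()
        totals[key] = totals.get(key, 0.0) + rec.statistical_charge
    return totals


def convolve_and_bin(
    accum: Mapping[str, float], prune: float = 0.0
) -> Spectrum:
    """Distribute accumulated charges over isotope patterns and normalize.

    Each formula's charge is spread across its unit-mass isotopologue
    distribution (pruned at ``prune`` relative abundance), summed on the
    integer m/z grid, then scaled so the most intense stick is exactly 100.
    """
    raw: dict[int, float] = {}
    provenance: dict[int, dict[str, float]] = {}
    for key, charge in accum.items():
        if charge <= 0:
            continue
        f = Formula.from_string(key)
        for mz, abundance in isotope_pattern(f, prune):
            raw[mz] = raw.get(mz, 0.0) + charge * abundance
            prov = provenance.setdefault(mz, {})
            prov[key] = prov.get(key, 0.0) + charge * abundance
    if not raw:
        return Spectrum([], {})
    base = max(raw.values())
    sticks = [(mz, 100.0 * raw[mz] / base) for mz in sorted(raw)]
    return Spectrum(sticks, provenance)


DEFAULT_WRITER_PRUNE = 0.1  # % of base peak below which writers drop sticks


def _pruned(spec: Spectrum, prune_percent: float) -> list[tuple[int, float]]:
    return [(mz, h) for mz, h in spec.sticks if h >= prune_percent]


def write_msp(
    spec: Spectrum,
    metadata: Mapping[str, str] | None = None,
    prune_percent: float = DEFAULT_WRITER_PRUNE,
) -> str:
    """Serialize to the NIST MSP dialect (Name / ... / Num Peaks / pairs)."""
    if not spec.sticks:
        raise ValueError("cannot write an empty spectrum")
    metadata = dict(metadata or {})
    name = metadata.pop("Name", metadata.pop("name", "eimsim spectrum"))
    lines = [f"Name: {name}"]
    for key, val in metadata.items():
        lines.append(f"{key}: {val}")
    sticks = _pruned(spec, prune_percent)
    lines.append(f"Num Peaks: {len(sticks)}")
    for mz, h in sticks:
        lines.append(f"{mz} {h:.6g}")
    return "\n".join(lines) + "\n"


def read_msp(text: str) -> tuple[Spectrum, dict[str, str]]:
    """Parse one MSP record back into a Spectrum plus its metadata."""
    metadata: dict[str, str] = {}
    sticks: list[tuple[int, float]] = []
    n_peaks = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = re.match(r"^([A-Za-z][A-Za-z _]*):\s*(.*)$", line)
        if m:
            key, val = m.group(1), m.group(2)
            if key.lower() == "num peaks":
                n_peaks = int(val)
            else:
                metadata[key] = val
            continue
        parts = line.replace(";", " ").split()
        for mz_s, h_s in zip(parts[0::2], parts[1::2]):
            sticks.append((int(float(mz_s)), float(h_s)))
    if n_peaks is not None and n_peaks != len(sticks):
        raise ValueError(f"Num Peaks says {n_peaks}, found {len(sticks)}")
    return Spectrum(sorted(sticks)), metadata


def write_jcamp(
    spec: Spectrum,
    metadata: Mapping[str, str] | None = None,
    prune_percent: float = DEFAULT_WRITER_PRUNE,
) -> str:
    """Serialize to JCAMP-DX 4.24 with an (XY..XY) peak list."""
    if not spec.sticks:
        raise ValueError("cannot write an empty spectrum")
    metadata = dict(metadata or {})
    title = metadata.pop("TITLE", metadata.pop("Name", "eimsim spectrum"))
    sticks = _pruned(spec, prune_percent)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=MASS SPECTRUM",
        "##XUNITS=M/Z",
        "##YUNITS=RELATIVE INTENSITY",
    ]
    for key, val in metadata.items():
        lines.append(f"##{key.upper()}={val}")
    lines.append(f"##NPOINTS={len(sticks)}")
    lines.append("##XYDATA=(XY..XY)")
    lines.extend(f"{mz},{h:.6g}" for mz, h in sticks)
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def read_jcamp(text: str) -> tuple[Spectrum, dict[str, str]]:
    """Parse a JCAMP-DX mass spectrum written by :func:`write_jcamp`."""
    metadata: dict[str, str] = {}
    sticks: list[tuple[int, float]] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            if key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            else:
                metadata[key] = val
            continue
        if in_data:
            for pair in line.split(";"):
                if not pair.strip():
                    continue
                x, _, y = pair.partition(",")
                sticks.append((int(float(x)), float(y)))
    return Spectrum(sorted(sticks)), metadata


def cosine_similarity(
    a: Spectrum, b: Spectrum, mz_weight_power: float = 0.0
) -> float:
    """Weighted dot-product similarity on the union m/z grid, in [0, 1].

    Intensities are weighted by ``mz ** mz_weight_power`` (0 = plain cosine;
    1–3 emphasize the chemically informative high-mass sticks as spectral
    library searches do).
    """
    if not a.sticks and not b.sticks:
        raise ValueError("both spectra are empty")
    if not a.sticks or not b.sticks:
        return 0.0
    grid = sorted({mz for mz, _ in a.sticks} | {mz for mz, _ in b.sticks})
    va = np.array([a.intensity_at(mz) * mz**mz_weight_power for mz in grid])
    vb = np.array([b.intensity_at(mz) * mz**mz_weight_power for mz in grid])
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(np.dot(va, vb) / denom)


def plot_head_to_tail(
    computed: Spectrum,
    reference: Spectrum,
    labels: tuple[str, str] = ("computed", "reference"),
    ax=None,
):
    """Head-to-tail stick plot: computed up, reference mirrored down."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for mz, h in computed.sticks:
        ax.vlines(mz, 0, h, color="tab:blue")
    for mz, h in reference.sticks:
        ax.vlines(mz, 0, -h, color="tab:red")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("relative intensity / %")
    ax.set_ylim(-110, 110)
    ax.annotate(labels[0], xy=(0.02, 0.92), xycoords="axes fraction", color="tab:blue")
    ax.annotate(labels[1], xy=(0.02, 0.05), xycoords="axes fraction", color="tab:red")
    return ax
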