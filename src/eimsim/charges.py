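"""Statistical charge assignment and cascade bookkeeping.

After a fragmentation event the single positive charge is shared among the M
products by a Boltzmann factor over their vertical ionization potentials at
the average fragment temperature:

    C_i = exp(-IP_i / (k_B T_Av)) / sum_j exp(-IP_j / (k_B T_Av))

The fragment with the highest statistical charge continues in a cascade; its
daughters' weights are multiplied by its own weight, so the stored charges of
all fragments of one production run — across every cascade level — sum to the
total molecular charge of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import K_B
from .fragments import FragmentRecord

__all__ = [
    "ChargeAssignment",
    "statistical_weights",
    "charge_assignment",
    "assign_and_select",
    "DEFAULT_DEPTH_CAP",
]

#: safety cap on cascade recursion depth
DEFAULT_DEPTH_CAP = 6


@dataclass
class ChargeAssignment:
    """Normalized weight vector for one fragmentation event."""

    weights: np.ndarray
    t_av: float  # K
    ips: np.ndarray  # eV
    selected_index: int

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def statistical_weights(ips, t_av: float) -> np.ndarray:
    """Boltzmann charge weights over vertical IPs at temperature ``t_av``.

    Computed shift-stably (minimum IP subtracted before exponentiation).
    ``t_av <= 0`` is treated as the zero-temperature limit — all weight on the
    minimum-IP fragment, ties split equally — with a warning.
    """
    ips = np.asarray(ips, dtype=float)
    if ips.size == 0:
        raise ValueError("no fragments to weight")
    if t_av <= 0:
        warnings.warn(
            "non-positive average fragment temperature; using the "
            "zero-temperature charge limit",
            stacklevel=2,
        )
        winners = ips == ips.min()
        return winners / winners.sum()
    x = -(ips - ips.min()) / (K_B * t_av)
    w = np.exp(x)
    return w / w.sum()


def charge_assignment(ips, t_av: float) -> ChargeAssignment:
    ips = np.asarray(ips, dtype=float)
    w = statistical_weights(ips, t_av)
    # argmax with ties broken by lowest fragment index (np.argmax already does)
    return ChargeAssignment(w, t_av, ips, int(np.argmax(w)))


def assign_and_select(
    fragments: list[FragmentRecord],
    parent_weight: float,
    depth_cap: int = DEFAULT_DEPTH_CAP,
) -> tuple[list[FragmentRecord], FragmentRecord | None]:
    """Assign statistical charges for one event and pick the cascade survivor.

    Each record's ``statistical_charge`` becomes ``parent_weight * C_i``. The
    argmax-weight fragment is returned as ``next`` for further propagation —
    unless it is a single atom or has reached the cascade depth cap, in which
    case it terminates the cascade and is stored with the others. The stored
    list is all non-selected fragments plus, at termination, the survivor.
    """
    if not 0.0 < parent_weight <= 1.0:
        raise ValueError("parent_weight must be in (0, 1]")
    if not fragments:
        raise ValueError("no fragments")
    t_av = float(np.mean([f.temperature for f in fragments]))
    assign = charge_assignment([f.vertical_ip for f in fragments], t_av)
    for rec, c in zip(fragments, assign.weights):
        rec.statistical_charge = parent_weight * float(c)
    sel = assign.selected_index
    chosen = fragments[sel]
    stored = [rec for i, rec in enumerate(fragments) if i != sel]
    terminal = chosen.mol.n_atoms == 1 or chosen.cascade_depth >= depth_cap
    if terminal:
        stored.append(chosen)
        return stored, None
    return stored, chosen
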