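"""Classical nuclear propagation: leap-frog MD, thermostatted equilibration,
snapshot sampling, and ionized production runs with heating and cascades.

The integrator is the kick–drift–kick form of the leap-frog algorithm (it
generates the identical position trajectory, with velocities synchronized to
the positions so kinetic and total energies are well-defined per step). The
default time step is 0.5 fs. The canonical-ensemble equilibration uses a
Berendsen velocity-rescaling thermostat (the protocol names the ensemble, not
the thermostat). Production runs heat the freshly ionized molecule over the
internal-conversion window, watch for persistent fragmentation, partition the
charge among products and continue the dominant ion in a cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_data import Molecule, formula_of
from .constants import ACC_CONV, K_B
from .fragments import (
    DEFAULT_BOND_SCALE,
    FragmentRecord,
    detect_bonds,
    fragment_temperature,
    kinetic_energy,
    split_indices,
)
from .ionization import (
    HeatingPlan,
    apply_heating_increment,
    build_heating_plan,
    ic_time,
    velocity_scale_factors,
)
from .charges import DEFAULT_DEPTH_CAP, assign_and_select
from .providers import Provider, ProviderError

__all__ = [
    "MDState",
    "ProductionResult",
    "leapfrog_step",
    "maxwell_boltzmann_velocities",
    "instantaneous_temperature",
    "equilibrate_nvt",
    "sample_snapshots",
    "run_production",
    "write_trajectory_frame",
]

DEFAULT_DT = 0.5  # fs
DEFAULT_CHECK_INTERVAL = 20  # steps between fragmentation checks (10 fs)
DEFAULT_PERSISTENCE = 3  # consecutive checks before a split is accepted
DEFAULT_THERMOSTAT_TAU = 100.0  # fs, Berendsen coupling constant


@dataclass(eq=False)
class MDState:
    mol: Molecule
    time: float = 0.0  # fs
    kinetic_energy: float = 0.0  # eV
    potential_energy: float = 0.0  # eV

    @property
    def total_energy(self) -> float:
        return self.kinetic_energy + self.potential_energy


@dataclass(eq=False)
class ProductionResult:
    fragment_records: list[FragmentRecord] = field(default_factory=list)
    n_steps: int = 0
    terminated_by: str = "no_fragmentation_timeout"
    error: str | None = None

    @property
    def success(self) -> bool:
        return self.terminated_by != "provider_failure"


def _accelerations(grad: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return -grad * ACC_CONV / masses[:, None]


def _kdk_step(
    state: MDState,
    provider: Provider,
    dt: float,
    electronic_temperature: float,
    grad: np.ndarray | None,
) -> tuple[MDState, np.ndarray]:
    """One kick–drift–kick leap-frog step; returns the new state and gradient."""
    mol = state.mol.copy()
    masses = mol.masses
    if grad is None:
        _, grad = provider.energy_gradient(mol, electronic_temperature)
    v_half = mol.velocities + 0.5 * dt * _accelerations(grad, masses)
    mol.coords = mol.coords + dt * v_half
    e_pot, grad_new = provider.energy_gradient(mol, electronic_temperature)
    mol.velocities = v_half + 0.5 * dt * _accelerations(grad_new, masses)
    return (
        MDState(mol, state.time + dt, kinetic_energy(mol), e_pot),
        grad_new,
    )


def leapfrog_step(
    state: MDState,
    provider: Provider,
    dt: float,
    electronic_temperature: float = 300.0,
) -> MDState:
    """Advance one leap-frog step with energies recomputed at the new state."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    try:
        new, _ = _kdk_step(state, provider, dt, electronic_temperature, None)
    except ProviderError as exc:
        raise ProviderError(f"provider failed at t = {state.time} fs: {exc}") from exc
    return new


def maxwell_boltzmann_velocities(
    mol: Molecule, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Thermal velocities (Å/fs) with the center-of-mass drift removed."""
    masses = mol.masses
    sigma = np.sqrt(K_B * temperature / (masses / ACC_CONV))
    v = rng.normal(size=(mol.n_atoms, 3)) * sigma[:, None]
    if mol.n_atoms > 1:
        v -= np.average(v, axis=0, weights=masses)
    return v


def instantaneous_temperature(mol: Molecule) -> float:
    """Kinetic temperature over translational-free degrees of freedom."""
    n_dof = 3 * mol.n_atoms - 3 if mol.n_atoms > 1 else 3
    return 2.0 * kinetic_energy(mol) / (n_dof * K_B)


def equilibrate_nvt(
    mol: Molecule,
    provider: Provider,
    temperature: float,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int | np.random.Generator = 0,
    tau: float = DEFAULT_THERMOSTAT_TAU,
    electronic_temperature: float = 300.0,
    temperature_history: list | None = None,
) -> MDState:
    """Canonical-ensemble equilibration with a Berendsen thermostat.

    Velocities are drawn Maxwell–Boltzmann from the seed; each step rescales
    them toward the set point with coupling constant ``tau``. Returns the final
    state (``duration = 0`` returns the freshly initialized state). Pass a list
    as ``temperature_history`` to record the instantaneous temperature after
    every step.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    work = mol.copy()
    work.velocities = maxwell_boltzmann_velocities(work, temperature, rng)
    e_pot, grad = provider.energy_gradient(work, electronic_temperature)
    state = MDState(work, 0.0, kinetic_energy(work), e_pot)
    n_steps = int(round(duration / dt))
    for step in range(n_steps):
        try:
            state, grad = _kdk_step(state, provider, dt, electronic_temperature, grad)
        except ProviderError as exc:
            raise ProviderError(f"equilibration failed at step {step}: {exc}") from exc
        t_inst = instantaneous_temperature(state.mol)
        if t_inst > 0:
            lam = np.sqrt(
                np.clip(1.0 + dt / tau * (temperature / t_inst - 1.0), 0.81, 1.21)
            )
            state.mol.velocities *= lam
            state.kinetic_energy = kinetic_energy(state.mol)
        if temperature_history is not None:
            temperature_history.append(instantaneous_temperature(state.mol))
    return state


def sample_snapshots(
    traj_spec: dict,
    state0: MDState,
    provider: Provider,
    dt: float = DEFAULT_DT,
    seed: int | np.random.Generator = 0,
    electronic_temperature: float = 300.0,
) -> list[MDState]:
    """Randomly sample ``n`` states (geometry and velocities) along an NVE run.

    ``traj_spec`` is ``{"duration": fs, "n": count}``; the sampled step
    indices are drawn uniformly without replacement and returned in time
    order.
    """
    duration, n = float(traj_spec["duration"]), int(traj_spec["n"])
    if n < 1:
        raise ValueError("need n >= 1 snapshots")
    n_steps = int(round(duration / dt))
    if n > n_steps:
        raise ValueError(f"cannot draw {n} snapshots from {n_steps} steps")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = np.sort(rng.choice(n_steps, size=n, replace=False))
    picked: list[MDState] = []
    state, grad = state0, None
    next_pick = 0
    for step in range(n_steps):
        try:
            state, grad = _kdk_step(state, provider, dt, electronic_temperature, grad)
        except ProviderError as exc:
            raise ProviderError(f"sampling failed at step {step}: {exc}") from exc
        if next_pick < n and step == picks[next_pick]:
            picked.append(MDState(state.mol.copy(), state.time,
                                  state.kinetic_energy, state.potential_energy))
            next_pick += 1
    return picked


def run_production(
    snapshot: MDState,
    provider: Provider,
    iee: float,
    ionized_mo: int,
    max_time: float = 10_000.0,
    dt: float = DEFAULT_DT,
    seed: int | np.random.Generator = 0,
    *,
    check_interval: int = DEFAULT_CHECK_INTERVAL,
    persistence: int = DEFAULT_PERSISTENCE,
    depth_cap: int = DEFAULT_DEPTH_CAP,
    bond_scale: float = DEFAULT_BOND_SCALE,
    electronic_temperature: float = 5000.0,
    alpha: float = 0.5,
    k_h: float = 2.0,
) -> ProductionResult:
    """One ionized production run: heat, propagate, fragment, cascade.

    The snapshot molecule is promoted to the +1 radical cation and heated by
    per-step velocity scaling over the internal-conversion window of the
    ionized orbital. Fragmentation is checked every ``check_interval`` steps
    and accepted once the same split persists for ``persistence`` consecutive
    checks; charges are then partitioned and the dominant ion re-enters
    propagation with a fresh time budget. Any provider failure terminates the
    run as unsuccessful.
    """
    if iee < 0:
        raise ValueError("iee must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ion = snapshot.mol.copy()
    ion.charge = 1
    ion.multiplicity = 2  # odd-electron radical cation (bookkeeping only)
    records: list[FragmentRecord] = []
    total_steps = 0
    try:
        plan: HeatingPlan
        if iee > 0:
            spec = provider.mo_spectrum(ion)
            t_ic = ic_time(spec, ionized_mo, alpha=alpha, k_h=k_h, dt=dt)
            factors = velocity_scale_factors(spec, ionized_mo, ion.n_atoms)
            plan = build_heating_plan(iee, t_ic, dt, factors)
        else:
            plan = build_heating_plan(0.0, max(dt, 1.0), dt, np.ones(ion.n_atoms))
    except (ProviderError, ValueError) as exc:
        return ProductionResult([], 0, "provider_failure", str(exc))

    current = ion
    cur_provider = provider
    cur_factors = plan.per_atom_scale_factors
    weight = 1.0
    depth = 0
    heat_idx = 0
    n_steps_budget = int(round(max_time / dt))

    try:
        while True:
            e_pot, grad = cur_provider.energy_gradient(current, electronic_temperature)
            state = MDState(current, 0.0, kinetic_energy(current), e_pot)
            persist = 0
            last_partition: tuple | None = None
            accepted: list[list[int]] | None = None
            for step in range(n_steps_budget):
                state, grad = _kdk_step(
                    state, cur_provider, dt, electronic_temperature, grad
                )
                total_steps += 1
                if heat_idx < plan.n_steps:
                    # internal conversion may outlast the first fragmentation;
                    # the remaining increments keep heating the surviving ion
                    apply_heating_increment(
                        state.mol, cur_factors,
                        float(plan.increments[heat_idx]), rng,
                    )
                    heat_idx += 1
                    state.kinetic_energy = kinetic_energy(state.mol)
                if (step + 1) % check_interval == 0:
                    comps = split_indices(
                        state.mol, detect_bonds(state.mol, bond_scale)
                    )
                    if len(comps) > 1:
                        partition = tuple(tuple(c) for c in comps)
                        persist = persist + 1 if partition == last_partition else 1
                        last_partition = partition
                        if persist >= persistence:
                            accepted = comps
                            break
                    else:
                        persist = 0
                        last_partition = None
            if accepted is None:
                # intact within the time budget: the current ion survives
                survivor = state.mol
                records.append(
                    FragmentRecord(
                        survivor,
                        formula_of(survivor),
                        cur_provider.vertical_ip(survivor),
                        fragment_temperature(survivor),
                        weight,
                        depth,
                    )
                )
                terminated = (
                    "no_fragmentation_timeout" if depth == 0 else "cascade_complete"
                )
                return ProductionResult(records, total_steps, terminated)

            frag_mols = [state.mol.subset(c) for c in accepted]
            for fm in frag_mols:
                fm.charge = 0
            event = [
                FragmentRecord(
                    fm,
                    formula_of(fm),
                    cur_provider.vertical_ip(fm),
                    fragment_temperature(fm),
                    0.0,
                    depth + 1,
                )
                for fm in frag_mols
            ]
            stored, chosen = assign_and_select(event, weight, depth_cap)
            records.extend(stored)
            if chosen is None:
                return ProductionResult(records, total_steps, "cascade_complete")
            sel_pos = event.index(chosen)
            weight = chosen.statistical_charge
            depth += 1
            current = chosen.mol
            current.charge = 1
            chosen.formula = formula_of(current)
            cur_provider = cur_provider.subset(accepted[sel_pos])
            cur_factors = cur_factors[accepted[sel_pos]]
    except (ProviderError, ValueError, FloatingPointError) as exc:
        return ProductionResult(records, total_steps, "provider_failure", str(exc))


def write_trajectory_frame(state: MDState, comment_extra: str = "") -> str:
    """One multi-frame-XYZ frame with time/energy bookkeeping in the comment."""
    from .chem_data import write_xyz

    comment = (
        f"t={state.time:.2f}fs Epot={state.potential_energy:.6f}eV "
        f"Ekin={state.kinetic_energy:.6f}eV {comment_extra}".rstrip()
    )
    return write_xyz(state.mol, comment)
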