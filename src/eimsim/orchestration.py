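"""Wire the three protocol stages into one reproducible, parallel run.

Stage (i): thermostatted equilibration of the neutral molecule and random
snapshot sampling along an NVE trajectory. Stage (ii): one orbital-spectrum
evaluation. Stage (iii): many independent ionized production runs, each with
its own internal excess energy, ionized orbital and deterministic seed
derived from the master seed, reduced into one spectrum. Failed runs are
counted, never silently dropped; run results are reduced in run-index order
so the spectrum is bit-identical regardless of the worker count.
"""

from __future__ import annotations

import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_data import Molecule, parse_xyz
from .fragments import DEFAULT_BOND_SCALE
from .ionization import IEEModel, sample_iee, select_ionized_mo
from .md import (
    DEFAULT_CHECK_INTERVAL,
    DEFAULT_DT,
    DEFAULT_PERSISTENCE,
    DEFAULT_THERMOSTAT_TAU,
    ProductionResult,
    equilibrate_nvt,
    run_production,
    sample_snapshots,
)
from .charges import DEFAULT_DEPTH_CAP
from .providers import Provider
from .spectrum import Spectrum, accumulate, convolve_and_bin

__all__ = ["RunConfig", "RunReport", "run_protocol", "load_config"]


@dataclass
class RunConfig:
    """Full protocol configuration; defaults are the standard EI conditions."""

    input_path: str | None = None
    fixture: str | None = None  # built-in fixture name instead of an XYZ file
    # ionization
    e_impact: float = 70.0  # eV
    iee_a: float = 0.2  # eV
    iee_b: float = 1.0
    iee_mode_per_atom: float = 0.6  # eV/atom
    fixed_iee: float | None = None  # override sampling (diagnostics)
    fixed_ionized_mo: int | None = None  # override MO selection (diagnostics)
    alpha: float = 0.5  # 1/eV, gap-law slope
    k_h: float = 2.0  # ps, gap-law prefactor
    # md
    dt: float = DEFAULT_DT  # fs
    equilibration_temperature: float = 500.0  # K
    equilibration_duration: float = 12_500.0  # fs
    sampling_duration: float = 25_000.0  # fs
    n_snapshots: int = 1000
    production_max_time: float = 10_000.0  # fs
    thermostat_tau: float = DEFAULT_THERMOSTAT_TAU
    check_interval: int = DEFAULT_CHECK_INTERVAL
    persistence: int = DEFAULT_PERSISTENCE
    depth_cap: int = DEFAULT_DEPTH_CAP
    bond_scale: float = DEFAULT_BOND_SCALE
    # electronic temperatures (forwarded to the provider)
    etemp_ground: float = 300.0  # K
    etemp_production: float = 5000.0  # K
    # run control
    n_runs: int = 1000
    master_seed: int = 42
    workers: int = 1
    # spectrum
    isotope_prune: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for name in ("dt", "equilibration_duration", "sampling_duration",
                     "production_max_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunReport:
    n_runs: int
    n_success: int
    n_failed: int
    per_run_seeds: list[int] = field(default_factory=list)
    failures: list[tuple[int, str]] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_runs

    def summary(self) -> str:
        lines = [
            f"production runs : {self.n_runs}",
            f"successful      : {self.n_success}",
            f"failed          : {self.n_failed} "
            f"({100.0 * self.failure_fraction:.1f}%)",
        ]
        for run_idx, msg in self.failures[:10]:
            lines.append(f"  run {run_idx}: {msg}")
        return "\n".join(lines)


def _run_seed(master_seed: int, run_index: int) -> int:
    """Deterministic per-run seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, run_index])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _one_production(args) -> tuple[int, ProductionResult]:
    (run_index, snapshot, provider, model, spec_pack, cfg) = args
    rng = np.random.default_rng(_run_seed(cfg.master_seed, run_index))
    n_atoms = snapshot.mol.n_atoms
    if cfg.fixed_iee is not None:
        iee = cfg.fixed_iee
    else:
        iee = sample_iee(model, n_atoms, rng)
    if cfg.fixed_ionized_mo is not None:
        ionized_mo = cfg.fixed_ionized_mo
    else:
        ionized_mo = select_ionized_mo(spec_pack, iee, rng)
    result = run_production(
        snapshot,
        provider,
        iee,
        ionized_mo,
        max_time=cfg.production_max_time,
        dt=cfg.dt,
        seed=rng,
        check_interval=cfg.check_interval,
        persistence=cfg.persistence,
        depth_cap=cfg.depth_cap,
        bond_scale=cfg.bond_scale,
        electronic_temperature=cfg.etemp_production,
        alpha=cfg.alpha,
        k_h=cfg.k_h,
    )
    return run_index, result


def run_protocol(
    cfg: RunConfig,
    molecule: Molecule | None = None,
    provider: Provider | None = None,
    log=None,
) -> tuple[Spectrum, RunReport]:
    """Execute stages i–iii and assemble the spectrum.

    ``molecule``/``provider`` may be passed directly; otherwise they are built
    from ``cfg.fixture`` or ``cfg.input_path``. Aborts if more than half the
    production runs fail (the sampling would be biased).
    """
    if molecule is None or provider is None:
        if cfg.fixture is not None:
            from .fixtures import get_fixture

            fix = get_fixture(cfg.fixture)
            molecule = molecule or fix.molecule()
            provider = provider or fix.provider()
        elif cfg.input_path is not None:
            if provider is None:
                raise ValueError(
                    "an XYZ input needs an explicit provider (external backend)"
                )
            molecule = parse_xyz(Path(cfg.input_path).read_text())
        else:
            raise ValueError("no molecule: set fixture or input_path")

    def _log(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    ss = np.random.SeedSequence(cfg.master_seed)
    equil_seed, sample_seed = (int(s) for s in ss.generate_state(2, np.uint32) % 2**31)

    _log(f"stage i: NVT {cfg.equilibration_duration} fs at "
         f"{cfg.equilibration_temperature} K, then NVE sampling")
    state = equilibrate_nvt(
        molecule,
        provider,
        cfg.equilibration_temperature,
        cfg.equilibration_duration,
        cfg.dt,
        seed=equil_seed,
        tau=cfg.thermostat_tau,
        electronic_temperature=cfg.etemp_ground,
    )
    n_snap = min(cfg.n_snapshots, cfg.n_runs)
    snapshots = sample_snapshots(
        {"duration": cfg.sampling_duration, "n": n_snap},
        state,
        provider,
        cfg.dt,
        seed=sample_seed,
        electronic_temperature=cfg.etemp_ground,
    )

    _log("stage ii: orbital spectrum")
    mo_spec = provider.mo_spectrum(molecule)
    model = IEEModel(
        a=cfg.iee_a,
        b=cfg.iee_b,
        mode_per_atom=cfg.iee_mode_per_atom,
        e_impact=cfg.e_impact,
        epsilon_homo=mo_spec.epsilon_homo,
    )

    _log(f"stage iii: {cfg.n_runs} production runs "
         f"({cfg.workers} worker{'s' if cfg.workers != 1 else ''})")
    tasks = [
        (i, snapshots[i % len(snapshots)], provider, model, mo_spec, cfg)
        for i in range(cfg.n_runs)
    ]
    results: dict[int, ProductionResult] = {}
    if cfg.workers > 1:
        with ProcessPoolExecutor(max_workers=cfg.workers) as pool:
            for run_index, result in pool.map(_one_production, tasks, chunksize=8):
                results[run_index] = result
    else:
        for task in tasks:
            run_index, result = _one_production(task)
            results[run_index] = result

    report = RunReport(
        n_runs=cfg.n_runs,
        n_success=0,
        n_failed=0,
        per_run_seeds=[_run_seed(cfg.master_seed, i) for i in range(cfg.n_runs)],
    )
    records = []
    for i in range(cfg.n_runs):  # fixed reduction order => worker-count invariant
        res = results[i]
        if res.success:
            report.n_success += 1
            records.extend(res.fragment_records)
        else:
            report.n_failed += 1
            report.failures.append((i, res.error or "provider failure"))
    if report.failure_fraction > 0.5:
        raise RuntimeError(
            f"{report.n_failed}/{report.n_runs} production runs failed; "
            "aborting (sampling would be biased). First errors:\n"
            + "\n".join(f"  run {i}: {msg}" for i, msg in report.failures[:5])
        )
    spec = convolve_and_bin(accumulate(records), cfg.isotope_prune)
    _log(report.summary())
    return spec, report


_TOML_SECTIONS = {
    "run": {
        "input": "input_path",
        "fixture": "fixture",
        "n_runs": "n_runs",
        "master_seed": "master_seed",
        "workers": "workers",
    },
    "ionization": {
        "e_impact": "e_impact",
        "a": "iee_a",
        "b": "iee_b",
        "mode_per_atom": "iee_mode_per_atom",
        "fixed_iee": "fixed_iee",
        "fixed_ionized_mo": "fixed_ionized_mo",
        "alpha": "alpha",
        "k_h": "k_h",
    },
    "md": {
        "dt": "dt",
        "equilibration_temperature": "equilibration_temperature",
        "equilibration_duration": "equilibration_duration",
        "sampling_duration": "sampling_duration",
        "n_snapshots": "n_snapshots",
        "production_max_time": "production_max_time",
        "thermostat_tau": "thermostat_tau",
        "check_interval": "check_interval",
        "persistence": "persistence",
        "depth_cap": "depth_cap",
        "bond_scale": "bond_scale",
    },
    "provider": {
        "etemp_ground": "etemp_ground",
        "etemp_production": "etemp_production",
    },
    "spectrum": {"isotope_prune": "isotope_prune"},
}


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML run configuration (sections [run], [ionization], [md],
    [provider], [spectrum]; unknown keys are rejected)."""
    if sys.version_info >= (3, 11):
        import tomllib
    else:  # pragma: no cover
        import tomli as tomllib
    raw = tomllib.loads(Path(path).read_text())
    kwargs = {}
    for section, mapping in _TOML_SECTIONS.items():
        for key, val in raw.get(section, {}).items():
            if key not in mapping:
                raise ValueError(f"unknown key [{section}] {key}")
            kwargs[mapping[key]] = val
    unknown = set(raw) - set(_TOML_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(**kwargs)
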