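# eimsim

Stochastic molecular-dynamics simulation of 70 eV electron-ionization (EI)
mass spectra, for mass spectrometrists and computational chemists who want
fragment spectra predicted from first-principles-style dynamics rather than
from fragmentation rule libraries.

## The model

An EI spectrum is simulated in three stages:

1. **Equilibration and sampling.** The neutral molecule is equilibrated for
   12.5 ps at 500 K (NVT, Berendsen velocity rescaling), then 1000 snapshots
   (geometry *and* nuclear velocities) are drawn at random along a 25 ps NVE
   trajectory. Nuclei are propagated with the leap-frog integrator at
   Δt = 0.5 fs throughout.
2. **Ionization energetics.** One orbital-spectrum evaluation supplies
   occupied-orbital energies ε_i and per-orbital Mulliken populations. Each
   production run draws an internal excess energy (IEE) E from a
   Poisson-like density with mode 0.6 eV per atom and support
   (0, E_impact − ε_HOMO], E_impact = 70 eV; picks an ionized occupied
   orbital j among those with ε_HOMO − ε_j ≤ E; and converts the IEE into
   nuclear kinetic energy over the internal-conversion window of the
   energy-gap law

       t_IC = k_h · exp(−α (ε_HOMO − ε_j)),   α = 0.5 eV⁻¹, k_h = 2 ps,

   scaling each nucleus in proportion to its Mulliken population in orbital
   j (below 35 atoms; unity above).
3. **Production runs and charge partitioning.** The hot +1 ion is propagated
   for up to 10 ps. When a fragmentation persists, the charge is shared
   among the M products by a Boltzmann factor over their vertical ionization
   potentials at the average fragment temperature T_Av,

       C_i = exp(−IP_i / k_B T_Av) / Σ_j exp(−IP_j / k_B T_Av),

   the highest-charge fragment continues in a cascade (daughter weights
   multiplied by its weight), and the stored statistical charges of one run
   sum to exactly 1. Charges accumulated over the run ensemble, convolved
   with natural isotope abundances on the unit-mass grid and normalized to
   the base peak, are the spectrum.

Forces, orbitals and vertical IPs come from a pluggable **provider**. The
built-in `SurrogateProvider` (Morse bonds over a frozen topology + short-range
repulsion, mock orbital tables, table-driven IPs) makes the whole protocol
runnable and testable on a laptop with analytically predictable fixtures;
quantitative spectra of real molecules require a quantum-chemistry backend
through the documented `ExternalEngineAdapter` subprocess contract.

## Worked example

Simulate the built-in weak-bond fixture — a CH3–OH skeleton whose bridge bond
(1 eV) is far weaker than its X–H bonds (6 eV), with vertical IPs of 7 eV
(CH3) and 11 eV (OH):

```toml
# dimer.toml
[run]
fixture = "weak_bond_dimer"
n_runs = 60
master_seed = 7

[md]
equilibration_duration = 1000.0
sampling_duration = 1000.0
production_max_time = 3000.0
```

```bash
eimsim run --config dimer.toml --msp-out dimer.msp
```

prints

```
production runs : 60
successful      : 60
failed          : 0 (0.0%)
wrote dimer.msp
```

and `dimer.msp` contains

```
Name: weak_bond_dimer
Comments: n_runs=60 seed=7
Num Peaks: 5
1 6.66957
14 6.59745
15 100
16 1.11528
17 0.253707
```

Reading the sticks: the base peak m/z 15 is CH3⁺ — the weak bridge cleaves
and the 4 eV IP gap routes essentially all the charge onto the methyl
moiety; m/z 16 is its ¹³C isotope satellite (≈1.1%); m/z 17 is the small OH⁺
share; m/z 14 (CH2⁺) and m/z 1 (H⁺) come from runs that ionized a deep
orbital, heated hard, and shed a hydrogen from the hot methyl daughter in a
second cascade level. Each stick's provenance (which formulas contributed
what charge) is retained on the `Spectrum` object.

The CLI also exposes `equilibrate`, `sample`, `spectrum` (format
conversion), `compare` (weighted cosine similarity, head-to-tail plot) and
`fixtures list`/`write`. Everything is importable as a library; see the
module docstrings.

## Determinism

Every source of randomness descends from one master seed; per-run seeds are
derived with `numpy.random.SeedSequence`, and run results are reduced in run
order, so a simulation is bit-reproducible regardless of the worker count.
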