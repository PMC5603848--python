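# Methods

This note records the physical model, the numerical choices, and the places
where the design was genuinely open — with the reasoning behind each choice.

## Protocol overview

The simulator reproduces the standard stochastic-MD protocol for 70 eV EI
spectra: neutral-state equilibration and conformer sampling, a single
orbital-spectrum evaluation, and an ensemble of independent ionized
production runs whose fragment charges are summed into a spectrum. Units are
Å, fs, eV, amu throughout; the two conversion constants (kinetic-energy
factor 1 amu·Å²/fs² = 103.6427 eV and k_B = 8.6173×10⁻⁵ eV/K) live in
`eimsim.constants`.

## Internal-excess-energy density (reconstruction)

The published constraints on the IEE density are: Poisson-like shape,
parameters a ≈ 0.2 eV and b = 1.0, mode at 0.6 eV per atom, support ending
at E_impact − ε_HOMO. The full closed form behind those constants is not
recoverable from the published description, so `sample_iee` implements a
*mode-anchored truncated gamma*: with mode m = 0.6·N eV and width w = a·N
eV, the scale solves θ² + mθ = w² and the shape is k = 1 + m/θ, so the gamma
mode is exactly m and the standard deviation is w. The knob b rescales
shape and scale together (shape b(k−1)+1, scale θ/b), sharpening (b > 1) or
flattening (b < 1) the density at fixed mode — this is the natural remaining
role for a dimensionless shape parameter. Truncation at the support maximum
is by rejection; for realistic molecules the support (tens of eV) is far
above the mode, so rejection is rare and the mode is unaffected. The density
is pluggable (`IEEModel` + `sample_iee`) so an exact form can be dropped in.
We claim protocol compatibility, not bit compatibility.

## Ionized-orbital selection (reconstruction)

Which occupied orbital the 70 eV electron ionizes is not specified beyond
the use of the ionized MO's populations. We select **uniformly among the
energetically accessible occupied orbitals** — those whose binding offset
ε_HOMO − ε_j does not exceed the available IEE; the HOMO is always
accessible. This is the least-informative rule consistent with the
energetics, and it is pluggable.

## Internal conversion and heating

The gap-law IC time is implemented as the single-gap exponential
t = k_h·exp(−α(ε_HOMO − ε_j)) with α = 0.5 eV⁻¹ and k_h = 2 ps, clamped to
[Δt, 10 ps]. For valence gaps up to 4.6 eV this spans 0.2–2 ps, inside the
observed 0.2–3.0 ps heating window.

Heating deposits the IEE in equal per-step energy increments over
⌈t_IC/Δt⌉ steps (uniform-in-time; front-loaded schedules would be an easy
variant but there is no stated basis for one). Each increment multiplies
atom A's velocity by 1 + λf_A, where f_A are the per-atom factors
(Mulliken-population-proportional below 35 atoms, unity above, normalized to
unit mean) and λ ≥ 0 solves the quadratic energy balance — so arbitrary
factor vectors still deposit *exactly* the requested energy, and the
executed plan converts the full IEE into nuclear kinetic energy to 10⁻⁹ eV.
A motionless subsystem is bootstrapped with ~1 K thermal noise before
scaling (net deposit still exact).

**Open case decided here:** if fragmentation is accepted before the IC
window has elapsed, the remaining increments continue on the *selected
daughter ion* (with the factor vector restricted to its atoms). Internal
conversion is a property of the ion, not of the parent geometry, and
dropping the remainder systematically starved daughter ions of energy and
truncated cascades.

## Integrator and thermostat

Kick–drift–kick leap-frog (velocity-Verlet form): the identical position
trajectory as the classic offset leap-frog, with velocities synchronized to
positions so per-step kinetic/total energies are well-defined. Δt = 0.5 fs
default. Energy drift on a bound diatomic is oscillatory and bounded; the
drift measured as the difference of windowed means over 10⁴ steps is below
10⁻⁴ eV.

The canonical ensemble is realized with a Berendsen velocity-rescaling
thermostat, coupling constant 100 fs (the protocol prescribes the ensemble,
not the thermostat; Berendsen is the simplest choice that holds a set point
tightly, and sampling exactness is immaterial here because the snapshots
only need to be a reasonable thermal ensemble). The rescaling factor is
clipped to ±10% per step for startup stability.

## Fragmentation detection

Bonds: distance < k·(R_i + R_j) on Cordero covalent radii, k = 1.2
(exposed in config — it controls fragmentation *timing*). Fragments are
connected components. A split is accepted only after persisting for 3
consecutive checks spaced 20 steps (10 fs) apart; transient bond stretches
must not count as fragmentation, and no persistence rule is published —
this one is the deviation knob most worth revisiting against a reference
implementation.

## Fragment temperature

Internal kinetic temperature: center-of-mass translation is always removed;
rigid rotation (via the inertia-tensor pseudoinverse) is removed for N ≥ 3.
Degrees of freedom: 3N−6 (nonlinear), 3N−5 (linear), and a single-mode
convention for diatomics (their internal energy after COM removal is the
relative motion, counted as one vibrational mode); single atoms are 0 K.
Whether the reference protocol uses 3N or 3N−6 is unstated; the vibrational
count is the physically meaningful one for energy-per-mode, but the choice
shifts charge-partition temperatures and is therefore documented here. The
average fragment temperature entering the charge model is the unweighted
mean over the fragments of one event.

## Statistical charges (reconstruction)

The charge weights are the Boltzmann/softmax form over vertical IPs at
T_Av — the only form consistent with all stated properties (normalization
to the total charge, dependence on IPs, T_Av and k_B, and lowest-IP
dominance at low temperature). Computed shift-stably (minimum IP subtracted
before exponentiation); T_Av ≤ 0 falls back to the zero-temperature limit
(all weight on the minimum IP, ties split equally) with a warning. Ties in
the argmax selection break toward the lower fragment index for determinism.
Cascade bookkeeping multiplies daughter weights by the survivor's weight;
charge conservation to 10⁻⁹ over arbitrary cascade trees is the module's
central tested theorem. Cascade depth is capped at 6 as a safety net
(natural termination — a single atom or an unfragmented survivor — is the
expected exit).

## Surrogate potential-energy surface

The desk-scale PES is a sum of Morse terms D_e[(1−e^{−a(r−r_e)})²−1] over a
**bond topology frozen at construction** plus an all-pairs exponential
repulsion (default 10 eV prefactor, 0.08 Å range — negligible at bonded
distances, a hard wall below ~0.4 Å). Freezing the topology keeps fixture
fragmentation analytically predictable: distant atoms can never spuriously
re-bond, so the designed bond strengths alone decide the chemistry. r_e
defaults to the covalent-radius sum. On a charged surface the *attractive
branch* of each Morse term is scaled by 1 − charge_softening (default 0.2):
the cation surface is everywhere at or above the neutral one (weaker
binding), and the scaled/unscaled branches join continuously at the Morse
zero crossing (a gradient kink deep inside the repulsive wall, at
r_e − ln2/a, which bound trajectories essentially never sample). Gradients
are analytic and verified against central differences to 10⁻⁶ eV/Å.

The electronic-temperature argument of the provider contract is accepted
and ignored by the surrogate (it has no electronic structure) and forwarded
verbatim by the external-engine adapter.

## Fixtures: what they emulate and what they do not

`weak_bond_dimer` (CH3–OH skeleton, 1 eV bridge vs 6 eV X–H bonds, IPs
7/11 eV, HOMO localized on the bridge) makes single-bond cleavage with
deterministic charge routing the designed outcome. `cascade_chain` (linear
hetero-chain with bond strengths growing toward the head, IPs decreasing
with fragment size) forces ordered tail-peeling through at least two
cascade levels. The fixtures exercise every protocol stage with
analytically predictable outcomes, but they are *not* chemistry: passing
tests demonstrates the correctness of the machinery (integration, heating
bookkeeping, charge conservation, determinism, isotope arithmetic), not the
accuracy of predicted spectra for real molecules, which depends entirely on
the quantum-chemistry backend plugged into the provider contract. With fast
uniform heating (deep-orbital ionization) the hot methyl daughter of the
dimer sometimes sheds a hydrogen — a correct consequence of the designed
energetics, visible as small m/z 14 and 1 sticks in the worked example.

## Problem sizes in the test suite

The configuration defaults are the standard protocol conditions (12.5 ps
NVT, 25 ps NVE, 1000 snapshots, 1000 production runs of up to 10 ps). The
end-to-end tests run the 6-atom fixtures at reduced lengths (0.5–1 ps
equilibration/sampling, 8–60 runs, 1.5–3 ps production windows) — the
package's own desk-scale choice: the fixtures' designed outcomes are
decided within the first picosecond, and the shortened windows change only
the parent-survival fraction, which the affected tests account for.

## Known limitations

* Singly charged cations only; no adducts, no high-resolution exact masses.
* No non-adiabatic charge hopping: the charge always follows the Boltzmann
  weights of the vertical IPs.
* The surrogate PES has no angular terms; fixture moieties are floppy, which
  is harmless for the designed bond-cleavage outcomes but means fixture
  "temperatures" should not be over-interpreted.
* The IEE density, MO-selection rule and gap-law form are reconstructions
  honoring all published constraints (see above); bit-level agreement with
  the reference implementation is out of scope.
* The Berendsen thermostat does not generate a rigorous canonical
  distribution; it is used only to prepare thermal snapshots.
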