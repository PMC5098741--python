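# Methods

## Model and assumptions

`knpsim` solves the discretized Nernst–Planck continuity equation for ion
concentrations in a 1D column of porous tissue, closed by Kirchhoff's
current law for the electrical potential (the KNP scheme). The key physical
assumptions:

- **Bulk electroneutrality.** Any net ionic charge entering an ECS box is
  taken to accumulate on the capacitive neural membranes inside it, so the
  bulk carries no net charge and the potential follows algebraically from
  current conservation instead of from a Poisson (charge-relaxation) solve.
  Formally, the time derivative of the box charge equals minus the
  capacitive transmembrane current, which is supplied as an input. This is
  valid at scales well above nanometers/nanoseconds; it is the same
  assumption that underlies the cable equation.
- **1D lateral homogeneity.** All gradients are vertical; the column
  cross-section is a parameter, not a resolved dimension.
- **Porous medium.** The ECS occupies a volume fraction `α` of the tissue;
  diffusion is hindered by tortuosity `λ` (`D_eff = D/λ²`). The diffusion
  constants stored in `IonSpecies` are free-solution values; `1/λ²` is
  applied inside every flux/conductivity formula. (Treating the stored
  values as already-effective ones would understate the baseline
  conductivity by a factor `λ² = 2.56` and contradict the 0.76 S/m the
  default electrolyte is known to conduct.)
- **One-way coupling.** Transmembrane sources are an external input; the
  ECS state does not feed back on them. Ion pumps, glial buffering and
  activity-coefficient corrections are out of scope.

Reservoir boundary conditions: the two edge boxes hold baseline
concentrations forever; `V = 0` in the bottom box is the potential
reference; no net electrical current crosses the top boundary interface,
i.e. `I^d + I^f = 0` there, so a diffusive current at the top is exactly
canceled by an opposing field current. The sign of this row is pinned down
by the frozen-conductivity equivalence and CSD round-trip tests, which fail
loudly if the boundary leaks current.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `n_subvolumes` | 15 | – | boxes incl. 2 reservoirs |
| `subvolume_height` l_c | 100e-6 | m | box height |
| `cross_section` A_c | 3000e-12 | m² | tissue cross-section |
| `volume_fraction` α | 0.2 | – | ECS share (ECS cross-section αA_c = 600 µm²) |
| `tortuosity` λ | 1.6 | – | hindrance, D_eff = D/λ² |
| `temperature` | 300 | K | sets ψ = RT/F ≈ 25.85 mV |
| K⁺ / Na⁺ / Ca²⁺ / X⁻ | 3 / 150 / 1.4 / 155.8 | mol/m³ | baselines, exactly electroneutral |
| D (K/Na/Ca/X) | 1.96 / 1.33 / 0.71 / 2.03 ×10⁻⁹ | m²/s | free-solution diffusion constants |
| `dt` | 1e-4 | s | Euler step |
| `record_stride` | 10 | – | record every k-th step |

The cross-section can be quoted either as the ECS share (600 µm²) or as
the tissue cross-section (3000 µm²) times `α = 0.2`; every formula uses
only the product `αA_c`, so the two readings are equivalent. We store the
tissue value. At the default 300 K the baseline electrolyte conducts
0.766 S/m (apparent tissue value `ασ ≈ 0.15 S/m`, between the ~0.1 and
~0.3 S/m figures in experimental and modelling use) and the soma-shift GHK
potential is −0.175 mV; the temperature is a configuration field.

## Numerical scheme

Per step, in fixed order: (1) interface conductivities and diffusive
currents from the current concentrations; (2) assemble and solve the
tridiagonal Kirchhoff system with the current source sample (direct banded
elimination — exact, and trivial at N = 15); (3) drift fluxes from the
solved potential; (4) forward-Euler update of interior concentrations.
The state recorded at each sample carries the potential solved *at* that
state, so the first record already reflects the initial profile.

- **Stability.** Explicit diffusion requires `max_k(D_k/λ²)·dt/l_c² < 0.5`;
  with the defaults the left side is ≈ 8×10⁻⁶, a margin of ~10⁵. The bound
  is checked and violated `dt` is rejected.
- **Convergence.** The scheme is first order in `dt`; halving the step
  halves the error (asserted by a convergence test).
- **Sources.** Zero-order hold between source samples when the solver step
  is finer than the source grid.
- **Negative concentrations** abort the run with the offending ion, box and
  time. Clipping would silently distort diffusion potentials, which are the
  whole point of the exercise.
- **No-diffusion mode** zeroes `J^d` in the continuity equation and `I^d`
  in the potential equation; the concentration dependence of σ is retained
  (its only remaining effect in that mode).
- **Frozen conductivity** (`freeze_conductivity`) pegs both σ and the drift
  weights at the initial interface concentrations. This keeps the recorded
  currents consistent with the solve, which is what makes the
  diffusion-on/off total-current equivalence exact: by telescoping
  Kirchhoff's law from the blocked top boundary, the per-interface total
  electrical current is determined by the sources alone.
- **Built-in telemetry.** Every run records its worst interior Kirchhoff
  residual, normalized by the largest individual current magnitude (so the
  figure is meaningful even when components cancel exactly); typical values
  are ~10⁻¹⁵.

## Synthetic population sources

The generator stands in for a compartmental-simulator export and emulates
the statistical structure of a small pyramidal population, not any specific
cell model:

- 10 neurons, independent Poisson AP trains at 5 /s each;
- per AP, a biphasic pulse pair into the soma box (n = 3): Na⁺ influx
  (−30 nA peak, α-kernel τ = 0.5 ms) followed 0.5 ms later by K⁺ efflux
  (+30 nA peak, τ = 1 ms);
- slow backgrounds per neuron (AR(1), τ = 50 ms): X⁻ at 0.5 nA and Ca²⁺
  at 0.05 nA scale, spread uniformly over the dendritic span (boxes 3–14);
- a capacitive return current distributed uniformly over the dendritic span
  that closes each neuron's current loop *exactly*, so the depth-summed
  total transmembrane current is identically zero at every sample — the
  property the potential solve requires. A real neuron distributes its
  return currents through cable dynamics; the uniform closure reproduces
  the conservation constraint, not the spatial fine structure.

Pulse amplitudes, firing rate, soma box and population size define the
emulated scenario; kernel widths, the K⁺ delay and the background
amplitudes are free parameters of this package, chosen once to give ~1 ms
AP signatures and minor non-somatic ion exchange. Consequently, tests
against generator-driven runs demonstrate the *solver's* conservation and
equivalence properties and the qualitative structure (soma-dominated
Na⁺/K⁺ exchange, slow concentration build-up); absolute trace and PSD
levels of driven runs depend on these free parameters and carry no claim of
fidelity to any particular cell model. Everything derived from the
source-free decay scenario (junction potentials, the 1/f² law, CSD
behaviour) is generator-independent.

For real exports, `map_segment_currents` converts per-segment channel
current densities to per-box ion fluxes via `J = iA/(z_k F)` (the valence
halves Ca²⁺ currents and flips the sign for the anion), with segments
assigned to boxes by their midpoint, and `read_source_series` imports
long-format delimited text.

## Diagnostics

- **PSD**: one-sided periodogram of the mean-subtracted signal (no taper by
  default; detrending beyond mean subtraction is deliberately omitted),
  then geometric binning at 0.1 decades per bin, each bin reporting the
  geometric-mean frequency of its members. Parseval consistency of the raw
  periodogram is tested at 1 %.
- **Power-law fit**: least squares on (log₁₀ f, log₁₀ PSD). The default
  band for 21 s decay records is 0.05–2 Hz: below 0.05 Hz the record
  length limits resolution, above ~2 Hz spectral leakage of the
  non-periodic decay competes with the physical Lorentzian tail. The band
  is always an explicit argument.
- **GHK potential** uses the textbook monovalent voltage equation with
  `D` as permeability (a shared tortuosity factor cancels); Ca²⁺ at 1.4 mM
  contributes negligibly and is excluded rather than shoehorned into a
  monovalent formula. **Henderson** handles arbitrary valences with
  mobilities ∝ `D|z|`; both linearize to `−ψ Σz D Δc / Σz² D c` and agree
  to ≤1 % for small monovalent shifts. On the large soma shift (ΔK/K =
  200 %) they differ by ~5 %, mostly from the Ca²⁺ exclusion; the
  KNP-solved decay potential (−0.167 mV) matches Henderson, while GHK
  gives −0.175 mV — both round to the same printed value.
- **CSD**: classical `−∇(σ∇V)` and diffusion-corrected
  `−[∇(σ∇V) − ∇i^d]`, as centered second differences with one-sided ends
  (no current crosses the outer faces), reported per unit ECS volume.
  Round-trip tests confirm the classical form inverts diffusion-free runs
  and the corrected form inverts electrodiffusive runs; on source-free
  decay snapshots the classical estimator reports phantom sources (the
  diffusive currents) while the corrected one reports ≈ 0.

## Problem sizes

The acceptance computation runs the 21 s decay at dt = 0.1 ms (210 000
steps, ~20 s wall time); solver property tests use 0.02 s driven runs and
the generator tests up to 10 s of synthetic drive. These sizes were chosen
so the whole suite exercises every claimed property at interactive speed.

## Known limitations

- 1D only; no ephaptic or concentration feedback onto the sources; no
  uptake mechanisms, so long driven runs accumulate unphysiologically
  monotone concentration shifts.
- Forward Euler is wasteful for stiff source kernels; the stability margin
  makes it safe but an implicit scheme would allow much larger steps.
- The text trajectory reader does not round-trip per-ion interface fluxes
  (currents and concentrations suffice for all shipped diagnostics).
- `analyze` assumes the trajectory was produced under the same ion set as
  the configuration it is given.
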