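# knpsim

Electrodiffusive simulation of extracellular potentials and ion
concentrations in a 1D column of neural tissue, using the
Kirchhoff–Nernst–Planck (KNP) scheme.

## The problem

Extracellular recordings (LFPs, current-source-density analysis) are almost
always interpreted with volume-conductor theory, which assumes all
extracellular-space (ECS) currents are Ohmic — driven by the electric field
alone. When neural activity shifts ECS ion concentrations by millimolars,
however, ions also *diffuse* along the resulting gradients, and because
different species have different mobilities, diffusion carries net charge.
This package simulates that interplay: given per-depth time series of
transmembrane ionic fluxes and capacitive currents (exported from a neuron
simulator, or synthesized by the built-in population generator), it computes
the coupled dynamics of ECS ion concentrations `c_n^k` and the ECS potential
`V_n`, with diffusion switchable on or off on identical sources.

It is intended for computational neuroscientists who want to quantify when
the no-diffusion assumption breaks down, and for anyone needing a compact,
well-tested liquid-junction/CSD toolbox (GHK and Henderson potentials,
log-binned PSDs with power-law fits, classical and diffusion-corrected CSD).

## The model

The tissue column is split into `N = 15` boxes of height `l_c = 100 µm` and
tissue cross-section `A_c = 3000 µm²`; the ECS occupies a volume fraction
`α = 0.2` of it and diffusion is hindered by tortuosity `λ = 1.6`
(`D_eff = D/λ²`). Four species are tracked: K⁺, Na⁺, Ca²⁺ and an
unspecified anion X⁻ (standing in for Cl⁻), at cerebrospinal-fluid-like
baselines (3, 150, 1.4, 155.8 mM; exactly electroneutral). For each
interface between boxes,

    J^d = −(αA_c/l_c) (D/λ²) Δc                      (diffusive flux, mol/s)
    J^f = −(αA_c/(ψ l_c)) z (D/λ²) c̄ ΔV             (drift flux, ψ = RT/F)
    σ   = (F/ψ) Σ_k (D_k z_k²/λ²) c̄_k               (conductivity, S/m)

and the potential is obtained each time step from Kirchhoff's current law:
the sum of all currents into each interior box — transmembrane ionic
`I^M`, capacitive `I^cap`, diffusive `I^d = FΣ z J^d` and field
`I^f = FΣ z J^f` — is zero. With `V_1 = 0` as reference and zero net
electrical current through the top boundary, this is a tridiagonal linear
system solved exactly every step; concentrations are then advanced by
forward Euler. Edge boxes are reservoirs clamped at baseline.

Because any net ionic charge entering a box must land on the membranes in
it, the scheme bypasses explicit charge relaxation (no Poisson solve) and
remains valid at tissue scales.

## Worked example

A classic demonstration that diffusion alone can generate potentials: shift
the "soma" box (n = 3) electroneutrally by ΔK = +6, ΔNa = −5.1,
ΔCa = −0.1, ΔX = +0.7 mM, remove all transmembrane sources, and let the
gradients relax:

```sh
knpsim decay --duration 21 --out decay_out
```

prints (abridged):

```json
{
  "initial_potential_mV": -0.1669,
  "final_potential_mV": -0.0446,
  "worst_kirchhoff_residual": 1.46e-15,
  "power_law": {"exponent": 1.9764, "band_Hz": [0.05, 2.0], "r_squared": 0.99994}
}
```

The perturbed box starts 0.167 mV *below* the rest of the column — the
liquid-junction (diffusion) potential of the composition step, which the
Goldman–Hodgkin–Katz equation independently estimates at −0.175 mV
(`knpsim.ghk_potential`). As diffusion smooths the gradients the potential
relaxes toward zero, and the PSD of `V₃` follows a Brownian-noise `1/f²`
power law over 0.05–2 Hz (fitted exponent 1.98). Re-running with
`--no-diffusion` gives `V ≡ 0` identically: without diffusive currents a
source-free column supports no potential. The per-run
`worst_kirchhoff_residual` is built-in correctness telemetry — the largest
violation of current conservation in any box, relative to the largest
current present.

Population-driven runs (10 neurons firing ~5 AP/s, soma-dominated ±30 nA
Na⁺/K⁺ pulse pairs, seeded and reproducible) compare both transport modes
on identical sources:

```sh
knpsim simulate --seed 1 --duration 5 --mode both --out sim_out
knpsim analyze --trajectory sim_out/with_diffusion --psd-subvolume 3 --csd -1
```

The library mirrors the CLI: `generate_population_sources` /
`read_source_series` → `run_simulation` → `power_spectrum`,
`fit_power_law`, `csd_standard`, `csd_diffusion_corrected`,
`ghk_potential`, `henderson_potential`.

## Documentation

`docs/methods.md` describes the numerical scheme, parameter choices, the
synthetic source generator and its limitations, and the design decisions in
detail.
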