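# crystaldepot

Analysis pipeline for **crystalline protein suspensions as long-acting
intravitreal depots**, built around a model anti-VEGF nanobody (~13.7 kDa)
whose surface mutants crystallize in different ("pseudo-polymorphic")
lattices.  Intravitreally injected protein solutions are cleared into the
aqueous humor with first-order kinetics, so doubling a bolus dose buys only
one elimination half-life of extra efficacious time; a slowly dissolving
crystal depot decouples the efficacious window from the dose.  The package is
aimed at formulation scientists and structural biologists who want to quantify
how lattice packing density translates into release kinetics.

It provides four analysis stages, a synthetic-data generator with exact ground
truth for all of them, and a CLI:

1. **Lattice density** (`crystaldepot.lattice`) — triclinic cell volume
   V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ), Matthews
   coefficient V_M = V/(Z·n·M) (Å³/Da), solvent content
   f = 1 − (v̄/0.6022)/V_M, and density ranking of crystal forms; readers for
   PDB `CRYST1`, mmCIF and a canonical CSV dialect.
2. **Depot pharmacokinetics** (`crystaldepot.pk`) — the two-compartment
   dissolution–elimination model
   dC/dt = A(M)·h·(Cs − C)/V − k·C, dM/dt = −A(M)·h·(Cs − C), with
   Noyes–Whitney dissolution (A surface area, Cs lattice solubility,
   h = k_D/L the mass-transfer coefficient), closed-form bolus references,
   time-above-threshold / dissolution-time analysis, and a hyperbolic
   zinc-suppressed solubility model Cs(zn) = Cs₀·K/(K + zn) for
   zinc-coordinated lattices.
3. **Dissolution imaging** (`crystaldepot.imaging`) — Otsu segmentation and 2D
   projected-area tracking of a single crystal through a bright-field
   time-lapse, percent-remaining release curves, complete-dissolution times,
   and one-way ANOVA between groups.
4. **Thermal propensity** (`crystaldepot.thermal`) — Tm1/Tm2 extraction from
   two-transition thermograms, aggregation-onset (Tagg) detection from static
   light scattering at 266/473 nm, and a three-way crystallization-propensity
   call from the Tagg(266 nm) window (< 36.1 °C precipitation-prone,
   ≥ 55.6 °C solution-stable, between: crystallization-prone with a favored
   45–50 °C band).

## Worked example

Density report for the five measured polymorphs (built-in reference table):

```text
$ crystaldepot lattice --out lat
      name  cell_volume_A3  matthews_A3_per_Da  solvent_fraction  solvent_pct  rank
    mNb-WT    48380.155144                1.76          0.301802        30.18     5
  mutant 2    94993.546690                1.73          0.289695        28.97     4
  mutant 7    86991.378537                1.57          0.217307        21.73     1
analogue 1    44186.207422                1.59          0.227152        22.72     3
analogue 2    43958.516024                1.58          0.222261        22.23     2
```

The wild type packs loosest (V_M = 1.76 Å³/Da, ~30% solvent); the
zinc-coordinated prismatic mutant 7 is the densest lattice (rank 1, ~22%
solvent) and, consistently, dissolves slowest in the release assay.

Default depot scenario (5 mg lamellar depot, A₀ = 2 cm², Cs = 0.08 mg/mL,
h = 0.5 cm/day, 9.5-day half-life, 4.5 mL vitreous, 0.01 mg/mL efficacy
threshold):

```text
$ crystaldepot pk --out pkrun
{
 "peak_Ct": 0.058352117092462706,
 "time_above_threshold": 382.6114930806952,
 "complete_dissolution_time": 1053.8247615576115,
 "dissolution_censored": false,
 "mass_balance_residual": 1.2434497875801752e-15
}
```

The depot holds the eye above the efficacy threshold for ~383 days; an equal
5 mg dose injected as a solution bolus (C₀ = 1.11 mg/mL) stays above the same
threshold for only ln(C₀/threshold)/k ≈ 64.6 days.  Peak free concentration
(0.058 mg/mL) stays well below the lattice solubility, and mass is conserved
to machine precision.

Other subcommands: `dissolve` (area tracking + ANOVA from TIFF stacks or a
manifest), `thermo` (Tm/Tagg extraction + propensity calls from curve CSVs),
`synth` (generate stacks, thermograms, SLS traces, crystal tables with
`.truth.json` sidecars), `report` (combined summary).

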