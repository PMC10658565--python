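# Methods

## Lattice density metrics

Cell volume uses the standard triclinic closed form, equal to √det G of the
metric tensor; non-realizable angle combinations (radicand ≤ 0) raise a
geometric-invalidity error rather than returning NaN.  The Matthews
coefficient divides the cell volume by Z·n·M (space-group general-position
multiplicity × copies per asymmetric unit × molar mass in Da).  Solvent
content is the conventional estimate f = 1 − (v̄/0.6022)/V_M with the protein
partial specific volume v̄ defaulting to 0.74 cm³/g (the constant behind the
familiar 1 − 1.23/V_M); v̄ is exposed as a parameter because published tables
rarely state the value used.  Ion and bound-solvent mass (sulfate, zinc) is
excluded from the molar mass: the reference coefficients are reproducible
without it.

Space-group multiplicities come from a built-in table of the Sohncke
(protein-compatible) groups keyed by normalized Hermann–Mauguin symbol;
unknown symbols fail loudly with the offending symbol named.  This is
deliberately not a symmetry engine — no operators, no coordinates.

Known data caveats, kept as documented residuals rather than forced to agree:

* The published cell volume of the densest (prismatic, zinc-coordinated)
  polymorph is ~0.4% below a·b·c computed from its own published orthorhombic
  cell parameters — an internal inconsistency in the source table.  That row
  is therefore excluded from exact-volume checks; the other four polymorphs
  reproduce to better than 0.005%.
* The published solvent percentages of the three densest forms sit
  0.15–0.25 points above the v̄ = 0.74 closed form evaluated at the published
  (rounded) V_M values; the exact v̄ and rounding path behind those figures
  are unstated.  The wild-type and first-mutant rows (30%, 29%) agree within
  rounding.

Percent reporting keeps the unrounded fraction internally and rounds only for
display.

## Depot pharmacokinetics

The model is one well-mixed intravitreal compartment with first-order
elimination (rate constant k, 1/day) plus a Noyes–Whitney dissolution source:

    dC/dt = A(M)·h·(Cs − C)/V − k·C
    dM/dt = −A(M)·h·(Cs − C)

The diffusion constant k_D and boundary-layer thickness L only ever appear as
a ratio, so they are merged into one mass-transfer coefficient h = k_D/L
(cm/day).  h has no published value in usable units and must be calibrated
per scenario; the default scenario uses 0.5 cm/day, which puts the 5 mg
lamellar depot's release on a months scale.

Surface area evolves as A(M) = A₀·(M/M₀)^p with p = 1 for lamellar crystals
(constant thickness, area ∝ mass — their projected area shrinks face-on) and
p = 2/3 for isometric/prismatic crystals shrinking self-similarly.  A
consequence worth stating explicitly: at equal M₀ and A₀ the isometric depot
holds a *larger* area at every partial mass (x^{2/3} > x on (0,1)) and
finishes in finite time, while the lamellar depot's mass decays exponentially
and is slower near exhaustion.  Under sink conditions the lamellar
complete-dissolution time is linear in M₀ at fixed A₀.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-10, scaled atol)
with a terminal event at M = 0; the post-exhaustion washout is filled in with
the exact exponential rather than integrated.  Mass balance
M + C·V + eliminated = M₀ + C₀·V is tracked as a third state and holds to
~1e-15 relative in practice (the tests require 1e-6).  "Complete dissolution"
means M < 1e-6·M₀, located by an integration event.  Sink mode (C ≡ 0)
approximates a release assay in a large medium volume; the coupled mode
models the eye.  Both are provided because the 10 µl drop assay being
emulated is ambiguous between them.

Zinc suppression of the zinc-coordinated lattice's solubility uses the
saturable hyperbola Cs(zn) = Cs₀·K/(K + zn) — the simplest bounded, strictly
decreasing form consistent with the observed monotone slow-down across the
20–300 mM zinc gradient.  Only orderings of dissolution times are meaningful;
the published assay times themselves are semiquantitative and are not
modelled.

Bolus analysis is closed-form throughout (C = C₀e^{−kt}); the
dose-doubling interval extension is computed as the difference of two
closed-form time-above-threshold values and equals ln2/k exactly, independent
of dose and threshold.  `time_above_threshold` on simulated profiles uses
piecewise-linear interpolation of threshold crossings, making it stable under
grid refinement.  Parameter recovery (`fit_dissolution_params`) refits
(Cs, h) in log space by Levenberg–Marquardt against a simulated profile with
k, V and geometry held known.

Scenario presets put the intravitreal aqueous volume at 4.5 mL (adult human)
with a 2.4 mL small-eye preset, and default the elimination half-life to
9.5 days, the midpoint of the 8–11 day range typical of intravitreally
injected proteins.  Multi-crystal suspensions can be summed linearly over
size classes since the model is linear in A.

## Dissolution imaging

`segment_crystal` binarizes one frame with a global Otsu threshold at the
configured contrast polarity (default: dark crystal on bright background),
fills holes, and keeps the largest 8-connected component — one crystal per
field, matching single-crystal drop assays.  Constant frames yield an empty
mask with a warning.  `percent_remaining_series` computes the Otsu threshold
once on the first frame and reuses it for the rest of the stack: late frames
containing only background noise would otherwise be thresholded on noise
alone and segment spuriously.  Projected area is pixel count × pixel size²;
percent remaining normalizes to the first frame.  "Completely dissolved"
means the area falls below 1% of the initial value (configurable) — a
sub-resolution remnant is indistinguishable from noise.  Timestamps come from
`<label>_t<minutes>.tif` filenames or a manifest CSV, defaulting to 2-minute
spacing (the assay interval) when absent.  Group comparison of dissolution
times is standard one-way fixed-effects ANOVA (`scipy.stats.f_oneway`),
validated in the tests against a hand-computed dataset (F = 3, p = 1/8).

## Thermal analysis

Thermogram peaks: subtract a linear baseline fitted to the outer 10% of the
scan, smooth with a Savitzky–Golay filter (window 17 points ≈ 3.4 °C at the
0.2 °C grid, order 2), take the two most prominent local maxima separated by
≥ 3 °C, and refine each to sub-grid precision with a local quadratic fit
(±7 points).  Only peak temperatures are reported — no ΔH/ΔCp fitting.  A
single qualifying peak is returned flagged rather than raising.

SLS onset: the initial plateau is the first 8 °C of the scan; the onset is
the first temperature where the signal exceeds the plateau median + 5 robust
SDs (1.4826·MAD, floored at 0.1% of the signal range so a noiseless trace
still requires a genuine rise) and stays above for 3 consecutive points.
The rule is invariant to uniform scaling of the signal.  The thresholds,
persistence and plateau span are all exposed because the instrument software
they replace is a black box.

Propensity classification partitions the Tagg(266 nm) axis
closed-left/open-right: (−∞, 36.1) → precipitation-prone, [36.1, 55.6) →
crystallization-prone (annotated "favored" in [45, 50)), [55.6, ∞) →
solution-stable; absent onset → indeterminate.  Tm2 is required; values at or
above 61.6 °C are noted as thermostable in the rationale.  All thresholds are
configurable: they derive from a nine-protein panel and are hypothesis-level,
not a validated decision rule.  The favored band is reported as an annotation,
not a fourth class.  Screening-condition counts are used only as an ordinal
concordance fixture (analogue 1 > analogue 2 > wild type > mutant 2), never
as predicted quantities.

## Synthetic data

Every generator takes an explicit seed, is bit-reproducible, and returns its
ground truth alongside the data (`.truth.json` sidecars on disk).

**Image stacks.**  A convex silhouette — regular hexagon for "lamella",
4:1 rectangle for "prism", echoing the observed morphologies — is scaled so
its exact polygon area follows the requested law (linear decay, or M(t)/M₀
from the sink-condition lamellar PK model, since projected area ∝ mass at
constant thickness), rendered at a default 20° orientation with *exact*
per-pixel coverage (shapely polygon∩pixel intersection in a boundary band),
then composited as dark-on-bright with additive Gaussian noise parameterized
as a fraction of the contrast.  The oblique default orientation avoids the
degenerate grid-aligned case, where every pixel along a straight edge
quantizes identically and hard pixel counting is biased by up to an edge
length; crystals in real micrographs lie at arbitrary angles.  Defaults:
2-minute frames, 0.5 µm/px, ~10,000 px initial silhouette on a 192×192
canvas, 5% noise.  What this does **not** emulate: optical blur, uneven
illumination, birefringence, debris, multiple crystals, or focus drift — so
passing recovery tests bound algorithmic error, not real-microscopy error.

**Thermograms.**  Two Gaussian peaks (default 55 and 63 °C, σ = 2.5/3.0 °C,
amplitudes 1.0/0.8) on a linear baseline over a 15–100 °C grid at 0.2 °C,
plus additive Gaussian noise scaled to the taller peak.  Transitions closer
than 3 °C trigger a warning (below the detector's separation limit); with the
default widths, transitions closer than ~2σ genuinely merge into one maximum
and no peak-picker can separate them.  Recovery sweeps therefore use
well-separated pairs (8–18 °C apart), as observed in this protein family.

**SLS traces.**  A flat baseline followed by a saturating-exponential rise
amp·(1 − e^{−(T−Tagg)/w}) that is exactly zero below Tagg, so the onset is
unambiguous ground truth (a centered logistic has no well-defined
"beginning"); default steepness w = 1 °C, 15–95 °C grid.

## Problem sizes and numerical choices

Recovery tests use 200 seeded thermal curves at 2% noise (detector errors:
median < 0.1 °C, max < 0.5 °C), ~160-case segmentation sweeps at ≤ 10% noise
(≤ 1.4% worst-case area error for shapes ≥ 500 px), and PK scenarios on
grids of a few hundred points.  ODE tolerances (rtol 1e-10) keep the mass-
balance invariant far below the 1e-6 test bound.  Ties in density ranking
break by Matthews coefficient, then name, keeping the sort stable and
permutation-invariant.

## Limitations

* One well-mixed ocular compartment; no retina/aqueous sub-compartments,
  protein binding, or in vivo PK calibration (no animal PK data exist for
  this system).
* The area-mass exponent is a geometric idealization; real crystal habits may
  evolve between the p = 1 and p = 2/3 limits.
* The zinc-solubility hyperbola encodes monotone suppression only; its K is
  not identifiable from published data.
* The propensity thresholds come from nine proteins; treat calls as
  hypothesis-generating.
* 2D projected area is a proxy for dissolved mass that is exact only for
  constant-thickness lamellae.
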