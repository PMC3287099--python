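# Methods

## The model

`oxymap` estimates the spatial distribution of chronic hypoxia in a tumor
cross-section from the geometry of its perfused vasculature, then uses the
resulting oxygenation map to assess measurement strategies and radiation
response.

A tumor section is a set of co-registered binary masks on a uniform square
grid (default 6 mm side, 100 × 100 cells, so one 60 µm cell is roughly one
capillary cross-section or a group of 5–6 tumor cells).  The oxygen
sources are the *perfused* vessels: the elementwise AND of the vessel
stain and the perfusion stain, giving the indicator field m_p(x).

Oxygen concentration K(x, t) and tumor-cell density c(x, t) obey coupled
reaction–diffusion equations on that grid:

    ∂K/∂t = D_K ∇²K + r·m_p − η·K − φ·c·K
    ∂c/∂t = D_c ∇²c + ρ·c(1 − c/c_lim) + γ·m_p·c

with reflecting (no-flux) boundaries on the square domain (oxygen may
diffuse into non-tumor background; quantification later restricts to the
tumor mask).  Vessels are a volumetric source term, not a Dirichlet
condition.  Starting from oxygen only inside the perfused vasculature and
a Gaussian initial cell distribution centered on the tumor centroid, the
system is advanced until the *relative* hypoxic fraction is stationary.
The result is an instantaneous oxygenation snapshot for a fixed vascular
geometry, not a time-accurate transient.

### Relative hypoxia

A tumor cell is hypoxic at level p% if K is below p% of the current field
maximum; HP2.5, HP5, HP10 are the conventional severe/moderate/mild
levels.  Because the definition is relative, every reported quantity is
invariant to the absolute oxygen scale: the intravascular level K_vessel
and the supply rate r are harmless scale factors (there is a regression
test that scales both by 8 and checks that hypoxic masks are bit-
identical).  The published parameter table mixes units that do not close
dimensionally (e.g. a supply rate in "O₂ s⁻¹" against a carrying capacity
in "cells s⁻¹"); we deliberately do not guess absolute oxygen units.  K is
carried in model units and only two dimensionless combinations shape the
solution: the effective supply r·dx²/D_K and the effective consumption
φ·c·dx²/D_K (≈ 0.115 per cell² at the defaults with c = c_lim, giving an
oxygen decay length of ≈ 3 cells ≈ 0.18 mm).

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| D_K | oxygen diffusion coefficient | 2.5e-5 | cm²/s |
| r | supply rate per perfused cell | 8.2e-3 | model units/s |
| η | oxygen decay | 0 | 1/s |
| φ | per-cell consumption | 3.8e-13 | 1/(cell·s) |
| D_c | cell diffusion | 4.05e-9 | cm²/s |
| ρ | proliferation rate | 1.85e-6 | 1/s |
| c_lim | carrying capacity | 2.1e11 | cells |
| γ | vascular growth boost | 2.96e-6 | 1/s |

The cell field barely moves over the oxygen equilibration horizon
(ρ·t ≈ 3e-3), so consumption is effectively set by the initial Gaussian
cell profile.  Its width (σ = 3 mm) and peak (c_lim) are configuration:
the width gives a mildly center-weighted consumption over a ~4.6 mm tumor,
and neither the width nor the peak is pinned by published values.

## Numerics

* Explicit forward Euler with a conservative five-point Laplacian and
  ghost-cell mirroring at the square boundary.  The stencil conserves mass
  exactly in the source/sink-free case (regression-tested at 1e-12
  relative per step).
* Operator splitting per step: the oxygen update uses the cell field of
  the previous step.
* Time step dt = 0.8·dx²/(4·D_K) ≈ 0.29 s.  The fixed point of the
  explicit update is independent of dt, and 0.8 of the diffusion stability
  bound preserves positivity (the per-cell update coefficient
  1 − 4λ − dt·φ·c_lim ≈ 0.18 stays positive), so the larger step changes
  only the transient path, not the stationary map.  A `dt_factor`
  parameter exposes more conservative settings.
* Stationarity: checkpoints every 120 s of model time.  Convergence
  requires (a) the monitored HP to move less than `tol_hp` = 0.001 between
  two consecutive checkpoints and (b) every traced HP at horizon T to
  agree with its interpolated value at T/2 within `tol_half` = 0.004 —
  the doubling-time form of "the hypoxic fraction is the same at any
  sufficiently late computational time".  The consecutive-checkpoint rule
  alone can stop on a slowly drifting tail; the doubling check is what
  guarantees the half-horizon robustness property.  Typical horizons are
  ~1000–1500 s of model time (~4–6 k steps, < 0.5 s wall time per tumor).
* Fields that blow up (non-finite values) raise a `StabilityError` naming
  the offending dt; fields are never clipped, nonnegativity holds by
  scheme construction.
* An independent stationary solver (`stationary_oxygen`, sparse direct
  solve of the frozen-cell linear system) serves as an oracle: the
  explicit stepper matches it to 1e-8 of the profile scale on 1-D strips
  and 2-D single-source problems.

### Degenerate inputs

* No perfused vessel: no oxygen source; the solve returns after one
  checkpoint with a degenerate flag and hypoxic fraction 1 (distance to an
  empty vessel set is +∞ by convention, so the synthetic reference mask
  marks the whole tumor in the same situation).
* Zero-maximum oxygen field: every tumor cell is hypoxic.
* All-identical readings in the variance analysis: components are 0/0; the
  percentage is defined as 0 and flagged degenerate.

## Synthetic tumor sections

Real stained sections are not distributed with the package; the generator
produces domains with the same gross features: a connected blob- or
ellipse-shaped tumor covering ≳ 25 % (typically ~45 %) of the frame,
single-cell vessel cross-sections placed inside it (uniformly, or
sequentially with lognormal nearest-neighbor spacing, median ≈ 0.35 mm),
a simple random perfused subset (default 60 % of vessels), and a
*reference hypoxia mask* marking tumor cells farther than a diffusion
limit from every perfused vessel — a geometric proxy for nitroimidazole
marker binding, which saturates in severely hypoxic tissue.

Cohorts vary the vessel count (default 12–68 per section) to create
genuine between-tumor heterogeneity; with 60 % perfusion this spans
perfused vascular area fractions of roughly 0.002–0.01 and stationary HP5
fractions of roughly 0.3–0.85.

What the generator does **not** emulate: vessel cross-sections larger than
one cell, spatially correlated perfusion loss, acute (fluctuating)
hypoxia, staining artifacts, or registration error.  Validation numbers
on synthetic cohorts therefore demonstrate internal consistency of the
method — that the transport model, the relative thresholds and the
electrode emulation fit together — not accuracy on real histology.

### Matching the reference mask to the solver

`effective_diffusion_distance(params, geometry, pct)` places a single
perfused cell in a uniform cell field, solves the stationary equation
directly, and returns the radius at which K crosses pct% of its maximum
(log-linear sub-cell interpolation).  At the defaults this gives
0.327 mm for HP5 (0.43 mm for HP2.5, 0.23 mm for HP10).  Using this value
as the generator's diffusion limit makes the distance-based reference mask
the model's own prediction for an isolated vessel; the cohort-level
HP5 agreement of ~90 % then measures how well the single-vessel picture
survives vessel interaction, consumption gradients and the global-maximum
threshold.  The generator's stand-alone default (0.15 mm) is the classic
literature diffusion distance instead.

## Virtual electrodes

Readings are taken every 0.2 mm along linear tracks, 25 per track by
default (protocols use 20–30), and each reading is the value of the grid
cell under the tip — at 60 µm resolution the cell *is* the instrument's
averaging volume.  Readings outside the grid are dropped with a warning;
readings outside the tumor mask are dropped silently by default because
the physical protocol samples tumor tissue, and background cells (no
vessels, no consumption) would otherwise read near-zero oxygen and
inflate every electrode HP estimate.  Pass `tumor_mask=None` to keep all
in-grid readings.  Instrument noise is off by default (the emulation is
of an error-free probe); a Gaussian `noise_sigma` is available for
robustness studies.

Strategies: `uniform` (parallel vertical tracks, equally spaced across
the tumor bounding box), `random` (boundary entry toward a random interior
point), `half_radial` (entries on a limited arc, default 60°–120°, the
10-to-2-o'clock case of one-sided surgical access, aimed at the
centroid), `full_radial` (entries around the full circle).  The arc is a
parameter, so 10–2, 9–3 and full-circle variants are all expressible.
Electrode HP estimates share the area method's reference maximum (the
global field max) so the two estimators are directly comparable.

## Variance components

Within- vs between-tumor decomposition uses the one-way random-effects
ANOVA estimators on pooled readings (method of moments, negative
components truncated at zero, unbalanced-design constant n0).  The
percentage of total variance attributable to within-tumor sampling is
reported on the scale of a *tumor-level assessment*: the within component
enters as the sampling variance of a per-tumor mean, σ²_w/n0.  Read
literally as a ratio of raw components the percentage would be constant
in the number of tracks in expectation; on the assessment scale it falls
like 1/k, which is the quantity that makes "how many tracks are enough?"
answerable and reproduces the diminishing return beyond 5–6 tracks
(`scale="reading"` gives the raw ratio).

Between-methods decomposition (area vs electrode HP per tumor) is the
two-factor tumor × method layout with one observation per cell and no
interaction term; the method share is Var(method) / (Var(method) +
Var(tumor)) · 100.

For the tracks sweep, the random strategy adds tracks incrementally
(first k of a max-track plan, as a clinician would insert one more
needle); uniform and radial strategies are re-laid out per k, since the
"first k" of an n-track equal spacing would degenerate to one side of the
tumor.

A normality check (skewness, excess kurtosis, D'Agostino–Pearson omnibus
on residuals from tumor means) is advisory only and never blocks an
analysis.

## Radiation response

Survival after a single dose D follows the LQ model S = exp(−αD − βD²)
(α = 0.3 Gy⁻¹, β = 0.03 Gy⁻², i.e. 48 % at 2 Gy when fully oxygenated).
Oxygen scales the effective dose through the oxygen modification factor
OMF = OER(pO₂)/OER_m with OER_m = 3 and half-saturation K_m = 3 mm Hg;
a single OMF multiplies the dose in both LQ terms (OER_α = OER_β).

Simulated fields are mapped to mm Hg by scaling the field maximum to
100 mm Hg — the scale implied by the 20-bin, 5 mm Hg histogram
convention; `po2_max` exposes it.  Six scenarios are evaluated: uniform
normoxia (60 mm Hg), uniform anoxia (0), uniform moderate hypoxia (5), a
binary profile (cells at ≤ 5 mm Hg represented at 5 mm Hg, the rest at
60 mm Hg, weighted by occupancy — the class representatives are the
moderate-hypoxia and normoxia levels of the uniform cases, since only the
cut is prescribed), the 5 mm Hg histogram (bin centers by default,
`bin_rep="edge"` for left edges), and the fully heterogeneous per-cell
map.  On severely hypoxic fields the heterogeneous curve lies above every
other non-anoxic scenario and hugs the anoxia curve from slightly below;
exact coincidence would require essentially all cells at pO₂ ≈ 0, because
cells at 1–5 mm Hg already have OMF 0.5–0.75, well above the anoxic 1/3.

## Problem sizes and reproducibility

Cohort-scale studies in the test suite and the acceptance script use the
full 6 mm / 100 × 100 grid with 8 tumors per cohort; the suite's shared
bank holds 20 cohorts (160 solved tumors, ≈ 80 s to build) and the
acceptance script regenerates 10 cohorts from its seed.  All randomness
flows from explicit seeds; per-module and per-tumor streams are derived
by hashing (master seed, module name, index), and the experiment driver
writes byte-identical CSV/JSON bundles for identical configurations
(floats rounded to 10 significant digits on output).

## Known limitations

* Two-dimensional sections only; no 3-D vasculature or insertion
  mechanics.
* Chronic hypoxia only: perfusion is a fixed snapshot, so acute
  (fluctuating) hypoxia is out of scope, and validation against markers
  that integrate over time would confound the two.
* No vascular remodeling, treatment effects on vasculature, electrode-
  induced damage, or probe oxygen consumption.
* Absolute oxygen tensions are not predicted; all hypoxia quantities are
  relative, and the mm Hg mapping in the radiation module is a declared
  scale choice, not a calibration.
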