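# Methods

This note documents the models, parameter choices and numerical decisions
behind `ccfd`, and what the synthetic-data experiments do and do not show
about real en-face OCTA data.

## Imaging model and synthetic generator

The generator emulates a compensated 6 × 6 mm en-face choriocapillaris
slab exported at 500 px (12 µm/px; both the grid and the field are
configurable, and all geometric operations consume physical units so the
pixel scale is never baked in).

**Flow image.** A granular background texture models the normal CC
speckle: `0.65 + 0.07·G`, where `G` is standardized Gaussian-smoothed
white noise with a 24 µm decorrelation scale, values on a unit intensity
scale. Flow deficits multiply the local texture by 0.18 (near-black
voids), the dark halo multiplies its annulus by 0.5 (a low-flow zone, not
a set of countable deficits), and additive Gaussian speckle with
sd = 0.02 is applied before clipping to [0, 1]. These constants were
chosen once as a realistic contrast configuration — deficits markedly
darker than the darkest background granules — and are exposed as
parameters for sensitivity work.

**Deficit planting.** Deficits are the lowest-quantile pixels of a
Gaussian-smoothed noise field, selected *per region* (each ring R1…R5 and
the remaining background) so the planted area fraction of every region is
exact to within half a pixel. `GroundTruth` records the recounted
fractions, so tests can compare measurements against exactly known truth.
`deficit_scale_um` is the texture's full decorrelation diameter: the
smoothing kernel uses σ = scale/4, so the autocorrelation
`exp(−d²/4σ²)` has fallen to e⁻⁴ at the stated scale. This definition
makes the texture stationary at the millimetre scale (sub-window planted
fractions stay close to the global fraction for scales ≤ 100 µm) while
still allowing window-filling deficits when the scale is set to several
hundred µm. Per-region quantile thresholds can differ slightly, producing
faint seams in the deficit mask at ring boundaries; the flow *texture* is
continuous across them.

**Lesion geometry.** The MNV is a star-shaped blob (radius modulated by
low-order harmonics) whose pixel count matches the target area exactly;
the default area is 0.52 mm² with a between-eye spread of 0.12 mm² in
cohorts, matching a typical treated type-1 MNV cohort. The dark halo is
the ≤ 150 µm neighbourhood of the MNV, so it touches the lesion boundary
and never overlaps it. Lesions violating the 1 mm scan-edge margin are
rejected. The halo width and its 0.5 attenuation are free parameters: the
intensity distribution of real dark halos is not characterized, so these
are modelling choices, not inferred quantities.

**Shadows.** Large retinal vessels are rendered as straight chords
(width 120 µm, attenuation ≈ 0.5) and drusen as Gaussian bumps
(σ = 90 µm, depth ≤ 0.25). One multiplicative attenuation field acts on
*both* the structure image (smooth baseline ≈ 0.75) and the flow image,
which makes structure-based compensation correct by construction and
testable against the recorded shadow-free flow.

**Cohorts.** Per eye, one lesion geometry is shared by T0/T1/T2 (the ring
configuration must not move between visits). Planted per-ring FD% values
follow `value = μ(ring, visit) + sd·(√ρ·b_eye + √(1−ρ)·ε_visit)` clipped
to [0, 100], giving within-eye correlation ρ (default 0.8). Defaults:
25 eyes, baseline means (50.5, 44.5, 39.7, 36.9, 34.9) % with SDs
(10.2, 9.6, 8.6, 7.5, 6.8) innermost → outermost, and a single planted
mean change of −4.1 points in R1 at T2 (reperfusion adjacent to the
halo); all other ring/visit means are flat.

**What the generator does not emulate:** 3-D OCT volumes, physical
speckle statistics, eye motion and blink artifacts, segmentation errors
in the CC slab, projection artifacts that differ between flow and
structure, or spatially structured (non-stationary) real CC deficit
patterns. Passing tests therefore demonstrate the *pipeline's* geometric
and numerical correctness and its statistical calibration under the
planted model, not clinical validity on device exports.

## Compensation

`comp = flow · S_ref / max(structure_σ, ε)` with σ = 50 µm smoothing,
S_ref the median smoothed structure over non-excluded pixels and ε the
0.02 quantile of the smoothed structure. The output is invariant to
global rescaling of the structure image, never negative, and clipped to
the input dtype's range. Pixels below the floor are flagged `low_signal`
and excluded rather than amplified. The smoothing suppresses structure
granularity but also means sharp shadow edges are only partially
compensated within ~2σ of the edge; vessel shadows are excluded anyway,
and median compensation error on synthetic scans stays ~2% of the unit
range. Published compensation schemes differ in detail (slab pairing,
signal models); this implementation asserts only the shadow-removal
property, verified on synthetic data.

## Ring topography

Exact Euclidean distance transform from MNV ∪ DH, distances converted to
µm, ring k = ⌊d/200⌋ + 1 for d < 1000 µm. Half-open bins resolve
boundary ties deterministically. Rings clipped by the 6 × 6 mm border are
analyzed as-is — the only geometric gate is the 1 mm MNV edge margin —
and the analyzable rings (after vessel/low-signal exclusion) are kept
separate from the geometric label image so geometric areas remain
recoverable.

## Binarization and metrics

Phansalkar thresholding uses a circular window (radius 15 px by default;
the radius is configured in pixels because device export resolutions
vary, so no fixed µm equivalent exists), constants k = 0.25, r = 0.5,
p = 2, q = 10, min-max normalization to [0, 1] over non-excluded pixels,
edge-replicated padding, and "deficit = intensity ≤ threshold" with ties
assigned to deficit. Excluded pixels are omitted from the window mean and
standard deviation (mask-weighted convolution), not zero-filled, and a
constant image is passed through normalization unchanged so the
closed-form threshold applies. The vectorized implementation (FFT
convolutions for the windowed moments) is tested for exact agreement with
an independent per-pixel loop.

Components are clipped at the ring boundary before 8-connected labelling
(each ring is its own region of interest, so a deficit spanning two rings
counts as a clipped fragment in each; connectivity is configurable to 4).
FDa is reported in µm² and the unit is declared in the output header —
agreement with unitless legacy reports is not claimed. The conservation
identity FDn·FDa = total deficit area holds exactly in pixel units.

## Statistics

Paired t-tests are computed in closed form (d = x − y,
t = mean/(sd/√n), df = n − 1, two-sided p) and always reported,
regardless of the Shapiro–Wilk screen (which is informational); a
zero-variance difference vector is flagged degenerate (t = ±∞ or 0).
No multiplicity correction is applied across the 5 rings × 3 metrics × 3
contrasts — matching standard practice for this analysis — but a
Bonferroni-adjusted flag column is emitted as a clearly-labelled extra.
ICC uses the two-way random-effects, absolute-agreement, average-measures
model ICC(A,k) on the graders' MNV areas (mm²), with the 95% CI obtained
from the single-measures F-bounds (Satterthwaite df) stepped up by
Spearman–Brown; the choice of model is this package's, as agreement
metrics are often reported without one. Eyes are treated as independent
units; mixed-effects modelling of fellow eyes is out of scope.

## Problem sizes and numerical choices

- Default grid 500 × 500 px; unit tests run at 128–256 px for speed, with
  the physical parameters unchanged.
- Calibration experiments (type-I rate and power of the R1 T2-vs-T0 test,
  200 cohorts of 25 eyes) run on the planted per-ring FD% values from the
  cohort sampler — the image-rendering stage adds sub-point measurement
  error (planted-recovery MAE ≈ 0.5 points) and is exercised separately,
  so sampling the planted values keeps the Monte-Carlo layer cheap
  without changing what it measures.
- Windowed variance uses `max(E[x²] − m², 0)` to absorb FFT round-off;
  component labelling and counts are integer-exact.
- All randomness derives from named `numpy.random.SeedSequence`
  substreams (per eye, per visit), so identical seeds give bit-identical
  scans and adding eyes does not perturb existing ones.

## Known limitations

- Binarization accuracy is characterized only for deficit textures
  coarser than the threshold window or much finer than it; deficit scales
  comparable to the window radius sit in a transition regime where local
  thresholding is least accurate.
- The compensation model assumes purely multiplicative, band-limited
  shadowing shared by flow and structure; additive projection artifacts
  are not modelled.
- The undefined-metric convention (NaN + flag) propagates to the cohort
  table by dropping the affected ring/visit records; a fully excluded
  ring therefore reduces that eye's paired sample rather than erroring.
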