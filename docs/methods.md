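# Methods

`iolens` models the optics of a pseudophakic human eye as a sequence of
rotationally symmetric conic refracting surfaces and optimizes the
intraocular lens (IOL) inside it with a real-coded genetic algorithm (GA).
This note records the model, its conventions, the numerical choices, and the
limits of what the packaged checks demonstrate.

## Optical model

A prescription is an ordered surface list (cornea, aqueous chamber, aperture
stop, three IOL/crystalline-lens surfaces, curved retina), each surface a
conic of revolution

    z(x) = c x^2 / (1 + sqrt(1 - (1+K) c^2 x^2)),

with curvature `c` (mm^-1, positive when the centre of curvature lies on the
image side), conic constant `K` (0 sphere, -1 paraboloid), an axial gap to
the next vertex, a semi-aperture, and the refractive index of the following
medium. Light travels in +z; all lengths are in millimetres. Media are
homogeneous; the gradient-index crystalline lens of the full physiological
model is deliberately out of scope because the transcribed design tables
specify homogeneous named media. Default indices (config-overridable via a
media table): cornea 1.376, aqueous/vitreous humor 1.336, IOL acrylic/PMMA
1.4918, equivalent homogeneous crystalline lens 1.42, all taken at the
photopic peak 555 nm. No dispersion is modelled.

The packaged prescriptions transcribe the published design tables. The "Y
Radius" columns are read as **curvature in mm^-1** (0.1287 mm^-1 is exactly
the 7.77 mm anterior corneal radius of the standard schematic eye); that
reading is applied uniformly. Conic constants are only printed for the two
aspheric IOL surfaces; unprinted conics are 0. The `initial_eye` fixture
follows its printed source verbatim even though the values are suspect (a
plane anterior lens surface, and a posterior curvature that actually matches
the standard *anterior* lens curvature 1/12.40 mm); the consequences are
discussed under *Known limitations*. Crystalline-lens semi-apertures are not
printed; 4.0 mm is used (the natural lens is ~9 mm wide, so this adds no
artificial vignetting).

## Refractive error

M "degrees" of myopia and N of astigmatism (100 degrees = 1 dioptre) map to
two scalar modifiers,

    cornea = (N/100) * 0.1,      humor = (M + N/2)/100 * 0.37,

which carry no units in their source form. Which surface parameter they
perturb is convention-selectable (`error_mode`):

- `axial` (default) reads both as millimetres added to the corneal and
  aqueous-depth thicknesses. The 0.37 coefficient is the classical
  axial-length-to-refraction ratio (~0.37 mm of axial elongation per
  dioptre), and this reading reproduces the order of magnitude of the
  reported third-order aberrations of the myopic study eye; for the
  550/175-degree study condition it lengthens the eye by 2.53 mm.
- `curvature` reads both as mm^-1 added to the cornea and aqueous surface
  curvatures. For the study condition this more than doubles corneal power
  and bends the aqueous surface to R = 0.42 mm, vignetting most of the
  pupil; it is retained for completeness.
- `hybrid` steepens the cornea (mm^-1) and lengthens the aqueous depth (mm).

Astigmatism is scalar — a rotationally symmetric perturbation with no
cylinder axis. All modes are additive, so perturbations invert exactly.

## Ray tracing

Real rays are intersected with each conic in closed form (stable quadratic
on the implicit surface `c r^2 - 2 s + (1+K) c s^2 = 0`; analytic plane for
|c| < 1e-12; candidate roots are validated against the single-valued sag
branch to 1e-8 relative). Refraction is vector Snell. A ray that misses a
surface's real extent, lands outside its semi-aperture (tolerance 1e-9 mm),
or undergoes total internal reflection is flagged vignetted with the
surface index, so launched rays are always accounted for. Zero-thickness
gaps (the stop sits on the IOL's front vertex) accept the t = 0 hit.

Pupil sizes of 5/6 mm are realised by scaling the launched beam so its
paraxial height at the stop equals the requested pupil radius; the stop's
3 mm semi-aperture from the design tables is never edited. Fans sample the
pupil on a hexapolar grid (default 10 rings, 331 rays) or a square raster.
Off-axis fans are centred on the real chief ray, found by secant iteration
on entrance height (tolerance 1e-10 mm, max 50 iterations) from a paraxial
seed. The paraxial path is the standard y-nu recursion; an afocal system is
an explicit error unless explicitly allowed.

## Image-quality metrics

- **RMS spot radius**: sqrt(mean[(xi-x0)^2 + (yi-y0)^2]) over the image
  intersections of a fan, reference point = centroid by default (chief-ray
  mode available). Vignetted rays are excluded and counted.
- **Seidel sums**: per-surface S_I..S_V from the refraction invariants, with
  the conic contribution `K c^3 (n'-n) y^4` (the fourth-order departure from
  the osculating sphere) and its chief-ray-weighted companions. Sign
  convention: a single positive refracting surface contributes positive S_I;
  the convention string is recorded in every summary. Spherical aberration
  is reported as SA = S_I; tangential coma as TCO = 3 S_II with the chief
  ray scaled to the requested field angle (default 5 degrees — the source
  analysis states no field angle, and coma vanishes on axis, so a small
  conventional field is required).
- **Geometric MTF**: |mean exp(-2 pi i f u)| over the spot coordinate along
  the chosen orientation — the characteristic function of the ray-based
  point spread — with frequencies in cycles/mm (lp/mm). Exactly 1 at f = 0,
  bounded in [0, 1], translation invariant. No diffraction.
- **Improvement rate**: aberration mode D = (|Y|-|X|)/|Y| x 100 (smaller is
  better), resolution mode D = (X-Y)/X x 100 (larger is better, used for
  MTF). These conventions reproduce every self-consistent row of the
  published comparison tables from their own printed inputs; the packaged
  reference readings live in `iolens.reference_data` and are inputs, never
  asserted as outputs of this tracer.

Numerical equality with the published third-order magnitudes is *not*
claimed: those came from proprietary design software under unstated
normalization and perturbation settings. Only arithmetic identities and
direction-of-effect comparisons are meaningful here.

## Genetic algorithm

The design vector holds six genes: anterior IOL curvature and conic,
anterior and mid thicknesses, posterior curvature and conic. Bounds bracket
all transcribed designs: curvature in [-0.2, 0.2] mm^-1, conic in [-30, 5],
thickness in [0.05, 2.5] mm. A candidate's merit is fin = w1|SA| + w2|TCO|
evaluated from the Seidel sums at the configured field (single field by
default), with unit weights. Defaults follow the published run: population
100, 70 generations, crossover rate 0.8, mutation rate 0.2.

Selection is roulette-wheel on the reflected fitness
`(fit_max + fit_min) - fin(i)`, normalised so lower merit gets a larger
slice; a degenerate population gets a uniform wheel. Crossover is the convex
blend `z = beta x + (1-beta) y` (bounds-preserving by construction); each
pairing yields the two symmetric blends. Mutation steps each gene by
`+- beta Delta` (Delta defaults to 5% of the gene range) and clamps to
bounds; the published trigger condition "mutate when alpha > p_m" (an 80%
trigger rate at p_m = 0.2) is implemented literally as the default
(`as_published`), with the conventional `standard` reading (alpha < p_m)
selectable. Elitism (default 1, not part of the source algorithm, set 0 to
match it literally) makes the best merit non-increasing and hence testable.
A gene mask can freeze the conic genes for designs where they are fixed.
Draw order per generation is documented in the module docstring so seeded
runs are bit-reproducible.

An optional damped-least-squares polish (Levenberg iteration on the residual
vector (sqrt(w1) SA, sqrt(w2) TCO) with central-difference Jacobian, bounded
steps, accept-only-if-better) refines the generation best; it provably never
increases the merit and falls back to its input on numerical failure.

The GA scores candidates through the paraxial/Seidel path only (~0.06 ms per
evaluation), so "infeasible" means no candidate has a finite, non-degenerate
paraxial solution. Spot and MTF metrics are computed by real tracing when a
design is analysed.

## Problem sizes in the packaged checks

The statistical suite uses 1e5 selection draws, 1e4 operator draws, a
50-generation elitism run, and ten seeded recovery runs at population 50 for
50 generations (~2500 merit evaluations each); the Gaussian-MTF oracle uses
1e5 samples, restricted to frequencies where the closed-form modulation
stays >= 0.45 so that a 1% relative tolerance clears the Monte-Carlo noise
floor (~2e-3 absolute). Selection frequencies are checked with the aggregate
chi-square across wheel slots at the 0.997 quantile — the multi-category
equivalent of a per-slot 3-sigma band without its multiplicity false alarms.

## Known limitations

- The verbatim `initial_eye` is strongly under-powered (paraxial image
  24.7 mm behind the lens, retina at 16.27 mm), so axial-elongation myopia
  moves its retina *toward* focus and its on-axis RMS improves rather than
  degrades; its SA still worsens in the expected direction. A physiological
  crystalline lens would restore the expected RMS ordering, but the fixture
  follows the printed source.
- Under this tracer the transcribed 6 mm GA design shows slightly larger
  tangential coma than the 6 mm built-in design (both by Seidel sums and by
  real tangential fans), while its RMS spot and MTF are better — the
  published coma ordering at 6 mm is not reproduced, and since both designs
  share the anterior segment verbatim, no pupil or field convention can
  flip it. The 5 mm coma ordering does reproduce.
- At the 6 mm analysis pupil, the IOL's 2.04 mm front semi-aperture
  physically vignettes the outer third of the stop; metrics are computed
  over surviving rays and the vignetted count is reported.
- No diffraction, polarization, dispersion, accommodation, toric surfaces,
  or Zernike/wavefront input.
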