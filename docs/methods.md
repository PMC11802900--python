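# Methods

This note documents the models implemented in `lepivision`, the defaults
chosen where the underlying literature leaves a choice open, and what the
synthetic-data generators do and do not emulate.

## Spectra

All computation happens on a working grid of 300–700 nm at 1 nm (inclusive
endpoints), matching the range over which wing reflectance is typically
measured and over which the bundled D65 table and pigment templates are
defined. Reflectance is stored as a fraction in [0, 1]; readers divide by
100 behind a `percent` flag. Resampling is linear interpolation with no
extrapolation by default (end-value clamping on request).

Smoothing is a centred moving average with window = span × grid length
(rounded odd), edges padded with the nearest value so constant spectra are
preserved exactly; a lowess mode is available. The smoothing span actually
used ahead of published reflectance figures is rarely reported; the default
span of 0.2 is a conventional choice and downstream JNDs are insensitive to
it at the 0.01-JND scale because quantum catches integrate over ~400 points.
Negative reflectances (spectrometer noise) are clipped to zero after
smoothing and the clip count logged.

Group aggregation is the pointwise arithmetic mean and sample standard
deviation (ddof = 1; zero for singleton groups).

## Pigment templates

Rhodopsin absorbance is the A1-chromophore nomogram: alpha band

    S(x) = 1 / [exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D],  x = λmax/λ

with A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104 and
a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940), plus an optional Gaussian beta
band 0.26·exp(−((λ−(189+0.315·λmax))/(−40.5+0.195·λmax))²). Butterfly
pigments use a 3-hydroxy chromophore, but fitted peaks are insensitive to
the A1/A3 distinction at the 1-nm scale.

Normalization divides by the template's peak over the full 300–700 nm
range, **not** over the evaluation grid, so the template is the same
function of wavelength on any fit window. The beta band defaults to ON for
blue/LW pigments and OFF for UV pigments (whose peak lies inside the alpha
band).

A note on regularity: the short-wavelength limb of the alpha band steepens
as λmax decreases, so the template's sensitivity to a 1-nm peak shift grows
toward the UV (max-norm change per nm ≈ 0.017 at λmax 530 but ≈ 0.036 at
355). Fits remain well-conditioned; this only means uniform Lipschitz
bounds on the template family must be quoted per spectral region.

## Peak estimation

`PigmentTemplateModel` minimizes Σ (s(λ) − a·T(λ; λmax))² over the fit
range; the amplitude a is solved in closed form (non-negative least
squares) at each candidate peak, and λmax by a 1-nm grid search followed by
bounded scalar refinement to 0.01 nm — deterministic, no starting-point
sensitivity. Estimates within one grid step of the search boundary are
flagged. Fewer than five points in the fit range is an error.

Difference spectra (recovered minus partially bleached eyeshine state) are
taken as directly proportional to rhodopsin absorbance and peak-normalized;
metarhodopsin photoproduct decay and tapetal double-pass are not modelled,
mirroring the approximation under which such measurements are interpreted.
A flat difference (identical states) cannot be normalized and is an error.

Pupillary spectral sensitivity is the normalized reciprocal of the
criterion quantum flux (default criterion: a 7% decrease in eyeshine
reflectance) on the 340–580 nm / 10 nm stimulus grid. The mixture model
fits the LW template over 490–580 nm first, subtracts its alpha-band tail
from the 340–380 nm window, then fits the UV template there; both
components are alpha-band-only, because an LW beta band (centred near
356 nm for a 530 nm pigment) would sit inside the UV window and be
double-counted against the UV amplitude and against the blue residual. The
intermediate 380–490 nm region is excluded from fitting; `blue_residual`
reports sensitivity minus fitted mixture over 390–480 nm, where a
systematically positive residual indicates a blue-sensitive receptor not
captured by the two fitted pigments.

## Opsin tuning sites

Blue-opsin λmax class is a pure function of the residue at site 195 of the
blue-opsin alignment: Y → 431 nm, F → 435 nm (the Y195F substitution is a
~4 nm red shift); other residues and gaps are reported as unknown, since
the substitution data cover only those two states. Site 135 has a
documented tuning effect but no usable rule, so its residue is reported
without interpretation. Site numbers map to alignment columns through an
identity offset by default, overridable when an alignment's numbering
differs. Pairwise identity counts columns where both residues are non-gap;
gap-containing columns are excluded from the denominator.

## Receptor-noise model

Quantum catches are trapezoidal integrals Q_i = ∫ R·I·S_i dλ on the 1-nm
grid. von Kries adaptation is always applied: f_i = ln(Q_i/Q_i^bg) against
the background's catches (in the mimicry analysis, the mean brown-patch
reflectance). The bundled D65 illuminant (standard CIE 10-nm relative SPD)
is converted from energy to photon units by multiplying by λ and
renormalizing — the model is invariant to illuminant scale, so only the
photon-unit *shape* matters.

Chromatic distance is the receptor-noise-limited closed form for 2, 3 or 4
receptors (the general-n noise-weighted line element restricted to the
chromatic subspace serves as a brute-force oracle in the tests; the closed
forms agree with it to 1e-9). Receptor noises are either per-receptor
Weber fractions or density-scaled from a single Weber fraction on a
reference receptor, e_i = ω_ref·√(η_ref/η_i); the reference defaults to the
longest-wavelength receptor, the convention of the established
colour-analysis tooling this package is designed to be comparable with.

The achromatic distance is |Δf_A|/ω_A through a single luminance channel:
the 530 nm receptor for the butterfly, a double cone modelled as the bare
563 nm (UV bird) or 571 nm (violet bird) pigment template. Whether a real
butterfly's luminance channel is the raw 530-nm catch or a weighted
receptor sum is not settled; the single-channel reading is implemented.
Avian sensitivities are bare pigment templates at the published peaks, with
no oil-droplet or ocular-media filtering.

Chromaticity coordinates map relative catches q_i = Q_i/ΣQ onto a regular
simplex centred at the origin (Maxwell triangle with unit circumradius,
short receptor at top; tetrahedron with circumradius 0.75, UV vertex on
+z). Coordinates are display-only and never feed JND computations.

Preset parameters (peaks, densities, Weber fractions) for the three
modelled systems are in `make_visual_system`'s docstring; custom systems
load from YAML.

## Bootstrapped colour distances

Each replicate resamples both groups with replacement at their original
sizes, forms each group's centroid catch as the per-receptor geometric mean
(arithmetic mean of f), and measures the chromatic and achromatic distance
between centroids. The reported point estimate is the mean of the replicate
distribution (median available); the interval is the simple percentile CI
(bias-corrected intervals deliberately not implemented — the simple
percentile is what the comparable tooling reports). Defaults: 1000
replicates, α = 0.05. One integer seed drives a single generator; within
each replicate the group-A indices are drawn before the group-B indices,
making results bit-reproducible.

Known limitation: the percentile interval undercovers for small groups —
nested simulation puts coverage near 92% at 25 spectra per group, reaching
the nominal ~95% by 50 per group. The calibration test therefore runs at
n = 50; results on groups of ~25 should be read with that slight
anti-conservatism in mind.

## Synthetic data

The generators produce data with the structure the analysis assumes, at
realistic sizes (group sizes 25/35 orange, 23/27 white, 29 brown in the
default pipeline configuration):

* **Wing patches.** Oranges: low plateau 0.05 rising logistically
  (midpoint 600 nm, steepness 12 nm) to 0.55, with the second orange's
  tail depressed by 0.08 above ~620 nm — so the two classes overlap
  through 300–600 nm and diverge beyond, the geometry that makes the
  long-wavelength-blind butterfly's discrimination hard. Whites ~0.70
  flat, browns 0.08 flat. These levels are modelling choices reproducing
  the described qualitative geometry, not measurements; all are
  overridable. Noise is multiplicative Gaussian per wavelength point
  (default sd 0.05), clipped to [0, 1] with the clip count logged.
* **Difference spectra / dark spectra.** Template plus additive Gaussian
  noise, renormalized.
* **Pupillary datasets.** Criterion flux = reciprocal of
  (uv_amplitude·T_UV + T_LW + optional Gaussian blue bump) with
  multiplicative noise, on the 25-point stimulus grid.
* **Opsin alignments.** Uniform random sequences; derived sequences mutate
  exactly k positions (tuning sites protected) for controlled identity,
  and requested residues are placed at site 195 (and optionally 135).

What the generators do **not** emulate: within-individual correlation
between repeated measurements (spectra are drawn independently, so
bootstrap CIs on synthetic groups are, if anything, slightly narrow),
specular glare, instrument drift, or any attempt to match the absolute
reflectance levels of real *Adelpha* wings. Passing tests on synthetic data
therefore validate the estimators and the model algebra under the assumed
noise structure — they are not evidence about real wings.

## Problem sizes and determinism

The default test suite and the acceptance script run at the sizes above:
401-point spectra, 25-point pupil grids, 1000 bootstrap replicates, 500
outer repetitions for the coverage check, 200 replicates for the bias
check. Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); identical configuration and seed give
byte-identical output tables, and the pipeline writes a manifest with the
config hash and seed alongside every run.
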