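# lepivision

Receptor-noise colour-vision modelling for butterflies and birds.

Mimetic butterflies converge on near-identical wing colour patterns; whether a
butterfly can nonetheless tell a conspecific from its co-mimic — and whether a
bird predator can tell them apart at all — is a question about the *viewer's*
visual system, not just the wings. `lepivision` implements the full modelling
chain needed to answer it for a trichromatic nymphalid butterfly
(*Adelpha fessonia*, photoreceptor peaks 355/431/530 nm) and two tetrachromatic
avian systems (a UV-sensitive blue-tit-like bird, 372/449/502/563 nm, and a
violet-sensitive chicken-like bird, 418/453/507/571 nm):

1. **Pigment characterization.** Rhodopsin absorbance is modelled with the
   standard A1 nomogram template T(λ; λ_max). Peaks are estimated by least
   squares from epi-microspectrophotometric difference spectra
   (`PigmentTemplateModel`) or from pupillary spectral sensitivities, the
   reciprocal of criterion quantum fluxes, via a two-pigment UV + LW mixture
   fit with the blue region excluded and exposed as a residual
   (`PigmentMixtureModel`).
2. **Sequence-based tuning.** Blue-opsin λ_max class is predicted from the
   residue at spectral tuning site 195 of an amino-acid alignment:
   Y → 431 nm, F → 435 nm (`predict_blue_peak`), with pairwise identity
   reporting.
3. **Perceptual modelling.** Quantum catches
   Q_i = ∫ R(λ) I(λ) S_i(λ) dλ under D65, von Kries adaptation to a
   background (f_i = ln Q_i/Q_i^bg), receptor-noise-limited chromatic
   distances ΔS (closed forms for di-, tri- and tetrachromats), luminance
   distances ΔL = |Δf_A|/ω_A, and Maxwell-triangle / tetrahedral
   chromaticity coordinates (`ReceptorNoiseModel`).
4. **Statistics.** Bootstrapped colour distances between stimulus groups
   (resample groups, compare centroid catches, 1000 replicates, 95%
   percentile CI) with threshold assessment against the 1-JND criterion
   (`bootcoldist`).
5. **Synthetic data.** Generators for every input class — wing reflectance
   patches (two overlapping-then-diverging oranges, whites, browns),
   noisy difference spectra, pupillary criterion-flux datasets, opsin
   alignments — so the whole pipeline runs and is tested without any
   measured data.

In the receptor-noise model, the chromatic distance between two stimuli with
adapted log signals f and f′ is the noise-weighted length of Δf = f − f′
restricted to the intensity-invariant subspace; for a trichromat

ΔS² = [e₁²(Δf₃−Δf₂)² + e₂²(Δf₃−Δf₁)² + e₃²(Δf₂−Δf₁)²] / [(e₁e₂)² + (e₁e₃)² + (e₂e₃)²]

with receptor noises e_i taken from Weber fractions directly or scaled from a
reference receptor by relative density, e_i = ω √(η_ref/η_i). Distances are in
just-noticeable differences (JND); 1 JND is the nominal laboratory threshold.

## Worked example

Fit the long-wavelength rhodopsin peak from a synthetic difference spectrum
generated at 530 nm:

```python
from lepivision import gen_difference_spectrum, fit_lambda_max

s = gen_difference_spectrum(530.0, noise_sd=0.02, seed=1)
res = fit_lambda_max(s, search=(400, 650))
print(res.summary())
```

```
Pigment template fit
--------------------
lambda_max              529.91 nm
amplitude               0.9873
residual SS          1.302e-01
fit range           300-700 nm (401 points)
search interval     400-650 nm
```

The estimate lands within 0.1 nm of the generating peak: with 2% additive
noise on a 1-nm grid, the template fit pins the peak to sub-nanometre
precision.

Run the full mimicry analysis on synthetic wings (group sizes mirroring a
typical reflectance dataset: 25/35 orange, 23/27 white measurements and a
29-spectrum brown background):

```python
from lepivision import RunConfig, run_full_analysis

bundle = run_full_analysis(RunConfig(output_dir="out", seed=1))
print(bundle["jnd_table"].round(3).to_string(index=False))
```

```
 group_a  group_b visual_system    channel  mean_jnd  ci_low  ci_high vs_threshold_1
orange_A orange_B      fessonia  chromatic     0.177   0.161    0.194          below
orange_A orange_B      fessonia achromatic     0.153   0.143    0.163          below
 white_A  white_B      fessonia  chromatic     0.015   0.003    0.030          below
 white_A  white_B      fessonia achromatic     0.011   0.001    0.023          below
orange_A orange_B       uv_bird  chromatic     0.422   0.405    0.440          below
orange_A orange_B       uv_bird achromatic     0.330   0.318    0.342          below
 white_A  white_B       uv_bird  chromatic     0.011   0.003    0.023          below
 white_A  white_B       uv_bird achromatic     0.010   0.002    0.020          below
orange_A orange_B   violet_bird  chromatic     0.840   0.809    0.871          below
orange_A orange_B   violet_bird achromatic     0.308   0.298    0.318          below
 white_A  white_B   violet_bird  chromatic     0.017   0.003    0.040          below
 white_A  white_B   violet_bird achromatic     0.009   0.001    0.017          below
```

Every comparison sits below the 1-JND threshold: the synthetic co-mimics are
predicted indistinguishable to butterfly and birds alike, chromatically and
achromatically, with the violet-sensitive bird coming closest on the orange
patches (whose reflectances diverge only above 600 nm, where the butterfly's
530 nm pigment has little sensitivity but the bird's 571 nm cone still
catches photons).

A command-line interface mirrors the library (`lepivision simulate`,
`process-spectra`, `fit-msp`, `fit-pupil`, `opsin-sites`, `jnd`, `colspace`,
`run-all`); `lepivision run-all --config cfg.yaml` writes processed spectra,
per-system chromaticity coordinate tables, the JND table above and a
provenance manifest.

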