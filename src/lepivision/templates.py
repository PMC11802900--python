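"""Visual-pigment absorbance templates (A1 nomogram).

A rhodopsin absorbance spectrum is well described by a universal template
parameterized only by its wavelength of peak absorbance, λmax.  The closed
form used here is the standard A1-chromophore nomogram: an alpha band

    S(x) = 1 / [exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D]

with x = λmax/λ, A = 69.7, B = 28, C = -14.9, D = 0.674,
a = 0.8795 + 0.0459 exp(-(λmax - 300)^2 / 11940), b = 0.922, c = 1.104,
plus an optional Gaussian beta band

    S_beta(λ) = 0.26 exp(-((λ - λmβ) / bβ)^2)

with λmβ = 189 + 0.315 λmax and bβ = -40.5 + 0.195 λmax.  Butterfly
pigments use a 3-hydroxy chromophore, but fitted peaks are insensitive to
the A1/A3 distinction at the 1-nm scale this package works at.

The beta band sits in the UV; it is included by default for blue and
long-wavelength pigments and should be disabled for UV pigments, whose
peak lies inside the alpha band itself.
"""

from __future__ import annotations

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum

# alpha-band constants of the A1 nomogram
_A = 69.7
_B = 28.0
_C = -14.9
_D = 0.674
_b = 0.922
_c = 1.104


_REF_GRID = np.arange(300.0, 701.0, 1.0)


def _raw(lambda_max: float, grid: np.ndarray, include_beta_band: bool) -> np.ndarray:
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    if include_beta_band:
        lam_beta = 189.0 + 0.315 * lambda_max
        b_beta = -40.5 + 0.195 * lambda_max
        return alpha + 0.26 * np.exp(-(((grid - lam_beta) / b_beta) ** 2))
    return alpha


def template_values(lambda_max: float, grid, include_beta_band: bool = True) -> np.ndarray:
    """Peak-normalized template samples on ``grid`` as an ndarray.

    Normalization uses the peak over the full 300-700 nm range (not over
    ``grid``), so the template is the same function of wavelength whatever
    window it is evaluated on.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise ValueError(f"lambda_max must be within [300, 700] nm, got {lambda_max}")
    grid = np.asarray(grid, dtype=float)
    peak = _raw(lambda_max, _REF_GRID, include_beta_band).max()
    return _raw(lambda_max, grid, include_beta_band) / peak


def pigment_template(
    lambda_max: float,
    grid=None,
    include_beta_band: bool = True,
    label: str | None = None,
) -> Spectrum:
    """Peak-normalized pigment absorbance template as a Spectrum.

    Parameters
    ----------
    lambda_max : float
        Wavelength of peak absorbance in nm, within [300, 700].
    grid : array, optional
        Wavelength grid (nm); defaults to 300-700 nm at 1 nm.
    include_beta_band : bool
        Add the Gaussian beta band before renormalizing.  Disable for UV
        pigments.
    """
    if grid is None:
        grid = DEFAULT_GRID
    vals = template_values(lambda_max, grid, include_beta_band)
    return Spectrum(
        np.asarray(grid, dtype=float),
        vals,
        kind="sensitivity",
        label=label if label is not None else f"T{lambda_max:g}",
        normalized=True,
    )
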