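"""Photopigment λmax estimation from spectra.

Two measurement routes are modelled:

* **Difference spectra** (epi-microspectrophotometry or expressed-pigment
  dark spectra): the spectrum is fitted by least squares to a single
  pigment template with free peak and amplitude
  (:class:`PigmentTemplateModel`).

* **Pupillary spectral sensitivity** (optophysiology): a criterion-flux
  dataset is inverted to a sensitivity S(λ) = 1/F(λ) and fitted by a
  two-pigment mixture, a UV template over its own wavelength window and a
  long-wavelength template over another, with the intermediate blue region
  excluded from fitting and exposed as a residual
  (:class:`PigmentMixtureModel`).

Both models follow the Model/Results convention: construct from data,
``fit()`` returns a results object with estimates, diagnostics, and a
``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra import DEFAULT_GRID, GridMismatchError, Spectrum
from .templates import pigment_template, template_values


class FlatSpectrumError(ValueError):
    """A flat (constant) spectrum cannot be peak-normalized."""


def difference_spectrum(recovered: Spectrum, bleached: Spectrum) -> Spectrum:
    """Estimate a rhodopsin absorbance spectrum from a partial bleach.

    The pointwise difference between the recovered and partially bleached
    states is taken as directly proportional to the pigment absorbance and
    peak-normalized to 1.  Photoproduct decay and tapetal double-pass are
    not modelled.
    """
    if recovered.wavelengths.shape != bleached.wavelengths.shape or not np.allclose(
        recovered.wavelengths, bleached.wavelengths
    ):
        raise GridMismatchError("recovered and bleached spectra must share a grid")
    diff = recovered.values - bleached.values
    if np.ptp(diff) == 0:
        raise FlatSpectrumError("difference spectrum is flat; cannot peak-normalize")
    m = diff.max()
    if m <= 0:
        raise FlatSpectrumError("difference spectrum has non-positive maximum")
    return Spectrum(
        recovered.wavelengths,
        diff / m,
        kind="absorbance",
        label=f"diff({recovered.label})",
        normalized=True,
    )


def _ls_amplitude(y: np.ndarray, t: np.ndarray) -> float:
    """Closed-form nonnegative least-squares amplitude for y ~ a*t."""
    denom = float(t @ t)
    if denom == 0:
        return 0.0
    return max(0.0, float(y @ t) / denom)


def _rss_at(lam: float, wl: np.ndarray, y: np.ndarray, beta: bool) -> tuple[float, float]:
    t = template_values(lam, wl, include_beta_band=beta)
    a = _ls_amplitude(y, t)
    r = y - a * t
    return float(r @ r), a


# ---------------------------------------------------------------------------
# single-template fit


@dataclass
class PigmentTemplateResults:
    """Results of a single-template least-squares λmax fit."""

    lambda_max_: float
    scale_: float
    rss: float
    fit_range: tuple[float, float]
    search: tuple[float, float]
    grid_step: float
    nobs: int
    on_boundary: bool
    include_beta_band: bool

    def fittedvalues(self, grid=None) -> Spectrum:
        g = DEFAULT_GRID if grid is None else grid
        t = pigment_template(self.lambda_max_, g, self.include_beta_band)
        return t.with_values(self.scale_ * t.values, normalized=False)

    def to_dict(self) -> dict:
        return {
            "lambda_max_nm": self.lambda_max_,
            "scale": self.scale_,
            "rss": self.rss,
            "fit_range_nm": list(self.fit_range),
            "search_nm": list(self.search),
            "grid_step_nm": self.grid_step,
            "nobs": self.nobs,
            "on_boundary": self.on_boundary,
        }

    def summary(self) -> str:
        lines = [
            "Pigment template fit",
            "--------------------",
            f"lambda_max          {self.lambda_max_:10.2f} nm",
            f"amplitude           {self.scale_:10.4f}",
            f"residual SS         {self.rss:10.3e}",
            f"fit range           {self.fit_range[0]:g}-{self.fit_range[1]:g} nm "
            f"({self.nobs} points)",
            f"search interval     {self.search[0]:g}-{self.search[1]:g} nm",
        ]
        if self.on_boundary:
            lines.append("WARNING: minimum on search boundary")
        return "\n".join(lines)


class PigmentTemplateModel:
    """Least-squares fit of a pigment template to an absorbance spectrum.

    Minimizes sum over the fit range of (s(λ) - a T(λ; λmax))^2 over λmax
    (coarse grid search then bounded refinement to 0.01 nm) with the
    amplitude a solved in closed form at each candidate peak.

    Parameters
    ----------
    spectrum : Spectrum
        Measured (typically normalized) absorbance or sensitivity.
    fit_range : (lo, hi), optional
        Wavelength window used for the fit; defaults to the full spectrum.
    include_beta_band : bool
        Whether the template carries a beta band (default True; disable
        for UV pigments).
    """

    def __init__(
        self,
        spectrum: Spectrum,
        fit_range: tuple[float, float] | None = None,
        include_beta_band: bool = True,
    ):
        self.spectrum = spectrum
        if fit_range is None:
            fit_range = (float(spectrum.wavelengths[0]), float(spectrum.wavelengths[-1]))
        self.fit_range = fit_range
        self.include_beta_band = include_beta_band
        sub = spectrum.restrict(*fit_range)
        if len(sub) < 5:
            raise ValueError(
                f"fewer than 5 points in fit range {fit_range}; cannot fit"
            )
        self._wl = sub.wavelengths
        self._y = sub.values

    def fit(self, search: tuple[float, float] = (300.0, 700.0), step: float = 1.0,
            xtol: float = 0.01) -> PigmentTemplateResults:
        lo, hi = search
        if not (300.0 <= lo < hi <= 700.0):
            raise ValueError(f"search interval must lie within [300, 700] nm, got {search}")
        beta = self.include_beta_band
        candidates = np.arange(lo, hi + step / 2, step)
        rss = np.array([_rss_at(l, self._wl, self._y, beta)[0] for l in candidates])
        i = int(np.argmin(rss))
        # bounded local refinement around the coarse winner
        blo = candidates[max(0, i - 1)]
        bhi = candidates[min(len(candidates) - 1, i + 1)]
        if bhi > blo:
            res = minimize_scalar(
                lambda l: _rss_at(l, self._wl, self._y, beta)[0],
                bounds=(blo, bhi), method="bounded",
                options={"xatol": xtol},
            )
            lam = float(res.x)
        else:
            lam = float(candidates[i])
        best_rss, amp = _rss_at(lam, self._wl, self._y, beta)
        on_boundary = lam - lo < step or hi - lam < step
        if on_boundary:
            warnings.warn(
                f"lambda_max estimate {lam:.2f} nm is on the search boundary {search}",
                stacklevel=2,
            )
        return PigmentTemplateResults(
            lambda_max_=lam,
            scale_=amp,
            rss=best_rss,
            fit_range=self.fit_range,
            search=(lo, hi),
            grid_step=step,
            nobs=len(self._y),
            on_boundary=on_boundary,
            include_beta_band=beta,
        )


def fit_lambda_max(
    s: Spectrum,
    search: tuple[float, float] = (300.0, 700.0),
    step: float = 1.0,
    fit_range: tuple[float, float] | None = None,
    include_beta_band: bool = True,
) -> PigmentTemplateResults:
    """Functional wrapper: fit a single pigment template to ``s``."""
    return PigmentTemplateModel(s, fit_range, include_beta_band).fit(search, step)


# ---------------------------------------------------------------------------
# pupillary sensitivity


@dataclass(frozen=True)
class PupilDataset:
    """Criterion-flux dataset from pupillary-response optophysiology.

    ``criterion_flux`` is the quantum flux (photons/s) producing the
    criterion response (a fractional decrease in eyeshine reflectance,
    default 7%) at each stimulus wavelength.
    """

    wavelengths: np.ndarray
    criterion_flux: np.ndarray
    criterion: float = 0.07

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        fx = np.asarray(self.criterion_flux, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "criterion_flux", fx)
        if wl.size != fx.size:
            raise ValueError("wavelengths and criterion_flux differ in length")
        if np.any(fx <= 0):
            raise ValueError("criterion fluxes must be strictly positive")
        if not 0 < self.criterion < 1:
            raise ValueError("criterion must be a fraction in (0, 1)")


def read_pupil_dataset(path: str | Path) -> PupilDataset:
    """Read a three-column (wavelength_nm, criterion_flux, criterion) table."""
    from .spectra import _read_table  # shares the tolerant delimited parser

    table = _read_table(Path(path))
    if table.shape[1] < 3:
        raise ValueError(f"{path}: pupil dataset needs 3 columns")
    return PupilDataset(table[:, 0], table[:, 1], float(table[0, 2]))


def flux_to_sensitivity(d: PupilDataset) -> Spectrum:
    """Spectral sensitivity as the normalized reciprocal of criterion flux."""
    s = 1.0 / d.criterion_flux
    return Spectrum(
        d.wavelengths, s / s.max(), kind="sensitivity",
        label="pupillary sensitivity", normalized=True,
    )


# ---------------------------------------------------------------------------
# two-pigment mixture fit


@dataclass
class PigmentMixtureResults:
    """Results of the two-window UV + LW mixture fit."""

    lambda_uv_: float
    lambda_lw_: float
    amplitude_uv_: float
    amplitude_lw_: float
    rss: float
    uv_range: tuple[float, float]
    lw_range: tuple[float, float]
    excluded_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "lambda_uv_nm": self.lambda_uv_,
            "lambda_lw_nm": self.lambda_lw_,
            "amplitude_uv": self.amplitude_uv_,
            "amplitude_lw": self.amplitude_lw_,
            "rss": self.rss,
            "uv_range_nm": list(self.uv_range),
            "lw_range_nm": list(self.lw_range),
            "excluded_range_nm": list(self.excluded_range),
        }

    def fittedvalues(self, grid) -> np.ndarray:
        g = np.asarray(grid, dtype=float)
        tuv = template_values(self.lambda_uv_, g, include_beta_band=False)
        tlw = template_values(self.lambda_lw_, g, include_beta_band=False)
        return self.amplitude_uv_ * tuv + self.amplitude_lw_ * tlw

    def summary(self) -> str:
        return "\n".join([
            "Two-pigment mixture fit",
            "-----------------------",
            f"UV peak             {self.lambda_uv_:10.2f} nm "
            f"(amplitude {self.amplitude_uv_:.4f}, window {self.uv_range[0]:g}-{self.uv_range[1]:g} nm)",
            f"LW peak             {self.lambda_lw_:10.2f} nm "
            f"(amplitude {self.amplitude_lw_:.4f}, window {self.lw_range[0]:g}-{self.lw_range[1]:g} nm)",
            f"residual SS         {self.rss:10.3e}",
            f"excluded window     {self.excluded_range[0]:g}-{self.excluded_range[1]:g} nm "
            "(inspect with blue_residual)",
        ])


class PigmentMixtureModel:
    """Fit UV and LW pigment templates to a pupillary sensitivity.

    Each window is assumed to be dominated by a single pigment and both
    components use alpha-band-only templates: a beta band on the LW
    component would sit in the UV/blue region, inside the other windows,
    and be double-counted against the UV amplitude and the blue residual.
    (Within the LW window itself the beta band is negligible, so this
    choice does not move the fitted LW peak.)  The intermediate region
    between the windows is excluded from fitting so that any
    blue-receptor contribution there can be read off with
    :func:`blue_residual`.
    """

    def __init__(
        self,
        sensitivity: Spectrum,
        uv_range: tuple[float, float] = (340.0, 380.0),
        lw_range: tuple[float, float] = (490.0, 580.0),
    ):
        if uv_range[1] >= lw_range[0]:
            raise ValueError(f"uv_range {uv_range} and lw_range {lw_range} overlap")
        self.sensitivity = sensitivity
        self.uv_range = uv_range
        self.lw_range = lw_range
        self._uv = sensitivity.restrict(*uv_range)
        self._lw = sensitivity.restrict(*lw_range)
        if len(self._uv) == 0 or len(self._lw) == 0:
            raise ValueError("a fit window contains no samples of the sensitivity grid")

    def fit(
        self,
        free_peaks: bool = True,
        uv_search: tuple[float, float] = (330.0, 410.0),
        lw_search: tuple[float, float] = (460.0, 620.0),
        fixed_peaks: tuple[float, float] | None = None,
        step: float = 1.0,
    ) -> PigmentMixtureResults:
        # The LW pigment dominates; fit it first, then fit the UV pigment
        # to the UV window with the LW alpha-band tail subtracted so the
        # tail is not absorbed into the UV amplitude.
        if free_peaks:
            lam_lw, a_lw, rss_lw = _fit_window(self._lw, lw_search, step, beta=False)
            uv_resid = self._uv.with_values(
                self._uv.values
                - a_lw * template_values(lam_lw, self._uv.wavelengths, False)
            )
            lam_uv, a_uv, rss_uv = _fit_window(uv_resid, uv_search, step, beta=False)
        else:
            if fixed_peaks is None:
                raise ValueError("fixed_peaks required when free_peaks is False")
            lam_uv, lam_lw = fixed_peaks
            rss_lw, a_lw = _rss_at(lam_lw, self._lw.wavelengths, self._lw.values, False)
            uv_y = self._uv.values - a_lw * template_values(lam_lw, self._uv.wavelengths, False)
            rss_uv, a_uv = _rss_at(lam_uv, self._uv.wavelengths, uv_y, False)
        return PigmentMixtureResults(
            lambda_uv_=lam_uv,
            lambda_lw_=lam_lw,
            amplitude_uv_=a_uv,
            amplitude_lw_=a_lw,
            rss=rss_uv + rss_lw,
            uv_range=self.uv_range,
            lw_range=self.lw_range,
            excluded_range=(self.uv_range[1], self.lw_range[0]),
        )


def _fit_window(sub: Spectrum, search: tuple[float, float], step: float,
                beta: bool) -> tuple[float, float, float]:
    if len(sub) < 3:
        raise ValueError("fit window has fewer than 3 samples")
    lo, hi = search
    candidates = np.arange(lo, hi + step / 2, step)
    rss = np.array([_rss_at(l, sub.wavelengths, sub.values, beta)[0] for l in candidates])
    i = int(np.argmin(rss))
    blo = candidates[max(0, i - 1)]
    bhi = candidates[min(len(candidates) - 1, i + 1)]
    res = minimize_scalar(
        lambda l: _rss_at(l, sub.wavelengths, sub.values, beta)[0],
        bounds=(blo, bhi), method="bounded", options={"xatol": 0.01},
    )
    lam = float(res.x)
    best_rss, amp = _rss_at(lam, sub.wavelengths, sub.values, beta)
    return lam, amp, best_rss


def fit_pigment_mixture(
    sens: Spectrum,
    uv_range: tuple[float, float] = (340.0, 380.0),
    lw_range: tuple[float, float] = (490.0, 580.0),
    free_peaks: bool = True,
    **fit_kwargs,
) -> PigmentMixtureResults:
    """Functional wrapper around :class:`PigmentMixtureModel`."""
    return PigmentMixtureModel(sens, uv_range, lw_range).fit(free_peaks, **fit_kwargs)


def blue_residual(
    sens: Spectrum,
    fit: PigmentMixtureResults,
    wavelength_range: tuple[float, float] = (390.0, 480.0),
) -> Spectrum:
    """Sensitivity minus the fitted UV+LW mixture over the blue window.

    A systematically positive residual here indicates a contribution from
    a blue-sensitive receptor not captured by the two fitted pigments.
    """
    sub = sens.restrict(*wavelength_range)
    if len(sub) == 0:
        raise ValueError(f"range {wavelength_range} contains no samples")
    resid = sub.values - fit.fittedvalues(sub.wavelengths)
    return Spectrum(sub.wavelengths, resid, kind="sensitivity",
                    label="blue residual")
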