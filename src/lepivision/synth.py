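"""Synthetic data generators.

Every input the analysis consumes can be generated here with the
statistical structure the method assumes, so the whole pipeline is
testable without any measured data:

* wing reflectance spectra of the four patch classes — two species'
  oranges that share a low plateau and logistic rise but diverge above
  ~620 nm, near-flat whites, and near-flat browns (the adapting
  background);
* noisy rhodopsin difference spectra around a generating template;
* pupillary criterion-flux datasets on the 340-580 nm / 10 nm grid;
* small opsin alignments with controlled site-195 residues and pairwise
  identity.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .opsins import AlignedProteinSet
from .pigments import PupilDataset
from .spectra import DEFAULT_GRID, Spectrum, SpectrumSet
from .templates import template_values

logger = logging.getLogger(__name__)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

PATCH_TYPES = ("orange_A", "orange_B", "white", "brown")


@dataclass(frozen=True)
class WingPatchParams:
    """Parameters of one synthetic wing-patch class.

    The orange classes are a low plateau with a logistic rise near 600 nm
    to a high plateau; ``orange_B`` shares the curve below 600 nm but its
    long tail is depressed by ``tail_delta`` above ~620 nm, so the two
    oranges overlap through 300-600 nm and diverge from 600-700 nm.
    Whites and browns are nearly flat at ``high`` and ``low`` respectively.
    Noise is multiplicative Gaussian (sd relative to value).
    """

    patch_type: str
    low: float = 0.05
    high: float = 0.55
    midpoint: float = 600.0
    steepness: float = 12.0
    tail_delta: float = 0.08
    white_level: float = 0.70
    brown_level: float = 0.08
    noise_sd: float = 0.05
    n: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.patch_type not in PATCH_TYPES:
            raise ValueError(f"patch_type must be one of {PATCH_TYPES}, got {self.patch_type!r}")
        for name in ("low", "high", "white_level", "brown_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 300.0 < self.midpoint < 700.0:
            raise ValueError("midpoint must be inside (300, 700) nm")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _patch_mean_curve(p: WingPatchParams, grid: np.ndarray) -> np.ndarray:
    if p.patch_type in ("orange_A", "orange_B"):
        curve = p.low + (p.high - p.low) / (1.0 + np.exp(-(grid - p.midpoint) / p.steepness))
        if p.patch_type == "orange_B":
            curve = curve - p.tail_delta / (1.0 + np.exp(-(grid - 620.0) / 8.0))
        return curve
    if p.patch_type == "white":
        return np.full_like(grid, p.white_level)
    return np.full_like(grid, p.brown_level)


def gen_wing_reflectance(p: WingPatchParams, grid=None) -> SpectrumSet:
    """Generate ``p.n`` noisy reflectance spectra of one patch class.

    Spectra are drawn independently (within-individual correlation is not
    modelled); values are clipped to [0, 1] after noise and the clip count
    logged.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    mean = _patch_mean_curve(p, grid)
    rng = np.random.default_rng(p.seed)
    spectra = []
    n_clipped = 0
    for i in range(p.n):
        noise = rng.normal(0.0, p.noise_sd, size=grid.size) if p.noise_sd > 0 else 0.0
        vals = mean * (1.0 + noise)
        n_clipped += int(np.sum((vals < 0) | (vals > 1)))
        vals = np.clip(vals, 0.0, 1.0)
        spectra.append(Spectrum(grid, vals, kind="reflectance",
                                label=f"{p.patch_type}_{i:03d}"))
    if n_clipped:
        logger.info("gen_wing_reflectance(%s): clipped %d points", p.patch_type, n_clipped)
    return SpectrumSet(spectra, {p.patch_type: list(range(p.n))})


def gen_difference_spectrum(
    lambda_max: float,
    noise_sd: float = 0.02,
    seed: int | None = None,
    grid=None,
    include_beta_band: bool = True,
) -> Spectrum:
    """A pigment template plus additive Gaussian noise, renormalized.

    Emulates a normalized rhodopsin difference spectrum (or an expressed
    pigment dark spectrum) around a known generating peak.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    vals = template_values(lambda_max, grid, include_beta_band)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=grid.size)
    vals = vals / vals.max()
    return Spectrum(grid, vals, kind="absorbance",
                    label=f"synthetic diff spectrum ({lambda_max:g} nm)",
                    normalized=True)


#: stimulus wavelengths of the pupillary experiment: 340-580 nm every 10 nm
PUPIL_GRID = np.arange(340.0, 581.0, 10.0)


def gen_pupil_dataset(
    lambda_uv: float = 355.0,
    lambda_lw: float = 530.0,
    uv_amplitude: float = 0.25,
    blue_bump: tuple[float, float] | None = None,
    noise_sd: float = 0.02,
    seed: int | None = None,
    grid=None,
    criterion: float = 0.07,
) -> PupilDataset:
    """Criterion-flux dataset from a two-pigment sensitivity mixture.

    The generating sensitivity is ``uv_amplitude * T(lambda_uv) +
    T(lambda_lw)`` (alpha bands only: each fitting window is assumed to be
    dominated by a single pigment, mirroring the inference the fit makes),
    plus an optional Gaussian blue bump ``(center nm, height)`` of 30 nm
    width.  Criterion flux is the reciprocal sensitivity with
    multiplicative Gaussian noise.
    """
    if grid is None:
        grid = PUPIL_GRID
    grid = np.asarray(grid, dtype=float)
    sens = (
        uv_amplitude * template_values(lambda_uv, grid, include_beta_band=False)
        + template_values(lambda_lw, grid, include_beta_band=False)
    )
    if blue_bump is not None:
        center, height = blue_bump
        sens = sens + height * np.exp(-(((grid - center) / 30.0) ** 2))
    flux = 1.0 / sens
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flux = flux * (1.0 + rng.normal(0.0, noise_sd, size=grid.size))
    return PupilDataset(grid, flux, criterion)


def gen_opsin_alignment(
    n_seqs: int,
    length: int = 330,
    site195_residues: list[str] | None = None,
    seed: int | None = None,
    site135_residues: list[str] | None = None,
    n_mutations: int | None = None,
) -> AlignedProteinSet:
    """A seeded random protein alignment with controlled tuning sites.

    Sequence ``seq_0`` is drawn uniformly over the 20 amino acids; each
    further sequence is a copy mutated at exactly ``n_mutations`` random
    positions (tuning sites excluded), giving controlled pairwise identity
    to the first sequence.  With ``n_mutations=None`` sequences are
    independent random draws.  Residues from ``site195_residues`` (and
    optionally ``site135_residues``) are then placed at the mapped columns.
    """
    if length < 195:
        raise ValueError("alignment length must cover site 195 under default numbering")
    rng = np.random.default_rng(seed)
    site_cols = {194}
    if site135_residues is not None or length >= 135:
        site_cols.add(134)
    base = rng.choice(_AMINO_ACIDS, size=length)
    seqs: dict[str, str] = {}
    for i in range(n_seqs):
        if i == 0 or n_mutations is None:
            row = rng.choice(_AMINO_ACIDS, size=length) if i else base.copy()
        else:
            row = base.copy()
            candidates = np.array(sorted(set(range(length)) - site_cols))
            pos = rng.choice(candidates, size=n_mutations, replace=False)
            for pj in pos:
                current = row[pj]
                choices = _AMINO_ACIDS[_AMINO_ACIDS != current]
                row[pj] = rng.choice(choices)
        if site195_residues is not None:
            row[194] = site195_residues[i % len(site195_residues)]
        if site135_residues is not None:
            row[134] = site135_residues[i % len(site135_residues)]
        seqs[f"seq_{i}"] = "".join(row)
    return AlignedProteinSet(seqs)
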