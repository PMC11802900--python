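"""Spectra: the common substrate of the package.

Every stage of the analysis — pigment-template fitting, quantum-catch
integration, colour distances — operates on sampled functions of wavelength.
This module provides the :class:`Spectrum` container, collections of spectra
with group structure (:class:`SpectrumSet`), readers for the two-column text
exports produced by spectrometer acquisition software, and the standard
processing steps (resampling to a common grid, smoothing, group aggregation).

Reflectances are stored as fractions in [0, 1]; readers accept percent units
behind a flag.  The working wavelength grid throughout the package is
300–700 nm at 1 nm (inclusive endpoints).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

#: default working grid, 300-700 nm inclusive at 1 nm
DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

VALID_KINDS = ("reflectance", "irradiance", "absorbance", "sensitivity")


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed (names the file and line)."""


class GridMismatchError(ValueError):
    """Two spectra that must share a wavelength grid do not."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength.

    Parameters
    ----------
    wavelengths : array of float
        Sample positions in nm, strictly increasing.
    values : array of float
        Sample values.  Unitless reflectance fraction, photon-flux
        irradiance, normalized absorbance, or normalized sensitivity
        depending on ``kind``.
    kind : str
        One of ``reflectance``, ``irradiance``, ``absorbance``,
        ``sensitivity``.
    label : str
        Free-text metadata (species, patch, wing side, sex, ...).
    normalized : bool
        True when the spectrum has been peak-normalized to 1.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"wavelengths ({wl.size}) and values ({vals.size}) differ in length"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, **changes) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), **changes)

    def interp(self, wavelengths_nm) -> np.ndarray:
        """Linear interpolation at arbitrary wavelengths (no extrapolation check)."""
        return np.interp(np.asarray(wavelengths_nm, float), self.wavelengths, self.values)

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        """The sub-spectrum with lo <= wavelength <= hi."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return replace(self, wavelengths=self.wavelengths[m], values=self.values[m])

    def peak_normalized(self) -> "Spectrum":
        m = float(np.max(self.values))
        if m <= 0:
            raise ValueError("cannot peak-normalize a spectrum with non-positive maximum")
        return self.with_values(self.values / m, normalized=True)


@dataclass
class SpectrumSet:
    """Spectra on a shared grid, partitioned into groups.

    ``grouping`` maps a group key (typically species x patch x side) to
    member indices.  Every member belongs to exactly one group; by default
    each spectrum's label is its group.
    """

    spectra: list[Spectrum]
    grouping: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grouping:
            self.grouping = {}
            for i, s in enumerate(self.spectra):
                self.grouping.setdefault(s.label or f"spectrum_{i}", []).append(i)
        seen: set[int] = set()
        for key, idx in self.grouping.items():
            for i in idx:
                if i in seen:
                    raise ValueError(f"spectrum {i} assigned to more than one group")
                seen.add(i)
        if self.spectra:
            ref = self.spectra[0].wavelengths
            for s in self.spectra[1:]:
                if s.wavelengths.shape != ref.shape or not np.allclose(s.wavelengths, ref):
                    raise GridMismatchError("all members of a SpectrumSet must share one grid")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def group(self, key: str) -> list[Spectrum]:
        return [self.spectra[i] for i in self.grouping[key]]

    def map(self, fn) -> "SpectrumSet":
        """Apply ``fn`` to every member, preserving the grouping."""
        return SpectrumSet([fn(s) for s in self.spectra], dict(self.grouping))


# ---------------------------------------------------------------------------
# reading

_DELIMS = re.compile(r"[,;\t]")


def _parse_row(line: str) -> list[float]:
    tokens = [t for t in _DELIMS.sub(" ", line).split() if t]
    return [float(t) for t in tokens]


def _read_table(path: Path) -> np.ndarray:
    """Parse a delimited numeric table, tolerating one header line."""
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        try:
            _parse_row(lines[0])
        except ValueError:
            start = 1  # header
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            row = _parse_row(line)
        except ValueError as exc:
            raise SpectrumParseError(f"{path}: line {lineno}: non-numeric row") from exc
        rows.append(row)
    if not rows:
        raise SpectrumParseError(f"{path}: no numeric data rows")
    ncol = len(rows[0])
    if ncol < 2:
        raise SpectrumParseError(f"{path}: need at least 2 numeric columns, got {ncol}")
    if any(len(r) != ncol for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != ncol)
        raise SpectrumParseError(f"{path}: ragged row near line {bad + start + 1}")
    return np.asarray(rows, dtype=float)


def read_spectra(
    paths: Iterable[str | Path],
    dialect: str = "two_column",
    kind: str = "reflectance",
    percent: bool = False,
    labels: Sequence[str] | None = None,
) -> SpectrumSet:
    """Read spectrometer text exports into a :class:`SpectrumSet`.

    ``two_column`` reads one spectrum per file (wavelength, value);
    ``multi_column`` reads the first column as wavelength and each further
    column as a spectrum.  Delimiters (comma/semicolon/tab/whitespace) are
    autodetected and a single header line is tolerated.  Set ``percent``
    when reflectances are recorded in percent; they are divided by 100.
    """
    if dialect not in ("two_column", "multi_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    paths = [Path(p) for p in paths]
    spectra: list[Spectrum] = []
    for ip, path in enumerate(paths):
        if not path.exists():
            raise FileNotFoundError(path)
        table = _read_table(path)
        wl = table[:, 0]
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise SpectrumParseError(f"{path}: wavelengths not strictly increasing")
        ncols = table.shape[1] if dialect == "multi_column" else 2
        for j in range(1, ncols):
            vals = table[:, j]
            if percent:
                vals = vals / 100.0
            if labels is not None:
                label = labels[len(spectra)]
            elif dialect == "multi_column" and ncols > 2:
                label = f"{path.stem}_{j}"
            else:
                label = path.stem
            spectra.append(Spectrum(wl, vals, kind=kind, label=label))
    return SpectrumSet(spectra)


# ---------------------------------------------------------------------------
# processing

def resample(s: Spectrum, grid, extrapolate: bool = False) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (nm).

    By default the grid must lie within the measured range; with
    ``extrapolate`` the end values are clamped outside it.
    """
    grid = np.asarray(grid, dtype=float)
    if not extrapolate:
        if grid.min() < s.wavelengths[0] or grid.max() > s.wavelengths[-1]:
            raise ValueError(
                f"requested grid [{grid.min()}, {grid.max()}] outside measured "
                f"range [{s.wavelengths[0]}, {s.wavelengths[-1]}]"
            )
    vals = np.interp(grid, s.wavelengths, s.values)
    return replace(s, wavelengths=grid, values=vals)


def smooth(s: Spectrum, span: float = 0.2, method: str = "moving_average") -> Spectrum:
    """Smooth a spectrum with a centred window of ``span`` x grid length.

    ``moving_average`` (default) is a centred boxcar, edges handled by
    nearest-value padding so constants are preserved exactly; ``lowess`` is
    locally weighted regression.  Negative reflectance values (spectrometer
    noise) are clipped to 0 afterwards and the clip count logged.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(s)
    if method == "moving_average":
        window = max(1, int(round(span * n)))
        if window % 2 == 0:
            window += 1
        vals = uniform_filter1d(s.values, size=window, mode="nearest")
    elif method == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        vals = lowess(s.values, s.wavelengths, frac=span, return_sorted=False)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    if s.kind == "reflectance":
        n_clipped = int(np.sum(vals < 0))
        if n_clipped:
            logger.info("smooth: clipped %d negative reflectance points in %r",
                        n_clipped, s.label)
        vals = np.clip(vals, 0.0, None)
    return s.with_values(vals)


def aggregate(sset: SpectrumSet, by: str | None = None) -> dict[str, tuple[Spectrum, Spectrum]]:
    """Pointwise group mean and sample standard deviation.

    Returns ``{group: (mean Spectrum, sd Spectrum)}``.  Singleton groups get
    sd = 0 everywhere.  Pass ``by`` to aggregate a single group only.
    """
    keys = [by] if by is not None else list(sset.grouping)
    out: dict[str, tuple[Spectrum, Spectrum]] = {}
    for key in keys:
        if key not in sset.grouping or not sset.grouping[key]:
            raise ValueError(f"empty or unknown group {key!r}")
        members = np.stack([sset.spectra[i].values for i in sset.grouping[key]])
        mean = members.mean(axis=0)
        sd = members.std(axis=0, ddof=1) if members.shape[0] > 1 else np.zeros(members.shape[1])
        proto = sset.spectra[sset.grouping[key][0]]
        out[key] = (
            proto.with_values(mean, label=f"{key}:mean"),
            proto.with_values(sd, label=f"{key}:sd"),
        )
    return out


# ---------------------------------------------------------------------------
# writing

def to_long_table(sset: SpectrumSet) -> pd.DataFrame:
    """Tidy long-format table (label, wavelength_nm, value) of a set."""
    frames = [
        pd.DataFrame(
            {"label": s.label, "wavelength_nm": s.wavelengths, "value": s.values}
        )
        for s in sset.spectra
    ]
    return pd.concat(frames, ignore_index=True)


def write_long_table(sset: SpectrumSet, path: str | Path) -> None:
    to_long_table(sset).to_csv(path, index=False)


def write_two_column(s: Spectrum, path: str | Path) -> None:
    """Write one spectrum in the two-column acquisition-export format."""
    np.savetxt(path, np.column_stack([s.wavelengths, s.values]),
               fmt="%.6g", delimiter=",", header="wavelength_nm,value")
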