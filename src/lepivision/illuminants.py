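"""Standard illuminants.

The bundled D65 table is the CIE standard daylight relative spectral power
distribution (energy units, normalized to 100 at 560 nm) tabulated at
10 nm over 300-700 nm.  Quantum-catch computation needs photon flux, so
the energy curve is multiplied by wavelength (photons per unit energy
scale with λ) and peak-normalized; the receptor-noise model is invariant
to the illuminant's overall scale, only its shape matters.
"""

from __future__ import annotations

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum

# CIE D65 relative SPD, 300-700 nm at 10 nm (energy units, 100 at 560 nm)
_D65_WL = np.arange(300.0, 701.0, 10.0)
_D65_E = np.array([
    0.0341, 3.2945, 20.236, 37.0535, 39.9488, 44.9117, 46.6383, 52.0891,
    49.9755, 54.6482, 82.7549, 91.486, 93.4318, 86.6823, 104.865, 117.008,
    117.812, 114.861, 115.923, 108.811, 109.354, 107.802, 104.79, 107.689,
    104.405, 104.046, 100.0, 96.3342, 95.788, 88.6856, 90.0062, 89.5991,
    87.6987, 83.2886, 83.6992, 80.0268, 80.2146, 82.2778, 78.2842, 69.7213,
    71.6091,
])


def d65_illuminant(grid=None, photon_units: bool = True) -> Spectrum:
    """Standard daylight (D65) interpolated to ``grid`` and peak-normalized.

    With ``photon_units`` (default) the energy-unit table is converted to
    relative photon flux by multiplying by wavelength before normalizing.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 300.0 or grid.max() > 700.0:
        raise ValueError("D65 table covers 300-700 nm")
    vals = np.interp(grid, _D65_WL, _D65_E)
    if photon_units:
        vals = vals * grid
    return Spectrum(grid, vals / vals.max(), kind="irradiance",
                    label="D65 (photon units)" if photon_units else "D65 (energy units)",
                    normalized=True)
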