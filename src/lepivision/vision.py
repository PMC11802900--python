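"""Receptor-noise-limited colour vision model.

Implements the standard receptor-noise framework for predicting
discriminability of two stimuli through a given visual system: quantum
catches of each photoreceptor under an illuminant, von Kries adaptation to
a background, noise-weighted chromatic distances (JND) for di-, tri- and
tetrachromats, an achromatic (luminance) distance through a single
channel, and chromaticity coordinates in the Maxwell triangle /
tetrahedral colour space.

Three presets are bundled: the trichromatic *Adelpha fessonia* butterfly
system (peaks 355/431/530 nm) and two tetrachromatic avian systems, a
UV-sensitive bird (blue tit pigment peaks 372/449/502/563 nm) and a
violet-sensitive bird (chicken, 418/453/507/571 nm).  Avian sensitivities
are bare pigment templates at the printed peaks, without oil-droplet or
ocular-media filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .spectra import DEFAULT_GRID, GridMismatchError, Spectrum
from .templates import pigment_template


class AdaptationError(ValueError):
    """von Kries signals undefined (a stimulus or background catch is 0)."""


@dataclass(frozen=True)
class Receptor:
    """A photoreceptor channel: sensitivity, relative density, Weber fraction.

    ``sensitivity`` may be given explicitly; otherwise it is built from the
    pigment template at ``lambda_max``.
    """

    name: str
    lambda_max: float | None = None
    sensitivity: Spectrum | None = None
    density: float = 1.0
    weber: float | None = None
    include_beta_band: bool = True

    def __post_init__(self) -> None:
        if self.lambda_max is None and self.sensitivity is None:
            raise ValueError(f"receptor {self.name}: need lambda_max or sensitivity")
        if self.density <= 0:
            raise ValueError(f"receptor {self.name}: density must be > 0")

    def sensitivity_on(self, grid) -> np.ndarray:
        if self.sensitivity is not None:
            if self.sensitivity.wavelengths.shape != np.shape(grid) or not np.allclose(
                self.sensitivity.wavelengths, grid
            ):
                raise GridMismatchError(f"receptor {self.name}: sensitivity grid mismatch")
            return self.sensitivity.values
        return pigment_template(self.lambda_max, grid, self.include_beta_band).values


@dataclass(frozen=True)
class VisualSystem:
    """An ordered (short to long wavelength) receptor set plus an
    achromatic channel.

    ``noise_mode`` is ``per_receptor`` (every receptor carries its own
    chromatic Weber fraction) or ``density_scaled`` (a single Weber
    fraction on a reference receptor, scaled to the others by the square
    root of relative density).
    """

    name: str
    receptors: tuple[Receptor, ...]
    noise_mode: str = "per_receptor"
    weber: float | None = None
    weber_reference: str | None = None
    achromatic: Receptor | None = None
    weber_achromatic: float | None = None

    def __post_init__(self) -> None:
        if len(self.receptors) < 2:
            raise ValueError("a visual system needs at least 2 receptors")
        if self.noise_mode == "per_receptor":
            if any(r.weber is None for r in self.receptors):
                raise ValueError("per_receptor noise mode requires a Weber fraction on every receptor")
        elif self.noise_mode == "density_scaled":
            if self.weber is None or self.weber_reference is None:
                raise ValueError("density_scaled noise mode requires weber and weber_reference")
        else:
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)

    def receptor(self, name: str) -> Receptor:
        for r in self.receptors:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass(frozen=True)
class ViewingConditions:
    """Illuminant (photon units) and adapting background (reflectance)."""

    illuminant: Spectrum
    background: Spectrum

    def __post_init__(self) -> None:
        if np.any(self.illuminant.values <= 0):
            raise ValueError("illuminant must be strictly positive on the grid")
        if np.any((self.background.values < 0) | (self.background.values > 1)):
            raise ValueError("background reflectance must lie in [0, 1]")


@dataclass(frozen=True)
class QuantumCatches:
    """Per-receptor photon catches Q_i and von Kries log signals f_i.

    ``f`` is ln(Q_i / Q_i^background); the trailing achromatic channel is
    carried separately as ``Q_achro`` / ``f_achro``.
    """

    Q: np.ndarray
    f: np.ndarray
    Q_achro: float | None = None
    f_achro: float | None = None
    label: str = ""


# ---------------------------------------------------------------------------
# presets (parameters of the three modelled visual systems)

def make_visual_system(preset: str, grid=None) -> VisualSystem:
    """Build one of the bundled visual-system presets.

    ``fessonia``: trichromat, peaks 355/431/530 nm, relative densities
    0.15:0.13:1, chromatic Weber fractions 0.13/0.06/0.12 (honeybee
    electrophysiology), achromatic channel = the 530 nm receptor with
    Weber fraction 0.16.

    ``uv_bird``: UV-sensitive tetrachromat (blue tit pigments), peaks
    372/449/502/563 nm, densities 1:2:2:4, single chromatic Weber fraction
    0.10 on the longest receptor scaled by density, double cone at 563 nm
    with achromatic Weber fraction 0.18.

    ``violet_bird``: violet-sensitive tetrachromat (chicken pigments),
    peaks 418/453/507/571 nm, densities 1:2:4:4, chromatic Weber fraction
    0.06, double cone at 571 nm with achromatic Weber fraction 0.22.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if preset == "fessonia":
        receptors = (
            Receptor("uv", 355.0, density=0.15, weber=0.13, include_beta_band=False),
            Receptor("s", 431.0, density=0.13, weber=0.06),
            Receptor("l", 530.0, density=1.0, weber=0.12),
        )
        return VisualSystem(
            name="fessonia", receptors=receptors, noise_mode="per_receptor",
            achromatic=Receptor("l_achro", 530.0),
            weber_achromatic=0.16,
        )
    if preset == "uv_bird":
        receptors = (
            Receptor("uv", 372.0, density=1.0, include_beta_band=False),
            Receptor("s", 449.0, density=2.0),
            Receptor("m", 502.0, density=2.0),
            Receptor("l", 563.0, density=4.0),
        )
        return VisualSystem(
            name="uv_bird", receptors=receptors, noise_mode="density_scaled",
            weber=0.10, weber_reference="l",
            achromatic=Receptor("dc", 563.0), weber_achromatic=0.18,
        )
    if preset == "violet_bird":
        receptors = (
            Receptor("v", 418.0, density=1.0),
            Receptor("s", 453.0, density=2.0),
            Receptor("m", 507.0, density=4.0),
            Receptor("l", 571.0, density=4.0),
        )
        return VisualSystem(
            name="violet_bird", receptors=receptors, noise_mode="density_scaled",
            weber=0.06, weber_reference="l",
            achromatic=Receptor("dc", 571.0), weber_achromatic=0.22,
        )
    raise ValueError(f"unknown visual system preset {preset!r}")


def visual_system_from_config(cfg: dict) -> VisualSystem:
    """Build a custom VisualSystem from a configuration mapping.

    Expected keys: ``name``, ``receptors`` (list of {name, lambda_max,
    density, weber?, beta_band?}), ``noise_mode``, ``weber`` /
    ``weber_reference`` for density_scaled mode, ``achromatic``
    ({lambda_max}) and ``weber_achromatic``.
    """
    receptors = tuple(
        Receptor(
            r["name"], float(r["lambda_max"]), density=float(r.get("density", 1.0)),
            weber=r.get("weber"), include_beta_band=bool(r.get("beta_band", True)),
        )
        for r in cfg["receptors"]
    )
    achro = cfg.get("achromatic")
    return VisualSystem(
        name=cfg.get("name", "custom"),
        receptors=receptors,
        noise_mode=cfg.get("noise_mode", "per_receptor"),
        weber=cfg.get("weber"),
        weber_reference=cfg.get("weber_reference"),
        achromatic=Receptor("achro", float(achro["lambda_max"])) if achro else None,
        weber_achromatic=cfg.get("weber_achromatic"),
    )


def load_visual_system(path) -> VisualSystem:
    with open(path) as fh:
        return visual_system_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# quantum catches

def _catch(reflectance: np.ndarray, illuminant: np.ndarray,
           sensitivity: np.ndarray, grid: np.ndarray) -> float:
    return float(np.trapezoid(reflectance * illuminant * sensitivity, grid))


def quantum_catch(
    reflectance: Spectrum,
    cond: ViewingConditions,
    vs: VisualSystem,
) -> QuantumCatches:
    """Photon catches Q_i = integral R(λ) I(λ) S_i(λ) dλ and von Kries
    log signals f_i = ln(Q_i / Q_i^bg), trapezoidal rule on the shared grid.
    """
    grid = reflectance.wavelengths
    for other in (cond.illuminant, cond.background):
        if other.wavelengths.shape != grid.shape or not np.allclose(other.wavelengths, grid):
            raise GridMismatchError("reflectance, illuminant and background must share a grid")
    sens = np.stack([r.sensitivity_on(grid) for r in vs.receptors])
    I = cond.illuminant.values
    Q = np.array([_catch(reflectance.values, I, s, grid) for s in sens])
    Qbg = np.array([_catch(cond.background.values, I, s, grid) for s in sens])
    if np.any(Qbg <= 0):
        raise AdaptationError("background quantum catch is zero for some receptor")
    if np.any(Q <= 0):
        raise AdaptationError(
            "stimulus quantum catch is zero for some receptor; von Kries signal undefined"
        )
    f = np.log(Q / Qbg)
    Q_a = f_a = None
    if vs.achromatic is not None:
        sa = vs.achromatic.sensitivity_on(grid)
        Q_a = _catch(reflectance.values, I, sa, grid)
        Qbg_a = _catch(cond.background.values, I, sa, grid)
        if Qbg_a <= 0 or Q_a <= 0:
            raise AdaptationError("achromatic quantum catch is zero")
        f_a = float(np.log(Q_a / Qbg_a))
    return QuantumCatches(Q=Q, f=f, Q_achro=Q_a, f_achro=f_a, label=reflectance.label)


# ---------------------------------------------------------------------------
# noise and distances

def noise_vector(vs: VisualSystem) -> np.ndarray:
    """Per-receptor noise standard deviations e_i of the log signals.

    per_receptor mode: e_i is each receptor's own Weber fraction.
    density_scaled mode: e_i = w_ref * sqrt(eta_ref / eta_i), with the
    single Weber fraction attached to the reference (conventionally the
    longest-wavelength, most abundant) receptor.
    """
    if vs.noise_mode == "per_receptor":
        return np.array([r.weber for r in vs.receptors], dtype=float)
    ref = vs.receptor(vs.weber_reference)
    return np.array(
        [vs.weber * np.sqrt(ref.density / r.density) for r in vs.receptors]
    )


def chromatic_distance_from_df(df: np.ndarray, e: np.ndarray) -> float:
    """Receptor-noise chromatic distance (JND) from a log-signal difference.

    Closed forms for 2, 3 and 4 receptors.  The distance is the
    noise-weighted length of ``df`` projected onto the chromatic
    (intensity-invariant) subspace, so uniform offsets map to 0.
    """
    df = np.asarray(df, dtype=float)
    e = np.asarray(e, dtype=float)
    n = df.size
    if e.size != n:
        raise ValueError("df and noise vector differ in length")
    if n == 2:
        return abs(df[0] - df[1]) / np.hypot(e[0], e[1])
    if n == 3:
        e1, e2, e3 = e
        num = (
            e1 ** 2 * (df[2] - df[1]) ** 2
            + e2 ** 2 * (df[2] - df[0]) ** 2
            + e3 ** 2 * (df[1] - df[0]) ** 2
        )
        den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
        return float(np.sqrt(num / den))
    if n == 4:
        e1, e2, e3, e4 = e
        d1, d2, d3, d4 = df
        num = (
            (e1 * e2) ** 2 * (d4 - d3) ** 2
            + (e1 * e3) ** 2 * (d4 - d2) ** 2
            + (e1 * e4) ** 2 * (d3 - d2) ** 2
            + (e2 * e3) ** 2 * (d4 - d1) ** 2
            + (e2 * e4) ** 2 * (d3 - d1) ** 2
            + (e3 * e4) ** 2 * (d2 - d1) ** 2
        )
        den = (
            (e1 * e2 * e3) ** 2
            + (e1 * e2 * e4) ** 2
            + (e1 * e3 * e4) ** 2
            + (e2 * e3 * e4) ** 2
        )
        return float(np.sqrt(num / den))
    raise ValueError(f"closed forms exist for 2-4 receptors, got {n}")


def chromatic_distance(a: QuantumCatches, b: QuantumCatches, vs: VisualSystem) -> float:
    """Chromatic JND between two adapted stimuli."""
    if a.f.size != vs.n_receptors or b.f.size != vs.n_receptors:
        raise ValueError("catch vectors do not match the visual system")
    return chromatic_distance_from_df(a.f - b.f, noise_vector(vs))


def achromatic_distance(a: QuantumCatches, b: QuantumCatches, vs: VisualSystem) -> float:
    """Achromatic (luminance) JND: |f_A(a) - f_A(b)| / w_achromatic."""
    if vs.achromatic is None or vs.weber_achromatic is None:
        raise ValueError(f"visual system {vs.name!r} has no achromatic channel")
    if a.f_achro is None or b.f_achro is None:
        raise ValueError("achromatic catches missing; recompute with this visual system")
    return abs(a.f_achro - b.f_achro) / vs.weber_achromatic


# ---------------------------------------------------------------------------
# chromaticity coordinates

# Maxwell triangle: unit circumradius, short receptor at top
TRIANGLE_VERTICES = np.array([
    [0.0, 1.0],
    [-np.sqrt(3) / 2, -0.5],
    [np.sqrt(3) / 2, -0.5],
])

# regular tetrahedron, circumradius 0.75, UV vertex on +z
TETRAHEDRON_VERTICES = np.array([
    [0.0, 0.0, 0.75],
    [-0.6123724357, -0.3535533906, -0.25],
    [0.6123724357, -0.3535533906, -0.25],
    [0.0, 0.7071067812, -0.25],
])


def chromaticity_coords(q: QuantumCatches | np.ndarray) -> np.ndarray:
    """Map relative catches onto the colour-space simplex.

    Relative catches q_i = Q_i / sum(Q) weight the vertices of a regular
    simplex centred at the origin: a Maxwell triangle (2-D) for three
    receptors, a tetrahedron (3-D) for four.  Coordinates are for display;
    they never feed JND computations.
    """
    Q = q.Q if isinstance(q, QuantumCatches) else np.asarray(q, dtype=float)
    total = Q.sum()
    if total <= 0:
        raise ValueError("all-zero catches cannot be mapped to the simplex")
    rel = Q / total
    if Q.size == 3:
        verts = TRIANGLE_VERTICES
    elif Q.size == 4:
        verts = TETRAHEDRON_VERTICES
    else:
        raise ValueError(f"chromaticity coordinates defined for 3 or 4 receptors, got {Q.size}")
    return rel @ verts


# ---------------------------------------------------------------------------
# model object

class ReceptorNoiseModel:
    """The receptor-noise discrimination model for one visual system under
    fixed viewing conditions.

    A thin object bundling a :class:`VisualSystem` and
    :class:`ViewingConditions`; stimuli (reflectance spectra) are turned
    into adapted quantum catches once and then compared with chromatic or
    achromatic distances, mapped to colour-space coordinates, or fed to the
    bootstrap comparison in :mod:`lepivision.bootstats`.
    """

    def __init__(self, visual_system: VisualSystem, conditions: ViewingConditions):
        self.visual_system = visual_system
        self.conditions = conditions

    def catch(self, reflectance: Spectrum) -> QuantumCatches:
        return quantum_catch(reflectance, self.conditions, self.visual_system)

    def catches(self, spectra) -> list[QuantumCatches]:
        return [self.catch(s) for s in spectra]

    def chromatic_distance(self, a: QuantumCatches, b: QuantumCatches) -> float:
        return chromatic_distance(a, b, self.visual_system)

    def achromatic_distance(self, a: QuantumCatches, b: QuantumCatches) -> float:
        return achromatic_distance(a, b, self.visual_system)

    def coords(self, q: QuantumCatches) -> np.ndarray:
        return chromaticity_coords(q)

    def bootcoldist(self, a, b, **kwargs):
        from .bootstats import bootcoldist

        return bootcoldist(a, b, self.visual_system, **kwargs)

    def plot_colorspace(self, groups: dict[str, list[QuantumCatches]], ax=None):
        """Scatter group catches in the Maxwell triangle (trichromats) or a
        2-D projection of the tetrahedron (tetrachromats).  Convenience
        layer; requires matplotlib."""
        import matplotlib.pyplot as plt

        n = self.visual_system.n_receptors
        verts = TRIANGLE_VERTICES if n == 3 else TETRAHEDRON_VERTICES[:, :2]
        if ax is None:
            _, ax = plt.subplots()
        ring = np.vstack([verts, verts[:1]])
        ax.plot(ring[:, 0], ring[:, 1], color="0.6", lw=0.8)
        for label, qs in groups.items():
            pts = np.array([self.coords(q)[:2] for q in qs])
            ax.scatter(pts[:, 0], pts[:, 1], s=12, label=label)
        ax.set_aspect("equal")
        ax.legend(fontsize=8)
        ax.set_title(self.visual_system.name)
        return ax
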