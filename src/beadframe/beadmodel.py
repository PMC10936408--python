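"""Physical emission model of a spherical fiducial bead.

The model: a sphere of constant emissivity and radius ``R`` (um), centered at
``(x0, y0)`` in the image plane and at depth ``zc`` (um) below the current
optical surface. The excitation laser illuminates a thin layer
``[zs, zs + dz]`` below the optical surface, and emission from depth ``z`` is
attenuated by the substrate as ``exp(-z / tau)`` with ``tau`` the substrate
optical depth. Integrating the attenuated emission along ``z`` across the
sphere chord that falls inside the excited layer gives the observed 2D
brightness profile in closed form:

    I(rho) = A * tau * (exp(-a/tau) - exp(-b/tau)) + B

where ``rho`` is the in-plane distance from the center, the chord through the
sphere spans ``zc +/- sqrt(R^2 - rho^2)``, and ``[a, b]`` is its intersection
with the excited layer (empty -> no signal). Both regimes fall out naturally:
an optical surface cutting through the bead (``|zc| < R``) and a fully
embedded bead emitting just under the surface (``zc > R``).

All depths are in um; in-plane coordinates are in pixels and converted via
the pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticsParams", "bead_profile", "render_bead", "projected_radius"]


@dataclass(frozen=True)
class OpticsParams:
    """Per-sample excitation/attenuation constants, frozen across bead fits.

    Attributes
    ----------
    zs : float
        Depth of the top of the excited layer below the optical surface (um).
    dz : float
        Thickness of the excited layer (um).
    tau : float
        Optical depth of the substrate (um); emission from depth z is
        attenuated by exp(-z/tau).
    """

    zs: float = 2.0
    dz: float = 5.0
    tau: float = 30.0

    @property
    def z_mid(self) -> float:
        return self.zs + 0.5 * self.dz


def projected_radius(radius_um: float, depth_um: float | np.ndarray) -> np.ndarray:
    """Apparent (chord) radius of a sphere cut at signed depth ``d`` from its center.

    ``r = sqrt(R^2 - d^2)``; 0 where the plane misses the sphere.
    """
    d = np.asarray(depth_um, dtype=float)
    return np.sqrt(np.clip(radius_um ** 2 - d ** 2, 0.0, None))


def bead_profile(xx, yy, x0, y0, radius_um, depth_um, amplitude, background,
                 optics: OpticsParams, pixel_scale_um: float) -> np.ndarray:
    """Evaluate the bead brightness model on pixel-coordinate grids ``xx, yy``.

    Parameters
    ----------
    xx, yy
        Pixel-center coordinate grids (px).
    x0, y0
        Bead center in the image plane (px).
    radius_um
        Sphere radius R (um).
    depth_um
        Depth ``zc`` of the sphere center below the optical surface (um);
        negative values put the center above the surface (bead partially
        cut away).
    amplitude
        Emissivity scale A (counts per um of attenuated chord).
    background
        Additive background level B (counts).
    """
    rho = np.hypot((np.asarray(xx, float) - x0) * pixel_scale_um,
                   (np.asarray(yy, float) - y0) * pixel_scale_um)
    half_chord = projected_radius(radius_um, 0.0) * 0.0 + np.sqrt(
        np.clip(radius_um ** 2 - rho ** 2, 0.0, None))
    # chord through the sphere along z, clipped to the excited layer
    lo = np.maximum(depth_um - half_chord, optics.zs)
    hi = np.minimum(depth_um + half_chord, optics.zs + optics.dz)
    seg = np.clip(hi - lo, 0.0, None)
    signal = np.where(
        seg > 0.0,
        optics.tau * (np.exp(-np.clip(lo, 0.0, None) / optics.tau)
                      - np.exp(-np.clip(hi, lo, None) / optics.tau)),
        0.0,
    )
    return amplitude * signal + background


def render_bead(shape, x0, y0, radius_um, depth_um, amplitude, background,
                optics: OpticsParams, pixel_scale_um: float,
                oversample: int = 1) -> np.ndarray:
    """Render a bead into an image of ``shape`` (rows, cols).

    ``oversample > 1`` averages the profile over subpixel sample points,
    approximating integration over the pixel area; the fitter always
    evaluates at pixel centers, so rendering with ``oversample=2`` exercises
    a deliberate (small) model mismatch.
    """
    h, w = shape
    if oversample <= 1:
        yy, xx = np.mgrid[0:h, 0:w]
        return bead_profile(xx, yy, x0, y0, radius_um, depth_um, amplitude,
                            background, optics, pixel_scale_um)
    off = (np.arange(oversample) + 0.5) / oversample - 0.5
    acc = np.zeros((h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for oy in off:
        for ox in off:
            acc += bead_profile(xx + ox, yy + oy, x0, y0, radius_um, depth_um,
                                amplitude, background, optics, pixel_scale_um)
    return acc / oversample ** 2
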