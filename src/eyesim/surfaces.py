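"""Refracting surface geometries and optical media.

All lengths are millimetres.  The optical axis is z, increasing from the
cornea toward the retina.  A surface stores the axial position of its
vertex; its shape is the sag z(x, y) measured from that vertex, positive
toward the retina.  The sign convention for radii is the usual sequential
ray-tracing one: positive radius means the centre of curvature lies to
the right (toward the retina).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import zernike

__all__ = ["Medium", "ConicSurface", "ZernikeSagSurface", "WavefrontShapedSurface"]

MM_PER_UM = 1e-3


@dataclass(frozen=True)
class Medium:
    """Homogeneous optical medium, indexed at 555 nm."""

    index: float

    def __post_init__(self):
        if self.index < 1.0:
            raise ValueError(f"refractive index {self.index} < 1")


@dataclass
class ConicSurface:
    """Rotationally symmetric conicoid z = c r^2 / (1 + sqrt(1 - (1+Q) c^2 r^2)).

    Parameters
    ----------
    radius_of_curvature : vertex radius R in mm (np.inf for a plane).
    conic_constant : asphericity Q (0 sphere, Q < 0 prolate).
    semi_aperture : clear semi-diameter in mm; rays beyond it vignette.
    axial_position : z of the vertex, mm from the anterior corneal vertex.
    """

    radius_of_curvature: float
    conic_constant: float = 0.0
    semi_aperture: float = 5.0
    axial_position: float = 0.0

    @property
    def curvature(self) -> float:
        return 0.0 if np.isinf(self.radius_of_curvature) else 1.0 / self.radius_of_curvature

    def sag(self, x, y):
        """Surface height above the vertex plane at (x, y)."""
        c = self.curvature
        if c == 0.0:
            return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
        disc = 1.0 - (1.0 + self.conic_constant) * c * c * r2
        if np.any(disc <= 0.0):
            raise ValueError(
                "point outside the conic domain: (1+Q) r^2 / R^2 >= 1 "
                f"(R={self.radius_of_curvature}, Q={self.conic_constant})"
            )
        return c * r2 / (1.0 + np.sqrt(disc))

    def sag_and_grad(self, x, y):
        """Sag and its Cartesian gradient; NaN where the conic domain is left."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = self.curvature
        if c == 0.0:
            z = np.zeros(np.broadcast(x, y).shape)
            return z, z, z
        r2 = x * x + y * y
        disc = 1.0 - (1.0 + self.conic_constant) * c * c * r2
        bad = disc <= 0.0
        disc = np.where(bad, np.nan, disc)
        root = np.sqrt(disc)
        z = c * r2 / (1.0 + root)
        # dz/dr = c r / sqrt(1 - (1+Q) c^2 r^2)
        g = c / root
        return z, x * g, y * g

    def to_dict(self) -> dict:
        return {
            "type": "conic",
            "radius_of_curvature": float(self.radius_of_curvature),
            "conic_constant": float(self.conic_constant),
            "semi_aperture": float(self.semi_aperture),
            "axial_position": float(self.axial_position),
        }


@dataclass
class ZernikeSagSurface:
    """Conic base plus Zernike-polynomial sag terms.

    ``zernike_sag_coeffs`` maps OSA double indices (n, m) to sag
    coefficients in micrometres, defined over ``normalization_radius``.
    With all coefficients zero the surface is exactly the base conic.
    """

    base: ConicSurface
    zernike_sag_coeffs: dict = field(default_factory=dict)
    normalization_radius: float = 3.25

    @property
    def radius_of_curvature(self):
        return self.base.radius_of_curvature

    @property
    def conic_constant(self):
        return self.base.conic_constant

    @property
    def semi_aperture(self):
        return self.base.semi_aperture

    @property
    def axial_position(self):
        return self.base.axial_position

    @property
    def curvature(self):
        return self.base.curvature

    def sag(self, x, y):
        z = self.base.sag(x, y)
        rn = self.normalization_radius
        for (n, m), c_um in self.zernike_sag_coeffs.items():
            if c_um:
                z = z + c_um * MM_PER_UM * zernike.zernike_eval(n, m, np.asarray(x) / rn, np.asarray(y) / rn)
        return z

    def sag_and_grad(self, x, y):
        z, gx, gy = self.base.sag_and_grad(x, y)
        rn = self.normalization_radius
        xn = np.asarray(x, dtype=float) / rn
        yn = np.asarray(y, dtype=float) / rn
        for (n, m), c_um in self.zernike_sag_coeffs.items():
            if c_um:
                s = c_um * MM_PER_UM
                z = z + s * zernike.zernike_eval(n, m, xn, yn)
                dx, dy = zernike.zernike_grad(n, m, xn, yn)
                gx = gx + s * dx / rn
                gy = gy + s * dy / rn
        return z, gx, gy

    def to_dict(self) -> dict:
        return {
            "type": "zernike_sag",
            "base": self.base.to_dict(),
            "zernike_sag_coeffs": {f"{n},{m}": float(c) for (n, m), c in self.zernike_sag_coeffs.items()},
            "normalization_radius": float(self.normalization_radius),
        }


@dataclass
class WavefrontShapedSurface:
    """Conic base with a smooth radial perturbation confined to a central zone.

    The perturbation is ``amplitude_um * (1 - (r/a)^2)**exponent`` for
    ``r < a`` and exactly zero outside, with ``a = zone_diameter / 2``.
    For ``exponent >= 2`` both the sag and its slope are continuous at
    the zone boundary, so the surface blends into the base conic without
    any light-splitting step.  This is the geometry used for the
    wavefront-shaping (EDOF) lens optic.
    """

    base: ConicSurface
    zone_diameter: float = 2.20
    amplitude_um: float = 0.0
    exponent: float = 3.0

    def __post_init__(self):
        if self.exponent < 2.0:
            raise ValueError("exponent < 2 breaks slope continuity at the zone edge")

    @property
    def radius_of_curvature(self):
        return self.base.radius_of_curvature

    @property
    def conic_constant(self):
        return self.base.conic_constant

    @property
    def semi_aperture(self):
        return self.base.semi_aperture

    @property
    def axial_position(self):
        return self.base.axial_position

    @property
    def curvature(self):
        return self.base.curvature

    def _bump(self, r2):
        a2 = (self.zone_diameter / 2.0) ** 2
        u = 1.0 - r2 / a2
        inside = u > 0.0
        uu = np.where(inside, u, 0.0)
        z = self.amplitude_um * MM_PER_UM * uu**self.exponent
        # dz/d(r2) = -A k u^(k-1) / a^2
        dz_dr2 = np.where(
            inside,
            -self.amplitude_um * MM_PER_UM * self.exponent * uu ** (self.exponent - 1.0) / a2,
            0.0,
        )
        return z, dz_dr2

    def sag(self, x, y):
        r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
        z, _ = self._bump(r2)
        return self.base.sag(x, y) + z

    def sag_and_grad(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z, gx, gy = self.base.sag_and_grad(x, y)
        zb, dz_dr2 = self._bump(x * x + y * y)
        return z + zb, gx + 2.0 * x * dz_dr2, gy + 2.0 * y * dz_dr2

    def to_dict(self) -> dict:
        return {
            "type": "wavefront_shaped",
            "base": self.base.to_dict(),
            "zone_diameter": float(self.zone_diameter),
            "amplitude_um": float(self.amplitude_um),
            "exponent": float(self.exponent),
        }


def surface_from_dict(d: dict):
    """Inverse of the surfaces' ``to_dict`` methods."""
    kind = d["type"]
    if kind == "conic":
        return ConicSurface(
            radius_of_curvature=d["radius_of_curvature"],
            conic_constant=d["conic_constant"],
            semi_aperture=d["semi_aperture"],
            axial_position=d["axial_position"],
        )
    if kind == "zernike_sag":
        coeffs = {tuple(int(v) for v in k.split(",")): c for k, c in d["zernike_sag_coeffs"].items()}
        return ZernikeSagSurface(
            base=surface_from_dict(d["base"]),
            zernike_sag_coeffs=coeffs,
            normalization_radius=d["normalization_radius"],
        )
    if kind == "wavefront_shaped":
        return WavefrontShapedSurface(
            base=surface_from_dict(d["base"]),
            zone_diameter=d["zone_diameter"],
            amplitude_um=d["amplitude_um"],
            exponent=d["exponent"],
        )
    raise ValueError(f"unknown surface type {kind!r}")
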