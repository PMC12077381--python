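"""Analytic test cases with closed-form expected values.

Every stage of the pipeline (tracing, wavefront handling, PSF/MTF,
Visual Strehl, halo metric) has at least one registered case whose
expected output comes from a formula, never from the pipeline itself:
pure-defocus wavefronts, single Zernike modes, the Airy pattern, the
uniform-disk pinhole image, a stigmatic refracting conicoid, an
aberration-free single-surface eye, and small random wavefronts in the
Marechal regime.  Cases are deterministic; random coefficient draws use
the fixed seed 20231101.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, pi, sqrt

import numpy as np

from . import zernike
from .raytrace import EyeModel, WavefrontMap
from .surfaces import ConicSurface

__all__ = ["AnalyticCase", "make_case", "registered_cases", "FIXTURE_SEED"]

FIXTURE_SEED = 20231101
_LAMBDA_UM = 0.555


@dataclass
class AnalyticCase:
    """A named generator plus its closed-form expectations.

    ``payload`` holds the generated object(s); ``expected`` maps
    quantity names to ``(value, tolerance)`` pairs computed from
    closed-form formulas.
    """

    name: str
    params: dict
    payload: dict
    expected: dict


def _wavefront_from_coeffs(coeffs: dict, pupil: float, mesh: int) -> WavefrontMap:
    c = (np.arange(mesh) - mesh // 2) * (pupil / mesh)
    xx, yy = np.meshgrid(c, c, indexing="xy")
    mask = xx**2 + yy**2 <= (pupil / 2.0) ** 2
    r = pupil / 2.0
    opd = np.zeros_like(xx)
    opd[mask] = zernike.reconstruct(coeffs, xx[mask] / r, yy[mask] / r)
    return WavefrontMap(opd=opd, mask=mask, pupil_diameter=pupil)


def _pure_defocus(defocus_d: float = 1.0, pupil: float = 3.0, mesh: int = 64) -> AnalyticCase:
    r_p = pupil / 2.0
    c20 = defocus_d * r_p**2 / (4.0 * sqrt(3.0))
    wmap = _wavefront_from_coeffs({(2, 0): c20}, pupil, mesh)
    return AnalyticCase(
        name="pure_defocus_wavefront",
        params={"defocus_d": defocus_d, "pupil": pupil, "mesh": mesh},
        payload={"wavefront": wmap},
        expected={"c20_um": (c20, 1e-6)},
    )


def _single_mode(n: int = 4, m: int = 0, amplitude: float = 0.15, pupil: float = 6.0,
                 mesh: int = 64) -> AnalyticCase:
    wmap = _wavefront_from_coeffs({(n, m): amplitude}, pupil, mesh)
    return AnalyticCase(
        name="single_zernike_mode",
        params={"n": n, "m": m, "amplitude": amplitude, "pupil": pupil, "mesh": mesh},
        payload={"wavefront": wmap, "mode": (n, m)},
        expected={"coefficient_um": (amplitude, 1e-6), "rms_um": (abs(amplitude), 1e-4)},
    )


def _airy(pupil: float = 5.0, mesh: int = 128) -> AnalyticCase:
    wmap = _wavefront_from_coeffs({}, pupil, mesh)
    first_zero = 1.22 * _LAMBDA_UM * 1e-3 / pupil * (180.0 / pi) * 60.0
    return AnalyticCase(
        name="airy_psf",
        params={"pupil": pupil, "mesh": mesh},
        payload={"wavefront": wmap},
        expected={"first_zero_arcmin": (first_zero, 0.02), "strehl": (1.0, 1e-3)},
    )


def _uniform_disk(diameter: float = 2.0, step_arcmin: float = 0.1, n: int = 1024) -> AnalyticCase:
    img = np.zeros((n, n))
    img[n // 2, n // 2] = 1.0
    return AnalyticCase(
        name="uniform_disk_image",
        params={"diameter": diameter, "step_arcmin": step_arcmin, "n": n},
        payload={"delta_psf": img, "step_arcmin": step_arcmin},
        expected={"halo_diameter_arcmin": (diameter / sqrt(2.0), 0.005 * diameter)},
    )


def _stigmatic(n2: float = 1.5, radius: float = 10.0) -> AnalyticCase:
    # collimated light entering a denser medium focuses stigmatically on a
    # prolate ellipsoid with Q = -(n1/n2)^2
    surf = ConicSurface(radius, -((1.0 / n2) ** 2), semi_aperture=radius * 0.45, axial_position=0.0)
    focus = n2 * radius / (n2 - 1.0)
    model = EyeModel(
        surfaces=[surf], media=[n2], stop_position=0.0,
        stop_diameter=2 * surf.semi_aperture, pupil_diameter=0.8 * radius,
        retina_position=focus,
    )
    return AnalyticCase(
        name="stigmatic_surface",
        params={"n2": n2, "radius": radius},
        payload={"model": model, "focus": focus},
        expected={"opl_spread_mm": (0.0, 1e-9), "spot_radius_mm": (0.0, 1e-9)},
    )


def _thin_lens_eye(n2: float = 1.336, radius: float = 5.6) -> AnalyticCase:
    """Aberration-free one-surface eye (stigmatic cornea-like conicoid)."""
    surf = ConicSurface(radius, -((1.0 / n2) ** 2), semi_aperture=3.5, axial_position=0.0)
    focus = n2 * radius / (n2 - 1.0)
    model = EyeModel(
        surfaces=[surf], media=[n2], stop_position=0.0, stop_diameter=7.0,
        pupil_diameter=4.0, retina_position=focus,
    )
    return AnalyticCase(
        name="thin_lens_eye",
        params={"n2": n2, "radius": radius},
        payload={"model": model},
        expected={"strehl": (1.0, 1e-3), "visual_strehl": (1.0, 1e-3),
                  "paraxial_focus_mm": (focus, 1e-6)},
    )


def _marechal(sigma_um: float = 0.03, pupil: float = 3.0, mesh: int = 64,
              seed: int = FIXTURE_SEED) -> AnalyticCase:
    rng = np.random.default_rng(seed)
    modes = [(n, m) for n in range(3, 7) for m in range(-n, n + 1, 2)]
    raw = {nm: rng.standard_normal() for nm in modes}
    norm = sqrt(sum(v * v for v in raw.values()))
    coeffs = {nm: v / norm * sigma_um for nm, v in raw.items()}
    wmap = _wavefront_from_coeffs(coeffs, pupil, mesh)
    strehl = exp(-((2.0 * pi * sigma_um / _LAMBDA_UM) ** 2))
    return AnalyticCase(
        name="marechal_psf",
        params={"sigma_um": sigma_um, "pupil": pupil, "mesh": mesh, "seed": seed},
        payload={"wavefront": wmap, "coeffs": coeffs},
        expected={"strehl": (strehl, 0.02 * strehl)},
    )


_REGISTRY = {
    "pure_defocus_wavefront": _pure_defocus,
    "single_zernike_mode": _single_mode,
    "airy_psf": _airy,
    "uniform_disk_image": _uniform_disk,
    "stigmatic_surface": _stigmatic,
    "thin_lens_eye": _thin_lens_eye,
    "marechal_psf": _marechal,
}


def registered_cases() -> list[str]:
    return sorted(_REGISTRY)


def make_case(name: str, **params) -> AnalyticCase:
    """Build a registered analytic case with optional parameter overrides."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown case {name!r}; registered: {registered_cases()}") from None
    return builder(**params)
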