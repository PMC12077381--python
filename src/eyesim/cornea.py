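"""Virgin and post-LASIK corneal models.

The virgin cornea is a conicoid anterior surface (R = 7.8 mm) whose
asphericity is solved so that the spherical aberration of the isolated
anterior surface, traced into stroma of index 1.3771, is +0.28 um over a
6.0-mm pupil, plus a fixed spherical posterior surface (R = 6.5 mm) and
0.55 mm central thickness.

Post-LASIK corneas change only the anterior surface: its radius is set
from the keratometric power change equal to the corrected spherical
error, its conic constant is re-solved to reproduce the regression-based
induced spherical aberration (measured in the single-surface
keratometric convention, n = 1.3391, 6.5-mm pupil), and the central
thickness is reduced per the Munnerlyn ablation depth for myopic
corrections.  Coma induction adds a Zernike c(3,1) sag term to the
anterior surface, iterated until the anterior-surface wavefront carries
the requested coma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .raytrace import EyeModel, compute_wavefront, fit_zernike, paraxial_focus
from .surfaces import ConicSurface, ZernikeSagSurface

__all__ = [
    "N_STROMA",
    "N_KERATOMETRIC",
    "R_ANTERIOR_VIRGIN",
    "CorneaSpec",
    "LasikSpec",
    "build_virgin_cornea",
    "induced_sa",
    "munnerlyn_depth_um",
    "build_lasik_cornea",
    "add_coma",
    "anterior_surface_wavefront",
]

N_STROMA = 1.3771          # corneal stromal index at 555 nm
N_KERATOMETRIC = 1.3391    # single-surface keratometric convention
R_ANTERIOR_VIRGIN = 7.8    # mm
R_POSTERIOR = 6.5          # mm, spherical, never altered
CENTRAL_THICKNESS = 0.55   # mm
VIRGIN_SA_TARGET = 0.280   # um, anterior surface alone, 6.0-mm pupil, n=1.3771
ABLATION_ZONE_DEFAULT = 6.0  # mm

# induced anterior-surface SA per diopter of correction, 6.5-mm pupil.
# Written in terms of the (positive) correction magnitude; this is the
# reading of the published regressions that reproduces the tabulated
# per-condition values.
_MYOPIC_SA = (-0.223, 0.169)     # dSA = a + b * magnitude
_HYPEROPIC_SA = (-0.050, -0.277)


@dataclass
class CorneaSpec:
    """Two-surface cornea: anterior (conic or Zernike-sag), stroma, posterior."""

    anterior: object
    central_thickness: float = CENTRAL_THICKNESS
    posterior: ConicSurface = field(
        default_factory=lambda: ConicSurface(R_POSTERIOR, 0.0, semi_aperture=4.5, axial_position=CENTRAL_THICKNESS)
    )
    n_stroma: float = N_STROMA

    def __post_init__(self):
        if self.central_thickness <= 0.3:
            raise ValueError(f"central thickness {self.central_thickness} mm below safe residual bed")
        if self.posterior.conic_constant != 0.0 or self.posterior.radius_of_curvature != R_POSTERIOR:
            raise ValueError("posterior corneal surface must stay spherical with R=6.5 mm")
        # keep posterior vertex at the (possibly thinned) central thickness
        self.posterior = replace(self.posterior, axial_position=self.central_thickness)

    def to_dict(self) -> dict:
        return {
            "anterior": self.anterior.to_dict(),
            "central_thickness": float(self.central_thickness),
            "n_stroma": float(self.n_stroma),
        }


@dataclass(frozen=True)
class LasikSpec:
    """A LASIK correction: magnitude (D, positive), type, and coma flag."""

    correction_magnitude: float
    surgery_type: str  # "myopic" | "hyperopic"
    include_coma: bool = False
    coma_target: float = 0.5       # um at definition pupil
    ablation_zone: float = ABLATION_ZONE_DEFAULT  # mm

    def __post_init__(self):
        if self.surgery_type not in ("myopic", "hyperopic"):
            raise ValueError("surgery_type must be 'myopic' or 'hyperopic'")
        if self.correction_magnitude <= 0:
            raise ValueError("correction magnitude must be positive")
        if self.correction_magnitude > 10.0:
            raise ValueError("correction magnitude outside regression support (>10 D)")

    @property
    def in_study_grid(self) -> bool:
        grid = {"myopic": (2.5, 4.5, 7.5), "hyperopic": (2.5, 4.5)}
        return self.correction_magnitude in grid[self.surgery_type]

    @property
    def signed_error(self) -> float:
        """Pre-op spherical error in D (negative for myopia)."""
        return -self.correction_magnitude if self.surgery_type == "myopic" else self.correction_magnitude


def induced_sa(spec: LasikSpec) -> float:
    """Induced anterior-surface spherical aberration, um at 6.5-mm pupil."""
    a, b = _MYOPIC_SA if spec.surgery_type == "myopic" else _HYPEROPIC_SA
    return a + b * spec.correction_magnitude


def munnerlyn_depth_um(correction: float, zone_mm: float = ABLATION_ZONE_DEFAULT) -> float:
    """Central ablation depth t = S^2 D / 3 (um), S in mm, D in diopters."""
    return zone_mm**2 * correction / 3.0


def anterior_surface_wavefront(
    anterior, n_image: float, pupil: float, mesh: int = 128, max_order: int = 8
):
    """Zernike expansion of the isolated anterior surface's wavefront.

    The surface is traced alone with the stated image-side index and the
    retina at its paraxial focus -- the convention in which both the
    virgin SA target (n=1.3771, 6-mm pupil) and the LASIK regressions
    (n=1.3391, 6.5-mm pupil) are defined.
    """
    surf = _at_origin(anterior)
    model = EyeModel(
        surfaces=[surf],
        media=[n_image],
        stop_position=0.0,
        stop_diameter=2.0 * surf.semi_aperture,
        pupil_diameter=pupil,
    )
    model = replace(model, retina_position=paraxial_focus(model))
    wmap = compute_wavefront(model, mesh=mesh)
    exp, _ = fit_zernike(wmap, max_order=max_order)
    return exp


def _at_origin(surface):
    if isinstance(surface, ZernikeSagSurface):
        return ZernikeSagSurface(
            base=replace(surface.base, axial_position=0.0),
            zernike_sag_coeffs=dict(surface.zernike_sag_coeffs),
            normalization_radius=surface.normalization_radius,
        )
    return replace(surface, axial_position=0.0)


def _solve_conic_for_sa(radius, sa_target, n_image, pupil, semi_aperture=4.5,
                        bracket=(-6.0, 8.0), mesh=128, tol=1e-5):
    """Root-find the conic constant giving the target c(4,0)."""

    def f(q):
        surf = ConicSurface(radius, q, semi_aperture=semi_aperture, axial_position=0.0)
        return anterior_surface_wavefront(surf, n_image, pupil, mesh=mesh)[(4, 0)] - sa_target

    lo, hi = bracket
    # oblate conics leave their domain at (1+Q) r^2 = R^2; stay clear of it
    hi = min(hi, 0.92 * radius**2 / (pupil / 2.0) ** 2 - 1.0)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"conic constant not bracketed in [{lo}, {hi}] for SA target {sa_target} um"
        )
    return brentq(f, lo, hi, xtol=tol)


def build_virgin_cornea(mesh: int = 128) -> CorneaSpec:
    """Virgin cornea with asphericity solved for +0.28 um SA at 6 mm."""
    q = _solve_conic_for_sa(
        R_ANTERIOR_VIRGIN, VIRGIN_SA_TARGET, N_STROMA, 6.0, bracket=(-1.0, 0.5), mesh=mesh
    )
    anterior = ConicSurface(R_ANTERIOR_VIRGIN, q, semi_aperture=4.5, axial_position=0.0)
    return CorneaSpec(anterior=anterior)


def keratometric_power(radius_mm: float) -> float:
    """Corneal power (D) under the keratometric single-surface convention."""
    return (N_KERATOMETRIC - 1.0) / (radius_mm * 1e-3)


def build_lasik_cornea(spec: LasikSpec, virgin: Optional[CorneaSpec] = None, mesh: int = 128) -> CorneaSpec:
    """Post-LASIK cornea reproducing the regression-based induced SA.

    The anterior radius realizes a keratometric power change equal to
    the corrected error (flattened for myopic, steepened for hyperopic
    corrections); the conic constant is re-solved so that the
    single-surface (n=1.3391, 6.5-mm pupil) c(4,0) equals the virgin
    baseline plus the regression's induced SA; myopic central thickness
    drops by the Munnerlyn depth.
    """
    if virgin is None:
        virgin = build_virgin_cornea(mesh=mesh)
    m = spec.correction_magnitude
    p0 = keratometric_power(R_ANTERIOR_VIRGIN)
    p_new = p0 - m if spec.surgery_type == "myopic" else p0 + m
    r_new = (N_KERATOMETRIC - 1.0) / p_new * 1e3

    baseline = anterior_surface_wavefront(virgin.anterior, N_KERATOMETRIC, 6.5, mesh=mesh)[(4, 0)]
    sa_target = baseline + induced_sa(spec)
    q_new = _solve_conic_for_sa(r_new, sa_target, N_KERATOMETRIC, 6.5, mesh=mesh)

    thickness = CENTRAL_THICKNESS
    if spec.surgery_type == "myopic":
        thickness -= munnerlyn_depth_um(m, spec.ablation_zone) * 1e-3
    anterior = ConicSurface(r_new, q_new, semi_aperture=4.5, axial_position=0.0)
    cornea = CorneaSpec(anterior=anterior, central_thickness=thickness)
    if spec.include_coma:
        cornea = add_coma(cornea, target=spec.coma_target)
    return cornea


def add_coma(cornea: CorneaSpec, target: float = 0.5, pupil: float = 6.5,
             mesh: int = 128, tol: float = 0.005, max_iter: int = 10) -> CorneaSpec:
    """Add a c(3,1) sag term until the anterior wavefront coma hits ``target``.

    Fixed-point iteration on the sag coefficient; the initial guess uses
    the thin-phase relation (wavefront ~ (n-1) * sag) in the
    keratometric convention.
    """
    if target < 0:
        raise ValueError("coma target must be non-negative")
    if target == 0.0:
        return cornea
    base = cornea.anterior if isinstance(cornea.anterior, ConicSurface) else cornea.anterior.base
    sag_coeff = target / (N_KERATOMETRIC - 1.0)
    for _ in range(max_iter):
        anterior = ZernikeSagSurface(
            base=base,
            zernike_sag_coeffs={(3, 1): sag_coeff},
            normalization_radius=pupil / 2.0,
        )
        measured = anterior_surface_wavefront(anterior, N_KERATOMETRIC, pupil, mesh=mesh)[(3, 1)]
        if abs(measured - target) <= tol:
            return CorneaSpec(anterior=anterior, central_thickness=cornea.central_thickness)
        sag_coeff *= target / measured
    raise RuntimeError(f"coma induction did not converge to {target} um in {max_iter} iterations")
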