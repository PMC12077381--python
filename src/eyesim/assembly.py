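"""Assembly of pseudophakic eye models.

A pseudophakic eye is the cornea (two surfaces and stroma), aqueous
humour, the IOL 4.5 mm behind the posterior corneal surface, vitreous,
and the retina, with the aperture stop at the iris plane just in front
of the IOL.  The retina is placed per model at the plane of minimum RMS
spot size for a distant object, mirroring the per-eye axial length
adjustment of the modelling procedure.

Two simulation modes are supported: ``full_surface`` rebuilds the
corneal geometry for each post-LASIK condition, while ``phase_plate``
keeps the virgin geometry and injects the LASIK-induced aberration
deltas analytically at the pupil.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import zernike
from .cornea import CorneaSpec, LasikSpec, induced_sa
from .iol import N_AQUEOUS, N_VITREOUS, IOLSpec
from .raytrace import (
    EyeModel,
    PhasePlate,
    ZernikeExpansion,
    entrance_beam_scale_at_stop,
    focus_retina,
)
from .surfaces import ConicSurface

__all__ = [
    "ACD_DEFAULT",
    "STOP_OFFSET",
    "PseudophakicEyeSpec",
    "assemble_eye",
    "make_phase_plate_eye",
    "lasik_delta_plate",
    "aberration_plate",
    "spot_compensating_defocus",
]

ACD_DEFAULT = 4.5  # mm, posterior cornea to IOL anterior vertex
STOP_OFFSET = 0.5  # mm, iris plane in front of the IOL anterior surface


@dataclass
class PseudophakicEyeSpec:
    """Components and working conditions of one pseudophakic eye model."""

    cornea: CorneaSpec
    iol: IOLSpec
    acd: float = ACD_DEFAULT
    pupil_diameter: float = 3.0
    mode: str = "full_surface"  # or "phase_plate"
    plate_aberrations: Optional[ZernikeExpansion] = None

    def __post_init__(self):
        if not 3.2 <= self.acd <= 4.5:
            raise ValueError(f"anterior chamber depth {self.acd} mm outside the 3.2-4.5 mm range")
        if self.pupil_diameter > 6.0:
            raise ValueError("pupil diameter above 6.0 mm is outside the model's validity")
        if self.mode not in ("full_surface", "phase_plate"):
            raise ValueError("mode must be 'full_surface' or 'phase_plate'")


def assemble_eye(spec: PseudophakicEyeSpec, focus: bool = True, focus_mesh: int = 64) -> EyeModel:
    """Build and (by default) focus the full eye model.

    The surface stack is anterior cornea / stroma / posterior cornea /
    aqueous / IOL anterior / IOL / IOL posterior / vitreous / retina.
    The stop diameter is set from the working pupil via the paraxial
    beam scale at the iris plane.
    """
    from .iol import _surface_at  # shared placement helper

    t_cornea = spec.cornea.central_thickness
    z_iol = t_cornea + spec.acd
    surfaces = [
        _surface_at(spec.cornea.anterior, 0.0),
        replace(spec.cornea.posterior, axial_position=t_cornea),
        _surface_at(spec.iol.anterior, z_iol),
        _surface_at(spec.iol.posterior, z_iol + spec.iol.central_thickness),
    ]
    media = [spec.cornea.n_stroma, N_AQUEOUS, spec.iol.n_iol, N_VITREOUS]
    model = EyeModel(
        surfaces=surfaces,
        media=media,
        stop_position=z_iol - STOP_OFFSET,
        stop_diameter=1.0,  # provisional; set from the paraxial beam scale below
        pupil_diameter=spec.pupil_diameter,
    )
    scale = entrance_beam_scale_at_stop(model)
    model = replace(model, stop_diameter=spec.pupil_diameter * scale)
    if focus:
        model = focus_retina(model, mesh=focus_mesh)
    return model


def make_phase_plate_eye(base_eye: EyeModel, aberrations: ZernikeExpansion) -> EyeModel:
    """Attach a Zernike phase screen at the pupil of an assembled eye.

    The geometry is untouched; the OPD described by ``aberrations``
    (defined over the working pupil radius) is added analytically
    during wavefront computation.
    """
    if abs(aberrations.pupil_radius - base_eye.pupil_diameter / 2.0) > 1e-9:
        raise ValueError(
            f"plate normalization radius {aberrations.pupil_radius} mm must equal the "
            f"working pupil radius {base_eye.pupil_diameter / 2.0} mm"
        )
    plate = PhasePlate(coeffs=dict(aberrations.coefficients), radius=aberrations.pupil_radius)
    return replace(base_eye, phase_plate=plate)


def spot_compensating_defocus(coeffs: dict, grid_n: int = 64) -> float:
    """Defocus coefficient minimizing the RMS transverse ray aberration.

    The geometric spot of a wavefront scales with its gradient, so the
    min-spot refocus applied to the full-surface models is mirrored on a
    phase screen by adding the c(2,0) that minimizes the mean squared
    gradient of the total OPD over the unit pupil.
    """
    c = (np.arange(grid_n) - grid_n // 2 + 0.5) * (2.0 / grid_n)
    xx, yy = np.meshgrid(c, c)
    m = xx**2 + yy**2 <= 1.0
    gx = np.zeros(m.sum())
    gy = np.zeros(m.sum())
    for (n, mm_), cv in coeffs.items():
        if cv and n >= 1:
            dx, dy = zernike.zernike_grad(n, mm_, xx[m], yy[m])
            gx += cv * dx
            gy += cv * dy
    zx, zy = zernike.zernike_grad(2, 0, xx[m], yy[m])
    denom = np.sum(zx**2 + zy**2)
    return float(-(np.sum(gx * zx) + np.sum(gy * zy)) / denom)


def aberration_plate(
    deltas: dict,
    pupil_diameter: float,
    definition_pupil: float = 6.5,
    refocus: bool = True,
    max_order: int = 8,
) -> ZernikeExpansion:
    """Aberration deltas, defined over a large zone, as a pupil phase screen.

    ``deltas`` maps OSA (n, m) indices to coefficients (um) over the
    ``definition_pupil`` diameter; they are rescaled to the working
    pupil by the standard Zernike aperture-scaling relation.  With
    ``refocus`` (default) the defocus produced by the rescaling is
    replaced by the min-spot compensating defocus, mirroring the
    per-condition retinal refocus of the full-surface mode.
    """
    scaled = zernike.scale_pupil(deltas, definition_pupil / 2.0, pupil_diameter / 2.0, max_order=max_order)
    scaled = {nm: c for nm, c in scaled.items() if abs(c) > 1e-12}
    if refocus:
        scaled.pop((2, 0), None)
        scaled[(2, 0)] = spot_compensating_defocus(scaled)
    return ZernikeExpansion(coefficients=scaled, pupil_radius=pupil_diameter / 2.0, max_order=max_order)


def lasik_delta_plate(
    lasik: LasikSpec,
    pupil_diameter: float,
    definition_pupil: float = 6.5,
    refocus: bool = True,
    max_order: int = 8,
) -> ZernikeExpansion:
    """LASIK-induced spherical aberration (and coma) as a pupil phase screen."""
    deltas = {(4, 0): induced_sa(lasik)}
    if lasik.include_coma:
        deltas[(3, 1)] = lasik.coma_target
    return aberration_plate(deltas, pupil_diameter, definition_pupil, refocus, max_order)
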