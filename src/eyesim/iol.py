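"""Parameterized intraocular lens models.

Two designs are provided: a monofocal aspheric biconvex lens (the
control) and an extended-depth-of-focus (EDOF) variant that adds a
smooth wavefront-shaping perturbation to the central 2.20 mm of the
anterior surface.  The proprietary commercial geometries are not
public, so both lenses are parameterized stand-ins: the monofocal is
constrained to its labeled paraxial power in situ and a target isolated
spherical aberration, and the EDOF central-zone amplitude is calibrated
once against the reported virgin-eye depth of focus and then frozen as
the repository default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .raytrace import EyeModel, compute_wavefront, fit_zernike, paraxial_focus, paraxial_power
from .surfaces import ConicSurface, WavefrontShapedSurface

__all__ = [
    "N_AQUEOUS",
    "N_VITREOUS",
    "IOLSpec",
    "EDOFProfile",
    "DEFAULT_EDOF_PROFILE",
    "design_monofocal",
    "design_edof",
    "isolated_iol_sa",
    "calibrate_edof",
]

N_AQUEOUS = 1.3374   # Le Grand aqueous index at 555 nm
N_VITREOUS = 1.3360  # Le Grand vitreous index at 555 nm
N_IOL_DEFAULT = 1.55          # hydrophobic acrylic
IOL_THICKNESS_DEFAULT = 0.6   # mm
OPTIC_DIAMETER = 6.0          # mm


@dataclass
class IOLSpec:
    """A biconvex IOL: labeled power, material, and two surfaces.

    Surface axial positions are relative to the anterior vertex; the
    assembly translates them into the eye.
    """

    labeled_power: float
    n_iol: float
    central_thickness: float
    anterior: object
    posterior: ConicSurface
    optic_diameter: float = OPTIC_DIAMETER
    target_iol_sa: float = -0.411

    def __post_init__(self):
        if self.anterior.radius_of_curvature <= 0 or self.posterior.radius_of_curvature >= 0:
            raise ValueError("IOL must be biconvex (anterior R > 0, posterior R < 0)")
        p = self.in_situ_power()
        if abs(p - self.labeled_power) > 0.05:
            raise ValueError(f"in-situ paraxial power {p:.3f} D deviates from label {self.labeled_power} D")

    def surfaces(self):
        return [self.anterior, self.posterior]

    def in_situ_power(self) -> float:
        """Paraxial power (D) between aqueous and vitreous."""
        return paraxial_power(self.surfaces(), [self.n_iol, N_VITREOUS], n_object=N_AQUEOUS)

    def to_dict(self) -> dict:
        return {
            "labeled_power": float(self.labeled_power),
            "n_iol": float(self.n_iol),
            "central_thickness": float(self.central_thickness),
            "anterior": self.anterior.to_dict(),
            "posterior": self.posterior.to_dict(),
            "optic_diameter": float(self.optic_diameter),
            "target_iol_sa": float(self.target_iol_sa),
        }


@dataclass(frozen=True)
class EDOFProfile:
    """Central wavefront-shaping zone of the EDOF anterior surface.

    ``sag = bump_amplitude_um * (1 - (r/a)^2)**exponent`` inside the
    zone (a = zone_diameter/2) and identically zero outside; value and
    slope are continuous at the boundary, so the wavefront is stretched
    rather than split.
    """

    zone_diameter: float = 2.20
    bump_amplitude_um: float = 0.0
    exponent: float = 3.0


# Frozen default, calibrated so the virgin pseudophakic eye with this
# profile reaches the clinically reported 2.50 D depth of focus at a
# 3.0-mm pupil (see calibrate_edof and docs/methods.md).
DEFAULT_EDOF_PROFILE = EDOFProfile(zone_diameter=2.20, bump_amplitude_um=2.23, exponent=4.0)


def isolated_iol_sa(iol: IOLSpec, aperture: float = 6.0, mesh: int = 128) -> float:
    """c(4,0) of the isolated lens in aqueous for a collimated bundle."""
    model = _isolated_model(iol)
    model = replace(model, pupil_diameter=aperture, retina_position=paraxial_focus(model))
    wmap = compute_wavefront(model, mesh=mesh)
    exp, _ = fit_zernike(wmap)
    return exp[(4, 0)]


def _isolated_model(iol: IOLSpec) -> EyeModel:
    ant = _surface_at(iol.anterior, 0.0)
    post = _surface_at(iol.posterior, iol.central_thickness)
    return EyeModel(
        surfaces=[ant, post],
        media=[iol.n_iol, N_VITREOUS],
        stop_position=0.0,
        stop_diameter=iol.optic_diameter,
        pupil_diameter=aperture_default(iol),
        n_object=N_AQUEOUS,
    )


def aperture_default(iol: IOLSpec) -> float:
    return min(6.0, iol.optic_diameter)


def _surface_at(surface, z):
    """Copy of a (possibly composite) surface placed at axial position z."""
    from .surfaces import ZernikeSagSurface

    if isinstance(surface, WavefrontShapedSurface):
        return WavefrontShapedSurface(
            base=replace(surface.base, axial_position=z),
            zone_diameter=surface.zone_diameter,
            amplitude_um=surface.amplitude_um,
            exponent=surface.exponent,
        )
    if isinstance(surface, ZernikeSagSurface):
        return ZernikeSagSurface(
            base=replace(surface.base, axial_position=z),
            zernike_sag_coeffs=dict(surface.zernike_sag_coeffs),
            normalization_radius=surface.normalization_radius,
        )
    return replace(surface, axial_position=z)


def design_monofocal(
    power: float = 22.0,
    target_sa: float = -0.411,
    n_iol: float = N_IOL_DEFAULT,
    central_thickness: float = IOL_THICKNESS_DEFAULT,
    mesh: int = 128,
) -> IOLSpec:
    """Equi-biconvex aspheric monofocal IOL.

    Radii are solved for the labeled in-situ paraxial power; the
    anterior conic constant is then solved so the isolated lens carries
    ``target_sa`` micrometres of c(4,0) over a 6-mm aperture in aqueous
    (negative for the usual aberration-correcting aspheric design).
    """
    if not 5.0 <= power <= 35.0:
        raise ValueError("labeled power outside the supported 5-35 D range")

    def power_err(r1):
        s = [
            ConicSurface(r1, 0.0, OPTIC_DIAMETER / 2, 0.0),
            ConicSurface(-r1, 0.0, OPTIC_DIAMETER / 2, central_thickness),
        ]
        return paraxial_power(s, [n_iol, N_VITREOUS], n_object=N_AQUEOUS) - power

    r1 = brentq(power_err, 2.0, 200.0, xtol=1e-10)

    def sa_err(q):
        trial = IOLSpec.__new__(IOLSpec)  # bypass power check during solve
        trial.labeled_power = power
        trial.n_iol = n_iol
        trial.central_thickness = central_thickness
        trial.anterior = ConicSurface(r1, q, OPTIC_DIAMETER / 2, 0.0)
        trial.posterior = ConicSurface(-r1, 0.0, OPTIC_DIAMETER / 2, central_thickness)
        trial.optic_diameter = OPTIC_DIAMETER
        trial.target_iol_sa = target_sa
        return isolated_iol_sa(trial, mesh=mesh) - target_sa

    # |Q| is capped where the conic stays defined over the 6-mm optic
    lo, hi = -49.0, 35.0
    if sa_err(lo) * sa_err(hi) > 0:
        raise ValueError(f"isolated SA target {target_sa} um unreachable with |Q| < 50")
    q = brentq(sa_err, lo, hi, xtol=1e-6)
    return IOLSpec(
        labeled_power=power,
        n_iol=n_iol,
        central_thickness=central_thickness,
        anterior=ConicSurface(r1, q, OPTIC_DIAMETER / 2, 0.0),
        posterior=ConicSurface(-r1, 0.0, OPTIC_DIAMETER / 2, central_thickness),
        target_iol_sa=target_sa,
    )


def design_edof(base: IOLSpec, profile: EDOFProfile = DEFAULT_EDOF_PROFILE) -> IOLSpec:
    """EDOF lens: the base monofocal plus the central wavefront-shaping zone.

    Outside the zone the anterior surface is identical to the base; the
    posterior surface and material are untouched.
    """
    if not isinstance(base.anterior, ConicSurface):
        raise ValueError("EDOF design expects a conic base anterior surface")
    shaped = WavefrontShapedSurface(
        base=base.anterior,
        zone_diameter=profile.zone_diameter,
        amplitude_um=profile.bump_amplitude_um,
        exponent=profile.exponent,
    )
    out = IOLSpec.__new__(IOLSpec)
    out.labeled_power = base.labeled_power
    out.n_iol = base.n_iol
    out.central_thickness = base.central_thickness
    out.anterior = shaped
    out.posterior = base.posterior
    out.optic_diameter = base.optic_diameter
    out.target_iol_sa = base.target_iol_sa
    return out


def calibrate_edof(
    dof_target: float = 2.50,
    pupil_diameter: float = 3.0,
    tol: float = 0.05,
    bracket: tuple = (1.2, 2.6),
    exponent: float = 4.0,
    mesh: int = 256,
) -> EDOFProfile:
    """Solve the central-zone amplitude for the virgin-eye depth of focus.

    Bisects the bump amplitude until the virgin pseudophakic eye at the
    stated pupil reaches ``dof_target`` (VS > 0.12 interval width).  The
    result of running this once with the defaults is frozen as
    :data:`DEFAULT_EDOF_PROFILE`.
    """
    from .assembly import PseudophakicEyeSpec, assemble_eye
    from .cornea import build_virgin_cornea
    from .image_quality import depth_of_focus, through_focus

    cornea = build_virgin_cornea()
    base = design_monofocal()

    def dof_of(amplitude):
        profile = EDOFProfile(bump_amplitude_um=amplitude, exponent=exponent)
        iol = design_edof(base, profile)
        eye = assemble_eye(PseudophakicEyeSpec(cornea=cornea, iol=iol, pupil_diameter=pupil_diameter))
        return depth_of_focus(through_focus(eye, mesh=mesh))

    lo, hi = bracket
    f_lo = dof_of(lo) - dof_target
    f_hi = dof_of(hi) - dof_target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"DOF target {dof_target} D not bracketed by amplitudes {bracket} "
            f"(DOF at bracket: {f_lo + dof_target:.2f}, {f_hi + dof_target:.2f} D)"
        )
    amp = brentq(dof_of_minus := (lambda a: dof_of(a) - dof_target), lo, hi, xtol=0.005)
    achieved = dof_of(amp)
    if abs(achieved - dof_target) > tol:
        raise RuntimeError(f"calibration landed at {achieved:.3f} D, outside +-{tol} of target")
    return EDOFProfile(bump_amplitude_um=round(amp, 4), exponent=exponent)
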