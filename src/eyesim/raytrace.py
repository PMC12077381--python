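"""Exact sequential ray tracing and wavefront computation.

Rays from a distant axial object (a collimated bundle parallel to the
optical axis) are traced surface by surface: the intersection with each
conic or Zernike-perturbed surface is found by damped Newton iteration
on the sag equation, refraction uses the exact vector form of Snell's
law, and the optical path length (OPL) accumulates ``n * geometric
path`` through every medium.  The wavefront map is the optical path
difference of each pupil ray relative to the chief ray, measured on a
reference sphere centred on the chief ray's retinal intersection with
its vertex at the paraxial exit pupil.

Units: millimetres for geometry, micrometres for wavefront OPD,
nanometres for wavelength, diopters for powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import zernike
from .surfaces import ConicSurface, Medium, surface_from_dict

__all__ = [
    "Ray",
    "PhasePlate",
    "EyeModel",
    "WavefrontMap",
    "ZernikeExpansion",
    "trace_ray",
    "trace_bundle",
    "compute_wavefront",
    "fit_zernike",
    "paraxial_power",
    "paraxial_focus",
    "exit_pupil_position",
    "focus_retina",
]

_NEWTON_TOL = 1e-10  # mm
_START_OFFSET = 5.0  # mm in front of the first surface


@dataclass
class Ray:
    """A single ray: origin, unit direction and accumulated OPL (mm)."""

    origin: np.ndarray
    direction: np.ndarray
    opl: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)


@dataclass
class PhasePlate:
    """Zernike phase screen applied analytically at the pupil.

    ``coeffs`` maps OSA (n, m) indices to wavefront coefficients in
    micrometres, defined over ``radius`` (mm), which must equal the
    working pupil radius of the model it is attached to.
    """

    coeffs: dict
    radius: float


@dataclass
class EyeModel:
    """Ordered surface stack with following media, stop, and retina.

    ``media`` holds the refractive index *after* each surface; the image
    space index is ``media[-1]``.  ``stop_position`` is the axial
    position of the aperture stop (iris) plane; the working pupil is
    specified as the entrance beam diameter ``pupil_diameter``, which is
    how aperture is defined in the wavefront computation.
    """

    surfaces: list
    media: list
    stop_position: float
    stop_diameter: float
    pupil_diameter: float = 3.0
    n_object: float = 1.0
    retina_position: Optional[float] = None
    wavelength_nm: float = 555.0
    phase_plate: Optional[PhasePlate] = None

    def __post_init__(self):
        if len(self.surfaces) != len(self.media):
            raise ValueError("need one following medium per surface")
        zs = [s.axial_position for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("surfaces must be strictly increasing in axial position")
        if self.retina_position is not None and self.retina_position <= zs[-1]:
            raise ValueError("retina must lie behind the last surface")
        min_semi = min(s.semi_aperture for s in self.surfaces)
        if self.stop_diameter > 2.0 * min_semi:
            raise ValueError("stop diameter exceeds twice the smallest semi-aperture")

    def to_dict(self) -> dict:
        d = {
            "surfaces": [s.to_dict() for s in self.surfaces],
            "media": [float(n) for n in self.media],
            "stop_position": float(self.stop_position),
            "stop_diameter": float(self.stop_diameter),
            "pupil_diameter": float(self.pupil_diameter),
            "n_object": float(self.n_object),
            "retina_position": None if self.retina_position is None else float(self.retina_position),
            "wavelength_nm": float(self.wavelength_nm),
        }
        if self.phase_plate is not None:
            d["phase_plate"] = {
                "coeffs": {f"{n},{m}": float(c) for (n, m), c in self.phase_plate.coeffs.items()},
                "radius": float(self.phase_plate.radius),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EyeModel":
        plate = None
        if d.get("phase_plate"):
            plate = PhasePlate(
                coeffs={tuple(int(v) for v in k.split(",")): c for k, c in d["phase_plate"]["coeffs"].items()},
                radius=d["phase_plate"]["radius"],
            )
        return cls(
            surfaces=[surface_from_dict(s) for s in d["surfaces"]],
            media=list(d["media"]),
            stop_position=d["stop_position"],
            stop_diameter=d["stop_diameter"],
            pupil_diameter=d["pupil_diameter"],
            n_object=d.get("n_object", 1.0),
            retina_position=d.get("retina_position"),
            wavelength_nm=d.get("wavelength_nm", 555.0),
            phase_plate=plate,
        )


# ---------------------------------------------------------------------------
# core trace


def _intersect(surface, px, py, pz, dx, dy, dz):
    """Newton iteration for the ray/surface intersection.

    Returns (t, x, y, z, gx, gy, ok); ``ok`` is False where the
    iteration left the surface domain or failed to converge.
    """
    z0 = surface.axial_position
    t = (z0 - pz) / dz  # plane-intersection initial guess
    gx = gy = None
    for _ in range(60):
        x = px + t * dx
        y = py + t * dy
        z = pz + t * dz
        with np.errstate(invalid="ignore"):
            s, gx, gy = surface.sag_and_grad(x, y)
            f = z - (z0 + s)
            df = dz - gx * dx - gy * dy
            step = f / df
        # damp pathological steps; ocular surfaces are gentle so this rarely fires
        step = np.clip(step, -1.0, 1.0)
        t = t - np.where(np.isfinite(step), step, 0.0)
        live = np.isfinite(step) & (np.abs(step) > _NEWTON_TOL)
        if not np.any(live):
            break
    x = px + t * dx
    y = py + t * dy
    z = pz + t * dz
    with np.errstate(invalid="ignore"):
        s, gx, gy = surface.sag_and_grad(x, y)
        resid = z - (z0 + s)
    ok = np.isfinite(resid) & (np.abs(resid) < 1e-8)
    return t, x, y, z, gx, gy, ok


def _refract(dx, dy, dz, gx, gy, n1, n2):
    """Vector Snell refraction at a surface with sag gradient (gx, gy)."""
    # surface normal, oriented along propagation (+z component positive)
    norm = np.sqrt(gx * gx + gy * gy + 1.0)
    nx, ny, nz = -gx / norm, -gy / norm, 1.0 / norm
    cosi = dx * nx + dy * ny + dz * nz
    eta = n1 / n2
    with np.errstate(invalid="ignore"):
        sin2t = eta * eta * (1.0 - cosi * cosi)
        tir = sin2t >= 1.0
        cost = np.sqrt(np.clip(1.0 - sin2t, 0.0, None))
        k = cost - eta * cosi
        ox = eta * dx + k * nx
        oy = eta * dy + k * ny
        oz = eta * dz + k * nz
    return ox, oy, oz, ~tir


def trace_bundle(model: EyeModel, x, y):
    """Trace a collimated bundle entering at heights (x, y).

    Returns a dict with image-space positions ``(px, py, pz)``, unit
    directions ``(dx, dy, dz)``, accumulated OPL in mm, and a boolean
    ``valid`` mask (False for vignetted / TIR / out-of-domain rays).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float)).ravel()
    y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
    npts = x.size
    z_start = model.surfaces[0].axial_position - _START_OFFSET
    px, py, pz = x.copy(), y.copy(), np.full(npts, z_start)
    dx = np.zeros(npts)
    dy = np.zeros(npts)
    dz = np.ones(npts)
    opl = np.zeros(npts)
    valid = np.ones(npts, dtype=bool)
    n = model.n_object
    for surf, n_next in zip(model.surfaces, model.media):
        t, ix, iy, iz, gx, gy, ok = _intersect(surf, px, py, pz, dx, dy, dz)
        inside = ix * ix + iy * iy <= surf.semi_aperture**2 + 1e-12
        valid &= ok & inside & (t > 0)
        opl = opl + n * t
        dx, dy, dz, no_tir = _refract(dx, dy, dz, gx, gy, n, n_next)
        valid &= no_tir
        px, py, pz = ix, iy, iz
        n = n_next
    return {
        "px": px, "py": py, "pz": pz,
        "dx": dx, "dy": dy, "dz": dz,
        "opl": opl, "valid": valid,
    }


def trace_ray(model: EyeModel, ray: Ray):
    """Trace a single ray, recording every surface intersection.

    Accepts arbitrary (non-collimated) incident rays; returns the exit
    :class:`Ray` and the list of intersection points.  Raises if the ray
    is vignetted or totally internally reflected.
    """
    px, py, pz = ray.origin
    dx, dy, dz = ray.direction
    opl = ray.opl
    n = model.n_object
    hits = []
    for surf, n_next in zip(model.surfaces, model.media):
        t, ix, iy, iz, gx, gy, ok = _intersect(
            surf, np.atleast_1d(px), np.atleast_1d(py), np.atleast_1d(pz),
            np.atleast_1d(dx), np.atleast_1d(dy), np.atleast_1d(dz),
        )
        if not bool(ok[0]) or ix[0] ** 2 + iy[0] ** 2 > surf.semi_aperture**2:
            raise ValueError(f"ray vignetted at surface z={surf.axial_position} mm")
        opl += n * float(t[0])
        hits.append(np.array([ix[0], iy[0], iz[0]]))
        dxa, dya, dza, no_tir = _refract(
            np.atleast_1d(dx), np.atleast_1d(dy), np.atleast_1d(dz),
            np.atleast_1d(gx), np.atleast_1d(gy), n, n_next,
        )
        if not bool(no_tir[0]):
            raise ValueError(f"total internal reflection at surface z={surf.axial_position} mm")
        px, py, pz = float(ix[0]), float(iy[0]), float(iz[0])
        dx, dy, dz = float(dxa[0]), float(dya[0]), float(dza[0])
        n = n_next
    return Ray(origin=[px, py, pz], direction=[dx, dy, dz], opl=opl), hits


# ---------------------------------------------------------------------------
# paraxial optics (y / nu trace)


def _paraxial_through(surf_media, n_in, y, u):
    """Paraxial marginal trace; y, u given at the first vertex plane."""
    n = n_in
    z = surf_media[0][0].axial_position if surf_media else 0.0
    for surf, n_next in surf_media:
        y = y + u * (surf.axial_position - z)
        z = surf.axial_position
        power = (n_next - n) * surf.curvature  # 1/mm
        u = (n * u - y * power) / n_next
        n = n_next
    return y, u, z, n


def paraxial_power(model_or_surfaces, media=None, n_object: float = 1.0) -> float:
    """Equivalent paraxial power in diopters of a model or surface subset."""
    if isinstance(model_or_surfaces, EyeModel):
        pairs = list(zip(model_or_surfaces.surfaces, model_or_surfaces.media))
        n_object = model_or_surfaces.n_object
    else:
        pairs = list(zip(model_or_surfaces, media))
    y0 = 0.1
    y, u, _, n_img = _paraxial_through(pairs, n_object, y0, 0.0)
    return -n_img * u / y0 * 1000.0


def paraxial_focus(model: EyeModel) -> float:
    """Axial position (mm) of the paraxial focus for a distant object."""
    pairs = list(zip(model.surfaces, model.media))
    y, u, z, _ = _paraxial_through(pairs, model.n_object, 0.1, 0.0)
    if u >= 0:
        raise ValueError("system does not converge a collimated beam")
    return z - y / u


def exit_pupil_position(model: EyeModel) -> float:
    """Axial position of the exit pupil (paraxial image of the stop)."""
    after = [(s, n) for s, n in zip(model.surfaces, model.media) if s.axial_position > model.stop_position]
    if not after:
        return model.stop_position
    n_in = model.media[model.surfaces.index(after[0][0]) - 1] if model.surfaces.index(after[0][0]) > 0 else model.n_object
    u0 = 0.05
    y = u0 * (after[0][0].axial_position - model.stop_position)
    n = n_in
    u = u0
    z = after[0][0].axial_position
    for surf, n_next in after:
        y = y + u * (surf.axial_position - z)
        z = surf.axial_position
        power = (n_next - n) * surf.curvature
        u = (n * u - y * power) / n_next
        n = n_next
    if u == 0.0:
        return np.inf
    return z - y / u


def entrance_beam_scale_at_stop(model: EyeModel) -> float:
    """Paraxial height ratio (stop plane)/(entrance) for a collimated ray."""
    before = [(s, n) for s, n in zip(model.surfaces, model.media) if s.axial_position < model.stop_position]
    if not before:
        return 1.0
    y0 = 1.0
    y, u, z, _ = _paraxial_through(before, model.n_object, y0, 0.0)
    return (y + u * (model.stop_position - z)) / y0


# ---------------------------------------------------------------------------
# wavefront


@dataclass
class WavefrontMap:
    """OPD map (micrometres) on an N x N Cartesian grid over the pupil.

    ``opd`` is referenced to the chief ray (zero at the pupil centre);
    ``mask`` flags valid samples (traced, unvignetted, inside the pupil
    disk).  Coordinates are entrance-beam coordinates; the pupil centre
    lies on the grid sample ``[N//2, N//2]``.
    """

    opd: np.ndarray
    mask: np.ndarray
    pupil_diameter: float
    wavelength_nm: float = 555.0

    @property
    def mesh(self) -> int:
        return self.opd.shape[0]

    def grid(self):
        """Pupil-plane coordinate arrays (mm), matching ``opd``."""
        n = self.mesh
        c = (np.arange(n) - n // 2) * (self.pupil_diameter / n)
        return np.meshgrid(c, c, indexing="xy")

    def rms(self, exclude_low_order: bool = True) -> float:
        """RMS OPD in micrometres over the valid pupil."""
        w = self.opd[self.mask]
        if exclude_low_order:
            coeffs, _ = fit_zernike(self, max_order=8)
            return zernike.rms_from_coeffs(coeffs.coefficients)
        return float(np.sqrt(np.mean((w - w.mean()) ** 2)))


@dataclass
class ZernikeExpansion:
    """RMS-normalized OSA Zernike coefficients of a wavefront (micrometres)."""

    coefficients: dict
    pupil_radius: float
    max_order: int = 8
    residual_rms: float = 0.0

    def __getitem__(self, nm: tuple) -> float:
        return self.coefficients.get(nm, 0.0)

    def rms(self, exclude_low: bool = True) -> float:
        return zernike.rms_from_coeffs(self.coefficients, exclude_low=exclude_low)

    def to_dict(self) -> dict:
        return {
            "coefficients": {f"{n},{m}": float(c) for (n, m), c in self.coefficients.items()},
            "pupil_radius": float(self.pupil_radius),
            "max_order": self.max_order,
            "residual_rms": float(self.residual_rms),
        }


def compute_wavefront(
    model: EyeModel,
    pupil_diameter: Optional[float] = None,
    mesh: int = 256,
    max_vignetted_fraction: float = 0.01,
) -> WavefrontMap:
    """OPD map of the model for a distant axial object.

    The reference sphere is centred on the chief ray's retinal
    intersection with radius equal to its distance from the exit pupil;
    OPD is positive where the wavefront is advanced (shorter optical
    path to the reference sphere than the chief ray).  A phase plate
    attached to the model is added analytically.
    """
    if model.retina_position is None:
        raise ValueError("retina position unset; run focus_retina first")
    D = model.pupil_diameter if pupil_diameter is None else pupil_diameter
    c = (np.arange(mesh) - mesh // 2) * (D / mesh)
    xx, yy = np.meshgrid(c, c, indexing="xy")
    mask = xx**2 + yy**2 <= (D / 2.0) ** 2

    chief = trace_bundle(model, np.array([0.0]), np.array([0.0]))
    if not chief["valid"][0]:
        raise ValueError("chief ray does not traverse the model")
    n_img = model.media[-1]
    tz = (model.retina_position - chief["pz"][0]) / chief["dz"][0]
    P = np.array(
        [chief["px"][0] + tz * chief["dx"][0], chief["py"][0] + tz * chief["dy"][0], model.retina_position]
    )
    E = np.array([0.0, 0.0, exit_pupil_position(model)])
    r_ref = np.linalg.norm(P - E)
    opl_chief = chief["opl"][0] + n_img * _sphere_path(chief, P, r_ref)[0]

    out = trace_bundle(model, xx[mask], yy[mask])
    t_sph = _sphere_path(out, P, r_ref)
    valid = out["valid"] & np.isfinite(t_sph)
    frac_bad = 1.0 - valid.sum() / valid.size
    if frac_bad > max_vignetted_fraction:
        raise ValueError(
            f"{100 * frac_bad:.1f}% of pupil rays vignetted -- model misconfigured"
        )
    opl = out["opl"] + n_img * t_sph
    w = np.zeros(mask.shape)
    wm = np.zeros(valid.shape)
    wm[valid] = (opl_chief - opl[valid]) * 1000.0  # mm -> um, advance positive
    w[mask] = wm
    full_mask = mask.copy()
    full_mask[mask] = valid

    if model.phase_plate is not None:
        plate = model.phase_plate
        if abs(plate.radius - D / 2.0) > 1e-9:
            raise ValueError(
                f"phase plate normalization radius {plate.radius} mm does not match "
                f"pupil radius {D / 2.0} mm"
            )
        w[full_mask] += zernike.reconstruct(plate.coeffs, xx[full_mask] / plate.radius, yy[full_mask] / plate.radius)
        # re-reference to the pupil centre (piston only)
        w[full_mask] -= zernike.reconstruct(plate.coeffs, 0.0, 0.0)

    w[~full_mask] = 0.0
    return WavefrontMap(opd=w, mask=full_mask, pupil_diameter=D, wavelength_nm=model.wavelength_nm)


def _sphere_path(bundle, P, r_ref):
    """Path length from each image-space ray to the reference sphere."""
    ocx = bundle["px"] - P[0]
    ocy = bundle["py"] - P[1]
    ocz = bundle["pz"] - P[2]
    b = bundle["dx"] * ocx + bundle["dy"] * ocy + bundle["dz"] * ocz
    cc = ocx**2 + ocy**2 + ocz**2 - r_ref**2
    with np.errstate(invalid="ignore"):
        disc = b * b - cc
        t = -b - np.sqrt(disc)
    return t


def fit_zernike(wmap: WavefrontMap, max_order: int = 8) -> tuple[ZernikeExpansion, float]:
    """Least-squares Zernike decomposition of a wavefront map."""
    xx, yy = wmap.grid()
    r = wmap.pupil_diameter / 2.0
    coeffs, resid = zernike.fit_zernike_coeffs(
        xx[wmap.mask] / r, yy[wmap.mask] / r, wmap.opd[wmap.mask], max_order=max_order
    )
    exp = ZernikeExpansion(coefficients=coeffs, pupil_radius=r, max_order=max_order, residual_rms=resid)
    return exp, resid


def focus_retina(model: EyeModel, mesh: int = 32) -> EyeModel:
    """Place the retina at the plane of minimum RMS transverse spot radius.

    A collimated bundle filling the working pupil is traced; since each
    ray's transverse position is linear in z, the RMS spot radius about
    the bundle centroid is an exactly quadratic function of z and the
    minimizer is closed-form (well below 0.1 um accuracy).
    """
    D = model.pupil_diameter
    c = (np.arange(mesh) - mesh // 2 + 0.5) * (D / mesh)
    xx, yy = np.meshgrid(c, c)
    m = xx**2 + yy**2 <= (D / 2.0) ** 2
    out = trace_bundle(model, xx[m], yy[m])
    v = out["valid"]
    if v.sum() < 10:
        raise ValueError("too few rays traverse the model to focus the retina")
    sx = out["dx"][v] / out["dz"][v]
    sy = out["dy"][v] / out["dz"][v]
    ax = out["px"][v] - out["pz"][v] * sx
    ay = out["py"][v] - out["pz"][v] * sy
    dax = ax - ax.mean()
    day = ay - ay.mean()
    dsx = sx - sx.mean()
    dsy = sy - sy.mean()
    denom = np.sum(dsx**2) + np.sum(dsy**2)
    if denom < 1e-16:
        raise ValueError("bundle leaves the model collimated; no focus exists")
    z_best = -(np.sum(dax * dsx) + np.sum(day * dsy)) / denom
    if z_best <= model.surfaces[-1].axial_position:
        raise ValueError("best focus falls inside the optical stack")
    return replace(model, retina_position=float(z_best))
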