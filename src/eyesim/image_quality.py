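"""Fourier-optics image quality: PSF, MTF, Visual Strehl, through-focus.

The generalized pupil function is ``exp(i 2 pi W / lambda)`` over the
pupil mask; the PSF is the squared modulus of its Fourier transform and
the MTF the modulus of the PSF's transform, normalized to unity at zero
frequency.  Retinal image quality is summarized by the Visual Strehl
ratio: the volume under the MTF weighted by a neural contrast
sensitivity function (CSF), normalized by the same volume for the
diffraction-limited pupil.  Through-focus curves sample Visual Strehl
on a grid of defocus values injected analytically as Zernike defocus
``c20 = D * r_p^2 / (4 sqrt(3))`` (um, with the pupil radius r_p in mm
and defocus D in diopters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import zernike
from .raytrace import EyeModel, WavefrontMap, compute_wavefront

__all__ = [
    "PSFImage",
    "MTFGrid",
    "CSFModel",
    "ThroughFocusCurve",
    "compute_psf",
    "compute_mtf",
    "visual_strehl",
    "through_focus",
    "depth_of_focus",
    "defocus_c20",
    "strehl_ratio",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi


@dataclass
class PSFImage:
    """Monochromatic PSF on an angular grid, energy-normalized to 1."""

    intensity: np.ndarray
    step_arcmin: float

    @property
    def field_arcmin(self) -> float:
        return self.intensity.shape[0] * self.step_arcmin

    def angular_grid(self):
        n = self.intensity.shape[0]
        c = (np.arange(n) - n // 2) * self.step_arcmin
        return np.meshgrid(c, c, indexing="xy")


@dataclass
class MTFGrid:
    """2-D modulation transfer function; frequencies in cycles/degree."""

    values: np.ndarray
    step_cpd: float

    def frequency_magnitude(self):
        n = self.values.shape[0]
        c = (np.arange(n) - n // 2) * self.step_cpd
        fx, fy = np.meshgrid(c, c, indexing="xy")
        return np.hypot(fx, fy)


@dataclass(frozen=True)
class CSFModel:
    """Radially symmetric neural contrast sensitivity ``S(f) = f^a exp(-b f)``.

    With the defaults the sensitivity peaks near 8 cycles/degree and
    is negligible by 60 cycles/degree, the usual band of the average
    photopic neural CSF; S(0) = 0 so the DC term never contributes.
    """

    exponent: float = 0.8
    decay: float = 0.10

    def __call__(self, f_cpd):
        f = np.asarray(f_cpd, dtype=float)
        return np.where(f > 0.0, f**self.exponent * np.exp(-self.decay * f), 0.0)

    @property
    def peak_frequency(self) -> float:
        return self.exponent / self.decay


@dataclass
class ThroughFocusCurve:
    """Visual Strehl sampled on a uniform defocus grid (diopters)."""

    defocus: np.ndarray
    vs: np.ndarray
    pupil_diameter: float

    @property
    def best_focus_index(self) -> int:
        return int(np.argmax(self.vs))

    @property
    def step(self) -> float:
        return float(self.defocus[1] - self.defocus[0])


def _pupil_field(wmap: WavefrontMap, padding: int):
    lam_um = wmap.wavelength_nm * 1e-3
    phase = 2.0 * np.pi * wmap.opd / lam_um
    n = wmap.mesh
    m = n * padding
    field = np.zeros((m, m), dtype=complex)
    field[:n, :n] = wmap.mask * np.exp(1j * phase)
    return field


def _sampling(wmap: WavefrontMap, padding: int):
    lam_mm = wmap.wavelength_nm * 1e-6
    step_rad = lam_mm / (padding * wmap.pupil_diameter)
    return step_rad * ARCMIN_PER_RAD


def check_sampling(wmap: WavefrontMap, padding: int,
                   max_step_arcmin: float = 0.25, min_field_arcmin: float = 30.0):
    """Enforce the PSF sampling contract, naming the fix when violated."""
    lam_mm = wmap.wavelength_nm * 1e-6
    step = _sampling(wmap, padding)
    field = wmap.mesh * (lam_mm / wmap.pupil_diameter) * ARCMIN_PER_RAD
    if step > max_step_arcmin:
        need = int(np.ceil(lam_mm / (max_step_arcmin / ARCMIN_PER_RAD) / wmap.pupil_diameter))
        raise ValueError(
            f"angular sampling {step:.3f} arcmin exceeds {max_step_arcmin}; "
            f"increase padding to at least {need}"
        )
    if field < min_field_arcmin:
        need = int(np.ceil(min_field_arcmin / (lam_mm / wmap.pupil_diameter * ARCMIN_PER_RAD)))
        raise ValueError(
            f"PSF field {field:.1f} arcmin below {min_field_arcmin}; "
            f"increase the wavefront mesh to at least {need}"
        )


def compute_psf(wmap: WavefrontMap, padding: int = 4) -> PSFImage:
    """PSF as the squared modulus of the Fourier-transformed pupil."""
    if padding < 4:
        raise ValueError("padding below 4 undersamples the PSF")
    check_sampling(wmap, padding)
    field = _pupil_field(wmap, padding)
    amp = np.fft.fftshift(np.fft.fft2(field))
    psf = np.abs(amp) ** 2
    psf /= psf.sum()
    return PSFImage(intensity=psf, step_arcmin=_sampling(wmap, padding))


def compute_mtf(psf: PSFImage) -> MTFGrid:
    """MTF = |FFT(PSF)| normalized to 1 at zero frequency."""
    otf = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf.intensity)))
    n = psf.intensity.shape[0]
    dc = np.abs(otf[n // 2, n // 2])
    step_cpd = 1.0 / (n * psf.step_arcmin / 60.0)
    return MTFGrid(values=np.abs(otf) / dc, step_cpd=step_cpd)


def strehl_ratio(wmap: WavefrontMap, padding: int = 4) -> float:
    """Conventional Strehl: peak PSF over the diffraction-limited peak."""
    psf = compute_psf(wmap, padding)
    ref = compute_psf(_reference_map(wmap), padding)
    return float(psf.intensity.max() / ref.intensity.max())


def _reference_map(wmap: WavefrontMap) -> WavefrontMap:
    return WavefrontMap(
        opd=np.zeros_like(wmap.opd), mask=wmap.mask,
        pupil_diameter=wmap.pupil_diameter, wavelength_nm=wmap.wavelength_nm,
    )


def _csf_weights(wmap: WavefrontMap, csf: CSFModel, padding: int):
    psf_ref = compute_psf(_reference_map(wmap), padding)
    mtf_ref = compute_mtf(psf_ref)
    w = csf(mtf_ref.frequency_magnitude())
    denom = float(np.sum(w * mtf_ref.values))
    return w, denom


def visual_strehl(wmap: WavefrontMap, csf: CSFModel | None = None, padding: int = 4) -> float:
    """CSF-weighted Visual Strehl ratio (1 for an unaberrated pupil)."""
    csf = csf or CSFModel()
    w, denom = _csf_weights(wmap, csf, padding)
    mtf = compute_mtf(compute_psf(wmap, padding))
    return float(np.sum(w * mtf.values) / denom)


def defocus_c20(defocus_d: float, pupil_diameter: float) -> float:
    """Zernike defocus coefficient (um) equivalent to a dioptric defocus."""
    r_p = pupil_diameter / 2.0
    return defocus_d * r_p**2 / (4.0 * np.sqrt(3.0))


def through_focus(
    eye: EyeModel,
    csf: CSFModel | None = None,
    focus_range: float = 8.0,
    step: float = 0.1,
    mesh: int = 256,
    padding: int = 4,
    wavefront: WavefrontMap | None = None,
) -> ThroughFocusCurve:
    """Visual Strehl vs. defocus over ``[-range/2, +range/2]`` diopters.

    The wavefront is traced once at the eye's focused far point; each
    defocus sample adds the equivalent Zernike defocus analytically.
    Positive defocus means the retina conjugates in front of the far
    point (a near target).
    """
    csf = csf or CSFModel()
    wmap = wavefront if wavefront is not None else compute_wavefront(eye, mesh=mesh)
    check_sampling(wmap, padding)
    half = focus_range / 2.0
    nsteps = int(round(focus_range / step)) + 1
    defocus = np.linspace(-half, half, nsteps)
    xx, yy = wmap.grid()
    r_p = wmap.pupil_diameter / 2.0
    z20 = zernike.zernike_eval(2, 0, xx / r_p, yy / r_p)
    w, denom = _csf_weights(wmap, csf, padding)
    vs = np.empty(nsteps)
    for i, d in enumerate(defocus):
        shifted = WavefrontMap(
            opd=wmap.opd + defocus_c20(d, wmap.pupil_diameter) * z20,
            mask=wmap.mask,
            pupil_diameter=wmap.pupil_diameter,
            wavelength_nm=wmap.wavelength_nm,
        )
        mtf = compute_mtf(compute_psf(shifted, padding))
        vs[i] = np.sum(w * mtf.values) / denom
    return ThroughFocusCurve(defocus=defocus, vs=vs, pupil_diameter=wmap.pupil_diameter)


def depth_of_focus(curve: ThroughFocusCurve, threshold: float = 0.12) -> float:
    """Width (D) of the contiguous super-threshold interval around the peak.

    Crossings are located by linear interpolation between samples; if
    the curve never rises above the threshold the DOF is 0.
    """
    vs = curve.vs
    d = curve.defocus
    imax = curve.best_focus_index
    if vs[imax] <= threshold:
        import warnings

        warnings.warn("through-focus curve never exceeds the threshold; DOF = 0")
        return 0.0
    lo = imax
    while lo > 0 and vs[lo - 1] > threshold:
        lo -= 1
    hi = imax
    while hi < len(vs) - 1 and vs[hi + 1] > threshold:
        hi += 1
    left = d[lo]
    if lo > 0:  # interpolate the crossing below
        left = d[lo - 1] + (threshold - vs[lo - 1]) / (vs[lo] - vs[lo - 1]) * (d[lo] - d[lo - 1])
    right = d[hi]
    if hi < len(vs) - 1:
        right = d[hi] + (threshold - vs[hi]) / (vs[hi + 1] - vs[hi]) * (d[hi + 1] - d[hi])
    return float(right - left)
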