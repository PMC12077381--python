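"""Zernike polynomial basis in the ANSI Z80.28 / OSA convention.

Modes are identified by the double index ``(n, m)`` with ``n >= |m|`` and
``n - |m|`` even; ``m >= 0`` selects the cosine harmonic and ``m < 0`` the
sine harmonic.  All modes are RMS-normalized over the unit disk, so a
coefficient of ``a`` micrometres contributes ``a`` micrometres to the
wavefront RMS.  Polynomials are represented internally as bivariate
Cartesian power series, which gives exact derivatives everywhere
(including the pupil centre, where polar-form gradients are singular).
"""

from __future__ import annotations

from functools import lru_cache
from math import comb, factorial, sqrt

import numpy as np

__all__ = [
    "osa_index",
    "osa_modes",
    "zernike_cartesian",
    "zernike_eval",
    "zernike_grad",
    "design_matrix",
    "fit_zernike_coeffs",
    "reconstruct",
    "scale_pupil",
    "rms_from_coeffs",
]


def osa_index(n: int, m: int) -> int:
    """Single OSA/ANSI index ``j`` for the double index ``(n, m)``."""
    return (n * (n + 2) + m) // 2


def osa_modes(max_order: int) -> list[tuple[int, int]]:
    """All ``(n, m)`` modes with ``n <= max_order``, in OSA ``j`` order."""
    return [(n, m) for n in range(max_order + 1) for m in range(-n, n + 1, 2)]


def _poly_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Product of two bivariate power series (coefficient matrices)."""
    out = np.zeros((a.shape[0] + b.shape[0] - 1, a.shape[1] + b.shape[1] - 1))
    for (i, j), ca in np.ndenumerate(a):
        if ca != 0.0:
            out[i : i + b.shape[0], j : j + b.shape[1]] += ca * b
    return out


def _radial_coeffs(n: int, m: int) -> dict[int, float]:
    """Coefficients of rho**(n-2k) in the radial polynomial R_n^|m|."""
    m = abs(m)
    coeffs = {}
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        coeffs[n - 2 * k] = float(c)
    return coeffs


def _harmonic_poly(m: int) -> np.ndarray:
    """Cartesian coefficients of rho**|m| * cos(|m| theta) (m>=0) or sin (m<0)."""
    am = abs(m)
    out = np.zeros((am + 1, am + 1))
    if am == 0:
        out[0, 0] = 1.0
        return out
    # (x + i y)**m = sum_k C(m,k) x**(m-k) (iy)**k ; cos -> real part, sin -> imag
    for k in range(am + 1):
        c = comb(am, k)
        if m >= 0 and k % 2 == 0:
            out[am - k, k] = c * (-1.0) ** (k // 2)
        elif m < 0 and k % 2 == 1:
            out[am - k, k] = c * (-1.0) ** ((k - 1) // 2)
    return out


@lru_cache(maxsize=None)
def zernike_cartesian(n: int, m: int) -> np.ndarray:
    """RMS-normalized Zernike mode as a Cartesian coefficient matrix.

    Returns ``C`` with ``Z(x, y) = sum_ij C[i, j] x**i y**j`` on the unit
    disk.
    """
    if (n - abs(m)) % 2 or abs(m) > n:
        raise ValueError(f"invalid Zernike index (n={n}, m={m})")
    norm = sqrt(2.0 * (n + 1)) if m != 0 else sqrt(n + 1.0)
    harm = _harmonic_poly(m)
    total = np.zeros((n + 1, n + 1))
    r2 = np.zeros((3, 3))
    r2[2, 0] = r2[0, 2] = 1.0  # x^2 + y^2
    for power, c in _radial_coeffs(n, m).items():
        p = (power - abs(m)) // 2  # rho^(power) trig = (r^2)^p * harmonic
        term = harm.copy()
        for _ in range(p):
            term = _poly_mul(term, r2)
        total[: term.shape[0], : term.shape[1]] += c * term
    return norm * total


@lru_cache(maxsize=None)
def _grad_coeffs(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    c = zernike_cartesian(n, m)
    gx = np.zeros_like(c)
    gy = np.zeros_like(c)
    for (i, j), v in np.ndenumerate(c):
        if v != 0.0:
            if i > 0:
                gx[i - 1, j] += i * v
            if j > 0:
                gy[i, j - 1] += j * v
    return gx, gy


def zernike_eval(n: int, m: int, x, y):
    """Evaluate Z_n^m at normalized pupil coordinates (x, y)."""
    return np.polynomial.polynomial.polyval2d(x, y, zernike_cartesian(n, m))


def zernike_grad(n: int, m: int, x, y):
    """Gradient (dZ/dx, dZ/dy) at normalized pupil coordinates."""
    gx, gy = _grad_coeffs(n, m)
    pv = np.polynomial.polynomial.polyval2d
    return pv(x, y, gx), pv(x, y, gy)


def design_matrix(x, y, modes) -> np.ndarray:
    """Least-squares design matrix; columns follow ``modes`` order."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    return np.column_stack([zernike_eval(n, m, x, y) for n, m in modes])


def fit_zernike_coeffs(x, y, values, max_order: int = 8):
    """Least-squares modal fit of sampled wavefront values.

    Parameters
    ----------
    x, y : arrays of pupil coordinates normalized to the unit disk.
    values : wavefront samples (any consistent unit).
    max_order : highest radial order fitted.

    Returns
    -------
    coeffs : dict mapping (n, m) to coefficient (same unit as values).
    residual_rms : RMS of the fit residual.
    """
    modes = osa_modes(max_order)
    v = np.asarray(values).ravel()
    if v.size < 10 * len(modes):
        raise ValueError(
            f"{v.size} samples is too few to fit {len(modes)} Zernike modes "
            "(need at least a 10x oversampling)"
        )
    A = design_matrix(x, y, modes)
    sol, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ sol
    if not np.all(np.isfinite(sol)):
        raise ValueError("rank-deficient Zernike fit (pupil mask too small)")
    return dict(zip(modes, sol)), float(np.sqrt(np.mean(resid**2)))


def reconstruct(coeffs: dict, x, y):
    """Wavefront values from modal coefficients at normalized coordinates."""
    out = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
    for (n, m), c in coeffs.items():
        if c != 0.0:
            out = out + c * zernike_eval(n, m, x, y)
    return out


def scale_pupil(coeffs: dict, old_radius: float, new_radius: float, max_order: int = 8) -> dict:
    """Re-express coefficients defined over ``old_radius`` on ``new_radius``.

    The wavefront described by ``coeffs`` over the larger pupil is sampled
    on the smaller concentric pupil and re-fitted, which is the standard
    aperture-scaling relation evaluated numerically (exact to fit
    precision for in-basis wavefronts).
    """
    if new_radius > old_radius:
        raise ValueError("can only scale down to a concentric sub-aperture")
    n_grid = 64
    c = np.linspace(-1.0, 1.0, n_grid)
    xx, yy = np.meshgrid(c, c)
    mask = xx**2 + yy**2 <= 1.0
    ratio = new_radius / old_radius
    w = reconstruct(coeffs, xx[mask] * ratio, yy[mask] * ratio)
    fitted, _ = fit_zernike_coeffs(xx[mask], yy[mask], w, max_order=max_order)
    return fitted


def rms_from_coeffs(coeffs: dict, exclude_low: bool = True) -> float:
    """Wavefront RMS implied by the coefficients.

    With ``exclude_low`` (default), piston, tip and tilt are left out, as
    they do not degrade image quality.
    """
    total = 0.0
    for (n, m), c in coeffs.items():
        if exclude_low and n <= 1:
            continue
        total += c * c
    return sqrt(total)
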