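"""Ray tracing, paraxial optics and wavefront computation."""

from dataclasses import replace

import numpy as np
import pytest

from eyesim.raytrace import (
    EyeModel,
    Ray,
    _refract,
    compute_wavefront,
    exit_pupil_position,
    fit_zernike,
    focus_retina,
    paraxial_focus,
    paraxial_power,
    trace_bundle,
    trace_ray,
)
from eyesim.surfaces import ConicSurface, ZernikeSagSurface


def _stigmatic_eye(n2=1.5, R=10.0, retina=None):
    surf = ConicSurface(R, -((1 / n2) ** 2), semi_aperture=4.5, axial_position=0.0)
    f = n2 * R / (n2 - 1)
    return EyeModel(
        surfaces=[surf], media=[n2], stop_position=0.0, stop_diameter=9.0,
        pupil_diameter=8.0, retina_position=f if retina is None else retina,
    ), f


def test_plane_interface_snell_closed_form():
    """30 degrees onto a flat n=1 -> 1.5 interface refracts to asin(sin30/1.5)."""
    plane = ConicSurface(np.inf, 0.0, 10.0, 0.0)
    m = EyeModel([plane], [1.5], 0.0, 10.0, pupil_diameter=5.0, retina_position=10.0)
    th = np.deg2rad(30.0)
    ray, hits = trace_ray(m, Ray([0.0, -2 * np.tan(th), -2.0], [0.0, np.sin(th), np.cos(th)]))
    assert np.arcsin(ray.direction[1]) == pytest.approx(np.arcsin(np.sin(th) / 1.5), abs=1e-12)
    assert hits[0][2] == pytest.approx(0.0, abs=1e-12)


def test_snell_residual_invariant():
    """|n1 sin(theta1) - n2 sin(theta2)| < 1e-12 for random incidences."""
    rng = np.random.default_rng(20231101)
    d = rng.normal(size=(200, 3))
    d[:, 2] = np.abs(d[:, 2]) + 1.0
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    gx = rng.uniform(-0.4, 0.4, 200)
    gy = rng.uniform(-0.4, 0.4, 200)
    n1, n2 = 1.3374, 1.55
    ox, oy, oz, ok = _refract(d[:, 0], d[:, 1], d[:, 2], gx, gy, n1, n2)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    nx, ny, nz = -gx / norm, -gy / norm, 1.0 / norm
    sin1 = np.linalg.norm(np.cross(d, np.column_stack([nx, ny, nz])), axis=1)
    out = np.column_stack([ox, oy, oz])
    assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)
    sin2 = np.linalg.norm(np.cross(out, np.column_stack([nx, ny, nz])), axis=1)
    assert np.max(np.abs(n1 * sin1 - n2 * sin2)[ok]) < 1e-12


def test_on_axis_ray_stays_on_axis(virgin_mono_eye3):
    out = trace_bundle(virgin_mono_eye3, np.array([0.0]), np.array([0.0]))
    assert out["valid"][0]
    assert abs(out["px"][0]) < 1e-14 and abs(out["py"][0]) < 1e-14
    assert out["dx"][0] == pytest.approx(0.0, abs=1e-14)


def test_stigmatic_conicoid_equal_opl_and_point_focus():
    """Collimated rays through the prolate ellipsoid with Q=-(n1/n2)^2 share
    the same OPL to the paraxial focus (Fermat) and focus to a point."""
    m, f = _stigmatic_eye()
    r = np.linspace(0.0, 4.0, 25)
    out = trace_bundle(m, r, np.zeros_like(r))
    t = (f - out["pz"]) / out["dz"]
    opl = out["opl"] + 1.5 * t
    assert np.ptp(opl) < 1e-9
    hx = out["px"] + t * out["dx"]
    assert np.max(np.abs(hx)) < 1e-9


def test_opl_is_nondecreasing_and_positive(virgin_mono_eye3):
    r = np.linspace(0, 1.4, 10)
    out = trace_bundle(virgin_mono_eye3, r, np.zeros_like(r))
    assert np.all(out["opl"] > 0)


def test_vignetted_ray_raises_in_single_ray_api(virgin_mono_eye3):
    with pytest.raises(ValueError, match="vignetted"):
        trace_ray(virgin_mono_eye3, Ray([10.0, 0.0, -5.0], [0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# paraxial


def test_single_surface_power_closed_form():
    """(n - 1)/R for the keratometric convention: 43.47 D at R = 7.8 mm."""
    p = paraxial_power([ConicSurface(7.8, 0.0, 4.5, 0.0)], [1.3391])
    assert p == pytest.approx((1.3391 - 1) / 0.0078, rel=1e-12)


def test_flat_surface_zero_power():
    assert paraxial_power([ConicSurface(np.inf, 0.0, 5.0, 0.0)], [1.5]) == 0.0


def test_full_virgin_cornea_power_near_43d(virgin_cornea):
    from eyesim.iol import N_AQUEOUS

    p = paraxial_power(
        [virgin_cornea.anterior, virgin_cornea.posterior], [virgin_cornea.n_stroma, N_AQUEOUS]
    )
    assert p == pytest.approx(43.0, abs=1.0)


def test_paraxial_focus_of_stigmatic_surface():
    m, f = _stigmatic_eye()
    assert paraxial_focus(m) == pytest.approx(f, rel=1e-12)


def test_exit_pupil_at_stop_when_no_following_surfaces():
    m, _ = _stigmatic_eye()
    assert exit_pupil_position(m) == 0.0


# ---------------------------------------------------------------------------
# wavefront


def test_aberration_free_wavefront_is_flat():
    m, _ = _stigmatic_eye()
    m = replace(m, pupil_diameter=6.0)
    w = compute_wavefront(m, mesh=128)
    assert np.ptp(w.opd[w.mask]) < 555e-3 / 100  # < lambda/100 peak-to-valley


def test_chief_ray_sample_is_zero(virgin_mono_wavefront3):
    n = virgin_mono_wavefront3.mesh
    assert virgin_mono_wavefront3.opd[n // 2, n // 2] == pytest.approx(0.0, abs=1e-12)


def test_rotational_symmetry_of_opd(virgin_mono_wavefront3):
    """m=0-only systems obey OPD(x, y) = OPD(-x, -y).

    With the FFT-centred grid the sample at index i sits at -x of index
    2*(N//2) - i, so row/column 0 is dropped before flipping.
    """
    w = virgin_mono_wavefront3.opd[1:, 1:]
    m = virgin_mono_wavefront3.mask[1:, 1:]
    flipped = np.flip(np.flip(w, 0), 1)
    both = m & np.flip(np.flip(m, 0), 1)
    assert np.max(np.abs(w[both] - flipped[both])) < 1e-10


def test_retina_displacement_matches_analytic_defocus():
    """Moving the reference image point axially adds the reference-sphere
    OPD difference, whose defocus term follows c20 = D r_p^2 / (4 sqrt(3))."""
    from eyesim.image_quality import defocus_c20

    m, f = _stigmatic_eye(n2=1.336, R=5.6)
    m = replace(m, pupil_diameter=4.0)
    dz = 0.05
    w = compute_wavefront(replace(m, retina_position=f + dz), mesh=128)
    c20 = fit_zernike(w)[0][(2, 0)]
    # exact oracle: the system is stigmatic about (0, f), so the OPD to the
    # displaced reference sphere is n2 (s_new - f), where s_new is the
    # back-distance from the old focus to the new sphere along each ray --
    # computed here purely from the surface geometry, independent of the trace
    n2 = 1.336
    xx, yy = w.grid()
    r = np.hypot(xx[w.mask], yy[w.mask])
    surf = m.surfaces[0]
    sag = surf.sag(r, np.zeros_like(r))
    dzc = (f - sag) / np.hypot(r, f - sag)  # z-component of the ray toward the focus
    s_new = -dz * dzc + np.sqrt(dz**2 * dzc**2 - dz**2 + (f + dz) ** 2)
    exact = n2 * (s_new - f) * 1e3  # um, phase-advance-positive convention
    from eyesim.zernike import fit_zernike_coeffs

    c_exact, _ = fit_zernike_coeffs(xx[w.mask] / 2.0, yy[w.mask] / 2.0, exact, max_order=8)
    assert c20 == pytest.approx(c_exact[(2, 0)], rel=1e-3)
    # first-order dioptric equivalent within a few percent
    d_equiv = 1000.0 * 1.336 * dz / f**2
    assert abs(c20) == pytest.approx(defocus_c20(d_equiv, 4.0), rel=0.04)


def test_phase_plate_requires_matching_radius(virgin_mono_eye3):
    from eyesim.raytrace import PhasePlate

    bad = replace(virgin_mono_eye3, phase_plate=PhasePlate(coeffs={(4, 0): 0.1}, radius=2.0))
    with pytest.raises(ValueError, match="radius"):
        compute_wavefront(bad, mesh=64)


def test_wavefront_requires_focused_retina(virgin_mono_eye3):
    with pytest.raises(ValueError, match="retina"):
        compute_wavefront(replace(virgin_mono_eye3, retina_position=None), mesh=64)


# ---------------------------------------------------------------------------
# focusing


def test_focus_retina_paraxial_limit():
    """An aberration-free model focuses at the paraxial focus within 1 um."""
    m, f = _stigmatic_eye()
    m = replace(m, retina_position=None, pupil_diameter=4.0)
    focused = focus_retina(m)
    assert focused.retina_position == pytest.approx(f, abs=1e-3)


def test_focus_retina_idempotent(virgin_mono_eye3):
    again = focus_retina(virgin_mono_eye3)
    assert again.retina_position == pytest.approx(virgin_mono_eye3.retina_position, abs=1e-4)


def test_positive_sa_best_focus_between_paraxial_and_marginal():
    """With positive SA the min-RMS-spot plane sits in front of the paraxial
    focus, between marginal and paraxial foci (brute-force spot scan)."""
    surf = ConicSurface(7.8, 0.0, 4.5, 0.0)  # spherical: strong positive SA
    m = EyeModel([surf], [1.3771], 0.0, 9.0, pupil_diameter=6.0)
    f_par = paraxial_focus(m)
    focused = focus_retina(m, mesh=64)
    assert focused.retina_position < f_par
    # brute-force scan oracle over a uniform-area bundle
    rng = np.random.default_rng(20231101)
    rr = 3.0 * np.sqrt(rng.uniform(0, 1, 4000))
    th = rng.uniform(0, 2 * np.pi, 4000)
    out = trace_bundle(m, rr * np.cos(th), rr * np.sin(th))
    zs = np.linspace(f_par - 2.0, f_par + 0.5, 600)
    spots = [
        np.mean(
            (out["px"] + (z - out["pz"]) / out["dz"] * out["dx"]) ** 2
            + (out["py"] + (z - out["pz"]) / out["dz"] * out["dy"]) ** 2
        )
        for z in zs
    ]
    z_scan = zs[int(np.argmin(spots))]
    assert focused.retina_position == pytest.approx(z_scan, abs=0.05)


def test_model_invariants_enforced():
    s1 = ConicSurface(7.8, 0.0, 4.5, 0.0)
    s2 = ConicSurface(6.5, 0.0, 4.5, 0.55)
    with pytest.raises(ValueError, match="increasing"):
        EyeModel([s2, s1], [1.3771, 1.3374], 0.0, 5.0)
    with pytest.raises(ValueError, match="retina"):
        EyeModel([s1, s2], [1.3771, 1.3374], 0.0, 5.0, retina_position=0.3)
    with pytest.raises(ValueError, match="stop"):
        EyeModel([s1, s2], [1.3771, 1.3374], 0.0, 12.0)
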