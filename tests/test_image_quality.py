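"""PSF/MTF computation, Visual Strehl, through-focus and depth of focus."""

from dataclasses import replace

import numpy as np
import pytest

from eyesim.fixtures import make_case
from eyesim.image_quality import (
    CSFModel,
    ThroughFocusCurve,
    check_sampling,
    compute_mtf,
    compute_psf,
    defocus_c20,
    depth_of_focus,
    strehl_ratio,
    through_focus,
    visual_strehl,
)
from eyesim.raytrace import WavefrontMap
from eyesim.zernike import zernike_eval


@pytest.fixture(scope="module")
def airy_map():
    return make_case("airy_psf", pupil=3.0, mesh=128).payload["wavefront"]


def test_psf_energy_normalized(airy_map):
    psf = compute_psf(airy_map)
    assert psf.intensity.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(psf.intensity >= 0.0)


def test_airy_first_zero_position():
    """First dark ring of the 5-mm diffraction PSF at 1.22 lambda/d."""
    case = make_case("airy_psf", pupil=5.0, mesh=128)
    psf = compute_psf(case.payload["wavefront"], padding=8)
    n = psf.intensity.shape[0]
    profile = psf.intensity[n // 2, n // 2:]
    minima = np.where((profile[1:-1] < profile[:-2]) & (profile[1:-1] < profile[2:]))[0] + 1
    first_zero = minima[0] * psf.step_arcmin
    value, tol = case.expected["first_zero_arcmin"]
    assert first_zero == pytest.approx(value, abs=tol)


def test_marechal_strehl_agreement():
    """Small random aberrations obey Strehl ~ exp(-(2 pi sigma / lambda)^2)."""
    case = make_case("marechal_psf", sigma_um=0.03)
    value, tol = case.expected["strehl"]
    assert strehl_ratio(case.payload["wavefront"]) == pytest.approx(value, abs=tol)


def test_mtf_unity_at_dc_and_bounded(airy_map):
    mtf = compute_mtf(compute_psf(airy_map))
    n = mtf.values.shape[0]
    assert mtf.values[n // 2, n // 2] == pytest.approx(1.0, abs=1e-12)
    assert mtf.values.max() <= 1.0 + 1e-9


def test_diffraction_limited_mtf_closed_form(airy_map):
    """The circular-aperture MTF is (2/pi)(acos nu - nu sqrt(1 - nu^2))."""
    mtf = compute_mtf(compute_psf(airy_map))
    n = mtf.values.shape[0]
    cutoff = 3e-3 / 555e-9 * np.pi / 180.0  # cycles/degree
    freqs = (np.arange(n) - n // 2) * mtf.step_cpd
    nu = np.abs(freqs) / cutoff
    sel = (nu > 0.02) & (nu < 0.98)
    analytic = 2 / np.pi * (np.arccos(nu[sel]) - nu[sel] * np.sqrt(1 - nu[sel] ** 2))
    assert np.max(np.abs(mtf.values[n // 2, sel] - analytic)) < 0.01


def test_mtf_vanishes_beyond_cutoff(airy_map):
    mtf = compute_mtf(compute_psf(airy_map))
    cutoff = 3e-3 / 555e-9 * np.pi / 180.0
    f = mtf.frequency_magnitude()
    assert np.max(mtf.values[f > 1.05 * cutoff]) < 1e-6


def test_pure_defocus_lowers_mtf_everywhere(airy_map):
    xx, yy = airy_map.grid()
    z20 = zernike_eval(2, 0, xx / 1.5, yy / 1.5)
    blurred = replace(airy_map, opd=airy_map.opd + 0.15 * z20 * airy_map.mask)
    m0 = compute_mtf(compute_psf(airy_map))
    m1 = compute_mtf(compute_psf(blurred))
    f = m0.frequency_magnitude()
    band = (f > 2.0) & (f < 60.0)
    assert np.all(m1.values[band] <= m0.values[band] + 1e-6)


def test_csf_default_shape():
    csf = CSFModel()
    assert 2.0 <= csf.peak_frequency <= 10.0
    assert csf(60.0) / csf(csf.peak_frequency) < 0.05
    assert csf(0.0) == 0.0


def test_visual_strehl_unaberrated_is_unity(airy_map):
    assert visual_strehl(airy_map) == pytest.approx(1.0, abs=1e-9)


def test_visual_strehl_invariant_to_piston_and_tilt(airy_map):
    xx, yy = airy_map.grid()
    tilted = replace(
        airy_map,
        opd=(0.3 + 0.2 * zernike_eval(1, 1, xx / 1.5, yy / 1.5)) * airy_map.mask,
    )
    assert visual_strehl(tilted) == pytest.approx(1.0, abs=1e-6)


def test_visual_strehl_monotone_in_aberration_strength(airy_map):
    xx, yy = airy_map.grid()
    z40 = zernike_eval(4, 0, xx / 1.5, yy / 1.5)
    vs = [
        visual_strehl(replace(airy_map, opd=a * z40 * airy_map.mask))
        for a in np.linspace(0.0, 0.555 / 4, 6)
    ]
    assert all(b < a for a, b in zip(vs, vs[1:]))


def test_visual_strehl_padding_convergence(airy_map):
    case = make_case("marechal_psf", sigma_um=0.05)
    w = case.payload["wavefront"]
    assert abs(visual_strehl(w, padding=4) - visual_strehl(w, padding=8)) < 0.005


def test_sampling_contract_error_names_remedy():
    w = make_case("airy_psf", pupil=5.0, mesh=32).payload["wavefront"]
    with pytest.raises(ValueError, match="mesh"):
        check_sampling(w, 4)


# ---------------------------------------------------------------------------
# through-focus and DOF


def test_through_focus_peaks_at_zero_for_aberration_free_eye():
    case = make_case("thin_lens_eye")
    model = replace(case.payload["model"], pupil_diameter=3.0)
    curve = through_focus(model, mesh=128)
    assert curve.defocus[curve.best_focus_index] == pytest.approx(0.0, abs=0.051)
    assert curve.vs.max() == pytest.approx(1.0, abs=1e-3)
    assert len(curve.defocus) == 81
    assert curve.step == pytest.approx(0.1, abs=1e-12)


def test_through_focus_symmetry_without_odd_aberrations():
    case = make_case("thin_lens_eye")
    model = replace(case.payload["model"], pupil_diameter=3.0)
    curve = through_focus(model, mesh=128)
    np.testing.assert_allclose(curve.vs, curve.vs[::-1], atol=1e-6)


def test_injected_defocus_shift_recovered():
    """Adding the c20 equivalent of +1 D moves the peak to the -1 D sample."""
    case = make_case("thin_lens_eye")
    model = replace(case.payload["model"], pupil_diameter=4.0)
    from eyesim.raytrace import compute_wavefront

    wmap = compute_wavefront(model, mesh=128)
    xx, yy = wmap.grid()
    z20 = zernike_eval(2, 0, xx / 2.0, yy / 2.0)
    shifted = replace(wmap, opd=wmap.opd + defocus_c20(1.0, 4.0) * z20 * wmap.mask)
    curve = through_focus(model, wavefront=shifted)
    assert curve.defocus[curve.best_focus_index] == pytest.approx(-1.0, abs=0.051)


def test_depth_of_focus_rectangular_curve():
    """A rectangular curve 0.5 on [0, 2] D yields 2 D, up to the linear
    interpolation of the crossings within one sample each side."""
    d = np.round(np.arange(-4.0, 4.05, 0.1), 10)
    vs = np.where((d >= 0.0) & (d <= 2.0), 0.5, 0.0)
    curve = ThroughFocusCurve(defocus=d, vs=vs, pupil_diameter=3.0)
    dof = depth_of_focus(curve)
    assert 2.0 <= dof <= 2.0 + 2 * 0.1


def test_depth_of_focus_interpolates_crossings():
    d = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
    vs = np.array([0.0, 0.12 * 2, 1.0, 0.12 * 2, 0.0])
    curve = ThroughFocusCurve(defocus=d, vs=vs, pupil_diameter=3.0)
    # crossings at +-0.15 by linear interpolation
    assert depth_of_focus(curve, threshold=0.12) == pytest.approx(0.3, abs=1e-9)


def test_depth_of_focus_zero_threshold_spans_positive_curve():
    d = np.arange(-4.0, 4.05, 0.1)
    curve = ThroughFocusCurve(defocus=d, vs=np.full_like(d, 0.4), pupil_diameter=3.0)
    assert depth_of_focus(curve, threshold=0.0) == pytest.approx(d[-1] - d[0], abs=1e-9)


def test_depth_of_focus_subthreshold_warns_and_returns_zero():
    d = np.arange(-1.0, 1.05, 0.1)
    curve = ThroughFocusCurve(defocus=d, vs=np.full_like(d, 0.05), pupil_diameter=3.0)
    with pytest.warns(UserWarning):
        assert depth_of_focus(curve) == 0.0
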