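"""Virgin and post-LASIK corneal construction."""

import numpy as np
import pytest

from eyesim.cornea import (
    LasikSpec,
    N_KERATOMETRIC,
    add_coma,
    anterior_surface_wavefront,
    build_lasik_cornea,
    build_virgin_cornea,
    induced_sa,
    keratometric_power,
    munnerlyn_depth_um,
)


@pytest.mark.parametrize(
    "magnitude,kind,expected",
    [
        (7.5, "myopic", 1.045),
        (4.5, "myopic", 0.538),
        (2.5, "myopic", 0.200),
        (2.5, "hyperopic", -0.743),
        (4.5, "hyperopic", -1.297),
    ],
)
def test_induced_sa_regressions_match_tabulated_values(magnitude, kind, expected):
    """The per-condition induced SA values (6.5-mm pupil, um)."""
    assert induced_sa(LasikSpec(magnitude, kind)) == pytest.approx(expected, abs=0.0005)


def test_induced_sa_rejects_out_of_support_magnitudes():
    with pytest.raises(ValueError):
        LasikSpec(11.0, "myopic")
    with pytest.raises(ValueError):
        LasikSpec(-2.0, "hyperopic")


def test_munnerlyn_depth_12um_per_diopter():
    """t = S^2 D / 3 gives 12 um per diopter at a 6-mm ablation zone."""
    assert munnerlyn_depth_um(1.0, 6.0) == pytest.approx(12.0, abs=1e-12)
    assert munnerlyn_depth_um(7.5, 6.0) == pytest.approx(90.0, abs=1e-12)


def test_virgin_conic_constant(virgin_cornea):
    """Optimizing the asphericity for +0.28 um SA at 6 mm yields Q near -0.117."""
    assert virgin_cornea.anterior.conic_constant == pytest.approx(-0.117, abs=0.002)
    assert virgin_cornea.anterior.radius_of_curvature == 7.8
    assert virgin_cornea.central_thickness == 0.55


def test_virgin_sa_retrace_residual(virgin_cornea):
    sa = anterior_surface_wavefront(virgin_cornea.anterior, 1.3771, 6.0)[(4, 0)]
    assert sa == pytest.approx(0.280, abs=0.001)


def test_spherical_anterior_has_more_sa_than_prolate():
    """SA decreases monotonically with Q in the corneal range."""
    from eyesim.surfaces import ConicSurface

    sa_sphere = anterior_surface_wavefront(ConicSurface(7.8, 0.0, 4.5, 0.0), 1.3771, 6.0)[(4, 0)]
    assert sa_sphere > 0.280


@pytest.mark.parametrize("magnitude,kind", [(2.5, "myopic"), (4.5, "hyperopic")])
def test_lasik_roundtrip_and_power_change(virgin_cornea, magnitude, kind):
    """Built corneas reproduce the target delta-SA (single-surface
    n=1.3391 / 6.5-mm convention) and the keratometric power change."""
    spec = LasikSpec(magnitude, kind)
    built = build_lasik_cornea(spec, virgin=virgin_cornea)
    base = anterior_surface_wavefront(virgin_cornea.anterior, N_KERATOMETRIC, 6.5)[(4, 0)]
    got = anterior_surface_wavefront(built.anterior, N_KERATOMETRIC, 6.5)[(4, 0)]
    assert got - base == pytest.approx(induced_sa(spec), abs=0.005)
    dp = keratometric_power(built.anterior.radius_of_curvature) - keratometric_power(7.8)
    expected = -magnitude if kind == "myopic" else magnitude
    assert dp == pytest.approx(expected, abs=0.01)


def test_myopic_thickness_loss_matches_munnerlyn(virgin_cornea):
    built = build_lasik_cornea(LasikSpec(7.5, "myopic"), virgin=virgin_cornea)
    assert built.central_thickness == pytest.approx(0.55 - 0.090, abs=1e-12)


def test_hyperopic_thickness_unchanged_and_steepened(virgin_cornea):
    built = build_lasik_cornea(LasikSpec(4.5, "hyperopic"), virgin=virgin_cornea)
    assert built.central_thickness == 0.55
    assert built.anterior.radius_of_curvature < 7.8


def test_posterior_surface_invariant_across_conditions(virgin_cornea):
    built = build_lasik_cornea(LasikSpec(2.5, "myopic"), virgin=virgin_cornea)
    assert built.posterior.radius_of_curvature == virgin_cornea.posterior.radius_of_curvature
    assert built.posterior.conic_constant == 0.0
    assert built.n_stroma == virgin_cornea.n_stroma


def test_add_coma_reaches_target_and_is_roughly_linear(virgin_cornea):
    with_coma = add_coma(virgin_cornea, target=0.5, pupil=6.5)
    exp = anterior_surface_wavefront(with_coma.anterior, N_KERATOMETRIC, 6.5)
    assert exp[(3, 1)] == pytest.approx(0.5, abs=0.005)
    # doubling the sag coefficient roughly doubles the wavefront coma
    from eyesim.surfaces import ZernikeSagSurface

    doubled = ZernikeSagSurface(
        base=with_coma.anterior.base,
        zernike_sag_coeffs={(3, 1): 2 * with_coma.anterior.zernike_sag_coeffs[(3, 1)]},
        normalization_radius=with_coma.anterior.normalization_radius,
    )
    exp2 = anterior_surface_wavefront(doubled, N_KERATOMETRIC, 6.5)
    assert exp2[(3, 1)] == pytest.approx(1.0, rel=0.05)


def test_add_coma_zero_target_is_identity(virgin_cornea):
    assert add_coma(virgin_cornea, target=0.0) is virgin_cornea


def test_thin_residual_bed_rejected():
    from eyesim.cornea import CorneaSpec
    from eyesim.surfaces import ConicSurface

    with pytest.raises(ValueError, match="thickness"):
        CorneaSpec(anterior=ConicSurface(7.8, -0.117, 4.5, 0.0), central_thickness=0.25)
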