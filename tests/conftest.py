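"""Shared fixtures: components are expensive to build, so they are
constructed once per session at a moderate mesh and reused."""

import pytest

from eyesim.assembly import PseudophakicEyeSpec, assemble_eye
from eyesim.cornea import build_virgin_cornea
from eyesim.iol import design_edof, design_monofocal
from eyesim.raytrace import compute_wavefront


@pytest.fixture(scope="session")
def virgin_cornea():
    return build_virgin_cornea(mesh=128)


@pytest.fixture(scope="session")
def monofocal():
    return design_monofocal(mesh=128)


@pytest.fixture(scope="session")
def edof_iol(monofocal):
    return design_edof(monofocal)


@pytest.fixture(scope="session")
def virgin_mono_eye3(virgin_cornea, monofocal):
    return assemble_eye(PseudophakicEyeSpec(cornea=virgin_cornea, iol=monofocal, pupil_diameter=3.0))


@pytest.fixture(scope="session")
def virgin_mono_wavefront3(virgin_mono_eye3):
    return compute_wavefront(virgin_mono_eye3, mesh=128)
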