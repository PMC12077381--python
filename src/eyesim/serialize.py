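"""YAML / CSV / JSON persistence for specs and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .cornea import CorneaSpec
from .iol import EDOFProfile, IOLSpec
from .raytrace import EyeModel, WavefrontMap, ZernikeExpansion
from .surfaces import surface_from_dict

__all__ = [
    "save_yaml",
    "load_yaml",
    "eye_to_yaml",
    "eye_from_yaml",
    "cornea_from_dict",
    "iol_from_dict",
    "wavefront_to_csv",
    "zernike_to_json",
]


def save_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def eye_to_yaml(model: EyeModel, path) -> None:
    save_yaml(model.to_dict(), path)


def eye_from_yaml(path) -> EyeModel:
    return EyeModel.from_dict(load_yaml(path))


def cornea_from_dict(d: dict) -> CorneaSpec:
    return CorneaSpec(
        anterior=surface_from_dict(d["anterior"]),
        central_thickness=d["central_thickness"],
        n_stroma=d.get("n_stroma", 1.3771),
    )


def iol_from_dict(d: dict) -> IOLSpec:
    return IOLSpec(
        labeled_power=d["labeled_power"],
        n_iol=d["n_iol"],
        central_thickness=d["central_thickness"],
        anterior=surface_from_dict(d["anterior"]),
        posterior=surface_from_dict(d["posterior"]),
        optic_diameter=d.get("optic_diameter", 6.0),
        target_iol_sa=d.get("target_iol_sa", -0.411),
    )


def wavefront_to_csv(wmap: WavefrontMap, path) -> None:
    """OPD grid as CSV (um); samples outside the pupil are written as nan."""
    out = np.where(wmap.mask, wmap.opd, np.nan)
    np.savetxt(path, out, delimiter=",", fmt="%.6e")


def zernike_to_json(exp: ZernikeExpansion, path) -> None:
    Path(path).write_text(json.dumps(exp.to_dict(), indent=2))
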