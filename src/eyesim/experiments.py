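"""Condition-grid driver: the full simulated study.

The study grid crosses six corneal conditions (virgin plus five LASIK
corrections: myopic 2.5/4.5/7.5 D and hyperopic 2.5/4.5 D), coma
on/off, two IOLs (monofocal, EDOF) and two pupils (3.0, 5.0 mm) -- 48
conditions.  For each condition the driver assembles and focuses the
eye, computes the wavefront, the through-focus Visual Strehl curve,
the depth of focus, and the halo metric, and aggregates summary
statistics (post-LASIK means and the paired rank test on DOF).

Everything is deterministic: rerunning an identical configuration
reproduces bit-identical tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .assembly import PseudophakicEyeSpec, assemble_eye, lasik_delta_plate, make_phase_plate_eye
from .cornea import CorneaSpec, LasikSpec, add_coma, build_virgin_cornea, build_lasik_cornea, induced_sa
from .halo import geometric_psf, halo_metric
from .image_quality import CSFModel, depth_of_focus, through_focus
from .iol import DEFAULT_EDOF_PROFILE, design_edof, design_monofocal
from .raytrace import compute_wavefront

__all__ = ["Condition", "ConditionResult", "GridConfig", "run_grid", "compare_modes", "paired_dof_test"]

LASIK_GRID = [
    ("myopic", 2.5),
    ("myopic", 4.5),
    ("myopic", 7.5),
    ("hyperopic", 2.5),
    ("hyperopic", 4.5),
]


@dataclass(frozen=True)
class Condition:
    """One cell of the study grid."""

    lasik: Optional[tuple] = None  # (surgery_type, magnitude) or None for virgin
    coma: bool = False
    iol: str = "monofocal"  # or "edof"
    pupil: float = 3.0

    @property
    def label(self) -> str:
        cornea = "virgin" if self.lasik is None else f"{self.lasik[0]}{self.lasik[1]:g}"
        coma = "+coma" if self.coma else ""
        return f"{cornea}{coma}/{self.iol}/{self.pupil:g}mm"


@dataclass
class ConditionResult:
    """Metrics of one condition in one simulation mode."""

    condition: Condition
    mode: str
    vs_far: float
    dof: float
    halo_arcmin: float
    induced_sa_um: float
    coma_um: float
    retina_position: float

    def row(self) -> dict:
        return {
            "condition": self.condition.label,
            "pupil_mm": self.condition.pupil,
            "iol": self.condition.iol,
            "induced_sa_um": self.induced_sa_um,
            "coma_um": self.coma_um,
            "mode": self.mode,
            "vs_far": self.vs_far,
            "dof_d": self.dof,
            "halo_arcmin": self.halo_arcmin,
            "retina_mm": self.retina_position,
        }


@dataclass
class GridConfig:
    """Configuration of a grid run; defaults reproduce the study grid."""

    pupils: tuple = (3.0, 5.0)
    iols: tuple = ("monofocal", "edof")
    include_virgin: bool = True
    lasik: tuple = tuple(LASIK_GRID)
    coma_options: tuple = (False, True)
    mode: str = "full_surface"
    mesh: int = 128
    csf_exponent: float = 0.8
    csf_decay: float = 0.10
    focus_range: float = 8.0
    focus_step: float = 0.1
    dof_threshold: float = 0.12

    def conditions(self) -> list[Condition]:
        out = []
        corneas = ([None] if self.include_virgin else []) + list(self.lasik)
        for lasik in corneas:
            for coma in self.coma_options:
                for iol in self.iols:
                    for pupil in self.pupils:
                        out.append(Condition(lasik=lasik, coma=coma, iol=iol, pupil=pupil))
        return out

    @property
    def csf(self) -> CSFModel:
        return CSFModel(exponent=self.csf_exponent, decay=self.csf_decay)


class _ComponentCache:
    """Builds corneas and IOLs once per grid run."""

    def __init__(self, mesh: int):
        self.mesh = mesh
        self.virgin = build_virgin_cornea(mesh=mesh)
        self.mono = design_monofocal(mesh=mesh)
        self.edof = design_edof(self.mono, DEFAULT_EDOF_PROFILE)
        self._corneas: dict = {}

    def cornea(self, lasik, coma: bool) -> CorneaSpec:
        key = (lasik, coma)
        if key not in self._corneas:
            if lasik is None:
                c = add_coma(self.virgin, 0.5, mesh=self.mesh) if coma else self.virgin
            else:
                spec = LasikSpec(lasik[1], lasik[0], include_coma=coma)
                c = build_lasik_cornea(spec, virgin=self.virgin, mesh=self.mesh)
            self._corneas[key] = c
        return self._corneas[key]

    def iol(self, name: str):
        return {"monofocal": self.mono, "edof": self.edof}[name]


def _evaluate(eye, cond: Condition, cfg: GridConfig, mode: str) -> ConditionResult:
    wmap = compute_wavefront(eye, mesh=cfg.mesh)
    curve = through_focus(
        eye, csf=cfg.csf, focus_range=cfg.focus_range, step=cfg.focus_step, wavefront=wmap
    )
    i_far = int(np.argmin(np.abs(curve.defocus)))
    dsa = 0.0 if cond.lasik is None else induced_sa(LasikSpec(cond.lasik[1], cond.lasik[0]))
    if mode == "phase_plate":
        halo = float("nan")  # halo is a geometric metric; rays ignore the phase screen
    else:
        halo = halo_metric(geometric_psf(eye, mesh=max(cfg.mesh, 256))).halo_diameter
    return ConditionResult(
        condition=cond,
        mode=mode,
        vs_far=float(curve.vs[i_far]),
        dof=depth_of_focus(curve, cfg.dof_threshold),
        halo_arcmin=halo,
        induced_sa_um=dsa,
        coma_um=0.5 if cond.coma else 0.0,
        retina_position=float(eye.retina_position),
    )


def _build_eye(cond: Condition, cfg: GridConfig, cache: _ComponentCache, mode: str):
    iol = cache.iol(cond.iol)
    if mode == "full_surface":
        cornea = cache.cornea(cond.lasik, cond.coma)
        spec = PseudophakicEyeSpec(cornea=cornea, iol=iol, pupil_diameter=cond.pupil)
        return assemble_eye(spec)
    # phase-plate mode: virgin geometry plus the induced deltas at the pupil
    spec = PseudophakicEyeSpec(cornea=cache.virgin, iol=iol, pupil_diameter=cond.pupil)
    eye = assemble_eye(spec)
    if cond.lasik is None and not cond.coma:
        return eye
    lasik = (
        LasikSpec(cond.lasik[1], cond.lasik[0], include_coma=cond.coma)
        if cond.lasik is not None
        else None
    )
    if lasik is None:
        from .assembly import aberration_plate

        plate = aberration_plate({(3, 1): 0.5}, cond.pupil)
    else:
        plate = lasik_delta_plate(lasik, cond.pupil)
    return make_phase_plate_eye(eye, plate)


def run_grid(cfg: GridConfig | None = None, mode: str | None = None,
             cache: _ComponentCache | None = None) -> pd.DataFrame:
    """Run every condition of the grid; returns one row per condition."""
    cfg = cfg or GridConfig()
    mode = mode or cfg.mode
    cache = cache or _ComponentCache(cfg.mesh)
    rows = []
    for cond in cfg.conditions():
        try:
            eye = _build_eye(cond, cfg, cache, mode)
            rows.append(_evaluate(eye, cond, cfg, mode).row())
        except Exception as err:
            raise RuntimeError(f"condition {cond.label} failed: {err}") from err
    return pd.DataFrame(rows)


def summarize_postlasik(df: pd.DataFrame, pupil: float = 3.0) -> pd.DataFrame:
    """Mean +- SD of DOF and VS over post-LASIK conditions, per IOL."""
    post = df[(df.pupil_mm == pupil) & (~df.condition.str.startswith("virgin"))]
    return post.groupby("iol").agg(
        dof_mean=("dof_d", "mean"),
        dof_sd=("dof_d", "std"),
        vs_mean=("vs_far", "mean"),
        vs_sd=("vs_far", "std"),
        n=("dof_d", "size"),
    )


def paired_dof_test(df: pd.DataFrame, pupil: float = 3.0):
    """Paired Wilcoxon signed-rank test: DOF EDOF vs monofocal, post-LASIK.

    Pairs the ten post-LASIK cells (five corrections x coma on/off) at
    the given pupil.  Returns (statistic, p_value, mean_difference).
    """
    from scipy.stats import wilcoxon

    post = df[(df.pupil_mm == pupil) & (~df.condition.str.startswith("virgin"))]
    key = ["condition"]
    e = post[post.iol == "edof"].sort_values(key).dof_d.to_numpy()
    m = post[post.iol == "monofocal"].sort_values(key).dof_d.to_numpy()
    if len(e) != len(m) or len(e) == 0:
        raise ValueError("grid must contain matched EDOF/monofocal post-LASIK cells")
    # condition labels embed the IOL; re-pair on the cornea part
    e_lab = sorted(c.rsplit("/", 2)[0] for c in post[post.iol == "edof"].condition)
    m_lab = sorted(c.rsplit("/", 2)[0] for c in post[post.iol == "monofocal"].condition)
    if e_lab != m_lab:
        raise ValueError("unmatched corneal conditions between IOL arms")
    stat, p = wilcoxon(e, m)
    return float(stat), float(p), float(np.mean(e - m))


def compare_modes(cfg: GridConfig | None = None, postlasik_only: bool = True) -> dict:
    """Full-surface vs. phase-plate agreement over the grid.

    Returns per-condition deltas and the average absolute differences
    in far Visual Strehl and depth of focus.  By default only the
    post-LASIK cells are compared (the virgin cells are identical in
    both modes by construction).
    """
    cfg = cfg or GridConfig()
    if postlasik_only:
        from dataclasses import replace as dreplace

        cfg = dreplace(cfg, include_virgin=False)
    cache = _ComponentCache(cfg.mesh)
    full = run_grid(cfg, mode="full_surface", cache=cache)
    plate = run_grid(cfg, mode="phase_plate", cache=cache)
    merged = full.merge(plate, on=["condition", "pupil_mm", "iol"], suffixes=("_full", "_plate"))
    merged["dvs"] = (merged.vs_far_full - merged.vs_far_plate).abs()
    merged["ddof"] = (merged.dof_d_full - merged.dof_d_plate).abs()
    return {
        "table": merged,
        "mean_abs_dvs": float(merged.dvs.mean()),
        "mean_abs_ddof": float(merged.ddof.mean()),
    }
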