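"""Morphometric scalars, shape classification and cohort statistics.

Automates the caliper measurements: bone height from the aligned surface
extent, thickness/width profiles per 1 mm craniocaudal level from the
thickness map, the thickest (superior, SL) and thinnest (inferior, IL)
levels, a heuristic footprint-shape classification, and the descriptive
statistics used for cohort tables (mean / SD / median / range, bootstrap
percentile confidence intervals, multiple linear regression).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import InputError
from .mapping import GridMap

__all__ = [
    "MorphometryRecord", "SummaryStats", "OlsResult", "LevelProfile",
    "bone_height", "level_profile", "extreme_levels", "classify_shape",
    "mean_stt", "summarize", "bootstrap_ci", "ols", "measure_subject",
]


@dataclass
class MorphometryRecord:
    """One subject's morphometric scalars (all mm)."""

    subject_id: str
    height_mm: float
    t_sl_mm: float
    t_il_mm: float
    w_sl_mm: float
    w_il_mm: float
    shape: str
    mean_stt_mm: float

    def __post_init__(self) -> None:
        if not (self.t_sl_mm >= self.t_il_mm > 0):
            raise InputError("thickness levels must satisfy t_SL >= t_IL > 0")
        if min(self.height_mm, self.w_sl_mm, self.w_il_mm) <= 0:
            raise InputError("height and widths must be positive")


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    ci_lo: float = np.nan
    ci_hi: float = np.nan


@dataclass
class OlsResult:
    """Multiple linear regression with intercept: coefficients, normal-theory
    95% intervals, two-sided p-values and the residual SD."""

    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    resid_sd: float

    def contains(self, name: str, value: float) -> bool:
        lo, hi = self.conf_int[name]
        return lo <= value <= hi


# ---------------------------------------------------------------------------
# per-subject scalars
# ---------------------------------------------------------------------------

def bone_height(subject) -> float:
    """Craniocaudal extent (max z - min z) of the bone surfaces, mm."""
    surfaces = subject if hasattr(subject, "bone_vertices") else subject.surfaces
    pts = surfaces.bone_vertices()
    if len(pts) == 0:
        raise InputError("empty surface")
    return float(pts[:, 2].max() - pts[:, 2].min())


@dataclass
class LevelProfile:
    """Per 1 mm craniocaudal level: representative thickness and width."""

    z_mm: np.ndarray          # cell-centre z of each qualifying row
    thickness_mm: np.ndarray  # row median of present cells
    width_mm: np.ndarray      # spacing x number of present cells


def level_profile(tmap: GridMap, min_cells: int = 10) -> LevelProfile:
    """Profile of a thickness map; rows with fewer than ``min_cells`` present
    cells (e.g. notch-fragmented rows) are excluded."""
    zs_all = tmap.cell_centers()[1]
    z, med, wid = [], [], []
    for j in range(tmap.shape[1]):
        row = tmap.values[:, j][tmap.present[:, j]]
        if len(row) >= min_cells:
            z.append(zs_all[j])
            med.append(float(np.median(row)))
            wid.append(len(row) * tmap.spacing)
    if not z:
        raise InputError(f"no rows with >= {min_cells} present cells")
    return LevelProfile(z_mm=np.asarray(z), thickness_mm=np.asarray(med),
                        width_mm=np.asarray(wid))


def extreme_levels(profile: LevelProfile) -> dict[str, float]:
    """Thickest (SL) and thinnest (IL) levels; ties resolved superior."""
    t = profile.thickness_mm
    j_sl = len(t) - 1 - int(np.argmax(t[::-1]))
    j_il = len(t) - 1 - int(np.argmin(t[::-1]))
    return {"t_sl": float(t[j_sl]), "w_sl": float(profile.width_mm[j_sl]),
            "t_il": float(t[j_il]), "w_il": float(profile.width_mm[j_il]),
            "z_sl": float(profile.z_mm[j_sl]), "z_il": float(profile.z_mm[j_il])}


def classify_shape(profile: LevelProfile, tri_below: float = 0.70,
                   quad_lo: float = 0.90, quad_hi: float = 1.10) -> str:
    """Heuristic footprint shape from the width taper.

    ``r`` is the mean width of the inferior third over the mean width of the
    superior third: strong taper (r < 0.70) reads as triangular, near-equal
    widths (0.90 <= r <= 1.10) as quadrangular, the rest as trapezoid.  A
    stand-in for the visual classification, validated on synthetic
    footprints only.
    """
    w = profile.width_mm
    n = len(w)
    third = max(n // 3, 1)
    r = float(np.mean(w[:third]) / np.mean(w[-third:]))  # inferior / superior
    if r < tri_below:
        return "triangular"
    if quad_lo <= r <= quad_hi:
        return "quadrangular"
    return "trapezoid"


def mean_stt(stt_map: GridMap) -> float:
    """Average soft-tissue thickness over present cells, mm."""
    if not stt_map.present.any():
        raise InputError("empty STT map")
    return float(stt_map.values[stt_map.present].mean())


def measure_subject(subject, tmap: GridMap, smap: GridMap,
                    min_cells: int = 10) -> MorphometryRecord:
    """Assemble a subject's full morphometry record from its maps."""
    prof = level_profile(tmap, min_cells=min_cells)
    ext = extreme_levels(prof)
    sid = getattr(subject, "subject_id", "subject")
    return MorphometryRecord(
        subject_id=sid, height_mm=bone_height(subject),
        t_sl_mm=ext["t_sl"], t_il_mm=ext["t_il"],
        w_sl_mm=ext["w_sl"], w_il_mm=ext["w_il"],
        shape=classify_shape(prof), mean_stt_mm=mean_stt(smap))


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def summarize(values) -> SummaryStats:
    """Mean / SD (n-1) / median / min / max; CIs are filled by
    :func:`bootstrap_ci` separately."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InputError("need at least one value")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return SummaryStats(n=int(v.size), mean=float(v.mean()), sd=sd,
                        median=float(np.median(v)), min=float(v.min()),
                        max=float(v.max()))


def bootstrap_ci(values, statistic: str = "mean", n_boot: int = 1000,
                 seed: int = 0, level: float = 95.0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval (default 95%, 1000 draws)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("bootstrap needs n >= 2")
    stat = {"mean": np.mean, "median": np.median}.get(statistic, statistic)
    if not callable(stat):
        raise InputError("statistic must be 'mean', 'median' or a callable")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    reps = np.apply_along_axis(stat, 1, v[idx])
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def ols(y, predictors, names: list[str] | None = None) -> OlsResult:
    """Least-squares fit of ``y`` on the predictor columns plus an intercept."""
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise InputError("names must match the number of predictors")
    if y.size <= X.shape[1] + 1:
        raise InputError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InputError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    labels = ["const"] + list(names)
    ci = fit.conf_int(alpha=0.05)
    return OlsResult(
        params=dict(zip(labels, fit.params)),
        conf_int={n: (float(ci[k, 0]), float(ci[k, 1]))
                  for k, n in enumerate(labels)},
        pvalues=dict(zip(labels, fit.pvalues)),
        resid_sd=float(np.sqrt(fit.mse_resid)))
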