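"""Per-subject thickness / soft-tissue / slope maps and cohort heat maps.

All maps live on a frontal-plane lattice of square cells (default 1 x 1 mm)
whose origin is anchored at the jugular notch.  Cells are the half-open
squares ``[x, x+1) x [z, z+1)``; a map value belongs to the cell centre.
Cohort aggregation identifies cells across subjects by their integer offset
from the common origin — no interpolation is performed, mirroring the
notch-based alignment of the subjects themselves.

Per-subject maps interrogate the aligned triangulated surfaces with lines
parallel to the anterior-posterior axis ``y``: unicortical thickness is the
``y`` distance from the anterior margin of the anterior cortex to the
anterior margin of the posterior cortex, soft-tissue thickness (STT) the
distance from skin to anterior cortex, and slope the angle between the
local anterior-surface normal and ``+y``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .io import InputError, TissueSurfaceSet

__all__ = [
    "GridMap", "thickness_map", "stt_map", "slope_map",
    "aggregate_presence", "aggregate_mean", "fraction_ge",
    "fraction_slope_le", "roi_map",
]

_KINDS = {"thickness", "stt", "slope", "presence", "mean", "fraction", "roi"}


@dataclass
class GridMap:
    """A frontal-plane lattice of scalars with a presence mask.

    ``values`` is indexed ``[ix, iz]``; cell ``(i, j)`` covers
    ``[x0 + i*s, x0 + (i+1)*s) x [z0 + j*s, z0 + (j+1)*s)`` and its centre is
    at ``(x0 + (i+.5)*s, z0 + (j+.5)*s)``.  ``origin_xz`` is therefore the mm
    position of the lower-left cell *origin*, kept on the integer lattice so
    that subjects share cells exactly.
    """

    values: np.ndarray
    present: np.ndarray
    origin_xz: tuple[float, float]
    spacing: float = 1.0
    kind: str = "thickness"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.values.shape != self.present.shape or self.values.ndim != 2:
            raise InputError("values/present must be congruent 2-D lattices")
        if self.spacing <= 0:
            raise InputError("spacing must be positive")
        if self.kind not in _KINDS:
            raise InputError(f"unknown map kind '{self.kind}'")
        if self.present.any() and not np.isfinite(self.values[self.present]).all():
            raise InputError("non-finite values at present cells")
        if self.kind in ("thickness", "stt") and self.present.any() \
                and (self.values[self.present] < -1e-9).any():
            raise InputError(f"{self.kind} map must be non-negative")
        if self.kind == "slope" and self.present.any():
            v = self.values[self.present]
            if (v < -1e-9).any() or (v > 90 + 1e-9).any():
                raise InputError("slope must lie in [0, 90] degrees")
        if self.kind in ("presence", "fraction", "roi") and self.present.any():
            v = self.values[self.present]
            if (v < -1e-9).any() or (v > 100 + 1e-9).any():
                raise InputError("percentage maps must lie in [0, 100]")

    # -- geometry helpers --------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, nz = self.shape
        x0, z0 = self.origin_xz
        xs = x0 + (np.arange(nx) + 0.5) * self.spacing
        zs = z0 + (np.arange(nz) + 0.5) * self.spacing
        return xs, zs

    def masked(self) -> np.ndarray:
        """Values with absent cells as NaN."""
        return np.where(self.present, self.values, np.nan)

    def value_at(self, x: float, z: float) -> float:
        i = int(np.floor((x - self.origin_xz[0]) / self.spacing))
        j = int(np.floor((z - self.origin_xz[1]) / self.spacing))
        if not (0 <= i < self.shape[0] and 0 <= j < self.shape[1]):
            return np.nan
        return self.values[i, j] if self.present[i, j] else np.nan


# ---------------------------------------------------------------------------
# vertical-ray surface interrogation
# ---------------------------------------------------------------------------

def _first_hits(mesh: trimesh.Trimesh, xs: np.ndarray, zs: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """First intersection, coming from anterior (largest y), of lines parallel
    to y through each lattice point of ``xs x zs``.

    Returns ``(y_hit, tri_index)`` with NaN / -1 where the line misses the
    surface.  Exact for rays parallel to ``y``: a hit is a point-in-triangle
    test on the frontal projection plus barycentric interpolation of the
    vertex ``y`` values.  Triangles whose frontal projection is degenerate
    (normal nearly perpendicular to ``y``, a grazing hit) are discarded.
    """
    tri = mesh.triangles  # (m, 3, 3)
    ax, az = tri[:, :, 0], tri[:, :, 2]
    ay = tri[:, :, 1]
    # signed area of the projected triangle; ~0 => grazing
    area = ((ax[:, 1] - ax[:, 0]) * (az[:, 2] - az[:, 0])
            - (ax[:, 2] - ax[:, 0]) * (az[:, 1] - az[:, 0]))
    keep = np.abs(area) > 1e-9
    tri_idx_all = np.flatnonzero(keep)
    ax, az, ay, area = ax[keep], az[keep], ay[keep], area[keep]

    nx, nz = len(xs), len(zs)
    y_hit = np.full((nx, nz), np.nan)
    t_hit = np.full((nx, nz), -1, dtype=int)
    if len(ax) == 0:
        return y_hit, t_hit

    # bucket triangles on a coarse grid to keep candidate lists short
    cell = 4.0
    bx_min = np.floor(ax.min(axis=1) / cell).astype(int)
    bx_max = np.floor(ax.max(axis=1) / cell).astype(int)
    bz_min = np.floor(az.min(axis=1) / cell).astype(int)
    bz_max = np.floor(az.max(axis=1) / cell).astype(int)
    buckets: dict[tuple[int, int], list[int]] = {}
    for t in range(len(ax)):
        for bi in range(bx_min[t], bx_max[t] + 1):
            for bj in range(bz_min[t], bz_max[t] + 1):
                buckets.setdefault((bi, bj), []).append(t)

    qx = np.repeat(xs, nz)
    qz = np.tile(zs, nx)
    qb = np.stack([np.floor(qx / cell).astype(int),
                   np.floor(qz / cell).astype(int)], axis=1)
    # group queries by bucket
    order = np.lexsort((qb[:, 1], qb[:, 0]))
    sorted_b = qb[order]
    breaks = np.flatnonzero(np.any(np.diff(sorted_b, axis=0) != 0, axis=1)) + 1
    groups = np.split(order, breaks)
    eps = 1e-9
    for g in groups:
        key = (qb[g[0], 0], qb[g[0], 1])
        cand = buckets.get(key)
        if not cand:
            continue
        c = np.asarray(cand)
        px = qx[g][:, None] - ax[c, 0][None, :]
        pz = qz[g][:, None] - az[c, 0][None, :]
        e1x = (ax[c, 1] - ax[c, 0])[None, :]
        e1z = (az[c, 1] - az[c, 0])[None, :]
        e2x = (ax[c, 2] - ax[c, 0])[None, :]
        e2z = (az[c, 2] - az[c, 0])[None, :]
        det = area[c][None, :]
        u = (px * e2z - pz * e2x) / det
        v = (e1x * pz - e1z * px) / det
        inside = (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
        if not inside.any():
            continue
        yv = (ay[c, 0][None, :]
              + u * (ay[c, 1] - ay[c, 0])[None, :]
              + v * (ay[c, 2] - ay[c, 0])[None, :])
        yv = np.where(inside, yv, -np.inf)
        best = np.argmax(yv, axis=1)
        rows = np.arange(len(g))
        ybest = yv[rows, best]
        hit = np.isfinite(ybest)
        gi = g[hit]
        y_hit.flat[gi] = ybest[hit]
        t_hit.flat[gi] = tri_idx_all[c[best[hit]]]
    return y_hit, t_hit


def _grid_for(vertices: np.ndarray, spacing: float) -> tuple[tuple[float, float], int, int]:
    x0 = np.floor(vertices[:, 0].min() / spacing) * spacing
    z0 = np.floor(vertices[:, 2].min() / spacing) * spacing
    nx = int(np.ceil((vertices[:, 0].max() - x0) / spacing)) + 1
    nz = int(np.ceil((vertices[:, 2].max() - z0) / spacing)) + 1
    return (float(x0), float(z0)), nx, nz


def _centers(origin: tuple[float, float], nx: int, nz: int, spacing: float):
    xs = origin[0] + (np.arange(nx) + 0.5) * spacing
    zs = origin[1] + (np.arange(nz) + 0.5) * spacing
    return xs, zs


def _pair_map(front: trimesh.Trimesh, back: trimesh.Trimesh, kind: str,
              spacing: float) -> GridMap:
    verts = np.vstack([front.vertices, back.vertices])
    origin, nx, nz = _grid_for(verts, spacing)
    xs, zs = _centers(origin, nx, nz, spacing)
    y_f, _ = _first_hits(front, xs, zs)
    y_b, _ = _first_hits(back, xs, zs)
    present = np.isfinite(y_f) & np.isfinite(y_b)
    values = np.where(present, y_f - y_b, 0.0)
    neg = present & (values < 0)
    if neg.any():
        warnings.warn(f"{kind} map: dropping {int(neg.sum())} cells with "
                      "reversed surface order")
        present &= ~neg
        values[neg] = 0.0
    if not present.any():
        warnings.warn(f"{kind} map: surfaces do not intersect any common "
                      "cell; returning empty map")
    return GridMap(values=values, present=present, origin_xz=origin,
                   spacing=spacing, kind=kind)


def thickness_map(subject, spacing: float = 1.0) -> GridMap:
    """Unicortical thickness per cell: y distance from the anterior margin of
    the anterior cortex to the anterior margin of the posterior cortex."""
    s = _surfaces_of(subject)
    return _pair_map(s.anterior_cortex_front, s.posterior_cortex_front,
                     "thickness", spacing)


def stt_map(subject, spacing: float = 1.0) -> GridMap:
    """Soft-tissue thickness per cell: skin to anterior cortex."""
    s = _surfaces_of(subject)
    return _pair_map(s.skin, s.anterior_cortex_front, "stt", spacing)


def slope_map(subject, spacing: float = 1.0) -> GridMap:
    """Anterior-surface slope per cell: angle (degrees, in [0, 90]) between
    the outward surface normal at the y-line intersection and ``+y``."""
    s = _surfaces_of(subject)
    mesh = s.anterior_cortex_front
    origin, nx, nz = _grid_for(mesh.vertices, spacing)
    xs, zs = _centers(origin, nx, nz, spacing)
    y_f, t_idx = _first_hits(mesh, xs, zs)
    present = np.isfinite(y_f)
    normals = mesh.face_normals
    values = np.zeros((nx, nz))
    if present.any():
        n = normals[t_idx[present]]
        ny = np.abs(n[:, 1])
        ang = np.degrees(np.arctan2(np.hypot(n[:, 0], n[:, 2]), ny))
        values[present] = np.clip(ang, 0.0, 90.0)
    return GridMap(values=values, present=present, origin_xz=origin,
                   spacing=spacing, kind="slope")


def _surfaces_of(subject) -> TissueSurfaceSet:
    if isinstance(subject, TissueSurfaceSet):
        return subject
    return subject.surfaces  # AlignedSubject or Phantom


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def _common_lattice(maps: list[GridMap]):
    if not maps:
        raise InputError("need at least one map")
    spacing = maps[0].spacing
    for m in maps:
        if abs(m.spacing - spacing) > 1e-12:
            raise InputError("maps must share spacing")
        off = (np.asarray(m.origin_xz) - np.asarray(maps[0].origin_xz)) / spacing
        if not np.allclose(off, np.round(off), atol=1e-9):
            raise InputError("map origins are not on a common lattice")
    x0 = min(m.origin_xz[0] for m in maps)
    z0 = min(m.origin_xz[1] for m in maps)
    nx = max(int(round((m.origin_xz[0] - x0) / spacing)) + m.shape[0] for m in maps)
    nz = max(int(round((m.origin_xz[1] - z0) / spacing)) + m.shape[1] for m in maps)
    return (x0, z0), nx, nz, spacing


def _embed(m: GridMap, origin, nx, nz):
    i0 = int(round((m.origin_xz[0] - origin[0]) / m.spacing))
    j0 = int(round((m.origin_xz[1] - origin[1]) / m.spacing))
    vals = np.zeros((nx, nz))
    pres = np.zeros((nx, nz), dtype=bool)
    vals[i0:i0 + m.shape[0], j0:j0 + m.shape[1]] = m.values
    pres[i0:i0 + m.shape[0], j0:j0 + m.shape[1]] = m.present
    return vals, pres


def map_agreement(measured: GridMap, reference: GridMap, tol: float
                  ) -> tuple[float, int]:
    """Fraction of cells present in both maps whose values agree within
    ``tol``, plus the number of compared cells."""
    origin, nx, nz, _ = _common_lattice([measured, reference])
    mv, mp = _embed(measured, origin, nx, nz)
    rv, rp = _embed(reference, origin, nx, nz)
    both = mp & rp
    n = int(both.sum())
    if n == 0:
        return 0.0, 0
    ok = both & (np.abs(mv - rv) <= tol)
    return float(ok.sum() / n), n


def aggregate_presence(maps: list[GridMap]) -> GridMap:
    """Per cell, the percentage of subjects with bone present."""
    origin, nx, nz, spacing = _common_lattice(maps)
    count = np.zeros((nx, nz))
    for m in maps:
        _, p = _embed(m, origin, nx, nz)
        count += p
    vals = 100.0 * count / len(maps)
    return GridMap(values=vals, present=np.ones_like(count, dtype=bool),
                   origin_xz=origin, spacing=spacing, kind="presence")


def aggregate_mean(maps: list[GridMap]) -> GridMap:
    """Per cell, the mean over the subjects in which the cell is present."""
    origin, nx, nz, spacing = _common_lattice(maps)
    total = np.zeros((nx, nz))
    count = np.zeros((nx, nz))
    for m in maps:
        v, p = _embed(m, origin, nx, nz)
        total += np.where(p, v, 0.0)
        count += p
    present = count > 0
    vals = np.where(present, total / np.maximum(count, 1), 0.0)
    return GridMap(values=vals, present=present, origin_xz=origin,
                   spacing=spacing, kind="mean")


def _fraction(maps: list[GridMap], predicate) -> GridMap:
    origin, nx, nz, spacing = _common_lattice(maps)
    count = np.zeros((nx, nz))
    for m in maps:
        v, p = _embed(m, origin, nx, nz)
        count += p & predicate(v)
    vals = 100.0 * count / len(maps)
    return GridMap(values=vals, present=np.ones_like(count, dtype=bool),
                   origin_xz=origin, spacing=spacing, kind="fraction")


def fraction_ge(maps: list[GridMap], implant_length_mm: float) -> GridMap:
    """Per cell, % of subjects whose thickness is >= the implant length."""
    return _fraction(maps, lambda v: v >= implant_length_mm)


def fraction_slope_le(maps: list[GridMap], theta_deg: float = 15.0,
                      strict: bool = True) -> GridMap:
    """Per cell, % of subjects whose slope passes the implantability
    threshold (default: strictly below 15 degrees)."""
    if strict:
        return _fraction(maps, lambda v: v < theta_deg)
    return _fraction(maps, lambda v: v <= theta_deg)


def roi_map(thickness_maps: list[GridMap], slope_maps: list[GridMap],
            implant_length_mm: float, theta_deg: float = 15.0,
            strict: bool = True) -> GridMap:
    """Region-of-interest map: % of subjects that simultaneously satisfy the
    thickness and slope predicates in a cell."""
    if len(thickness_maps) != len(slope_maps):
        raise InputError("thickness and slope map lists must be paired")
    origin, nx, nz, spacing = _common_lattice(list(thickness_maps) + list(slope_maps))
    count = np.zeros((nx, nz))
    for tm, sm in zip(thickness_maps, slope_maps):
        tv, tp = _embed(tm, origin, nx, nz)
        sv, sp = _embed(sm, origin, nx, nz)
        s_ok = (sv < theta_deg) if strict else (sv <= theta_deg)
        count += tp & sp & (tv >= implant_length_mm) & s_ok
    vals = 100.0 * count / len(thickness_maps)
    return GridMap(values=vals, present=np.ones_like(count, dtype=bool),
                   origin_xz=origin, spacing=spacing, kind="roi")
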