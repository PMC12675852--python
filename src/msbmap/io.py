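"""File formats and in-memory containers for the mapping pipeline.

Surfaces travel as binary STL (one file per tissue role), volumes as a pair
of NIfTI-1 images (HU + integer labels), and heat maps as a small CSV grid
format with explicit cell-origin headers.  Everything is millimetres.
"""
from __future__ import annotations

import hashlib
import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .transforms import RigidTransform

__all__ = [
    "SURFACE_ROLES", "LABELS", "TissueSurfaceSet", "LabeledVolume",
    "FixtureTables", "load_fixture_tables",
    "read_surface_set", "write_surface_set",
    "read_labeled_volume", "write_labeled_volume",
    "read_grid_map", "write_grid_map", "render_grid_map",
]

#: tissue roles of the three segmented surfaces, in canonical order
SURFACE_ROLES = ("skin", "anterior_cortex_front", "posterior_cortex_front")

#: voxel label codes
LABELS = {"background": 0, "soft_tissue": 1, "cortical": 2, "cancellous": 3}


class FormatError(ValueError):
    """Malformed file content."""


class InputError(ValueError):
    """Inconsistent or missing inputs."""


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def _check_mesh(mesh: trimesh.Trimesh, role: str) -> trimesh.Trimesh:
    if len(mesh.vertices) < 4:
        raise FormatError(f"surface '{role}' has fewer than 4 vertices")
    if not np.isfinite(mesh.vertices).all():
        raise FormatError(f"surface '{role}' contains non-finite coordinates")
    return mesh


@dataclass
class TissueSurfaceSet:
    """Role-tagged triangulated surfaces of one subject, in a common mm frame.

    ``skin`` is the anterior skin surface, ``anterior_cortex_front`` the
    anterior margin of the anterior cortex, and ``posterior_cortex_front``
    the anterior margin of the posterior cortex (the far side of the
    unicortical thickness measurement).  ``frame_id`` is one of
    ``raw | oriented | aligned``.
    """

    skin: trimesh.Trimesh
    anterior_cortex_front: trimesh.Trimesh
    posterior_cortex_front: trimesh.Trimesh
    frame_id: str = "raw"

    def __post_init__(self) -> None:
        for role in SURFACE_ROLES:
            _check_mesh(getattr(self, role), role)

    def surface(self, role: str) -> trimesh.Trimesh:
        if role not in SURFACE_ROLES:
            raise InputError(f"unknown surface role '{role}'")
        return getattr(self, role)

    def bone_vertices(self) -> np.ndarray:
        """Vertices of both cortical surfaces, the 'bone point cloud'."""
        return np.vstack([self.anterior_cortex_front.vertices,
                          self.posterior_cortex_front.vertices])

    def transformed(self, tf: RigidTransform, frame_id: str | None = None) -> "TissueSurfaceSet":
        out = {}
        for role in SURFACE_ROLES:
            m = self.surface(role)
            out[role] = trimesh.Trimesh(vertices=tf.apply(m.vertices),
                                        faces=m.faces.copy(), process=False)
        return TissueSurfaceSet(frame_id=frame_id or self.frame_id, **out)


def write_surface_set(surfaces: TissueSurfaceSet, directory: str | Path) -> dict[str, Path]:
    """Write one binary STL per role; returns the role -> path mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role in SURFACE_ROLES:
        p = directory / f"{role}.stl"
        surfaces.surface(role).export(p, file_type="stl")
        paths[role] = p
    return paths


def read_surface_set(paths: dict[str, str | Path], frame_id: str = "raw") -> TissueSurfaceSet:
    """Read a role -> STL path mapping.  All three roles are required."""
    missing = [r for r in SURFACE_ROLES if r not in paths]
    if missing:
        raise InputError(f"missing surface role(s): {missing}")
    meshes = {}
    for role in SURFACE_ROLES:
        p = Path(paths[role])
        if not p.exists():
            raise InputError(f"no such file: {p}")
        if p.stat().st_size == 0:
            raise FormatError(f"empty STL file: {p} (byte offset 0)")
        try:
            m = trimesh.load_mesh(p, file_type="stl", process=False)
            m.merge_vertices()  # STL is a triangle soup; restore sharing
        except Exception as exc:  # trimesh raises a mix of types
            raise FormatError(f"malformed STL {p}: {exc}") from exc
        meshes[role] = _check_mesh(m, role)
    return TissueSurfaceSet(frame_id=frame_id, **meshes)


# ---------------------------------------------------------------------------
# labeled volumes
# ---------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """Voxel lattice of HU values plus tissue labels on the same grid.

    ``spacing`` is mm per axis (x, y, z); ``origin`` the mm position of the
    centre of voxel (0, 0, 0).  Label codes follow :data:`LABELS`.
    """

    hu: np.ndarray
    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.hu.shape != self.labels.shape:
            raise InputError("hu and labels must have congruent shapes")
        if not (self.spacing > 0).all():
            raise InputError("spacing must be positive")

    def mask(self, tissue: str) -> np.ndarray:
        if tissue not in LABELS:
            raise InputError(f"unknown tissue '{tissue}'")
        return self.labels == LABELS[tissue]

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return idx * self.spacing + self.origin


def _affine(vol: LabeledVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    return aff


def write_labeled_volume(vol: LabeledVolume, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(vol)
    paths = {"hu": directory / "hu.nii", "labels": directory / "labels.nii"}
    nib.save(nib.Nifti1Image(vol.hu.astype(np.float32), aff), paths["hu"])
    nib.save(nib.Nifti1Image(vol.labels.astype(np.uint8), aff), paths["labels"])
    return paths


def read_labeled_volume(path_hu: str | Path, path_labels: str | Path) -> LabeledVolume:
    img_hu = nib.load(str(path_hu))
    img_lb = nib.load(str(path_labels))
    if img_hu.shape != img_lb.shape:
        raise InputError("HU and label images must share shape")
    ah, al = img_hu.affine, img_lb.affine
    if not np.allclose(ah, al, atol=1e-6):
        raise InputError("HU and label images must share spacing/origin")
    spacing = np.diag(ah)[:3].copy()
    origin = ah[:3, 3].copy()
    return LabeledVolume(hu=np.asanyarray(img_hu.dataobj, dtype=np.float32),
                         labels=np.asanyarray(img_lb.dataobj, dtype=np.uint8),
                         spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# grid maps (CSV)
# ---------------------------------------------------------------------------
# The CSV grid uses half-open 1 mm cells [x, x+1) x [z, z+1) with the value at
# the cell centre.  Absent cells are written as an explicit sentinel rather
# than zero: a zero thickness is a meaningful measurement.

_SENTINEL = "NA"


def write_grid_map(gmap, path: str | Path) -> Path:
    """Write a :class:`~msbmap.mapping.GridMap` as CSV; deterministic bytes."""
    from .mapping import GridMap  # local import to avoid a cycle

    assert isinstance(gmap, GridMap)
    if not np.isfinite(gmap.values[gmap.present]).all():
        raise InputError("grid map has non-finite values at present cells")
    path = Path(path)
    nx, nz = gmap.values.shape
    lines = [f"# msbmap grid v1,kind={gmap.kind},spacing={gmap.spacing!r},"
             f"origin_x={gmap.origin_xz[0]!r},origin_z={gmap.origin_xz[1]!r},"
             f"nx={nx},nz={nz}"]
    lines.append("z_mm\\x_mm," + ",".join(
        repr(gmap.origin_xz[0] + i * gmap.spacing) for i in range(nx)))
    # rows from superior (large z) to inferior, one row per z cell
    for j in range(nz - 1, -1, -1):
        zc = gmap.origin_xz[1] + j * gmap.spacing
        cells = [repr(float(gmap.values[i, j])) if gmap.present[i, j] else _SENTINEL
                 for i in range(nx)]
        lines.append(f"{zc!r}," + ",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_grid_map(path: str | Path):
    from .mapping import GridMap

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# msbmap grid v1"):
        raise FormatError("not an msbmap grid CSV")
    header = dict(kv.split("=", 1) for kv in lines[0].split(",")[1:])
    nx, nz = int(header["nx"]), int(header["nz"])
    spacing = float(header["spacing"])
    origin = (float(header["origin_x"]), float(header["origin_z"]))
    values = np.zeros((nx, nz))
    present = np.zeros((nx, nz), dtype=bool)
    rows = lines[2:]
    if len(rows) != nz:
        raise FormatError(f"expected {nz} rows, found {len(rows)}")
    for k, line in enumerate(rows):
        j = nz - 1 - k
        cells = line.split(",")[1:]
        if len(cells) != nx:
            raise FormatError(f"ragged row at z index {j}: {len(cells)} cells")
        for i, c in enumerate(cells):
            if c != _SENTINEL:
                values[i, j] = float(c)
                present[i, j] = True
    return GridMap(values=values, present=present, origin_xz=origin,
                   spacing=spacing, kind=header["kind"])


def render_grid_map(gmap, path: str | Path, cmap: str = "viridis") -> Path:
    """Optional PNG rendering of a heat map (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.where(gmap.present, gmap.values, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4))
    x0, z0 = gmap.origin_xz
    nx, nz = arr.shape
    im = ax.imshow(arr.T, origin="lower", cmap=cmap,
                   extent=(x0, x0 + nx * gmap.spacing, z0, z0 + nz * gmap.spacing))
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_title(gmap.kind)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# packaged fixture tables
# ---------------------------------------------------------------------------

_CHECKSUMS = {
    "table3.csv": "19bafd1bc9a1a12478711336855069c8b799e66362fd91ab49a3f07ce72127b9",
    "table4.csv": "48b12345589c45901e0048a84ab50f583cfaad13a4b42ab887166de26dd0893d",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture bytes do not match their recorded checksum."""


@dataclass
class FixtureTables:
    """The packaged per-subject study tables (49 subjects each).

    ``table3`` holds morphometry: bone height, unicortical thickness and
    width at the superior (thickest, SL) and inferior (thinnest, IL) levels,
    the visually assigned shape, and the subject's average soft-tissue
    thickness.  ``table4`` holds scan settings and bone density: median HU
    of the cortical and cancellous compartments plus the Norton & Gamble
    (computed from HU) and Lekholm & Zarb (visual, annotation-only) classes.
    """

    table3: pd.DataFrame
    table4: pd.DataFrame


def _read_packaged(name: str) -> bytes:
    res = importlib.resources.files("msbmap").joinpath("data", name)
    data = res.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")
    return data


def load_fixture_tables() -> FixtureTables:
    import io as _io

    t3 = pd.read_csv(_io.BytesIO(_read_packaged("table3.csv")))
    t4 = pd.read_csv(_io.BytesIO(_read_packaged("table4.csv")))
    for t in (t3, t4):
        if len(t) != 49:
            raise FixtureIntegrityError("fixture tables must have 49 rows")
    return FixtureTables(table3=t3, table4=t4)
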