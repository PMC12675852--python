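"""Orientation and jugular-notch alignment of segmented bone surfaces.

The alignment chain puts an arbitrarily posed subject into the canonical
frame in three steps:

1. :func:`pca_orient` — principal-component analysis of the bone point
   cloud.  The smallest-spread principal direction becomes the plate normal
   ``y``; the two in-plane directions are assigned to mediolateral ``x`` and
   longitudinal ``z`` by looking for the notch (the concave indentation of
   the boundary), which also fixes the superior direction; the skin surface
   fixes the anterior direction.
2. :func:`frontal_rotation` — a refinement rotation about ``y``.  Vertices
   are trimmed bilaterally by mediolateral percentiles (to drop the
   costochondral-junction regions) and the principal direction of the
   remaining frontal-plane points is snapped to the nearest coordinate axis.
3. :func:`detect_notch` — the boundary of the frontal projection is
   extracted on a 1 mm occupancy grid; on each side of the midline the
   boundary point maximal in the chosen criterion (anterior-most ``y`` by
   default, superior-most ``z`` optionally) is selected, and their midpoint
   is taken as the jugular notch, which is then translated to the origin.

:func:`align` composes the three into one rigid transform; a manually
picked notch can be supplied in place of the automatic detection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import InputError, TissueSurfaceSet
from .transforms import RigidTransform

__all__ = ["AlignedSubject", "pca_orient", "frontal_rotation",
           "detect_notch", "align", "pose_recovery_errors",
           "DegeneracyWarning", "NotchDetectionError"]


class DegeneracyWarning(UserWarning):
    """The point set is too isotropic for a meaningful principal frame."""


class NotchDetectionError(RuntimeError):
    """Automatic notch detection failed; a manual notch is required."""


@dataclass
class AlignedSubject:
    """A subject in the canonical frame with its alignment bookkeeping."""

    surfaces: TissueSurfaceSet
    total_transform: RigidTransform
    notch_xz: tuple[float, float]
    manual_override_used: bool = False
    subject_id: str = "subject"


# ---------------------------------------------------------------------------
# step 1: PCA orientation
# ---------------------------------------------------------------------------

def _occupancy_top_profile(x: np.ndarray, z: np.ndarray, cell: float = 1.0):
    """For each occupied 1 mm x-column, the z of its top-most occupied cell."""
    ix = np.floor(x / cell).astype(int)
    iz = np.floor(z / cell).astype(int)
    order = np.lexsort((iz, ix))
    ixs, izs = ix[order], iz[order]
    first = np.r_[True, np.diff(ixs) != 0]
    # per column, max iz: reverse trick
    cols, top = [], []
    start = np.flatnonzero(first)
    end = np.r_[start[1:], len(ixs)]
    for s, e in zip(start, end):
        cols.append(ixs[s])
        top.append(izs[s:e].max())
    return (np.asarray(cols) + 0.5) * cell, (np.asarray(top) + 1.0) * cell


def _notch_score(x: np.ndarray, z: np.ndarray) -> float:
    """Concavity of the superior boundary at the midline: positive when a
    notch-like indentation is present at the top centre."""
    xc, top = _occupancy_top_profile(x, z)
    central = np.abs(xc) <= 3.0
    left = (xc < -3.0) & (xc >= -25.0)
    right = (xc > 3.0) & (xc <= 25.0)
    if not central.any() or not left.any() or not right.any():
        return -np.inf
    shoulder = min(top[left].max(), top[right].max())
    return float(shoulder - top[central].max())


def pca_orient(surfaces: TissueSurfaceSet
               ) -> tuple[TissueSurfaceSet, RigidTransform]:
    """Rotate the bone point cloud onto its principal axes.

    Contract: afterwards the smallest-spread direction of the bone lies
    along ``y`` (the plate normal); the in-plane axes are assigned so that
    the concave, notch-bearing end of the footprint points to ``+z``
    (superior) and the skin lies at larger ``y`` than the bone (anterior).
    Near-isotropic clouds (smallest principal-value ratio below 1.05) get a
    :class:`DegeneracyWarning` and an identity rotation about the centroid.
    """
    pts = surfaces.bone_vertices()
    center = pts.mean(axis=0)
    q = pts - center
    cov = q.T @ q / len(q)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 0 or evals[1] / max(evals[0], 1e-30) < 1.05 ** 2:
        warnings.warn("near-isotropic point set; orientation is arbitrary",
                      DegeneracyWarning)
        tf = RigidTransform(np.eye(3), -center)
        return surfaces.transformed(tf, frame_id="oriented"), tf
    e_y = evecs[:, 0]
    cand_a, cand_b = evecs[:, 2], evecs[:, 1]
    # in-plane coordinates
    a = q @ cand_a
    b = q @ cand_b
    best, best_score = None, -np.inf
    for e_z_try, xcoord, zcoord in ((cand_a, b, a), (-cand_a, b, -a),
                                    (cand_b, a, b), (-cand_b, a, -b)):
        score = _notch_score(xcoord, zcoord)
        if score > best_score:
            best, best_score = e_z_try, score
    e_z = best
    # anterior: skin lies at greater y than the bone
    skin_mean = surfaces.skin.vertices.mean(axis=0) - center
    if float(skin_mean @ e_y) < 0:
        e_y = -e_y
    e_x = np.cross(e_y, e_z)
    R = np.vstack([e_x, e_y, e_z])
    tf = RigidTransform(R, -R @ center)
    return surfaces.transformed(tf, frame_id="oriented"), tf


# ---------------------------------------------------------------------------
# step 2: frontal-plane refinement rotation
# ---------------------------------------------------------------------------

def frontal_rotation(surfaces: TissueSurfaceSet, trim_lo: float = 5.0,
                     trim_hi: float = 95.0
                     ) -> tuple[TissueSurfaceSet, RigidTransform]:
    """Refine the in-plane rotation about ``y``.

    Bone vertices with mediolateral coordinate between the ``trim_lo`` and
    ``trim_hi`` percentiles are kept (a bilateral trim that drops the
    costochondral-junction outliers); the leading principal direction of
    their frontal-plane projection is rotated about ``y`` onto the nearest
    coordinate axis.  Excluded vertices are still transformed.
    """
    pts = surfaces.bone_vertices()
    lo, hi = np.percentile(pts[:, 0], [trim_lo, trim_hi])
    keep = (pts[:, 0] >= lo) & (pts[:, 0] <= hi)
    if keep.sum() < 10:
        raise InputError("fewer than 10 vertices retained by the trim")
    xz = pts[keep][:, [0, 2]]
    xz = xz - xz.mean(axis=0)
    cov = xz.T @ xz / len(xz)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] > 2.25 * max(evals[0], 1e-30):  # spread ratio >= 1.5
        u = evecs[:, 1]  # leading direction in the frontal plane
        theta = np.degrees(np.arctan2(u[1], u[0]))
        if theta > 90:
            theta -= 180
        elif theta <= -90:
            theta += 180
        psi = theta if abs(theta) <= 45 else theta - np.sign(theta) * 90
    else:
        # The frontal footprint is nearly isotropic, so second moments carry
        # almost no in-plane orientation signal (the very degeneracy that
        # rules out a plain frontal-plane PCA).  Fall back to the bone's
        # bilateral symmetry: pick the rotation that best mirrors the
        # frontal occupancy about the mid-sagittal line.
        psi = _mirror_symmetry_angle(xz)
    tf = RigidTransform.rotation_about("y", psi)
    return surfaces.transformed(tf, frame_id="oriented"), tf


def _mirror_mismatch(xz: np.ndarray, psi_deg: float, cell: float = 1.0) -> float:
    c, s = np.cos(np.radians(psi_deg)), np.sin(np.radians(psi_deg))
    # R_y(psi) acting on (x, z): x' = c x + s z, z' = -s x + c z
    x = c * xz[:, 0] + s * xz[:, 1]
    z = -s * xz[:, 0] + c * xz[:, 1]
    x = x - x.mean()
    ix = np.floor(x / cell).astype(int)
    iz = np.floor(z / cell).astype(int)
    occ = set(zip(ix.tolist(), iz.tolist()))
    mirrored = {(-1 - i, j) for (i, j) in occ}
    return len(occ.symmetric_difference(mirrored)) / max(len(occ), 1)


def _mirror_symmetry_angle(xz: np.ndarray, span: float = 20.0) -> float:
    """In-plane angle (deg) that maximises mirror symmetry about x = 0."""
    coarse = np.arange(-span, span + 0.5, 0.5)
    scores = [_mirror_mismatch(xz, a) for a in coarse]
    best = coarse[int(np.argmin(scores))]
    fine = np.arange(best - 0.5, best + 0.55, 0.1)
    scores = [_mirror_mismatch(xz, a) for a in fine]
    return float(fine[int(np.argmin(scores))])


# ---------------------------------------------------------------------------
# step 3: notch detection and alignment
# ---------------------------------------------------------------------------

def detect_notch(surfaces: TissueSurfaceSet, criterion: str = "y",
                 cell: float = 1.0) -> tuple[float, float]:
    """Locate the jugular notch on oriented surfaces.

    The frontal projection of the bone cloud is rasterised on a ``cell`` mm
    occupancy grid; boundary cells are occupied cells with at least one
    empty 4-neighbour.  On each side of the midline ``x = 0`` the boundary
    point maximal under the criterion (``y``: most anterior, the literal
    reading; ``z``: most superior) is selected — ties broken toward smaller
    ``|x|`` — and the midpoint of the two is returned.
    """
    if criterion not in ("y", "z"):
        raise InputError("criterion must be 'y' or 'z'")
    from scipy.ndimage import binary_closing, binary_fill_holes

    pts = surfaces.bone_vertices()
    ix = np.floor(pts[:, 0] / cell).astype(int)
    iz = np.floor(pts[:, 2] / cell).astype(int)
    i0, j0 = ix.min() - 1, iz.min() - 1
    occ = np.zeros((ix.max() - i0 + 3, iz.max() - j0 + 3), dtype=bool)
    occ[ix - i0, iz - j0] = True
    # mesh vertices can be sparser than the grid, leaving thin empty seams
    # in the rasterisation; close them and fill enclosed holes so that only
    # the true outline remains boundary (the notch void stays open to the
    # exterior and is preserved)
    occ = binary_fill_holes(binary_closing(occ, structure=np.ones((3, 3))))
    nb = np.zeros_like(occ, dtype=int)
    nb[1:, :] += occ[:-1, :]
    nb[:-1, :] += occ[1:, :]
    nb[:, 1:] += occ[:, :-1]
    nb[:, :-1] += occ[:, 1:]
    boundary = occ & (nb < 4)
    cell_of = (ix - i0) * occ.shape[1] + (iz - j0)
    on_boundary = boundary[ix - i0, iz - j0]
    if not on_boundary.any():
        raise NotchDetectionError("no boundary cells found")
    bpts = pts[on_boundary]
    crit = bpts[:, 1] if criterion == "y" else bpts[:, 2]
    sides = []
    for side in (bpts[:, 0] < 0, bpts[:, 0] > 0):
        if not side.any():
            raise NotchDetectionError(
                "all boundary points on one side of x = 0; manual notch "
                "selection required")
        c = crit[side]
        cand = np.flatnonzero(c >= c.max() - 1e-9)
        # tie-break: smallest |x|
        k = cand[np.argmin(np.abs(bpts[side][cand, 0]))]
        sides.append(bpts[side][k])
    mid = 0.5 * (sides[0] + sides[1])
    return float(mid[0]), float(mid[2])


def align(surfaces: TissueSurfaceSet,
          manual_notch: tuple[float, float] | None = None,
          notch_criterion: str = "y",
          trim_lo: float = 5.0, trim_hi: float = 95.0,
          subject_id: str = "subject") -> AlignedSubject:
    """Full alignment: PCA orientation, frontal refinement, notch to origin."""
    s1, t1 = pca_orient(surfaces)
    s2, t2 = frontal_rotation(s1, trim_lo, trim_hi)
    if manual_notch is not None:
        nx, nz = float(manual_notch[0]), float(manual_notch[1])
        manual = True
    else:
        nx, nz = detect_notch(s2, criterion=notch_criterion)
        manual = False
    t3 = RigidTransform.translation_of((-nx, 0.0, -nz))
    s3 = s2.transformed(t3, frame_id="aligned")
    total = t3.compose(t2.compose(t1))
    return AlignedSubject(surfaces=s3, total_transform=total,
                          notch_xz=(0.0, 0.0), manual_override_used=manual,
                          subject_id=subject_id)


# ---------------------------------------------------------------------------
# recovery scoring against phantom ground truth
# ---------------------------------------------------------------------------

def pose_recovery_errors(subject: AlignedSubject, phantom) -> tuple[float, float]:
    """(orientation error deg, notch localisation error mm) of an alignment
    of a phantom whose applied pose is known.

    A perfect alignment inverts the applied transform, so the rotation part
    of ``total o applied`` measures the orientation error, and the aligned
    image of the true notch point measures the notch error in the frontal
    plane.
    """
    residual = subject.total_transform.compose(phantom.truth.applied_transform)
    ang = residual.rotation_angle_deg()
    notch3d = np.array([phantom.truth.notch_xz[0],
                        phantom.truth.true_scalars.get("notch_y", 0.0),
                        phantom.truth.notch_xz[1]])
    img = residual.apply(notch3d[None, :])[0]
    return float(ang), float(np.hypot(img[0], img[2]))
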