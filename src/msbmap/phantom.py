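"""Synthetic manubrium-sterni phantoms with analytic ground truth.

A phantom is a parametric plate in the canonical frame (x mediolateral,
y anterior, z superior): a superior-wide trapezoidal footprint with rounded
corners and a circular-segment jugular-notch cut at the superior midline,
an anterior cortical face carrying a smooth dome (whose maximum inclination
is ``face_curvature_deg``) and two paramedian apical protuberances, a flat
posterior-cortex front at ``y = 0``, and a skin surface offset anteriorly
by the soft-tissue thickness.  The frame is anchored so that the lowest
point of the notch cut sits at ``(x, z) = (0, 0)``.

Because every surface is an explicit function of ``(x, z)``, the
unicortical-thickness, slope and soft-tissue-thickness fields, the notch
location and all morphometric scalars are known in closed form; they are
stored as :class:`PhantomGroundTruth` and never derived from the emitted
meshes, which makes every downstream stage testable by recovery.

A cohort generator draws subject covariates (sex, body height, BMI) and
sets the morphometric scalars as linear functions of them with configurable
effect sizes, so that regression analyses can be validated against the
generating coefficients.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
import trimesh
from scipy import ndimage
from scipy.spatial import Delaunay
from scipy.stats import truncnorm
from shapely.geometry import Point, Polygon

from .io import LABELS, LabeledVolume, TissueSurfaceSet
from .mapping import GridMap
from .transforms import RigidTransform

__all__ = [
    "PhantomSpec", "PopulationParams", "PhantomGroundTruth", "Phantom",
    "generate_phantom", "apply_rigid", "sample_cohort", "sample_cohort_table",
]


class ParameterError(ValueError):
    """A phantom parameter violates its invariant."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and radiodensity parameters of one phantom (mm / HU)."""

    height_mm: float = 52.0
    width_sup_mm: float = 53.0
    width_inf_mm: float = 57.0
    base_thickness_mm: float = 11.0
    protuberance_amp_mm: float = 2.0
    protuberance_sigma_mm: float = 9.0
    protuberance_offset_x_mm: float = 12.0
    protuberance_offset_z_mm: float = 10.0   # depth below the superior edge
    cortex_mm: float = 1.4
    stt_base_mm: float = 14.4
    notch_depth_mm: float = 5.0
    notch_radius_mm: float = 10.0
    face_curvature_deg: float = 10.0
    hu_cortical_mean: float = 325.0
    hu_cortical_sd: float = 73.0
    hu_cancellous_mean: float = 60.0
    hu_cancellous_sd: float = 35.0
    hu_soft_mean: float = 40.0
    hu_soft_sd: float = 25.0
    voxel_mm: float = 0.7
    mesh_mm: float = 1.25
    corner_radius_mm: float = 5.0

    def validate(self) -> None:
        for name in ("height_mm", "width_sup_mm", "width_inf_mm",
                     "base_thickness_mm", "cortex_mm", "stt_base_mm",
                     "voxel_mm", "mesh_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.cortex_mm >= self.base_thickness_mm / 2:
            raise ParameterError("cortex_mm must be < base_thickness_mm / 2")
        if self.voxel_mm > 1.0:
            raise ParameterError("voxel_mm must be <= 1.0 (sub-grid)")
        if self.protuberance_amp_mm < 0 or self.protuberance_sigma_mm <= 0:
            raise ParameterError("protuberance amplitude must be >= 0, sigma > 0")
        if self.notch_depth_mm < 0 or self.notch_radius_mm <= self.notch_depth_mm / 2:
            raise ParameterError("notch radius too small for requested depth")
        if not (0 <= self.face_curvature_deg < 90):
            raise ParameterError("face_curvature_deg must be in [0, 90)")
        model = _AnalyticModel(self)
        for sx in (+1.0, -1.0):
            px = sx * self.protuberance_offset_x_mm
            pz = model.z_sup - self.protuberance_offset_z_mm
            if not model.footprint.contains(Point(px, pz)):
                raise ParameterError("protuberance centers must lie inside "
                                     "the plate footprint")


@dataclass(frozen=True)
class PopulationParams:
    """Population structure of the synthetic cohort.

    ``beta_*`` are the linear effect sizes used to set per-subject
    morphometric scalars from covariates: sex coded 0 = female, 1 = male;
    body height centred at its population mean (cm); BMI centred at its
    population median.  ``resid_*`` are the SDs of the independent residual
    noise added on top of each linear predictor.
    """

    beta_sex_thickness_sl: float = 1.387     # mm
    beta_sex_thickness_il: float = 1.914     # mm
    beta_sex_width_il: float = 7.098         # mm
    beta_height_thickness_sl: float = 0.072  # mm per cm
    beta_height_width_sl: float = 0.422      # mm per cm
    beta_bmi_stt: float = 1.069              # mm per BMI unit
    beta_sex_cancellous: float = 22.017      # HU

    mean_body_height_cm: float = 172.5
    sd_body_height_cm: float = 8.1
    median_bmi: float = 22.3
    bmi_log_sd: float = 0.22                 # BMI is lognormal (right-skewed)

    baseline_height: float = 52.0
    baseline_t_sl: float = 12.41
    baseline_t_il: float = 7.74
    baseline_w_sl: float = 53.2
    baseline_w_il: float = 53.55
    baseline_stt: float = 14.4
    baseline_cancellous: float = 49.0
    cortical_hu_mean: float = 325.0
    cortical_hu_sd: float = 72.0

    resid_height: float = 5.7
    resid_t_sl: float = 1.3
    resid_t_il: float = 1.3
    resid_w_sl: float = 7.3
    resid_w_il: float = 5.6
    resid_stt: float = 4.0
    resid_cancellous: float = 33.0

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if name.startswith(("resid_", "sd_", "bmi_log")) and v < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Analytic ground truth of one phantom, in the canonical (aligned) frame."""

    thickness_field: GridMap
    slope_field: GridMap
    stt_field: GridMap
    notch_xz: tuple[float, float]
    applied_transform: RigidTransform
    covariates: dict | None
    true_scalars: dict


@dataclass
class Phantom:
    spec: PhantomSpec
    seed: int
    surfaces: TissueSurfaceSet
    truth: PhantomGroundTruth
    volume: LabeledVolume | None = None
    subject_id: str = "phantom"


# ---------------------------------------------------------------------------
# analytic model
# ---------------------------------------------------------------------------

class _AnalyticModel:
    """Closed-form surfaces and fields for a :class:`PhantomSpec`."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.z_sup = spec.notch_depth_mm             # superior edge
        self.z_inf = spec.notch_depth_mm - spec.height_mm
        hw_sup = spec.width_sup_mm / 2.0
        hw_inf = spec.width_inf_mm / 2.0
        plate = Polygon([(-hw_inf, self.z_inf), (hw_inf, self.z_inf),
                         (hw_sup, self.z_sup), (-hw_sup, self.z_sup)])
        r = min(spec.corner_radius_mm,
                0.25 * min(spec.width_sup_mm, spec.width_inf_mm, spec.height_mm))
        if r > 0:
            plate = plate.buffer(-r, quad_segs=16).buffer(r, quad_segs=16)
        notch = Point(0.0, spec.notch_radius_mm).buffer(
            spec.notch_radius_mm, quad_segs=64)
        self.footprint = plate.difference(notch)
        shapely.prepare(self.footprint)
        # The face inclination budget tan(face_curvature_deg) is split between
        # a lateral (x) quadratic falloff and a gentle anterior rise toward
        # the superior border (the bone curls anteriorly at the notch), so
        # the maximum anterior-face inclination equals face_curvature_deg at
        # the lateral edge.
        # The inclination budget tan(face_curvature_deg) is split between a
        # lateral (x) quadratic falloff and a craniocaudal thickness
        # gradient; the plate thickens superiorly but the gradient is shared
        # symmetrically by the two cortical faces, so the plate mid-plane
        # stays flat.
        tan_c = np.tan(np.radians(spec.face_curvature_deg))
        self._a = 0.98 * tan_c                       # lateral falloff strength
        self._g = 0.40 * tan_c                       # dt/dz, superior thickening
        self.half_width = max(spec.width_sup_mm, spec.width_inf_mm) / 2.0
        self.z_mid = 0.5 * (self.z_sup + self.z_inf)
        zp = self.z_sup - spec.protuberance_offset_z_mm
        self._prot_centers = [(+spec.protuberance_offset_x_mm, zp),
                              (-spec.protuberance_offset_x_mm, zp)]
        self._sdf = None
        # Anchor the frame at the jugular notch as the detection criterion
        # defines it: the boundary point of greatest anterior y on each side
        # of the midline lies on the notch arc, and the frame origin is the
        # midpoint of that symmetric pair.
        z_star = 0.0
        if spec.notch_depth_mm > 0:
            R = spec.notch_radius_mm
            x_top = np.sqrt(max(R ** 2 - (R - self.z_sup) ** 2, 0.0))
            xa = np.linspace(0.05, 0.999 * x_top, 256)
            za = R - np.sqrt(R ** 2 - xa ** 2)
            z_star = float(za[int(np.argmax(self.anterior_y(xa, za)))])
        if z_star != 0.0:
            self.footprint = shapely.affinity.translate(self.footprint,
                                                        yoff=-z_star)
            shapely.prepare(self.footprint)
            self.z_sup -= z_star
            self.z_inf -= z_star
            self.z_mid -= z_star
            self._prot_centers = [(cx, cz - z_star)
                                  for (cx, cz) in self._prot_centers]

    # -- scalar fields -----------------------------------------------------
    def contains(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return shapely.contains_xy(self.footprint, np.asarray(x, dtype=float),
                                   np.asarray(z, dtype=float))

    def _face(self, x, z):
        """Sculpting of the anterior face: lateral falloff + half the
        craniocaudal thickness gradient."""
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        return (-self._a * x ** 2 / (2.0 * self.half_width)
                + 0.5 * self._g * (z - self.z_mid))

    def posterior_y(self, x, z):
        """Anterior margin of the posterior cortex (carries the other half
        of the thickness gradient, keeping the mid-plane flat)."""
        z = np.asarray(z, dtype=float)
        return np.broadcast_to(-0.5 * self._g * (z - self.z_mid),
                               np.broadcast_shapes(np.shape(x), np.shape(z))).copy()

    def thickness(self, x, z):
        return self.anterior_y(x, z) - self.posterior_y(x, z)

    def _prot(self, x, z):
        s = self.spec
        out = np.zeros_like(np.asarray(x, dtype=float))
        if s.protuberance_amp_mm > 0:
            for cx, cz in self._prot_centers:
                out += s.protuberance_amp_mm * np.exp(
                    -((np.asarray(x) - cx) ** 2 + (np.asarray(z) - cz) ** 2)
                    / (2.0 * s.protuberance_sigma_mm ** 2))
        return out

    def anterior_y(self, x, z):
        """Anterior margin of the anterior cortex (the unicortical thickness)."""
        return self.spec.base_thickness_mm + self._prot(x, z) + self._face(x, z)

    def gradient(self, x, z):
        s = self.spec
        gx = np.zeros_like(np.asarray(x, dtype=float))
        gz = np.zeros_like(gx)
        gx -= self._a * np.asarray(x) / self.half_width
        gz += 0.5 * self._g
        if s.protuberance_amp_mm > 0:
            for cx, cz in self._prot_centers:
                g = s.protuberance_amp_mm * np.exp(
                    -((np.asarray(x) - cx) ** 2 + (np.asarray(z) - cz) ** 2)
                    / (2.0 * s.protuberance_sigma_mm ** 2))
                gx += g * -(np.asarray(x) - cx) / s.protuberance_sigma_mm ** 2
                gz += g * -(np.asarray(z) - cz) / s.protuberance_sigma_mm ** 2
        return gx, gz

    def slope_deg(self, x, z):
        gx, gz = self.gradient(x, z)
        return np.degrees(np.arctan(np.hypot(gx, gz)))

    # -- boundary distance (for the lateral cortical shell) ----------------
    def boundary_distance(self, x, z):
        if self._sdf is None:
            h = 0.5
            minx, minz, maxx, maxz = self.footprint.bounds
            gx = np.arange(minx - 2, maxx + 2 + h, h)
            gz = np.arange(minz - 2, maxz + 2 + h, h)
            GX, GZ = np.meshgrid(gx, gz, indexing="ij")
            inside = self.contains(GX.ravel(), GZ.ravel()).reshape(GX.shape)
            dist = ndimage.distance_transform_edt(inside) * h
            self._sdf = (gx[0], gz[0], h, dist)
        x0, z0, h, dist = self._sdf
        ci = (np.asarray(x, dtype=float) - x0) / h
        cj = (np.asarray(z, dtype=float) - z0) / h
        return ndimage.map_coordinates(dist, [np.atleast_1d(ci), np.atleast_1d(cj)],
                                       order=1, mode="constant", cval=0.0)

    # -- voxel labelling ---------------------------------------------------
    def labels_at(self, pts: np.ndarray) -> np.ndarray:
        """Tissue label of canonical-frame points ``(n, 3)``."""
        s = self.spec
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        out = np.zeros(len(pts), dtype=np.uint8)
        inside = self.contains(x, z)
        if not inside.any():
            return out
        f = self.anterior_y(x[inside], z[inside])
        pb = self.posterior_y(x[inside], z[inside])
        yi = y[inside]
        bone = (yi >= pb - s.cortex_mm) & (yi <= f)
        soft = (yi > f) & (yi <= f + s.stt_base_mm)
        d2b = self.boundary_distance(x[inside], z[inside])
        cortical = bone & ((yi <= pb) | (yi >= f - s.cortex_mm)
                           | (d2b <= s.cortex_mm))
        lab = np.zeros(inside.sum(), dtype=np.uint8)
        lab[soft] = LABELS["soft_tissue"]
        lab[bone & ~cortical] = LABELS["cancellous"]
        lab[cortical] = LABELS["cortical"]
        out[inside] = lab
        return out


# ---------------------------------------------------------------------------
# mesh and volume construction
# ---------------------------------------------------------------------------

def _triangulate_footprint(model: _AnalyticModel, mesh_mm: float):
    minx, minz, maxx, maxz = model.footprint.bounds
    # keep the lattice mirror-symmetric about x = 0 (the footprint is)
    kx = int(np.ceil(max(maxx, -minx) / mesh_mm))
    gx = np.concatenate([-(np.arange(kx) + 0.5)[::-1], np.arange(kx) + 0.5]) * mesh_mm
    gz = np.arange(minz, maxz + mesh_mm, mesh_mm)
    GX, GZ = np.meshgrid(gx, gz, indexing="ij")
    pts = np.column_stack([GX.ravel(), GZ.ravel()])
    keep = model.contains(pts[:, 0], pts[:, 1])
    interior = pts[keep]
    ring = shapely.segmentize(model.footprint.exterior, mesh_mm)
    boundary = np.asarray(ring.coords)[:-1]
    pts2 = np.vstack([interior, boundary])
    tri = Delaunay(pts2)
    cent = pts2[tri.simplices].mean(axis=1)
    # Delaunay fills the convex hull; keep only faces inside the footprint
    ok = shapely.contains_xy(model.footprint.buffer(1e-6),
                             cent[:, 0], cent[:, 1])
    return pts2, tri.simplices[ok]


def _lift(pts2: np.ndarray, y: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    verts = np.column_stack([pts2[:, 0], y, pts2[:, 1]])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # orient all faces with an anterior-pointing (+y) normal
    flip = mesh.face_normals[:, 1] < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _truth_fields(model: _AnalyticModel, spacing: float = 1.0):
    minx, minz, maxx, maxz = model.footprint.bounds
    x0 = np.floor(minx / spacing) * spacing
    z0 = np.floor(minz / spacing) * spacing
    nx = int(np.ceil((maxx - x0) / spacing)) + 1
    nz = int(np.ceil((maxz - z0) / spacing)) + 1
    xs = x0 + (np.arange(nx) + 0.5) * spacing
    zs = z0 + (np.arange(nz) + 0.5) * spacing
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    present = model.contains(X.ravel(), Z.ravel()).reshape(X.shape)
    thick = np.where(present, model.thickness(X, Z), 0.0)
    slope = np.where(present, model.slope_deg(X, Z), 0.0)
    stt = np.where(present, model.spec.stt_base_mm, 0.0)
    origin = (float(x0), float(z0))
    return (GridMap(thick, present, origin, spacing, "thickness"),
            GridMap(np.clip(slope, 0, 90), present, origin, spacing, "slope"),
            GridMap(stt, present, origin, spacing, "stt"))


def _row_extremes(tmap: GridMap, min_cells: int = 10):
    """(t_sl, w_sl, t_il, w_il) from row medians / widths of a truth field."""
    med, wid, zidx = [], [], []
    for j in range(tmap.shape[1]):
        row = tmap.values[:, j][tmap.present[:, j]]
        if len(row) >= min_cells:
            med.append(float(np.median(row)))
            wid.append(len(row) * tmap.spacing)
            zidx.append(j)
    med = np.asarray(med)
    wid = np.asarray(wid)
    j_sl = len(med) - 1 - int(np.argmax(med[::-1]))   # ties -> superior
    j_il = len(med) - 1 - int(np.argmin(med[::-1]))
    return med[j_sl], wid[j_sl], med[j_il], wid[j_il]


def _rasterize(model: _AnalyticModel, pose: RigidTransform,
               hu_rng: np.random.Generator, margin: float = 2.0) -> LabeledVolume:
    s = model.spec
    # world-frame bounds: transform the canonical bounding box corners
    minx, minz, maxx, maxz = model.footprint.bounds
    ymin = -s.cortex_mm - 0.5 * np.tan(np.radians(s.face_curvature_deg)) \
        * s.height_mm - margin
    ymax = s.base_thickness_mm + s.protuberance_amp_mm * 2 + s.stt_base_mm + margin
    corners = np.array([(x, y, z)
                        for x in (minx - margin, maxx + margin)
                        for y in (ymin, ymax)
                        for z in (minz - margin, maxz + margin)])
    wc = pose.apply(corners)
    lo, hi = wc.min(axis=0), wc.max(axis=0)
    h = s.voxel_mm
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    axes = [lo[k] + np.arange(shape[k]) * h for k in range(3)]
    inv = pose.inverse()
    identity_pose = pose.rotation_angle_deg() < 1e-12 and \
        np.allclose(pose.translation, 0.0)
    if identity_pose:
        # canonical fast path: labels are separable in (x, z) columns
        X, Z = np.meshgrid(axes[0], axes[2], indexing="ij")
        inside = model.contains(X.ravel(), Z.ravel()).reshape(X.shape)
        f = model.anterior_y(X, Z)
        pb = model.posterior_y(X, Z)
        d2b = model.boundary_distance(X.ravel(), Z.ravel()).reshape(X.shape)
        labels = np.zeros(tuple(shape), dtype=np.uint8)
        Y = axes[1][None, :, None]
        ins = inside[:, None, :]
        fb = f[:, None, :]
        pbb = pb[:, None, :]
        db = d2b[:, None, :]
        bone = ins & (Y >= pbb - s.cortex_mm) & (Y <= fb)
        soft = ins & (Y > fb) & (Y <= fb + s.stt_base_mm)
        cort = bone & ((Y <= pbb) | (Y >= fb - s.cortex_mm) | (db <= s.cortex_mm))
        labels[soft] = LABELS["soft_tissue"]
        labels[bone & ~cort] = LABELS["cancellous"]
        labels[cort] = LABELS["cortical"]
    else:
        P = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        labels = model.labels_at(inv.apply(P)).reshape(tuple(shape))
    hu = np.full(tuple(shape), -1000.0, dtype=np.float32)
    for tissue, mean, sd, lo_t, hi_t in (
            ("soft_tissue", s.hu_soft_mean, s.hu_soft_sd, -300.0, 300.0),
            ("cortical", s.hu_cortical_mean, s.hu_cortical_sd, 100.0, 1200.0),
            ("cancellous", s.hu_cancellous_mean, s.hu_cancellous_sd, -200.0, 500.0)):
        m = labels == LABELS[tissue]
        n = int(m.sum())
        if n and sd > 0:
            a, b = (lo_t - mean) / sd, (hi_t - mean) / sd
            hu[m] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                  random_state=hu_rng)
        elif n:
            hu[m] = mean
    return LabeledVolume(hu=hu, labels=labels, spacing=np.full(3, h), origin=lo)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0,
                     with_volume: bool = True,
                     subject_id: str = "phantom") -> Phantom:
    """Generate a phantom in the canonical frame with analytic ground truth.

    Same ``(spec, seed)`` always yields bit-identical output.  The truth
    fields are evaluated from the closed-form model, never from the meshes.
    """
    spec.validate()
    model = _AnalyticModel(spec)
    pts2, faces = _triangulate_footprint(model, spec.mesh_mm)
    f = model.anterior_y(pts2[:, 0], pts2[:, 1])
    anterior = _lift(pts2, f, faces)
    posterior = _lift(pts2, model.posterior_y(pts2[:, 0], pts2[:, 1]), faces)
    skin = _lift(pts2, f + spec.stt_base_mm, faces)
    surfaces = TissueSurfaceSet(skin=skin, anterior_cortex_front=anterior,
                                posterior_cortex_front=posterior,
                                frame_id="aligned")
    tfield, sfield, stfield = _truth_fields(model)
    t_sl, w_sl, t_il, w_il = _row_extremes(tfield)
    truth = PhantomGroundTruth(
        thickness_field=tfield, slope_field=sfield, stt_field=stfield,
        notch_xz=(0.0, 0.0), applied_transform=RigidTransform.identity(),
        covariates=None,
        true_scalars={"height": spec.height_mm, "t_sl": float(t_sl),
                      "t_il": float(t_il), "w_sl": float(w_sl),
                      "w_il": float(w_il), "mean_stt": spec.stt_base_mm,
                      "notch_y": float(model.anterior_y(np.array([0.0]),
                                                        np.array([0.0]))[0])})
    volume = None
    if with_volume:
        volume = _rasterize(model, RigidTransform.identity(),
                            np.random.default_rng(seed))
    return Phantom(spec=spec, seed=seed, surfaces=surfaces, truth=truth,
                   volume=volume, subject_id=subject_id)


def apply_rigid(phantom: Phantom, rotation_deg: tuple[float, float, float],
                translation_mm: tuple[float, float, float]) -> Phantom:
    """Apply a proper rigid transform to a phantom.

    Surfaces are transformed exactly; the labeled volume is re-rasterized in
    the new frame by pulling voxel centres back through the inverse
    transform into the analytic model (same HU noise stream).  The ground
    truth keeps its canonical-frame fields and records the composed
    transform.
    """
    angles = np.asarray(rotation_deg, dtype=float)
    trans = np.asarray(translation_mm, dtype=float)
    if not (np.isfinite(angles).all() and np.isfinite(trans).all()):
        raise ParameterError("rotation/translation must be finite")
    tf = RigidTransform.from_euler_deg(tuple(angles), tuple(trans))
    surfaces = phantom.surfaces.transformed(tf, frame_id="raw")
    total = tf.compose(phantom.truth.applied_transform)
    truth = replace(phantom.truth, applied_transform=total)
    volume = None
    if phantom.volume is not None:
        model = _AnalyticModel(phantom.spec)
        volume = _rasterize(model, total, np.random.default_rng(phantom.seed))
    return Phantom(spec=phantom.spec, seed=phantom.seed, surfaces=surfaces,
                   truth=truth, volume=volume, subject_id=phantom.subject_id)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _subseed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + 7919 * k + 1) % 2_147_483_647)


def sample_cohort_table(n: int, population: PopulationParams = PopulationParams(),
                        seed: int = 0) -> pd.DataFrame:
    """Draw covariates and linear-model morphometric scalars for ``n`` subjects.

    Sex is balanced, body height normal, BMI lognormal (right-skewed around
    the population median).  The returned scalars are exactly linear in the
    covariates plus independent Gaussian residuals — they are the cohort's
    ground truth, suitable for regression-recovery checks — and are *not*
    clipped; geometric realisation clips separately where physical bounds
    require it.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    population.validate()
    p = population
    rng = np.random.default_rng(seed)
    male = np.zeros(n, dtype=int)
    male[:(n + 1) // 2] = 1
    rng.shuffle(male)
    height_cm = rng.normal(p.mean_body_height_cm, p.sd_body_height_cm, size=n)
    bmi = np.exp(rng.normal(np.log(p.median_bmi), p.bmi_log_sd, size=n))
    hc = height_cm - p.mean_body_height_cm
    bc = bmi - p.median_bmi
    e = {k: rng.normal(0.0, getattr(p, "resid_" + k), size=n)
         for k in ("height", "t_sl", "t_il", "w_sl", "w_il", "stt", "cancellous")}
    df = pd.DataFrame({
        "subject_id": [f"S{k + 1:03d}" for k in range(n)],
        "sex": np.where(male == 1, "M", "F"),
        "male": male,
        "body_height_cm": height_cm,
        "bmi": bmi,
        "height": p.baseline_height + e["height"],
        "t_sl": (p.baseline_t_sl + p.beta_sex_thickness_sl * male
                 + p.beta_height_thickness_sl * hc + e["t_sl"]),
        "t_il": p.baseline_t_il + p.beta_sex_thickness_il * male + e["t_il"],
        "w_sl": p.baseline_w_sl + p.beta_height_width_sl * hc + e["w_sl"],
        "w_il": p.baseline_w_il + p.beta_sex_width_il * male + e["w_il"],
        "stt": p.baseline_stt + p.beta_bmi_stt * bc + e["stt"],
        "cortical_hu": rng.normal(p.cortical_hu_mean, p.cortical_hu_sd, size=n),
        "cancellous_hu": (p.baseline_cancellous
                          + p.beta_sex_cancellous * male + e["cancellous"]),
    })
    return df


def _spec_from_scalars(row: pd.Series, base: PhantomSpec) -> PhantomSpec:
    """Invert the analytic model approximately: choose spec parameters whose
    realised t_SL / t_IL / widths track the subject's true scalars."""
    height = float(np.clip(row["height"], 35.0, 80.0))
    probe = replace(base, height_mm=height)
    model = _AnalyticModel(probe)
    t_il = float(np.clip(row["t_il"], 2 * base.cortex_mm + 1.0, 25.0))
    t_sl = float(np.clip(row["t_sl"], t_il + 0.2, 30.0))
    # t_IL tracks the inferior rows (no tilt rise, median lateral falloff),
    # t_SL the protuberance rows; 0.45 is the protuberance's approximate
    # contribution to a row median.
    # constants calibrated once against the realised truth fields of the
    # default geometry: t_IL tracks base - 2.28 (gradient + lateral falloff
    # at the inferior rows), and each mm of protuberance amplitude adds
    # ~0.87 mm to t_SL - t_IL beyond the gradient's 3.22 mm.
    base_t = t_il + 2.28
    amp = float(np.clip((t_sl - t_il - 3.22) / 0.87, 1.0, 8.0))
    w_il = float(np.clip(row["w_il"], 25.0, 90.0))
    w_sl = float(np.clip(row["w_sl"], 25.0, 90.0))
    dz = base.protuberance_offset_z_mm
    frac = dz / height
    w_sup = (w_sl - w_il * frac) / (1.0 - frac)
    w_sup = float(np.clip(w_sup, 25.0, 90.0))
    stt = float(np.clip(row["stt"], 1.0, 60.0))
    return replace(base, height_mm=height, width_sup_mm=w_sup,
                   width_inf_mm=w_il, base_thickness_mm=base_t,
                   protuberance_amp_mm=amp, stt_base_mm=stt,
                   hu_cortical_mean=float(np.clip(row["cortical_hu"], 150, 600)),
                   hu_cancellous_mean=float(np.clip(row["cancellous_hu"],
                                                    -150, 400)))


def sample_cohort(n: int, population: PopulationParams = PopulationParams(),
                  seed: int = 0, base_spec: PhantomSpec = PhantomSpec(),
                  with_volume: bool = False, misorient: bool = True,
                  rot_max_deg: float = 30.0, trans_max_mm: float = 20.0
                  ) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate ``n`` phantoms with covariate-driven morphometry.

    Subject ``k`` uses a deterministically derived sub-seed of ``seed``.
    When ``misorient`` is set, each phantom is put in a random rigid pose
    (rotations uniform within +/- ``rot_max_deg`` per axis) recorded in its
    ground truth, so that orientation recovery can be scored.
    """
    table = sample_cohort_table(n, population, seed)
    phantoms: list[Phantom] = []
    for k, row in table.iterrows():
        sub = _subseed(seed, int(k))
        spec = _spec_from_scalars(row, base_spec)
        ph = generate_phantom(spec, seed=sub, with_volume=with_volume,
                              subject_id=str(row["subject_id"]))
        ph.truth.covariates = {"sex": str(row["sex"]),
                               "body_height_cm": float(row["body_height_cm"]),
                               "bmi": float(row["bmi"])}
        ph.truth.true_scalars = {"height": float(row["height"]),
                                 "t_sl": float(row["t_sl"]),
                                 "t_il": float(row["t_il"]),
                                 "w_sl": float(row["w_sl"]),
                                 "w_il": float(row["w_il"]),
                                 "mean_stt": float(row["stt"])}
        if misorient:
            rng = np.random.default_rng(sub + 1)
            ang = rng.uniform(-rot_max_deg, rot_max_deg, size=3)
            tr = rng.uniform(-trans_max_mm, trans_max_mm, size=3)
            ph = apply_rigid(ph, tuple(ang), tuple(tr))
        phantoms.append(ph)
    return phantoms, table
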