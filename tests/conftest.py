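"""Shared fixtures: phantoms and hand-constructed surface sets."""
from __future__ import annotations

import numpy as np
import pytest
import trimesh

from msbmap.io import TissueSurfaceSet
from msbmap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom with labeled volume (seed 1)."""
    return generate_phantom(PhantomSpec(), seed=1, with_volume=True)


@pytest.fixture(scope="session")
def default_phantom_nv():
    """Default phantom, surfaces only (seed 1)."""
    return generate_phantom(PhantomSpec(), seed=1, with_volume=False)


@pytest.fixture(scope="session")
def flat_phantom():
    """Slab phantom: no protuberances, no face curvature, 10 mm thick."""
    spec = PhantomSpec(base_thickness_mm=10.0, protuberance_amp_mm=0.0,
                       face_curvature_deg=0.0)
    return generate_phantom(spec, seed=0, with_volume=False)


def make_sheet(fn, x_range=(-25.0, 25.0), z_range=(-50.0, 0.0),
               spacing=1.0) -> trimesh.Trimesh:
    """Height-field sheet y = fn(x, z) triangulated on a regular grid."""
    xs = np.arange(x_range[0], x_range[1] + spacing / 2, spacing)
    zs = np.arange(z_range[0], z_range[1] + spacing / 2, spacing)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = np.broadcast_to(fn(X, Z), X.shape)
    nx, nz = X.shape
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(nz - 1):
            a = i * nz + j
            b = (i + 1) * nz + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)


def make_plate_set(thickness=10.0, stt=14.4, anterior_fn=None,
                   x_range=(-25.0, 25.0), z_range=(-50.0, 0.0),
                   spacing=1.0) -> TissueSurfaceSet:
    """Flat posterior plate at y=0 with an anterior face (default: constant
    ``thickness``) and a skin sheet offset by ``stt``."""
    if anterior_fn is None:
        def anterior_fn(x, z):
            return np.full_like(np.asarray(x, dtype=float), thickness)
    post = make_sheet(lambda x, z: np.zeros_like(np.asarray(x, dtype=float)),
                      x_range, z_range, spacing)
    ant = make_sheet(anterior_fn, x_range, z_range, spacing)
    skin = make_sheet(lambda x, z: anterior_fn(x, z) + stt,
                      x_range, z_range, spacing)
    return TissueSurfaceSet(skin=skin, anterior_cortex_front=ant,
                            posterior_cortex_front=post, frame_id="aligned")
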