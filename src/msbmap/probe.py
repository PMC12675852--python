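"""Independent voxel-marching thickness probe.

Walks anterior-to-posterior through a labeled voxel volume, column by
column, reading the unicortical thickness straight off the label lattice:
from the first cortical voxel encountered (the anterior margin of the
anterior cortex) to the first cortical voxel that follows a cancellous run
(the anterior margin of the posterior cortex).  It shares no code with the
mesh ray-casting path in :mod:`msbmap.mapping`, so the two can validate
each other on phantoms.
"""
from __future__ import annotations

import numpy as np

from .io import LABELS, LabeledVolume
from .mapping import GridMap

__all__ = ["probe_thickness_map"]


def probe_thickness_map(volume: LabeledVolume, spacing: float = 1.0) -> GridMap:
    """Brute-force unicortical thickness on the frontal grid.

    Columns without a cancellous run (e.g. the all-cortical lateral shell)
    are absent.  Expect agreement with the surface-based map within about
    two voxel spacings.
    """
    lab = volume.labels
    cort = LABELS["cortical"]
    canc = LABELS["cancellous"]
    h = volume.spacing
    x0 = np.floor(volume.origin[0] / spacing) * spacing
    z0 = np.floor(volume.origin[2] / spacing) * spacing
    nx = int(np.ceil((volume.origin[0] + lab.shape[0] * h[0] - x0) / spacing)) + 1
    nz = int(np.ceil((volume.origin[2] + lab.shape[2] * h[2] - z0) / spacing)) + 1
    values = np.zeros((nx, nz))
    present = np.zeros((nx, nz), dtype=bool)
    for i in range(nx):
        vx = int(round((x0 + (i + 0.5) * spacing - volume.origin[0]) / h[0]))
        if not (0 <= vx < lab.shape[0]):
            continue
        for j in range(nz):
            vz = int(round((z0 + (j + 0.5) * spacing - volume.origin[2]) / h[2]))
            if not (0 <= vz < lab.shape[2]):
                continue
            col = lab[vx, :, vz]
            y_front = y_back = None
            seen_cancellous = False
            for k in range(col.shape[0] - 1, -1, -1):  # march from anterior
                v = col[k]
                if v == cort and y_front is None:
                    y_front = volume.origin[1] + k * h[1]
                elif v == canc and y_front is not None:
                    seen_cancellous = True
                elif v == cort and seen_cancellous:
                    y_back = volume.origin[1] + k * h[1]
                    break
            if y_front is not None and y_back is not None:
                values[i, j] = y_front - y_back
                present[i, j] = True
    return GridMap(values=values, present=present, origin_xz=(float(x0), float(z0)),
                   spacing=spacing, kind="thickness")
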