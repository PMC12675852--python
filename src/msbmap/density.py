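"""Bone density extraction and Norton & Gamble classification.

Bone quality is summarised per tissue compartment by the median Hounsfield
unit over the segmented voxels and graded on HU thresholds: class 1 above
850 HU, class 2-3 from 500 to 850 HU, class 4 from 0 up to (but excluding)
500 HU, and the "additional type 4" failure zone below 0 HU, where the
negative attenuation indicates considerable surface contact with fat
marrow and a poor implant prognosis.  The endpoint conventions are
[500, 850] -> 2-3 and [0, 500) -> 4, preserving "< 0 HU" as the sole
criterion for the failure zone.

The Lekholm & Zarb grade is a visual classification; it is carried through
as an annotation and never computed.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import InputError, LabeledVolume

__all__ = ["DensityRecord", "NG_CLASSES", "median_hu", "classify_ng",
           "classify_cohort"]

NG_CLASSES = ("1", "2-3", "4", "4-additional")


@dataclass
class DensityRecord:
    """Median HU of the two bone compartments plus their classifications."""

    subject_id: str
    cortical_median_hu: float
    cancellous_median_hu: float
    ng_class: str = ""
    lz_class: str = ""   # visual grade, annotation only

    def __post_init__(self) -> None:
        computed = classify_ng(self.cancellous_median_hu)
        if not self.ng_class:
            self.ng_class = computed
        elif self.ng_class != computed:
            raise InputError(
                f"{self.subject_id}: ng_class '{self.ng_class}' inconsistent "
                f"with cancellous median {self.cancellous_median_hu} HU "
                f"(expected '{computed}')")


def median_hu(volume: LabeledVolume, tissue: str) -> float:
    """Exact median HU over the voxels carrying the given tissue label."""
    mask = volume.mask(tissue)
    if not mask.any():
        raise InputError(f"no voxels labelled '{tissue}'")
    return float(np.median(volume.hu[mask]))


def classify_ng(hu: float) -> str:
    """Norton & Gamble bone-type class of a median HU value."""
    hu = float(hu)
    if not np.isfinite(hu):
        raise InputError("HU value must be finite")
    if hu > 850:
        return "1"
    if hu >= 500:
        return "2-3"
    if hu >= 0:
        return "4"
    return "4-additional"


def classify_cohort(records: list[DensityRecord]) -> dict[str, int]:
    """Tally of Norton & Gamble classes over the cancellous medians."""
    if not records:
        raise InputError("need at least one record")
    counts = Counter(classify_ng(r.cancellous_median_hu) for r in records)
    return {c: counts.get(c, 0) for c in NG_CLASSES}
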