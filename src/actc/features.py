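"""Per-object feature measurement.

Four measurements drive classification: the standard deviation of the CK-PE
signal over the object mask (texture of the cytokeratin stain), the peak DAPI
and CD45 intensities near the object (nuclear content and leukocyte marker),
and the object size.  Sizes are carried both in pixels and in µm² via the
fixed pixel area, together with the equivalent-circle diameter used by the
micro-particle definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ChannelStack, SegmentedObject

FEATURE_NAMES = ("ck_std", "dapi_peak", "cd45_peak", "size_px", "size_um2", "eq_diameter_um")


@dataclass(frozen=True)
class FeatureVector:
    """The measurements the classifier consumes, all nonnegative.

    ``size_um2 = size_px * pixel_area_um2`` exactly, and
    ``eq_diameter_um = 2 * sqrt(size_um2 / pi)``.
    """

    ck_std: float
    dapi_peak: float
    cd45_peak: float
    size_px: int
    size_um2: float
    eq_diameter_um: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def feature_vector_from_size(
    ck_std: float, dapi_peak: float, cd45_peak: float, size_px: int,
    pixel_area_um2: float,
) -> FeatureVector:
    """Build a vector with the derived size fields filled in consistently."""
    size_um2 = size_px * pixel_area_um2
    return FeatureVector(
        ck_std=float(ck_std),
        dapi_peak=float(dapi_peak),
        cd45_peak=float(cd45_peak),
        size_px=int(size_px),
        size_um2=size_um2,
        eq_diameter_um=2.0 * math.sqrt(size_um2 / math.pi),
    )


def _dilated(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    selem = yy * yy + xx * xx <= radius * radius
    return ndimage.binary_dilation(mask, structure=selem)


def measure_features(
    obj: SegmentedObject, stack: ChannelStack, peak_dilation_px: int = 2
) -> FeatureVector:
    """Measure the classifier features for one segmented object.

    ``ck_std`` is the population (divide-by-N) standard deviation of CK-PE
    over the object mask.  ``dapi_peak`` and ``cd45_peak`` are maxima over the
    measurement mask — the object mask dilated by ``peak_dilation_px`` pixels
    (nuclei and CD45 staining can extend past the cytokeratin boundary;
    radius 0 restricts to the strict CK mask).  The dilated mask is clipped at
    tile edges.
    """
    if obj.size_px == 0 or not obj.mask.any():
        raise ValueError("cannot measure features on an empty mask")
    h, w = stack.tile_shape
    r0, c0, r1, c1 = obj.bbox
    pad = peak_dilation_px
    er0, ec0 = max(r0 - pad, 0), max(c0 - pad, 0)
    er1, ec1 = min(r1 + pad, h), min(c1 + pad, w)
    wide = np.zeros((er1 - er0, ec1 - ec0), dtype=bool)
    wide[r0 - er0 : r0 - er0 + obj.mask.shape[0],
         c0 - ec0 : c0 - ec0 + obj.mask.shape[1]] = obj.mask
    meas = _dilated(wide, pad)

    ck = stack.channel("ck")[obj.tile, r0:r1, c0:c1].astype(float)
    dapi = stack.channel("dapi")[obj.tile, er0:er1, ec0:ec1]
    cd45 = stack.channel("cd45")[obj.tile, er0:er1, ec0:ec1]

    return feature_vector_from_size(
        ck_std=float(np.std(ck[obj.mask])),  # population convention
        dapi_peak=float(dapi[meas].max()),
        cd45_peak=float(cd45[meas].max()),
        size_px=obj.size_px,
        pixel_area_um2=stack.pixel_area_um2,
    )


def measure_sample(
    stack: ChannelStack,
    objects: list[SegmentedObject],
    peak_dilation_px: int = 2,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Feature table for a sample: one row per object."""
    rows = []
    for i, obj in enumerate(objects):
        fv = measure_features(obj, stack, peak_dilation_px=peak_dilation_px)
        row = {"object_id": i, "tile": obj.tile,
               "y": obj.centroid[0], "x": obj.centroid[1], **fv.as_dict()}
        if sample_id is not None:
            row = {"sample_id": sample_id, **row}
        rows.append(row)
    cols = (["sample_id"] if sample_id is not None else []) + [
        "object_id", "tile", "y", "x", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)
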