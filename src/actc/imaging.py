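"""Image loading, imaging-area detection and CK-PE object segmentation.

A sample arrives as a stack of four-channel fluorescence tiles recorded from
an EpCAM-enrichment cartridge.  The channels are: a FITC control channel
(auto-fluorescent debris and the cartridge border), cytokeratin-PE (the
positive identification stain used for segmentation), DNA-DAPI and CD45-APC.
Candidate objects are the 8-connected components of the CK-PE channel above a
per-sample histogram threshold (triangle method), restricted to the true
imaging area detected from the FITC channel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger("actc")

#: canonical channel order used on disk and in memory
CHANNELS = ("fitc", "ck", "dapi", "cd45")

#: pixel area of the imaging system, µm² per pixel (back-computed from the
#: printed 500 px == 224 µm² size-bound pair)
DEFAULT_PIXEL_AREA_UM2 = 0.448

DEFAULT_CHANNEL_ROLES = {name: i for i, name in enumerate(CHANNELS)}


class FormatError(ValueError):
    """Raised when an image archive does not have the expected layout."""


@dataclass
class ChannelStack:
    """One sample's tiles as a ``(n_tiles, 4, H, W)`` intensity array.

    Parameters
    ----------
    tiles
        Integer intensity array, one 4-layer raster per tile.
    channel_roles
        Mapping from channel role (``fitc``, ``ck``, ``dapi``, ``cd45``) to
        layer index.
    bit_depth
        Bits per pixel; intensities are "counts" in ``[0, 2**bit_depth - 1]``.
    pixel_area_um2
        Physical area of one pixel.
    """

    tiles: np.ndarray
    channel_roles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )
    bit_depth: int = 8
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles)
        if self.tiles.ndim != 4:
            raise FormatError(
                f"expected (n_tiles, 4, H, W) array, got shape {self.tiles.shape}"
            )
        if self.tiles.shape[1] != 4:
            raise FormatError(
                f"expected 4 layers per tile, got {self.tiles.shape[1]}"
            )
        if set(self.channel_roles) != set(CHANNELS):
            raise ValueError(f"channel_roles must map exactly {CHANNELS}")
        if len(set(self.channel_roles.values())) != 4:
            raise ValueError("each channel role must map to a distinct layer")

    @property
    def n_tiles(self) -> int:
        return self.tiles.shape[0]

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles.shape[2], self.tiles.shape[3]

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(n_tiles, H, W)`` array for one channel role."""
        return self.tiles[:, self.channel_roles[role]]


@dataclass
class ImagingArea:
    """Per-tile boolean masks of valid (non-border) pixels."""

    masks: np.ndarray  # (n_tiles, H, W) bool

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if not self.masks.any():
            raise ValueError("imaging area is empty")


@dataclass
class SegmentedObject:
    """One connected CK-PE component.

    ``mask`` is a boolean array the size of the bounding box; ``bbox`` is
    ``(row_start, col_start, row_stop, col_stop)`` in tile coordinates.
    """

    tile: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    size_px: int
    centroid: tuple[float, float]


# ---------------------------------------------------------------------------
# loading


def write_sample(stack: ChannelStack, path) -> None:
    """Write a stack as a multi-page TIFF, one page per channel per tile."""
    meta = {
        "channels": list(CHANNELS),
        "channel_roles": stack.channel_roles,
        "bit_depth": stack.bit_depth,
        "pixel_area_um2": stack.pixel_area_um2,
        "n_tiles": stack.n_tiles,
    }
    tifffile.imwrite(
        path, stack.tiles, photometric="minisblack", description=json.dumps(meta)
    )


def load_sample(path) -> ChannelStack:
    """Load a sample written by :func:`write_sample` (or any structurally
    compatible multi-page TIFF with 4 layers per tile).

    Raises
    ------
    FormatError
        If any tile does not have exactly four layers or tiles differ in
        shape.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 3:
        # flat page sequence: regroup into tiles of 4 layers
        if data.shape[0] % 4 != 0:
            raise FormatError(
                f"{path}: page count {data.shape[0]} is not a multiple of 4; "
                "tile 0 does not have 4 layers"
            )
        data = data.reshape(data.shape[0] // 4, 4, *data.shape[1:])
    if data.ndim != 4:
        raise FormatError(f"{path}: unexpected TIFF layout {data.shape}")
    if data.shape[1] != 4:
        raise FormatError(
            f"{path}: tiles have {data.shape[1]} layers, expected 4"
        )
    roles = meta.get("channel_roles", dict(DEFAULT_CHANNEL_ROLES))
    return ChannelStack(
        tiles=data,
        channel_roles={k: int(v) for k, v in roles.items()},
        bit_depth=int(meta.get("bit_depth", 8)),
        pixel_area_um2=float(meta.get("pixel_area_um2", DEFAULT_PIXEL_AREA_UM2)),
    )


# ---------------------------------------------------------------------------
# imaging-area detection


def _edge_band_width(profile: np.ndarray, interior: float, contrast: float) -> int:
    """Walk inward from index 0 while the mean-intensity profile stays below
    ``(1 - contrast) * interior``; return the number of border lines."""
    if interior <= 0:
        return 0
    limit = (1.0 - contrast) * interior
    width = 0
    cap = len(profile) // 2  # a border cannot cover half the tile
    while width < cap and profile[width] < limit:
        width += 1
    return width


def detect_imaging_area(
    stack: ChannelStack, contrast: float = 0.25
) -> ImagingArea:
    """Locate the true imaging area from the FITC (debris) channel.

    The cartridge border shows up as a band of depressed intensity along tile
    edges in the FITC channel.  For each tile and each of the four edges, the
    1-D mean-intensity profile is scanned inward from the edge; consecutive
    lines darker than ``(1 - contrast)`` times the tile-interior median are
    excluded.  If no edge shows a sufficient transition (including an all-zero
    FITC channel) the full tile is kept and a warning is logged.
    """
    fitc = stack.channel("fitc").astype(float)
    n, h, w = fitc.shape
    masks = np.ones((n, h, w), dtype=bool)
    any_border = False
    for t in range(n):
        img = fitc[t]
        interior = float(np.median(img[h // 4 : h - h // 4, w // 4 : w - w // 4]))
        if interior <= 0:
            continue
        rows = img.mean(axis=1)
        cols = img.mean(axis=0)
        top = _edge_band_width(rows, interior, contrast)
        bottom = _edge_band_width(rows[::-1], interior, contrast)
        left = _edge_band_width(cols, interior, contrast)
        right = _edge_band_width(cols[::-1], interior, contrast)
        if top:
            masks[t, :top, :] = False
        if bottom:
            masks[t, h - bottom :, :] = False
        if left:
            masks[t, :, :left] = False
        if right:
            masks[t, :, w - right :] = False
        if top or bottom or left or right:
            any_border = True
    if not any_border:
        logger.warning(
            "no cartridge border transition found in the FITC channel; "
            "using the full tile area"
        )
    return ImagingArea(masks=masks)


# ---------------------------------------------------------------------------
# triangle (Zack) threshold


def triangle_threshold(histogram: np.ndarray) -> int:
    """Per-sample histogram threshold by the triangle (Zack) construction.

    ``histogram[i]`` is the number of pixels with intensity ``i`` (one bin per
    integer intensity level, pooled over all tiles of the sample).  A line is
    drawn from the histogram peak to the last nonzero bin on the long-tail
    side; the threshold is the bin whose histogram point lies at maximal
    perpendicular distance from that line.  Ties are broken toward the lowest
    intensity, which keeps more candidate objects for the classifier to
    filter.

    Raises
    ------
    ValueError
        If the histogram is empty or has no nonzero bin.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size == 0 or not (h > 0).any():
        raise ValueError("histogram must contain at least one nonzero bin")
    nz = np.flatnonzero(h > 0)
    peak = int(np.argmax(h))  # argmax takes the lowest index on ties
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        return first
    # long-tail side: the nonzero extreme farther from the peak (ties -> right,
    # the bright tail in fluorescence imagery)
    tail = last if (last - peak) >= (peak - first) else first
    lo, hi = (peak, tail) if peak <= tail else (tail, peak)
    idx = np.arange(lo, hi + 1)
    # perpendicular distance from (i, h[i]) to the peak->tail chord
    dx, dy = tail - peak, h[tail] - h[peak]
    dist = np.abs(dx * (h[idx] - h[peak]) - dy * (idx - peak)) / np.hypot(dx, dy)
    return int(idx[np.argmax(dist)])  # argmax: lowest intensity on ties


def sample_histogram(stack: ChannelStack, role: str = "ck") -> np.ndarray:
    """Pooled integer-bin intensity histogram of one channel over all tiles."""
    data = stack.channel(role)
    return np.bincount(data.ravel().astype(np.int64), minlength=stack.max_count + 1)


# ---------------------------------------------------------------------------
# segmentation

_EIGHT = np.ones((3, 3), dtype=int)


def segment_objects(
    stack: ChannelStack, area: ImagingArea, threshold: float
) -> list[SegmentedObject]:
    """Segment candidate objects from the CK-PE channel.

    Returns one :class:`SegmentedObject` per 8-connected component of
    ``{CK-PE > threshold} ∩ imaging area``.  No minimum-size filter is applied
    here; size selection belongs to the classifier.
    """
    ck = stack.channel("ck")
    out: list[SegmentedObject] = []
    for t in range(stack.n_tiles):
        fg = (ck[t] > threshold) & area.masks[t]
        if not fg.any():
            continue
        labels, n = ndimage.label(fg, structure=_EIGHT)
        slices = ndimage.find_objects(labels)
        centroids = ndimage.center_of_mass(fg, labels, range(1, n + 1))
        for lab, (sl, com) in enumerate(zip(slices, centroids), start=1):
            mask = labels[sl] == lab
            out.append(
                SegmentedObject(
                    tile=t,
                    bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                    mask=mask,
                    size_px=int(mask.sum()),
                    centroid=(float(com[0]), float(com[1])),
                )
            )
    return out


def segment_sample(
    stack: ChannelStack, contrast: float = 0.25
) -> tuple[list[SegmentedObject], int, ImagingArea]:
    """Full per-sample segmentation: imaging area, pooled-histogram triangle
    threshold, connected components.  Returns (objects, threshold, area)."""
    area = detect_imaging_area(stack, contrast=contrast)
    thr = triangle_threshold(sample_histogram(stack, "ck"))
    return segment_objects(stack, area, thr), thr, area
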