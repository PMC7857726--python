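"""Image preprocessing applied before quantification.

Covers background subtraction (rolling-ball family, implemented as grayscale
opening with a flat disk element), binarization of molecule-count maps, and
sampling of band ROIs along segmented border lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import grey_opening

from .datatypes import BinaryMask, BorderRoi, MoleculeMap, RasterImage

__all__ = [
    "rolling_ball_subtract",
    "binarize_molecule_map",
    "sample_border_band",
    "disk_footprint",
]


def disk_footprint(radius: int) -> np.ndarray:
    """Flat disk: pixels whose center lies within ``radius`` of the origin."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx * xx + yy * yy) <= r * r


def rolling_ball_subtract(image: RasterImage, radius_px: int) -> RasterImage:
    """Subtract a slowly varying background estimated by grayscale opening.

    The background is the morphological opening of the image with a flat
    disk-shaped structuring element of the given pixel radius; features
    narrower than the element survive the subtraction, broad background is
    removed. Output is clipped at zero.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    h, w = image.shape
    if 2 * radius_px + 1 > max(h, w):
        raise ValueError(
            f"radius {radius_px} px exceeds the image extent {h}x{w}"
        )
    bg = grey_opening(image.pixels.astype(float),
                      footprint=disk_footprint(radius_px), mode="nearest")
    out = np.clip(image.pixels.astype(float) - bg, 0.0, None)
    return RasterImage(pixels=out, pixel_size_nm=image.pixel_size_nm,
                       channel=image.channel)


def binarize_molecule_map(mmap: MoleculeMap, min_count: int = 1) -> BinaryMask:
    """Mask of pixels holding at least ``min_count`` molecules."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return BinaryMask(bits=mmap.counts >= min_count)


def sample_border_band(image: RasterImage, roi: BorderRoi) -> pd.DataFrame:
    """Sample pixel values in a band of ``roi.width_px`` along the polyline.

    The polyline is walked in unit arc-length steps; at each step the band
    covers nearest pixels at signed perpendicular offsets spanning the width.
    Returns a DataFrame with columns ``arc_px``, ``arc_nm``, ``offset_px``,
    ``row``, ``col``, ``value``, ordered along the polyline.

    Raises ``ValueError`` naming the first vertex that leaves the image.
    """
    h, w = image.shape
    verts = roi.polyline
    for i, (x, y) in enumerate(verts):
        if not (0 <= x <= w and 0 <= y <= h):
            raise ValueError(
                f"polyline vertex {i} at ({x:.1f}, {y:.1f}) lies outside "
                f"the {h}x{w} image"
            )

    half = (roi.width_px - 1) // 2
    offsets = np.arange(-half, half + 1)
    records: list[tuple] = []
    arc0 = 0.0
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        seg_len = float(np.hypot(x1 - x0, y1 - y0))
        if seg_len == 0:
            continue
        tx, ty = (x1 - x0) / seg_len, (y1 - y0) / seg_len
        nx, ny = -ty, tx  # unit normal
        n_steps = int(np.floor(seg_len))
        for s in range(n_steps + 1):
            cx, cy = x0 + s * tx, y0 + s * ty
            for o in offsets:
                col = int(round(cx + o * nx - 0.5))
                row = int(round(cy + o * ny - 0.5))
                if 0 <= row < h and 0 <= col < w:
                    records.append((arc0 + s, o, row, col,
                                    float(image.pixels[row, col])))
        arc0 += seg_len
    df = pd.DataFrame(records,
                      columns=["arc_px", "offset_px", "row", "col", "value"])
    df.insert(1, "arc_nm", df["arc_px"] * image.pixel_size_nm)
    return df
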