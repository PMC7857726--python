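"""dSTORM puncta pipeline: cluster segmentation and per-punctum metrics.

Clusters are found on the binarized molecule map by a morphological closing
(disk element, default 17 px radius) followed by connected-component labeling
(default 8-connectivity); labels are then restricted to the originally-true
pixels, so closing only decides membership, never adds member pixels.
Clusters holding >= 10 molecules qualify as puncta and get molecule count,
convex-hull area, and density (count / hull area); the rest contribute to the
non-qualifying pixel tally. A manual exclusion list removes mis-merged puncta
from downstream statistics, mirroring curation of the hull overlays.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial import ConvexHull
from scipy.spatial import QhullError
from skimage.draw import polygon_perimeter
from skimage.measure import label as cc_label

from .datatypes import BinaryMask, MoleculeMap, PunctaRecord, PunctaTable, RasterImage
from .preprocess import disk_footprint

__all__ = [
    "segment_clusters",
    "measure_puncta",
    "apply_manual_filter",
    "puncta_summary",
    "hull_overlay",
]


def segment_clusters(
    mask: BinaryMask, closing_radius_px: int = 17, connectivity: int = 8
) -> np.ndarray:
    """Label clusters on the closed mask, restricted to original pixels.

    Returns an integer label map the shape of the mask: 0 for background,
    dense ids from 1 for cluster membership of each originally-true pixel.
    The closing is computed as on an infinite empty plane (the mask is
    embedded in a false frame wider than the element before dilate/erode).
    """
    if closing_radius_px < 0:
        raise ValueError("closing_radius_px must be non-negative")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    bits = mask.bits
    if closing_radius_px > 0:
        pad = closing_radius_px + 1
        fp = disk_footprint(closing_radius_px)
        padded = np.pad(bits, pad)
        closed = binary_erosion(binary_dilation(padded, structure=fp),
                                structure=fp)
        closed = closed[pad:-pad, pad:-pad]
    else:
        closed = bits
    labels = cc_label(closed, connectivity=1 if connectivity == 4 else 2)
    restricted = labels * bits
    # re-densify ids in case a closed component contained no original pixel
    # (cannot happen for a true closing, but keeps the contract explicit)
    ids = np.unique(restricted)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[restricted]


def measure_puncta(
    clusters: np.ndarray, mmap: MoleculeMap, min_molecules: int = 10
) -> PunctaTable:
    """Turn labeled clusters into a table of qualifying puncta.

    Molecule count sums the pre-binarization pixel values over the cluster;
    area is the convex hull of the pixel centers; density = count / area.
    Hulls of fewer than 3 or collinear pixels are degenerate: flagged, zero
    area, density undefined. Clusters under ``min_molecules`` contribute
    their pixels and molecules to the non-qualifying tallies.
    """
    clusters = np.asarray(clusters)
    if clusters.shape != mmap.shape:
        raise ValueError(
            f"cluster map shape {clusters.shape} != molecule map {mmap.shape}"
        )
    puncta: list[PunctaRecord] = []
    nq_pixels = 0
    nq_molecules = 0
    for cid in np.unique(clusters):
        if cid == 0:
            continue
        rows, cols = np.nonzero(clusters == cid)
        count = int(mmap.counts[rows, cols].sum())
        if count < min_molecules:
            nq_pixels += len(rows)
            nq_molecules += count
            continue
        area, degenerate = _hull_area(rows, cols)
        density = count / area if not degenerate else float("nan")
        puncta.append(PunctaRecord(
            id=int(cid), pixel_coords=np.column_stack([rows, cols]),
            molecule_count=count, hull_area_px2=area, density=density,
            degenerate=degenerate))
    return PunctaTable(puncta=puncta, non_qualifying_pixel_count=nq_pixels,
                       non_qualifying_molecule_count=nq_molecules,
                       pixel_size_nm=mmap.pixel_size_nm)


def _hull_area(rows: np.ndarray, cols: np.ndarray) -> tuple[float, bool]:
    if len(rows) < 3:
        return 0.0, True
    pts = np.column_stack([cols, rows]).astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear pixel centers
        return 0.0, True
    return float(hull.volume), False  # ConvexHull.volume is the 2D area


def apply_manual_filter(table: PunctaTable, exclude_ids) -> PunctaTable:
    """Mark puncta for exclusion from all downstream statistics."""
    exclude = set(int(i) for i in exclude_ids)
    known = {p.id for p in table.puncta}
    unknown = exclude - known
    if unknown:
        raise ValueError(f"unknown punctum ids: {sorted(unknown)}")
    return replace(table, excluded_ids=table.excluded_ids | exclude)


def puncta_summary(table: PunctaTable) -> pd.DataFrame:
    """Mean, s.d., s.e. and n of count / hull area / density over retained puncta.

    Density statistics exclude degenerate (zero-hull) records.
    """
    retained = table.retained
    if not retained:
        raise ValueError("no retained puncta to summarize")
    metrics = {
        "molecule_count": [p.molecule_count for p in retained],
        "hull_area_px2": [p.hull_area_px2 for p in retained],
        "density_per_px2": [p.density for p in retained if not p.degenerate],
    }
    rows = {}
    for name, vals in metrics.items():
        v = np.asarray(vals, dtype=float)
        n = len(v)
        mean = v.mean() if n else float("nan")
        sd = v.std(ddof=1) if n > 1 else (0.0 if n == 1 else float("nan"))
        rows[name] = {"mean": mean, "sd": sd,
                      "se": sd / np.sqrt(n) if n else float("nan"), "n": n}
    return pd.DataFrame(rows).T[["mean", "sd", "se", "n"]]


def hull_overlay(table: PunctaTable, shape: tuple[int, int]) -> RasterImage:
    """Raster with each retained punctum's hull outline drawn as its id.

    The overlay is the review artifact supporting the manual exclusion list.
    Degenerate puncta are drawn as their member pixels.
    """
    out = np.zeros(shape, dtype=np.int32)
    for p in table.retained:
        rows = p.pixel_coords[:, 0]
        cols = p.pixel_coords[:, 1]
        if rows.max() >= shape[0] or cols.max() >= shape[1]:
            raise ValueError(f"punctum {p.id} exceeds overlay shape {shape}")
        if p.degenerate:
            out[rows, cols] = p.id
            continue
        hull = ConvexHull(np.column_stack([cols, rows]).astype(float))
        verts = hull.points[hull.vertices]
        rr, cc = polygon_perimeter(verts[:, 1], verts[:, 0], shape=shape)
        out[rr, cc] = p.id
    return RasterImage(pixels=out, pixel_size_nm=table.pixel_size_nm,
                       channel="hull_overlay")
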