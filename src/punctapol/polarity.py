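"""Nematic polarity of junctional fluorescence.

Planar polarity of a junctional signal is 180-degree periodic (an axis, not a
direction), so per cell we form the intensity-weighted nematic vector

    Q = (q1, q2) = sum_j I_j (cos 2 theta_j, sin 2 theta_j) / sum_j I_j

over the cell's junction pixels, with theta_j the local junction tangent
angle. |Q| in [0, 1] is the cell's polarity magnitude and atan2(q2, q1) / 2
its axis. The tissue-level magnitude of average polarity Mp is the magnitude
of the unweighted mean of per-cell Q vectors; nematic vectors of cells
polarized along perpendicular axes cancel.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CellPolarity, TissuePolarity, TissueSegmentation

__all__ = ["junction_orientations", "cell_polarity", "tissue_polarity"]


def junction_orientations(label_map: np.ndarray,
                          half_window: int = 2) -> np.ndarray:
    """Estimate tangent angles of junction pixels from the label map.

    Junction pixels are those labeled 0. For each one, the principal
    direction of the junction pixels in the surrounding (2*half_window+1)^2
    neighborhood gives the tangent; angles lie in [0, pi). Returns an (n, 3)
    array of (row, col, theta). Isolated junction pixels (no junction
    neighbor in the window) are excluded.
    """
    label_map = np.asarray(label_map)
    jmask = label_map == 0
    rows, cols = np.nonzero(jmask)
    h, w = label_map.shape
    out = []
    for r, c in zip(rows, cols):
        r0, r1 = max(r - half_window, 0), min(r + half_window + 1, h)
        c0, c1 = max(c - half_window, 0), min(c + half_window + 1, w)
        rr, cc = np.nonzero(jmask[r0:r1, c0:c1])
        if len(rr) < 2:  # isolated pixel: no direction to estimate
            continue
        y = rr + r0 - r
        x = cc + c0 - c
        # principal axis of the centered neighborhood point set
        cxx = float((x * x).sum())
        cyy = float((y * y).sum())
        cxy = float((x * y).sum())
        theta = 0.5 * np.arctan2(2.0 * cxy, cxx - cyy) % np.pi
        out.append((r, c, theta))
    return np.asarray(out, dtype=float).reshape(-1, 3)


def cell_polarity(segmentation: TissueSegmentation,
                  intensity_image: np.ndarray | None = None,
                  min_junction_pixels: int = 8) -> list[CellPolarity]:
    """Per-cell intensity-weighted nematic vectors.

    Uses the segmentation's stored per-junction-pixel intensities unless an
    ``intensity_image`` is given, in which case intensities are re-sampled
    from it at the junction pixel positions. Cells with fewer than
    ``min_junction_pixels`` junction pixels or zero total junction intensity
    are skipped.
    """
    cells = []
    for cid in segmentation.cell_ids:
        jp = segmentation.junction_pixels[cid]
        if len(jp) < min_junction_pixels:
            continue
        theta = jp[:, 2]
        if intensity_image is not None:
            img = np.asarray(intensity_image)
            inten = img[jp[:, 0].astype(int), jp[:, 1].astype(int)]
        else:
            inten = jp[:, 3]
        total = inten.sum()
        if total <= 0:
            continue
        q1 = float((inten * np.cos(2.0 * theta)).sum() / total)
        q2 = float((inten * np.sin(2.0 * theta)).sum() / total)
        cells.append(CellPolarity(cell_id=cid, q1=q1, q2=q2))
    return cells


def tissue_polarity(cells: list[CellPolarity],
                    n_bins: int = 18) -> TissuePolarity:
    """Tissue magnitude of average polarity Mp and the mean axis.

    Mp is the magnitude of the mean per-cell nematic vector (vector average
    first, magnitude second); per-cell axes are binned into a circular
    histogram over [0, pi).
    """
    if not cells:
        raise ValueError("no valid cells")
    q = np.array([[c.q1, c.q2] for c in cells])
    mean_q = q.mean(axis=0)
    mp = float(np.hypot(*mean_q))
    mean_axis = float(np.arctan2(mean_q[1], mean_q[0]) / 2.0 % np.pi)
    axes = np.array([c.axis for c in cells])
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    hist, _ = np.histogram(axes, bins=edges)
    return TissuePolarity(mp=mp, mean_axis=mean_axis, n_cells=len(cells),
                          axis_histogram=hist, bin_edges=edges)
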