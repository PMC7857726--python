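"""Synthetic ground-truth generators for every input the pipeline consumes.

Each generator emulates one class of experimental input — rendered
localization-count maps of junctional puncta, planar point patterns, FRAP
recovery traces, polarized epithelial meshes, and two-channel border images —
with the generating parameters returned alongside so downstream estimators can
be validated against known truth. All randomness flows through a single seed
per call; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .datatypes import (
    BorderRoi,
    FrapTrace,
    MoleculeMap,
    PointPattern,
    RasterImage,
    TissueSegmentation,
)

__all__ = [
    "PunctaSimParams",
    "FrapSimParams",
    "make_puncta_map",
    "make_point_pattern",
    "make_frap_trace",
    "make_polarized_tissue",
    "make_border_channels",
    "make_cell_pair",
]


@dataclass
class PunctaSimParams:
    """Parameters of the junctional puncta generator.

    The wild-type regime is dense, regular puncta along a narrow junctional
    band: cluster centers are laid down sequentially along the border with
    near-constant spacing, each contributing a Poisson number of molecules
    spread isotropically around the center. All lengths in nm.
    """

    border_length_nm: float = 1500.0
    band_width_nm: float = 25.0  # s.d. of perpendicular center offset
    cluster_spacing_nm: float = 150.0
    spacing_jitter_nm: float = 20.0
    molecules_per_cluster_mean: float = 60.0
    cluster_sigma_nm: float = 20.0
    pixel_size_nm: float = 3.0
    background_rate: float = 0.0  # molecules per px^2, uniform
    poisson_molecules: bool = True  # False: exactly the mean per cluster
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("border_length_nm", "band_width_nm", "cluster_spacing_nm",
                     "cluster_sigma_nm", "pixel_size_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spacing_jitter_nm < 0:
            raise ValueError("spacing_jitter_nm must be non-negative")
        if self.molecules_per_cluster_mean < 0:
            raise ValueError("molecules_per_cluster_mean must be non-negative")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")


@dataclass
class FrapSimParams:
    """Parameters of the single-exponential FRAP recovery model.

    F(t) = F_bleach + M (F_pre - F_bleach)(1 - e^(-k t)) + noise for t after
    the bleach, preceded by ``n_pre`` pre-bleach frames at F_pre + noise.
    Defaults mirror a 30 s pre-bleach / 5 min recovery acquisition sampled
    every 10 s.
    """

    f_pre: float = 100.0
    f_bleach: float = 20.0
    mobile_fraction: float = 0.5
    rate_constant: float = 0.02  # 1/s
    noise_sd: float = 0.0
    n_pre: int = 3
    frame_interval_s: float = 10.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.f_bleach >= self.f_pre:
            raise ValueError("f_bleach must be below f_pre")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.noise_sd < 0 or self.rate_constant < 0:
            raise ValueError("noise_sd and rate_constant must be non-negative")


@dataclass
class PunctaGroundTruth:
    """What the puncta generator actually drew."""

    centers_nm: np.ndarray  # (k, 2) cluster centers, (x, y)
    molecules_per_cluster: np.ndarray  # (k,) rasterized molecule counts
    n_background: int
    profile: str


# profile multipliers relative to the wild-type defaults: the mutant spreads
# centers over a ~4x broader band with ~0.4x the molecules per cluster
_PROFILE_SCALE = {
    "wt": (1.0, 1.0),
    "crsh": (4.0, 0.4),
}


def make_puncta_map(
    params: PunctaSimParams, profile: str = "wt"
) -> tuple[MoleculeMap, PunctaGroundTruth]:
    """Render a molecule-count map of puncta along one cell border.

    ``profile`` selects the regime: ``wt`` (dense, narrow, evenly spaced
    clusters), ``crsh`` (band width x4, molecules per cluster x0.4), or
    ``csr`` (the same expected molecule total placed uniformly at random).
    Returns the map and the generating ground truth.
    """
    if profile not in ("wt", "crsh", "csr"):
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_nm

    if profile == "csr":
        band_w, mol_scale = 1.0, 1.0
    else:
        band_w, mol_scale = _PROFILE_SCALE[profile]
    band_sd = params.band_width_nm * band_w
    mol_mean = params.molecules_per_cluster_mean * mol_scale

    width_px = int(np.ceil(params.border_length_nm / px))
    half_h_nm = 3.0 * band_sd + 4.0 * params.cluster_sigma_nm + 10.0
    height_px = 2 * int(np.ceil(half_h_nm / px)) + 1
    if width_px <= 0 or height_px <= 0:
        raise ValueError("non-positive raster dimensions")
    y_mid = (height_px // 2 + 0.5) * px

    if profile == "csr":
        expected_clusters = params.border_length_nm / params.cluster_spacing_nm
        n_mol = int(rng.poisson(expected_clusters * mol_mean))
        xy = np.column_stack([
            rng.uniform(0, width_px * px, n_mol),
            rng.uniform(0, height_px * px, n_mol),
        ])
        centers = np.empty((0, 2))
        per_cluster = np.zeros(0, dtype=int)
        mol_xy = xy
    else:
        # sequential spacing draws, truncated positive, reproduce the
        # evenly-spaced phenotype
        xs = []
        pos = _trunc_normal(rng, params.cluster_spacing_nm / 2.0,
                            params.spacing_jitter_nm)
        while pos < params.border_length_nm:
            xs.append(pos)
            pos += _trunc_normal(rng, params.cluster_spacing_nm,
                                 params.spacing_jitter_nm)
        ys = y_mid + rng.normal(0.0, band_sd, len(xs))
        centers = np.column_stack([xs, ys]) if xs else np.empty((0, 2))
        if params.poisson_molecules:
            per_cluster = rng.poisson(mol_mean, len(xs)).astype(int)
        else:
            per_cluster = np.full(len(xs), int(round(mol_mean)), dtype=int)
        offs = []
        for (cx, cy), k in zip(centers, per_cluster):
            offs.append(
                np.column_stack([cx + rng.normal(0, params.cluster_sigma_nm, k),
                                 cy + rng.normal(0, params.cluster_sigma_nm, k)])
            )
        mol_xy = np.concatenate(offs) if offs else np.empty((0, 2))

    n_bg = int(rng.poisson(params.background_rate * width_px * height_px))
    if n_bg:
        bg = np.column_stack([rng.uniform(0, width_px * px, n_bg),
                              rng.uniform(0, height_px * px, n_bg)])
        mol_xy = np.concatenate([mol_xy, bg]) if len(mol_xy) else bg

    counts = np.zeros((height_px, width_px), dtype=np.int64)
    if len(mol_xy):
        cols = np.clip((mol_xy[:, 0] / px).astype(int), 0, width_px - 1)
        rows = np.clip((mol_xy[:, 1] / px).astype(int), 0, height_px - 1)
        np.add.at(counts, (rows, cols), 1)

    truth = PunctaGroundTruth(centers_nm=centers,
                              molecules_per_cluster=per_cluster,
                              n_background=n_bg, profile=profile)
    return MoleculeMap(counts=counts, pixel_size_nm=px), truth


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw Normal(mean, sd) truncated to positive values by resampling."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("truncated normal failed to produce a positive draw")


def make_point_pattern(
    n: int,
    window: tuple[float, float, float, float],
    mode: str = "csr",
    cluster_params: dict[str, Any] | None = None,
    seed: int = 0,
) -> tuple[PointPattern, dict[str, Any]]:
    """Simulate a point pattern in a rectangular window.

    ``csr`` places exactly ``n`` independent uniform points. ``thomas`` draws
    a Thomas cluster process: ``n`` uniform parents, Poisson(``mu``) offspring
    each, displaced by an isotropic Gaussian of s.d. ``sigma``; offspring
    landing outside the window are thinned. Ground truth (parents, offspring
    assignment) is returned for the clustered mode.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    x0, x1, y0, y1 = window
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate window")
    rng = np.random.default_rng(seed)

    if mode == "csr":
        pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
        return PointPattern(points=pts, window=window), {"mode": "csr"}
    if mode != "thomas":
        raise ValueError(f"unknown mode {mode!r}")

    cp = {"mu": 10.0, "sigma": 10.0, **(cluster_params or {})}
    parents = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    pts, parent_of = [], []
    for i, (px_, py_) in enumerate(parents):
        k = rng.poisson(cp["mu"])
        off = np.column_stack([px_ + rng.normal(0, cp["sigma"], k),
                               py_ + rng.normal(0, cp["sigma"], k)])
        keep = ((off[:, 0] >= x0) & (off[:, 0] <= x1)
                & (off[:, 1] >= y0) & (off[:, 1] <= y1))
        pts.append(off[keep])
        parent_of.extend([i] * int(keep.sum()))
    points = np.concatenate(pts) if pts else np.empty((0, 2))
    truth = {"mode": "thomas", "parents": parents,
             "parent_of": np.asarray(parent_of, dtype=int), **cp}
    return PointPattern(points=points, window=window), truth


def make_frap_trace(params: FrapSimParams) -> FrapTrace:
    """Simulate one FRAP trace under the single-exponential recovery model."""
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_s
    n_post = int(round(params.duration_s / dt)) + 1
    t_pre = np.arange(params.n_pre) * dt
    t_post = t_pre[-1] + dt + np.arange(n_post) * dt
    rec = np.arange(n_post) * dt  # time since bleach; frame 0 holds F_bleach
    amp = params.mobile_fraction * (params.f_pre - params.f_bleach)
    f_post = params.f_bleach + amp * (1.0 - np.exp(-params.rate_constant * rec))
    intens = np.concatenate([np.full(params.n_pre, params.f_pre), f_post])
    if params.noise_sd > 0:
        intens = intens + rng.normal(0.0, params.noise_sd, len(intens))
    return FrapTrace(times_s=np.concatenate([t_pre, t_post]),
                     intensities=intens,
                     bleach_index=params.n_pre, n_pre=params.n_pre)


def make_polarized_tissue(
    n_cells: int,
    polarity_amplitude: float,
    axis_angle: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    axis_noise_sd: float = 0.0,
    mesh_jitter: float = 0.15,
    cell_diameter_px: int = 24,
    base_intensity: float = 100.0,
) -> tuple[TissueSegmentation, RasterImage, dict[str, Any]]:
    """Build a hexagonal epithelium whose junction intensity is polarized.

    Cells are the Voronoi regions of a (jittered) hexagonal lattice of seeds.
    Each shared cell edge is sampled at unit arc-length steps, so a cell's
    junction samples weight every edge by its length regardless of its
    orientation relative to the pixel grid; each sample carries the tangent
    angle of the edge (exact by construction) and intensity
    I = I0 (1 + p cos 2(theta - theta0 - eps)) + noise, clipped at zero,
    where eps is per-edge polarity-axis jitter of s.d. ``axis_noise_sd``
    (radians) decoupling the intensity pattern from the local geometry and
    degrading the tissue order parameter. Only cells
    fully interior to the image contribute junction samples, so every
    reported cell has a complete boundary. Returns the segmentation, a
    rendered intensity image, and the generating truth.
    """
    p = polarity_amplitude
    if not 0.0 <= p <= 1.0:
        raise ValueError("polarity amplitude must lie in [0, 1]")
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)

    # lay a hex lattice with one ring of guard cells around the requested count
    n_side = int(np.ceil(np.sqrt(n_cells)))
    ncol, nrow = n_side + 2, int(np.ceil(n_cells / n_side)) + 2
    a = float(cell_diameter_px)
    dy = a * np.sqrt(3.0) / 2.0
    seeds = []
    for r in range(nrow):
        for c in range(ncol):
            x = a * c + (a / 2.0 if r % 2 else 0.0)
            y = dy * r
            seeds.append((x, y))
    seeds = np.asarray(seeds, dtype=float)
    if mesh_jitter > 0:
        seeds = seeds + rng.normal(0.0, mesh_jitter * a, seeds.shape)

    h = int(np.ceil(seeds[:, 1].max())) + 1
    w = int(np.ceil(seeds[:, 0].max())) + 1
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])

    from scipy.spatial import Voronoi, cKDTree

    dists, idx = cKDTree(seeds).query(pix, k=2)
    is_junction = (dists[:, 1] - dists[:, 0]) < 1.0
    label_map = (idx[:, 0] + 1).astype(np.int32)
    label_map[is_junction] = 0
    label_map = label_map.reshape(h, w)

    # interior cells: a full ring away from every image edge
    margin = 1.2 * a
    interior = set(
        int(i) + 1
        for i, (sx, sy) in enumerate(seeds)
        if margin <= sx <= w - margin and margin <= sy <= h - margin
    )
    interior = set(sorted(interior)[:n_cells])

    vor = Voronoi(seeds)
    junction_pixels: dict[int, list] = {cid: [] for cid in interior}
    img = np.zeros((h, w), dtype=float)
    for (i, j), verts in zip(vor.ridge_points, vor.ridge_vertices):
        ca, cb = int(i) + 1, int(j) + 1
        if ca not in junction_pixels and cb not in junction_pixels:
            continue
        if verts[0] < 0 or verts[1] < 0:
            continue  # unbounded ridge: only touches guard cells
        v0, v1 = vor.vertices[verts[0]], vor.vertices[verts[1]]
        length = float(np.hypot(*(v1 - v0)))
        if length == 0:
            continue
        theta = float(np.arctan2(v1[1] - v0[1], v1[0] - v0[0]) % np.pi)
        n_samp = max(int(round(length)), 1)
        t = (np.arange(n_samp) + 0.5) / n_samp
        sx = v0[0] + t * (v1[0] - v0[0])
        sy = v0[1] + t * (v1[1] - v0[1])
        eps = rng.normal(0.0, axis_noise_sd) if axis_noise_sd > 0 else 0.0
        level = base_intensity * (
            1.0 + p * np.cos(2.0 * (theta - axis_angle - eps)))
        inten = np.full(n_samp, level)
        if noise_sd > 0:
            inten = inten + rng.normal(0.0, noise_sd, n_samp)
        inten = np.clip(inten, 0.0, None)
        for cid in (ca, cb):
            if cid in junction_pixels:
                junction_pixels[cid].extend(
                    zip(sy, sx, [theta] * n_samp, inten))
        rr = np.clip(np.round(sy - 0.5).astype(int), 0, h - 1)
        cc = np.clip(np.round(sx - 0.5).astype(int), 0, w - 1)
        img[rr, cc] = inten
    jp = {cid: np.asarray(v, dtype=float).reshape(-1, 4)
          for cid, v in junction_pixels.items()}
    seg = TissueSegmentation(label_map=label_map, junction_pixels=jp)
    truth = {"p": p, "theta0": axis_angle % np.pi, "seeds": seeds,
             "interior_cells": sorted(interior)}
    return seg, RasterImage(pixels=img, channel="junction"), truth


def make_border_channels(
    mode: str,
    length_nm: float = 3000.0,
    offset_nm: float = 40.0,
    domain_len_nm: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_nm: float = 30.0,
    amplitude: float = 100.0,
    blur_px: float = 2.0,
) -> tuple[RasterImage, RasterImage, BorderRoi, dict[str, Any]]:
    """Simulate a two-channel cell border in one of three configurations.

    ``identical``: both channels carry the same along-border puncta profile on
    the border line. ``cross``: the same profile, but the channels sit on
    opposite sides of the border, displaced by ``offset_nm`` perpendicular to
    it (cross-junctional asymmetry: the proteins co-occur along the border).
    ``lateral``: complementary anti-phase square-wave domains of length
    ``domain_len_nm`` along the border (lateral separation: the proteins
    alternate). The signal has a Gaussian cross-section of s.d. ``blur_px``
    perpendicular to the border, emulating the optical transfer of the
    microscope at the ~30 nm/px SIM sampling.
    """
    if mode not in ("identical", "cross", "lateral"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "lateral" and domain_len_nm <= 0:
        raise ValueError("domain_len_nm must be positive in lateral mode")
    rng = np.random.default_rng(seed)
    px = pixel_size_nm
    w = int(np.ceil(length_nm / px))
    h = max(2 * int(np.ceil((abs(offset_nm) + 6 * blur_px * px) / px)) + 1, 15)
    row0 = h // 2
    s_nm = (np.arange(w) + 0.5) * px
    y_px = np.arange(h) + 0.5
    yc = row0 + 0.5  # border centerline in pixel coordinates

    if mode == "lateral":
        phase = np.floor(s_nm / domain_len_nm).astype(int) % 2
        prof1 = amplitude * (phase == 0).astype(float)
        prof2 = amplitude * (phase == 1).astype(float)
        centers_y = (yc, yc)
    else:
        # shared puncta profile: regular bumps every ~300 nm
        centers = np.arange(150.0, length_nm, 300.0)
        prof = np.zeros(w)
        for c in centers:
            prof += np.exp(-0.5 * ((s_nm - c) / 60.0) ** 2)
        prof1 = prof2 = amplitude * prof / max(prof.max(), 1e-12)
        if mode == "cross":
            half_off = offset_nm / (2.0 * px)
            centers_y = (yc - half_off, yc + half_off)
        else:
            centers_y = (yc, yc)

    ch = []
    sigma = max(blur_px, 1e-6)
    for prof_i, cy in zip((prof1, prof2), centers_y):
        cross = np.exp(-0.5 * ((y_px - cy) / sigma) ** 2)
        img = np.outer(cross, prof_i)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        ch.append(img)

    roi = BorderRoi(polyline=np.array([[0.5, row0 + 0.5],
                                       [w - 0.5, row0 + 0.5]]), width_px=5)
    truth = {"mode": mode, "domain_len_nm": domain_len_nm,
             "offset_nm": offset_nm}
    return (RasterImage(ch[0], px, "ch1"), RasterImage(ch[1], px, "ch2"),
            roi, truth)


def make_cell_pair(
    border_factor: float = 2.0,
    cell_intensity: float = 50.0,
    size_px: int = 100,
    border_width_px: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[RasterImage, np.ndarray, np.ndarray, dict[str, Any]]:
    """Two adjacent square cells with a brighter shared border strip.

    Returns the image, the border mask, the cell-pair mask and the designed
    enrichment ratio (border mean over cell-pair mean).
    """
    rng = np.random.default_rng(seed)
    h, w = size_px, 2 * size_px
    img = np.full((h, w), cell_intensity, dtype=float)
    half = border_width_px // 2
    border = np.zeros((h, w), dtype=bool)
    border[:, size_px - half:size_px + border_width_px - half] = True
    img[border] = border_factor * cell_intensity
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pair = np.ones((h, w), dtype=bool)
    frac = border.sum() / pair.sum()
    designed = border_factor / (frac * border_factor + (1 - frac) * 1.0)
    truth = {"designed_ratio": designed, "border_factor": border_factor}
    return RasterImage(img), border, pair, truth
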