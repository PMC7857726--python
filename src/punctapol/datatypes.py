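"""Core in-memory containers shared across the pipeline.

Conventions: rasters are row-major 2D numpy arrays, 0-based indices, pixel-center
geometry, y increasing downward. Physical lengths are carried in nanometres via
``pixel_size_nm``; point-pattern coordinates are already in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RasterImage:
    """A single-channel intensity raster with a physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MoleculeMap:
    """Molecule-count rendering of a localization dataset.

    ``counts[r, c]`` is the integer number of molecules localized in that pixel;
    the substrate of the puncta pipeline. Default 3 nm/px rendering.
    """

    counts: np.ndarray
    pixel_size_nm: float = 3.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError(f"expected a 2D count map, got ndim={self.counts.ndim}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("molecule counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("molecule counts must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total_molecules(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinaryMask:
    """Boolean mask aligned to a source raster."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape


@dataclass
class BorderRoi:
    """Segmented-line ROI along a cell border.

    ``polyline`` is an ordered (N, 2) array of (x, y) vertices in pixel
    coordinates (pixel-center convention); ``width_px`` is the odd width of the
    sampling band perpendicular to the line.
    """

    polyline: np.ndarray
    width_px: int = 5

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (N, 2) array of (x, y) vertices")
        if len(self.polyline) < 2:
            raise ValueError("polyline needs at least 2 vertices")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("width_px must be a positive odd integer")


@dataclass
class PointPattern:
    """Planar point pattern in a rectangular observation window (nm units).

    One point per occupied pixel: duplicate coordinates are not allowed and are
    collapsed (with a warning) by the constructors that build patterns from
    rasters.
    """

    points: np.ndarray
    window: tuple[float, float, float, float]  # (x_min, x_max, y_min, y_max)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        x0, x1, y0, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValueError("window must have positive area")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < x0).any() or (x > x1).any() or (y < y0).any() or (y > y1).any():
                raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def window_area(self) -> float:
        x0, x1, y0, y1 = self.window
        return (x1 - x0) * (y1 - y0)


@dataclass
class LFunction:
    """Ripley's L summary, L(r) = sqrt(K(r)/pi), on an ascending r grid (nm)."""

    r_grid: np.ndarray
    l_values: np.ndarray
    correction: str
    n_points: int

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.l_values = np.asarray(self.l_values, dtype=float)
        if self.r_grid.shape != self.l_values.shape:
            raise ValueError("r_grid and l_values must share a shape")
        if (np.diff(self.r_grid) <= 0).any():
            raise ValueError("r_grid must be strictly ascending")
        if not np.isfinite(self.l_values).all():
            raise ValueError("L values must be finite")


@dataclass
class StudPermResult:
    """Result of the studentized permutation test between groups of patterns."""

    statistic: float
    p_value: float
    n_permutations: int
    r_interval: tuple[float, float]
    group_sizes: tuple[int, ...]
    variant: str = "tbar"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be non-negative")


@dataclass
class FrapTrace:
    """Timestamped ROI intensities for one photobleaching experiment.

    ``bleach_index`` points at the first post-bleach frame (this frame holds
    F_bleach); the ``n_pre`` frames before it are pre-bleach.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    bleach_index: int
    n_pre: int
    name: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape or self.times_s.ndim != 1:
            raise ValueError("times and intensities must be matching 1D arrays")
        if (np.diff(self.times_s) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")
        if not (1 <= self.n_pre <= self.bleach_index):
            raise ValueError("need bleach_index >= n_pre >= 1")
        if self.bleach_index >= len(self.times_s):
            raise ValueError("bleach_index out of range")


@dataclass
class FrapResult:
    """Normalized recovery curve and the mobile fraction of one trace."""

    normalized: np.ndarray
    mobile_fraction: float
    f_pre: float
    f_bleach: float
    f_end: float
    flagged: bool = False  # mobile fraction outside [-0.1, 1.1]


@dataclass
class PunctaRecord:
    """One qualifying punctum: >=10-molecule cluster in the rendered map."""

    id: int
    pixel_coords: np.ndarray  # (n, 2) array of (row, col)
    molecule_count: int
    hull_area_px2: float
    density: float  # molecules per px^2 of convex hull; nan when degenerate
    degenerate: bool = False  # hull of collinear pixels (zero area)


@dataclass
class PunctaTable:
    """All puncta of one border plus the below-threshold remainder."""

    puncta: list[PunctaRecord]
    non_qualifying_pixel_count: int
    non_qualifying_molecule_count: int
    excluded_ids: set[int] = field(default_factory=set)
    pixel_size_nm: float = 3.0
    source: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.puncta]
        if len(ids) != len(set(ids)):
            raise ValueError("punctum ids must be unique")
        unknown = set(self.excluded_ids) - set(ids)
        if unknown:
            raise ValueError(f"excluded_ids not in table: {sorted(unknown)}")

    @property
    def retained(self) -> list[PunctaRecord]:
        return [p for p in self.puncta if p.id not in self.excluded_ids]


@dataclass
class TissueSegmentation:
    """Labeled epithelium with per-cell junction pixels.

    ``label_map`` assigns each pixel a cell id (0 = junction/membrane);
    ``junction_pixels`` maps cell id -> (n, 4) array of
    (row, col, tangent_angle_rad, intensity) with angle in [0, pi). Pixels on a
    border shared by two cells appear in both cells' lists.
    """

    label_map: np.ndarray
    junction_pixels: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        for cid, arr in self.junction_pixels.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 4)
            theta = arr[:, 2]
            if ((theta < 0) | (theta >= np.pi)).any():
                raise ValueError(f"cell {cid}: tangent angles must lie in [0, pi)")
            if (arr[:, 3] < 0).any():
                raise ValueError(f"cell {cid}: intensities must be non-negative")
            self.junction_pixels[cid] = arr

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.junction_pixels)


@dataclass
class CellPolarity:
    """Intensity-weighted nematic order of one cell's junctional signal."""

    cell_id: int
    q1: float
    q2: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.q1, self.q2))

    @property
    def axis(self) -> float:
        """Polarity axis in [0, pi)."""
        return float(np.arctan2(self.q2, self.q1) / 2.0 % np.pi)


@dataclass
class TissuePolarity:
    """Tissue-level magnitude of average polarity (Mp) and mean axis."""

    mp: float
    mean_axis: float
    n_cells: int
    axis_histogram: np.ndarray  # circular histogram counts over [0, pi)
    bin_edges: np.ndarray
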