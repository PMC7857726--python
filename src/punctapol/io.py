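"""File I/O: TIFF rasters, CSV tables and traces, JSON ROIs and sidecars.

Round-trip guarantees: MoleculeMap counts are exact (integer TIFF),
FrapTrace values survive to 6 decimals (CSV), BorderRoi is exact (JSON).
Every raster writer drops a ``.json`` sidecar with the pixel size and any
ground-truth metadata handed to it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .datatypes import BorderRoi, FrapTrace, MoleculeMap, PunctaTable, RasterImage

__all__ = [
    "write_molecule_map", "read_molecule_map",
    "write_raster", "read_raster",
    "write_frap_trace", "read_frap_trace",
    "write_border_roi", "read_border_roi",
    "write_puncta_table",
    "write_point_pattern_csv", "read_point_pattern_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_molecule_map(mmap: MoleculeMap, path: str | Path,
                       metadata: dict[str, Any] | None = None) -> None:
    path = Path(path)
    counts = mmap.counts
    if counts.max(initial=0) <= np.iinfo(np.uint16).max:
        counts = counts.astype(np.uint16)
    tifffile.imwrite(path, counts)
    meta = {"pixel_size_nm": mmap.pixel_size_nm, **(metadata or {})}
    _sidecar(path).write_text(json.dumps(meta, default=_jsonable, indent=1))


def read_molecule_map(path: str | Path) -> MoleculeMap:
    path = Path(path)
    counts = tifffile.imread(path).astype(np.int64)
    pixel_size = 3.0
    sc = _sidecar(path)
    if sc.exists():
        pixel_size = float(json.loads(sc.read_text()).get("pixel_size_nm", 3.0))
    return MoleculeMap(counts=counts, pixel_size_nm=pixel_size)


def write_raster(img: RasterImage, path: str | Path,
                 metadata: dict[str, Any] | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    meta = {"pixel_size_nm": img.pixel_size_nm, "channel": img.channel,
            **(metadata or {})}
    _sidecar(path).write_text(json.dumps(meta, default=_jsonable, indent=1))


def read_raster(path: str | Path) -> RasterImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    pixel_size, channel = 1.0, ""
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        pixel_size = float(meta.get("pixel_size_nm", 1.0))
        channel = meta.get("channel", "")
    return RasterImage(pixels=pixels, pixel_size_nm=pixel_size, channel=channel)


def write_frap_trace(trace: FrapTrace, path: str | Path) -> None:
    phase = np.array(["post"] * len(trace.times_s), dtype=object)
    phase[:trace.n_pre] = "pre"
    phase[trace.bleach_index] = "bleach"
    df = pd.DataFrame({"time_s": np.round(trace.times_s, 6),
                       "intensity": np.round(trace.intensities, 6),
                       "phase": phase})
    df.to_csv(path, index=False)


def read_frap_trace(path: str | Path) -> FrapTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        missing = {"time_s", "intensity", "phase"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        bleach = df.index[df["phase"] == "bleach"]
        if len(bleach) != 1:
            raise ValueError("expected exactly one 'bleach' row")
        n_pre = int((df["phase"] == "pre").sum())
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed FRAP trace {path}: {exc}") from exc
    return FrapTrace(times_s=df["time_s"].to_numpy(),
                     intensities=df["intensity"].to_numpy(),
                     bleach_index=int(bleach[0]), n_pre=n_pre,
                     name=path.stem)


def write_border_roi(roi: BorderRoi, path: str | Path) -> None:
    payload = {"polyline": roi.polyline.tolist(), "width_px": roi.width_px}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_border_roi(path: str | Path) -> BorderRoi:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return BorderRoi(polyline=np.asarray(payload["polyline"], dtype=float),
                         width_px=int(payload.get("width_px", 5)))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed ROI file {path}: {exc}") from exc


def puncta_frame(table: PunctaTable) -> pd.DataFrame:
    """Per-punctum records as a DataFrame (excluded puncta marked)."""
    nm2 = table.pixel_size_nm ** 2
    rows = [{
        "id": p.id,
        "n_pixels": len(p.pixel_coords),
        "molecule_count": p.molecule_count,
        "hull_area_px2": p.hull_area_px2,
        "hull_area_nm2": p.hull_area_px2 * nm2,
        "density_per_px2": p.density,
        "degenerate": p.degenerate,
        "excluded": p.id in table.excluded_ids,
    } for p in table.puncta]
    cols = ["id", "n_pixels", "molecule_count", "hull_area_px2",
            "hull_area_nm2", "density_per_px2", "degenerate", "excluded"]
    return pd.DataFrame(rows, columns=cols)


def write_puncta_table(table: PunctaTable, path: str | Path) -> None:
    puncta_frame(table).to_csv(path, index=False)
    meta = {"non_qualifying_pixel_count": table.non_qualifying_pixel_count,
            "non_qualifying_molecule_count": table.non_qualifying_molecule_count,
            "excluded_ids": sorted(table.excluded_ids),
            "pixel_size_nm": table.pixel_size_nm,
            "source": table.source}
    _sidecar(Path(path)).write_text(json.dumps(meta, indent=1))


def write_point_pattern_csv(points: np.ndarray,
                            window: tuple[float, float, float, float],
                            path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(np.asarray(points).reshape(-1, 2),
                 columns=["x_nm", "y_nm"]).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"window": list(window)}))


def read_point_pattern_csv(path: str | Path):
    from .datatypes import PointPattern

    path = Path(path)
    df = pd.read_csv(path)
    sc = _sidecar(path)
    pts = df[["x_nm", "y_nm"]].to_numpy()
    if sc.exists():
        window = tuple(json.loads(sc.read_text())["window"])
    else:
        from .ripley import build_window
        window = build_window(pts)
    return PointPattern(points=pts, window=window)


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
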