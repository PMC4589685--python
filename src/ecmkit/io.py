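"""Readers and writers for images and coordinate tables.

Images: single-channel TIFF (raw/enhanced stages as float or 16-bit,
binary masks as 8-bit {0, 255}) and 8-bit PNG.  Tables: CSV with the
schemas below; times in minutes, positions/lengths in micrometres.

* tracks:      ``cell_id, t_min, x_um, y_um``
* protrusions: ``cell_id, t_min, angle_deg`` *or* ``partition``, ``length_um``
* ground truth (synthetic fibers): ``fiber_id, x0, y0, x1, y1, width_px``
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .image import Image
from .motility import ProtrusionRecord, Trajectory

TRACK_COLUMNS = ("cell_id", "t_min", "x_um", "y_um")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_size_um: float = 1.0, stage: str = "raw") -> Image:
    """Read a single-channel TIFF/PNG image; fails loudly on RGB input."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        elif suffix == ".png":
            import imageio.v3 as iio

            arr = iio.imread(path)
        else:
            raise FormatError(f"unsupported image format {suffix!r}: {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel 2D image, got shape {arr.shape} "
            "(RGB/multi-channel input is rejected)"
        )
    vals = arr.astype(float)
    if stage == "binary":
        vals = (vals > 0).astype(float)
    return Image(values=vals, pixel_size_um=pixel_size_um, stage=stage,
                 meta={"source": str(path), "dtype": str(arr.dtype)})


def write_image(img: Image, path: str | Path) -> Path:
    """Write an image; binary masks as 8-bit {0,255}, others per format.

    TIFF keeps float32 for non-binary stages (lossless for analysis
    intermediates); PNG quantizes non-binary data to 16-bit over the
    image range.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if img.stage == "binary":
        arr = (img.values > 0).astype(np.uint8) * 255
    elif suffix in (".tif", ".tiff"):
        arr = img.values.astype(np.float32)
    else:
        v = img.values
        span = np.ptp(v)
        scaled = (v - v.min()) / span if span > 0 else np.zeros_like(v)
        arr = (scaled * 65535).round().astype(np.uint16)
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported image format {suffix!r}: {path}")
    return path


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such table: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"could not parse {path}: {exc}") from exc


def read_tracks(path: str | Path) -> list[Trajectory]:
    """Read per-cell trajectories from a tracks CSV.

    Rows are grouped by ``cell_id`` and sorted by time (with a warning if
    the file was unsorted); a duplicated time point within a cell is a
    validation error naming the cell and data line.
    """
    df = _read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing track columns {missing}")
    bad = df[list(TRACK_COLUMNS[1:])].apply(pd.to_numeric, errors="coerce")
    bad_rows = bad.isna().any(axis=1)
    if bad_rows.any():
        lines = (df.index[bad_rows] + 2).tolist()  # header is line 1
        raise SchemaError(f"{path}: malformed numeric values at lines {lines[:10]}")
    df[list(TRACK_COLUMNS[1:])] = bad

    out: list[Trajectory] = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        dup = grp["t_min"].duplicated()
        if dup.any():
            line = int(grp.index[dup][0]) + 2
            raise SchemaError(
                f"{path}: duplicated time point for cell {cell_id!r} at line {line}"
            )
        if not grp["t_min"].is_monotonic_increasing:
            warnings.warn(f"{path}: times for cell {cell_id!r} unsorted; auto-sorting",
                          stacklevel=2)
            grp = grp.sort_values("t_min")
        out.append(Trajectory(
            cell_id=str(cell_id), times_min=grp["t_min"].to_numpy(),
            x_um=grp["x_um"].to_numpy(), y_um=grp["y_um"].to_numpy(),
        ))
    return out


def write_tracks(trajectories: list[Trajectory], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame({"cell_id": t.cell_id, "t_min": t.times_min,
                      "x_um": t.x_um, "y_um": t.y_um})
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
    return path


def read_protrusions(
    path: str | Path, min_length_um: float = 5.0, duration_min: float = 720.0,
    anterior_axis_deg: Optional[dict[str, float]] = None,
) -> list[ProtrusionRecord]:
    """Read protrusion event streams from CSV.

    The header declares the orientation column: either ``partition``
    (1..8, already relative to the anterior axis) or ``angle_deg``
    (absolute; per-cell anterior axes supplied via ``anterior_axis_deg``).
    """
    df = _read_csv(path)
    for col in ("cell_id", "t_min", "length_um"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing protrusion column {col!r}")
    has_partition = "partition" in df.columns
    has_angle = "angle_deg" in df.columns
    if not (has_partition or has_angle):
        raise SchemaError(f"{path}: need a 'partition' or 'angle_deg' column")

    out: list[ProtrusionRecord] = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_min")
        events = {"t_min": grp["t_min"].to_numpy(dtype=float),
                  "length_um": grp["length_um"].to_numpy(dtype=float)}
        if has_partition:
            events["partition"] = grp["partition"].to_numpy(dtype=int)
        else:
            events["angle_rad"] = np.deg2rad(grp["angle_deg"].to_numpy(dtype=float))
        axis = math.radians((anterior_axis_deg or {}).get(str(cell_id), 0.0))
        out.append(ProtrusionRecord(
            cell_id=str(cell_id), events=pd.DataFrame(events),
            anterior_axis_rad=axis, duration_min=duration_min,
            min_length_um=min_length_um,
        ))
    return out


def write_protrusions(records: list[ProtrusionRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for rec in records:
        f = rec.events.copy()
        f.insert(0, "cell_id", rec.cell_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
    return path


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False, float_format="%.9g")
    return path
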