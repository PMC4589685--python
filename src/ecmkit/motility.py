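"""Cell motility statistics from trajectory and protrusion tables.

The tracked quantities mirror standard 3D single-cell migration assays:

* **speed** — mean Euclidean step length per sampling interval (um/min),
  for cells imaged at a fixed interval (2 min in the targeted assay);
* **net invasion distance** — maximum displacement from the starting
  position over the whole observation window;
* **protrusion orientation** — protrusions (>= 5 um from the cell
  periphery) binned into eight equal 45-degree radial partitions, with
  partition 1 centered on the anterior axis set by the longest initial
  protrusion and fixed thereafter;
* **polarization index** — (C1 - C2) / (C1 + C2), where C1 counts
  protrusions in the anteroposterior partitions (1 and 5) and C2 in the
  lateral partitions (3 and 7).  1 means the cell stayed polarized along
  its initial axis; 0 means axial and lateral protrusion were balanced
  (isotropic exploration); diagonal partitions (2, 4, 6, 8) contribute to
  the orientation fractions but to neither count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: Half-width of each of the eight radial partitions, radians (22.5 deg).
SECTOR_HALF_WIDTH = math.pi / 8

ANTEROPOSTERIOR = (1, 5)
LATERAL = (3, 7)


@dataclass
class Trajectory:
    """Time-stamped positions of one tracked cell (times in minutes, x/y in um)."""

    cell_id: str
    times_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.times_min)
        if len(self.x_um) != n or len(self.y_um) != n:
            raise InvalidInputError(f"trajectory {self.cell_id}: column lengths differ")
        if n == 0:
            raise InvalidInputError(f"trajectory {self.cell_id}: empty")
        if np.any(np.diff(self.times_min) <= 0):
            raise InvalidInputError(f"trajectory {self.cell_id}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass
class ProtrusionRecord:
    """Protrusion events of one cell over an observation window.

    ``events`` has columns ``t_min``, ``length_um`` and either
    ``partition`` (1..8) or ``angle_rad`` (absolute, image frame); when
    only angles are present, partitions are assigned relative to
    ``anterior_axis_rad`` at binning time.
    """

    cell_id: str
    events: pd.DataFrame
    anterior_axis_rad: float = 0.0
    duration_min: float = 720.0
    min_length_um: float = 5.0

    def __post_init__(self) -> None:
        ev = self.events
        if "t_min" not in ev.columns or "length_um" not in ev.columns:
            raise InvalidInputError("events need t_min and length_um columns")
        if "partition" not in ev.columns and "angle_rad" not in ev.columns:
            raise InvalidInputError("events need a partition or angle_rad column")
        if self.duration_min <= 0:
            raise InvalidInputError("duration_min must be positive")
        if len(ev) and (ev["length_um"] < self.min_length_um - 1e-12).any():
            raise InvalidInputError(
                f"record {self.cell_id}: event shorter than the {self.min_length_um} um minimum"
            )
        if "partition" in ev.columns and len(ev):
            parts = ev["partition"].to_numpy()
            if not np.all(np.isin(parts, np.arange(1, 9))):
                raise InvalidInputError(f"record {self.cell_id}: partitions must be in 1..8")


@dataclass
class MotilitySummary:
    """Per-cell motility metrics; ``None`` marks undefined quantities."""

    cell_id: str
    speed_um_per_min: Optional[float] = None
    net_invasion_um: Optional[float] = None
    protrusions_per_90min: Optional[float] = None
    orientation_fractions: Optional[np.ndarray] = None
    polarization_index: Optional[float] = None
    C1: int = 0
    C2: int = 0
    extras: dict = field(default_factory=dict)


def cell_speed(traj: Trajectory, interval_tolerance: float = 0.01) -> float:
    """Mean distance travelled per sampling interval, in um/min.

    Requires uniform sampling (relative spread of intervals within
    ``interval_tolerance``); tracks with dropped frames are rejected
    rather than interpolated.
    """
    if len(traj) < 2:
        raise InvalidInputError(f"trajectory {traj.cell_id}: need >= 2 points for speed")
    dts = np.diff(traj.times_min)
    if np.max(np.abs(dts - dts.mean())) > interval_tolerance * dts.mean():
        raise InvalidInputError(
            f"trajectory {traj.cell_id}: non-uniform sampling intervals "
            f"(spread exceeds {interval_tolerance:.0%}); resampling is out of scope"
        )
    steps = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um))
    return float(np.mean(steps / dts))


def net_invasion(traj: Trajectory) -> float:
    """Maximum Euclidean displacement from the first recorded position (um)."""
    dx = traj.x_um - traj.x_um[0]
    dy = traj.y_um - traj.y_um[0]
    return float(np.max(np.hypot(dx, dy)))


def assign_partition(angle_rad: float, anterior_axis_rad: float) -> int:
    """Map an absolute protrusion angle to one of the eight radial partitions.

    Partition 1 spans the anterior axis +/- 22.5 deg; numbering proceeds
    counter-clockwise; an angle exactly on a boundary goes to the
    counter-clockwise (higher-numbered) sector.
    """
    rel = (angle_rad - anterior_axis_rad) % (2 * math.pi)
    idx = int(math.floor((rel + SECTOR_HALF_WIDTH) / (2 * SECTOR_HALF_WIDTH))) % 8
    return idx + 1


def partition_events(rec: ProtrusionRecord) -> tuple[Optional[np.ndarray], int, int]:
    """Bin protrusion events into the eight partitions.

    Returns ``(orientation_fractions, C1, C2)``; fractions are ``None``
    (undefined, not zero) for an empty record.
    """
    ev = rec.events
    if len(ev) == 0:
        return None, 0, 0
    if "partition" in ev.columns:
        parts = ev["partition"].to_numpy(dtype=int)
    else:
        parts = np.array(
            [assign_partition(a, rec.anterior_axis_rad) for a in ev["angle_rad"]], dtype=int
        )
    counts = np.bincount(parts, minlength=9)[1:9]
    fractions = counts / counts.sum()
    c1 = int(counts[0] + counts[4])  # partitions 1 and 5
    c2 = int(counts[2] + counts[6])  # partitions 3 and 7
    return fractions, c1, c2


def polarization_index(c1: int, c2: int) -> float:
    """Polarization index (C1 - C2) / (C1 + C2).

    1 when every axial-or-lateral protrusion is anteroposterior, 0 when
    axial and lateral counts balance, -1 when all are lateral.  Undefined
    (error) when no protrusion falls on either axis.
    """
    if c1 < 0 or c2 < 0:
        raise InvalidInputError("counts must be nonnegative")
    total = c1 + c2
    if total == 0:
        raise InvalidInputError("polarization index undefined: C1 + C2 = 0")
    return (c1 - c2) / total


def protrusion_rate(rec: ProtrusionRecord, window_min: float = 90.0) -> float:
    """Number of protrusion events per ``window_min`` of observation."""
    if rec.duration_min <= 0:
        raise InvalidInputError("observation duration must be positive")
    return len(rec.events) * window_min / rec.duration_min


def summarize_cell(
    traj: Optional[Trajectory] = None,
    rec: Optional[ProtrusionRecord] = None,
    window_min: float = 90.0,
) -> MotilitySummary:
    """Combine trajectory and protrusion metrics for one cell."""
    if traj is None and rec is None:
        raise InvalidInputError("need a trajectory or a protrusion record")
    cell_id = traj.cell_id if traj is not None else rec.cell_id  # type: ignore[union-attr]
    out = MotilitySummary(cell_id=cell_id)
    if traj is not None:
        out.speed_um_per_min = cell_speed(traj) if len(traj) >= 2 else None
        out.net_invasion_um = net_invasion(traj)
    if rec is not None:
        fractions, c1, c2 = partition_events(rec)
        out.orientation_fractions = fractions
        out.C1, out.C2 = c1, c2
        out.polarization_index = polarization_index(c1, c2) if c1 + c2 > 0 else None
        out.protrusions_per_90min = protrusion_rate(rec, window_min)
    return out


def condition_means(summaries: Sequence[MotilitySummary]) -> pd.DataFrame:
    """Mean and s.e.m. over cells for each metric, the per-condition summary
    convention used for correlation tables."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "cell_id": s.cell_id,
                "speed_um_per_min": s.speed_um_per_min,
                "net_invasion_um": s.net_invasion_um,
                "protrusions_per_90min": s.protrusions_per_90min,
                "polarization_index": s.polarization_index,
            }
        )
    df = pd.DataFrame(rows)
    metrics = df.drop(columns=["cell_id"])
    n = metrics.notna().sum()
    mean = metrics.mean()
    sem = metrics.std(ddof=1) / np.sqrt(n.clip(lower=1))
    return pd.DataFrame({"mean": mean, "sem": sem, "n": n})
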