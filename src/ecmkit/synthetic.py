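"""Synthetic test-data generators with exact ground truth.

Three generators emulate the inputs of the analysis pipeline so every
stage can be exercised against known truth:

* :func:`generate_fiber_image` — a 2D fibrous network rendered as hard
  straight strokes of controlled width, with an optional radially
  symmetric interference-style background and Gaussian speckle, emulating
  a reflection-confocal slice of a collagen gel.  Fiber orientation is
  axial (defined on [0, pi)), drawn either uniformly or from a wrapped
  von Mises via the doubled-angle construction, so anisotropy is
  controlled by a single concentration parameter ``kappa``.
* :func:`generate_trajectory` — a persistent random walk at fixed speed
  and sampling interval; ``persistence`` interpolates between an
  uncorrelated 2D random walk (0) and straight-line motion (1).
* :func:`generate_protrusion_stream` — a Poisson stream of protrusion
  events assigned to the eight radial partitions, with ``axial_bias``
  the extra probability mass forced onto the anteroposterior partitions.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError
from .image import Image
from .motility import ProtrusionRecord, Trajectory


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


def _finite(*vals: float) -> bool:
    return all(np.isfinite(v) for v in vals)


# ---------------------------------------------------------------------------
# fiber images
# ---------------------------------------------------------------------------

@dataclass
class FiberFieldParams:
    """Ground-truth knobs of the synthetic fiber network.

    ``orientation_kappa`` = 0 gives an isotropic network; large values an
    aligned one centered on ``orientation_center_rad``.  ``width_px`` is
    the exact rendered stroke width (pixels within width/2 of the segment
    axis are on), so geometric ground truth is exact by construction.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.2
    n_fibers: int = 150
    mean_length_px: float = 40.0
    length_jitter: float = 0.25
    width_px: float = 2.0
    orientation_mode: str = "von-mises"
    orientation_center_rad: float = 0.0
    orientation_kappa: float = 0.0
    fiber_intensity: float = 1.0
    blur_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        _require(h >= 64 and w >= 64, "image_size_px must be at least 64 px per side")
        _require(
            _finite(self.pixel_size_um, self.mean_length_px, self.width_px,
                    self.orientation_center_rad),
            "fiber-field parameters must be finite",
        )
        _require(not math.isnan(self.orientation_kappa), "orientation_kappa must not be NaN")
        _require(self.pixel_size_um > 0, "pixel_size_um must be positive")
        _require(self.n_fibers >= 0, "n_fibers must be nonnegative")
        _require(self.mean_length_px > 0, "mean_length_px must be positive")
        _require(self.length_jitter >= 0, "length_jitter must be nonnegative")
        _require(self.width_px >= 1, "width_px must be >= 1")
        _require(self.orientation_mode in ("uniform", "von-mises"),
                 f"unknown orientation_mode {self.orientation_mode!r}")
        _require(0 <= self.orientation_center_rad < math.pi,
                 "orientation_center_rad must lie in [0, pi)")
        _require(self.orientation_kappa >= 0, "orientation_kappa must be nonnegative")


@dataclass
class BackgroundParams:
    """Radially symmetric interference-style background plus speckle.

    The deterministic part is a Gaussian falloff of the given scale from
    the image center (a surrogate for the laser interference pattern of
    reflection imaging); speckle is zero-mean Gaussian noise clipped at 0
    after addition.
    """

    center_intensity: float = 0.5
    falloff_scale_px: float = 200.0
    speckle_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _require(_finite(self.center_intensity, self.falloff_scale_px, self.speckle_sd),
                 "background parameters must be finite")
        _require(self.center_intensity >= 0, "center_intensity must be nonnegative")
        _require(self.falloff_scale_px > 0, "falloff_scale_px must be positive")
        _require(self.speckle_sd >= 0, "speckle_sd must be nonnegative")


def sample_orientations(params: FiberFieldParams, rng: np.random.Generator) -> np.ndarray:
    """Draw axial fiber orientations on [0, pi).

    von Mises mode uses the doubled-angle construction: sample phi from a
    von Mises with mean 2*center and concentration kappa, return phi/2
    wrapped to [0, pi).  This is the standard way to put a unimodal
    concentration structure on an axial (undirected) angle.
    """
    n = params.n_fibers
    if params.orientation_mode == "uniform" or params.orientation_kappa == 0:
        return rng.uniform(0.0, math.pi, size=n)
    if math.isinf(params.orientation_kappa):
        # kappa -> infinity surrogate: a fully degenerate distribution
        return np.full(n, params.orientation_center_rad)
    phi = rng.vonmises(mu=2 * params.orientation_center_rad, kappa=params.orientation_kappa, size=n)
    return (phi / 2.0) % math.pi


def radial_background(shape: tuple[int, int], bg: BackgroundParams) -> np.ndarray:
    """Deterministic radial part of the background (no speckle)."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return bg.center_intensity * np.exp(-r2 / (2.0 * bg.falloff_scale_px**2))


def _render_segment(canvas: np.ndarray, x0: float, y0: float, x1: float, y1: float,
                    width: float, value: float) -> None:
    """Set pixels within width/2 of the segment to at least ``value`` (hard stroke)."""
    h, w = canvas.shape
    half = width / 2.0
    rmin = max(int(math.floor(min(y0, y1) - half - 1)), 0)
    rmax = min(int(math.ceil(max(y0, y1) + half + 1)), h - 1)
    cmin = max(int(math.floor(min(x0, x1) - half - 1)), 0)
    cmax = min(int(math.ceil(max(x0, x1) + half + 1)), w - 1)
    if rmin > rmax or cmin > cmax:
        return
    yy, xx = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dx, dy = x1 - x0, y1 - y0
    seg_len2 = dx * dx + dy * dy
    if seg_len2 == 0:
        dist = np.hypot(xx - x0, yy - y0)
    else:
        t = ((xx - x0) * dx + (yy - y0) * dy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
    patch = canvas[rmin : rmax + 1, cmin : cmax + 1]
    on = dist <= half
    patch[on] = np.maximum(patch[on], value)


def generate_fiber_image(
    params: FiberFieldParams, bg: Optional[BackgroundParams] = None
) -> tuple[Image, pd.DataFrame]:
    """Render a synthetic fiber network and return it with its ground truth.

    Returns
    -------
    image
        ``raw``-stage :class:`~ecmkit.image.Image`; zero everywhere when
        ``n_fibers`` is 0 and no background is supplied.
    ground_truth
        One row per rendered fiber: ``fiber_id, x0, y0, x1, y1,
        orientation_rad, length_px, width_px`` (pixel coordinates,
        x right / y down, orientation axial in [0, pi)).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    canvas = np.zeros((h, w), dtype=float)

    thetas = sample_orientations(params, rng)
    cx = rng.uniform(0, w, size=params.n_fibers)
    cy = rng.uniform(0, h, size=params.n_fibers)
    lengths = params.mean_length_px * (
        1.0 + params.length_jitter * rng.standard_normal(params.n_fibers)
    )
    lengths = np.clip(lengths, 2.0, None)

    rows = []
    for i in range(params.n_fibers):
        th, L = thetas[i], lengths[i]
        x0 = cx[i] - 0.5 * L * math.cos(th)
        y0 = cy[i] - 0.5 * L * math.sin(th)
        x1 = cx[i] + 0.5 * L * math.cos(th)
        y1 = cy[i] + 0.5 * L * math.sin(th)
        _render_segment(canvas, x0, y0, x1, y1, params.width_px, params.fiber_intensity)
        rows.append(
            {"fiber_id": i, "x0": x0, "y0": y0, "x1": x1, "y1": y1,
             "orientation_rad": th, "length_px": L, "width_px": params.width_px}
        )
    truth = pd.DataFrame(
        rows, columns=["fiber_id", "x0", "y0", "x1", "y1",
                       "orientation_rad", "length_px", "width_px"],
    )

    if params.blur_sigma_px > 0:
        canvas = ndimage.gaussian_filter(canvas, params.blur_sigma_px)

    if bg is not None:
        canvas = canvas + radial_background((h, w), bg)
        if bg.speckle_sd > 0:
            bg_rng = np.random.default_rng(bg.seed)
            canvas = canvas + bg_rng.normal(0.0, bg.speckle_sd, size=canvas.shape)
        canvas = np.clip(canvas, 0.0, None)

    img = Image(
        values=canvas, pixel_size_um=params.pixel_size_um, stage="raw",
        meta={"generator": "fiber_field", "n_fibers": params.n_fibers,
              "orientation_kappa": params.orientation_kappa, "seed": params.seed},
    )
    return img, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class WalkParams:
    """Persistent-random-walk parameters (2-min sampling by default)."""

    n_steps: int = 495
    dt_min: float = 2.0
    speed_um_per_min: float = 0.5
    persistence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_steps >= 1, "n_steps must be >= 1")
        _require(_finite(self.dt_min, self.speed_um_per_min, self.persistence),
                 "walk parameters must be finite")
        _require(self.dt_min > 0, "dt_min must be positive")
        _require(self.speed_um_per_min >= 0, "speed must be nonnegative")
        _require(0 <= self.persistence <= 1, "persistence must lie in [0, 1]")


def generate_trajectory(params: WalkParams, cell_id: str = "sim") -> Trajectory:
    """Simulate a persistent random walk sampled at fixed intervals.

    Every step has length exactly ``speed * dt``; the turning angle per
    step is ``(1 - persistence) * U`` with U uniform on (-pi, pi], so
    persistence 1 gives a straight line and persistence 0 an uncorrelated
    walk whose mean-squared displacement follows 2D diffusive scaling.
    """
    rng = np.random.default_rng(params.seed)
    step = params.speed_um_per_min * params.dt_min
    heading = rng.uniform(-math.pi, math.pi)
    turns = (1.0 - params.persistence) * rng.uniform(-math.pi, math.pi, size=params.n_steps)
    headings = heading + np.concatenate(([0.0], np.cumsum(turns[1:])))
    dx = step * np.cos(headings)
    dy = step * np.sin(headings)
    x = np.concatenate(([0.0], np.cumsum(dx)))
    y = np.concatenate(([0.0], np.cumsum(dy)))
    t = params.dt_min * np.arange(params.n_steps + 1)
    return Trajectory(cell_id=cell_id, times_min=t, x_um=x, y_um=y)


# ---------------------------------------------------------------------------
# protrusion streams
# ---------------------------------------------------------------------------

@dataclass
class ProtrusionStreamParams:
    """Poisson protrusion stream over an observation window.

    ``axial_bias`` is the probability that an event is forced onto the
    anteroposterior partitions {1, 5}; the remaining mass is uniform over
    all eight partitions, so bias 0 is isotropic and bias 1 fully axial.
    """

    duration_min: float = 720.0
    rate_per_90min: float = 4.0
    axial_bias: float = 0.5
    min_length_um: float = 5.0
    mean_excess_length_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(_finite(self.duration_min, self.rate_per_90min, self.axial_bias,
                         self.min_length_um), "protrusion parameters must be finite")
        _require(self.duration_min > 0, "duration_min must be positive")
        _require(self.rate_per_90min >= 0, "rate_per_90min must be nonnegative")
        _require(0 <= self.axial_bias <= 1, "axial_bias must lie in [0, 1]")
        _require(self.min_length_um > 0, "min_length_um must be positive")


def generate_protrusion_stream(
    params: ProtrusionStreamParams, cell_id: str = "sim"
) -> ProtrusionRecord:
    """Simulate protrusion events with known axial bias.

    Event count is Poisson with mean ``rate_per_90min * duration / 90``;
    times are uniform over the window; lengths are ``min_length_um`` plus
    an exponential excess.
    """
    rng = np.random.default_rng(params.seed)
    n = int(rng.poisson(params.rate_per_90min * params.duration_min / 90.0))
    times = np.sort(rng.uniform(0.0, params.duration_min, size=n))
    axial = rng.uniform(size=n) < params.axial_bias
    partitions = rng.integers(1, 9, size=n)
    partitions[axial] = rng.choice([1, 5], size=int(axial.sum()))
    lengths = params.min_length_um + rng.exponential(params.mean_excess_length_um, size=n)
    events = pd.DataFrame({"t_min": times, "partition": partitions, "length_um": lengths})
    return ProtrusionRecord(
        cell_id=cell_id, events=events, anterior_axis_rad=0.0,
        duration_min=params.duration_min, min_length_um=params.min_length_um,
    )
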