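"""Matrix microstructure measurements: pore-size granulometry and the
FFT-based fiber-alignment index.

**Pore size** is measured on the binary fiber mask by granulometry: the
pore (void) image is the complement of the fiber mask; sequential
morphological openings with digital disks of increasing radius r remove
every void region narrower than the disk, and the retained pore area
I(r) is a nonincreasing curve whose decrements P(r) = I(r) - I(r+1)
give the area occupied by pores of characteristic radius r.  Normalizing
P yields the pore-size frequency distribution f(r) and its mean.

**Fiber alignment** is a bulk anisotropy index of the whole image.  The
centered 2D DFT magnitude of the (mean-subtracted) image is integrated
along diameter lines at angles theta covering [0, pi) (a Radon-style
line integral), giving the angular power F_I(theta).  Mapping each
(theta, F_I) sample to Cartesian points (F_I cos theta, F_I sin theta)
and taking the eigenvalues lambda1 >= lambda2 of the 2x2 second-moment
matrix gives the alignment index

    alpha = 1 - lambda2 / lambda1,

which is 0 for an isotropic network and 1 for perfectly aligned fibers.
Because the spectrum of a fiber image concentrates perpendicular to the
fiber axis, the principal orientation of the *fibers* is the principal
spectral orientation rotated by 90 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError, UndefinedAlignmentError
from .image import Image, central_crop
from .preprocess import ThresholdSpec, preprocess_chain

#: Mean pore radius (px) below which the measurement approaches the
#: spatial resolution of the imaging system and is flagged unreliable.
RESOLUTION_LIMIT_PX = 2.0


# ---------------------------------------------------------------------------
# granulometry
# ---------------------------------------------------------------------------

def disk_footprint(radius: int) -> np.ndarray:
    """Digital disk: pixels within Euclidean distance radius + 0.5 of the center."""
    if radius < 0:
        raise InvalidParameterError("radius must be nonnegative")
    size = 2 * radius + 1
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (np.hypot(yy, xx) <= radius + 0.5).reshape(size, size)


@dataclass
class PoreSizeSpectrum:
    """Granulometric pore-size spectrum of a binary fiber mask.

    ``retained_area[i]`` is I(r) for ``radii_px[i]``; ``freq`` sums to 1
    when any pore area exists.  ``mean_radius_px`` is NaN (missing) for
    an all-fiber mask.  ``truncated`` flags pore area surviving the
    largest opening (the terminal bin absorbs it); ``near_resolution_limit``
    flags means below ~2 px, where pore sizes approach the imaging
    resolution and are unreliable.
    """

    radii_px: np.ndarray
    retained_area: np.ndarray
    freq: np.ndarray
    mean_radius_px: float
    pixel_size_um: float
    truncated: bool = False

    @property
    def mean_diameter_um(self) -> float:
        return 2.0 * self.mean_radius_px * self.pixel_size_um

    @property
    def near_resolution_limit(self) -> bool:
        return bool(np.isfinite(self.mean_radius_px) and self.mean_radius_px < RESOLUTION_LIMIT_PX)

    @property
    def empty(self) -> bool:
        return not np.isfinite(self.mean_radius_px)


def pore_spectrum(mask: Image, max_radius_px: int) -> PoreSizeSpectrum:
    """Granulometry of the pore space of a binary fiber mask.

    The pore image is the complement of the fiber mask.  For each radius
    r in 0..max_radius the pore image is opened with a digital disk of
    radius r and the retained area I(r) recorded; P(r) = I(r) - I(r+1)
    (the final bin keeps everything surviving the largest opening),
    f = P / sum(P), and the mean radius is the f-weighted mean.
    """
    vals = mask.values
    if not np.all(np.isin(np.unique(vals), (0.0, 1.0))):
        raise InvalidInputError("pore_spectrum requires a binary {0,1} mask")
    if max_radius_px < 1:
        raise InvalidParameterError("max_radius_px must be >= 1")
    if max_radius_px > min(vals.shape) // 2:
        raise InvalidParameterError(
            f"max_radius_px={max_radius_px} exceeds half the minimum image side"
        )

    pores = vals == 0
    radii = np.arange(max_radius_px + 1)
    retained = np.empty(max_radius_px + 1, dtype=float)
    # Digital Euclidean disks are not a perfect sieve (an opening at r+1
    # can occasionally retain jagged boundary pixels the opening at r
    # removed), so the openings are accumulated by intersection, which
    # restores the nesting the continuous-space granulometry guarantees
    # and keeps I(r) monotone nonincreasing.
    kept = pores
    for r in radii:
        if r > 0:
            kept = kept & ndimage.binary_opening(pores, structure=disk_footprint(int(r)))
        retained[r] = float(kept.sum())

    per_radius = np.empty_like(retained)
    per_radius[:-1] = retained[:-1] - retained[1:]
    per_radius[-1] = retained[-1]
    truncated = retained[-1] > 0

    total = per_radius.sum()
    if total <= 0:
        warnings.warn("mask has no pore area; mean pore size undefined", stacklevel=2)
        freq = np.zeros_like(per_radius)
        mean_r = math.nan
    else:
        freq = per_radius / total
        mean_r = float(np.sum(radii * freq))
        if mean_r < RESOLUTION_LIMIT_PX:
            warnings.warn(
                f"mean pore radius {mean_r:.2f} px approaches the imaging "
                "resolution limit; value may be unreliable", stacklevel=2,
            )
    return PoreSizeSpectrum(
        radii_px=radii, retained_area=retained, freq=freq,
        mean_radius_px=mean_r, pixel_size_um=mask.pixel_size_um, truncated=bool(truncated),
    )


# ---------------------------------------------------------------------------
# FFT alignment
# ---------------------------------------------------------------------------

@dataclass
class SpectrumFT:
    """Origin-centered 2D DFT of an image: real/imaginary parts and magnitude."""

    real: np.ndarray
    imag: np.ndarray
    magnitude: np.ndarray
    origin_centered: bool = True
    dc_removed: bool = True


@dataclass
class PolarPower:
    """Angular distribution F_I(theta) of integrated DFT magnitude over [0, pi)."""

    thetas_rad: np.ndarray
    power: np.ndarray
    dc_removed: bool = True

    def __post_init__(self) -> None:
        self.thetas_rad = np.asarray(self.thetas_rad, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.thetas_rad) < 2:
            raise InvalidInputError("need at least 2 orientations")
        if np.any(self.power < 0):
            raise InvalidInputError("angular power must be nonnegative")


@dataclass
class AlignmentResult:
    """Eigenvalue alignment index alpha = 1 - lambda2/lambda1 in [0, 1]."""

    lambda1: float
    lambda2: float
    alpha: float
    principal_orientation_rad: float
    fiber_orientation_rad: Optional[float] = None


def ft_magnitude(img: Image, dc_remove: bool = True) -> SpectrumFT:
    """Centered 2D DFT with magnitude sqrt(R^2 + I^2).

    With ``dc_remove`` the image mean is subtracted before the transform
    so the isotropic center spike does not compress the alignment index.
    """
    vals = img.values
    if dc_remove:
        vals = vals - vals.mean()
    ft = np.fft.fftshift(np.fft.fft2(vals))
    return SpectrumFT(
        real=ft.real, imag=ft.imag, magnitude=np.abs(ft),
        origin_centered=True, dc_removed=dc_remove,
    )


def angular_power(
    spec: SpectrumFT, n_thetas: int = 180, interpolation: str = "linear"
) -> PolarPower:
    """Integrate the DFT magnitude along diameter lines through the center.

    For each theta in ``n_thetas`` even steps over [0, pi) the magnitude
    is sampled every 1 px along the full diameter at that angle (bilinear
    by default, nearest optionally) and summed — a Radon-style line
    integral through the spectrum origin.  The center sample is excluded
    when the DC term was not removed, since it would add an isotropic
    constant to every orientation.
    """
    if not spec.origin_centered:
        raise InvalidInputError("angular_power requires an origin-centered spectrum")
    if n_thetas < 8:
        raise InvalidParameterError("need at least 8 orientations")
    if interpolation not in ("linear", "nearest"):
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0

    mag = spec.magnitude
    h, w = mag.shape
    cy, cx = h // 2, w // 2  # fftshift origin
    radius = min(cy, cx, h - 1 - cy, w - 1 - cx)
    t = np.arange(-radius, radius + 1, dtype=float)
    if not spec.dc_removed:
        t = t[t != 0]

    thetas = np.linspace(0.0, math.pi, n_thetas, endpoint=False)
    power = np.empty(n_thetas)
    for i, th in enumerate(thetas):
        rows = cy + t * math.sin(th)
        cols = cx + t * math.cos(th)
        samples = ndimage.map_coordinates(mag, [rows, cols], order=order, mode="constant")
        power[i] = samples.sum()
    return PolarPower(thetas_rad=thetas, power=power, dc_removed=spec.dc_removed)


def alignment_index(pp: PolarPower) -> AlignmentResult:
    """Eigenvalue anisotropy of the angular power distribution.

    Rows (F_I cos theta, F_I sin theta) form an n x 2 matrix C; the
    eigenvalues lambda1 >= lambda2 of C^T C give
    alpha = 1 - lambda2/lambda1.  A delta distribution yields alpha = 1;
    a uniform distribution over evenly spaced orientations yields
    alpha = 0 (the off-diagonal sums cancel exactly).
    """
    f = pp.power
    if not np.all(np.isfinite(f)):
        raise InvalidInputError("angular power contains non-finite values")
    c = np.column_stack([f * np.cos(pp.thetas_rad), f * np.sin(pp.thetas_rad)])
    second_moment = c.T @ c
    evals, evecs = np.linalg.eigh(second_moment)
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam1 <= 0:
        raise UndefinedAlignmentError("all-zero angular power: alignment undefined")
    lam2 = max(lam2, 0.0)  # clip tiny negative round-off
    alpha = 1.0 - lam2 / lam1
    v = evecs[:, 1]
    principal = math.atan2(v[1], v[0]) % math.pi
    # spectral power concentrates perpendicular to the fiber axis
    fiber_orientation = (principal + math.pi / 2) % math.pi
    return AlignmentResult(
        lambda1=lam1, lambda2=lam2, alpha=alpha,
        principal_orientation_rad=principal, fiber_orientation_rad=fiber_orientation,
    )


def alignment_from_image(
    img: Image, n_thetas: int = 180, dc_remove: bool = True,
    interpolation: str = "linear",
) -> AlignmentResult:
    """Convenience composition: DFT magnitude -> angular power -> alpha."""
    spec = ft_magnitude(img, dc_remove=dc_remove)
    pp = angular_power(spec, n_thetas=n_thetas, interpolation=interpolation)
    return alignment_index(pp)


# ---------------------------------------------------------------------------
# composed analysis
# ---------------------------------------------------------------------------

@dataclass
class MicrostructureConfig:
    """Parameters of the composed microstructure analysis.

    ``crop_um`` selects the central square analyzed extent (61 um for the
    targeted confocal settings); ``alignment_source`` chooses whether the
    DFT sees the binary mask (default) or the normalized image.
    """

    mask_size: int = 5
    n_orientations: int = 15
    gaussian_sd: float = 0.7
    threshold_method: str = "otsu"
    threshold_value: float = 0.0
    max_radius_px: int = 30
    n_thetas: int = 180
    dc_remove: bool = True
    radon_interpolation: str = "linear"
    crop_um: Optional[float] = 61.0
    alignment_source: str = "binary"

    def __post_init__(self) -> None:
        if self.alignment_source not in ("binary", "normalized"):
            raise InvalidParameterError(
                f"alignment_source must be binary|normalized, got {self.alignment_source!r}"
            )


@dataclass
class MicrostructureReport:
    """Joint pore-size and alignment measurement of one image."""

    pore: PoreSizeSpectrum
    alignment: AlignmentResult
    stages: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Flat JSON-serializable summary of the measurement."""
        return {
            "mean_pore_radius_px": self.pore.mean_radius_px,
            "mean_pore_diameter_um": self.pore.mean_diameter_um,
            "pore_near_resolution_limit": self.pore.near_resolution_limit,
            "pore_spectrum_truncated": self.pore.truncated,
            "alpha": self.alignment.alpha,
            "lambda1": self.alignment.lambda1,
            "lambda2": self.alignment.lambda2,
            "principal_orientation_deg": math.degrees(self.alignment.principal_orientation_rad),
            "fiber_orientation_deg": math.degrees(self.alignment.fiber_orientation_rad),
            "parameters": self.parameters,
        }


def analyze_microstructure(
    img: Image, config: MicrostructureConfig | None = None
) -> MicrostructureReport:
    """Full measurement of one raw image: preprocess, pore spectrum, alignment."""
    config = config or MicrostructureConfig()
    if config.crop_um is not None:
        img = central_crop(img, config.crop_um)
    try:
        stages = preprocess_chain(
            img, mask_size=config.mask_size, n_orientations=config.n_orientations,
            gaussian_sd=config.gaussian_sd,
            threshold=ThresholdSpec(config.threshold_method, config.threshold_value),
        )
    except Exception as exc:  # annotate where the chain failed
        raise type(exc)(f"preprocess stage failed: {exc}") from exc

    max_r = min(config.max_radius_px, min(stages["binary"].shape) // 2)
    pore = pore_spectrum(stages["binary"], max_r)
    source = stages[config.alignment_source]
    alignment = alignment_from_image(
        source, n_thetas=config.n_thetas, dc_remove=config.dc_remove,
        interpolation=config.radon_interpolation,
    )
    params = {
        "mask_size": config.mask_size, "n_orientations": config.n_orientations,
        "gaussian_sd": config.gaussian_sd,
        "threshold": stages["binary"].meta.get("threshold"),
        "threshold_method": config.threshold_method,
        "max_radius_px": int(max_r), "n_thetas": config.n_thetas,
        "dc_remove": config.dc_remove, "crop_um": config.crop_um,
        "alignment_source": config.alignment_source,
        "pixel_size_um": img.pixel_size_um,
    }
    return MicrostructureReport(pore=pore, alignment=alignment, stages=stages, parameters=params)
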