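"""Image container used throughout the preprocessing chain.

A reflection-confocal frame passes through five stages: the raw intensity
image, the estimated interference background, the background-normalized
image, the fiber-enhanced image, and the thresholded binary fiber mask.
Each stage keeps the physical pixel size so downstream pore sizes can be
reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidInputError

#: Valid processing-stage tags, in pipeline order.
STAGES = ("raw", "background", "normalized", "enhanced", "binary")


@dataclass
class Image:
    """A single-channel 2D image with physical pixel size.

    Parameters
    ----------
    values
        2D float array of nonnegative intensities (binary stage: {0, 1}).
    pixel_size_um
        Physical size of one pixel in micrometres (0.20 um/px for the
        confocal settings this pipeline targets).
    stage
        Which processing stage the image represents; one of
        ``raw | background | normalized | enhanced | binary``.
    meta
        Free-form provenance (threshold used, filter-bank parameters, ...).
    """

    values: np.ndarray
    pixel_size_um: float = 1.0
    stage: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(
                f"expected a 2D single-channel image, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("image contains non-finite values")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise InvalidInputError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "binary":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise InvalidInputError("binary-stage image must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, stage: str, **meta: Any) -> "Image":
        """Derive a new stage image, preserving pixel size and provenance."""
        merged = dict(self.meta)
        merged.update(meta)
        return Image(values=values, pixel_size_um=self.pixel_size_um, stage=stage, meta=merged)


def central_crop(img: Image, crop_um: float) -> Image:
    """Centrally crop to a square of side ``crop_um`` micrometres.

    If the requested extent meets or exceeds the image, the image is
    returned unchanged (no padding is ever applied).
    """
    side_px = int(round(crop_um / img.pixel_size_um))
    h, w = img.shape
    if side_px <= 0:
        raise InvalidInputError(f"crop_um={crop_um} yields a non-positive crop")
    if side_px >= min(h, w):
        return img
    r0 = (h - side_px) // 2
    c0 = (w - side_px) // 2
    cropped = img.values[r0 : r0 + side_px, c0 : c0 + side_px]
    return img.with_values(cropped, stage=img.stage, crop_um=crop_um)
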