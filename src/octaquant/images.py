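"""Core image containers for en-face OCT angiography slabs.

An en-face slab is a square grayscale projection of a depth-segmented
retinal or choroidal layer (superficial capillary plexus, deep capillary
plexus, avascular outer retina, or choriocapillaris).  Pixels are stored
as floats on the 8-bit [0, 255] scale so that intermediate processing
(contrast stretching, artifact rescaling) does not accumulate rounding
error; images are rounded to uint8 only on disk I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np

SLAB_KINDS = ("SCP", "DCP", "avascular", "CC")


@dataclass
class EnFaceImage:
    """One grayscale en-face slab with physical calibration.

    Parameters
    ----------
    pixels
        2-D float array, square, intensities in [0, 255].
    extent_mm
        Physical side length of the field of view (3.0 or 6.0 mm for
        the macular scan patterns modelled here).
    slab_kind
        One of ``SCP``, ``DCP``, ``avascular``, ``CC``.
    """

    pixels: np.ndarray
    extent_mm: float
    slab_kind: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("en-face slab must be a square 2-D grid")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if self.slab_kind not in SLAB_KINDS:
            raise ValueError(f"slab_kind must be one of {SLAB_KINDS}")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 255 + 1e-9:
            raise ValueError("intensities must lie within [0, 255]")

    @property
    def grid_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def mm_per_px(self) -> float:
        return self.extent_mm / self.grid_px

    @property
    def area_mm2(self) -> float:
        return self.extent_mm**2

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Copy of this image with new pixel data, metadata unchanged."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))

    def save(self, path: str | Path) -> None:
        iio.imwrite(Path(path), np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8))

    @classmethod
    def load(cls, path: str | Path, extent_mm: float, slab_kind: str) -> "EnFaceImage":
        arr = np.asarray(iio.imread(Path(path)))
        if arr.ndim == 3:  # tolerate grayscale saved with redundant channels
            arr = arr[..., 0]
        return cls(pixels=arr.astype(np.float64), extent_mm=extent_mm, slab_kind=slab_kind)


@dataclass
class ScanRecord:
    """One acquisition: a set of en-face slabs plus scan metadata.

    ``scan_index`` distinguishes the two back-to-back same-visit scans
    (1 and 2).  ``signal_strength`` is the device-reported 0-10 quality
    score; ``motion_score`` is a quantitative horizontal-artifact proxy
    (fraction of decorrelated adjacent row pairs).
    """

    subject_id: str
    eye: str = "OD"
    visit_id: str = "V1"
    scan_index: int = 1
    signal_strength: int = 10
    motion_score: float = 0.0
    slabs: Mapping[str, EnFaceImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scan_index not in (1, 2):
            raise ValueError("scan_index must be 1 or 2")
        if not 0 <= self.signal_strength <= 10:
            raise ValueError("signal_strength must lie in [0, 10]")
        if self.motion_score < 0:
            raise ValueError("motion_score must be >= 0")

    def slab(self, kind: str) -> EnFaceImage:
        try:
            return self.slabs[kind]
        except KeyError:
            raise KeyError(
                f"scan {self.subject_id}/{self.scan_index} has no {kind} slab"
            ) from None
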