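"""Choriocapillaris flow-void quantification on 6x6-mm slabs.

Pipeline per scan pair: standardize each slab; binarize the superficial
plexus (SCP) slab and use it as an overlay to suppress projection
artifacts in the choriocapillaris (CC) slab; align the two same-visit
CC slabs by integer translation; crop both to the overlapping area;
derive the flow-deficit intensity threshold T = mean + 1.96*SD from the
scan's own (cropped, standardized) avascular slab; count CC pixels at
or below T as flow void and convert to mm².

Projection artifacts are decorrelation tails of superficial vessels
that darken the CC slab along the SCP vascular pattern and would be
falsely read as flow deficits; the overlay step rescales the intensity
of artifact-flagged pixels so their mean matches the unflagged pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .images import EnFaceImage, ScanRecord
from .preprocessing import contrast_stretch
from .vessel_metrics import binarize_otsu


class ArtifactRemovalWarning(UserWarning):
    """Overlay mask was trivial (all or none); CC slab returned unchanged."""


class AlignmentError(RuntimeError):
    """Best translation leaves less than 25% of the image area overlapping."""


def binarize_scp_for_overlay(scp: EnFaceImage) -> np.ndarray:
    """Binarize a standardized SCP slab for artifact overlay (Otsu, bright=vessel)."""
    return binarize_otsu(scp)


def remove_projection_artifacts(cc: EnFaceImage, scp_mask: np.ndarray) -> EnFaceImage:
    """Raise artifact-region intensities to neutralize superficial-vessel shadows.

    Pixels flagged by the SCP overlay are linearly rescaled so that
    their mean equals the mean of the unflagged pixels (the affine map
    also matches the unflagged SD, so the correction neither inflates
    nor crushes the local intensity spread whatever gain the
    standardization applied); unflagged pixels are untouched; output
    is clipped to [0, 255].  A trivial mask (all-true or all-false)
    leaves the slab unchanged with an :class:`ArtifactRemovalWarning`.
    """
    if scp_mask.shape != cc.pixels.shape:
        raise ValueError("CC slab and SCP mask must share dimensions")
    n_true = int(np.count_nonzero(scp_mask))
    if n_true == 0 or n_true == scp_mask.size:
        warnings.warn(
            "trivial overlay mask; projection-artifact removal skipped",
            ArtifactRemovalWarning,
            stacklevel=2,
        )
        return cc
    px = cc.pixels.copy()
    art, rest = px[scp_mask], px[~scp_mask]
    scale = rest.std() / art.std() if art.std() > 0 else 0.0
    px[scp_mask] = rest.mean() + (art - art.mean()) * scale
    return cc.with_pixels(np.clip(px, 0.0, 255.0))


def _rect_sum(cum: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
    return cum[r1, c1] - cum[r0, c1] - cum[r1, c0] + cum[r0, c0]


def _overlap_slices(h: int, w: int, dy: int, dx: int):
    """Index bounds of the overlap in image-1 and image-2 coordinates."""
    r0a, r1a = max(0, -dy), h + min(0, -dy)
    c0a, c1a = max(0, -dx), w + min(0, -dx)
    r0b, r1b = max(0, dy), h + min(0, dy)
    c0b, c1b = max(0, dx), w + min(0, dx)
    return (r0a, r1a, c0a, c1a), (r0b, r1b, c0b, c1b)


def register_translation(
    img1: EnFaceImage, img2: EnFaceImage, max_shift_px: int | None = None
) -> tuple[int, int]:
    """Integer translation (dx, dy) of img2 relative to img1.

    Exhaustive search over all shifts with |dx|, |dy| <= max_shift_px
    for the one maximizing the normalized cross-correlation over the
    overlap region; the cross-term is evaluated by FFT correlation and
    the per-shift overlap statistics by integral images, which is
    algebraically identical to the naive per-shift computation.  Ties
    are broken by smallest |dx|+|dy|, then lexicographically on
    (dx, dy).  Shifts whose overlap has zero variance in either image
    are not candidates; if no shift is a candidate (e.g. constant
    images) the tie-break answer (0, 0) is returned.

    ``max_shift_px`` defaults to grid_px // 10, a generous bound for
    same-visit scans without repositioning.
    """
    a, b = img1.pixels, img2.pixels
    if a.shape != b.shape:
        raise ValueError("images must share dimensions")
    h, w = a.shape
    m = h // 10 if max_shift_px is None else int(max_shift_px)
    if m < 0:
        raise ValueError("max_shift_px must be >= 0")
    m = min(m, h - 1)

    # cross-correlation sums S12(dy, dx) for every lag, via FFT
    xcorr = signal.correlate(b, a, mode="full", method="fft")

    cum1 = np.zeros((h + 1, w + 1))
    cum1[1:, 1:] = a.cumsum(0).cumsum(1)
    cum1_sq = np.zeros((h + 1, w + 1))
    cum1_sq[1:, 1:] = (a**2).cumsum(0).cumsum(1)
    cum2 = np.zeros((h + 1, w + 1))
    cum2[1:, 1:] = b.cumsum(0).cumsum(1)
    cum2_sq = np.zeros((h + 1, w + 1))
    cum2_sq[1:, 1:] = (b**2).cumsum(0).cumsum(1)

    shifts = [(dx, dy) for dy in range(-m, m + 1) for dx in range(-m, m + 1)]
    shifts.sort(key=lambda s: (abs(s[0]) + abs(s[1]), s))

    best: tuple[int, int] | None = None
    best_ncc = -np.inf
    tol = 1e-9
    for dx, dy in shifts:
        (r0a, r1a, c0a, c1a), (r0b, r1b, c0b, c1b) = _overlap_slices(h, w, dy, dx)
        n = (r1a - r0a) * (c1a - c0a)
        if n <= 1:
            continue
        s1 = _rect_sum(cum1, r0a, r1a, c0a, c1a)
        s11 = _rect_sum(cum1_sq, r0a, r1a, c0a, c1a)
        s2 = _rect_sum(cum2, r0b, r1b, c0b, c1b)
        s22 = _rect_sum(cum2_sq, r0b, r1b, c0b, c1b)
        s12 = xcorr[h - 1 + dy, w - 1 + dx]
        var1 = s11 - s1 * s1 / n
        var2 = s22 - s2 * s2 / n
        if var1 <= tol or var2 <= tol:
            continue
        ncc = (s12 - s1 * s2 / n) / np.sqrt(var1 * var2)
        if ncc > best_ncc + tol:  # ties keep the earlier, preferred shift
            best_ncc = ncc
            best = (dx, dy)
    if best is None:
        return (0, 0)
    dx, dy = best
    if (h - abs(dy)) * (w - abs(dx)) < 0.25 * h * w:
        raise AlignmentError("best shift leaves under 25% of the image overlapping")
    return best


@dataclass
class AlignedPair:
    """Two same-visit slabs cropped to their common field of view."""

    image1: EnFaceImage
    image2: EnFaceImage
    offset_px: tuple[int, int]

    @property
    def analyzed_area_mm2(self) -> float:
        h, w = self.image1.pixels.shape
        return h * w * self.image1.mm_per_px**2


def _crop_arrays(a: np.ndarray, b: np.ndarray, offset: tuple[int, int]):
    dx, dy = offset
    h, w = a.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError("offset leaves no overlap")
    (r0a, r1a, c0a, c1a), (r0b, r1b, c0b, c1b) = _overlap_slices(h, w, dy, dx)
    return a[r0a:r1a, c0a:c1a], b[r0b:r1b, c0b:c1b]


def crop_to_overlap(
    img1: EnFaceImage, img2: EnFaceImage, offset: tuple[int, int]
) -> AlignedPair:
    """Crop both images to the area both scans cover, given img2's offset.

    For an offset (dx, dy) the outputs are (grid-|dy|) x (grid-|dx|)
    and corresponding pixels sample the same retinal location.  The
    physical pixel footprint (mm/px) is unchanged; the analyzed area
    shrinks with the crop.
    """
    ca, cb = _crop_arrays(img1.pixels, img2.pixels, offset)
    # acquisition slabs are square; cropped working images may be
    # rectangular, so they are built without the square-grid invariant
    out1 = _cropped_image(img1, ca)
    out2 = _cropped_image(img2, cb)
    return AlignedPair(image1=out1, image2=out2, offset_px=tuple(offset))


class _CroppedImage(EnFaceImage):
    """Rectangular working image produced by overlap cropping."""

    def __post_init__(self) -> None:  # relax the square-grid invariant only
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")

    @property
    def mm_per_px(self) -> float:
        return self._mm_per_px

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * self._mm_per_px**2


def _cropped_image(src: EnFaceImage, arr: np.ndarray) -> _CroppedImage:
    out = _CroppedImage(pixels=arr, extent_mm=src.extent_mm, slab_kind=src.slab_kind)
    out._mm_per_px = src.mm_per_px
    return out


def flow_void_threshold(avascular: EnFaceImage) -> float:
    """Flow-deficit threshold T = mean + 1.96*SD of the avascular slab.

    The avascular outer-retina slab images a layer with no flow, so its
    intensity distribution characterizes the no-flow signal; T marks
    the upper 97.5% bound of that distribution.  The SD is the
    population form over all pixels.
    """
    px = avascular.pixels
    return float(px.mean() + 1.96 * px.std())


@dataclass
class FlowVoidResult:
    """Flow-void measurement: threshold, mask, void and analyzed areas (mm²)."""

    threshold_T: float
    void_mask: np.ndarray
    void_area_mm2: float
    analyzed_area_mm2: float

    @property
    def void_fraction(self) -> float:
        return self.void_area_mm2 / self.analyzed_area_mm2


def measure_flow_void(
    cc: EnFaceImage, threshold_T: float, mm_per_px: float | None = None
) -> FlowVoidResult:
    """Count CC pixels at or below T (inclusive) and convert to mm².

    No minimum-region-size filtering is applied: the result is the
    total flow-void area.
    """
    mmpp = cc.mm_per_px if mm_per_px is None else mm_per_px
    mask = cc.pixels <= threshold_T
    area = float(np.count_nonzero(mask)) * mmpp**2
    h, w = cc.pixels.shape
    return FlowVoidResult(
        threshold_T=float(threshold_T),
        void_mask=mask,
        void_area_mm2=area,
        analyzed_area_mm2=h * w * mmpp**2,
    )


def _prepare_cc(scan: ScanRecord, artifact_removal: bool) -> EnFaceImage:
    """Standardize the CC slab and suppress projection artifacts via SCP overlay."""
    cc = contrast_stretch(scan.slab("CC"))
    if artifact_removal:
        scp = contrast_stretch(scan.slab("SCP"))
        cc = remove_projection_artifacts(cc, binarize_scp_for_overlay(scp))
    return cc


def measure_cc_scan(scan: ScanRecord, artifact_removal: bool = True) -> FlowVoidResult:
    """Single-scan flow-void measurement (no pair alignment).

    Standardize -> SCP overlay artifact removal -> avascular-slab
    threshold -> flow-void count, on the full uncropped field.
    """
    cc = _prepare_cc(scan, artifact_removal)
    avas = contrast_stretch(scan.slab("avascular"))
    t = flow_void_threshold(avas)
    return measure_flow_void(cc, t)


def ccfv_pipeline(
    scan1: ScanRecord,
    scan2: ScanRecord,
    max_shift_px: int | None = None,
    artifact_removal: bool = True,
) -> tuple[FlowVoidResult, FlowVoidResult]:
    """Paired same-visit choriocapillaris flow-void pipeline.

    Runs standardization, SCP-overlay artifact removal, translation
    registration of the two CC slabs, cropping of CC and avascular
    slabs to the overlap, per-scan thresholding from the scan's own
    cropped avascular slab, and flow-void measurement.  Both results
    share the analyzed (overlap) area.
    """
    cc1 = _prepare_cc(scan1, artifact_removal)
    cc2 = _prepare_cc(scan2, artifact_removal)
    offset = register_translation(cc1, cc2, max_shift_px)
    pair = crop_to_overlap(cc1, cc2, offset)

    av1 = contrast_stretch(scan1.slab("avascular"))
    av2 = contrast_stretch(scan2.slab("avascular"))
    av1c, av2c = _crop_arrays(av1.pixels, av2.pixels, offset)

    t1 = float(av1c.mean() + 1.96 * av1c.std())
    t2 = float(av2c.mean() + 1.96 * av2c.std())
    r1 = measure_flow_void(pair.image1, t1)
    r2 = measure_flow_void(pair.image2, t2)
    return r1, r2
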