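"""Image standardization and quality-control gating.

Both quantification pipelines (choriocapillaris flow voids, plexus
vessel metrics) start from the same standardization step: brightness
histogram contrast stretching, using a centered square covering 50% of
the image side as the reference region.  The linear map sends the
reference square's 1st and 99th intensity percentiles to 0 and 255 and
clips; this makes images acquired at different overall brightness
comparable without assuming a particular intensity distribution.

Quality control excludes scans with device signal strength below 7/10
or with a motion score above a configurable threshold; the motion score
is a horizontal-artifact proxy (fraction of adjacent row pairs whose
Pearson correlation falls below a cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .images import EnFaceImage, ScanRecord

#: reference percentiles for the stretch map
P_LO = 1.0
P_HI = 99.0

#: device signal-strength floor for inclusion (scans < 7/10 are excluded)
MIN_SIGNAL_STRENGTH = 7


class DegenerateStandardizationWarning(UserWarning):
    """Central reference square has no intensity spread; image left unchanged."""


def central_square(pixels: np.ndarray) -> np.ndarray:
    """Centered square covering half the image side, used as stretch reference."""
    n = pixels.shape[0]
    if n < 4:
        raise ValueError("image too small for a central reference square")
    side = n // 2
    start = (n - side) // 2
    return pixels[start : start + side, start : start + side]


def contrast_stretch(image: EnFaceImage) -> EnFaceImage:
    """Standardize brightness by percentile contrast stretching.

    The affine map ``a*x + b`` is chosen so the central square's
    (1st, 99th) percentiles map to (0, 255); output is clipped to
    [0, 255].  A constant (zero-spread) reference square triggers a
    :class:`DegenerateStandardizationWarning` and the image is returned
    unchanged.
    """
    ref = central_square(image.pixels)
    lo, hi = np.percentile(ref, [P_LO, P_HI])
    if hi - lo <= 0:
        warnings.warn(
            "central reference square has zero intensity spread; "
            "standardization skipped",
            DegenerateStandardizationWarning,
            stacklevel=2,
        )
        return image
    a = 255.0 / (hi - lo)
    stretched = np.clip((image.pixels - lo) * a, 0.0, 255.0)
    return image.with_pixels(stretched)


def motion_score(image: EnFaceImage, corr_cutoff: float = 0.2) -> float:
    """Fraction of adjacent-row pairs with Pearson correlation below cutoff.

    Horizontal motion artifacts in en-face angiograms appear as rows
    decorrelated from their neighbours; this score counts them.  Rows
    with zero variance are treated as decorrelated unless both rows of
    the pair are constant and equal.
    """
    px = image.pixels
    a, b = px[:-1], px[1:]
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    num = (am * bm).sum(axis=1)
    den = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    flat_pair = (np.abs(am).max(axis=1) == 0) & (np.abs(bm).max(axis=1) == 0)
    equal_rows = np.all(a == b, axis=1)
    bad = np.where(np.isnan(r), ~(flat_pair & equal_rows), r < corr_cutoff)
    return float(bad.mean())


@dataclass
class QCDecision:
    """Inclusion decision for one scan; ``included`` iff no reasons."""

    included: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must be true iff reasons is empty")


def qc_assess(
    record: ScanRecord,
    motion_threshold: float = 0.1,
    floater_flag: bool = False,
) -> QCDecision:
    """Apply the exclusion rules to one scan.

    Scans with signal strength below 7/10 are excluded (``low_signal``);
    scans whose motion score exceeds ``motion_threshold`` are excluded
    (``motion_artifact``); a manual floater flag from the cohort
    manifest excludes with ``floater``.  Reasons may co-occur.
    """
    if record.signal_strength is None or record.motion_score is None:
        raise ValueError("scan record lacks signal_strength or motion_score")
    reasons: list[str] = []
    if record.signal_strength < MIN_SIGNAL_STRENGTH:
        reasons.append("low_signal")
    if record.motion_score > motion_threshold:
        reasons.append("motion_artifact")
    if floater_flag:
        reasons.append("floater")
    return QCDecision(included=not reasons, reasons=reasons)


def quality_difference_correlation(
    abs_diffs: np.ndarray, quality_metric: np.ndarray
) -> float:
    """Squared Pearson correlation between |paired difference| and a quality metric.

    Used as a screen for whether scan quality (signal strength, motion)
    drives test-retest differences; returns r² in [0, 1].
    """
    d = np.asarray(abs_diffs, dtype=float)
    q = np.asarray(quality_metric, dtype=float)
    if d.shape != q.shape or d.ndim != 1 or d.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(d) == 0 or np.ptp(q) == 0:
        raise ValueError("inputs must have nonzero variance")
    r = stats.pearsonr(d, q).statistic
    return float(r * r)
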