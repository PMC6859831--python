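"""Synthetic en-face angiography cohorts with known ground truth.

No image data are distributed with this package, so every downstream
stage (standardization, binarization, artifact removal, registration,
flow-void and vessel quantification, repeatability statistics) is
exercised on simulated cohorts that emulate the acquisition protocol:
each subject contributes two back-to-back same-visit scans without
repositioning, so the second scan images the same scene under a small
translation with fresh noise.

The generator controls, per subject, a true value of each quantitative
index (choriocapillaris flow-void fraction, plexus vessel density, FAZ
area) drawn with a stated between-subject SD, and realizes a per-scan
measurement error with a stated within-subject SD *through the image
construction itself* (toggling void/vessel pixels between the two
scans), so the cohort's true intraclass correlation
``between² / (between² + within²)`` is known exactly.

Scene construction uses rank-thresholded smoothed noise fields plus
drawn branching curves: the same score field thresholded at different
quantiles yields nested pixel sets, so changing the target fraction
perturbs rather than replaces the spatial pattern, and the two scans
of a pair stay spatially correlated (a prerequisite for meaningful
registration).  All randomness descends from one integer seed through
per-subject spawned streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .images import EnFaceImage, ScanRecord
from .repeatability import PairedMeasurements

# rendering levels (8-bit intensity units) for clean synthetic slabs
VESSEL_LEVEL = 200.0
BACKGROUND_LEVEL = 40.0
CC_FLOW_LEVEL = 180.0
CC_DEFICIT_LEVEL = 50.0
AVASCULAR_BASE_LEVEL = 50.0
AVASCULAR_SPECK_LEVEL = 180.0
AVASCULAR_SPECK_FRACTION = 0.08


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the published uveitis cohort summary: 85 subjects,
    choriocapillaris flow-void area mean 1.16 mm² [SD 1.88] on the
    36 mm² slab and repeatability coefficient 0.401 mm², converted to
    fractions of the analyzed area (mean 0.0322, between-subject SD
    0.0522, within-subject SD 0.401/1.96/sqrt(2)/36 = 0.0040).  The
    between-subject draw is truncated to keep fractions physical.
    """

    n_subjects: int = 85
    grid_px: int = 512
    cc_extent_mm: float = 6.0
    vessel_extent_mm: float = 3.0
    mean_index: float = 0.0322
    between_subject_sd: float = 0.0522
    within_subject_sd: float = 0.0040
    noise_sd: float = 5.0
    max_shift_px: int = 8
    seed: int = 0
    index_bounds: tuple[float, float] = (0.002, 0.6)
    artifact_depth: float = 60.0
    scp_overlay_density: float = 0.30
    scp_vd_mean: float = 0.324
    scp_vd_between_sd: float = 0.0737
    scp_vd_within_sd: float = 0.0225
    dcp_vd_mean: float = 0.407
    dcp_vd_between_sd: float = 0.0744
    dcp_vd_within_sd: float = 0.0308
    scp_faz_mean_mm2: float = 0.412
    scp_faz_sd_mm2: float = 0.252
    dcp_faz_mean_mm2: float = 0.741
    dcp_faz_sd_mm2: float = 0.214

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.grid_px < 64:
            raise ValueError("grid_px must be >= 64")
        if self.cc_extent_mm <= 0 or self.vessel_extent_mm <= 0:
            raise ValueError("physical extents must be positive")
        for sd in (self.between_subject_sd, self.within_subject_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.max_shift_px < self.grid_px / 4:
            raise ValueError("max_shift_px must lie in [0, grid_px/4)")

    @property
    def true_icc(self) -> float:
        """Ground-truth ICC = between² / (between² + within²)."""
        b2 = self.between_subject_sd**2
        w2 = self.within_subject_sd**2
        if b2 + w2 == 0:
            return 1.0
        return b2 / (b2 + w2)


@dataclass
class GroundTruth:
    """Known truth for generated scenes.

    For a single generated object the scalar fields apply; for a
    cohort the per-subject maps carry the drawn true index values and
    per-scan realized values, and ``true_icc`` the variance-ratio ICC
    implied by the configured SDs.
    """

    vessel_mask: np.ndarray | None = None
    faz_area_mm2: float | None = None
    void_fraction: float | None = None
    void_mask: np.ndarray | None = None
    true_index_per_subject: dict[str, float] = field(default_factory=dict)
    per_scan_index: dict[tuple[str, int], float] = field(default_factory=dict)
    per_subject_truth: dict[str, dict[str, float]] = field(default_factory=dict)
    true_icc: float | None = None


# ---------------------------------------------------------------------------
# scene primitives


def _branch_curves(rng: np.random.Generator, n: int, n_seeds: int = 5) -> np.ndarray:
    """Draw a few branching vessel-like curves from the image margins inward."""
    canvas = np.zeros((n, n), dtype=bool)
    stack: list[tuple[float, float, float, float, int]] = []
    for _ in range(n_seeds):
        side = rng.integers(4)
        t = rng.uniform(0.1, 0.9) * n
        if side == 0:
            y, x, ang = 0.0, t, math.pi / 2
        elif side == 1:
            y, x, ang = float(n - 1), t, -math.pi / 2
        elif side == 2:
            y, x, ang = t, 0.0, 0.0
        else:
            y, x, ang = t, float(n - 1), math.pi
        stack.append((y, x, ang + rng.normal(0, 0.3), n / 180.0 + 1.5, 0))
    while stack:
        y, x, ang, width, depth = stack.pop()
        for _ in range(int(rng.integers(n // 8, n // 3))):
            rr, cc = draw_disk((y, x), max(1.0, width), shape=canvas.shape)
            canvas[rr, cc] = True
            ang += rng.normal(0, 0.18)
            y += 2.0 * math.sin(ang)
            x += 2.0 * math.cos(ang)
            if not (0 <= y < n and 0 <= x < n):
                break
            if depth < 3 and rng.random() < 0.03:
                stack.append((y, x, ang + rng.choice([-1, 1]) * rng.uniform(0.5, 1.0),
                              width * 0.7, depth + 1))
    return canvas


def _rank_select(score: np.ndarray, allowed: np.ndarray, count: int) -> np.ndarray:
    """Boolean mask of the ``count`` highest-scoring allowed pixels."""
    mask = np.zeros(score.shape, dtype=bool)
    if count <= 0:
        return mask
    flat_idx = np.flatnonzero(allowed.ravel())
    if count > flat_idx.size:
        raise ValueError("requested density exceeds available (non-FAZ) pixels")
    order = np.argsort(score.ravel()[flat_idx], kind="stable")[::-1]
    mask.ravel()[flat_idx[order[:count]]] = True
    return mask


def _faz_disc(grid_px: int, faz_radius_mm: float, extent_mm: float) -> np.ndarray:
    c = (grid_px - 1) / 2.0
    r_px = faz_radius_mm * grid_px / extent_mm
    yy, xx = np.ogrid[:grid_px, :grid_px]
    return (yy - c) ** 2 + (xx - c) ** 2 < r_px**2


def _ring_boost(
    score: np.ndarray, grid_px: int, faz_radius_mm: float, extent_mm: float, count: int
) -> np.ndarray:
    """Boost the score on a thin annulus just outside the avascular disc.

    The FAZ is bounded in vivo by a perifoveal anastomotic capillary
    arcade; boosting the annulus makes it fill first during rank
    selection, so seeded flood-fill delineation sees a closed border.
    """
    if faz_radius_mm <= 0 or count <= 0:
        return score
    c = (grid_px - 1) / 2.0
    r_px = faz_radius_mm * grid_px / extent_mm
    yy, xx = np.ogrid[:grid_px, :grid_px]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    ring = (d2 >= r_px**2) & (d2 < (r_px + 2.0) ** 2)
    if ring.sum() <= count:
        score = score + 100.0 * ring
    return score


def _vessel_score(rng: np.random.Generator, grid_px: int) -> np.ndarray:
    noise = rng.standard_normal((grid_px, grid_px))
    band = gaussian_filter(noise, 1.0) - gaussian_filter(noise, 4.0)
    band = band / max(band.std(), 1e-12)
    return band + 10.0 * _branch_curves(rng, grid_px)


def generate_vessel_network(
    grid_px: int,
    target_density: float,
    faz_radius_mm: float,
    extent_mm: float,
    seed: int,
) -> tuple[np.ndarray, GroundTruth]:
    """Binary vessel network at a controlled pixel density with a central FAZ.

    A band-pass spatial noise field (capillary texture) plus drawn
    branching curves (larger vessels) is rank-thresholded so that
    exactly ``round(target_density * grid_px²)`` pixels are vessel;
    no vessel pixel falls inside the central avascular disc of radius
    ``faz_radius_mm``.  Deterministic for a fixed seed.
    """
    if not 0 <= target_density <= 0.9:
        raise ValueError("target_density must lie in [0, 0.9]")
    if faz_radius_mm < 0 or faz_radius_mm >= extent_mm / 2:
        raise ValueError("faz_radius_mm must lie in [0, extent_mm/2)")
    rng = np.random.default_rng(seed)
    score = _vessel_score(rng, grid_px)
    faz = _faz_disc(grid_px, faz_radius_mm, extent_mm)
    count = round(target_density * grid_px * grid_px)
    score = _ring_boost(score, grid_px, faz_radius_mm, extent_mm, count)
    mask = _rank_select(score, ~faz, count)
    truth = GroundTruth(
        vessel_mask=mask,
        faz_area_mm2=math.pi * faz_radius_mm**2,
    )
    return mask, truth


def render_slab(
    vessel_mask: np.ndarray,
    vessel_level: float = VESSEL_LEVEL,
    background_level: float = BACKGROUND_LEVEL,
    noise_sd: float = 0.0,
    seed: int = 0,
    extent_mm: float = 3.0,
    slab_kind: str = "SCP",
) -> EnFaceImage:
    """Render a binary vessel network as a grayscale en-face slab.

    Vessel pixels are drawn at ``vessel_level`` and background at
    ``background_level``, with independent additive Gaussian noise of
    SD ``noise_sd`` clipped to [0, 255].
    """
    if not 0 <= background_level < vessel_level <= 255:
        raise ValueError("need 0 <= background_level < vessel_level <= 255")
    clean = np.where(vessel_mask, float(vessel_level), float(background_level))
    return EnFaceImage(
        pixels=_add_noise(clean, noise_sd, np.random.default_rng(seed)),
        extent_mm=extent_mm,
        slab_kind=slab_kind,
    )


def _add_noise(clean: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, clean.shape)
    return np.clip(clean, 0.0, 255.0)


def _void_score(rng: np.random.Generator, grid_px: int) -> np.ndarray:
    noise = rng.standard_normal((grid_px, grid_px))
    return gaussian_filter(noise, 2.0)


def _cc_clean(
    void_mask: np.ndarray, scp_mask: np.ndarray | None, artifact_depth: float
) -> np.ndarray:
    clean = np.where(void_mask, CC_DEFICIT_LEVEL, CC_FLOW_LEVEL)
    if scp_mask is not None and artifact_depth > 0:
        clean = clean - artifact_depth * scp_mask
    return np.clip(clean, 0.0, 255.0)


def generate_cc_slab(
    grid_px: int,
    void_fraction: float,
    scp_mask: np.ndarray | None = None,
    artifact_depth: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    extent_mm: float = 6.0,
) -> tuple[EnFaceImage, GroundTruth]:
    """Choriocapillaris slab with a known flow-void pixel set.

    Exactly ``round(void_fraction * grid_px²)`` pixels (contiguous
    blobs from a smoothed random field) are drawn at the flow-deficit
    level, the rest at the flow level.  Pixels under ``scp_mask`` are
    then darkened by ``artifact_depth``, simulating projection
    artifacts of the superficial plexus; the recorded ground-truth
    void set predates artifact injection.
    """
    if not 0 <= void_fraction <= 1:
        raise ValueError("void_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    score = -_void_score(rng, grid_px)  # low field values become voids
    count = round(void_fraction * grid_px * grid_px)
    void_mask = _rank_select(score, np.ones((grid_px, grid_px), bool), count)
    clean = _cc_clean(void_mask, scp_mask, artifact_depth)
    img = EnFaceImage(
        pixels=_add_noise(clean, noise_sd, rng), extent_mm=extent_mm, slab_kind="CC"
    )
    truth = GroundTruth(void_fraction=count / grid_px**2, void_mask=void_mask)
    return img, truth


def generate_avascular_slab(
    grid_px: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    extent_mm: float = 6.0,
    speck_fraction: float = AVASCULAR_SPECK_FRACTION,
) -> EnFaceImage:
    """Avascular outer-retina slab: no-flow background with sparse bright specks.

    The speck mixture gives the slab a realistic upper intensity tail,
    so that after per-image standardization its mean + 1.96·SD lands
    between the deficit and flow levels of the matching CC slab — the
    property the flow-deficit threshold relies on in vivo.
    """
    rng = np.random.default_rng(seed)
    score = gaussian_filter(rng.standard_normal((grid_px, grid_px)), 1.5)
    count = round(speck_fraction * grid_px * grid_px)
    specks = _rank_select(score, np.ones((grid_px, grid_px), bool), count)
    clean = np.where(specks, AVASCULAR_SPECK_LEVEL, AVASCULAR_BASE_LEVEL)
    return EnFaceImage(
        pixels=_add_noise(clean, noise_sd, rng), extent_mm=extent_mm,
        slab_kind="avascular",
    )


# ---------------------------------------------------------------------------
# subjects, pairs, cohorts


@dataclass
class SubjectScene:
    """Clean (noise-free) padded scene for one subject.

    Arrays are padded by ``pad`` pixels on every side so that shifted
    windows of the same scene can be extracted for the two same-visit
    scans.  Per-scan arrays (first axis of length 2) embody the
    within-subject measurement error: the two scans' void/vessel pixel
    sets are nested perturbations of the subject's base set.
    """

    subject_id: str
    grid_px: int
    pad: int
    cc_extent_mm: float
    vessel_extent_mm: float
    cc_clean: np.ndarray          # (2, P, P) CC slab with artifacts applied
    avascular_clean: np.ndarray   # (P, P)
    scp6_clean: np.ndarray        # (P, P) SCP slab rendered at the CC extent
    scp3_clean: np.ndarray        # (2, P, P)
    dcp3_clean: np.ndarray        # (2, P, P)
    true_void_fraction: float
    scan_void_fractions: tuple[float, float]
    faz_scp_mm2: float
    faz_dcp_mm2: float
    scan_scp_vd: tuple[float, float]
    scan_dcp_vd: tuple[float, float]


def _window(arr: np.ndarray, pad: int, n: int, shift: tuple[int, int]) -> np.ndarray:
    """Window of a padded scene seen by a scan shifted by (dx, dy)."""
    dx, dy = shift
    return arr[pad - dy : pad - dy + n, pad - dx : pad - dx + n]


def build_subject_scene(
    subject_id: str,
    config: CohortConfig,
    true_fraction: float,
    scan_fractions: tuple[float, float],
    scp_vd: tuple[float, float],
    dcp_vd: tuple[float, float],
    faz_scp_mm2: float,
    faz_dcp_mm2: float,
    rng: np.random.Generator,
) -> SubjectScene:
    """Construct the padded clean scene realizing the subject's true indices."""
    n = config.grid_px
    pad = config.max_shift_px
    p = n + 2 * pad
    total = p * p

    # choriocapillaris scene: nested void sets from one smoothed field
    void_score = -_void_score(rng, p)
    scp6_mask, _ = generate_vessel_network(
        p, config.scp_overlay_density,
        faz_radius_mm=math.sqrt(faz_scp_mm2 / math.pi),
        extent_mm=config.cc_extent_mm, seed=int(rng.integers(2**31)),
    )
    allowed = np.ones((p, p), bool)
    cc_clean = np.stack([
        _cc_clean(
            _rank_select(void_score, allowed, round(f * total)),
            scp6_mask, config.artifact_depth,
        )
        for f in scan_fractions
    ])
    avascular = generate_avascular_slab(
        p, noise_sd=0.0, seed=int(rng.integers(2**31)), extent_mm=config.cc_extent_mm
    ).pixels
    scp6_clean = np.where(scp6_mask, VESSEL_LEVEL, BACKGROUND_LEVEL)

    # 3x3-mm plexus scenes: nested vessel sets from one score field each
    def plexus(vds: tuple[float, float], faz_mm2: float) -> np.ndarray:
        score = _vessel_score(rng, p)
        r_mm = math.sqrt(faz_mm2 / math.pi)
        faz = _faz_disc(p, r_mm, config.vessel_extent_mm)
        score = _ring_boost(score, p, r_mm, config.vessel_extent_mm,
                            round(min(vds) * total))
        return np.stack([
            np.where(_rank_select(score, ~faz, round(v * total)),
                     VESSEL_LEVEL, BACKGROUND_LEVEL)
            for v in vds
        ])

    return SubjectScene(
        subject_id=subject_id,
        grid_px=n,
        pad=pad,
        cc_extent_mm=config.cc_extent_mm,
        vessel_extent_mm=config.vessel_extent_mm,
        cc_clean=cc_clean,
        avascular_clean=avascular,
        scp6_clean=scp6_clean,
        scp3_clean=plexus(scp_vd, faz_scp_mm2),
        dcp3_clean=plexus(dcp_vd, faz_dcp_mm2),
        true_void_fraction=true_fraction,
        scan_void_fractions=tuple(scan_fractions),
        faz_scp_mm2=faz_scp_mm2,
        faz_dcp_mm2=faz_dcp_mm2,
        scan_scp_vd=tuple(scp_vd),
        scan_dcp_vd=tuple(dcp_vd),
    )


def generate_intravisit_pair(
    scene: SubjectScene,
    shift_px: tuple[int, int],
    noise_sd: float,
    seed: int,
    modality: Literal["cc", "vessel"] = "cc",
    signal_strength: tuple[int, int] = (10, 10),
) -> tuple[ScanRecord, ScanRecord]:
    """Render the two same-visit scans of one subject.

    Scan 2 images the same underlying scene translated by
    ``shift_px = (dx, dy)`` (feature at (x, y) in scan 1 appears at
    (x+dx, y+dy) in scan 2) with fresh additive noise.  ``modality``
    selects the 6x6-mm choriocapillaris acquisition (CC, SCP and
    avascular slabs) or the 3x3-mm plexus acquisition (SCP and DCP).
    """
    dx, dy = shift_px
    if abs(dx) > scene.pad or abs(dy) > scene.pad:
        raise ValueError("shift exceeds the scene's maximum translation bound")
    rng = np.random.default_rng(seed)
    n = scene.grid_px
    records = []
    for scan_idx, shift in ((1, (0, 0)), (2, (dx, dy))):
        j = scan_idx - 1
        if modality == "cc":
            ext = scene.cc_extent_mm
            slabs = {
                "CC": EnFaceImage(
                    _add_noise(_window(scene.cc_clean[j], scene.pad, n, shift), noise_sd, rng),
                    ext, "CC"),
                "SCP": EnFaceImage(
                    _add_noise(_window(scene.scp6_clean, scene.pad, n, shift), noise_sd, rng),
                    ext, "SCP"),
                "avascular": EnFaceImage(
                    _add_noise(_window(scene.avascular_clean, scene.pad, n, shift), noise_sd, rng),
                    ext, "avascular"),
            }
        elif modality == "vessel":
            ext = scene.vessel_extent_mm
            slabs = {
                "SCP": EnFaceImage(
                    _add_noise(_window(scene.scp3_clean[j], scene.pad, n, shift), noise_sd, rng),
                    ext, "SCP"),
                "DCP": EnFaceImage(
                    _add_noise(_window(scene.dcp3_clean[j], scene.pad, n, shift), noise_sd, rng),
                    ext, "DCP"),
            }
        else:
            raise ValueError("modality must be 'cc' or 'vessel'")
        records.append(
            ScanRecord(
                subject_id=scene.subject_id,
                scan_index=scan_idx,
                signal_strength=int(signal_strength[j]),
                slabs=slabs,
            )
        )
    return records[0], records[1]


@dataclass
class Cohort:
    """A generated cohort: per-subject scan pairs plus the ground truth."""

    config: CohortConfig
    cc_pairs: list[tuple[ScanRecord, ScanRecord]]
    vessel_pairs: list[tuple[ScanRecord, ScanRecord]]
    truth: GroundTruth
    scenes: list[SubjectScene]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Normal draw truncated by redrawing (falls back to clipping)."""
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(v, lo, hi))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full paired-scan cohort under the configured conditions.

    Subject i's true flow-void fraction is drawn around the configured
    mean with SD ``between_subject_sd`` (truncated to
    ``index_bounds``); each scan realizes it with an independent error
    of SD ``within_subject_sd`` through the pixel construction.  The
    implied true ICC ``between²/(between²+within²)`` is recorded in
    the ground truth.  Bit-identical for identical config and seed.
    """
    root = np.random.SeedSequence(config.seed)
    truth = GroundTruth(true_icc=config.true_icc)
    cc_pairs, vessel_pairs, scenes = [], [], []
    lo, hi = config.index_bounds
    for i, child in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        sid = f"S{i + 1:03d}"
        f_true = _truncated_normal(rng, config.mean_index, config.between_subject_sd, lo, hi)
        f_scans = tuple(
            float(np.clip(f_true + rng.normal(0, config.within_subject_sd), 0.0, 0.9))
            for _ in range(2)
        )
        scp_vd_true = _truncated_normal(rng, config.scp_vd_mean, config.scp_vd_between_sd, 0.05, 0.8)
        dcp_vd_true = _truncated_normal(rng, config.dcp_vd_mean, config.dcp_vd_between_sd, 0.05, 0.8)
        scp_vd = tuple(
            float(np.clip(scp_vd_true + rng.normal(0, config.scp_vd_within_sd), 0.02, 0.9))
            for _ in range(2)
        )
        dcp_vd = tuple(
            float(np.clip(dcp_vd_true + rng.normal(0, config.dcp_vd_within_sd), 0.02, 0.9))
            for _ in range(2)
        )
        faz_scp = _truncated_normal(rng, config.scp_faz_mean_mm2, config.scp_faz_sd_mm2, 0.02, 2.0)
        faz_dcp = _truncated_normal(rng, config.dcp_faz_mean_mm2, config.dcp_faz_sd_mm2, 0.02, 2.0)

        scene = build_subject_scene(
            sid, config, f_true, f_scans, scp_vd, dcp_vd, faz_scp, faz_dcp, rng
        )
        m = config.max_shift_px
        shift_cc = (int(rng.integers(-m, m + 1)), int(rng.integers(-m, m + 1))) if m else (0, 0)
        shift_v = (int(rng.integers(-m, m + 1)), int(rng.integers(-m, m + 1))) if m else (0, 0)
        cc_pairs.append(generate_intravisit_pair(
            scene, shift_cc, config.noise_sd, int(rng.integers(2**31)), "cc"
        ))
        vessel_pairs.append(generate_intravisit_pair(
            scene, shift_v, config.noise_sd, int(rng.integers(2**31)), "vessel"
        ))
        scenes.append(scene)
        truth.true_index_per_subject[sid] = f_true
        truth.per_scan_index[(sid, 1)] = f_scans[0]
        truth.per_scan_index[(sid, 2)] = f_scans[1]
        truth.per_subject_truth[sid] = {
            "void_fraction": f_true,
            "scp_vd": scp_vd_true,
            "dcp_vd": dcp_vd_true,
            "scp_faz_mm2": faz_scp,
            "dcp_faz_mm2": faz_dcp,
        }
    return Cohort(config=config, cc_pairs=cc_pairs, vessel_pairs=vessel_pairs,
                  truth=truth, scenes=scenes)


def simulate_paired_measurements(
    n_subjects: int,
    mean: float,
    between_subject_sd: float,
    within_subject_sd: float,
    seed: int,
    index_name: str = "index",
) -> tuple[PairedMeasurements, float]:
    """Measurement-level paired cohort with a known true ICC.

    Draws subject true values ~ Normal(mean, between_subject_sd) and
    two measurements per subject with error SD ``within_subject_sd``;
    returns the pairs and the true ICC
    ``between²/(between²+within²)``.  Used for statistical parameter-
    recovery studies where the image pipeline is not under test.
    """
    rng = np.random.default_rng(seed)
    true_vals = rng.normal(mean, between_subject_sd, n_subjects)
    m1 = true_vals + rng.normal(0, within_subject_sd, n_subjects)
    m2 = true_vals + rng.normal(0, within_subject_sd, n_subjects)
    b2, w2 = between_subject_sd**2, within_subject_sd**2
    true_icc = 1.0 if b2 + w2 == 0 else b2 / (b2 + w2)
    pairs = PairedMeasurements(
        subject_ids=[f"S{i + 1:03d}" for i in range(n_subjects)],
        m1=m1, m2=m2, index_name=index_name,
    )
    return pairs, true_icc


def jittered_faz_polygon(
    faz_area_mm2: float,
    center_px: tuple[float, float],
    mm_per_px: float,
    seed: int,
    n_vertices: int = 24,
    radial_jitter: float = 0.05,
) -> list[tuple[float, float]]:
    """Simulate one manual FAZ tracing: a noisy polygon around the true disc.

    Vertices sit at the true FAZ radius perturbed by multiplicative
    Gaussian jitter of relative SD ``radial_jitter``, emulating
    operator tracing variability; repeated calls with different seeds
    give different tracings of the same FAZ, so manual-mode area
    measurements exhibit a nonzero repeatability coefficient while the
    automated indices do not.
    """
    rng = np.random.default_rng(seed)
    r_px = math.sqrt(faz_area_mm2 / math.pi) / mm_per_px
    cx, cy = center_px
    angles = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    radii = r_px * np.clip(1.0 + rng.normal(0.0, radial_jitter, n_vertices), 0.3, 2.0)
    return [(cx + r * math.cos(a), cy + r * math.sin(a))
            for a, r in zip(angles, radii)]


# ---------------------------------------------------------------------------
# on-disk cohort format


def write_cohort(cohort: Cohort, out_dir: str | Path) -> tuple[Path, Path]:
    """Write slab PNGs, a manifest CSV and a ground-truth CSV.

    Manifest columns: subject_id, eye, visit_id, scan_index, slab_kind,
    path, signal_strength, extent_mm.  Returns (manifest_path,
    truth_path).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for pairs in (cohort.cc_pairs, cohort.vessel_pairs):
        for rec1, rec2 in pairs:
            for rec in (rec1, rec2):
                for kind, img in rec.slabs.items():
                    fname = (
                        f"{rec.subject_id}_{rec.eye}_{rec.visit_id}"
                        f"_scan{rec.scan_index}_{kind}_{img.extent_mm:g}mm.png"
                    )
                    img.save(out / "images" / fname)
                    rows.append({
                        "subject_id": rec.subject_id,
                        "eye": rec.eye,
                        "visit_id": rec.visit_id,
                        "scan_index": rec.scan_index,
                        "slab_kind": kind,
                        "path": str(Path("images") / fname),
                        "signal_strength": rec.signal_strength,
                        "extent_mm": img.extent_mm,
                    })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    truth_rows = [
        {"subject_id": sid, **vals}
        for sid, vals in cohort.truth.per_subject_truth.items()
    ]
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return manifest, truth_path
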