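"""Cohort orchestration: manifests, configuration, logging, end-to-end runs.

A cohort lives on disk as 8-bit grayscale PNG slabs plus a manifest
CSV (one row per slab) and flows through quality control, the paired
choriocapillaris flow-void pipeline (6x6-mm acquisitions), the vessel
pipeline (3x3-mm acquisitions, SCP and DCP), and the repeatability
report.  Runs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ccfv import ccfv_pipeline
from .images import EnFaceImage, ScanRecord
from .preprocessing import motion_score, qc_assess
from .repeatability import PairedMeasurements, repeatability_report
from .vessel_metrics import FazDelineation, vessel_pipeline

log = logging.getLogger("octaquant")

MANIFEST_COLUMNS = (
    "subject_id", "eye", "scan_index", "slab_kind", "path",
    "signal_strength", "extent_mm",
)


@dataclass
class RunConfig:
    """Options for one end-to-end run (confidence level fixed at 95%)."""

    manifest: Path
    out_dir: Path
    artifact_removal: bool = True
    faz_mode: str = "seeded_auto"
    motion_threshold: float = 0.1
    max_shift_px: int | None = None
    eye_priority: str = "OD"  # one eye per subject; prefer this one
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if self.ci_level != 0.95:
            raise ValueError("the confidence level is fixed at 95%")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Requires the standard columns and rejects duplicate
    (subject, eye, scan_index, slab_kind, extent) keys.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    key_cols = ["subject_id", "eye", "scan_index", "slab_kind", "extent_mm"]
    dups = df[df.duplicated(key_cols, keep=False)]
    if len(dups):
        key = tuple(dups.iloc[0][key_cols])
        raise ValueError(f"duplicate manifest entry for key {key}")
    return df


def load_scan_records(
    manifest: pd.DataFrame, base_dir: Path, extent_mm: float
) -> dict[str, dict[int, ScanRecord]]:
    """Assemble ScanRecords for one acquisition extent, keyed by subject then scan."""
    sel = manifest[manifest["extent_mm"] == extent_mm]
    records: dict[str, dict[int, ScanRecord]] = {}
    for (sid, eye, idx), grp in sel.groupby(["subject_id", "eye", "scan_index"]):
        slabs: dict[str, EnFaceImage] = {}
        for _, row in grp.iterrows():
            img_path = base_dir / row["path"]
            try:
                slabs[row["slab_kind"]] = EnFaceImage.load(
                    img_path, extent_mm=extent_mm, slab_kind=row["slab_kind"]
                )
            except OSError as exc:
                raise OSError(
                    f"cannot read image for {sid}/{eye}/scan{idx}/"
                    f"{row['slab_kind']}: {img_path}"
                ) from exc
        first = next(iter(slabs.values()))
        rec = ScanRecord(
            subject_id=str(sid),
            eye=str(eye),
            scan_index=int(idx),
            signal_strength=int(grp["signal_strength"].iloc[0]),
            motion_score=motion_score(first),
            slabs=slabs,
        )
        records.setdefault(str(sid), {})[int(idx)] = rec
    return records


def select_one_eye(manifest: pd.DataFrame, priority: str = "OD") -> pd.DataFrame:
    """Keep one eye per subject, preferring ``priority`` when both are present."""
    keep = []
    for sid, grp in manifest.groupby("subject_id"):
        eyes = sorted(grp["eye"].unique())
        eye = priority if priority in eyes else eyes[0]
        keep.append(grp[grp["eye"] == eye])
    return pd.concat(keep, ignore_index=True)


def run_full(config: RunConfig) -> "pd.DataFrame":
    """QC -> paired quantification -> repeatability report, with artifacts on disk.

    Per-record failures are logged and skipped so one bad scan does
    not abort the cohort; QC accounting (included + excluded = input)
    is written to the run log.  Outputs: per-pair measurement CSV and
    the agreement report as CSV and JSON.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_full(config)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_full(config: RunConfig) -> pd.DataFrame:
    manifest = select_one_eye(read_manifest(config.manifest), config.eye_priority)
    base = config.manifest.parent
    log.info("run config: %s", config)

    measurements: dict[str, list[tuple[str, float, float]]] = {}
    n_in = n_ok = 0

    def qc_pair(recs: dict[int, ScanRecord]) -> bool:
        nonlocal n_in, n_ok
        n_in += 1
        if set(recs) != {1, 2}:
            log.info("qc: %s incomplete pair", next(iter(recs.values())).subject_id)
            return False
        decisions = {j: qc_assess(recs[j], config.motion_threshold) for j in (1, 2)}
        for j, dec in decisions.items():
            if not dec.included:
                log.info("qc: excluded %s scan %d (%s)",
                         recs[j].subject_id, j, ",".join(dec.reasons))
        ok = all(d.included for d in decisions.values())
        n_ok += ok
        return ok

    # 6x6-mm choriocapillaris pairs
    for sid, recs in load_scan_records(manifest, base, 6.0).items():
        if not qc_pair(recs):
            continue
        try:
            r1, r2 = ccfv_pipeline(recs[1], recs[2],
                                   max_shift_px=config.max_shift_px,
                                   artifact_removal=config.artifact_removal)
        except Exception as exc:  # keep processing the rest of the cohort
            log.warning("ccfv: %s failed: %s", sid, exc)
            continue
        measurements.setdefault("cc_flow_void_mm2", []).append(
            (sid, r1.void_area_mm2, r2.void_area_mm2))
        log.info("ccfv: %s areas %.4f / %.4f mm2 (T %.1f / %.1f)",
                 sid, r1.void_area_mm2, r2.void_area_mm2,
                 r1.threshold_T, r2.threshold_T)

    # 3x3-mm plexus pairs
    for sid, recs in load_scan_records(manifest, base, 3.0).items():
        if not qc_pair(recs):
            continue
        for kind in ("SCP", "DCP"):
            try:
                results = []
                for j in (1, 2):
                    img = recs[j].slab(kind)
                    c = img.grid_px // 2
                    delin = FazDelineation("seeded_auto", seed_point=(c, c))
                    results.append(vessel_pipeline(recs[j], kind, delin))
            except Exception as exc:
                log.warning("vessels: %s %s failed: %s", sid, kind, exc)
                continue
            measurements.setdefault(f"{kind.lower()}_tva_mm2", []).append(
                (sid, results[0].tva_mm2, results[1].tva_mm2))
            measurements.setdefault(f"{kind.lower()}_faz_mm2", []).append(
                (sid, results[0].faz_area_mm2, results[1].faz_area_mm2))

    log.info("qc accounting: %d pairs in, %d included, %d excluded",
             n_in, n_ok, n_in - n_ok)

    rows = [
        {"index": name, "subject_id": sid, "m1": m1, "m2": m2}
        for name, triples in measurements.items()
        for sid, m1, m2 in triples
    ]
    meas_df = pd.DataFrame(rows)
    meas_df.to_csv(config.out_dir / "measurements.csv", index=False)

    paired = {
        name: PairedMeasurements(
            subject_ids=[t[0] for t in triples],
            m1=np.array([t[1] for t in triples]),
            m2=np.array([t[2] for t in triples]),
            index_name=name,
        )
        for name, triples in measurements.items()
        if len(triples) >= 3
    }
    report = repeatability_report(paired)
    frame = report.to_frame()
    frame.to_csv(config.out_dir / "agreement_report.csv", index=False)
    with open(config.out_dir / "agreement_report.json", "w") as fh:
        json.dump(frame.to_dict(orient="records"), fh, indent=2)
    return frame
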