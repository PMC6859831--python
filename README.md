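# octaquant

Quantification of en-face OCT angiography (OCTA) slabs and test–retest
repeatability analysis, built for studies that scan each eye twice in a
single visit — for example uveitis cohorts where choroidal and retinal
microvascular indices are candidate disease biomarkers — and need to know
how much of the scan-to-scan difference is measurement noise.

## What it computes

**Choriocapillaris flow-void area** (6×6-mm slabs). Each slab is
standardized by brightness-histogram contrast stretching against a central
reference square, projection artifacts of the superficial capillary plexus
(SCP) are suppressed by binarizing the SCP slab (Otsu) and rescaling the
intensities under its vascular pattern, the two same-visit scans are
aligned by exhaustive integer-translation normalized cross-correlation and
cropped to their common field, and the flow-deficit threshold is taken
from the scan's own avascular outer-retina slab:

    T = A_p + 1.96 · S_d

where *A_p* and *S_d* are the mean and SD of the avascular slab's pixel
intensities. Pixels at or below *T* are flow void; their summed area (mm²)
is the total FV.

**Vessel metrics** (3×3-mm slabs, SCP and DCP). Otsu global binarization
gives the vessel mask; total vessel area TVA = vessel-pixel count × pixel
footprint; vessel density VD = TVA / image area; the foveal avascular zone
(FAZ) is measured from a manually traced polygon (shoelace area) or a
seeded flood fill of the avascular center.

**Repeatability statistics.** For paired measurements m1, m2 across
subjects: Bland–Altman bias and 95% limits of agreement, the coefficient
of repeatability CR = 1.96·SD(m1−m2), CR as a fraction of the cohort mean,
the two-way mixed-effects consistency intraclass correlation ICC(3,1) =
(BMS−EMS)/(BMS+EMS) with its exact F-based 95% CI, and the within-person
coefficient of variation CV = 100·√(mean d²/2)/mean.

Because no image data accompany the method, a first-class synthetic cohort
generator (`octaquant.synthetic`) renders paired same-visit slabs with
known vessel density, FAZ area, flow-void fraction, projection artifacts,
inter-scan translation and stated between-/within-subject variance, so
every stage is validated against ground truth.

## Worked example

```python
import numpy as np
from octaquant import (ScanRecord, generate_vessel_network, generate_cc_slab,
                       render_slab, measure_cc_scan)
from octaquant.synthetic import generate_avascular_slab

scp_mask, _ = generate_vessel_network(256, 0.3, 0.3, 6.0, seed=1)
cc, truth = generate_cc_slab(256, void_fraction=0.2, scp_mask=scp_mask,
                             artifact_depth=60, noise_sd=5, seed=2)
scan = ScanRecord(subject_id="S1", slabs={
    "CC": cc,
    "SCP": render_slab(scp_mask, noise_sd=5, seed=3, extent_mm=6.0),
    "avascular": generate_avascular_slab(256, noise_sd=5, seed=4),
})
res = measure_cc_scan(scan)
print(f"T = {res.threshold_T:.1f}")
print(f"measured void fraction {res.void_fraction:.4f} (truth {truth.void_fraction:.4f})")
print(f"flow-void area {res.void_area_mm2:.2f} of {res.analyzed_area_mm2:.0f} mm2")
```

prints

```
T = 159.2
measured void fraction 0.2000 (truth 0.2000)
flow-void area 7.20 of 36 mm2
```

i.e. on a 36 mm² slab with a known 20% flow-deficit fraction, the
avascular-slab threshold lands between the deficit and flow intensity
modes and the measured flow-void area (7.20 mm²) recovers the constructed
truth exactly.

The `analysis/` directory holds the narrative pipeline (simulate a cohort,
quantify flow voids and vessels, assemble the agreement report, check the
published table's internal consistency); run the scripts in order with
`python analysis/01_simulate_cohort.py` etc. A CLI mirrors the same steps
(`octaquant simulate|ccfv|vessels|repeat|run-full`).

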