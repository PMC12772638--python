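# vsreport

Standardized imaging biomarkers for **vestibular schwannoma (VS)
surveillance**: from longitudinal intrameatal/extrameatal segmentation
masks to the measurements, growth classification and one-page reports a
skull-base multidisciplinary team (MDT) reviews.

VS management hinges on whether the tumor is growing.  Manual linear
measurement on PACS is slow and observer-dependent, and volumetry rarely
reaches routine practice.  Given segmentation masks (from any source — a
deep-learning model, semi-automated tools, or the built-in synthetic
phantom), `vsreport` computes for every session:

* **D_WT / D_EM** — maximum in-plane (axial) diameter of the whole tumor /
  of the extrameatal portion, via convex hull + rotating calipers (exactly
  equal to the brute-force maximum over pixel centers);
* **d(intra,∥), d(extra,∥), d(extra,⊥)** — compartment extents parallel
  and perpendicular to the porus-plane trace, estimated from the
  intra/extrameatal interface geometry;
* **V_intra, V_extra, V_whole** — compartment volumes in cm³.

One diameter is displayed per session (operated tumors → D_WT; entirely
intrameatal → D_WT; otherwise `IF d(intra,∥) ≥ d(extra,∥) → D_WT, ELSE IF
d(extra,⊥) > 2 mm → D_EM, ELSE → D_WT`), and change between sessions is
classified against the EAONO significant-growth criteria

> growth ⇔ ΔD > 2 mm **or** ΔV > 1.2 cm³ **or** ΔV > 20 %

with strict inequalities, a mirrored *reduction* category, and a
configurable *equivocal* band (default: past half a threshold).  Headline
comparisons follow MDT practice: index → latest and
second-most-recent → latest.  See `docs/methods.md` for the full model.

## Worked example

Generate a fully synthetic three-visit phantom series (capsule-shaped
intrameatal part joined to an extrameatal ellipsoid, voxelized at 0.8 mm,
growing 10 % then 30 % in linear size) and run the pipeline:

```bash
python - <<'EOF'
from vsreport.phantom import PhantomParams, make_phantom_timeline
make_phantom_timeline(PhantomParams(spacing=0.8), [1.0, 1.1, 1.3],
    ["2020-01-10", "2021-01-12", "2022-01-15"], "demo",
    decisions=["surveillance", "surveillance", "SRS"])
EOF
vsreport measure demo/manifest.csv --out demo/measurements.csv
vsreport report demo/manifest.csv --out-dir demo/reports
```

`demo/measurements.csv` (diameters mm, volumes cm³):

```
patient_id,date,months_since_index,status,d_wt_mm,d_em_mm,...,v_whole_cm3,...
phantom-001,2020-01-10,0.0,preoperative,30.8701,16.9517,...,1.7572,...
phantom-001,2021-01-12,12.09,preoperative,33.752,18.7275,...,2.3496,...
phantom-001,2022-01-15,24.18,preoperative,40.1995,22.2854,...,3.8815,...
```

The tumor's displayed diameter grows 30.87 → 40.20 mm and its whole
volume 1.76 → 3.88 cm³ (the 1.3× linear scale cubes to ≈ 2.2× volume).
`demo/reports/assessments.csv` classifies every comparison:

```
comparison,baseline_date,follow_date,status,delta_d_mm,delta_v_cm3,delta_v_pct,triggered_by
consecutive,2020-01-10,2021-01-12,growth,1.7758,0.5924,33.7121,volume_pct
consecutive,2021-01-12,2022-01-15,growth,3.5579,1.5319,65.1994,diameter|volume_abs|volume_pct
index_vs_latest,2020-01-10,2022-01-15,growth,5.3337,2.1243,120.8916,diameter|volume_abs|volume_pct
penultimate_vs_latest,2021-01-12,2022-01-15,growth,3.5579,1.5319,65.1994,diameter|volume_abs|volume_pct
```

The first interval shows why volumetry matters: ΔD = 1.78 mm is below the
2 mm diameter criterion, but the +33.7 % volume change already classifies
the interval as growth.  `demo/reports/phantom-001_summary.html` is the
one-page report — per-session axial snapshots with the measured diameter
drawn, red/orange/green change coding, volume bars, the diameter-vs-months
line chart with decision markers, and a legend;
`phantom-001_extended.html` adds the full measurement table, orthographic
silhouettes and an STL surface mesh per session.  Growth thresholds,
component filtering and the volume-suppression rule are configurable via
flags or a YAML config (`vsreport report --help`).

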