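# sabrevol

Landmark-driven regional brain volumetrics for structural MRI, built for
aging, cerebrovascular and neurodegenerative cohorts where fully
automatic template-warping tools struggle with stroke lesions and focal
atrophy.

From four coregistered contrasts (T1, T2, PD, FLAIR) plus a small set of
manually identified anatomical landmarks and manual masks (stroke
delineation, hippocampi, ventricle seeds), the pipeline produces one
spreadsheet row per subject:

* **ST-TIV** — supratentorial total intracranial volume: everything
  below the dura and above the tentorium, *including* sub-arachnoid CSF,
  so focal atrophy (brain replaced by CSF) does not shrink the head-size
  measure;
* **normal-appearing tissue** — NAGM, NAWM, sulcal and ventricular CSF
  from a T1 segmentation that fits localized intensity histograms to
  three Gaussians per block (robust to scanner inhomogeneity), then
  corrects the GM/CSF inflation caused by white matter hyperintensities
  being GM-isointense on T1;
* **small vessel disease markers** — white matter hyperintensities split
  into periventricular and deep compartments (3D 26-connectivity to the
  ventricles by default; 13 mm distance and proportional-distance rules
  are also implemented), lacunes (3–15 mm, PD-bright, FLAIR rim — or
  T2-based capture in the basal ganglia/thalamus where FLAIR is
  insensitive), perivascular spaces (< 3 mm, linear, PD-isointense to
  GM), and manually delineated chronic stroke;
* **regional breakdown** — every class cross-tabulated over a
  Talairach-style grid of 13 regions per hemisphere (26 total, 28 after
  hippocampal merge), with hippocampal parenchyma / hypointensity /
  stroke sub-volumes;
* **head-size correction** — every volume also reported as a proportion
  of ST-TIV.

The ten coded classes partition the supratentorial mask exactly, so the
class volumes always sum to ST-TIV.

Because no imaging data ships with the package, a deterministic
multi-contrast **digital phantom** (`sabrevol.phantom`) generates studies
with known ground truth — nested-ellipsoid anatomy, analytically placed
landmarks, and seeded lesions rendered with the correct relative
intensity signatures — so every stage is testable end to end.

## Worked example

```bash
python examples/run_full_pipeline.py
```

generates a default 96 mm phantom with the standard lesion load, runs the
full pipeline, and prints:

```
subject phantom
ST-TIV     200.9 cc   (everything below the dura, above the tentorium)

global volumes (tissue in cc, lesions in mm^3):
  NAGM          75.5 cc    /ST-TIV 0.37552
  NAWM          79.5 cc    /ST-TIV 0.39547
  sCSF          40.6 cc    /ST-TIV 0.20181
  vCSF           3.6 cc    /ST-TIV 0.01770
  pWMH         331.0 mm3   /ST-TIV 0.00165
  dWMH          55.0 mm3   /ST-TIV 0.00027
  pLACN          0.0 mm3   /ST-TIV 0.00000
  dLACN        204.0 mm3   /ST-TIV 0.00102
  PVS           42.0 mm3   /ST-TIV 0.00021
  Stroke      1278.0 mm3   /ST-TIV 0.00636

conservation error (sum of classes vs ST-TIV): 1.41e-16
regions with voxels: 28
whole-brain WMH burden (pWMH + dWMH): 386 mm^3
hippocampus left : parenchyma 0.574 cc, hypointensity 0.002 cc, stroke 0.000 cc
hippocampus right: parenchyma 0.572 cc, hypointensity 0.004 cc, stroke 0.000 cc
```

The phantom head is a 96 mm miniature, so the absolute volumes are small;
what matters is that the recovered lesion volumes match the generator's
inventory voxel-for-voxel (331 mm³ of periventricular WMH against two
embedded caps of 155 + 176 voxels, and so on), the ten classes sum to
ST-TIV at machine precision, and corrected proportions divide by ST-TIV.

Other narrative examples: `examples/generate_phantom_study.py` (the
generator and its ground truth), `examples/compare_split_methods.py`
(where the three periventricular/deep rules agree and diverge),
`examples/cohort_summary.py` (pooled statistics with the log1p lesion
transform), `examples/agreement_metrics.py` (Dice and ICC(2,1) QC
metrics).

A thin CLI wraps the same library:

```bash
sabrevol phantom --out study/ --seed 42
sabrevol report study/manifest.json --out volumes.csv
sabrevol summarize volumes.csv --out cohort.csv --transform log1p
```

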