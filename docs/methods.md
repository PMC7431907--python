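# Methods

This note documents the models and procedures implemented in
`sabrevol`, their assumptions, the parameters that matter, and what the
phantom-based validation does and does not demonstrate.

## Coordinate conventions

Voxel indices are 0-based; a NIfTI-style affine maps them to a RAS+
world frame in millimetres. All geometry — plane cuts, lesion widths,
distance transforms — is computed in world mm, so anisotropic voxels are
handled correctly. Phantom grids are centred on the origin with the
mid-sagittal plane at x = 0 between voxel columns, which makes
mirror-symmetry exact and keeps every voxel strictly off the plane.

## Supratentorial TIV

Head size is measured as everything inside the dural envelope and above
the tentorium. The envelope is found on T1 as the largest closed
low-gradient boundary around the head foreground: a four-class Otsu
threshold (lowest cut) separates background from tissue, morphological
closing (ball radius 2 voxels, configurable) and hole filling recover
interior CSF without eroding the sulcal rind, and the largest connected
component is kept. The tentorium is modelled as a single oblique plane
through the `tentorial_cut_point` landmark (default normal
(0, 0.2, 0.98), configurable): the pipeline only needs infratentorial
structures removed, not tentorial anatomy. A guard aborts if the plane
would discard more than 60 % of the foreground, which indicates a
misplaced landmark.

Because the measure is bounded by the envelope rather than the brain
surface, swapping parenchyma for sulcal CSF (focal atrophy) leaves
ST-TIV unchanged; the phantom's `atrophy_mm` parameter exercises exactly
this invariance.

## Landmark grid (26/28 regions)

The parcellation is a Talairach-style grid built per hemisphere from 14
named landmarks. The construction implemented here is this package's
own operationalization — the landmark inventory and plane recipe are a
design choice, documented as such:

* mid-sagittal plane from `mid_sagittal_point`/`mid_sagittal_normal`
  (hemisphere assignment);
* coronal planes through AC and PC along the PC→AC axis (frontal /
  central / posterior bands) and through the occipital boundary
  landmarks (occipital band);
* an axial plane containing the AC–PC line (dorsal / ventral tiers),
  with one proportional plane at half the distance to the superior brain
  extent splitting the dorsal frontal tier (SF vs MF; the fraction is
  configurable);
* a parasagittal plane through each hemisphere's central landmark
  (lateral vs medial ranks).

Band × tier × rank yields 13 codes per hemisphere: SF/MF/IF and
MSF/MMF/MIF in the frontal band, SP (dorsal-lateral), AT
(ventral-lateral) and ABGT (medial) in the central band, IP, PT and PBGT
in the posterior band, and O for the occipital band. All planes are
half-open (boundary points go to the anterior/left/superior —
medial for the parasagittal cut — side), so region assignment is a total
function and the regions partition the mask exactly. Hippocampal masks,
supplied externally, overwrite the underlying temporal/BGT labels to
give 28 ROIs.

Region assignment depends only on world coordinates relative to the
landmarks, so rigidly moving the volume and landmarks together leaves
region voxel counts unchanged.

## Tissue segmentation

T1 intensities are modelled as a three-component 1D Gaussian mixture
(CSF < GM < WM by mean), fitted by EM to *binned* histograms (256 bins).
To absorb scanner inhomogeneity the mixture is fitted per overlapping
block (32³ voxels, 50 % overlap), and each voxel is classified under
parameters trilinearly interpolated from the surrounding block centres.

Choices that matter:

* **Initialization.** The global fit starts from equal-count intensity
  tertiles, which makes it equivariant under positive affine intensity
  maps. Each block fit starts from the *global* parameters; a component
  whose responsibility mass collapses in a block keeps the global
  values. This pins the CSF/GM/WM correspondence in blocks that lack a
  class entirely (deep WM blocks contain no CSF) — with independent
  tertile initialization the lowest component would capture GM there and
  mislabel it.
* **Scale floor.** Component standard deviations are floored at one
  histogram bin width (and 1e-4 of the intensity span). A binned EM
  cannot resolve scales below the bin spacing, and without the floor a
  noise-free spike half a bin away from a tiny-sd component receives
  zero likelihood and starves it. The floor is proportional to the data
  span, preserving affine equivariance.
* **Convergence.** Absolute log-likelihood gain < 1e-6 or 500
  iterations; blocks under 200 masked voxels or with near-constant
  intensity inherit the global fit. A near-constant *global* histogram
  (sd < 1e-6 of the range) is an error.
* **Ties.** Posterior ties break toward the larger local weight, then
  the lower mean — determinism over elegance.

All CSF is initially sulcal. Ventricular CSF is then relabelled by
seeded 26-connected components, mirroring the manual relabelling step of
the semi-automated workflow: only CSF components containing a seed
become vCSF, and interior non-CSF voxels (choroid-plexus-like islands)
are never smoothed into the ventricle. Seeds come from a mask or from
world-mm points; there is deliberately no automatic default.

## Lesion analysis

All z-scores are robust — (x − median)/(1.4826·MAD) over a reference
mask, floored at 1e-3 of the contrast span so noise-free images stay
finite — because lesions contaminate means. References are the initial
WM labels (NAWM) and GM labels. All 3D connectivity is 26-connectivity,
which makes the brute-force flood-fill oracle unambiguous.

**WMH.** Candidate voxels exceed FLAIR z > 3 *and* T2 z > 2 against the
WM reference, outside ventricles and stroke; components under 5 voxels
are dropped. The joint FLAIR∧T2 condition keeps lacune rims (FLAIR-
bright but T2-normal) and CSF out. Lowering the FLAIR threshold can
only grow the mask.

**Normal-appearing correction.** Lesion voxels are removed from the
GM/WM/sCSF pools; what remains is NAGM/NAWM. Precedence when masks
overlap: stroke > lacunes > PVS > WMH > tissue, mirroring the manual
workflow where the analyst's stroke delineation overrides automatic
labels. The result is a ten-class partition of the supratentorial mask,
so volumes are conserved by construction.

**Periventricular vs deep.** Three interchangeable rules:
connectivity (default: a component is periventricular iff it touches
vCSF, 26-adjacency), distance (world-mm EDT to vCSF ≤ 13 mm), and
proportional (d_vCSF/(d_vCSF + d_dura) ≤ 0.5, the dural surface being
the supratentorial mask boundary). Each returns an exact two-way
partition. Lacunes are split with the same connectivity rule. PVS are
reported as a single class — the periventricular/deep distinction is
established for WMH and lacunes only.

**Lacune/PVS candidates.** The search territory is the hole-filled WM
mask (fluid cavities enclosed by WM) plus the basal ganglia/thalamus
regions, minus ventricles, stroke, and CSF connected to the dural
surface. A candidate voxel must be CSF-like dark on T1 — z below −2.5
against *both* the NAWM and the GM references — and must itself segment
as fluid. The double reference departs from using NAWM alone on
purpose: under phantom conditions the robust scale is pure noise, so
normal GM (and GM-isointense WMH) sits many noise-sd below WM and would
flood a NAWM-only net, while the radiological definition of these
cavities is "darker than grey matter".

**Rule cascade.** Per candidate component, principal-axis extents in
world mm (padded by one voxel so a 3-voxel line has width 1 mm, length
3 mm): width is the larger minor extent, elongation the major/smallest
ratio. The deterministic cascade:

* **PVS** — width < 3 mm, elongation ≥ 2, PD z within ±1.5 of the GM
  reference;
* **lacune** — 3 mm ≤ width ≤ 15 mm (the consensus size band; the upper
  bound and lower bound follow the standard reporting convention), PD
  z > 2 vs NAWM, and either a FLAIR rim (mean shell z − mean core z
  > 1.5) or, for BGT-territory components, T2 z > 2 with FLAIR z < 2 —
  the thalamic capture path, since FLAIR is insensitive there and a
  FLAIR-*bright* BGT component is WMH, not a lacune;
* otherwise **reject**.

The published workflow performs false-positive minimization manually;
here it is operationalized as this deterministic cascade, with manual
mask overrides still possible through the bundle's manual masks.

**Stroke.** Chronic stroke masks are ingested, not segmented. The mask
is validated against the supratentorial mask and its signature checked
(warn if mean FLAIR z ≤ 0 or mean T1 z ≥ 0); the analyst's delineation
always wins.

**Hippocampus.** Within each hippocampal mask: stroke voxels first,
then CSF-like hypointensities (T1 z < −2.5 against the *GM* reference —
the hippocampus is grey matter, so an NAWM reference would flag normal
parenchyma), remainder parenchyma. The three sub-volumes sum exactly to
the mask volume.

## Reporting

Units follow the published convention: cc for TIV/tissue/CSF, mm³ for
lesion classes; hippocampal sub-volumes are reported in cc. Every
volume has a head-size-corrected twin (raw / ST-TIV, dimensionless).
The CSV column order is canonical (ST-TIV, the ten global codes,
hippocampal sub-volumes, region × class cells in table order, corrected
twins), values are serialized with full float repr, and re-reading uses
round-trip parsing, so equal records are byte-identical and round trips
are exact. Cohort summaries give n/mean/sd/median/IQR, with an optional
log1p transform for the right-skewed lesion volumes (log1p, not log, so
zero-lesion subjects stay finite). Aggregation sums regional cells into
lobes (published lobe membership), whole brain, or custom groups;
pWMH + dWMH is the whole-brain WMH burden.

Agreement metrics: Dice 2|A∩B|/(|A|+|B|) (defined as 1 when both masks
are empty) and ICC(2,1) — two-way random effects, absolute agreement,
single rater — from the standard mean-square decomposition. The ICC
flavour is fixed and documented because "ICC" alone is ambiguous.

## The phantom: what it emulates and what it does not

The generator emulates the *contrast logic* of the four sequences, not
MRI physics. Anatomy is nested ellipsoids (dura, GM shell, WM core,
ventricles, hippocampi, an infratentorial stub below the tentorial
plane); landmarks are placed analytically; intensities are class means
plus i.i.d. Gaussian noise. The default intensity table is arbitrary in
its absolute values but enforces the relative orderings the pipeline
relies on — WMH bright on FLAIR/T2 and GM-isointense on T1; lacunes
dark on T1, bright on PD/T2, dark FLAIR core with bright rim; thalamic
lacunes without FLAIR signal; PVS PD-isointense to GM; stroke
FLAIR-bright/T1-dark; renders that violate an ordering abort with the
violated constraint named. The default noise sd (3.0) is 10 % of the
GM–WM T1 gap, the level at which analyst-grade Dice ≥ 0.90 is the
acceptance bar.

Lesion placement is seeded and deterministic (100 retries per lesion,
then an error): pWMH caps grow from the ventricular surface; dWMH are
punctate spheres kept > 13 mm from the ventricles by default so the
connectivity and distance splitters agree (hard mode moves them into
the ambiguous 5–13 mm band to surface method disagreement); lacunes are
4–10 mm ellipsoids with a recorded one-voxel WM rim, placed ≥ 2.5 mm
from the ventricles (so the default phantom has no periventricular
lacunes — that path is exercised on constructed masks); PVS are tubes
≤ 3 mm wide and ≥ 3× longer than wide, strictly interior to WM; the
stroke wedge is a spherical sector at the cortical surface spanning GM
and WM. Different lesion classes never overlap and keep a one-voxel
margin.

Passing the phantom suite therefore shows the pipeline implements its
stated rules exactly and recovers volumes under idealized noise. It
does **not** show robustness to bias fields, partial-volume effects,
motion, anatomical variability, or imperfect coregistration — none of
which the phantom models.

## Problem sizes

The default phantom is a 96³ grid at 1 mm isotropic (a miniature head;
all thresholds are in mm, so scale carries no meaning beyond runtime).
The twenty-phantom conservation batch runs at 64³ in hard mode —
conservation is size-independent and the default deep-WMH distance band
does not exist inside a 64 mm head. Oracle equivalence uses 24³ random
masks where exhaustive BFS and nearest-neighbour scans are tractable.

## Known limitations

* The grid construction is a faithful but original operationalization;
  regional boundaries will not coincide with any particular published
  atlas implementation.
* Lacunes 26-connected to the ventricular system are absorbed into vCSF
  during seeded relabelling before lesion analysis; genuinely
  ventricle-adjacent lacunes would need a manual override mask.
* No bias-field model beyond histogram localization; no partial-volume
  classes; no microbleed support (a visual-rating measure, not a
  segmentation target).
* Stroke ingestion trusts the manual mask; it warns on, but does not
  reject, a signature mismatch.
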