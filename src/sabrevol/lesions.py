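"""Small vessel disease lesion analysis.

Covers FLAIR/T2-driven white matter hyperintensity (WMH) segmentation,
normal-appearing tissue correction, the three periventricular/deep
splitting rules (3D connectivity — the supported default — a fixed
distance cutoff, and a proportional distance to the dural surface),
subcortical hypointensity candidate detection with per-component shape
and intensity features, the deterministic lacune-versus-perivascular-
space rule cascade (with the thalamic T2 fallback for the poor FLAIR
sensitivity in that territory), manual stroke mask ingestion, and
hippocampal sub-classification.

All intensity z-scores are robust: (x - median) / (1.4826 * MAD) against
a reference tissue mask, with a floor on the scale so noise-free images
remain well defined.  All 3D connectivity is 26-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import (
    CandidateConfig,
    ClassifierConfig,
    PipelineConfig,
    SplitConfig,
    WMHConfig,
)
from .core_io import LabelVolume, StudyBundle, binary_scheme, tissue_scheme
from .parcellation import SupratentorialMask

_STRUCT26 = np.ones((3, 3, 3), bool)


# ---------------------------------------------------------------------------
# robust references
# ---------------------------------------------------------------------------

def robust_stats(values: np.ndarray, span: float | None = None
                 ) -> tuple[float, float]:
    """Median and MAD-based scale (1.4826 * MAD), floored at 1e-3 of the
    intensity span so z-scores stay finite on noise-free data."""
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty reference for robust statistics")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if span is None:
        span = float(np.ptp(v))
    floor = max(1e-3 * span, 1e-9)
    return med, max(1.4826 * mad, floor)


@dataclass
class IntensityReferences:
    """Per-contrast robust (median, scale) for the NAWM and GM references."""

    nawm: dict[str, tuple[float, float]]
    gm: dict[str, tuple[float, float]]

    @classmethod
    def from_bundle(cls, bundle: StudyBundle, wm_mask: np.ndarray,
                    gm_mask: np.ndarray) -> "IntensityReferences":
        if not wm_mask.any():
            raise ValueError("no WM voxels to form the reference")
        if not gm_mask.any():
            raise ValueError("no GM voxels to form the reference")
        nawm, gm = {}, {}
        for tag, vol in bundle.volumes.items():
            span = float(np.ptp(vol.voxels))
            nawm[tag] = robust_stats(vol.voxels[wm_mask], span)
            gm[tag] = robust_stats(vol.voxels[gm_mask], span)
        return cls(nawm=nawm, gm=gm)

    def z_nawm(self, bundle: StudyBundle, tag: str) -> np.ndarray:
        med, scale = self.nawm[tag]
        return (bundle.volumes[tag].voxels - med) / scale

    def z_gm(self, bundle: StudyBundle, tag: str) -> np.ndarray:
        med, scale = self.gm[tag]
        return (bundle.volumes[tag].voxels - med) / scale


# ---------------------------------------------------------------------------
# WMH
# ---------------------------------------------------------------------------

def segment_wmh(bundle: StudyBundle, tissue: LabelVolume,
                mask: SupratentorialMask,
                stroke: np.ndarray | None = None,
                config: WMHConfig | None = None) -> np.ndarray:
    """Binary WMH mask from joint FLAIR and T2 hyperintensity.

    Candidate voxels exceed the FLAIR robust z threshold *and* the T2
    threshold against the initial-WM reference, restricted to
    supratentorial, non-ventricular, non-stroke voxels; connected
    components below the minimum size are discarded.
    """
    config = config or WMHConfig()
    wm = tissue.labels == tissue.scheme["WM"]
    if not wm.any():
        raise ValueError("no WM voxels to form the reference")
    vcsf = tissue.labels == tissue.scheme["vCSF"]

    spanF = float(np.ptp(bundle.flair.voxels))
    spanT2 = float(np.ptp(bundle.t2.voxels))
    medF, sF = robust_stats(bundle.flair.voxels[wm], spanF)
    medT2, sT2 = robust_stats(bundle.t2.voxels[wm], spanT2)
    zF = (bundle.flair.voxels - medF) / sF
    zT2 = (bundle.t2.voxels - medT2) / sT2

    cand = (zF > config.tau_flair) & (zT2 > config.tau_t2) & mask.mask & ~vcsf
    if stroke is not None:
        cand &= ~stroke

    comp, n = ndimage.label(cand, structure=_STRUCT26)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= config.min_component_voxels) + 1
        cand = np.isin(comp, keep)
    return cand


# ---------------------------------------------------------------------------
# periventricular / deep splitting
# ---------------------------------------------------------------------------

def split_periventricular_deep(wmh: np.ndarray, vcsf: np.ndarray,
                               method: str = "connectivity",
                               spacing=(1.0, 1.0, 1.0),
                               mask: np.ndarray | None = None,
                               config: SplitConfig | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Split a lesion mask into periventricular and deep compartments.

    ``connectivity``: a voxel is periventricular iff its 26-connected
    lesion component contains a voxel 26-adjacent to ventricular CSF.
    ``distance``: periventricular iff the world-mm Euclidean distance to
    the nearest vCSF voxel is at most the cutoff (default 13 mm).
    ``proportional``: periventricular iff d(vCSF) / (d(vCSF) + d(dural
    surface)) is at most the fraction (default 0.5); requires ``mask``
    whose boundary stands in for the dura.  Always returns an exact
    two-way partition of ``wmh``.
    """
    config = config or SplitConfig()
    wmh = np.asarray(wmh, bool)
    vcsf = np.asarray(vcsf, bool)
    if not vcsf.any():
        raise ValueError("empty ventricular CSF mask")

    if method == "connectivity":
        comp, n = ndimage.label(wmh, structure=_STRUCT26)
        touch = ndimage.binary_dilation(vcsf, _STRUCT26)
        touching = np.unique(comp[touch & wmh])
        pv = np.isin(comp, touching[touching > 0]) & wmh
    elif method == "distance":
        dist = ndimage.distance_transform_edt(~vcsf, sampling=list(spacing))
        pv = wmh & (dist <= config.distance_cutoff_mm)
    elif method == "proportional":
        if mask is None:
            raise ValueError("proportional method requires the supratentorial "
                             "mask (dural surface)")
        dist_v = ndimage.distance_transform_edt(~vcsf, sampling=list(spacing))
        dist_d = ndimage.distance_transform_edt(np.asarray(mask, bool),
                                                sampling=list(spacing))
        denom = dist_v + dist_d
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, dist_v / denom, 0.0)
        pv = wmh & (frac <= config.proportional_fraction)
    else:
        raise ValueError(f"unknown split method {method!r}")
    return pv, wmh & ~pv


def allocate_pv_deep_lacunes(lacunes: np.ndarray, vcsf: np.ndarray,
                             spacing=(1.0, 1.0, 1.0),
                             config: SplitConfig | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the periventricular/deep connectivity rule to lacunes."""
    return split_periventricular_deep(lacunes, vcsf, method="connectivity",
                                      spacing=spacing, config=config)


# ---------------------------------------------------------------------------
# component features + classifier
# ---------------------------------------------------------------------------

@dataclass
class ComponentFeatures:
    """Shape and intensity descriptors of one candidate component."""

    component_id: int
    voxel_count: int
    volume_mm3: float
    max_width_mm: float          # largest of the two minor principal extents
    elongation: float            # major / smallest principal extent
    z_nawm: dict[str, float] = field(default_factory=dict)
    z_gm: dict[str, float] = field(default_factory=dict)
    flair_rim_score: float = 0.0  # mean FLAIR z in the 1-voxel shell - core
    location_class: str = "other"  # "BGT" or "other"
    indices: np.ndarray | None = None

    def __post_init__(self):
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")


def principal_extents_mm(points_mm: np.ndarray, voxel_size_mm: float
                         ) -> np.ndarray:
    """Sorted (descending) extents of a voxel cloud along its principal
    axes, padded by one voxel size so single-voxel clouds have extent one
    voxel rather than zero."""
    pts = np.atleast_2d(points_mm)
    centred = pts - pts.mean(axis=0)
    if len(pts) == 1:
        return np.full(3, voxel_size_mm)
    cov = centred.T @ centred / len(pts)
    _, vecs = np.linalg.eigh(cov)
    proj = centred @ vecs
    extents = np.ptp(proj, axis=0) + voxel_size_mm
    return np.sort(extents)[::-1]


def extract_component_features(bundle: StudyBundle, comp_labels: np.ndarray,
                               references: IntensityReferences,
                               regions: LabelVolume | None = None,
                               mask: np.ndarray | None = None
                               ) -> list[ComponentFeatures]:
    """Compute :class:`ComponentFeatures` for every labelled component."""
    n = int(comp_labels.max())
    if n == 0:
        return []
    vol = bundle.t1
    voxel_mm3 = vol.voxel_volume_mm3
    vsize = float(np.mean(vol.spacing))
    coords = vol.world_coordinates()

    z_nawm = {t: references.z_nawm(bundle, t) for t in bundle.volumes}
    z_gm = {t: references.z_gm(bundle, t) for t in bundle.volumes}

    bgt_codes = set()
    if regions is not None:
        bgt_codes = {v for c, v in regions.scheme.mapping.items()
                     if c.endswith("ABGT") or c.endswith("PBGT")}

    feats = []
    for cid in range(1, n + 1):
        m = comp_labels == cid
        count = int(m.sum())
        pts = coords[m]
        extents = principal_extents_mm(pts, vsize)

        shell = ndimage.binary_dilation(m, _STRUCT26) & ~m
        if mask is not None:
            shell &= mask
        core_z = float(z_nawm["FLAIR"][m].mean())
        shell_z = float(z_nawm["FLAIR"][shell].mean()) if shell.any() else core_z

        loc = "other"
        if regions is not None and bgt_codes:
            reg_vals, reg_counts = np.unique(regions.labels[m],
                                             return_counts=True)
            if reg_vals.size and reg_vals[np.argmax(reg_counts)] in bgt_codes:
                loc = "BGT"

        feats.append(ComponentFeatures(
            component_id=cid,
            voxel_count=count,
            volume_mm3=count * voxel_mm3,
            max_width_mm=float(extents[1]),
            elongation=float(extents[0] / max(extents[2], 1e-9)),
            z_nawm={t: float(z_nawm[t][m].mean()) for t in z_nawm},
            z_gm={t: float(z_gm[t][m].mean()) for t in z_gm},
            flair_rim_score=shell_z - core_z,
            location_class=loc,
            indices=np.argwhere(m),
        ))
    return feats


def detect_subcortical_hypointensity_candidates(
        bundle: StudyBundle, tissue: LabelVolume, regions: LabelVolume,
        mask: SupratentorialMask, references: IntensityReferences,
        stroke: np.ndarray | None = None,
        config: CandidateConfig | None = None
) -> tuple[np.ndarray, list[ComponentFeatures]]:
    """Find T1-hypointense candidates in the white-matter/BGT territory.

    The territory is the hole-filled WM mask (so fluid-filled cavities
    enclosed by WM are searched) united with the basal ganglia/thalamus
    regions; ventricular CSF, the stroke mask, and the sulcal CSF body
    (CSF connected to the dural surface) are excluded.  A candidate must
    be CSF-like dark: below the T1 threshold against *both* the NAWM and
    the GM references — WMH are GM-isointense on T1 and must not enter
    this net.  Returns the component label array and per-component
    features.
    """
    config = config or CandidateConfig()
    wm = tissue.labels == tissue.scheme["WM"]
    vcsf = tissue.labels == tissue.scheme["vCSF"]
    scsf = tissue.labels == tissue.scheme["sCSF"]

    territory = ndimage.binary_fill_holes(wm)
    bgt = np.isin(regions.labels,
                  [v for c, v in regions.scheme.mapping.items()
                   if c.endswith("ABGT") or c.endswith("PBGT")])
    territory |= bgt
    territory &= mask.mask & ~vcsf
    if stroke is not None:
        territory &= ~stroke

    # the sulcal CSF body: CSF components reaching the dural surface
    shell = mask.mask & ~ndimage.binary_erosion(mask.mask, _STRUCT26)
    csf_comp, nc = ndimage.label(scsf, structure=_STRUCT26)
    if nc:
        at_surface = np.unique(csf_comp[shell & scsf])
        territory &= ~np.isin(csf_comp, at_surface[at_surface > 0])

    z_t1 = references.z_nawm(bundle, "T1")
    z_t1_gm = references.z_gm(bundle, "T1")
    # a candidate voxel must also *segment* as fluid (sCSF): isolated GM
    # voxels with deep negative noise excursions are not cavities
    cand = ((z_t1 < -config.tau_t1) & (z_t1_gm < -config.tau_t1)
            & territory & scsf)
    comp, _ = ndimage.label(cand, structure=_STRUCT26)
    feats = extract_component_features(bundle, comp, references,
                                       regions=regions, mask=mask.mask)
    return comp, feats


def classify_lacune_vs_pvs(candidate: ComponentFeatures,
                           config: ClassifierConfig | None = None) -> str:
    """Deterministic rule cascade: returns ``"PVS"``, ``"lacune"``, or
    ``"reject"``.

    A perivascular space is narrow (< 3 mm), linear (elongation at least
    2), and PD-isointense to GM.  A lacune is 3-15 mm wide, PD-bright
    against NAWM, and shows either a FLAIR rim (hyperintense shell around
    a dark core) or — in the basal ganglia/thalamus, where FLAIR is
    insensitive — a T2 hyperintensity *without* FLAIR hyperintensity (a
    FLAIR-bright BGT component is WMH, not a lacune).
    """
    cfg = config or ClassifierConfig()
    f = candidate
    if (f.max_width_mm < cfg.pvs_max_width_mm
            and f.elongation >= cfg.pvs_min_elongation
            and abs(f.z_gm.get("PD", 0.0)) <= cfg.pvs_pd_gm_band):
        return "PVS"
    if (cfg.lacune_min_width_mm <= f.max_width_mm <= cfg.lacune_max_width_mm
            and f.z_nawm.get("PD", 0.0) > cfg.lacune_pd_z):
        if f.flair_rim_score > cfg.lacune_rim_min:
            return "lacune"
        if (f.location_class == "BGT"
                and f.z_nawm.get("T2", 0.0) > cfg.lacune_t2_z
                and f.z_nawm.get("FLAIR", 0.0) < cfg.bgt_flair_max):
            return "lacune"
    return "reject"


def classify_candidates(comp_labels: np.ndarray,
                        features: list[ComponentFeatures],
                        config: ClassifierConfig | None = None
                        ) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Apply the cascade to every component; return (lacune mask, PVS mask,
    per-component verdicts)."""
    lacunes = np.zeros(comp_labels.shape, bool)
    pvs = np.zeros(comp_labels.shape, bool)
    verdicts = {}
    for f in features:
        verdict = classify_lacune_vs_pvs(f, config)
        verdicts[f.component_id] = verdict
        m = comp_labels == f.component_id
        if verdict == "lacune":
            lacunes |= m
        elif verdict == "PVS":
            pvs |= m
    return lacunes, pvs, verdicts


# ---------------------------------------------------------------------------
# stroke + hippocampus
# ---------------------------------------------------------------------------

def ingest_stroke_mask(bundle: StudyBundle, manual_stroke: LabelVolume,
                       mask: SupratentorialMask,
                       references: IntensityReferences | None = None
                       ) -> np.ndarray:
    """Validate a manually delineated chronic stroke mask.

    Chronic cortical strokes are FLAIR-bright and T1-dark; a mask whose
    mean signature disagrees triggers a warning (the delineation is still
    accepted — it is the analyst's authority).  Raises if the mask leaves
    the supratentorial mask.
    """
    m = manual_stroke.labels > 0
    if not m.any():
        return m
    if np.any(m & ~mask.mask):
        raise ValueError("stroke mask extends outside the supratentorial mask")
    if references is not None:
        zF = float(references.z_nawm(bundle, "FLAIR")[m].mean())
        zT1 = float(references.z_nawm(bundle, "T1")[m].mean())
        if zF <= 0 or zT1 >= 0:
            warnings.warn("stroke mask intensity signature mismatch: expected "
                          f"FLAIR-bright/T1-dark, got FLAIR z={zF:.2f}, "
                          f"T1 z={zT1:.2f}", stacklevel=2)
    return m


def subclassify_hippocampus(bundle: StudyBundle, hp_mask: LabelVolume,
                            stroke: np.ndarray | None,
                            references: IntensityReferences,
                            tau_t1: float = 2.5) -> dict[str, float]:
    """Split a hippocampal mask into parenchyma / hypointensity / stroke
    volumes (cc).  The three sub-volumes sum exactly to the mask volume.

    Hypointensities are CSF-like cavities: T1 z below the threshold
    against the *GM* reference (the hippocampus is a grey-matter
    structure, so NAWM would flag normal parenchyma)."""
    m = hp_mask.labels > 0
    voxel_cc = float(abs(np.linalg.det(np.asarray(hp_mask.affine)[:3, :3]))) / 1000.0
    stroke = np.zeros(m.shape, bool) if stroke is None else stroke
    z_t1 = references.z_gm(bundle, "T1")

    in_stroke = m & stroke
    hypo = m & ~stroke & (z_t1 < -tau_t1)
    paren = m & ~stroke & ~hypo
    return {"parenchyma_cc": float(paren.sum()) * voxel_cc,
            "hypointensity_cc": float(hypo.sum()) * voxel_cc,
            "stroke_cc": float(in_stroke.sum()) * voxel_cc,
            "total_cc": float(m.sum()) * voxel_cc}


# ---------------------------------------------------------------------------
# final partition
# ---------------------------------------------------------------------------

@dataclass
class LesionMaskSet:
    """Pairwise-disjoint binary lesion masks on the study grid."""

    pwmh: np.ndarray
    dwmh: np.ndarray
    placn: np.ndarray
    dlacn: np.ndarray
    pvs: np.ndarray
    stroke: np.ndarray

    def __post_init__(self):
        masks = self.as_dict()
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(masks[a] & masks[b]):
                    raise ValueError(f"lesion masks {a} and {b} overlap")

    @property
    def wmh(self) -> np.ndarray:
        return self.pwmh | self.dwmh

    @property
    def lacunes(self) -> np.ndarray:
        return self.placn | self.dlacn

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"pWMH": self.pwmh, "dWMH": self.dwmh, "pLACN": self.placn,
                "dLACN": self.dlacn, "PVS": self.pvs, "Stroke": self.stroke}

    @classmethod
    def empty(cls, shape) -> "LesionMaskSet":
        z = np.zeros(shape, bool)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


def correct_tissue_labels(tissue: LabelVolume, lesions: LesionMaskSet
                          ) -> LabelVolume:
    """Build the final ten-class partition with normal-appearing tissue.

    Lesion voxels are removed from the GM/WM/sCSF counts (the T1-based
    segmentation sees WMH as GM or CSF, inflating those volumes); what
    remains of GM and WM becomes NAGM and NAWM.  Precedence when masks
    disagree: stroke > lacunes > PVS > WMH > tissue, mirroring the manual
    workflow where the stroke delineation overrides automatic labels.
    Raises if any lesion mask touches ventricular CSF (an upstream bug).
    """
    raw = tissue.scheme
    final = tissue_scheme()
    vcsf = tissue.labels == raw["vCSF"]
    for name, m in lesions.as_dict().items():
        if np.any(m & vcsf):
            raise ValueError(f"lesion mask {name} overlaps ventricular CSF")

    out = np.zeros(tissue.labels.shape, dtype=np.int16)
    out[tissue.labels == raw["GM"]] = final["NAGM"]
    out[tissue.labels == raw["WM"]] = final["NAWM"]
    out[tissue.labels == raw["sCSF"]] = final["sCSF"]
    out[vcsf] = final["vCSF"]
    # ascending precedence
    for code, m in (("pWMH", lesions.pwmh), ("dWMH", lesions.dwmh),
                    ("PVS", lesions.pvs), ("pLACN", lesions.placn),
                    ("dLACN", lesions.dlacn), ("Stroke", lesions.stroke)):
        out[m & (out > 0)] = final[code]
    return LabelVolume(out, final, tissue.affine)
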