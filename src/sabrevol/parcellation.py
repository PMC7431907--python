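"""Supratentorial TIV extraction and landmark-driven region parcellation.

The head-size measure used throughout is the *supratentorial total
intracranial volume* (ST-TIV): everything inside the dural envelope and
above the tentorial cut plane, including sub-arachnoid/sulcal CSF.
Because the envelope — not the brain surface — bounds the measure, focal
atrophy (GM replaced by sulcal CSF) leaves the TIV unchanged.

The region grid is a Talairach-style construction from manually
identified landmarks: a mid-sagittal plane, coronal planes through AC
and PC and through the occipital boundary, an axial plane containing the
AC-PC line, a per-hemisphere parasagittal plane through the central
landmark, and a proportional dorsal-frontal split.  It yields 13 regions
per hemisphere (26 total), extendable to 28 by overlaying left/right
hippocampal masks.  All planes are half-open so every point lands in
exactly one region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .config import GridConfig, StripConfig
from .core_io import (
    LabelVolume,
    LandmarkSet,
    StudyBundle,
    grids_match,
    region_scheme,
    world_coordinates,
)

_STRUCT26 = np.ones((3, 3, 3), bool)


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), bool)
    ax = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= radius * radius


@dataclass
class SupratentorialMask:
    """Binary supratentorial mask plus the ST-TIV it implies."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    @property
    def tiv_cc(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_mm3 / 1000.0


def strip_to_supratentorial(bundle: StudyBundle,
                            landmarks: LandmarkSet | None = None,
                            config: StripConfig | None = None
                            ) -> SupratentorialMask:
    """Extract the supratentorial intracranial mask from the T1 volume.

    The dural envelope is found as the largest closed boundary around the
    head foreground: a multi-class Otsu threshold separates background
    from tissue, morphological closing and hole filling recover internal
    CSF (no erosion of the sulcal rind), and everything below the
    tentorial cut plane is removed.
    """
    config = config or StripConfig()
    landmarks = landmarks or bundle.landmark_set
    if landmarks is None:
        raise ValueError("landmarks required (tentorial_cut_point)")

    t1 = bundle.t1.voxels
    rng_span = float(t1.max() - t1.min())
    if rng_span < 1e-9:
        raise ValueError("empty foreground: constant T1 volume")
    try:
        thr = threshold_multiotsu(t1, classes=4)[0]
    except ValueError:  # fewer than 4 grey levels
        thr = threshold_multiotsu(t1, classes=2)[0] \
            if len(np.unique(t1)) > 2 else float(t1.min()) + 0.5 * rng_span
    fg = t1 > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")

    fg = ndimage.binary_closing(fg, _ball(config.closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg, structure=_STRUCT26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))

    point = landmarks["tentorial_cut_point"]
    normal = landmarks.points.get("tentorial_cut_normal")
    if normal is None:
        normal = np.array([0.0, 0.2, 0.98])
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    coords = world_coordinates(t1.shape, bundle.affine)
    above = np.einsum("...a,a->...", coords - point, normal) >= 0

    removed = np.count_nonzero(fg & ~above) / max(int(fg.sum()), 1)
    if removed > config.max_infratentorial_fraction:
        raise ValueError(
            f"tentorial plane excludes {removed:.0%} of the foreground; "
            "the tentorial_cut_point landmark is likely wrong")
    return SupratentorialMask(fg & above, bundle.affine)


# ---------------------------------------------------------------------------
# SABRE-style grid
# ---------------------------------------------------------------------------

@dataclass
class SabreGrid:
    """Plane inventory and total region lookup for one study.

    Axes are derived from the landmarks: the anterior-posterior unit
    vector runs PC->AC, the superior axis is its cross product with the
    mid-sagittal normal.  Region assignment is a pure function of world
    position, total on any point set.
    """

    ms_point: np.ndarray
    ms_normal: np.ndarray         # unit, oriented toward the right (+x-ish)
    ac: np.ndarray
    pc: np.ndarray
    ap_axis: np.ndarray           # unit, posterior -> anterior
    up_axis: np.ndarray           # unit, ventral -> dorsal
    y_pc: float                   # PC offset along ap_axis, relative to AC
    y_occ: float                  # occipital plane offset
    z_frontal_split: float        # SF/MF split height above the AC-PC plane
    lateral_offset: dict          # per side: |distance| of the parasagittal cut

    #: per-hemisphere region codes in canonical order
    HEMI_CODES = ("SF", "MF", "IF", "MIF", "MSF", "MMF",
                  "SP", "IP", "O", "AT", "PT", "ABGT", "PBGT")

    def classify_points(self, points: np.ndarray) -> np.ndarray:
        """Assign the 26-region integer label to each world-mm point.

        Half-open convention: a point exactly on a cut plane belongs to
        the anterior / left / superior side (medial for the parasagittal
        cut), so the assignment partitions space.
        """
        scheme = region_scheme()
        pts = np.atleast_2d(np.asarray(points, float))
        d_mid = (pts - self.ms_point) @ self.ms_normal
        y = (pts - self.ac) @ self.ap_axis
        z = (pts - self.ac) @ self.up_axis

        right = d_mid > 0  # boundary (d==0) goes to the left hemisphere
        out = np.zeros(len(pts), dtype=np.int16)
        for side, sel in (("L", ~right), ("R", right)):
            if not sel.any():
                continue
            lat = np.abs(d_mid[sel]) > self.lateral_offset[side]
            ys, zs = y[sel], z[sel]
            code = np.empty(sel.sum(), dtype="U4")

            frontal = ys >= 0.0
            central = (~frontal) & (ys >= self.y_pc)
            posterior = (ys < self.y_pc) & (ys >= self.y_occ)
            occipital = ys < self.y_occ

            dorsal = zs >= 0.0
            sf = zs >= self.z_frontal_split

            code[frontal & lat & sf] = "SF"
            code[frontal & lat & ~sf & dorsal] = "MF"
            code[frontal & lat & ~dorsal] = "IF"
            code[frontal & ~lat & sf] = "MSF"
            code[frontal & ~lat & ~sf & dorsal] = "MMF"
            code[frontal & ~lat & ~dorsal] = "MIF"
            code[central & lat & dorsal] = "SP"
            code[central & lat & ~dorsal] = "AT"
            code[central & ~lat] = "ABGT"
            code[posterior & lat & dorsal] = "IP"
            code[posterior & lat & ~dorsal] = "PT"
            code[posterior & ~lat] = "PBGT"
            code[occipital] = "O"

            ints = np.array([scheme[f"{side}_{c}"] for c in self.HEMI_CODES],
                            dtype=np.int16)
            lut = {c: i for c, i in zip(self.HEMI_CODES, ints)}
            out[sel] = np.vectorize(lut.__getitem__, otypes=[np.int16])(code)
        return out


def build_sabre_grid(landmarks: LandmarkSet, mask: SupratentorialMask,
                     config: GridConfig | None = None) -> SabreGrid:
    """Construct the per-hemisphere cut planes from the landmark set."""
    config = config or GridConfig()
    if not mask.mask.any():
        raise ValueError("empty supratentorial mask")

    ac, pc = landmarks["AC"], landmarks["PC"]
    if np.linalg.norm(ac - pc) < 1e-6:
        raise ValueError("degenerate landmarks: AC == PC")
    ms_normal = np.asarray(landmarks["mid_sagittal_normal"], float)
    n = np.linalg.norm(ms_normal)
    if n < 1e-9:
        raise ValueError("degenerate landmarks: mid_sagittal_normal ~ 0")
    ms_normal = ms_normal / n
    if ms_normal[0] < 0:  # orient toward the right for a stable L/R convention
        ms_normal = -ms_normal

    ap = ac - pc
    ap = ap / np.linalg.norm(ap)
    up = np.cross(ms_normal, ap)
    up = up / np.linalg.norm(up)
    if up[2] < 0:
        up = -up

    y_pc = float((pc - ac) @ ap)
    occ = 0.5 * (landmarks["occipital_boundary_left"]
                 + landmarks["occipital_boundary_right"])
    y_occ = float((occ - ac) @ ap)
    if not (y_occ < y_pc < 0.0):
        raise ValueError("landmark ordering violated: need occipital < PC < AC "
                         "along the AP axis")

    z_sup = float((landmarks["brain_extent_superior"] - ac) @ up)
    z_split = config.frontal_split_fraction * z_sup

    lateral_offset = {
        "L": abs(float((landmarks["central_landmark_left"]
                        - landmarks["mid_sagittal_point"]) @ ms_normal)),
        "R": abs(float((landmarks["central_landmark_right"]
                        - landmarks["mid_sagittal_point"]) @ ms_normal)),
    }

    grid = SabreGrid(ms_point=np.asarray(landmarks["mid_sagittal_point"], float),
                     ms_normal=ms_normal, ac=np.asarray(ac, float),
                     pc=np.asarray(pc, float), ap_axis=ap, up_axis=up,
                     y_pc=y_pc, y_occ=y_occ, z_frontal_split=z_split,
                     lateral_offset=lateral_offset)

    # warn (not fail) on regions that catch no masked voxel
    regions = assign_sabre_regions(grid, mask)
    counts = regions.counts()
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        warnings.warn(f"regions with zero voxels inside the mask: {empty}",
                      stacklevel=2)
    return grid


def assign_sabre_regions(grid: SabreGrid, mask: SupratentorialMask
                         ) -> LabelVolume:
    """Label every masked voxel with its region; unmasked voxels stay 0."""
    labels = np.zeros(mask.mask.shape, dtype=np.int16)
    coords = world_coordinates(mask.mask.shape, mask.affine)
    pts = coords[mask.mask]
    if len(pts):
        labels[mask.mask] = grid.classify_points(pts)
    return LabelVolume(labels, region_scheme(), mask.affine)


def merge_hippocampus_rois(regions: LabelVolume, hp_left: LabelVolume,
                           hp_right: LabelVolume) -> LabelVolume:
    """Overlay hippocampal masks as HP_L / HP_R, yielding the 28-ROI map.

    Hippocampal labels override the underlying temporal/BGT labels; all
    other voxels are untouched.  Raises if a hippocampal voxel falls
    outside the parcellated (supratentorial) area.
    """
    scheme28 = region_scheme(include_hippocampus=True)
    out = regions.labels.copy()
    for lv, code in ((hp_left, "L_HP"), (hp_right, "R_HP")):
        if not grids_match(regions.labels.shape, regions.affine,
                           lv.labels.shape, lv.affine):
            raise ValueError("grid mismatch between regions and hippocampal mask")
        m = lv.labels > 0
        if np.any(m & (regions.labels == 0)):
            raise ValueError(f"hippocampal mask {code} extends outside the "
                             "supratentorial mask")
        out[m] = scheme28[code]
    return LabelVolume(out, scheme28, regions.affine)
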