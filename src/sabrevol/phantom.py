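"""Seeded multi-contrast digital brain phantom with known ground truth.

The phantom is a nested-ellipsoid head: a dural envelope enclosing a GM
shell around a WM core, a sulcal CSF rind between parenchyma and dura,
bilateral ventricles, bilateral hippocampal ellipsoids, and an
infratentorial stub below an oblique tentorial plane.  Small vessel
disease lesions (periventricular/deep WMH, lacunes with FLAIR rims,
perivascular-space tubes, an optional cortical stroke wedge) are embedded
with recorded per-lesion inventories.  Four contrasts (T1/T2/PD/FLAIR)
are rendered from a class intensity table plus Gaussian noise.

Everything is deterministic given ``PhantomSpec.seed``: anatomy is fully
analytic, lesion placement and rendering use independent child streams of
a single seed sequence, so a fixed spec reproduces output bit-for-bit.

The *relative orderings* of the intensity table are constrained by the
radiological signatures the pipeline relies on (WMH bright on FLAIR and
T2 but GM-like on T1; lacunes dark on T1, bright on PD/T2, dark FLAIR
core with a bright rim — except in the thalamic territory where FLAIR is
insensitive; PVS narrow, elongated, PD-isointense to GM).  The absolute
values are arbitrary and live in :data:`DEFAULT_INTENSITY_TABLE`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core_io import (
    CONTRASTS,
    LabelScheme,
    LabelVolume,
    LandmarkSet,
    StudyBundle,
    Volume3D,
    binary_scheme,
    world_coordinates,
)

#: Ground-truth label scheme.  Lacunes are one truth class; the pipeline is
#: responsible for the periventricular/deep allocation.
TRUTH_CODES = {"GM": 1, "WM": 2, "sCSF": 3, "vCSF": 4,
               "pWMH": 5, "dWMH": 6, "LACN": 7, "PVS": 8, "Stroke": 9}

#: Render-only classes: rim voxels are WM in the truth but FLAIR-bright;
#: thalamic lacunes are lacunes whose FLAIR signal stays WM-like.
RENDER_EXTRA = {"LACN_RIM": 10, "LACN_THAL": 11}


def truth_scheme() -> LabelScheme:
    return LabelScheme("phantom_truth", dict(TRUTH_CODES))


#: (mean, sd-scale) per class and contrast.  The sd-scale multiplies
#: ``PhantomSpec.noise_sd``; absolute means are arbitrary, orderings are not.
DEFAULT_INTENSITY_TABLE = {
    #            T1         T2         PD         FLAIR
    "GM":        {"T1": (90, 1), "T2": (80, 1), "PD": (85, 1), "FLAIR": (70, 1)},
    "WM":        {"T1": (120, 1), "T2": (60, 1), "PD": (70, 1), "FLAIR": (70, 1)},
    "sCSF":      {"T1": (30, 1), "T2": (140, 1), "PD": (60, 1), "FLAIR": (20, 1)},
    "vCSF":      {"T1": (30, 1), "T2": (140, 1), "PD": (60, 1), "FLAIR": (20, 1)},
    "pWMH":      {"T1": (90, 1), "T2": (130, 1), "PD": (110, 1), "FLAIR": (140, 1)},
    "dWMH":      {"T1": (90, 1), "T2": (130, 1), "PD": (110, 1), "FLAIR": (140, 1)},
    "LACN":      {"T1": (30, 1), "T2": (140, 1), "PD": (130, 1), "FLAIR": (25, 1)},
    "LACN_THAL": {"T1": (30, 1), "T2": (140, 1), "PD": (130, 1), "FLAIR": (70, 1)},
    "LACN_RIM":  {"T1": (120, 1), "T2": (60, 1), "PD": (70, 1), "FLAIR": (130, 1)},
    "PVS":       {"T1": (30, 1), "T2": (130, 1), "PD": (85, 1), "FLAIR": (70, 1)},
    "Stroke":    {"T1": (30, 1), "T2": (130, 1), "PD": (100, 1), "FLAIR": (140, 1)},
}


@dataclass
class LesionLoad:
    """Counts and size ranges (mm) for each embedded lesion family."""

    n_pwmh: int = 2
    pwmh_radius_mm: tuple[float, float] = (3.0, 5.0)
    n_dwmh: int = 3
    dwmh_radius_mm: tuple[float, float] = (1.4, 1.8)
    #: deep WMH are kept at > 13 mm from the ventricles by default so the
    #: connectivity and distance splitters agree; hard mode moves them into
    #: the ambiguous 5-13 mm band.
    dwmh_distance_mm: tuple[float, float] = (15.0, 30.0)
    n_lacunes: int = 1
    lacune_diameter_mm: tuple[float, float] = (5.0, 8.0)
    n_thalamic_lacunes: int = 1
    thalamic_lacune_diameter_mm: tuple[float, float] = (4.0, 6.0)
    n_pvs: int = 2
    pvs_width_mm: float = 1.8
    pvs_length_mm: tuple[float, float] = (6.0, 9.0)
    n_stroke: int = 1
    stroke_radius_mm: tuple[float, float] = (7.0, 10.0)
    hp_cavity_voxels: int = 0

    def total(self) -> int:
        return (self.n_pwmh + self.n_dwmh + self.n_lacunes
                + self.n_thalamic_lacunes + self.n_pvs + self.n_stroke
                + (1 if self.hp_cavity_voxels else 0))

    @classmethod
    def none(cls) -> "LesionLoad":
        return cls(n_pwmh=0, n_dwmh=0, n_lacunes=0, n_thalamic_lacunes=0,
                   n_pvs=0, n_stroke=0, hp_cavity_voxels=0)


@dataclass
class PhantomSpec:
    """Full description of a phantom study; (spec, seed) fix the output."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.0
    intensity_table: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_INTENSITY_TABLE))
    lesion_load: LesionLoad = field(default_factory=LesionLoad)
    noise_sd: float = 3.0
    seed: int = 0
    #: widen the sulcal CSF rind by shrinking the parenchyma (simulated
    #: focal/global atrophy); the dural envelope is untouched.
    atrophy_mm: float = 0.0
    subject_id: str = "phantom"

    def __post_init__(self):
        if min(self.grid_shape) < 32:
            raise ValueError("grid too small to host all structures "
                             "(need >= 32 voxels per axis)")
        if self.lesion_load.total() < 0 or any(
                n < 0 for n in (self.lesion_load.n_pwmh, self.lesion_load.n_dwmh,
                                self.lesion_load.n_lacunes, self.lesion_load.n_pvs,
                                self.lesion_load.n_thalamic_lacunes,
                                self.lesion_load.n_stroke)):
            raise ValueError("lesion counts must be >= 0")
        for cls in TRUTH_CODES:
            tab = self.intensity_table.get(cls if cls in self.intensity_table
                                           else cls)
            if cls not in self.intensity_table:
                raise ValueError(f"intensity table missing class {cls}")
            for contrast in CONTRASTS:
                if contrast not in self.intensity_table[cls]:
                    raise ValueError(
                        f"intensity table missing ({cls}, {contrast})")

    def hard_mode(self) -> "PhantomSpec":
        """Variant with deep WMH placed 5-13 mm from the ventricles."""
        load = replace(self.lesion_load, dwmh_distance_mm=(5.0, 13.0))
        return replace(self, lesion_load=load)

    @property
    def affine(self) -> np.ndarray:
        """Grid centred on the world origin; RAS+, isotropic spacing."""
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.spacing_mm
        a[:3, 3] = -(np.asarray(self.grid_shape) - 1) * self.spacing_mm / 2.0
        return a


# ---------------------------------------------------------------------------
# analytic geometry (all fractions of the half-extent; absolute mm elsewhere)
# ---------------------------------------------------------------------------

_GEOM_FRACTIONS = {
    "dura_semi": (0.750, 0.875, 0.708),
    "gm_semi": (0.688, 0.813, 0.646),
    "wm_semi": (0.542, 0.667, 0.500),
    "ventricle_center": (0.167, -0.125, 0.042),   # mirrored in x
    "ventricle_semi": (0.104, 0.292, 0.125),
    "hippocampus_center": (0.500, -0.250, -0.292),
    "hippocampus_semi": (0.073, 0.188, 0.094),
    "stub_center": (0.0, -0.167, -0.594),
    "stub_semi": (0.146, 0.104, 0.063),
    "ac": (0.0, 0.250, -0.042),
    "pc": (0.0, -0.292, -0.042),
    "tentorial_point": (0.0, 0.0, -0.500),
    "occipital_y": -0.583,
    "central_x": 0.375,
}

_TENTORIAL_NORMAL = np.array([0.0, 0.2, 0.98])
_TENTORIAL_NORMAL = _TENTORIAL_NORMAL / np.linalg.norm(_TENTORIAL_NORMAL)


@dataclass
class PhantomGeometry:
    """Ellipsoid centres/semi-axes and cut planes, in world mm."""

    half_extent: np.ndarray
    dura_semi: np.ndarray
    gm_semi: np.ndarray
    wm_semi: np.ndarray
    ventricle_center: np.ndarray
    ventricle_semi: np.ndarray
    hippocampus_center: np.ndarray
    hippocampus_semi: np.ndarray
    stub_center: np.ndarray
    stub_semi: np.ndarray
    ac: np.ndarray
    pc: np.ndarray
    tentorial_point: np.ndarray
    tentorial_normal: np.ndarray
    occipital_y: float
    central_x: float

    @classmethod
    def from_spec(cls, spec: PhantomSpec) -> "PhantomGeometry":
        h = np.asarray(spec.grid_shape) * spec.spacing_mm / 2.0
        f = _GEOM_FRACTIONS
        gm = np.asarray(f["gm_semi"]) * h - spec.atrophy_mm
        return cls(
            half_extent=h,
            dura_semi=np.asarray(f["dura_semi"]) * h,
            gm_semi=gm,
            wm_semi=np.minimum(np.asarray(f["wm_semi"]) * h, gm - 2.0),
            ventricle_center=np.asarray(f["ventricle_center"]) * h,
            ventricle_semi=np.asarray(f["ventricle_semi"]) * h,
            hippocampus_center=np.asarray(f["hippocampus_center"]) * h,
            hippocampus_semi=np.asarray(f["hippocampus_semi"]) * h,
            stub_center=np.asarray(f["stub_center"]) * h,
            stub_semi=np.asarray(f["stub_semi"]) * h,
            ac=np.asarray(f["ac"]) * h,
            pc=np.asarray(f["pc"]) * h,
            tentorial_point=np.asarray(f["tentorial_point"]) * h,
            tentorial_normal=_TENTORIAL_NORMAL.copy(),
            occipital_y=f["occipital_y"] * h[1],
            central_x=f["central_x"] * h[0],
        )

    def landmarks(self) -> LandmarkSet:
        d = self.dura_semi
        pts = {
            "AC": self.ac,
            "PC": self.pc,
            "mid_sagittal_point": np.zeros(3),
            "mid_sagittal_normal": np.array([1.0, 0.0, 0.0]),
            "tentorial_cut_point": self.tentorial_point,
            "brain_extent_anterior": np.array([0.0, d[1], 0.0]),
            "brain_extent_posterior": np.array([0.0, -d[1], 0.0]),
            "brain_extent_superior": np.array([0.0, 0.0, d[2]]),
            "occipital_boundary_left": np.array([-10.0, self.occipital_y, 0.0]),
            "occipital_boundary_right": np.array([10.0, self.occipital_y, 0.0]),
            "temporal_boundary_left": np.array([-d[0], -5.0, -8.0]),
            "temporal_boundary_right": np.array([d[0], -5.0, -8.0]),
            "central_landmark_left": np.array([-self.central_x, 0.0, 5.0]),
            "central_landmark_right": np.array([self.central_x, 0.0, 5.0]),
        }
        return LandmarkSet(pts)


def _inside_ellipsoid(coords, center, semi) -> np.ndarray:
    d = (coords - center) / semi
    return np.einsum("...a,...a->...", d, d) <= 1.0


def _mirror(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    out[0] = -out[0]
    return out


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground-truth labels, landmarks, geometry and lesion inventory."""

    tissue_truth: LabelVolume
    landmark_set: LandmarkSet
    geometry: PhantomGeometry
    spec: PhantomSpec
    lesion_inventory: list[dict] = field(default_factory=list)
    #: auxiliary boolean masks: hippocampus_left/right, lacune_rim (WM voxels
    #: rendered FLAIR-bright), thalamic_lacune (LACN voxels with no FLAIR
    #: signal), hp_cavity.
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.tissue_truth.labels

    def supratentorial_truth(self) -> np.ndarray:
        """Analytic supratentorial mask: inside dura, above tentorial plane."""
        coords = world_coordinates(self.tissue_truth.labels.shape,
                                   self.tissue_truth.affine)
        g = self.geometry
        inside = _inside_ellipsoid(coords, np.zeros(3), g.dura_semi)
        above = np.einsum("...a,a->...", coords - g.tentorial_point,
                          g.tentorial_normal) >= 0
        return inside & above

    def class_mask(self, code: str) -> np.ndarray:
        return self.labels == TRUTH_CODES[code]

    def inventory_count(self, cls: str) -> int:
        return sum(1 for r in self.lesion_inventory if r["class"] == cls)


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def generate_anatomy(spec: PhantomSpec) -> PhantomTruth:
    """Build the lesion-free nested-ellipsoid anatomy and its landmarks.

    The label volume covers GM, WM, sulcal CSF (the rind between parenchyma
    and dura plus the infratentorial stub's surround), and bilateral
    ventricular CSF.  Left/right mirror symmetry is exact when no lesions
    are embedded, because every structure is either midline or mirrored and
    the grid is centred on the mid-sagittal plane.
    """
    geom = PhantomGeometry.from_spec(spec)
    coords = world_coordinates(spec.grid_shape, spec.affine)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    dura = _inside_ellipsoid(coords, np.zeros(3), geom.dura_semi)
    gm = _inside_ellipsoid(coords, np.zeros(3), geom.gm_semi)
    wm = _inside_ellipsoid(coords, np.zeros(3), geom.wm_semi)

    labels[dura] = TRUTH_CODES["sCSF"]          # rind (and infratentorial fill)
    labels[gm] = TRUTH_CODES["GM"]
    labels[wm] = TRUTH_CODES["WM"]

    vc, vs = geom.ventricle_center, geom.ventricle_semi
    vent = (_inside_ellipsoid(coords, vc, vs)
            | _inside_ellipsoid(coords, _mirror(vc), vs))
    labels[vent] = TRUTH_CODES["vCSF"]

    hc, hs = geom.hippocampus_center, geom.hippocampus_semi
    hp_r = _inside_ellipsoid(coords, hc, hs)
    hp_l = _inside_ellipsoid(coords, _mirror(hc), hs)
    labels[hp_r | hp_l] = TRUTH_CODES["GM"]     # hippocampal parenchyma

    stub = _inside_ellipsoid(coords, geom.stub_center, geom.stub_semi) & dura
    labels[stub] = TRUTH_CODES["GM"]            # infratentorial tissue stub

    truth = PhantomTruth(
        tissue_truth=LabelVolume(labels, truth_scheme(), spec.affine),
        landmark_set=geom.landmarks(),
        geometry=geom,
        spec=spec,
        masks={"hippocampus_left": hp_l, "hippocampus_right": hp_r,
               "lacune_rim": np.zeros(spec.grid_shape, bool),
               "thalamic_lacune": np.zeros(spec.grid_shape, bool),
               "hp_cavity": np.zeros(spec.grid_shape, bool)},
    )
    return truth


# ---------------------------------------------------------------------------
# lesion embedding
# ---------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """A lesion could not be placed within the retry budget."""


_RETRIES = 100
_STRUCT26 = np.ones((3, 3, 3), bool)


def _sphere(coords, center, radius):
    d = coords - center
    return np.einsum("...a,...a->...", d, d) <= radius * radius


def _pick(rng, candidates: np.ndarray) -> tuple[int, int, int]:
    idx = np.flatnonzero(candidates)
    if idx.size == 0:
        raise PlacementError("no candidate voxels for lesion placement")
    return np.unravel_index(idx[rng.integers(idx.size)], candidates.shape)


def embed_small_vessel_lesions(truth: PhantomTruth,
                               spec: PhantomSpec | None = None,
                               rng: np.random.Generator | None = None
                               ) -> PhantomTruth:
    """Embed the requested lesion load into a generated anatomy.

    Adds periventricular WMH caps contiguous with the ventricular surface,
    punctate deep WMH at a controlled distance from the ventricles, deep and
    thalamic-territory lacunes (each with a recorded one-voxel WM rim
    shell), perivascular-space tubes at least three times longer than wide,
    and an optional cortical stroke wedge spanning GM and WM.  Lesions of
    different classes never overlap (a one-voxel separation margin is kept)
    and every lesion stays supratentorial.  Raises :class:`PlacementError`
    after 100 failed attempts for any single lesion.
    """
    spec = spec or truth.spec
    load = spec.lesion_load
    if load.total() == 0:
        return truth
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(spec.seed) % (2 ** 31), 1])))

    truth = PhantomTruth(
        tissue_truth=LabelVolume(truth.labels.copy(), truth.tissue_truth.scheme,
                                 truth.tissue_truth.affine),
        landmark_set=truth.landmark_set, geometry=truth.geometry, spec=spec,
        lesion_inventory=list(truth.lesion_inventory),
        masks={k: v.copy() for k, v in truth.masks.items()},
    )
    labels = truth.labels
    geom = truth.geometry
    coords = world_coordinates(labels.shape, truth.tissue_truth.affine)
    spacing = float(spec.spacing_mm)
    supra = truth.supratentorial_truth()

    wm = labels == TRUTH_CODES["WM"]
    gm = labels == TRUTH_CODES["GM"]
    vcsf = labels == TRUTH_CODES["vCSF"]
    hp = truth.masks["hippocampus_left"] | truth.masks["hippocampus_right"]

    # world-mm distance to the nearest ventricular voxel
    dist_vcsf = ndimage.distance_transform_edt(~vcsf, sampling=[spacing] * 3)

    occupied = ndimage.binary_dilation(hp, _STRUCT26)

    def _free(blob):
        return not np.any(blob & occupied)

    def _commit(blob, code, cls, record):
        labels[blob] = TRUTH_CODES[code]
        nonlocal occupied
        occupied |= ndimage.binary_dilation(blob, _STRUCT26)
        record.update(
            {"class": cls,
             "centroid_mm": [float(x) for x in coords[blob].mean(axis=0)],
             "voxel_count": int(blob.sum())})
        truth.lesion_inventory.append(record)

    # --- periventricular WMH caps: grown from the ventricular surface -----
    vent_surface_wm = wm & ndimage.binary_dilation(vcsf, _STRUCT26)
    for _ in range(load.n_pwmh):
        for attempt in range(_RETRIES):
            c = _pick(rng, vent_surface_wm & ~occupied)
            r = rng.uniform(*load.pwmh_radius_mm)
            blob = _sphere(coords, coords[c], r) & wm & supra
            if blob.any() and _free(blob) and np.any(
                    blob & ndimage.binary_dilation(vcsf, _STRUCT26)):
                _commit(blob, "pWMH", "pWMH", {"nominal_radius_mm": float(r)})
                break
        else:
            raise PlacementError("could not place periventricular WMH cap")

    # --- deep punctate WMH at a controlled ventricular distance -----------
    d0, d1 = load.dwmh_distance_mm
    for _ in range(load.n_dwmh):
        for attempt in range(_RETRIES):
            r = rng.uniform(*load.dwmh_radius_mm)
            band = wm & supra & (dist_vcsf >= d0 + r) & (dist_vcsf <= d1)
            c = _pick(rng, band & ~occupied)
            blob = _sphere(coords, coords[c], r) & wm & supra
            if blob.any() and _free(blob) and dist_vcsf[blob].min() >= d0:
                _commit(blob, "dWMH", "dWMH", {"nominal_radius_mm": float(r)})
                break
        else:
            raise PlacementError("could not place deep WMH")

    # --- lacunes: ellipsoidal cavities with a recorded WM rim shell -------
    def _place_lacune(diam_range, region_ok, thalamic):
        for attempt in range(_RETRIES):
            diam = rng.uniform(*diam_range)
            r = diam / 2.0
            interior = wm & supra & (dist_vcsf >= r + 2.5) & region_ok
            c = _pick(rng, interior & ~occupied)
            semi = np.array([r, r * rng.uniform(1.0, 1.3), r])
            core = _inside_ellipsoid(coords, coords[c], semi) & supra
            rim = ndimage.binary_dilation(core, _STRUCT26) & ~core
            if (core.any() and np.all(wm[core]) and np.all(wm[rim])
                    and _free(core | rim) and dist_vcsf[core].min() >= 2.5):
                _commit(core, "LACN",
                        "LACN_thalamic" if thalamic else "LACN",
                        {"nominal_diameter_mm": float(diam)})
                if thalamic:
                    truth.masks["thalamic_lacune"] |= core
                else:
                    truth.masks["lacune_rim"] |= rim
                return
        raise PlacementError("could not place lacune")

    # deep (frontal white matter) lacunes, outside the BGT territory
    frontal = coords[..., 1] >= geom.ac[1] + 3.0
    for _ in range(load.n_lacunes):
        _place_lacune(load.lacune_diameter_mm, frontal, thalamic=False)

    # thalamic-territory lacunes: medial, between the AC and PC coronal
    # planes, below the AC-PC axial plane (lands in the BGT region)
    bgt_box = ((np.abs(coords[..., 0]) >= 3.0)
               & (np.abs(coords[..., 0]) <= 0.6 * geom.central_x)
               & (coords[..., 1] > geom.pc[1] + 2.0)
               & (coords[..., 1] < geom.ac[1] - 2.0)
               & (coords[..., 2] < geom.ac[2] - 1.0))
    for _ in range(load.n_thalamic_lacunes):
        _place_lacune(load.thalamic_lacune_diameter_mm, bgt_box, thalamic=True)

    # --- perivascular space tubes -----------------------------------------
    # tubes must sit strictly inside WM (one-voxel clearance) so the
    # fluid-filled cavity they leave is fully enclosed by white matter
    wm_interior = ndimage.binary_erosion(wm, _STRUCT26)
    for _ in range(load.n_pvs):
        for attempt in range(_RETRIES):
            length = rng.uniform(*load.pvs_length_mm)
            radius = load.pvs_width_mm / 2.0
            interior = wm_interior & supra & (dist_vcsf >= 3.0)
            c = _pick(rng, interior & ~occupied)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rel = coords - coords[c]
            t = np.einsum("...a,a->...", rel, u)
            t_clamped = np.clip(t, -length / 2.0, length / 2.0)
            closest = coords[c] + t_clamped[..., None] * u
            d2 = np.einsum("...a,...a->...", coords - closest, coords - closest)
            near = np.abs(t) <= length / 2.0 + radius + 1.0
            tube = (d2 < radius * radius) & near & supra
            if tube.any() and np.all(wm_interior[tube]) and _free(tube):
                _commit(tube, "PVS", "PVS",
                        {"nominal_width_mm": float(load.pvs_width_mm),
                         "nominal_length_mm": float(length),
                         "axis": [float(x) for x in u]})
                break
        else:
            raise PlacementError("could not place PVS tube")

    # --- cortical stroke wedge: spherical sector at the GM surface --------
    for _ in range(load.n_stroke):
        for attempt in range(_RETRIES):
            u = rng.normal(size=3)
            u[0] = np.sign(u[0] or 1.0) * max(abs(u[0]), 0.6)  # lateral
            u[2] = abs(u[2])                                   # dorsal
            u /= np.linalg.norm(u)
            surface = u / np.linalg.norm(u / geom.gm_semi)     # on GM ellipsoid
            r = rng.uniform(*load.stroke_radius_mm)
            ball = _sphere(coords, surface, r)
            inward = np.einsum("...a,a->...", coords - surface, -u)
            wedge = ball & (inward >= -0.25 * r) & (gm | wm) & supra
            wedge &= dist_vcsf > 2.0
            if (wedge.any() and np.any(wedge & gm) and np.any(wedge & wm)
                    and _free(wedge)):
                _commit(wedge, "Stroke", "Stroke",
                        {"nominal_radius_mm": float(r),
                         "direction": [float(x) for x in u]})
                break
        else:
            raise PlacementError("could not place stroke wedge")

    # --- hippocampal cavity (CSF-like hypointensity inside left HP) -------
    if load.hp_cavity_voxels > 0:
        hp_l = truth.masks["hippocampus_left"]
        eroded = ndimage.binary_erosion(hp_l, _STRUCT26)
        target = eroded if eroded.sum() >= load.hp_cavity_voxels else hp_l
        c = _pick(rng, target)
        d = coords - coords[c]
        order = np.argsort(np.einsum("...a,...a->...", d, d)[target].ravel())
        idx = np.argwhere(target)[order[:load.hp_cavity_voxels]]
        cavity = np.zeros_like(hp_l)
        cavity[tuple(idx.T)] = True
        labels[cavity] = TRUTH_CODES["sCSF"]
        truth.masks["hp_cavity"] = cavity
        truth.lesion_inventory.append(
            {"class": "hp_cavity", "voxel_count": int(cavity.sum()),
             "centroid_mm": [float(x) for x in coords[cavity].mean(axis=0)]})

    truth.tissue_truth = LabelVolume(labels, truth_scheme(),
                                     truth.tissue_truth.affine)
    return truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _mean(table, cls, contrast):
    return float(table[cls][contrast][0])


#: (description, predicate over the mean table) — violated orderings abort
#: rendering with an error naming the constraint.
_ORDERING_CONSTRAINTS = [
    ("T1: WM > GM", lambda m: m("WM", "T1") > m("GM", "T1")),
    ("T1: GM > CSF", lambda m: m("GM", "T1") > m("sCSF", "T1")
        and m("GM", "T1") > m("vCSF", "T1")),
    ("T1: WMH isointense to GM", lambda m: max(
        abs(m("pWMH", "T1") - m("GM", "T1")),
        abs(m("dWMH", "T1") - m("GM", "T1")))
        <= 0.25 * (m("WM", "T1") - m("sCSF", "T1"))),
    ("T1: lacune hypointense", lambda m: m("LACN", "T1") < m("GM", "T1")
        and m("LACN_THAL", "T1") < m("GM", "T1")),
    ("T1: PVS hypointense", lambda m: m("PVS", "T1") < m("GM", "T1")),
    ("T1: stroke hypointense", lambda m: m("Stroke", "T1") < m("GM", "T1")),
    ("T2: CSF bright", lambda m: m("sCSF", "T2") > m("GM", "T2")
        and m("sCSF", "T2") > m("WM", "T2")),
    ("T2: WMH bright", lambda m: m("pWMH", "T2") > m("WM", "T2")
        and m("dWMH", "T2") > m("WM", "T2")),
    ("T2: lacune bright", lambda m: m("LACN", "T2") > m("WM", "T2")),
    ("T2: PVS bright", lambda m: m("PVS", "T2") > m("WM", "T2")),
    ("PD: lacune bright", lambda m: m("LACN", "PD") > m("GM", "PD")
        and m("LACN_THAL", "PD") > m("GM", "PD")),
    ("PD: PVS isointense to GM", lambda m: abs(m("PVS", "PD") - m("GM", "PD"))
        <= 0.25 * (m("LACN", "PD") - m("WM", "PD"))),
    ("FLAIR: WMH bright", lambda m: m("pWMH", "FLAIR") > m("WM", "FLAIR")
        and m("dWMH", "FLAIR") > m("WM", "FLAIR")),
    ("FLAIR: CSF dark", lambda m: m("sCSF", "FLAIR") < m("WM", "FLAIR")),
    ("FLAIR: lacune core dark", lambda m: m("LACN", "FLAIR") < m("WM", "FLAIR")),
    ("FLAIR: lacune rim bright", lambda m: m("LACN_RIM", "FLAIR") > m("WM", "FLAIR")),
    ("FLAIR: thalamic lacune not bright", lambda m: m("LACN_THAL", "FLAIR")
        <= m("WM", "FLAIR")
        + 0.15 * (m("pWMH", "FLAIR") - m("WM", "FLAIR"))),
    ("FLAIR: stroke bright", lambda m: m("Stroke", "FLAIR") > m("WM", "FLAIR")),
]


def validate_intensity_table(table: dict) -> None:
    """Check all radiological ordering constraints; raise naming the first
    violated one."""
    for cls in list(TRUTH_CODES) + list(RENDER_EXTRA):
        if cls not in table:
            raise ValueError(f"intensity table missing class {cls}")
        for contrast in CONTRASTS:
            if contrast not in table[cls]:
                raise ValueError(f"intensity table missing ({cls}, {contrast})")
    m = lambda cls, contrast: _mean(table, cls, contrast)  # noqa: E731
    for name, ok in _ORDERING_CONSTRAINTS:
        if not ok(m):
            raise ValueError(f"intensity table violates ordering: {name}")


def render_sequences(truth: PhantomTruth, spec: PhantomSpec | None = None,
                     rng: np.random.Generator | None = None) -> StudyBundle:
    """Render the four contrasts from the intensity table plus noise.

    Lacune rims are FLAIR-bright WM voxels (they keep WM intensity on the
    other contrasts); thalamic lacunes keep a WM-like FLAIR signal.  The
    bundle carries the landmarks and the manual masks the semi-automated
    workflow would provide: the stroke delineation, both hippocampi, and
    ventricle seeds.
    """
    spec = spec or truth.spec
    validate_intensity_table(spec.intensity_table)
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(spec.seed) % (2 ** 31), 2])))

    render = truth.labels.astype(np.int16).copy()
    render[truth.masks["lacune_rim"]] = RENDER_EXTRA["LACN_RIM"]
    render[truth.masks["thalamic_lacune"]] = RENDER_EXTRA["LACN_THAL"]

    all_codes = {**TRUTH_CODES, **RENDER_EXTRA}
    vols = {}
    for contrast in CONTRASTS:
        means = np.zeros(max(all_codes.values()) + 1)
        scales = np.zeros_like(means)
        for cls, code in all_codes.items():
            mu, sd_scale = spec.intensity_table[cls][contrast]
            means[code] = mu
            scales[code] = sd_scale
        img = means[render]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape) \
                * scales[render].clip(min=0)
        vols[contrast] = Volume3D(img, spec.affine, contrast)

    vox = np.zeros(truth.labels.shape, dtype=np.int16)
    masks = {}
    stroke = truth.class_mask("Stroke")
    if stroke.any():
        masks["stroke"] = LabelVolume(stroke.astype(np.int16),
                                      binary_scheme("stroke"), spec.affine)
    for role in ("hippocampus_left", "hippocampus_right"):
        masks[role] = LabelVolume(truth.masks[role].astype(np.int16),
                                  binary_scheme(role), spec.affine)
    seeds = vox.copy()
    coords = world_coordinates(truth.labels.shape, spec.affine)
    for center in (truth.geometry.ventricle_center,
                   _mirror(truth.geometry.ventricle_center)):
        seeds[_sphere(coords, center, 2.0)] = 1
    masks["ventricle_seed"] = LabelVolume(seeds, binary_scheme("ventricle_seed"),
                                          spec.affine)

    return StudyBundle(vols["T1"], vols["T2"], vols["PD"], vols["FLAIR"],
                       subject_id=spec.subject_id,
                       landmark_set=truth.landmark_set, manual_masks=masks)


def generate_phantom(spec: PhantomSpec) -> tuple[StudyBundle, PhantomTruth]:
    """Anatomy -> lesions -> rendering, fully determined by the PhantomSpec."""
    truth = generate_anatomy(spec)
    truth = embed_small_vessel_lesions(truth, spec)
    bundle = render_sequences(truth, spec)
    return bundle, truth
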