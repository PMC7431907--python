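"""Data model, coded label schemes, and I/O for the volumetrics pipeline.

All geometry is carried in world millimetres through a NIfTI-style affine
(RAS+ orientation): voxel indices are 0-based and ``affine @ [i, j, k, 1]``
gives the world position of a voxel centre.  Distances, plane cuts, and
lesion widths are always computed in world mm so anisotropic voxels are
handled correctly.

Label schemes are small frozen code->integer mappings.  Two families exist:

* tissue/lesion codes — the ten classes of the final per-voxel partition
  (NAGM, NAWM, sCSF, vCSF, pWMH, dWMH, pLACN, dLACN, PVS, Stroke), plus a
  four-class "raw" scheme (GM, WM, sCSF, vCSF) used before lesion
  correction;
* region codes — 13 landmark-derived regions per hemisphere (26 total),
  extendable to 28 with left/right hippocampus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

CONTRASTS = ("T1", "T2", "PD", "FLAIR")

#: Final tissue/lesion classes, in canonical (spreadsheet) order.
TISSUE_CODES = (
    "NAGM", "NAWM", "sCSF", "vCSF",
    "pWMH", "dWMH", "pLACN", "dLACN", "PVS", "Stroke",
)

#: Classes reported in cubic centimetres; the lesion classes use mm^3.
CC_CODES = frozenset({"NAGM", "NAWM", "sCSF", "vCSF"})

#: Per-hemisphere region codes in canonical row order.
REGION_ROW_ORDER = (
    "SF", "MF", "IF", "MIF", "MSF", "MMF",
    "SP", "IP", "O", "AT", "PT", "ABGT", "PBGT",
)

#: Lobe membership of each per-hemisphere region code.
LOBE_OF = {
    "SF": "Frontal", "MF": "Frontal", "IF": "Frontal",
    "MIF": "Frontal", "MSF": "Frontal", "MMF": "Frontal",
    "SP": "Parietal", "IP": "Parietal",
    "O": "Occipital",
    "AT": "Temporal", "PT": "Temporal",
    "ABGT": "Basal ganglia/thalamus", "PBGT": "Basal ganglia/thalamus",
    "HP": "Medial temporal",
}

#: Landmarks every study must provide (world mm; the mid-sagittal normal is
#: a direction vector, all other entries are points).
REQUIRED_LANDMARKS = (
    "AC", "PC", "mid_sagittal_point", "mid_sagittal_normal",
    "tentorial_cut_point",
    "brain_extent_anterior", "brain_extent_posterior", "brain_extent_superior",
    "occipital_boundary_left", "occipital_boundary_right",
    "temporal_boundary_left", "temporal_boundary_right",
    "central_landmark_left", "central_landmark_right",
)

MANUAL_MASK_ROLES = ("stroke", "hippocampus_left", "hippocampus_right", "ventricle_seed")


# ---------------------------------------------------------------------------
# label schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelScheme:
    """Bijective mapping between code strings and positive integer labels."""

    name: str
    mapping: Mapping[str, int]

    def __post_init__(self):
        vals = list(self.mapping.values())
        if len(set(self.mapping)) != len(self.mapping):
            raise ValueError("duplicate codes in label scheme")
        if len(set(vals)) != len(vals):
            raise ValueError("duplicate integers in label scheme")
        if any(v <= 0 for v in vals):
            raise ValueError("label integers must be positive (0 is background)")
        object.__setattr__(self, "mapping", dict(self.mapping))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def __getitem__(self, code: str) -> int:
        return self.mapping[code]

    def code_of(self, value: int) -> str:
        for c, v in self.mapping.items():
            if v == value:
                return c
        raise KeyError(value)

    def __len__(self) -> int:
        return len(self.mapping)


def tissue_scheme() -> LabelScheme:
    """Final ten-class tissue/lesion scheme."""
    return LabelScheme("tissue", {c: i + 1 for i, c in enumerate(TISSUE_CODES)})


def raw_tissue_scheme() -> LabelScheme:
    """Pre-correction tissue scheme: GM, WM, sulcal and ventricular CSF."""
    return LabelScheme("raw_tissue", {"GM": 1, "WM": 2, "sCSF": 3, "vCSF": 4})


def region_scheme(include_hippocampus: bool = False) -> LabelScheme:
    """26-region scheme (13 per hemisphere), optionally with L/R hippocampus."""
    mapping = {}
    i = 1
    for side in ("L", "R"):
        for code in REGION_ROW_ORDER:
            mapping[f"{side}_{code}"] = i
            i += 1
    if include_hippocampus:
        mapping["L_HP"] = i
        mapping["R_HP"] = i + 1
    return LabelScheme("regions", mapping)


def binary_scheme(code: str = "mask") -> LabelScheme:
    return LabelScheme("binary", {code: 1})


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("world mapping is not invertible")
    return affine


@dataclass
class Volume3D:
    """A single 3D contrast volume with its world mapping.

    ``voxels`` is a 3D scalar array; ``affine`` maps 0-based voxel indices
    to RAS+ world mm; ``contrast_tag`` is one of T1/T2/PD/FLAIR.
    """

    voxels: np.ndarray
    affine: np.ndarray
    contrast_tag: str

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("each axis must have length >= 1")
        self.affine = _check_affine(self.affine)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        if self.contrast_tag not in CONTRASTS:
            raise ValueError(f"unknown contrast tag {self.contrast_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape (*shape, 3)."""
        return world_coordinates(self.shape, self.affine)


def world_coordinates(shape, affine) -> np.ndarray:
    idx = np.indices(shape, dtype=float)  # (3, *shape)
    lin = np.asarray(affine, dtype=float)
    out = np.einsum("ab,b...->...a", lin[:3, :3], idx)
    out += lin[:3, 3]
    return out


@dataclass
class LabelVolume:
    """Integer-coded 3D map on a study grid; background is 0."""

    labels: np.ndarray
    scheme: LabelScheme
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.labels)) - {0}
        allowed = set(self.scheme.mapping.values())
        if not present <= allowed:
            raise ValueError(f"labels {sorted(present - allowed)} not in scheme "
                             f"{self.scheme.name!r}")

    def mask(self, code: str) -> np.ndarray:
        return self.labels == self.scheme[code]

    def counts(self) -> dict[str, int]:
        return {c: int(np.count_nonzero(self.labels == v))
                for c, v in self.scheme.mapping.items()}


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named anatomical points in world mm driving skull-strip and grid cuts."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float).reshape(3)
                       for k, v in self.points.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.points]
        if missing:
            raise ValueError(f"missing required landmarks: {missing}")
        if np.allclose(self.points["AC"], self.points["PC"]):
            raise ValueError("degenerate landmarks: AC == PC")
        if np.linalg.norm(self.points["mid_sagittal_normal"]) < 1e-9:
            raise ValueError("degenerate landmarks: mid_sagittal_normal ~ 0")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls({k: np.asarray(v, dtype=float)
                        for k, v in json.load(fh).items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: [float(x) for x in v] for k, v in self.points.items()},
                      fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

def grids_match(shape_a, affine_a, shape_b, affine_b, rtol: float = 1e-4) -> bool:
    if tuple(shape_a) != tuple(shape_b):
        return False
    a, b = np.asarray(affine_a, float), np.asarray(affine_b, float)
    scale = max(np.abs(a).max(), 1.0)
    return bool(np.allclose(a, b, atol=rtol * scale))


@dataclass
class StudyBundle:
    """Four coregistered contrasts plus optional landmarks and manual masks."""

    t1: Volume3D
    t2: Volume3D
    pd: Volume3D
    flair: Volume3D
    subject_id: str = "subject"
    landmark_set: LandmarkSet | None = None
    manual_masks: dict[str, LabelVolume] = field(default_factory=dict)

    def __post_init__(self):
        tags = [v.contrast_tag for v in (self.t1, self.t2, self.pd, self.flair)]
        if tags != list(CONTRASTS):
            raise ValueError(f"contrast tags must be {CONTRASTS}, got {tags}")
        ref = self.t1
        for v in (self.t2, self.pd, self.flair):
            if not grids_match(ref.shape, ref.affine, v.shape, v.affine):
                raise ValueError(f"grid mismatch between T1 and {v.contrast_tag}")
        for role, m in self.manual_masks.items():
            if not grids_match(ref.shape, ref.affine, m.labels.shape, m.affine):
                raise ValueError(f"grid mismatch between T1 and mask {role!r}")

    @property
    def affine(self) -> np.ndarray:
        return self.t1.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    @property
    def volumes(self) -> dict[str, Volume3D]:
        return {"T1": self.t1, "T2": self.t2, "PD": self.pd, "FLAIR": self.flair}


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, contrast_tag: str) -> Volume3D:
    """Read a NIfTI-1 file as a single-contrast volume.

    The affine and voxel data are taken from the header unmodified.  Raises
    on a missing file or an image that is not 3-dimensional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"expected 3 dimensions, got {data.ndim} in {path}")
    return Volume3D(data, img.affine, contrast_tag)


def write_volume(volume: Volume3D, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32),
                             volume.affine), str(path))


def read_label_volume(path, scheme: LabelScheme) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"expected 3 dimensions, got {data.ndim} in {path}")
    return LabelVolume(np.rint(data).astype(np.int16), scheme, img.affine)


def write_label_volume(label_volume: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(label_volume.labels.astype(np.int16),
                             label_volume.affine), str(path))


# ---------------------------------------------------------------------------
# study manifests
# ---------------------------------------------------------------------------

def load_study_bundle(manifest) -> StudyBundle:
    """Load a study from a JSON manifest.

    The manifest names one NIfTI file per contrast (keys ``t1``, ``t2``,
    ``pd``, ``flair``), an optional ``landmarks`` JSON, optional
    ``masks`` mapping role -> NIfTI path, and ``subject_id``.  Relative
    paths resolve against the manifest's directory.  All four contrasts are
    grid-validated against each other.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        doc = json.load(fh)
    base = manifest.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    vols = {}
    for tag in CONTRASTS:
        key = tag.lower()
        if key not in doc:
            raise ValueError(f"missing contrast {tag}")
        vols[tag] = read_volume(_resolve(doc[key]), tag)

    landmarks = None
    if doc.get("landmarks"):
        landmarks = LandmarkSet.from_json(_resolve(doc["landmarks"]))

    masks = {}
    for role, p in (doc.get("masks") or {}).items():
        if role not in MANUAL_MASK_ROLES:
            raise ValueError(f"unknown manual mask role {role!r}")
        masks[role] = read_label_volume(_resolve(p), binary_scheme(role))

    return StudyBundle(vols["T1"], vols["T2"], vols["PD"], vols["FLAIR"],
                       subject_id=doc.get("subject_id", manifest.stem),
                       landmark_set=landmarks, manual_masks=masks)


def save_study_bundle(bundle: StudyBundle, directory) -> Path:
    """Write a bundle's volumes, landmarks and masks; return the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc: dict = {"subject_id": bundle.subject_id}
    for tag, vol in bundle.volumes.items():
        name = f"{tag.lower()}.nii.gz"
        write_volume(vol, directory / name)
        doc[tag.lower()] = name
    if bundle.landmark_set is not None:
        bundle.landmark_set.to_json(directory / "landmarks.json")
        doc["landmarks"] = "landmarks.json"
    if bundle.manual_masks:
        doc["masks"] = {}
        for role, m in bundle.manual_masks.items():
            name = f"mask_{role}.nii.gz"
            write_label_volume(m, directory / name)
            doc["masks"][role] = name
    manifest = directory / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return manifest


def write_volumetrics_record(record, path) -> None:
    """Write a per-subject volumetric record as a canonical one-row CSV.

    Delegates to :mod:`sabrevol.report`, which owns the record type and its
    deterministic column order.
    """
    from .report import write_volumetrics_record as _write
    _write(record, path)
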