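"""Per-subject volumetric records, cohort summaries and agreement metrics.

The record is one spreadsheet row per subject: the supratentorial TIV,
the ten global tissue/lesion volumes, hippocampal sub-volumes, and every
(region x class) cell, each with a head-size-corrected twin (raw volume
divided by ST-TIV).  Units follow the published convention: cc for TIV,
tissue and CSF classes, mm^3 for lesion classes.

Cohort summaries report n / mean / sd / median / IQR per measure, with
an optional log1p transform for the (heavily right-skewed) lesion
volumes before mean/sd.  Agreement metrics are the Dice similarity index
for masks and the two-way random-effects, absolute-agreement, single-
rater intraclass correlation ICC(2,1) for continuous ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    CC_CODES,
    LOBE_OF,
    REGION_ROW_ORDER,
    TISSUE_CODES,
    LabelVolume,
    grids_match,
)
from .lesions import LesionMaskSet
from .parcellation import SupratentorialMask

#: canonical region order (hippocampi last, matching the 28-ROI scheme)
REGION_ORDER = tuple(f"{s}_{c}" for s in ("L", "R") for c in REGION_ROW_ORDER) \
    + ("L_HP", "R_HP")

HP_SUBVOL_KEYS = ("parenchyma_cc", "hypointensity_cc", "stroke_cc", "total_cc")


@dataclass
class VolumetricsRecord:
    """One subject's complete coded volumetric profile."""

    subject_id: str
    st_tiv_cc: float
    global_volumes: dict[str, float]               # code -> cc or mm^3
    regional: pd.DataFrame                         # regions x classes, per-class units
    hippocampus: dict[str, dict[str, float]] = field(default_factory=dict)
    corrected: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in TISSUE_CODES if c not in self.global_volumes]
        if missing:
            raise ValueError(f"record missing codes: {missing}")
        if any(v < 0 for v in self.global_volumes.values()):
            raise ValueError("volumes must be >= 0")

    def conservation_error(self) -> float:
        """Relative error of sum(all ten classes) against ST-TIV."""
        total_cc = 0.0
        for code, v in self.global_volumes.items():
            total_cc += v if code in CC_CODES else v / 1000.0
        return abs(total_cc - self.st_tiv_cc) / max(self.st_tiv_cc, 1e-12)


def _unit_factor(code: str) -> float:
    """mm^3 -> reporting unit for a class."""
    return 1e-3 if code in CC_CODES else 1.0


def tabulate_volumes(final_labels: LabelVolume, regions: LabelVolume,
                     tiv: SupratentorialMask,
                     hippocampus: dict[str, dict[str, float]] | None = None,
                     subject_id: str = "subject") -> VolumetricsRecord:
    """Cross-tabulate the final partition against the region map.

    Every (region, class) cell is voxel count x voxel volume, converted
    to the class's reporting unit; global volumes are the row sums.
    Raises if the label partition is violated (a masked voxel with no
    class, or vice versa).
    """
    if not grids_match(final_labels.labels.shape, final_labels.affine,
                       regions.labels.shape, regions.affine):
        raise ValueError("grid mismatch between labels and regions")
    m = tiv.mask
    unlabelled = int(np.count_nonzero(m & (final_labels.labels == 0)))
    stray = int(np.count_nonzero(~m & (final_labels.labels != 0)))
    if unlabelled or stray:
        raise ValueError(f"partition violation: {unlabelled} masked voxels "
                         f"without a class, {stray} labelled voxels outside "
                         "the mask")

    voxel_mm3 = tiv.voxel_volume_mm3
    region_codes = [c for c in REGION_ORDER if c in regions.scheme.mapping]
    table = pd.DataFrame(0.0, index=region_codes, columns=list(TISSUE_CODES))
    cls_vals = {c: final_labels.scheme[c] for c in TISSUE_CODES}
    reg_lab = regions.labels[m]
    cls_lab = final_labels.labels[m]
    for rcode in region_codes:
        rsel = reg_lab == regions.scheme[rcode]
        if not rsel.any():
            continue
        sub = cls_lab[rsel]
        for ccode, cval in cls_vals.items():
            n = int(np.count_nonzero(sub == cval))
            table.loc[rcode, ccode] = n * voxel_mm3 * _unit_factor(ccode)

    global_volumes = {c: float(table[c].sum()) for c in TISSUE_CODES}
    return VolumetricsRecord(subject_id=subject_id, st_tiv_cc=tiv.tiv_cc,
                             global_volumes=global_volumes, regional=table,
                             hippocampus=hippocampus or {})


def head_size_correct(record: VolumetricsRecord) -> VolumetricsRecord:
    """Attach the proportional (volume / ST-TIV) twin of every volume.

    Corrections are dimensionless fractions of the supratentorial TIV;
    raw values are retained.  Raises on zero TIV.
    """
    if record.st_tiv_cc <= 0:
        raise ValueError("cannot head-size-correct with zero ST-TIV")
    tiv_mm3 = record.st_tiv_cc * 1000.0
    corrected = {}
    for code, v in record.global_volumes.items():
        corrected[code] = (v / _unit_factor(code)) / tiv_mm3
    for rcode in record.regional.index:
        for ccode in record.regional.columns:
            v = record.regional.loc[rcode, ccode]
            corrected[f"{rcode}_{ccode}"] = (v / _unit_factor(ccode)) / tiv_mm3
    record.corrected = corrected
    return record


def aggregate_regions(record: VolumetricsRecord,
                      grouping="lobes") -> pd.DataFrame:
    """Sum regional cells into larger ROIs.

    ``grouping`` is ``"lobes"`` (the published lobe membership, pooling
    hemispheres), ``"whole-brain"``, or a custom mapping region-code ->
    group name covering each region at most once.
    """
    if grouping == "lobes":
        mapping = {}
        for rcode in record.regional.index:
            base = rcode.split("_", 1)[1]
            mapping[rcode] = LOBE_OF[base]
    elif grouping == "whole-brain":
        mapping = {rcode: "whole-brain" for rcode in record.regional.index}
    elif isinstance(grouping, dict):
        unknown = set(grouping) - set(record.regional.index)
        if unknown:
            raise ValueError(f"unknown region codes in grouping: {sorted(unknown)}")
        mapping = grouping
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = sorted(set(mapping.values()))
    out = pd.DataFrame(0.0, index=rows, columns=record.regional.columns)
    for rcode, group in mapping.items():
        out.loc[group] += record.regional.loc[rcode]
    return out


def summarize_cohort(records: list[VolumetricsRecord],
                     transform: str = "none") -> pd.DataFrame:
    """n / mean / sd / median / IQR per measure over a cohort.

    ``transform="log1p"`` applies log1p to the lesion-class volumes
    before mean/sd (median and IQR stay on the raw scale); zero-lesion
    subjects therefore remain finite.
    """
    if not records:
        raise ValueError("empty cohort")
    if transform not in ("none", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    measures = ["ST_TIV"] + list(TISSUE_CODES)
    data = {"ST_TIV": [r.st_tiv_cc for r in records]}
    for c in TISSUE_CODES:
        data[c] = [r.global_volumes[c] for r in records]

    rows = []
    for mname in measures:
        x = np.asarray(data[mname], float)
        xm = x
        if transform == "log1p" and mname not in CC_CODES and mname != "ST_TIV":
            xm = np.log1p(x)
        q75, q25 = np.percentile(x, [75, 25])
        rows.append({"measure": mname, "n": len(x),
                     "mean": float(xm.mean()),
                     "sd": float(xm.std(ddof=1)) if len(x) > 1 else 0.0,
                     "median": float(np.median(x)),
                     "iqr": float(q75 - q25)})
    return pd.DataFrame(rows).set_index("measure")


def to_long_frame(records: list[VolumetricsRecord],
                  cohort: str = "cohort") -> pd.DataFrame:
    """Long-format (subject, cohort, measure, value) table for plotting."""
    rows = []
    for r in records:
        rows.append({"subject_id": r.subject_id, "cohort": cohort,
                     "measure": "ST_TIV", "value": r.st_tiv_cc})
        for c in TISSUE_CODES:
            rows.append({"subject_id": r.subject_id, "cohort": cohort,
                         "measure": c, "value": r.global_volumes[c]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement metrics
# ---------------------------------------------------------------------------

def dice_similarity(a, b) -> float:
    """Dice similarity index 2|A∩B| / (|A|+|B|); 1.0 when both are empty."""
    if isinstance(a, LabelVolume) and isinstance(b, LabelVolume):
        if not grids_match(a.labels.shape, a.affine, b.labels.shape, b.affine):
            raise ValueError("grid mismatch between masks")
        a, b = a.labels > 0, b.labels > 0
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("grid mismatch between masks")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def intraclass_correlation(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects x k raters) table with no missing
    cells.  Computed from the ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, float)
    if isinstance(ratings, pd.DataFrame):
        x = ratings.to_numpy(float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("missing cells in the ratings table")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        return 1.0 if abs(msr - mse) < 1e-300 else float("nan")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def record_columns(record: VolumetricsRecord) -> list[tuple[str, float]]:
    """Canonical (column, value) order: ST_TIV, global codes, hippocampal
    sub-volumes, region x class cells, then every corrected twin."""
    cols: list[tuple[str, float]] = [("ST_TIV", record.st_tiv_cc)]
    for c in TISSUE_CODES:
        cols.append((c, record.global_volumes[c]))
    for side in ("left", "right"):
        sub = record.hippocampus.get(side, {})
        for key in HP_SUBVOL_KEYS:
            cols.append((f"HP_{side}_{key}", float(sub.get(key, 0.0))))
    for rcode in (c for c in REGION_ORDER if c in record.regional.index):
        for ccode in TISSUE_CODES:
            cols.append((f"{rcode}_{ccode}",
                         float(record.regional.loc[rcode, ccode])))
    for key in sorted(record.corrected):
        cols.append((f"{key}_pTIV", record.corrected[key]))
    return cols


def write_volumetrics_record(record: VolumetricsRecord, path) -> None:
    """Write a one-row CSV in the canonical column order.

    Values are serialized with Python float repr, so a write/read round
    trip is exact and two records with equal content are byte-identical
    regardless of construction order.
    """
    cols = record_columns(record)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id," + ",".join(name for name, _ in cols) + "\n")
        fh.write(record.subject_id + ","
                 + ",".join(repr(float(v)) for _, v in cols) + "\n")


def read_volumetrics_record(path) -> pd.DataFrame:
    # round_trip parsing so written repr values come back bit-exact
    return pd.read_csv(path, float_precision="round_trip")
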