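"""End-to-end orchestration: a study bundle in, a volumetric record out.

Stages, in order: supratentorial strip and TIV, landmark grid and region
map, localized-Gaussian tissue segmentation, seeded ventricular CSF
relabelling, WMH segmentation, stroke ingestion, subcortical
hypointensity candidates and the lacune/PVS cascade, periventricular/
deep splits, normal-appearing tissue correction (the final ten-class
partition), hippocampal ROI merge and sub-classification, tabulation
and head-size correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .core_io import LabelVolume, StudyBundle
from .lesions import (
    IntensityReferences,
    LesionMaskSet,
    classify_candidates,
    correct_tissue_labels,
    detect_subcortical_hypointensity_candidates,
    ingest_stroke_mask,
    segment_wmh,
    split_periventricular_deep,
    subclassify_hippocampus,
)
from .parcellation import (
    SabreGrid,
    SupratentorialMask,
    assign_sabre_regions,
    build_sabre_grid,
    merge_hippocampus_rois,
    strip_to_supratentorial,
)
from .report import VolumetricsRecord, head_size_correct, tabulate_volumes
from .segmentation import (
    LocalGaussianModel,
    classify_tissue,
    fit_local_gaussian_model,
    relabel_ventricular_csf,
)


@dataclass
class PipelineResult:
    """Everything a study run produces, for auditing and reporting."""

    mask: SupratentorialMask
    grid: SabreGrid
    regions: LabelVolume                  # 26-region map
    regions_with_hp: LabelVolume          # 28-ROI map (if hippocampi given)
    model: LocalGaussianModel
    tissue: LabelVolume                   # 4-class map after vCSF relabelling
    lesions: LesionMaskSet
    final_labels: LabelVolume             # ten-class partition
    candidates: list = field(default_factory=list)
    verdicts: dict = field(default_factory=dict)
    hippocampus: dict = field(default_factory=dict)
    record: VolumetricsRecord | None = None


def run_study(bundle: StudyBundle, config: PipelineConfig | None = None
              ) -> PipelineResult:
    """Run the full volumetrics pipeline on one coregistered study."""
    config = config or PipelineConfig()
    if bundle.landmark_set is None:
        raise ValueError("bundle has no landmark set")

    mask = strip_to_supratentorial(bundle, config=config.strip)
    grid = build_sabre_grid(bundle.landmark_set, mask, config.grid)
    regions = assign_sabre_regions(grid, mask)

    model = fit_local_gaussian_model(bundle.t1, mask, config.segmentation)
    tissue = classify_tissue(bundle.t1, model, mask)
    seeds = bundle.manual_masks.get("ventricle_seed")
    if seeds is None:
        raise ValueError("bundle has no ventricle_seed mask; ventricular "
                         "relabelling is a required (manual) input")
    tissue = relabel_ventricular_csf(tissue, seeds)

    wm0 = tissue.labels == tissue.scheme["WM"]
    gm0 = tissue.labels == tissue.scheme["GM"]
    vcsf = tissue.labels == tissue.scheme["vCSF"]
    references = IntensityReferences.from_bundle(bundle, wm0, gm0)

    stroke = np.zeros(bundle.shape, bool)
    if "stroke" in bundle.manual_masks:
        manual = bundle.manual_masks["stroke"]
        clipped = LabelVolume((manual.labels > 0) & mask.mask,
                              manual.scheme, manual.affine)
        stroke = ingest_stroke_mask(bundle, clipped, mask, references)

    wmh = segment_wmh(bundle, tissue, mask, stroke=stroke, config=config.wmh)

    comp, candidates = detect_subcortical_hypointensity_candidates(
        bundle, tissue, regions, mask, references, stroke=stroke,
        config=config.candidates)
    lacunes, pvs, verdicts = classify_candidates(comp, candidates,
                                                 config.classifier)

    # precedence before the disjoint mask set is assembled
    pvs &= ~stroke & ~lacunes
    wmh = wmh & ~stroke & ~lacunes & ~pvs
    lacunes &= ~stroke

    spacing = tuple(bundle.t1.spacing)
    pwmh, dwmh = split_periventricular_deep(
        wmh, vcsf, method=config.split.method, spacing=spacing,
        mask=mask.mask, config=config.split)
    placn, dlacn = split_periventricular_deep(
        lacunes, vcsf, method="connectivity", spacing=spacing,
        config=config.split) if lacunes.any() else (lacunes, lacunes.copy())

    lesion_set = LesionMaskSet(pwmh=pwmh, dwmh=dwmh, placn=placn,
                               dlacn=dlacn, pvs=pvs, stroke=stroke)
    final = correct_tissue_labels(tissue, lesion_set)

    regions_hp = regions
    hippocampus: dict = {}
    hp_l = bundle.manual_masks.get("hippocampus_left")
    hp_r = bundle.manual_masks.get("hippocampus_right")
    if hp_l is not None and hp_r is not None:
        regions_hp = merge_hippocampus_rois(regions, hp_l, hp_r)
        hippocampus = {
            "left": subclassify_hippocampus(bundle, hp_l, stroke, references,
                                            config.hippocampus_tau_t1),
            "right": subclassify_hippocampus(bundle, hp_r, stroke, references,
                                             config.hippocampus_tau_t1),
        }

    record = tabulate_volumes(final, regions_hp, mask,
                              hippocampus=hippocampus,
                              subject_id=bundle.subject_id)
    record = head_size_correct(record)

    return PipelineResult(mask=mask, grid=grid, regions=regions,
                          regions_with_hp=regions_hp, model=model,
                          tissue=tissue, lesions=lesion_set,
                          final_labels=final, candidates=candidates,
                          verdicts=verdicts, hippocampus=hippocampus,
                          record=record)
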