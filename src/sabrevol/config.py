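"""Tunable thresholds for the pipeline, grouped per stage.

Every number that is a methodological choice rather than a mathematical
necessity lives here, with its unit in the field name where one applies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class StripConfig:
    #: radius (voxels) of the morphological closing applied to the head
    #: foreground before hole filling
    closing_radius: int = 2
    #: abort if the tentorial plane would discard more than this fraction
    #: of the foreground (the landmark is probably wrong)
    max_infratentorial_fraction: float = 0.6


@dataclass
class GridConfig:
    #: dorsal-frontal split between the superior and middle frontal tiers,
    #: as a fraction of the distance from the AC-PC axial plane to the
    #: superior brain extent
    frontal_split_fraction: float = 0.5


@dataclass
class SegmentationConfig:
    block_size: int = 32          # voxels per block edge
    overlap: float = 0.5          # fractional block overlap
    min_block_voxels: int = 200   # below this a block inherits the global fit
    min_mask_voxels: int = 1000
    max_iter: int = 500
    tol: float = 1e-6             # absolute log-likelihood gain
    n_bins: int = 256


@dataclass
class WMHConfig:
    tau_flair: float = 3.0        # FLAIR robust z threshold vs the WM reference
    tau_t2: float = 2.0           # T2 robust z threshold
    min_component_voxels: int = 5


@dataclass
class CandidateConfig:
    tau_t1: float = 2.5           # |T1 z| below -tau vs NAWM marks a candidate


@dataclass
class ClassifierConfig:
    """Rule cascade separating perivascular spaces from lacunes."""

    pvs_max_width_mm: float = 3.0
    pvs_min_elongation: float = 2.0
    pvs_pd_gm_band: float = 1.5   # |PD z vs GM| must stay inside this band
    lacune_min_width_mm: float = 3.0
    lacune_max_width_mm: float = 15.0
    lacune_pd_z: float = 2.0      # PD z vs NAWM must exceed this
    lacune_rim_min: float = 1.5   # FLAIR rim score threshold
    lacune_t2_z: float = 2.0      # T2 fallback for BGT/thalamic candidates
    #: the BGT fallback requires *absent* FLAIR evidence (a FLAIR-bright
    #: BGT component is WMH, not a lacune)
    bgt_flair_max: float = 2.0


@dataclass
class SplitConfig:
    method: str = "connectivity"  # connectivity | distance | proportional
    distance_cutoff_mm: float = 13.0
    proportional_fraction: float = 0.5


@dataclass
class PipelineConfig:
    strip: StripConfig = field(default_factory=StripConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    wmh: WMHConfig = field(default_factory=WMHConfig)
    candidates: CandidateConfig = field(default_factory=CandidateConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    #: T1 z below -2.5 vs NAWM inside the hippocampal mask counts as a
    #: CSF-like hypointensity
    hippocampus_tau_t1: float = 2.5

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = json.load(fh)
        cfg = cls()
        for name, sub in doc.items():
            cur = getattr(cfg, name)
            if dataclasses.is_dataclass(cur):
                setattr(cfg, name, type(cur)(**sub))
            else:
                setattr(cfg, name, sub)
        return cfg
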