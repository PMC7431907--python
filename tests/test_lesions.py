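"""WMH segmentation, splitters with exhaustive oracles, rule cascade,
stroke ingestion, hippocampal sub-classification, and the final partition."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from conftest import (
    bfs_periventricular_oracle,
    nearest_distance_oracle,
    random_mask_pair,
)
from sabrevol import (
    LesionLoad,
    LesionMaskSet,
    PhantomSpec,
    classify_lacune_vs_pvs,
    correct_tissue_labels,
    dice_similarity,
    generate_phantom,
    run_study,
    segment_wmh,
    split_periventricular_deep,
)
from sabrevol.config import ClassifierConfig, WMHConfig
from sabrevol.lesions import (
    ComponentFeatures,
    IntensityReferences,
    allocate_pv_deep_lacunes,
    detect_subcortical_hypointensity_candidates,
    ingest_stroke_mask,
    principal_extents_mm,
    subclassify_hippocampus,
)
from sabrevol.phantom import TRUTH_CODES

S26 = np.ones((3, 3, 3), bool)


class TestWMHSegmentation:
    def test_noise_free_dice_against_truth(self, result_clean, phantom_clean):
        _, truth = phantom_clean
        est = result_clean.lesions.wmh
        tm = np.isin(truth.labels, [TRUTH_CODES["pWMH"], TRUTH_CODES["dWMH"]])
        assert dice_similarity(est, tm & result_clean.mask.mask) >= 0.95

    def test_zero_wmh_load_yields_empty_mask(self):
        load = LesionLoad(n_pwmh=0, n_dwmh=0, n_lacunes=0,
                          n_thalamic_lacunes=0, n_pvs=0, n_stroke=0)
        bundle, _ = generate_phantom(PhantomSpec(seed=17, lesion_load=load,
                                                 grid_shape=(64, 64, 64)))
        res = run_study(bundle)
        assert not res.lesions.wmh.any()

    def test_mask_grows_monotonically_as_flair_threshold_drops(
            self, phantom_default, result_default):
        bundle, _ = phantom_default
        tissue, mask = result_default.tissue, result_default.mask
        prev = None
        for tau in (5.0, 4.0, 3.0, 2.5):
            cfg = WMHConfig(tau_flair=tau)
            cur = segment_wmh(bundle, tissue, mask, config=cfg)
            if prev is not None:
                assert np.all(cur | ~prev)  # prev is a subset of cur
            prev = cur


class TestTissueCorrection:
    def test_empty_lesion_set_is_identity_on_tissue(self, result_anatomy):
        tissue = result_anatomy.tissue
        empty = LesionMaskSet.empty(tissue.labels.shape)
        out = correct_tissue_labels(tissue, empty)
        gm = tissue.labels == tissue.scheme["GM"]
        assert np.array_equal(out.labels == out.scheme["NAGM"], gm)
        wm = tissue.labels == tissue.scheme["WM"]
        assert np.array_equal(out.labels == out.scheme["NAWM"], wm)

    def test_wmh_correction_restores_true_gm_volume(self, result_default,
                                                    phantom_default):
        # WMH render as GM on T1, inflating GM; the corrected NAGM volume
        # must land within 2% of the generating GM volume
        _, truth = phantom_default
        sup = truth.supratentorial_truth()
        truth_gm = int(((truth.labels == TRUTH_CODES["GM"]) & sup).sum())
        nagm = int((result_default.final_labels.labels
                    == result_default.final_labels.scheme["NAGM"]).sum())
        assert abs(nagm - truth_gm) / truth_gm < 0.02

    def test_class_volumes_sum_to_supratentorial_tiv(self, result_default):
        assert result_default.record.conservation_error() < 1e-6

    def test_lesion_overlap_with_ventricles_rejected(self, result_anatomy):
        tissue = result_anatomy.tissue
        bad = LesionMaskSet.empty(tissue.labels.shape)
        vidx = np.argwhere(tissue.labels == tissue.scheme["vCSF"])[0]
        bad.pwmh[tuple(vidx)] = True
        with pytest.raises(ValueError, match="overlaps ventricular"):
            correct_tissue_labels(tissue, bad)

    def test_final_partition_is_exclusive_and_exhaustive(self, result_default):
        final, mask = result_default.final_labels, result_default.mask
        assert np.all(final.labels[mask.mask] > 0)
        assert np.all(final.labels[~mask.mask] == 0)


class TestPeriventricularDeepSplit:
    def test_component_touching_ventricle_is_fully_periventricular(self):
        wmh = np.zeros((16, 16, 16), bool)
        vcsf = np.zeros_like(wmh)
        vcsf[8, 8, 8] = True
        wmh[8, 9:14, 8] = True  # touches the ventricle voxel
        pv, deep = split_periventricular_deep(wmh, vcsf, "connectivity")
        assert pv.sum() == wmh.sum() and not deep.any()

    def test_punctate_lesion_20mm_away_is_deep_under_all_methods(self):
        shape = (40, 40, 40)
        wmh = np.zeros(shape, bool)
        vcsf = np.zeros(shape, bool)
        vcsf[5, 5, 5] = True
        wmh[25, 5, 5] = True  # 20 mm from the ventricle, 15 mm from boundary
        mask = np.zeros(shape, bool)
        mask[2:29, 2:38, 2:38] = True  # dural boundary ~4 mm away laterally
        for method in ("connectivity", "distance", "proportional"):
            pv, deep = split_periventricular_deep(wmh, vcsf, method,
                                                  mask=mask)
            assert deep[25, 5, 5] and not pv.any(), method

    def test_split_is_always_an_exact_partition(self):
        rng = np.random.default_rng(0)
        wmh, vcsf = random_mask_pair(rng)
        for method in ("connectivity", "distance"):
            pv, deep = split_periventricular_deep(wmh, vcsf, method)
            assert np.array_equal(pv | deep, wmh)
            assert not np.any(pv & deep)

    @pytest.mark.parametrize("seed", range(8))
    def test_connectivity_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        wmh, vcsf = random_mask_pair(rng)
        pv, _ = split_periventricular_deep(wmh, vcsf, "connectivity")
        assert np.array_equal(pv, bfs_periventricular_oracle(wmh, vcsf))

    @pytest.mark.parametrize("seed", range(8))
    def test_distance_matches_exhaustive_nearest_scan(self, seed):
        rng = np.random.default_rng(200 + seed)
        wmh, vcsf = random_mask_pair(rng)
        pv, _ = split_periventricular_deep(wmh, vcsf, "distance")
        dist = nearest_distance_oracle(wmh, vcsf)
        assert np.array_equal(pv, wmh & (dist <= 13.0))

    def test_empty_ventricles_rejected(self):
        wmh = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="empty ventricular"):
            split_periventricular_deep(wmh, np.zeros_like(wmh), "connectivity")

    def test_unknown_method_rejected(self):
        m = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="unknown split method"):
            split_periventricular_deep(m, m.copy(), "nearest-dura")

    def test_lacune_allocation_mirrors_wmh_rule(self):
        rng = np.random.default_rng(33)
        lac, vcsf = random_mask_pair(rng, p_wmh=0.03)
        placn, dlacn = allocate_pv_deep_lacunes(lac, vcsf)
        assert np.array_equal(placn, bfs_periventricular_oracle(lac, vcsf))
        assert np.array_equal(placn | dlacn, lac)


class TestCandidatesAndCascade:
    def test_one_lacune_two_pvs_give_three_candidates(self):
        load = LesionLoad(n_pwmh=0, n_dwmh=0, n_lacunes=1,
                          n_thalamic_lacunes=0, n_pvs=2, n_stroke=0)
        bundle, truth = generate_phantom(
            PhantomSpec(seed=23, lesion_load=load))
        res = run_study(bundle)
        assert len(res.candidates) == 3
        verdicts = sorted(res.verdicts.values())
        assert verdicts == ["PVS", "PVS", "lacune"]

    def test_zero_lesion_phantom_has_no_candidates(self, result_anatomy):
        assert result_anatomy.candidates == []

    def test_three_voxel_line_features(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        extents = principal_extents_mm(pts, voxel_size_mm=1.0)
        assert extents[0] == pytest.approx(3.0)
        assert extents[1] == pytest.approx(1.0)  # max width
        assert extents[0] / extents[2] == pytest.approx(3.0)

    @pytest.mark.parametrize("feat,expected", [
        # narrow, linear, PD-isointense to GM -> perivascular space
        (dict(max_width_mm=2.0, elongation=4.0,
              z_nawm={"PD": 1.0, "T2": 3.0, "FLAIR": 0.0},
              z_gm={"PD": 0.3}, flair_rim_score=0.0,
              location_class="other"), "PVS"),
        # 6 mm, PD-bright, FLAIR rim -> lacune
        (dict(max_width_mm=6.0, elongation=1.2,
              z_nawm={"PD": 3.1, "T2": 4.0, "FLAIR": -5.0},
              z_gm={"PD": 2.0}, flair_rim_score=5.0,
              location_class="other"), "lacune"),
        # thalamic: no FLAIR signal, T2-bright, BGT -> lacune
        (dict(max_width_mm=6.0, elongation=1.2,
              z_nawm={"PD": 3.0, "T2": 3.0, "FLAIR": 0.1},
              z_gm={"PD": 2.0}, flair_rim_score=0.0,
              location_class="BGT"), "lacune"),
        # FLAIR-bright BGT component is WMH, not a lacune
        (dict(max_width_mm=6.0, elongation=1.2,
              z_nawm={"PD": 3.0, "T2": 3.0, "FLAIR": 20.0},
              z_gm={"PD": 2.0}, flair_rim_score=-5.0,
              location_class="BGT"), "reject"),
        # too wide for a PVS, too PD-dim for a lacune
        (dict(max_width_mm=4.0, elongation=3.0,
              z_nawm={"PD": 0.5, "T2": 1.0, "FLAIR": 0.0},
              z_gm={"PD": 0.0}, flair_rim_score=0.0,
              location_class="other"), "reject"),
        # wider than the 15 mm lacune bound
        (dict(max_width_mm=20.0, elongation=1.1,
              z_nawm={"PD": 5.0, "T2": 5.0, "FLAIR": 0.0},
              z_gm={"PD": 3.0}, flair_rim_score=5.0,
              location_class="other"), "reject"),
    ])
    def test_rule_cascade_on_signature_features(self, feat, expected):
        f = ComponentFeatures(component_id=1, voxel_count=10,
                              volume_mm3=10.0, **feat)
        assert classify_lacune_vs_pvs(f, ClassifierConfig()) == expected

    def test_cascade_is_total_on_noisy_phantom_candidates(self, result_default):
        for f in result_default.candidates:
            assert classify_lacune_vs_pvs(f) in ("PVS", "lacune", "reject")


class TestStrokeIngestion:
    def test_phantom_wedge_accepted_without_warning(self, phantom_default,
                                                    result_default):
        import warnings
        bundle, _ = phantom_default
        refs = IntensityReferences.from_bundle(
            bundle,
            result_default.tissue.labels == result_default.tissue.scheme["WM"],
            result_default.tissue.labels == result_default.tissue.scheme["GM"])
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            m = ingest_stroke_mask(bundle, bundle.manual_masks["stroke"],
                                   result_default.mask, refs)
        assert m.sum() == (bundle.manual_masks["stroke"].labels > 0).sum()

    def test_empty_mask_accepted(self, phantom_default, result_default):
        from sabrevol.core_io import LabelVolume, binary_scheme
        bundle, _ = phantom_default
        empty = LabelVolume(np.zeros(bundle.shape, np.int16),
                            binary_scheme("stroke"), bundle.affine)
        m = ingest_stroke_mask(bundle, empty, result_default.mask)
        assert not m.any()

    def test_mask_over_normal_wm_warns_signature_mismatch(
            self, phantom_clean, result_clean):
        # noise-free: normal WM has T1 z exactly 0, violating the
        # FLAIR-bright / T1-dark chronic stroke signature
        from sabrevol.core_io import LabelVolume, binary_scheme
        bundle, truth = phantom_clean
        wm = (truth.labels == TRUTH_CODES["WM"]) & result_clean.mask.mask \
            & ~truth.masks["lacune_rim"]
        blob = np.zeros(bundle.shape, bool)
        idx = np.argwhere(wm)[500:540]
        blob[tuple(idx.T)] = True
        lv = LabelVolume(blob.astype(np.int16), binary_scheme("stroke"),
                         bundle.affine)
        refs = IntensityReferences.from_bundle(
            bundle,
            result_clean.tissue.labels == result_clean.tissue.scheme["WM"],
            result_clean.tissue.labels == result_clean.tissue.scheme["GM"])
        with pytest.warns(UserWarning, match="signature mismatch"):
            ingest_stroke_mask(bundle, lv, result_clean.mask, refs)


class TestHippocampus:
    def test_uniform_parenchyma_has_no_hypointensity_or_stroke(
            self, phantom_default, result_default):
        bundle, _ = phantom_default
        refs = IntensityReferences.from_bundle(
            bundle,
            result_default.tissue.labels == result_default.tissue.scheme["WM"],
            result_default.tissue.labels == result_default.tissue.scheme["GM"])
        sub = subclassify_hippocampus(
            bundle, bundle.manual_masks["hippocampus_right"], None, refs)
        assert sub["stroke_cc"] == 0.0
        assert sub["hypointensity_cc"] <= 0.02 * sub["total_cc"]

    def test_cavity_voxels_count_as_hypointensity(self):
        load = dataclasses.replace(LesionLoad.none(), hp_cavity_voxels=20)
        spec = PhantomSpec(seed=29, noise_sd=0.0, lesion_load=load)
        bundle, truth = generate_phantom(spec)
        res = run_study(bundle)
        voxel_cc = bundle.t1.voxel_volume_mm3 / 1000.0
        assert res.hippocampus["left"]["hypointensity_cc"] == pytest.approx(
            20 * voxel_cc)

    def test_subvolumes_sum_to_total(self, result_default):
        for side in ("left", "right"):
            sub = result_default.hippocampus[side]
            assert sub["parenchyma_cc"] + sub["hypointensity_cc"] \
                + sub["stroke_cc"] == pytest.approx(sub["total_cc"])


class TestLesionRecoveryOnPhantom:
    def test_per_class_volume_error_within_10_percent_at_default_noise(
            self, result_default, phantom_default):
        _, truth = phantom_default
        sup = truth.supratentorial_truth()
        est = result_default.final_labels
        s = est.scheme
        pairs = {
            "WMH": (np.isin(truth.labels, [TRUTH_CODES["pWMH"],
                                           TRUTH_CODES["dWMH"]]) & sup,
                    np.isin(est.labels, [s["pWMH"], s["dWMH"]])),
            "LACN": ((truth.labels == TRUTH_CODES["LACN"]) & sup,
                     np.isin(est.labels, [s["pLACN"], s["dLACN"]])),
            "PVS": ((truth.labels == TRUTH_CODES["PVS"]) & sup,
                    est.labels == s["PVS"]),
            "Stroke": ((truth.labels == TRUTH_CODES["Stroke"]) & sup,
                       est.labels == s["Stroke"]),
        }
        for name, (tm, em) in pairs.items():
            t, e = int(tm.sum()), int(em.sum())
            assert t > 0, name
            assert abs(e - t) / t <= 0.10, name

    def test_detection_excludes_ventricles_and_wmh(self, result_default):
        lesions = result_default.lesions
        tissue = result_default.tissue
        vcsf = tissue.labels == tissue.scheme["vCSF"]
        assert not np.any(lesions.lacunes & vcsf)
        assert not np.any(lesions.pvs & lesions.wmh)
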