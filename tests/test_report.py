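"""Volumetric records, head-size correction, aggregation, summaries,
Dice and ICC agreement metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sabrevol import (
    aggregate_regions,
    dice_similarity,
    head_size_correct,
    intraclass_correlation,
    summarize_cohort,
    write_volumetrics_record,
)
from sabrevol.core_io import TISSUE_CODES
from sabrevol.report import (
    REGION_ORDER,
    VolumetricsRecord,
    read_volumetrics_record,
    record_columns,
    to_long_frame,
)


def _make_record(subject="s1", tiv=1000.0, lesion=50.0):
    """Small synthetic record: one value per class spread over two regions."""
    regional = pd.DataFrame(0.0, index=["L_SF", "R_SF"],
                            columns=list(TISSUE_CODES))
    regional.loc["L_SF", "NAGM"] = 300.0
    regional.loc["R_SF", "NAGM"] = 250.0
    regional.loc["L_SF", "NAWM"] = 200.0
    regional.loc["R_SF", "NAWM"] = 199.95
    regional.loc["L_SF", "sCSF"] = 30.0
    regional.loc["L_SF", "vCSF"] = 20.0
    regional.loc["L_SF", "pWMH"] = lesion * 1000.0  # mm^3
    globals_ = {c: float(regional[c].sum()) for c in TISSUE_CODES}
    return VolumetricsRecord(subject_id=subject, st_tiv_cc=tiv,
                             global_volumes=globals_, regional=regional)


class TestTabulation:
    def test_pipeline_record_matches_direct_recount(self, result_default):
        rec = result_default.record
        final = result_default.final_labels
        vox_mm3 = result_default.mask.voxel_volume_mm3
        for code in TISSUE_CODES:
            n = int((final.labels == final.scheme[code]).sum())
            expect = n * vox_mm3 * (1e-3 if code in
                                    ("NAGM", "NAWM", "sCSF", "vCSF") else 1.0)
            assert rec.global_volumes[code] == pytest.approx(expect)

    def test_global_equals_sum_of_regional_cells(self, result_default):
        rec = result_default.record
        for code in TISSUE_CODES:
            assert rec.global_volumes[code] == pytest.approx(
                float(rec.regional[code].sum()))

    def test_zero_lesion_phantom_has_zero_lesion_cells(self, result_anatomy):
        rec = result_anatomy.record
        for code in ("pWMH", "dWMH", "pLACN", "dLACN", "PVS", "Stroke"):
            assert rec.global_volumes[code] == 0.0
            assert float(rec.regional[code].sum()) == 0.0

    def test_record_requires_all_codes(self):
        rec = _make_record()
        bad = dict(rec.global_volumes)
        del bad["PVS"]
        with pytest.raises(ValueError, match="missing codes"):
            VolumetricsRecord("s", 1000.0, bad, rec.regional)


class TestHeadSizeCorrection:
    def test_fifty_cc_over_one_liter_is_five_percent(self):
        rec = head_size_correct(_make_record(tiv=1000.0, lesion=50.0))
        assert rec.corrected["pWMH"] == pytest.approx(0.05)

    def test_corrected_proportions_sum_to_one_for_pipeline_run(
            self, result_default):
        rec = result_default.record
        total = sum(rec.corrected[c] for c in TISSUE_CODES)
        assert total == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_correction_invariant_under_isotropic_rescaling(self, scale):
        a = head_size_correct(_make_record(tiv=1000.0))
        b_rec = _make_record(tiv=1000.0 * scale)
        b_rec.regional *= scale
        b_rec.global_volumes = {k: v * scale
                                for k, v in b_rec.global_volumes.items()}
        b = head_size_correct(b_rec)
        for k in a.corrected:
            assert b.corrected[k] == pytest.approx(a.corrected[k])

    def test_zero_tiv_rejected(self):
        with pytest.raises(ValueError, match="zero ST-TIV"):
            head_size_correct(_make_record(tiv=0.0))


class TestAggregation:
    def test_whole_brain_grouping_equals_global_column(self, result_default):
        rec = result_default.record
        agg = aggregate_regions(rec, "whole-brain")
        for code in TISSUE_CODES:
            assert agg.loc["whole-brain", code] == pytest.approx(
                rec.global_volumes[code])

    def test_frontal_lobe_sums_its_six_member_regions(self, result_default):
        rec = result_default.record
        agg = aggregate_regions(rec, "lobes")
        members = [f"{s}_{c}" for s in ("L", "R")
                   for c in ("SF", "MF", "IF", "MIF", "MSF", "MMF")]
        expect = rec.regional.loc[members, "NAGM"].sum()
        assert agg.loc["Frontal", "NAGM"] == pytest.approx(expect)

    def test_summed_pwmh_dwmh_equals_total_wmh_volume(self, result_default):
        rec = result_default.record
        lesions = result_default.lesions
        vox = result_default.mask.voxel_volume_mm3
        total = rec.global_volumes["pWMH"] + rec.global_volumes["dWMH"]
        assert total == pytest.approx(int(lesions.wmh.sum()) * vox)

    def test_unknown_region_in_custom_grouping_rejected(self):
        with pytest.raises(ValueError, match="unknown region codes"):
            aggregate_regions(_make_record(), {"L_XX": "nowhere"})


class TestCohortSummary:
    def test_single_record_has_zero_spread(self):
        out = summarize_cohort([_make_record()])
        assert out.loc["NAGM", "sd"] == 0.0
        assert out.loc["NAGM", "iqr"] == 0.0
        assert out.loc["NAGM", "n"] == 1

    def test_three_point_mean_and_median(self):
        recs = [_make_record(subject=f"s{i}", tiv=t)
                for i, t in enumerate((1.0, 2.0, 3.0))]
        out = summarize_cohort(recs)
        assert out.loc["ST_TIV", "mean"] == pytest.approx(2.0)
        assert out.loc["ST_TIV", "median"] == pytest.approx(2.0)

    def test_log1p_summary_recovers_lognormal_location(self):
        # simulated right-skewed WMH volumes; the log1p mean must land on
        # the generating log-mean within Monte-Carlo error
        rng = np.random.default_rng(11)
        mu, sigma, n = 6.0, 1.0, 1000
        draws = np.exp(rng.normal(mu, sigma, n))
        recs = [_make_record(subject=f"s{i}", lesion=d / 1000.0)
                for i, d in enumerate(draws)]
        out = summarize_cohort(recs, transform="log1p")
        se = sigma / np.sqrt(n)
        assert abs(out.loc["pWMH", "mean"] - mu) < 4 * se + 1e-3

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            summarize_cohort([])

    def test_long_frame_layout(self):
        frame = to_long_frame([_make_record()], cohort="demo")
        assert set(frame.columns) == {"subject_id", "cohort", "measure",
                                      "value"}
        assert len(frame) == 1 + len(TISSUE_CODES)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert dice_similarity(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros_like(a)
        a[0], b[4] = True, True
        assert dice_similarity(a, b) == 0.0

    def test_half_overlap_closed_form(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 0, 2] = True
        assert dice_similarity(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_similarity(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            dice_similarity(np.zeros((3, 3, 3), bool),
                            np.zeros((4, 4, 4), bool))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_dice_is_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) < 0.3
        b = rng.random((6, 6, 6)) < 0.3
        d = dice_similarity(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice_similarity(b, a)
        assert dice_similarity(a, a) == 1.0


class TestICC:
    def test_identical_rater_columns_give_one(self):
        x = np.tile(np.random.default_rng(1).normal(size=12)[:, None], (1, 4))
        assert intraclass_correlation(x) == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        x = np.random.default_rng(3).normal(size=(200, 3))
        assert abs(intraclass_correlation(x)) < 0.15

    def test_hand_computed_three_by_three_table(self):
        # worked ANOVA decomposition, kept independent of the implementation
        x = np.array([[9.0, 2.0, 5.0],
                      [6.0, 1.0, 3.0],
                      [8.0, 4.0, 6.0]])
        n, k = 3, 3
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - x.mean(1, keepdims=True) - x.mean(0) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert intraclass_correlation(x) == pytest.approx(expect, abs=1e-10)

    def test_matches_published_two_way_random_effects_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(50, 10, 20)[:, None] + rng.normal(0, 3, (20, 3)) \
            + np.array([0.0, 1.0, 2.0])
        long = pd.DataFrame({"subject": np.repeat(np.arange(20), 3),
                             "rater": np.tile(np.arange(3), 20),
                             "score": x.ravel()})
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        ref = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert intraclass_correlation(x) == pytest.approx(ref, abs=1e-10)

    def test_contract_violations_rejected(self):
        with pytest.raises(ValueError, match="2 raters"):
            intraclass_correlation(np.ones((5, 1)))
        with pytest.raises(ValueError, match="3 subjects"):
            intraclass_correlation(np.ones((2, 3)))
        bad = np.ones((4, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            intraclass_correlation(bad)


class TestRecordCSV:
    def test_tiv_cell_is_plain_float_repr(self, tmp_path):
        rec = _make_record(tiv=1000.0)
        path = tmp_path / "rec.csv"
        write_volumetrics_record(rec, path)
        df = read_volumetrics_record(path)
        assert df.loc[0, "ST_TIV"] == 1000.0
        text = path.read_text()
        header, row = text.strip().split("\n")
        col = header.split(",").index("ST_TIV")
        assert row.split(",")[col] == "1000.0"

    def test_write_read_round_trip_is_exact(self, tmp_path, result_default):
        rec = result_default.record
        path = tmp_path / "rec.csv"
        write_volumetrics_record(rec, path)
        df = read_volumetrics_record(path)
        for name, value in record_columns(rec):
            assert df.loc[0, name] == value  # repr round trip is exact

    def test_construction_order_does_not_change_bytes(self, tmp_path):
        a = _make_record()
        b = _make_record()
        # permute the construction order of every container
        b.global_volumes = dict(reversed(list(b.global_volumes.items())))
        b.regional = b.regional.iloc[::-1][list(reversed(b.regional.columns))]
        write_volumetrics_record(a, tmp_path / "a.csv")
        write_volumetrics_record(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() \
            == (tmp_path / "b.csv").read_bytes()

    def test_canonical_order_is_global_then_regional(self):
        names = [n for n, _ in record_columns(_make_record())]
        assert names[0] == "ST_TIV"
        assert names[1:11] == list(TISSUE_CODES)
        regional = [n for n in names
                    if n.startswith(("L_SF_", "R_SF_")) and
                    not n.endswith("_pTIV")]
        expect = [f"{r}_{c}" for r in REGION_ORDER if r in ("L_SF", "R_SF")
                  for c in TISSUE_CODES]
        assert regional == expect
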