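"""Plate QC, viability exclusion and the normalization cascade."""

import numpy as np
import pandas as pd
import pytest

from rnaiscreen import (
    DegenerateControlsError,
    DegenerateScaleError,
    InsufficientControlsError,
    MAD_SCALE,
    UndefinedRatioError,
    exclude_low_viability,
    normalize_activity,
    normalize_screen,
    npi_normalize,
    orient_and_combine,
    plate_qc,
    plate_zscores,
)
from tests.conftest import make_plate


class TestPlateQC:
    @pytest.mark.parametrize(
        "neg_viab,passed,reason",
        [
            ((2.6, 2.7, 2.8), False, "mean_too_high"),  # mean 2.7 > 2.5
            ((0.1, 0.15, 0.2), False, "mean_too_low"),  # mean 0.15 < 0.2
            ((1.0, 1.1, 0.9), True, None),  # CV 10% <= 50%
            ((1.0, 0.1, 2.0), False, "cv_too_high"),
        ],
    )
    def test_rule_application(self, config, neg_viab, passed, reason):
        qc = plate_qc(make_plate(neg_viab=neg_viab), config)
        assert qc.passed is passed
        if reason:
            assert reason in qc.reasons

    def test_reasons_can_cooccur(self, config):
        # mean 3.0 > 2.5 and CV > 50%
        qc = plate_qc(make_plate(neg_viab=(0.5, 2.5, 6.0)), config)
        assert set(qc.reasons) >= {"mean_too_high", "cv_too_high"}

    def test_requires_two_neg_controls(self, config):
        plate = make_plate()
        plate = plate[~((plate["role"] == "neg_ctrl") & (plate.index > 0))]
        with pytest.raises(InsufficientControlsError):
            plate_qc(plate, config)

    def test_passed_iff_no_reasons(self, config):
        qc = plate_qc(make_plate(), config)
        assert qc.passed == (len(qc.reasons) == 0)


class TestWellViabilityFilter:
    @pytest.mark.parametrize(
        "viab,excluded",
        [(0.35, True), (0.45, False), (0.40, False)],  # boundary 0.40 kept: strict <
    )
    def test_forty_percent_rule(self, config, viab, excluded):
        plate = make_plate(neg_viab=(1.0, 1.0, 1.0), sample_viab=[viab, 1.0])
        mask = exclude_low_viability(plate, config)
        sample_mask = mask[plate["role"] == "sample"].tolist()
        assert sample_mask[0] is excluded or sample_mask[0] == excluded
        assert not sample_mask[1]

    def test_controls_subject_to_same_rule(self, config):
        plate = make_plate(neg_viab=(1.0, 1.0, 1.0, 0.2))
        mask = exclude_low_viability(plate, config)
        neg_mask = mask[plate["role"] == "neg_ctrl"].tolist()
        # neg mean 0.8; cutoff 0.32; the 0.2 control itself is excluded
        assert neg_mask == [False, False, False, True]


class TestRatios:
    @pytest.mark.parametrize(
        "act,viab,expected", [(1000.0, 2.0, 500.0), (0.8, 1.6, 0.5), (0.0, 1.0, 0.0)]
    )
    def test_activity_ratio(self, act, viab, expected):
        assert normalize_activity(act, viab) == expected

    def test_zero_viability_is_error(self):
        with pytest.raises(UndefinedRatioError):
            normalize_activity(10.0, 0.0)


class TestNPI:
    def test_anchors_and_midpoint(self):
        assert npi_normalize(100.0, 100.0, 20.0) == 0.0
        assert npi_normalize(20.0, 100.0, 20.0) == 1.0
        assert npi_normalize(60.0, 100.0, 20.0) == 0.5

    def test_degenerate_controls(self):
        with pytest.raises(DegenerateControlsError):
            npi_normalize(50.0, 80.0, 80.0)

    def test_affine_invariance(self, rng):
        x = rng.uniform(10, 1000, 50)
        neg, pos = 800.0, 100.0
        for factor in (0.5, 3.7, 42.0):
            np.testing.assert_allclose(
                npi_normalize(factor * x, factor * neg, factor * pos),
                npi_normalize(x, neg, pos),
                rtol=1e-12,
            )


class TestPlateZScores:
    def test_neg_median_maps_to_zero(self, rng):
        neg = rng.normal(5, 1, 8)
        samples = rng.normal(5, 2, 100)
        z = plate_zscores(np.array([np.median(neg)]), neg, samples)
        assert z[0] == 0.0

    def test_mad_example_hand_enumerated(self):
        # samples {1..5}: median 3, |x-3| = {2,1,0,1,2}, MAD = 1
        samples = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        neg = np.array([3.0, 3.0])
        z = plate_zscores(np.array([5.0]), neg, samples)
        assert z[0] == pytest.approx(2.0 / MAD_SCALE, abs=1e-12)  # ~1.349

    def test_neg_sd_scale_option(self):
        neg = np.array([1.0, 3.0, 5.0])  # median 3, sd 2
        z = plate_zscores(np.array([7.0]), neg, np.array([0.0]), method="neg_sd")
        assert z[0] == pytest.approx(2.0)

    def test_zero_scale_raises(self):
        with pytest.raises(DegenerateScaleError):
            plate_zscores(np.array([1.0]), np.array([0.0, 0.0]), np.array([2.0, 2.0]))


class TestNormalizeScreen:
    def test_failed_plate_excludes_all_wells_with_plate_reason(self, config):
        good = make_plate(plate_id="P1")
        bad = make_plate(plate_id="P2", neg_viab=(2.6, 2.7, 2.8))
        norm, reports = normalize_screen(pd.concat([good, bad], ignore_index=True), config)
        on_bad = norm[norm["plate_id"] == "P2"]
        assert on_bad["excluded"].all()
        assert set(on_bad["exclusion_reason"]) == {"plate_failed"}
        assert {r.plate_id: r.passed for r in reports} == {"P1": True, "P2": False}

    def test_count_conservation(self, config):
        plate = make_plate(sample_viab=[0.1, 1.0, 1.0, 1.0, 0.2])
        norm, _ = normalize_screen(plate, config)
        kept = int((~norm["excluded"]).sum())
        excl = int(norm["excluded"].sum())
        assert kept + excl == len(plate)
        assert excl == 2  # the two low-viability wells

    def test_low_viability_reason_only_on_passing_plates(self, config):
        plate = make_plate(neg_viab=(0.1, 0.1, 0.1), sample_viab=[0.01] * 5)
        norm, _ = normalize_screen(plate, config)
        assert set(norm["exclusion_reason"]) == {"plate_failed"}

    def test_npi_zero_at_neg_one_at_pos(self, config):
        norm, _ = normalize_screen(make_plate(), config)
        neg_npi = norm.loc[norm["role"] == "neg_ctrl", "npi"]
        pos_npi = norm.loc[norm["role"] == "pos_ctrl_pathway", "npi"]
        assert neg_npi.mean() == pytest.approx(0.0, abs=1e-12)
        assert pos_npi.mean() == pytest.approx(1.0, abs=1e-12)

    def test_plate_rescaling_leaves_npi_unchanged(self, config):
        plate = make_plate()
        norm1, _ = normalize_screen(plate, config)
        scaled = plate.copy()
        scaled[["readout_activity", "readout_viability"]] *= 2.5
        norm2, _ = normalize_screen(scaled, config)
        pd.testing.assert_series_equal(norm1["npi"], norm2["npi"], atol=1e-10)

    def test_neg_median_z_zero_every_plate(self, config, rng):
        plates = []
        for p in range(5):
            plates.append(
                make_plate(
                    plate_id=f"P{p}",
                    neg_viab=tuple(rng.uniform(0.8, 1.2, 4)),
                    sample_activity=list(rng.uniform(100, 1000, 20)),
                )
            )
        norm, _ = normalize_screen(pd.concat(plates, ignore_index=True), config)
        for _, grp in norm.groupby("plate_id"):
            neg_z = grp.loc[grp["role"] == "neg_ctrl", "z"]
            assert np.median(neg_z) == pytest.approx(0.0, abs=1e-12)


class TestOrientAndCombine:
    def test_median_of_replicates(self, config):
        plates = []
        for rep, acts in enumerate(
            [[500.0, 900.0], [300.0, 900.0], [350.0, 900.0], [400.0, 900.0]], start=1
        ):
            plates.append(
                make_plate(plate_id=f"P{rep}", replicate=rep, sample_activity=acts)
            )
        norm, _ = normalize_screen(pd.concat(plates, ignore_index=True), config)
        scores, meta = orient_and_combine(norm)
        row = scores[scores["sirna_id"] == "G001_s1"].iloc[0]
        zs = [float(v) for v in row["replicate_z"].split(";")]
        assert row["n_replicates_used"] == 4
        assert row["median_z"] == pytest.approx(np.median(zs))
        assert "inhibition" in meta["orientation"]

    def test_median_example(self):
        assert np.median([1.2, 2.5, 2.1, 1.9]) == 2.0

    def test_excluded_replicates_reduce_n_used(self, config):
        plates = []
        for rep in range(1, 5):
            viab = [0.1, 1.0, 1.0, 1.0, 1.0] if rep <= 2 else [1.0] * 5
            plates.append(
                make_plate(
                    plate_id=f"P{rep}", replicate=rep,
                    sample_activity=[500.0, 900.0, 700.0, 650.0, 820.0],
                    sample_viab=viab,
                )
            )
        norm, _ = normalize_screen(pd.concat(plates, ignore_index=True), config)
        scores, _ = orient_and_combine(norm)
        row = scores[scores["sirna_id"] == "G001_s1"].iloc[0]
        assert row["n_replicates_used"] == 2

    def test_zero_surviving_replicates_flagged_missing(self, config):
        plate = make_plate(
            sample_activity=[500.0, 900.0, 700.0, 650.0, 820.0],
            sample_viab=[0.1, 1.0, 1.0, 1.0, 1.0],
        )
        norm, _ = normalize_screen(plate, config)
        scores, _ = orient_and_combine(norm)
        row = scores[scores["sirna_id"] == "G001_s1"].iloc[0]
        assert row["n_replicates_used"] == 0
        assert np.isnan(row["median_z"])

    def test_determinism(self, config):
        plate = make_plate()
        norm, _ = normalize_screen(plate, config)
        s1, _ = orient_and_combine(norm)
        s2, _ = orient_and_combine(norm)
        pd.testing.assert_frame_equal(s1, s2)
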