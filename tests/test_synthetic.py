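"""Forward-model generator: determinism, ground-truth consistency, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from lipoform.hydrodynamics import paired_device_summary
from lipoform.pipeline import (
    compute_lamellarity,
    compute_metrics,
    correlation_screen,
    fit_calibration,
)
from lipoform.synthetic import (
    DEFAULT_TRENDS,
    DeviceTrends,
    GeneratorConfig,
    NoiseModel,
    generate_campaign,
    paper_like_campaign,
    paper_like_conditions,
)

ZERO_NOISE = NoiseModel(dls_rel=0, fluorescence_rel=0, titration_rel=0, calibration_rel=0)


def unilamellar_trends():
    return {
        dev: DeviceTrends(
            **{
                **vars(t),
                "lam_base": 1.0,
                "lam_ilc_slope": 0.0,
                "lam_floor": 1.0,
            }
        )
        for dev, t in DEFAULT_TRENDS.items()
    }


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = paper_like_campaign(seed=42)
        b = paper_like_campaign(seed=42)
        pd.testing.assert_frame_equal(a.campaign, b.campaign)
        pd.testing.assert_frame_equal(a.titrations, b.titrations)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = paper_like_campaign(seed=1)
        b = paper_like_campaign(seed=2)
        assert not a.campaign["mean_diameter_nm"].equals(b.campaign["mean_diameter_nm"])


class TestGridStructure:
    def test_row_count_is_devices_times_conditions(self):
        camp = paper_like_campaign(seed=0)
        # 2 devices x 5 flow settings x 5 ILC levels
        assert len(camp.campaign) == len(paper_like_conditions()) == 50
        assert camp.campaign["sample_id"].is_unique

    def test_sm_pdi_below_shm_pdi(self):
        camp = paper_like_campaign(seed=0)
        res = paired_device_summary(camp.campaign)
        assert res["mean_pdi_sm"] < res["mean_pdi_shm"]

    def test_sm_sizes_larger(self):
        camp = paper_like_campaign(seed=0)
        assert res_positive(paired_device_summary(camp.campaign))


def res_positive(res):
    return (res["per_ilc_size_difference"]["size_difference_nm"] > 0).all()


class TestGroundTruthConsistency:
    def test_loss_free_unilamellar_pipeline_ee_equals_tee(self):
        """Zero noise, lamellarity 1, no mixing shortfall, no carry-over:
        the measured chain reproduces the geometric TEE to 1e-9."""
        config = GeneratorConfig(
            seed=5,
            conditions=paper_like_conditions()[:6],
            trends=unilamellar_trends(),
            ee_shortfall=1.0,
            carryover_dilution=math.inf,
            noise=ZERO_NOISE,
        )
        camp = generate_campaign(config)
        lipid_cal = fit_calibration(camp.calibrations["lipid"], "lipid")
        calcein_cal = fit_calibration(camp.calibrations["calcein"], "calcein")
        metrics = compute_metrics(camp.campaign, lipid_cal, calcein_cal)
        joined = camp.truth.merge(metrics, on="sample_id")
        assert np.allclose(joined["ee_pct"], joined["tee_pct"], rtol=1e-9)
        assert np.allclose(joined["ee_pct"], joined["true_tee_pct"], rtol=1e-9)

    def test_ee_never_exceeds_tee_for_unilamellar_or_worse(self):
        camp = paper_like_campaign(seed=3)
        t = camp.truth
        mask = t["true_lamellarity"] >= 1.0
        assert mask.any()
        assert (
            t.loc[mask, "true_ee_apparent_pct"]
            <= t.loc[mask, "true_tee_pct"] + 1e-12
        ).all()

    def test_ee_above_100_rejected(self):
        # Sub-unilamellar population (lamellarity 0.5) at an extreme lipid
        # load: the forward model would imply EE > 100% and must refuse.
        halved = {
            dev: DeviceTrends(
                **{**vars(t), "lam_base": 0.5, "lam_ilc_slope": 0.0, "lam_floor": 0.5}
            )
            for dev, t in DEFAULT_TRENDS.items()
        }
        config = GeneratorConfig(
            seed=0,
            conditions=(paper_like_conditions()[0].__class__(
                device="SM", tfr=1500, frr=3, ilc=50_000
            ),),
            trends=halved,
            ee_shortfall=1.0,
            noise=ZERO_NOISE,
        )
        with pytest.raises(ValueError, match="> 100%"):
            generate_campaign(config)

    def test_empty_conditions_rejected(self):
        with pytest.raises(ValueError, match="no conditions"):
            GeneratorConfig(seed=0, conditions=())


class TestPipelineRecovery:
    def test_lamellarity_recovered_from_titrations(self):
        camp = paper_like_campaign(seed=8)
        est = compute_lamellarity(camp.titrations)
        joined = camp.truth.merge(est, on="sample_id")
        rel = (joined["lamellarity"] - joined["true_lamellarity"]).abs() / joined[
            "true_lamellarity"
        ]
        assert (rel < 0.10).all()

    def test_correlation_structure_of_generated_campaign(self, campaign, calibrations):
        lipid_cal, calcein_cal = calibrations
        metrics = compute_metrics(campaign.campaign, lipid_cal, calcein_cal)
        merged = campaign.campaign.merge(metrics, on="sample_id")
        pooled_matrix, _ = correlation_screen(merged)
        assert pooled_matrix.r.loc["device_code", "pdi"] < -0.5
        per_device = correlation_screen(merged, per_device=True)
        for _, (matrix, strong) in per_device.items():
            assert matrix.r.loc["ilc_mg_ml", "mean_diameter_nm"] > 0.5
            assert ("ilc_mg_ml", "mean_diameter_nm") in {
                (a, b) for a, b, _, _ in strong
            } | {(b, a) for a, b, _, _ in strong}
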