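"""Geometric unilamellar encapsulation model."""

import math

import numpy as np
import pytest

from lipoform.encapsulation_metrics import FormulationCondition, LipidComposition
from lipoform.size_distribution import DlsReadout, from_dls
from lipoform.tee_model import (
    LipidSample,
    TEEParameters,
    lipids_per_vesicle,
    tee,
    tee_for_condition,
)

PARAMS = TEEParameters(membrane_thickness_d=4.8, area_per_lipid_a=0.43)


def closed_form_tee_percent(r, c_mm, d=4.8, a=0.43, n_avogadro=6.02e23):
    """Independent monodisperse closed form, from first principles.

    Lipid molecules per nm^3 of dispersion times the lumen volume per
    lipid: TEE% = 100 * c*N_A[nm^-3] * a * (4/3)pi(r-d)^3 / (4pi(r^2+(r-d)^2)).
    """
    c_per_nm3 = c_mm * 1e-3 * n_avogadro / 1e24
    lumen = (4.0 / 3.0) * math.pi * (r - d) ** 3
    leaflets = 4.0 * math.pi * (r**2 + (r - d) ** 2)
    return 100.0 * c_per_nm3 * lumen * a / leaflets


class TestLipidsPerVesicle:
    def test_hand_arithmetic_r50(self):
        # 4*pi*(2500 + 45.2^2)/0.43 computed by hand.
        assert lipids_per_vesicle(50.0, PARAMS) == pytest.approx(1.328e5, rel=1e-3)

    def test_inner_leaflet_vanishes_at_r_equal_d(self):
        expected = 4 * math.pi * 4.8**2 / 0.43
        assert lipids_per_vesicle(4.8, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_halves_when_area_doubles(self):
        doubled = TEEParameters(membrane_thickness_d=4.8, area_per_lipid_a=0.86)
        assert lipids_per_vesicle(37.0, doubled) == pytest.approx(
            lipids_per_vesicle(37.0, PARAMS) / 2, rel=1e-12
        )

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            lipids_per_vesicle(0.0, PARAMS)


class TestTee:
    def test_monodisperse_oracle(self):
        dist = from_dls(DlsReadout(mean_diameter=100, pdi=0))
        res = tee(dist, LipidSample(10.0), PARAMS)
        assert res.tee_percent == pytest.approx(1.75, abs=0.01)
        assert res.tee_percent == pytest.approx(
            closed_form_tee_percent(50.0, 10.0), rel=1e-9
        )

    def test_zero_lipid_gives_zero(self):
        dist = from_dls(DlsReadout(100, 0.05))
        assert tee(dist, LipidSample(0.0), PARAMS).tee_percent == 0.0

    def test_volume_independence(self):
        dist = from_dls(DlsReadout(150, 0.1))
        results = [
            tee(dist, LipidSample(5.0, sample_volume_V=v), PARAMS).tee_percent
            for v in (0.1, 1.0, 10.0)
        ]
        assert max(results) - min(results) <= 1e-12 * results[0]

    def test_linearity_in_concentration(self):
        dist = from_dls(DlsReadout(120, 0.08))
        base = tee(dist, LipidSample(4.0), PARAMS).tee_percent
        for k in (0.5, 2.0, 3.0):
            scaled = tee(dist, LipidSample(4.0 * k), PARAMS).tee_percent
            assert scaled == pytest.approx(k * base, rel=1e-12)

    def test_pdi_to_zero_limit_recovers_monodisperse(self):
        mono = tee(from_dls(DlsReadout(100, 0)), LipidSample(10.0), PARAMS).tee_percent
        near = tee(
            from_dls(DlsReadout(100, 1e-6)), LipidSample(10.0), PARAMS
        ).tee_percent
        assert near == pytest.approx(mono, rel=1e-3)

    def test_monotone_in_mean_radius(self):
        means = [30, 60, 100, 160, 250, 400]
        tees = [
            tee(from_dls(DlsReadout(m, 0.05)), LipidSample(5.0), PARAMS).tee_percent
            for m in means
        ]
        assert all(a < b for a, b in zip(tees, tees[1:]))

    def test_grid_independence(self):
        readout = DlsReadout(180, 0.2)
        t1 = tee(from_dls(readout, n_points=1000), LipidSample(8.0), PARAMS).tee_percent
        t2 = tee(from_dls(readout, n_points=2000), LipidSample(8.0), PARAMS).tee_percent
        assert t2 == pytest.approx(t1, rel=1e-3)

    def test_distribution_below_membrane_thickness_warns_and_zero(self):
        dist = from_dls(DlsReadout(mean_diameter=8.0, pdi=0))  # r = 4 nm < d
        with pytest.warns(UserWarning, match="membrane"):
            res = tee(dist, LipidSample(5.0), PARAMS)
        assert res.tee_percent == 0.0

    def test_capped_at_100_with_warning(self):
        dist = from_dls(DlsReadout(400, 0))
        with pytest.warns(UserWarning, match="cap"):
            res = tee(dist, LipidSample(5000.0), PARAMS)
        assert res.tee_percent == 100.0


class TestTeeForCondition:
    def test_post_mixing_mass_concentration(self):
        # ILC/(1+FRR): 15/(1+3) = 3.75 and 90/6 = 15 mg/mL.
        assert 15 / (1 + 3) == 3.75
        comp = LipidComposition.default()
        cond = FormulationCondition(device="SM", tfr=1500, frr=3, ilc=15)
        readout = DlsReadout(200, 0.05)
        res = tee_for_condition(cond, readout, composition=comp)
        c_mm = 3.75 / comp.mean_molar_mass * 1e3
        direct = tee(from_dls(readout), LipidSample(c_mm), TEEParameters())
        assert res.tee_percent == pytest.approx(direct.tee_percent, rel=1e-12)

    def test_full_chain_matches_hand_converted_concentration(self):
        comp = LipidComposition(components=(("X", 1.0, 700.0),))
        cond = FormulationCondition(device="SHM", tfr=1500, frr=5, ilc=90)
        readout = DlsReadout(200, 0.05)
        res = tee_for_condition(cond, readout, composition=comp)
        # 90/6 = 15 mg/mL = 15 g/L / 700 g/mol = 21.428... mM
        direct = tee(from_dls(readout), LipidSample(15.0 / 700.0 * 1e3))
        assert res.tee_percent == pytest.approx(direct.tee_percent, rel=1e-12)

    def test_tee_doubles_with_ilc_at_fixed_distribution(self):
        comp = LipidComposition.default()
        readout = DlsReadout(150, 0.1)
        cond1 = FormulationCondition(device="SM", tfr=1500, frr=3, ilc=30)
        cond2 = FormulationCondition(device="SM", tfr=1500, frr=3, ilc=60)
        t1 = tee_for_condition(cond1, readout, composition=comp).tee_percent
        t2 = tee_for_condition(cond2, readout, composition=comp).tee_percent
        assert t2 == pytest.approx(2 * t1, rel=1e-12)


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [{"membrane_thickness_d": 0}, {"area_per_lipid_a": -1}])
    def test_bad_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TEEParameters(**kwargs)
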