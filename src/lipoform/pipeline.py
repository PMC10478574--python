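"""End-to-end analysis of a formulation campaign.

Chains the stages: calibration fitting, intensity -> concentration
conversion, LRR / loading / EE, geometric TEE per sample, TNS
lamellarity against the unilamellar standard, cross-device summaries and
the correlation screen.  Each stage is also usable on its own; this
module only wires them together on the table schemas of :mod:`.io`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import constants
from .correlation import encode_device, flag_strong, pearson_matrix
from .encapsulation_metrics import (
    FluorescenceCalibration,
    FormulationCondition,
    LipidComposition,
    MixedSolutionReference,
    SampleMeasurement,
    calibrate,
    encapsulation_efficiency,
    lipid_recovery_rate,
    loading,
)
from .lamellarity import TNSTitration, fit_slope, lamellarity
from .size_distribution import DlsReadout
from .tee_model import TEEParameters, tee_for_condition

__all__ = [
    "fit_calibration",
    "compute_metrics",
    "compute_lamellarity",
    "correlation_screen",
]

DEFAULT_CORR_VARIABLES = [
    "device_code",
    "tfr_ul_min",
    "frr",
    "ilc_mg_ml",
    "mean_diameter_nm",
    "pdi",
    "lrr_pct",
    "ee_pct",
    "loading",
]


def fit_calibration(table: pd.DataFrame, channel: str) -> FluorescenceCalibration:
    """OLS fit of a (concentration, intensity) calibration table."""
    fit = stats.linregress(table["concentration"], table["intensity"])
    return FluorescenceCalibration(
        channel=channel, slope=float(fit.slope), intercept=float(fit.intercept)
    )


def compute_metrics(
    campaign: pd.DataFrame,
    lipid_cal: FluorescenceCalibration,
    calcein_cal: FluorescenceCalibration,
    lipid_read_dilution: float = 10.0,
    calcein_stock_mm: float = constants.DEFAULT_CALCEIN_STOCK_MM,
    composition: LipidComposition | None = None,
    tee_params: TEEParameters | None = None,
) -> pd.DataFrame:
    """Per-sample LRR, loading, EE, TEE and the EE-TEE gap.

    The mixed-solution reference is reconstructed from each row's FRR and
    ILC; lipid intensities are read after ``lipid_read_dilution``-fold
    dilution (the ethanol solubilization step).
    """
    composition = composition or LipidComposition.default()
    tee_params = tee_params or TEEParameters()
    out = []
    for _, row in campaign.iterrows():
        cond = FormulationCondition(
            device=row["device"], tfr=row["tfr_ul_min"], frr=row["frr"], ilc=row["ilc_mg_ml"]
        )
        ms = MixedSolutionReference.from_condition(cond, calcein_stock_mm)
        meas = SampleMeasurement(
            lipid_conc_post_device=calibrate(
                row["lipid_intensity_post_device"], lipid_cal, lipid_read_dilution
            ),
            lipid_conc_post_purification=calibrate(
                row["lipid_intensity_post_purification"], lipid_cal, lipid_read_dilution
            ),
            calcein_conc_post_purification=calibrate(
                row["calcein_intensity_post_purification"], calcein_cal
            ),
        )
        tee_res = tee_for_condition(
            cond,
            DlsReadout(mean_diameter=row["mean_diameter_nm"], pdi=row["pdi"]),
            composition=composition,
            params=tee_params,
        )
        ee = encapsulation_efficiency(meas, ms)
        out.append(
            {
                "sample_id": row["sample_id"],
                "lrr_pct": lipid_recovery_rate(meas, ms),
                "loading": loading(meas),
                "ee_pct": ee,
                "tee_pct": tee_res.tee_percent,
                "ee_tee_gap": tee_res.tee_percent - ee,
            }
        )
    return pd.DataFrame(out)


def compute_lamellarity(
    titrations: pd.DataFrame, standard_id: str = "STANDARD"
) -> pd.DataFrame:
    """Per-sample TNS slope and lamellarity against the standard."""

    def slope_of(sample_id: str) -> float:
        sub = titrations[titrations["sample_id"] == sample_id]
        if sub.empty:
            raise ValueError(f"no titration rows for sample {sample_id!r}")
        sub = sub.sort_values("lipid_amount")
        return fit_slope(
            TNSTitration(
                lipid_amounts=sub["lipid_amount"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
            )
        )

    standard_slope = slope_of(standard_id)
    rows = []
    for sid in titrations["sample_id"].unique():
        if sid == standard_id:
            continue
        res = lamellarity(slope_of(sid), standard_slope)
        rows.append(
            {"sample_id": sid, "tns_slope": res.slope, "lamellarity": res.lamellarity}
        )
    return pd.DataFrame(rows)


def correlation_screen(
    campaign_with_metrics: pd.DataFrame,
    variables: list[str] | None = None,
    threshold: float = 0.5,
    per_device: bool = False,
):
    """Pearson matrix plus strong-pair report on a metrics-joined campaign.

    With ``per_device=True`` the screen is stratified: one matrix per
    device (the device code drops out), mirroring per-device scatterplot
    matrices; the default pools both devices with the device entering as a
    1/2-coded variable.
    """
    table = campaign_with_metrics.copy()
    if "device_code" not in table.columns and "device" in table.columns:
        table["device_code"] = encode_device(table["device"])
    variables = variables or [
        v for v in DEFAULT_CORR_VARIABLES if v in table.columns
    ]
    if per_device:
        out = {}
        sub_vars = [v for v in variables if v != "device_code"]
        for device, sub in table.groupby("device"):
            matrix = pearson_matrix(sub, sub_vars)
            out[device] = (matrix, flag_strong(matrix, threshold))
        return out
    matrix = pearson_matrix(table, variables)
    return matrix, flag_strong(matrix, threshold)
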