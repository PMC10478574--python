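"""Hydrodynamic condition descriptors and cross-device campaign summaries.

The static mixer (SM, millimetre-scale channel) and the staggered
herringbone micromixer (SHM, microchannel) run at the same volumetric flow
rates but wildly different linear velocities because their cross-sections
differ by a factor of ~50.  This module converts flow settings into linear
velocity and post-mixing solvent fractions, and reduces a paired campaign
table into the per-ILC size-difference / PDI summaries used to compare the
two devices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MixerGeometry",
    "linear_flow_velocity",
    "final_solvent_fraction",
    "paired_device_summary",
]

#: Cross-section ratio between the SM channel and the conventional SHM.
SM_TO_SHM_AREA_RATIO = 50.0


@dataclass(frozen=True)
class MixerGeometry:
    """Flow-path cross-section, given either as a circular-channel diameter
    (mm) or directly as an area (mm^2).  Exactly one must be supplied."""

    channel_diameter: float | None = None
    cross_section_area: float | None = None

    def __post_init__(self) -> None:
        if (self.channel_diameter is None) == (self.cross_section_area is None):
            raise ValueError(
                "specify exactly one of channel_diameter or cross_section_area"
            )
        if self.area_mm2 <= 0:
            raise ValueError("cross-section area must be positive")

    @property
    def area_mm2(self) -> float:
        if self.cross_section_area is not None:
            return self.cross_section_area
        return math.pi * (self.channel_diameter / 2.0) ** 2

    @classmethod
    def sm_default(cls) -> "MixerGeometry":
        """1 mm circular channel of the static mixer."""
        return cls(channel_diameter=1.0)

    @classmethod
    def shm_default(cls) -> "MixerGeometry":
        """SHM cross-section via the 50x-smaller-than-SM relation.

        The exact SHM dimensions are not fixed here; override with a
        measured cross_section_area when available.
        """
        return cls(cross_section_area=cls.sm_default().area_mm2 / SM_TO_SHM_AREA_RATIO)


def linear_flow_velocity(tfr: float, geom: MixerGeometry) -> float:
    """Mean linear flow velocity in cm/s for a TFR in uL/min.

    TFR is converted to cm^3/s (1 uL = 1e-3 cm^3) and divided by the
    cross-section in cm^2 (1 mm^2 = 1e-2 cm^2).
    """
    if not tfr > 0:
        raise ValueError("tfr must be > 0")
    flow_cm3_s = tfr * 1e-3 / 60.0
    area_cm2 = geom.area_mm2 * 1e-2
    return flow_cm3_s / area_cm2


def final_solvent_fraction(frr: float) -> float:
    """Ethanol volume fraction after complete mixing: 1/(1 + FRR)."""
    if not frr > 0:
        raise ValueError("frr must be > 0")
    return 1.0 / (1.0 + frr)


def paired_device_summary(records: pd.DataFrame) -> dict:
    """Cross-device comparison of matched SM/SHM conditions.

    ``records`` needs columns device, tfr_ul_min, frr, ilc_mg_ml,
    mean_diameter_nm, pdi.  Rows are matched across devices on identical
    (TFR, FRR, ILC); unmatched conditions are skipped with a warning.

    Returns a dict with a per-ILC table of mean SM-minus-SHM size
    differences, their unweighted overall mean, per-device mean PDI and
    the SHM/SM PDI ratio.  Averages are unweighted means over conditions,
    so the summary is invariant to row order and to duplicating a matched
    pair changes only that pair's internal mean.
    """
    keys = ["tfr_ul_min", "frr", "ilc_mg_ml"]
    sm = records[records["device"] == "SM"]
    shm = records[records["device"] == "SHM"]
    merged = pd.merge(
        sm.groupby(keys, as_index=False)[["mean_diameter_nm", "pdi"]].mean(),
        shm.groupby(keys, as_index=False)[["mean_diameter_nm", "pdi"]].mean(),
        on=keys,
        how="outer",
        suffixes=("_sm", "_shm"),
        indicator=True,
    )
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        warnings.warn(
            f"skipping {len(unmatched)} condition(s) without a matched "
            "SM/SHM pair",
            stacklevel=2,
        )
    matched = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    if matched.empty:
        raise ValueError("no matched SM/SHM conditions in the table")
    matched["size_difference_nm"] = (
        matched["mean_diameter_nm_sm"] - matched["mean_diameter_nm_shm"]
    )
    per_ilc = (
        matched.groupby("ilc_mg_ml", as_index=False)["size_difference_nm"]
        .mean()
        .sort_values("ilc_mg_ml")
        .reset_index(drop=True)
    )
    mean_pdi_sm = float(matched["pdi_sm"].mean())
    mean_pdi_shm = float(matched["pdi_shm"].mean())
    return {
        "per_ilc_size_difference": per_ilc,
        "overall_mean_size_difference_nm": float(
            per_ilc["size_difference_nm"].mean()
        ),
        "mean_pdi_sm": mean_pdi_sm,
        "mean_pdi_shm": mean_pdi_shm,
        "pdi_ratio_shm_over_sm": mean_pdi_shm / mean_pdi_sm,
    }
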