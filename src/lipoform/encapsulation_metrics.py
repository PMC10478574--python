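"""Measured encapsulation metrics: lipid recovery rate, loading, EE.

All three metrics are ratios of fluorescence-calibrated concentrations
against a mixed-solution (MS) reference — the two feed solutions combined
by pipetting at the experimental flow-rate ratio without passing through a
mixing device:

* LRR%   = 100 * [lipid after device] / [lipid of MS]
* Loading = [calcein after purification] / [lipid after purification]
* EE%    = 100 * Loading * [lipid after device] / [calcein of MS]

Lipid concentrations are mass concentrations (mg/mL) from the DiD channel;
calcein concentrations are mM.  LRR above 100% is reported as-is: it is
measurement noise, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import constants

__all__ = [
    "FormulationCondition",
    "LipidComposition",
    "FluorescenceCalibration",
    "MixedSolutionReference",
    "SampleMeasurement",
    "lipid_recovery_rate",
    "loading",
    "encapsulation_efficiency",
    "calibrate",
]


@dataclass(frozen=True)
class FormulationCondition:
    """One mixer run's knobs: device label, TFR (uL/min), FRR, ILC (mg/mL)."""

    device: str
    tfr: float
    frr: float
    ilc: float

    def __post_init__(self) -> None:
        if self.device not in ("SM", "SHM"):
            raise ValueError(f"device must be 'SM' or 'SHM', got {self.device!r}")
        for name in ("tfr", "frr", "ilc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class LipidComposition:
    """Lipid mixture as (name, molar ratio, molar mass g/mol) components."""

    components: tuple = field(default=constants.DEFAULT_COMPOSITION)

    def __post_init__(self) -> None:
        for name, ratio, mass in self.components:
            if ratio <= 0 or mass <= 0:
                raise ValueError(f"nonpositive ratio or molar mass for {name}")

    @classmethod
    def default(cls) -> "LipidComposition":
        return cls()

    @property
    def mean_molar_mass(self) -> float:
        """Mole-fraction-weighted mean molar mass, g/mol."""
        total_ratio = sum(r for _, r, _ in self.components)
        return sum(r * m for _, r, m in self.components) / total_ratio

    def mass_to_millimolar(self, mass_conc_mg_ml: float) -> float:
        """Convert a lipid mass concentration (mg/mL) to mM."""
        return mass_conc_mg_ml / self.mean_molar_mass * 1e3


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Linear intensity-to-concentration map for one fluorescence channel."""

    channel: str
    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")


@dataclass(frozen=True)
class MixedSolutionReference:
    """Feed concentrations after pipette mixing at the experimental FRR.

    lipid_conc_ms = ILC/(1+FRR) mg/mL; calcein_conc_ms is the aqueous
    calcein stock diluted by its volume fraction FRR/(1+FRR), mM.
    """

    lipid_conc_ms: float
    calcein_conc_ms: float

    @classmethod
    def from_condition(
        cls,
        condition: FormulationCondition,
        calcein_stock_mm: float = constants.DEFAULT_CALCEIN_STOCK_MM,
    ) -> "MixedSolutionReference":
        frr = condition.frr
        return cls(
            lipid_conc_ms=condition.ilc / (1.0 + frr),
            calcein_conc_ms=calcein_stock_mm * frr / (1.0 + frr),
        )


@dataclass(frozen=True)
class SampleMeasurement:
    """Calibrated concentrations at the two pipeline stages.

    lipid concentrations in mg/mL, calcein in mM; 'post device' is the raw
    mixer output, 'post purification' follows ultrafiltration.
    """

    lipid_conc_post_device: float
    lipid_conc_post_purification: float
    calcein_conc_post_purification: float

    def __post_init__(self) -> None:
        for name in (
            "lipid_conc_post_device",
            "lipid_conc_post_purification",
            "calcein_conc_post_purification",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def lipid_recovery_rate(meas: SampleMeasurement, ms: MixedSolutionReference) -> float:
    """LRR in percent: lipid out of the device relative to the MS feed."""
    if not ms.lipid_conc_ms > 0:
        raise ValueError("mixed-solution lipid concentration must be > 0")
    return 100.0 * meas.lipid_conc_post_device / ms.lipid_conc_ms


def loading(meas: SampleMeasurement) -> float:
    """Calcein per unit lipid after purification (mM per mg/mL)."""
    if not meas.lipid_conc_post_purification > 0:
        raise ValueError("post-purification lipid concentration must be > 0")
    return meas.calcein_conc_post_purification / meas.lipid_conc_post_purification


def encapsulation_efficiency(
    meas: SampleMeasurement, ms: MixedSolutionReference
) -> float:
    """EE in percent: encapsulated calcein relative to the MS feed calcein."""
    if not ms.calcein_conc_ms > 0:
        raise ValueError("mixed-solution calcein concentration must be > 0")
    return 100.0 * loading(meas) * meas.lipid_conc_post_device / ms.calcein_conc_ms


def calibrate(
    intensity: float, cal: FluorescenceCalibration, dilution_factor: float = 1.0
) -> float:
    """Convert a fluorescence intensity to a concentration.

    Applies the inverse linear map (intensity - intercept)/slope, then
    multiplies by the sample dilution applied before the plate read (e.g.
    the 10x ethanol solubilization step for the DiD channel).  Negative
    results are floored at zero with a warning — they indicate a reading
    below the calibration blank.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    conc = (intensity - cal.intercept) / cal.slope * dilution_factor
    if conc < 0:
        warnings.warn(
            f"{cal.channel}: intensity {intensity} below calibration blank; "
            "flooring concentration at 0",
            stacklevel=2,
        )
        conc = 0.0
    return conc
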