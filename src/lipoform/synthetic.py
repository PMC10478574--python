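"""Synthetic formulation campaigns with known ground truth.

The generator runs the measurement chain forwards: condition-level trend
models set each sample's true mean size, PDI and lamellarity; the
geometric unilamellar model gives its theoretical encapsulation
efficiency (TEE); the true EE is the TEE scaled down by a mixing
shortfall and divided by lamellarity (inner bilayers consume lipid
without adding encapsulation volume).  Concentrations are then pushed
through linear fluorescence calibrations with multiplicative log-normal
noise, ultrafiltration leaves a residual of unencapsulated calcein at
1/dilution of the outer phase, and TNS titrations are emitted with slope
inversely proportional to lamellarity.  Every draw comes from one seeded
stream, so equal seeds give bit-identical campaigns.

Trend defaults emulate a two-device study (static mixer SM vs staggered
herringbone micromixer SHM): SM sizes larger and growing steeply with
initial lipid concentration (ILC) at low PDI, SHM sizes near 100 nm with
PDI rising with ILC, SM lamellarity climbing past 10 at high ILC while
SHM stays near unilamellar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants
from .encapsulation_metrics import FormulationCondition, LipidComposition
from .size_distribution import DlsReadout
from .tee_model import TEEParameters, tee_for_condition

__all__ = [
    "DeviceTrends",
    "NoiseModel",
    "GeneratorConfig",
    "SyntheticCampaign",
    "generate_campaign",
    "paper_like_conditions",
    "paper_like_campaign",
    "simulate_titration",
]


@dataclass(frozen=True)
class DeviceTrends:
    """Linear trend models for one device.

    Size: mean diameter (nm) = size_base + size_ilc_slope*ILC
    + size_tfr_slope*(TFR - 1500).  PDI and lamellarity are linear in ILC;
    lamellarity is floored at lam_floor.
    """

    size_base_nm: float
    size_ilc_slope: float
    size_tfr_slope: float
    pdi_base: float
    pdi_ilc_slope: float
    lam_base: float
    lam_ilc_slope: float
    lam_floor: float = 0.5

    def mean_diameter(self, ilc: float, tfr: float) -> float:
        return (
            self.size_base_nm
            + self.size_ilc_slope * ilc
            + self.size_tfr_slope * (tfr - 1500.0)
        )

    def pdi(self, ilc: float) -> float:
        return self.pdi_base + self.pdi_ilc_slope * ilc

    def lamellarity(self, ilc: float) -> float:
        return max(self.lam_base + self.lam_ilc_slope * ilc, self.lam_floor)


# Trend coefficients anchored to the observed two-device behaviour:
# SHM ~91 nm at ILC 15 rising to ~131 nm at ILC 90 with PDI 0.074 -> 0.224,
# lamellarity ~0.93 -> 1.3; SM ~175 -> ~286 nm at PDI ~0.073 with
# lamellarity 1.7 -> 11.9 over the same ILC range.
DEFAULT_TRENDS = {
    "SHM": DeviceTrends(
        size_base_nm=83.0,
        size_ilc_slope=0.533,
        size_tfr_slope=-0.005,
        pdi_base=0.044,
        pdi_ilc_slope=0.0020,
        lam_base=0.856,
        lam_ilc_slope=0.00493,
    ),
    "SM": DeviceTrends(
        size_base_nm=152.8,
        size_ilc_slope=1.48,
        size_tfr_slope=-0.032,
        pdi_base=0.070,
        pdi_ilc_slope=0.0001,
        lam_base=-0.34,
        lam_ilc_slope=0.136,
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Relative noise SDs: additive Gaussian on DLS summaries,
    multiplicative log-normal on fluorescence and titration intensities."""

    dls_rel: float = 0.02
    fluorescence_rel: float = 0.02
    titration_rel: float = 0.02
    calibration_rel: float = 0.01

    def __post_init__(self) -> None:
        for name in ("dls_rel", "fluorescence_rel", "titration_rel", "calibration_rel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ChannelModel:
    """Forward fluorescence response of one plate-reader channel."""

    slope: float
    intercept: float
    read_dilution: float = 1.0  # sample is diluted this much before the read


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    conditions: tuple = ()
    trends: dict = field(default_factory=lambda: dict(DEFAULT_TRENDS))
    ee_shortfall: float = 0.7  # mixing-shortfall factor in (0, 1]
    calcein_stock_mm: float = constants.DEFAULT_CALCEIN_STOCK_MM
    carryover_dilution: float = constants.DEFAULT_CARRYOVER_DILUTION
    purification_factor: float = 0.8  # lipid conc change through ultrafiltration
    lrr_mean: float = 0.90
    lrr_sd: float = 0.08
    noise: NoiseModel = field(default_factory=NoiseModel)
    standard_tns_slope: float = 8.6
    tns_background: float = 1.0
    titration_amounts: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    # Channel gains chosen so the faintest samples still sit well above the
    # instrument blank (signal-to-blank >= ~3), as a plate-reader assay
    # would be configured for this concentration range.
    lipid_channel: ChannelModel = field(
        default_factory=lambda: ChannelModel(slope=500.0, intercept=50.0, read_dilution=10.0)
    )
    calcein_channel: ChannelModel = field(
        default_factory=lambda: ChannelModel(slope=2.0e4, intercept=20.0)
    )
    composition: LipidComposition = field(default_factory=LipidComposition)
    tee_params: TEEParameters = field(default_factory=TEEParameters)

    def __post_init__(self) -> None:
        if not 0 < self.ee_shortfall <= 1:
            raise ValueError("ee_shortfall must lie in (0, 1]")
        if self.carryover_dilution < 1:
            raise ValueError("carryover_dilution must be >= 1")
        if not self.conditions:
            raise ValueError("no conditions configured")


@dataclass(frozen=True)
class SyntheticCampaign:
    """Generated tables plus the ground truth behind them."""

    campaign: pd.DataFrame
    titrations: pd.DataFrame
    calibrations: dict
    truth: pd.DataFrame
    config: GeneratorConfig


def paper_like_conditions() -> tuple:
    """The two-device condition grid of the emulated study.

    Per device: TFR 1500/2000/2500 uL/min at FRR 3, plus FRR 4/5 at TFR
    1500 — five flow settings — each at ILC 15/30/45/60/90 mg/mL.
    """
    flows = [(1500, 3), (2000, 3), (2500, 3), (1500, 4), (1500, 5)]
    ilcs = [15, 30, 45, 60, 90]
    return tuple(
        FormulationCondition(device=dev, tfr=tfr, frr=frr, ilc=ilc)
        for dev in ("SHM", "SM")
        for (tfr, frr) in flows
        for ilc in ilcs
    )


def simulate_titration(
    lam: float,
    rng: np.random.Generator,
    standard_slope: float = 8.6,
    amounts=(1.0, 2.0, 3.0, 4.0, 5.0),
    background: float = 1.0,
    noise_rel: float = 0.02,
) -> pd.DataFrame:
    """One TNS titration for a population of lamellarity ``lam``.

    Accessible surface area per lipid scales as 1/lam, so the generating
    slope is standard_slope/lam; intensities carry multiplicative
    log-normal noise on top of an additive background.
    """
    x = np.asarray(amounts, dtype=float)
    clean = standard_slope / lam * x + background
    noisy = clean * _lognormal_factor(rng, noise_rel, x.size)
    return pd.DataFrame({"lipid_amount": x, "intensity": noisy})


def _lognormal_factor(rng: np.random.Generator, rel_sd: float, size) -> np.ndarray:
    if rel_sd == 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=rel_sd, size=size)


def _forward_intensity(
    conc: float, channel: ChannelModel, rng: np.random.Generator, rel_sd: float
) -> float:
    clean = channel.slope * conc / channel.read_dilution + channel.intercept
    return float(clean * _lognormal_factor(rng, rel_sd, 1)[0])


def _calibration_table(
    channel: ChannelModel,
    concentrations: np.ndarray,
    rng: np.random.Generator,
    rel_sd: float,
) -> pd.DataFrame:
    clean = channel.slope * concentrations + channel.intercept
    noisy = clean * _lognormal_factor(rng, rel_sd, concentrations.size)
    return pd.DataFrame({"concentration": concentrations, "intensity": noisy})


def generate_campaign(config: GeneratorConfig) -> SyntheticCampaign:
    """Run the forward model over the configured condition grid.

    Returns the campaign table (DLS readouts plus raw fluorescence
    intensities), per-sample TNS titrations including the unilamellar
    STANDARD, calibration tables per channel, and the ground-truth table.
    """
    rng = np.random.default_rng(config.seed)
    nz = config.noise

    rows, truth_rows, titration_frames = [], [], []

    # Calibration tables first so their draws are independent of grid size.
    calibrations = {
        "lipid": _calibration_table(
            config.lipid_channel, np.linspace(0.05, 2.0, 8), rng, nz.calibration_rel
        ),
        "calcein": _calibration_table(
            config.calcein_channel, np.linspace(0.0005, 0.04, 8), rng, nz.calibration_rel
        ),
    }

    std = simulate_titration(
        1.0,
        rng,
        standard_slope=config.standard_tns_slope,
        amounts=config.titration_amounts,
        background=config.tns_background,
        noise_rel=nz.titration_rel,
    )
    std.insert(0, "sample_id", "STANDARD")
    titration_frames.append(std)

    for idx, cond in enumerate(config.conditions):
        sample_id = f"{cond.device}-T{cond.tfr:.0f}-F{cond.frr:g}-L{cond.ilc:g}"
        trends = config.trends[cond.device]

        # True physical state: trend plus process noise.
        mean_d = trends.mean_diameter(cond.ilc, cond.tfr)
        mean_d = mean_d * (1.0 + nz.dls_rel * rng.standard_normal())
        pdi = trends.pdi(cond.ilc)
        pdi = min(max(pdi + pdi * nz.dls_rel * rng.standard_normal(), 1e-4), 0.5)
        lam = trends.lamellarity(cond.ilc)

        tee_res = tee_for_condition(
            cond,
            DlsReadout(mean_diameter=mean_d, pdi=pdi),
            composition=config.composition,
            params=config.tee_params,
        )
        tee_pct = tee_res.tee_percent
        ee_pct = config.ee_shortfall * tee_pct / lam
        if ee_pct > 100:
            raise ValueError(
                f"config yields EE {ee_pct:.1f}% > 100% for {sample_id}"
            )

        # Concentration chain.
        lipid_ms = cond.ilc / (1.0 + cond.frr)
        calcein_ms = config.calcein_stock_mm * cond.frr / (1.0 + cond.frr)
        lrr_true = float(np.clip(rng.normal(config.lrr_mean, config.lrr_sd), 0.5, 1.25))
        lipid_pd = lrr_true * lipid_ms
        lipid_pp = config.purification_factor * lipid_pd
        loading_true = (ee_pct / 100.0) * calcein_ms / lipid_pd
        calcein_encap_pp = loading_true * lipid_pp
        free_residual = (
            calcein_ms * (1.0 - ee_pct / 100.0) / config.carryover_dilution
            if math.isfinite(config.carryover_dilution)
            else 0.0
        )
        calcein_pp = calcein_encap_pp + free_residual
        # EE a noise-free measurement chain would report (carry-over bias in).
        ee_apparent = 100.0 * (calcein_pp / lipid_pp) * lipid_pd / calcein_ms

        rows.append(
            {
                "sample_id": sample_id,
                "device": cond.device,
                "tfr_ul_min": cond.tfr,
                "frr": cond.frr,
                "ilc_mg_ml": cond.ilc,
                "mean_diameter_nm": mean_d,
                "pdi": pdi,
                "lipid_intensity_post_device": _forward_intensity(
                    lipid_pd, config.lipid_channel, rng, nz.fluorescence_rel
                ),
                "lipid_intensity_post_purification": _forward_intensity(
                    lipid_pp, config.lipid_channel, rng, nz.fluorescence_rel
                ),
                "calcein_intensity_post_purification": _forward_intensity(
                    calcein_pp, config.calcein_channel, rng, nz.fluorescence_rel
                ),
            }
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "true_mean_diameter_nm": mean_d,
                "true_pdi": pdi,
                "true_lamellarity": lam,
                "true_tee_pct": tee_pct,
                "true_ee_pct": ee_pct,
                "true_ee_apparent_pct": ee_apparent,
                "true_lrr_pct": 100.0 * lrr_true,
                "true_lipid_post_device": lipid_pd,
                "true_lipid_post_purification": lipid_pp,
                "true_calcein_post_purification": calcein_pp,
                "true_loading": loading_true,
            }
        )
        tit = simulate_titration(
            lam,
            rng,
            standard_slope=config.standard_tns_slope,
            amounts=config.titration_amounts,
            background=config.tns_background,
            noise_rel=nz.titration_rel,
        )
        tit.insert(0, "sample_id", sample_id)
        titration_frames.append(tit)

    return SyntheticCampaign(
        campaign=pd.DataFrame(rows),
        titrations=pd.concat(titration_frames, ignore_index=True),
        calibrations=calibrations,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def paper_like_campaign(seed: int = 0, **overrides) -> SyntheticCampaign:
    """Generate the default two-device study campaign."""
    config = GeneratorConfig(seed=seed, conditions=paper_like_conditions())
    if overrides:
        config = replace(config, **overrides)
    return generate_campaign(config)
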