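"""Geometric theoretical encapsulation efficiency (TEE) for unilamellar vesicles.

The model treats every vesicle as a sphere of outer radius r bounded by a
single bilayer of thickness d.  Two leaflets — outer at radius r, inner at
radius r - d — are tiled by lipids of molecular area a, so a vesicle of
radius r consumes 4*pi*(r^2 + (r-d)^2)/a lipid molecules.  A dispersion
with lipid molar concentration c and volume V holds c*V*N_A molecules,
which fixes the vesicle number; the aqueous lumen of radius r - d then
gives the total encapsulated volume, and TEE% is that volume as a
percentage of the dispersion volume.  Averaging both the lipid demand and
the lumen volume over a radius distribution extends this to polydisperse
samples.  V cancels analytically; the result depends only on c and the
size distribution.

Vesicles with r <= d have no lumen: their inner leaflet and lumen are
clamped to zero but they stay in the lipid budget, which keeps the radius
weights normalized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import constants
from .size_distribution import DlsReadout, SizeDistribution, from_dls, moment

__all__ = [
    "TEEParameters",
    "LipidSample",
    "TEEResult",
    "lipids_per_vesicle",
    "tee",
    "tee_for_condition",
]


@dataclass(frozen=True)
class TEEParameters:
    """Bilayer geometry: membrane thickness d (nm), area per lipid a (nm^2)."""

    membrane_thickness_d: float = constants.DEFAULT_MEMBRANE_THICKNESS_NM
    area_per_lipid_a: float = constants.DEFAULT_AREA_PER_LIPID_NM2
    avogadro: float = constants.AVOGADRO

    def __post_init__(self) -> None:
        if not self.membrane_thickness_d > 0:
            raise ValueError("membrane_thickness_d must be > 0")
        if not self.area_per_lipid_a > 0:
            raise ValueError("area_per_lipid_a must be > 0")


@dataclass(frozen=True)
class LipidSample:
    """Lipid molar concentration (mM) and dispersion volume (mL)."""

    lipid_molar_concentration_c: float
    sample_volume_V: float = 1.0

    def __post_init__(self) -> None:
        if self.lipid_molar_concentration_c < 0:
            raise ValueError("lipid concentration must be >= 0")
        if self.sample_volume_V < 0:
            raise ValueError("sample volume must be >= 0")


@dataclass(frozen=True)
class TEEResult:
    """TEE as a percentage plus the intermediate geometry bookkeeping."""

    tee_percent: float
    vesicle_number_concentration: float  # vesicles per mL
    lipids_per_vesicle_mean: float

    def __post_init__(self) -> None:
        if not 0 <= self.tee_percent <= 100:
            raise ValueError(f"tee_percent out of [0, 100]: {self.tee_percent}")


def lipids_per_vesicle(r, params: TEEParameters = TEEParameters()):
    """Lipid molecules in one vesicle of outer radius ``r`` (nm).

    4*pi*(r^2 + max(r - d, 0)^2) / a — outer plus inner leaflet area over
    the molecular area.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    inner = np.maximum(r - params.membrane_thickness_d, 0.0)
    out = 4.0 * math.pi * (r**2 + inner**2) / params.area_per_lipid_a
    return float(out) if out.ndim == 0 else out


def _lumen_volume_nm3(r, d: float):
    inner = np.maximum(np.asarray(r, dtype=float) - d, 0.0)
    return (4.0 / 3.0) * math.pi * inner**3


def tee(
    dist: SizeDistribution,
    sample: LipidSample,
    params: TEEParameters = TEEParameters(),
) -> TEEResult:
    """Theoretical encapsulation efficiency of a unilamellar dispersion.

    Vesicle count N = c*V*N_A / E[lipids per vesicle]; encapsulated volume
    is N * E[lumen volume]; tee_percent is the encapsulated fraction of V
    as a percentage.  The volume V cancels, so the result is V-independent.
    """
    d = params.membrane_thickness_d
    mean_lipids = moment(dist, lambda r: lipids_per_vesicle(r, params))
    mean_lumen_nm3 = moment(dist, lambda r: _lumen_volume_nm3(r, d))

    c_molar = sample.lipid_molar_concentration_c * constants.MM_TO_MOLAR
    # Lipid molecules per litre of dispersion; V cancels in TEE so work per
    # unit volume directly.
    lipids_per_litre = c_molar * params.avogadro
    vesicles_per_litre = lipids_per_litre / mean_lipids
    encapsulated_litre_per_litre = (
        vesicles_per_litre * mean_lumen_nm3 / constants.NM3_PER_LITRE
    )
    tee_percent = 100.0 * encapsulated_litre_per_litre
    if tee_percent > 100.0:
        warnings.warn(
            f"geometric TEE {tee_percent:.1f}% exceeds 100%; capping "
            "(lipid budget inconsistent with the dispersion volume)",
            stacklevel=2,
        )
        tee_percent = 100.0

    if mean_lumen_nm3 == 0.0 and c_molar > 0:
        warnings.warn(
            "size distribution lies entirely at or below the membrane "
            "thickness; TEE is 0",
            stacklevel=2,
        )
    return TEEResult(
        tee_percent=tee_percent,
        vesicle_number_concentration=vesicles_per_litre * constants.ML_TO_LITRE,
        lipids_per_vesicle_mean=mean_lipids,
    )


def tee_for_condition(
    condition,
    readout: DlsReadout,
    composition=None,
    params: TEEParameters = TEEParameters(),
    n_points: int = 1000,
    span: float = 5.0,
) -> TEEResult:
    """TEE for one formulation condition and its DLS readout.

    The post-mixing lipid mass concentration is ILC/(1 + FRR) mg/mL; the
    composition's mean molar mass converts it to mM before the geometric
    model is applied to the log-normal distribution implied by the readout.
    """
    from .encapsulation_metrics import LipidComposition

    if composition is None:
        composition = LipidComposition.default()
    mass_conc = condition.ilc / (1.0 + condition.frr)  # mg/mL == g/L
    c_mm = mass_conc / composition.mean_molar_mass * 1e3
    dist = from_dls(readout, n_points=n_points, span=span)
    return tee(dist, LipidSample(lipid_molar_concentration_c=c_mm), params)
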