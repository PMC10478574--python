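"""Lamellarity estimation from TNS titration slopes.

TNS binds the accessible membrane surface, so at matched lipid
concentration the slope of fluorescence intensity against the amount of
liposome sample added is proportional to surface area per lipid.  A
multilamellar vesicle buries lipid in inner bilayers that contribute no
accessible surface, which lowers the slope in proportion to the number of
bilayers.  Lamellarity is therefore estimated as the ratio

    lamellarity = slope(unilamellar standard) / slope(sample)

The regression fits a free intercept (background fluorescence) and only
the slope is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TNSTitration", "LamellarityResult", "fit_slope", "lamellarity"]


@dataclass(frozen=True)
class TNSTitration:
    """Paired (lipid amount, fluorescence intensity) titration points."""

    lipid_amounts: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.lipid_amounts, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("amounts and intensities must be 1-D and equally long")
        if x.size < 3:
            raise ValueError("a titration needs at least 3 points")
        if not np.all(np.diff(x) > 0):
            raise ValueError("lipid amounts must be strictly increasing")
        object.__setattr__(self, "lipid_amounts", x)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class LamellarityResult:
    slope: float
    lamellarity: float


def fit_slope(titration: TNSTitration) -> float:
    """Ordinary-least-squares slope of intensity against lipid amount."""
    fit = stats.linregress(titration.lipid_amounts, titration.intensities)
    return float(fit.slope)


def lamellarity(sample_slope: float, standard_slope: float) -> LamellarityResult:
    """Bilayer count estimate: standard (unilamellar) slope over sample slope."""
    if not sample_slope > 0:
        raise ValueError(
            f"sample slope must be > 0 (got {sample_slope}); a nonpositive "
            "TNS slope means the titration did not resolve a surface signal"
        )
    if not standard_slope > 0:
        raise ValueError(f"standard slope must be > 0 (got {standard_slope})")
    return LamellarityResult(
        slope=sample_slope, lamellarity=standard_slope / sample_slope
    )
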