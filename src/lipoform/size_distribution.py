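"""Log-normal vesicle radius distributions from DLS summary statistics.

Dynamic light scattering reports a mean hydrodynamic diameter and a
polydispersity index (PDI).  The encapsulation model needs a full radius
distribution, so the (mean, PDI) pair is mapped onto a number-weighted
log-normal: the PDI is read as the squared coefficient of variation of the
radius (CV^2 = PDI) and the arithmetic mean radius is half the reported
diameter.  The continuous density is then discretized on a geometric grid
for downstream moment sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = ["DlsReadout", "SizeDistribution", "from_dls", "moment"]


@dataclass(frozen=True)
class DlsReadout:
    """A DLS summary readout: mean diameter (nm) and polydispersity index."""

    mean_diameter: float
    pdi: float

    def __post_init__(self) -> None:
        if not self.mean_diameter > 0:
            raise ValueError(f"mean_diameter must be > 0, got {self.mean_diameter}")
        if not 0 <= self.pdi < 1:
            raise ValueError(
                f"pdi must lie in [0, 1); got {self.pdi} "
                "(the log-normal moment map CV^2 = PDI is undefined at PDI >= 1)"
            )


@dataclass(frozen=True)
class SizeDistribution:
    """Discretized log-normal radius distribution.

    Attributes
    ----------
    radii : ndarray
        Strictly increasing vesicle radii r_i, nm.
    probabilities : ndarray
        Weights P_i summing to one.
    mu_log, sigma_log : float
        Parameters of the underlying log-normal radius law,
        ln r ~ Normal(mu_log, sigma_log^2).  sigma_log = 0 marks the
        monodisperse special case.
    """

    radii: np.ndarray
    probabilities: np.ndarray
    mu_log: float
    sigma_log: float

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if r.shape != p.shape or r.ndim != 1:
            raise ValueError("radii and probabilities must be 1-D and equally long")
        if not np.all(r > 0):
            raise ValueError("all radii must be positive")
        if r.size > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("radii must be strictly increasing")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum():.12f})")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "probabilities", p)

    @property
    def mean_radius(self) -> float:
        """Arithmetic mean radius of the discretized distribution, nm."""
        return float(np.dot(self.probabilities, self.radii))


def from_dls(readout: DlsReadout, n_points: int = 1000, span: float = 5.0) -> SizeDistribution:
    """Build a discretized log-normal radius distribution from a DLS readout.

    The map uses the log-normal moment identities E[r] = exp(mu + sigma^2/2)
    and CV^2 = exp(sigma^2) - 1, with CV^2 = PDI and E[r] = mean_diameter/2.
    The grid is geometric over mu_log +/- span*sigma_log; weights are the
    continuous density integrated per log-spaced cell and renormalized so
    truncation never breaks normalization.

    Parameters
    ----------
    readout : DlsReadout
    n_points : int
        Grid resolution; >= 2 unless pdi == 0.
    span : float
        Half-width of the grid in units of sigma_log, in log space.
    """
    mean_radius = readout.mean_diameter / 2.0
    if readout.pdi == 0:
        return SizeDistribution(
            radii=np.array([mean_radius]),
            probabilities=np.array([1.0]),
            mu_log=math.log(mean_radius),
            sigma_log=0.0,
        )
    if n_points < 2:
        raise ValueError("n_points must be >= 2 for a polydisperse readout")
    if span <= 0:
        raise ValueError("span must be positive")

    sigma = math.sqrt(math.log1p(readout.pdi))
    mu = math.log(mean_radius) - sigma**2 / 2.0

    # Cell-integrated weights: integrate the normal density of ln r over
    # n_points equal cells covering mu +/- span*sigma, take cell centres as
    # the representative radii.
    edges = np.linspace(mu - span * sigma, mu + span * sigma, n_points + 1)
    weights = np.diff(ndtr((edges - mu) / sigma))
    centres = 0.5 * (edges[:-1] + edges[1:])
    weights = weights / weights.sum()
    return SizeDistribution(
        radii=np.exp(centres), probabilities=weights, mu_log=mu, sigma_log=sigma
    )


def moment(dist: SizeDistribution, transform) -> float:
    """Expectation sum_i P_i * f(r_i) for a per-radius function ``f``.

    ``transform`` must accept an ndarray of radii and return values of the
    same shape (any numpy ufunc or vectorized callable qualifies).
    """
    values = np.asarray(transform(dist.radii), dtype=float)
    return float(np.dot(dist.probabilities, values))
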