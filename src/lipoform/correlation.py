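"""Pairwise Pearson correlation screening with t-based significance.

Mirrors a scatterplot-matrix workflow: every pair of campaign variables
gets a product-moment correlation r, the t statistic
t = r*sqrt(n-2)/sqrt(1-r^2), a two-sided p-value from Student's t with
n-2 degrees of freedom, and significance stars at 0.05 / 0.01 / 0.001.
Observations are pairwise-complete; a constant column leaves its cells
flagged as undefined (NaN) rather than silently zeroed.  The categorical
device label is encoded 1 (SHM) / 2 (SM) so it can enter the matrix as a
point-biserial-style variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "pearson_matrix", "flag_strong", "encode_device"]

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def encode_device(labels: pd.Series) -> pd.Series:
    """Numeric device coding for correlation: SHM -> 1, SM -> 2."""
    mapping = {"SHM": 1.0, "SM": 2.0}
    bad = set(labels.unique()) - set(mapping)
    if bad:
        raise ValueError(f"unknown device labels: {sorted(bad)}")
    return labels.map(mapping)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation screen over a set of variables.

    r, t, p and n are square DataFrames indexed by variable; stars holds
    the significance codes ('' when not significant, NaN cells where r is
    undefined)."""

    variables: tuple
    r: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame


def _pearson_cell(x: np.ndarray, y: np.ndarray):
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs per cell")
    sx, sy = x.std(ddof=0), y.std(ddof=0)
    if sx == 0 or sy == 0:
        return np.nan, np.nan, np.nan, n  # constant column: undefined r
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.inf * np.sign(r), 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(t), float(p), n


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for level, code in _STAR_LEVELS:
        if p < level:
            return code
    return ""


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise Pearson screen over ``variables`` of a campaign table."""
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    k = len(variables)
    r = np.eye(k)
    t = np.full((k, k), np.inf)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    cols = {v: table[v].to_numpy(dtype=float) for v in variables}
    for i, vi in enumerate(variables):
        n[i, i] = np.isfinite(cols[vi]).sum()
        for j in range(i + 1, k):
            rij, tij, pij, nij = _pearson_cell(cols[vi], cols[variables[j]])
            r[i, j] = r[j, i] = rij
            t[i, j] = t[j, i] = tij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij

    def frame(a, dtype=float):
        return pd.DataFrame(a, index=variables, columns=variables).astype(dtype)

    p_df = frame(p)
    stars = p_df.map(_stars)
    return CorrelationMatrix(
        variables=tuple(variables),
        r=frame(r),
        t=frame(t),
        p=p_df,
        n=frame(n, int),
        stars=stars,
    )


def flag_strong(matrix: CorrelationMatrix, threshold: float = 0.5) -> list[tuple]:
    """Variable pairs with |r| >= threshold, strongest first.

    Returns (var_a, var_b, r, p) tuples for the upper triangle.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    pairs = []
    vs = matrix.variables
    for i, vi in enumerate(vs):
        for j in range(i + 1, len(vs)):
            r = matrix.r.iloc[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                pairs.append((vi, vs[j], float(r), float(matrix.p.iloc[i, j])))
    return sorted(pairs, key=lambda rec: abs(rec[2]), reverse=True)
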