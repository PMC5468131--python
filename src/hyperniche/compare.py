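"""Pairwise niche statistics and univariate density profiles.

Overlap statistics operate on the uniform point clouds the hypervolumes
carry: since each cloud is exactly uniform over its support, the
fraction of A-points falling inside B estimates |A∩B| / |A| without
bias, and the symmetrized estimator

    I = 1/2 [ frac(A-points in B) |A| + frac(B-points in A) |B| ]

is symmetric by construction.  The Soerensen similarity
S = 2|A∩B| / (|A| + |B|) then follows directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, ZeroVarianceError
from .hypervolume import Hypervolume, contains

__all__ = [
    "NicheComparison", "intersection_volume", "soerensen",
    "centroid_distance", "axis_contributions", "compare_pair",
    "comparison_matrix", "centroid_matrix", "contribution_table",
    "DensityProfile", "density_profile",
]


def _check_dims(a: Hypervolume, b: Hypervolume):
    if a.dim != b.dim:
        raise ConfigurationError(f"dimension mismatch: {a.dim} vs {b.dim}")


def intersection_volume(a: Hypervolume, b: Hypervolume):
    """Estimated |A∩B| with its (binomial, propagated) standard error."""
    _check_dims(a, b)
    in_b = contains(b, a.uniform_points)
    in_a = contains(a, b.uniform_points)
    fa, fb = in_b.mean(), in_a.mean()
    est = 0.5 * (fa * a.volume + fb * b.volume)
    se_fa = np.sqrt(fa * (1 - fa) / in_b.size)
    se_fb = np.sqrt(fb * (1 - fb) / in_a.size)
    se = 0.5 * np.hypot(a.volume * se_fa, b.volume * se_fb)
    return float(est), float(se)


def soerensen(a: Hypervolume, b: Hypervolume):
    """Soerensen similarity S = 2|A∩B| / (|A| + |B|), with SE.

    Clipped to [0, 1] only if Monte Carlo noise overshoots; the clip is
    reported in the third return value.
    """
    _check_dims(a, b)
    denom = a.volume + b.volume
    if denom == 0:
        raise ConfigurationError("both hypervolumes have zero volume")
    inter, se_i = intersection_volume(a, b)
    s = 2.0 * inter / denom
    clipped = bool(s < 0 or s > 1)
    return float(np.clip(s, 0.0, 1.0)), 2.0 * se_i / denom, clipped


def centroid_distance(a: Hypervolume, b: Hypervolume) -> float:
    """Euclidean distance between the uniform-cloud centroids (PC units)."""
    _check_dims(a, b)
    return float(np.linalg.norm(a.centroid - b.centroid))


def axis_contributions(hv: Hypervolume) -> np.ndarray:
    """Per-axis spread of the support, normalized to the first axis.

    contribution(j) = span of the uniform cloud along axis j divided by
    the span along axis 1, so the first axis always reports 1.00.  This
    is one reasonable operationalization of "relative contribution of
    each axis to the total volume"; it is deliberately simple and
    swappable.
    """
    spans = np.ptp(hv.uniform_points, axis=0)
    if spans[0] == 0:
        raise ZeroVarianceError("zero span on axis 1; contributions undefined")
    return spans / spans[0]


@dataclass
class NicheComparison:
    """All pairwise statistics for one (a, b) hypervolume pair."""

    group_a: str
    group_b: str
    volume_a: float
    volume_b: float
    intersection: float
    intersection_se: float
    soerensen: float
    soerensen_se: float
    unique_a: float
    unique_b: float
    centroid_dist: float
    mc_meta: dict = field(default_factory=dict)


def compare_pair(name_a, a: Hypervolume, name_b, b: Hypervolume) -> NicheComparison:
    inter, se_i = intersection_volume(a, b)
    s, se_s, clipped = soerensen(a, b)
    return NicheComparison(
        group_a=name_a, group_b=name_b,
        volume_a=a.volume, volume_b=b.volume,
        intersection=inter, intersection_se=se_i,
        soerensen=s, soerensen_se=se_s,
        unique_a=a.volume - inter, unique_b=b.volume - inter,
        centroid_dist=centroid_distance(a, b),
        mc_meta={"clipped": clipped},
    )


def comparison_matrix(hvs: dict) -> pd.DataFrame:
    """Square table: volumes on the diagonal, intersection volumes below
    it, Soerensen similarities above it (the conventional layout for
    reporting niche-overlap matrices)."""
    names = list(hvs)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, gi in enumerate(names):
        out.loc[gi, gi] = hvs[gi].volume
        for gj in names[i + 1:]:
            cmpr = compare_pair(gi, hvs[gi], gj, hvs[gj])
            out.loc[gj, gi] = cmpr.intersection  # below diagonal
            out.loc[gi, gj] = cmpr.soerensen     # above diagonal
    return out


def centroid_matrix(hvs_lower: dict, hvs_upper: dict = None) -> pd.DataFrame:
    """Pairwise centroid distances; optionally a second method's
    distances above the diagonal (lower = first argument)."""
    names = list(hvs_lower)
    upper = hvs_upper or hvs_lower
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            out.loc[gj, gi] = centroid_distance(hvs_lower[gi], hvs_lower[gj])
            out.loc[gi, gj] = centroid_distance(upper[gi], upper[gj])
    return out


def contribution_table(hvs: dict) -> pd.DataFrame:
    """One row per group: per-axis contributions (first axis = 1.00)."""
    rows = {g: axis_contributions(hv) for g, hv in hvs.items()}
    d = len(next(iter(rows.values())))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"PC {j + 1}" for j in range(d)])


# --------------------------------------------------------------------- #
# univariate density profiles                                           #
# --------------------------------------------------------------------- #
@dataclass
class DensityProfile:
    """Per-group Gaussian KDE curves of one variable on a shared grid."""

    variable: str
    grid: np.ndarray
    densities: dict        # group -> density curve on grid
    bandwidths: dict       # group -> normal-reference bandwidth used

    def to_frame(self) -> pd.DataFrame:
        """Tidy layout: variable, group, x, density."""
        parts = [
            pd.DataFrame({"variable": self.variable, "group": g,
                          "x": self.grid, "density": d})
            for g, d in self.densities.items()
        ]
        return pd.concat(parts, ignore_index=True)


def density_profile(values_by_group: dict, variable: str = "",
                    n_grid: int = 512) -> DensityProfile:
    """Univariate Gaussian kernel density per group on a shared grid.

    Bandwidth per group by the normal-reference rule
    h = 1.06 sigma n^(-1/5); the grid spans the pooled range extended by
    3 of the largest bandwidth.  Groups with < 2 values or zero
    variance are rejected (a degenerate spike is not a density).
    """
    bandwidths = {}
    arrays = {}
    for g, vals in values_by_group.items():
        x = np.asarray(vals, dtype=float).ravel()
        if x.size < 2:
            raise ConfigurationError(f"group '{g}' has fewer than 2 values")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError(f"group '{g}' has zero variance")
        arrays[g] = x
        bandwidths[g] = 1.06 * sd * x.size ** (-1 / 5)
    pooled = np.concatenate(list(arrays.values()))
    pad = 3 * max(bandwidths.values())
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, n_grid)
    densities = {}
    for g, x in arrays.items():
        h = bandwidths[g]
        densities[g] = norm.pdf((grid[:, None] - x) / h).mean(axis=1) / h
    return DensityProfile(variable=variable, grid=grid,
                          densities=densities, bandwidths=bandwidths)
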