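"""Orthogonal climate space: extraction, thinning, and correlation-matrix PCA.

The niche analyses downstream all operate in an orthogonal environment
space obtained by a PCA of the standardized (correlation-matrix)
environmental variables, keeping the components with eigenvalue > 1
(Kaiser criterion).  The fit sample is normally the full set of valid
background cells of the analysis extent, so the axes describe the
*available* climate space rather than the occupied part of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ZeroVarianceError
from .occurrences import OccurrenceSet
from .raster import EnvRasterStack

__all__ = [
    "PCATransform",
    "extract_env",
    "dedupe_per_cell",
    "fit_pca",
    "pc_scores",
    "loadings",
    "kaiser_retention",
]


def extract_env(stack: EnvRasterStack, occ: OccurrenceSet):
    """Extract environment values at occurrence records.

    Records on nodata cells or outside the grid are not fatal: they are
    returned in ``dropped`` (DataFrame with ``id, reason``).  The
    environment matrix rows align with the surviving records and carry
    the record ids as index.
    """
    lon, lat = occ.lonlat()
    rows, cols = stack.cell_index(lon, lat)
    reasons = np.full(len(occ), "", dtype=object)
    outside = rows < 0
    reasons[outside] = "outside"
    inside = ~outside
    nodata = np.zeros(len(occ), dtype=bool)
    nodata[inside] = stack.nodata_mask[rows[inside], cols[inside]]
    reasons[nodata] = "nodata"
    keep = ~(outside | nodata)
    values = stack.values[:, rows[keep], cols[keep]].T
    matrix = pd.DataFrame(values, columns=list(stack.names),
                          index=occ.df.loc[keep, "id"].to_numpy())
    dropped = occ.df.loc[~keep, ["id"]].copy()
    dropped["reason"] = reasons[~keep]
    return matrix, dropped


def dedupe_per_cell(occ: OccurrenceSet, stack: EnvRasterStack) -> OccurrenceSet:
    """Keep at most one record per (cell, group), first by input order.

    Records outside the grid are kept untouched (they drop later at
    extraction, with a report).
    """
    lon, lat = occ.lonlat()
    rows, cols = stack.cell_index(lon, lat)
    flat = rows * stack.ncols + cols
    df = occ.df.copy()
    df["_cell"] = flat
    on_grid = df["_cell"] >= 0
    deduped = df[on_grid].drop_duplicates(subset=["_cell", "group"], keep="first")
    out = pd.concat([deduped, df[~on_grid]]).sort_index()
    return OccurrenceSet(out.drop(columns="_cell"))


def kaiser_retention(eigenvalues) -> int:
    """Number of components retained under the eigenvalue > 1 rule."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0))


@dataclass
class PCATransform:
    """Standardization + eigenstructure of a correlation-matrix PCA.

    ``eigvecs`` columns are unit eigenvectors in descending-eigenvalue
    order, sign-fixed so that each component's largest-|loading|
    variable loads positive.  ``k`` components (eigenvalue > 1) are
    retained for scoring.
    """

    variables: list
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray
    eigvecs: np.ndarray
    k: int
    fit_info: dict = field(default_factory=dict)

    @property
    def explained_variance_pct(self):
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    def standardize(self, matrix) -> np.ndarray:
        X = self._aligned(matrix)
        return (X - self.means) / self.sds

    def _aligned(self, matrix) -> np.ndarray:
        if isinstance(matrix, pd.DataFrame):
            missing = [v for v in self.variables if v not in matrix.columns]
            if missing:
                raise ConfigurationError(f"matrix lacks fitted variables {missing}")
            return matrix[self.variables].to_numpy(dtype=float)
        X = np.asarray(matrix, dtype=float)
        if X.shape[1] != len(self.variables):
            raise ConfigurationError(
                f"matrix has {X.shape[1]} columns, PCA was fitted on "
                f"{len(self.variables)}"
            )
        return X


def fit_pca(matrix, fit_info=None) -> PCATransform:
    """Correlation-matrix PCA with Kaiser (eigenvalue > 1) retention.

    ``matrix`` is samples x variables (DataFrame preferred: column names
    become variable names).  Eigenvalues sum to the number of variables;
    eigenvector signs are fixed so the largest-|loading| variable of
    each component loads positive.
    """
    if isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        variables = [f"var{i + 1}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ConfigurationError("PCA requires at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ZeroVarianceError(
            f"zero-variance variable(s): {[variables[i] for i in zero]}"
        )
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-|loading| variable of each PC loads positive
    for j in range(evecs.shape[1]):
        i_star = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_star, j] < 0:
            evecs[:, j] = -evecs[:, j]
    k = kaiser_retention(evals)
    if k == 0:
        raise ConfigurationError("no component has eigenvalue > 1; nothing to retain")
    return PCATransform(variables=variables, means=means, sds=sds,
                        eigenvalues=evals, eigvecs=evecs, k=k,
                        fit_info=dict(fit_info or {}, n_samples=X.shape[0]))


def pc_scores(pca: PCATransform, matrix, n_components=None) -> np.ndarray:
    """Scores (samples x k) on the retained axes."""
    k = pca.k if n_components is None else n_components
    Z = pca.standardize(matrix)
    return Z @ pca.eigvecs[:, :k]


def loadings(pca: PCATransform, matrix) -> pd.DataFrame:
    """Variable x PC Pearson-correlation table for the fit sample.

    The layout mirrors a standard PCA summary: one row per variable with
    its correlation against each retained score, plus ``Eigenvalues``
    and ``Explained Variance`` (percent) rows.  For a correlation-matrix
    PCA the entries equal eigenvector * sqrt(eigenvalue); they are
    nevertheless computed as actual correlations on the given sample.
    """
    Z = pca.standardize(matrix)
    scores = pc_scores(pca, matrix)
    n = Z.shape[0]
    zc = Z - Z.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    denom = np.outer(zc.std(axis=0, ddof=1), sc.std(axis=0, ddof=1)) * (n - 1)
    table = (zc.T @ sc) / denom
    cols = [f"PC {j + 1}" for j in range(pca.k)]
    out = pd.DataFrame(table, index=pca.variables, columns=cols)
    out.loc["Eigenvalues"] = pca.eigenvalues[: pca.k]
    out.loc["Explained Variance"] = pca.explained_variance_pct[: pca.k]
    return out
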