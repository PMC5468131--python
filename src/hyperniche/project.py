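"""Geographic projection of hypervolumes and presence-background evaluation.

A hypervolume defined in retained PC space is projected back into
geographic space by scoring every raster cell's environment and testing
membership: the result is a binary suitability map (1 = conditions
inside the niche volume, 0 = outside).  Projections can be made
*crosswise* - a model trained on one region's records scored over
another region - to locate climatically matching areas.

Because the prediction is binary, the ROC reduces to a single operating
point and the tie-corrected rank AUC equals (sensitivity +
specificity) / 2 exactly; that identity is the contract the evaluator
is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import cohen_kappa_score

from .envspace import PCATransform, pc_scores
from .errors import ConfigurationError
from .hypervolume import Hypervolume, contains
from .occurrences import OccurrenceSet
from .raster import EnvRasterStack, write_ascii_grid

__all__ = ["SuitabilityMap", "EvalResult", "project", "crosswise_project",
           "evaluate"]


@dataclass
class SuitabilityMap:
    """Binary suitability grid aligned to a stack (-1 = nodata)."""

    values: np.ndarray          # int8 grid: 1 inside, 0 outside, -1 nodata
    provenance: dict = field(default_factory=dict)

    def value_at(self, stack: EnvRasterStack, lon, lat):
        """Predicted class at point locations; -1 for nodata/off-grid."""
        rows, cols = stack.cell_index(np.atleast_1d(lon), np.atleast_1d(lat))
        out = np.full(rows.shape, -1, dtype=int)
        ok = rows >= 0
        out[ok] = self.values[rows[ok], cols[ok]]
        return out

    def write(self, path, stack: EnvRasterStack):
        grid = np.where(self.values < 0, np.nan, self.values.astype(float))
        write_ascii_grid(path, grid, stack.west, stack.south, stack.cellsize)


def project(hv: Hypervolume, pca: PCATransform, stack: EnvRasterStack,
            extent_mask=None, provenance=None) -> SuitabilityMap:
    """Score every valid cell of ``extent_mask`` by hypervolume membership."""
    if list(stack.names) != list(pca.variables):
        raise ConfigurationError(
            f"stack layers {list(stack.names)} do not match PCA variables "
            f"{list(pca.variables)}")
    df, rows, cols = stack.cell_matrix(extent_mask)
    grid = np.full((stack.nrows, stack.ncols), -1, dtype=np.int8)
    if len(df):
        inside = contains(hv, pc_scores(pca, df))
        grid[rows, cols] = inside.astype(np.int8)
    return SuitabilityMap(values=grid, provenance=dict(provenance or {}))


def crosswise_project(hvs: dict, pca: PCATransform, stack: EnvRasterStack,
                      region_masks: dict) -> dict:
    """All train x target region combinations, train = target included.

    Returns {(train, target): SuitabilityMap}.  Requires at least two
    regions to be meaningful, but will happily project a single one.
    """
    out = {}
    for train, hv in hvs.items():
        for target, mask in region_masks.items():
            out[(train, target)] = project(
                hv, pca, stack, extent_mask=mask,
                provenance={"train": train, "target": target,
                            "method": hv.method})
    return out


@dataclass
class EvalResult:
    """Presence-background skill of a binary suitability map."""

    auc: float
    cor: float
    kappa: float
    tp: int
    fp: int
    fn: int
    tn: int
    n_presence: int
    n_background: int
    seed: int = None
    n_dropped: int = 0

    @property
    def sensitivity(self):
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self):
        return self.tn / (self.tn + self.fp)


def _rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with tie correction (midranks)."""
    ranks = rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(smap: SuitabilityMap, stack: EnvRasterStack,
             presences: OccurrenceSet, background: OccurrenceSet,
             seed: int = None) -> EvalResult:
    """Score a binary map against presences and background points.

    Points on nodata cells or outside the grid are dropped (counted in
    ``n_dropped``), never silently rescored.  AUC uses the tie-corrected
    rank formulation; COR is the Pearson (point-biserial) correlation
    between binary prediction and label (0 if the prediction is
    constant); kappa comes from the 2x2 confusion table.
    """
    if len(presences) == 0 or len(background) == 0:
        raise ConfigurationError("presence and background sets must be non-empty")
    preds, labels = [], []
    n_dropped = 0
    for occ, label in ((presences, 1), (background, 0)):
        lon, lat = occ.lonlat()
        p = smap.value_at(stack, lon, lat)
        ok = p >= 0
        n_dropped += int((~ok).sum())
        preds.append(p[ok])
        labels.append(np.full(ok.sum(), label))
    pred = np.concatenate(preds)
    label = np.concatenate(labels)
    if label.min() == label.max():
        raise ConfigurationError("need both presence and background after drops")
    tp = int(((pred == 1) & (label == 1)).sum())
    fp = int(((pred == 1) & (label == 0)).sum())
    fn = int(((pred == 0) & (label == 1)).sum())
    tn = int(((pred == 0) & (label == 0)).sum())
    auc = _rank_auc(pred.astype(float), label)
    cor = 0.0 if pred.min() == pred.max() else float(np.corrcoef(pred, label)[0, 1])
    kappa = float(cohen_kappa_score(label, pred))
    return EvalResult(auc=auc, cor=cor, kappa=kappa, tp=tp, fp=fp, fn=fn,
                      tn=tn, n_presence=int((label == 1).sum()),
                      n_background=int((label == 0).sum()),
                      seed=seed, n_dropped=n_dropped)
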