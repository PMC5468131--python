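"""n-dimensional hypervolumes from point clouds in ordination space.

Two delineations of a niche support are provided:

``bdw``
    The union of axis-aligned hyperboxes (Chebyshev balls) of fixed
    half-width *bandwidth* around each source point: every condition
    within a multidimensional buffer of `bandwidth` PC units of some
    record is deemed suitable.  Volume is estimated by multiplicity-
    weighted Monte Carlo over the boxes and reported with a standard
    error.
``mcp``
    The minimum convex polytope (convex hull) of the source points.
    Volume is exact, by simplicial decomposition of a triangulation.

Every hypervolume carries a cloud of points *exactly* uniformly
distributed over its support (rejection by inverse multiplicity for
``bdw``; volume-weighted barycentric simplex sampling for ``mcp``),
which downstream overlap statistics rely on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .errors import ConfigurationError, DegenerateGeometryError

__all__ = ["Hypervolume", "build_bdw", "build_mcp", "contains",
           "save_hypervolume", "load_hypervolume"]


@dataclass
class Hypervolume:
    """A niche support with volume and a uniform random point cloud.

    ``support`` holds what is needed to test membership and to rebuild
    the object: source points and bandwidth (bdw) or hull vertices and
    facet half-space coefficients (mcp).  ``mc_meta`` records sample
    counts, the seed, the volume standard error (0 for the exact mcp
    volume) and any warnings raised during construction.
    """

    method: str
    dim: int
    volume: float
    uniform_points: np.ndarray
    support: dict
    mc_meta: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        return self.mc_meta.get("volume_se", 0.0)

    def contains(self, points, tol=1e-9):
        return contains(self, points, tol)

    @property
    def centroid(self) -> np.ndarray:
        return self.uniform_points.mean(axis=0)


def _as_scores(scores) -> np.ndarray:
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ConfigurationError("scores must be a non-empty (n, d) matrix")
    return X


def build_bdw(scores, bandwidth: float = 0.5, n_mc: int = None,
              target_points: int = 10_000, seed: int = None) -> Hypervolume:
    """Fixed-bandwidth hyperbox-union hypervolume.

    The support is U_i {z : max_axis |z - x_i| <= bandwidth}.  Monte
    Carlo draws a source box uniformly and a point uniformly inside it;
    a point covered by m boxes is counted with weight 1/m, giving

        volume = n_boxes * (2 bandwidth)^d * mean(1/m)

    which is unbiased for the union volume.  The same draws, accepted
    with probability 1/m, are exactly uniform over the union and seed
    the ``uniform_points`` cloud (extra batches are drawn if needed to
    reach ``target_points``; the volume estimate uses only the first
    ``n_mc`` draws).

    Default ``n_mc`` is max(1e5, 1000 * n_boxes); an ``n_mc`` below
    100 * n_boxes is accepted but flagged in ``mc_meta['warnings']``.
    """
    X = _as_scores(scores)
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be > 0")
    n_boxes, d = X.shape
    if n_mc is None:
        n_mc = max(100_000, 1000 * n_boxes)
    warns = []
    if n_mc < 100 * n_boxes:
        warns.append(f"n_mc={n_mc} < 100 * n_boxes={100 * n_boxes}; "
                     "volume SE may be large")
    tree = cKDTree(X)
    rng = np.random.default_rng(seed)
    box_vol = (2.0 * bandwidth) ** d

    def batch(size):
        idx = rng.integers(0, n_boxes, size)
        pts = X[idx] + rng.uniform(-bandwidth, bandwidth, (size, d))
        m = tree.query_ball_point(pts, bandwidth, p=np.inf,
                                  return_length=True)
        m = np.maximum(np.asarray(m), 1)  # own box always covers (fp guard)
        return pts, 1.0 / m

    pts, w = batch(n_mc)
    volume = n_boxes * box_vol * w.mean()
    se = n_boxes * box_vol * w.std(ddof=1) / np.sqrt(n_mc) if n_mc > 1 else np.inf
    keep = rng.uniform(size=n_mc) < w
    cloud = [pts[keep]]
    n_cloud = int(keep.sum())
    extra_draws = 0
    while n_cloud < target_points and extra_draws < 100 * n_mc:
        pts2, w2 = batch(n_mc)
        keep2 = rng.uniform(size=n_mc) < w2
        cloud.append(pts2[keep2])
        n_cloud += int(keep2.sum())
        extra_draws += n_mc
    cloud = np.concatenate(cloud)[:target_points]
    return Hypervolume(
        method="bdw", dim=d, volume=float(volume), uniform_points=cloud,
        support={"source_points": X, "bandwidth": float(bandwidth)},
        mc_meta={"n_mc": int(n_mc), "seed": seed, "volume_se": float(se),
                 "target_points": int(target_points),
                 "acceptance_rate": float(w.mean()), "warnings": warns},
    )


def build_mcp(scores, target_points: int = 10_000,
              seed: int = None) -> Hypervolume:
    """Minimum-convex-polytope hypervolume.

    The volume is exact: the hull interior is triangulated (Delaunay)
    and simplex volumes |det| / d! are summed.  Uniform points are drawn
    by picking a simplex with probability proportional to its volume
    and a point by flat-Dirichlet barycentric coordinates, which is
    exactly uniform over the hull.  Rank-deficient clouds raise
    :class:`DegenerateGeometryError` rather than silently collapsing.
    """
    X = _as_scores(scores)
    n, d = X.shape
    rank = np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-10) if n > 1 else 0
    if n < d + 1 or rank < d:
        raise DegenerateGeometryError(rank, d)
    hull = ConvexHull(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # qhull chatter on cospherical inputs
        tri = Delaunay(X)
    verts = tri.points[tri.simplices]  # (nsimplex, d+1, d)
    mats = verts[:, 1:, :] - verts[:, :1, :]
    simplex_vols = np.abs(np.linalg.det(mats)) / np.prod(np.arange(1, d + 1))
    volume = float(simplex_vols.sum())
    rng = np.random.default_rng(seed)
    probs = simplex_vols / simplex_vols.sum()
    pick = rng.choice(simplex_vols.size, size=target_points, p=probs)
    bary = rng.dirichlet(np.ones(d + 1), size=target_points)
    cloud = np.einsum("ij,ijk->ik", bary, verts[pick])
    scale = 1.0 + np.max(np.abs(X[hull.vertices]))
    return Hypervolume(
        method="mcp", dim=d, volume=volume, uniform_points=cloud,
        support={"vertices": X[hull.vertices], "equations": hull.equations,
                 "scale": float(scale)},
        mc_meta={"seed": seed, "volume_se": 0.0,
                 "target_points": int(target_points),
                 "qhull_volume": float(hull.volume), "warnings": []},
    )


def contains(hv: Hypervolume, points, tol: float = 1e-9) -> np.ndarray:
    """Boolean membership of ``points`` (rows) in the support.

    bdw: Chebyshev distance to the nearest source point <= bandwidth + tol.
    mcp: all facet half-space constraints satisfied within tol * scale.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[1] != hv.dim:
        raise ConfigurationError(
            f"points have dimension {P.shape[1]}, hypervolume {hv.dim}")
    if hv.method == "bdw":
        tree = cKDTree(hv.support["source_points"])
        dist, _ = tree.query(P, k=1, p=np.inf)
        return dist <= hv.support["bandwidth"] + tol
    eq = hv.support["equations"]
    slack = P @ eq[:, :-1].T + eq[:, -1]
    return (slack <= tol * hv.support["scale"]).all(axis=1)


# --------------------------------------------------------------------- #
# serialization: JSON header + CSV point cloud                          #
# --------------------------------------------------------------------- #
def save_hypervolume(hv: Hypervolume, basepath):
    """Write ``<basepath>.json`` (header) and ``<basepath>_points.csv``.

    Floats are written with 17 significant digits so the round trip is
    exact; the header embeds the support so the object can be rebuilt
    without the original scores.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "method": hv.method, "dim": hv.dim, "volume": hv.volume,
        "support": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in hv.support.items()},
        "mc_meta": hv.mc_meta,
    }
    with open(basepath.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=2, sort_keys=True)
    np.savetxt(basepath.parent / f"{basepath.name}_points.csv",
               hv.uniform_points, delimiter=",", fmt="%.17g",
               header=",".join(f"PC{j + 1}" for j in range(hv.dim)),
               comments="")


def load_hypervolume(basepath) -> Hypervolume:
    basepath = Path(basepath)
    with open(basepath.with_suffix(".json")) as fh:
        header = json.load(fh)
    support = {k: (np.asarray(v) if isinstance(v, list) else v)
               for k, v in header["support"].items()}
    pts = np.loadtxt(basepath.parent / f"{basepath.name}_points.csv",
                     delimiter=",", skiprows=1, ndmin=2)
    return Hypervolume(method=header["method"], dim=header["dim"],
                       volume=header["volume"], uniform_points=pts,
                       support=support, mc_meta=header["mc_meta"])
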