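"""Virtual-species worlds with analytically known niche geometry.

A synthetic world is a small lon/lat climate raster stack plus one
occurrence set per group, generated so that every downstream statistic
has an exact, independently computable ground truth:

* Each climate layer is a deterministic smooth field (linear gradient +
  sinusoid) plus seeded Gaussian noise.  The default world builds six
  layers as three highly correlated pairs, each pair sharing one latent
  field, so a correlation-matrix PCA retains exactly three axes.
* The "true" niche of a group is an axis-aligned box in *standardized
  environment space* (per-layer z-scores over all valid cells).  Box
  volumes and box-box overlaps have closed forms; the image of a box
  under the fitted standardize->rotate->truncate PCA map is a zonotope
  whose volume and pairwise intersections are computed exactly from
  convex-hull geometry.
* Occurrences are cells drawn uniformly, without replacement, from the
  cells of a group's geographic region whose environment lies inside
  its truth box.

Invasive groups are derived from the native truth by known translation
and rescaling, so recovered overlap statistics can be checked against
closed-form targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .envspace import PCATransform, pc_scores
from .errors import ConfigurationError, InfeasibleSamplingError
from .occurrences import OccurrenceSet
from .raster import EnvRasterStack

__all__ = [
    "LayerRecipe",
    "WorldConfig",
    "NicheTruth",
    "SyntheticWorld",
    "generate_env_stack",
    "make_region_masks",
    "sample_occurrences",
    "shifted_truth",
    "analytic_overlap",
    "pc_image_vertices",
    "pc_image_volume",
    "pc_image_intersection_volume",
    "pc_image_soerensen",
    "default_world",
    "evaluation_world",
]


# --------------------------------------------------------------------- #
# configuration                                                         #
# --------------------------------------------------------------------- #
@dataclass
class LayerRecipe:
    """One climate layer = gradient + sinusoid + noise.

    ``gradient_angle_deg`` is measured from east (0 = west->east
    increase, 90 = south->north); the gradient is linear in normalized
    grid coordinates u, v in [0, 1].  ``sin_freq`` counts full sinusoid
    periods across the (u, v) domain.
    """

    name: str
    gradient_angle_deg: float = 0.0
    gradient_amplitude: float = 0.0
    sin_freq: tuple = (0.0, 0.0)
    sin_amplitude: float = 0.0
    sin_phase: float = 0.0
    noise_sd: float = 0.0
    shared_field: str = None       # name of a shared seeded random field
    shared_amplitude: float = 0.0


@dataclass
class WorldConfig:
    """Grid geometry, layer recipes and the master seed of a world."""

    grid_nrows: int = 100
    grid_ncols: int = 100
    lon_min: float = 10.0
    lon_max: float = 35.0
    lat_min: float = -40.0
    lat_max: float = -15.0
    layers: list = field(default_factory=list)
    master_seed: int = 20170815
    region_split_lon: float = None  # default: domain midpoint

    def __post_init__(self):
        if self.grid_nrows < 1 or self.grid_ncols < 1:
            raise ConfigurationError("grid must have positive dimensions")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ConfigurationError("lon/lat extents define an empty box")
        if self.region_split_lon is None:
            self.region_split_lon = 0.5 * (self.lon_min + self.lon_max)

    @property
    def n_env(self):
        return len(self.layers)


def _default_layers(noise_sd=0.03):
    """Six layers in three correlated pairs (one latent field per pair).

    Each pair shares one latent field of SD ~1; within-pair correlation
    is then ~1/(1+noise_sd^2) ~ 0.99, so the correlation PCA retains
    exactly one axis per pair (eigenvalues ~{2, 2, 2, ~0}).  Pair 1's
    latent is a latitudinal gradient (uniform marginal); pairs 2 and 3
    use seeded shared random fields with uniform marginals plus a small
    shared sinusoid for spatial texture.  Deterministic functions of
    the two map coordinates alone would confine the climate cloud to a
    2-D sheet in the 3-D retained space, so at least two latents must
    carry randomness for the cloud to fill volumes; uniform marginals
    keep truth-box corners populated.  All three latents span their
    full range within both longitude-half regions.
    """
    grad = dict(gradient_angle_deg=90.0, gradient_amplitude=3.464)  # SD(v)=0.289
    wet = dict(shared_field="wetness", shared_amplitude=1.0,
               sin_freq=(2.0, 0.0), sin_amplitude=0.2)
    seas = dict(shared_field="seasonality", shared_amplitude=1.0,
                sin_freq=(3.0, 2.0), sin_amplitude=0.2)
    return [
        LayerRecipe("annual_mean_temp", noise_sd=noise_sd, **grad),
        LayerRecipe("max_temp_warmest_month", noise_sd=noise_sd, **grad),
        LayerRecipe("annual_precip", noise_sd=noise_sd, **wet),
        LayerRecipe("precip_wettest_month", noise_sd=noise_sd, **wet),
        LayerRecipe("temp_seasonality", noise_sd=noise_sd, **seas),
        LayerRecipe("precip_seasonality", noise_sd=noise_sd, **seas),
    ]


# --------------------------------------------------------------------- #
# truth geometry                                                        #
# --------------------------------------------------------------------- #
@dataclass
class NicheTruth:
    """Axis-aligned box niche in standardized environment space."""

    center: np.ndarray
    half_widths: np.ndarray
    region_mask_name: str = ""

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.half_widths = np.asarray(self.half_widths, dtype=float)
        if self.center.shape != self.half_widths.shape:
            raise ConfigurationError("center/half_widths dimension mismatch")
        if (self.half_widths <= 0).any():
            raise ConfigurationError("half_widths must all be > 0")

    @property
    def dim(self):
        return self.center.size

    @property
    def volume(self):
        """Analytic box volume in z-units: prod(2 * half_width)."""
        return float(np.prod(2.0 * self.half_widths))

    def contains_z(self, z) -> np.ndarray:
        """Membership of standardized environment vectors (rows)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return (np.abs(z - self.center) <= self.half_widths).all(axis=1)

    def corners_z(self) -> np.ndarray:
        """The 2^d corners of the box, in z-space."""
        d = self.dim
        signs = np.array(
            [[1 if (i >> j) & 1 else -1 for j in range(d)] for i in range(2 ** d)],
            dtype=float,
        )
        return self.center + signs * self.half_widths


def shifted_truth(base: NicheTruth, delta, scale) -> NicheTruth:
    """Translate the box center by ``delta`` and rescale half-widths."""
    delta = np.broadcast_to(np.asarray(delta, dtype=float), base.center.shape)
    scale = np.broadcast_to(np.asarray(scale, dtype=float), base.center.shape)
    if (scale <= 0).any():
        raise ConfigurationError("scale must be > 0 elementwise")
    return NicheTruth(center=base.center + delta,
                      half_widths=scale * base.half_widths,
                      region_mask_name=base.region_mask_name)


def analytic_overlap(a: NicheTruth, b: NicheTruth):
    """Exact (intersection_volume, Soerensen) for two truth boxes.

    Intersection is the product of per-axis interval overlap lengths;
    the Soerensen similarity is 2|A∩B| / (|A| + |B|).
    """
    if a.dim != b.dim:
        raise ConfigurationError("truth boxes differ in dimension")
    lo = np.maximum(a.center - a.half_widths, b.center - b.half_widths)
    hi = np.minimum(a.center + a.half_widths, b.center + b.half_widths)
    lengths = np.clip(hi - lo, 0.0, None)
    inter = float(np.prod(lengths))
    soer = 2.0 * inter / (a.volume + b.volume)
    return inter, soer


# --------------------------------------------------------------------- #
# raster generation                                                     #
# --------------------------------------------------------------------- #
def generate_env_stack(config: WorldConfig) -> EnvRasterStack:
    """Build the climate stack of a world.

    Each layer is evaluated on normalized cell-center coordinates
    u, v in (0, 1) (u west->east, v south->north):

        layer = A_g * (cos(a) u + sin(a) v)
              + A_s * sin(2 pi (fx u + fy v) + phase)
              + noise_sd * N(0, 1)

    Noise uses a per-layer child seed of ``master_seed`` so identical
    configs reproduce bit-identical stacks.
    """
    if config.n_env < 2:
        raise ConfigurationError("need at least 2 environmental layers")
    nr, nc = config.grid_nrows, config.grid_ncols
    u = (np.arange(nc) + 0.5) / nc
    v_north_first = ((nr - np.arange(nr)) - 0.5) / nr  # row 0 = north
    U, V = np.meshgrid(u, v_north_first)
    # shared random fields (uniform marginal, SD 1), one child seed each
    shared_names = sorted({rec.shared_field for rec in config.layers
                           if rec.shared_field})
    shared = {}
    for si, name in enumerate(shared_names):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, 2, si]))
        shared[name] = rng.uniform(-np.sqrt(3), np.sqrt(3), (nr, nc))
    layers = []
    for i, rec in enumerate(config.layers):
        a = np.deg2rad(rec.gradient_angle_deg)
        fld = rec.gradient_amplitude * (np.cos(a) * U + np.sin(a) * V)
        fx, fy = rec.sin_freq
        fld = fld + rec.sin_amplitude * np.sin(
            2 * np.pi * (fx * U + fy * V) + rec.sin_phase
        )
        if rec.shared_field:
            fld = fld + rec.shared_amplitude * shared[rec.shared_field]
        if rec.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, 0, i])
            )
            fld = fld + rec.noise_sd * rng.standard_normal((nr, nc))
        layers.append(fld)
    cellsize_lon = (config.lon_max - config.lon_min) / nc
    cellsize_lat = (config.lat_max - config.lat_min) / nr
    if not np.isclose(cellsize_lon, cellsize_lat):
        raise ConfigurationError("extents/grid must give square cells")
    return EnvRasterStack(
        names=[rec.name for rec in config.layers],
        values=np.stack(layers),
        west=config.lon_min,
        north=config.lat_max,
        cellsize=cellsize_lon,
    )


def make_region_masks(stack: EnvRasterStack, regions: dict, split_lon: float):
    """Boolean cell masks for named regions.

    ``regions`` maps name -> one of {"west", "east", "all"} relative to
    ``split_lon``.  West/east masks are disjoint by construction.
    """
    lon_grid = np.broadcast_to(stack.lons, (stack.nrows, stack.ncols))
    out = {}
    for name, kind in regions.items():
        if kind == "west":
            m = lon_grid < split_lon
        elif kind == "east":
            m = lon_grid >= split_lon
        elif kind == "all":
            m = np.ones_like(lon_grid, dtype=bool)
        else:
            raise ConfigurationError(f"unknown region kind '{kind}'")
        out[name] = m & ~stack.nodata_mask
    return out


def sample_occurrences(stack: EnvRasterStack, truth: NicheTruth, region_mask,
                       n: int, seed: int, group: str = None) -> OccurrenceSet:
    """Sample ``n`` distinct qualifying cells, uniformly without replacement.

    A cell qualifies if it lies in ``region_mask`` and its standardized
    environment vector is inside the truth box.  Raises
    :class:`InfeasibleSamplingError` (naming the available count) if
    fewer than ``n`` cells qualify.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    z, rows, cols = stack.cell_z(region_mask)
    inside = truth.contains_z(z.to_numpy())
    qual_rows, qual_cols = rows[inside], cols[inside]
    if qual_rows.size < n:
        raise InfeasibleSamplingError(n, int(qual_rows.size), "qualifying cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(qual_rows.size, size=n, replace=False)
    lon, lat = stack.cell_centers(qual_rows[pick], qual_cols[pick])
    group = group or truth.region_mask_name or "group"
    df = pd.DataFrame({
        "id": [f"{group}_{i + 1:04d}" for i in range(n)],
        "lon": lon, "lat": lat, "group": group,
    })
    return OccurrenceSet(df)


# --------------------------------------------------------------------- #
# PC-image (zonotope) oracles                                           #
# --------------------------------------------------------------------- #
def pc_image_vertices(truth: NicheTruth, pca: PCATransform,
                      stack: EnvRasterStack, dilate: float = 0.0) -> np.ndarray:
    """Images of the truth-box corners in retained PC space.

    The truth box lives in stack-wide z-space; the PCA may be fitted on
    a different sample (different means/SDs), so corners are first
    mapped back to raw environment units and then scored.  The map is
    affine, hence the image of the box is the convex hull of these
    2^d corner images (a zonotope when the map is a projection).

    ``dilate`` > 0 returns vertices of the Minkowski sum of the image
    with a Chebyshev ball (hypercube) of that half-width - the analytic
    counterpart of a fixed-bandwidth kernel support built on records
    that fill the truth box.
    """
    means, sds = stack.layer_stats()
    raw = means + sds * truth.corners_z()
    pts = pc_scores(pca, raw)
    if dilate > 0:
        k = pts.shape[1]
        signs = np.array(
            [[dilate if (i >> j) & 1 else -dilate for j in range(k)]
             for i in range(2 ** k)])
        pts = (pts[:, None, :] + signs[None, :, :]).reshape(-1, k)
    return pts


def pc_image_volume(truth, pca, stack, dilate: float = 0.0) -> float:
    """Exact volume of the (optionally dilated) truth-box image."""
    pts = pc_image_vertices(truth, pca, stack, dilate)
    if pts.shape[1] == 1:
        return float(pts.max() - pts.min())
    return float(ConvexHull(pts).volume)


def _interior_point(halfspaces):
    """Chebyshev center of an H-polytope; None if (near-)empty."""
    A, b = halfspaces[:, :-1], -halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    d = A.shape[1]
    # maximize r s.t. A x + r||a_i|| <= b
    res = linprog(c=np.r_[np.zeros(d), -1.0],
                  A_ub=np.hstack([A, norms]), b_ub=b,
                  bounds=[(None, None)] * d + [(0, None)], method="highs")
    if not res.success or res.x[-1] <= 1e-12:
        return None
    return res.x[:-1]


def pc_image_intersection_volume(truth_a, truth_b, pca, stack,
                                 dilate: float = 0.0) -> float:
    """Exact intersection volume of two truth-box images in PC space.

    Both images are convex polytopes; their intersection volume is
    computed by stacking the two half-space systems, locating a strictly
    interior point by the Chebyshev-center LP, and taking the hull of
    the half-space intersection's vertices.  Returns 0.0 when the
    intersection is empty or lower-dimensional.
    """
    hulls = []
    for t in (truth_a, truth_b):
        pts = pc_image_vertices(t, pca, stack, dilate)
        hulls.append(ConvexHull(pts))
    halfspaces = np.vstack([h.equations for h in hulls])
    centre = _interior_point(halfspaces)
    if centre is None:
        return 0.0
    hs = HalfspaceIntersection(halfspaces, centre)
    return float(ConvexHull(hs.intersections).volume)


def pc_image_soerensen(truth_a, truth_b, pca, stack,
                       dilate: float = 0.0) -> float:
    """Exact Soerensen similarity of the two (dilated) truth-box images."""
    inter = pc_image_intersection_volume(truth_a, truth_b, pca, stack, dilate)
    va = pc_image_volume(truth_a, pca, stack, dilate)
    vb = pc_image_volume(truth_b, pca, stack, dilate)
    return 2.0 * inter / (va + vb)


# --------------------------------------------------------------------- #
# whole worlds                                                          #
# --------------------------------------------------------------------- #
@dataclass
class SyntheticWorld:
    """A generated stack + truths + occurrences, with full provenance."""

    config: WorldConfig
    stack: EnvRasterStack
    regions: dict
    truths: dict
    occurrences: dict
    provenance: dict = field(default_factory=dict)

    def region_masks(self):
        return make_region_masks(self.stack, self.regions,
                                 self.config.region_split_lon)

    def all_occurrences(self) -> OccurrenceSet:
        return OccurrenceSet.concat(list(self.occurrences.values()))

    def write(self, directory):
        """Write layers (.asc), occurrences (CSV) and a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = self.stack.write(directory)
        self.all_occurrences().write_csv(directory / "occurrences.csv")
        sidecar = {
            "config": {
                **{k: v for k, v in asdict(self.config).items() if k != "layers"},
                "layers": [asdict(r) for r in self.config.layers],
            },
            "regions": self.regions,
            "truths": {
                g: {"center": t.center.tolist(),
                    "half_widths": t.half_widths.tolist(),
                    "region": t.region_mask_name}
                for g, t in self.truths.items()
            },
            "provenance": self.provenance,
        }
        with open(directory / "world.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
        return paths


def build_world(config: WorldConfig, regions: dict, truths: dict,
                n_records: dict) -> SyntheticWorld:
    """Generate stack + occurrences for configured groups.

    Occurrence seeds are children of the master seed (stage offset 1,
    then group index in sorted order), recorded in provenance.
    """
    stack = generate_env_stack(config)
    masks = make_region_masks(stack, regions, config.region_split_lon)
    occurrences, seeds = {}, {}
    for gi, group in enumerate(sorted(truths)):
        truth = truths[group]
        seed = np.random.SeedSequence(
            [config.master_seed, 1, gi]
        ).generate_state(1)[0] % (2 ** 31)
        seeds[group] = int(seed)
        occurrences[group] = sample_occurrences(
            stack, truth, masks[truth.region_mask_name],
            n_records[group], int(seed), group=group)
    return SyntheticWorld(
        config=config, stack=stack, regions=regions, truths=truths,
        occurrences=occurrences,
        provenance={"master_seed": config.master_seed, "occurrence_seeds": seeds,
                    "n_records": dict(n_records)},
    )


def default_world(master_seed: int = 20170815, n_native: int = 1200,
                  n_invaded: int = 360) -> SyntheticWorld:
    """The default two-region invasion world.

    100x100 grid, six layers in three correlated pairs (k = 3 retained
    axes).  The native niche is a centered box of half-width 1.2 z-units
    occupying the western half; the invaded niche is the native truth
    rescaled by 0.65 and shifted by (0.2, 0.2, 0.15, 0.15, 0.1, 0.1) -
    a strict subset of the native box, mirroring an introduced
    population that occupies part of the source population's climate
    envelope.  Sample sizes are near-balanced so the two groups carry
    comparable convex-hull coverage, which overlap estimates depend on.
    """
    config = WorldConfig(layers=_default_layers(), master_seed=master_seed)
    native = NicheTruth(center=np.zeros(6), half_widths=np.full(6, 1.2),
                        region_mask_name="native")
    invaded = shifted_truth(native, delta=[0.2, 0.2, 0.15, 0.15, 0.1, 0.1],
                            scale=0.65)
    invaded.region_mask_name = "invaded"
    return build_world(
        config,
        regions={"native": "west", "invaded": "east"},
        truths={"native": native, "invaded": invaded},
        n_records={"native": n_native, "invaded": n_invaded},
    )


def evaluation_world(master_seed: int = 20170815,
                     n_records: int = 300) -> SyntheticWorld:
    """A single-group world with a rare niche, for model evaluation tests.

    The truth box (half-width 0.7 z-units, whole domain as region)
    covers only ~5% of the available climate space, so
    presence-background evaluation of a truth-matched model has high
    discrimination: a regime where AUC and kappa are both informative.
    """
    config = WorldConfig(layers=_default_layers(), master_seed=master_seed)
    truth = NicheTruth(center=np.zeros(6), half_widths=np.full(6, 0.7),
                       region_mask_name="species")
    return build_world(
        config,
        regions={"species": "all"},
        truths={"species": truth},
        n_records={"species": n_records},
    )
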