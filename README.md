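# hyperniche

Quantify and compare the realized climatic niches of populations — for
example a species' native range against its invasive ranges — as
*n*-dimensional hypervolumes in an orthogonal climate space, project the
fitted niches back onto maps (including *crosswise*, scoring one
region's geography with another region's model), and evaluate the
resulting binary suitability maps against presences and random
background points.

The package targets invasion macroecology workflows: given bioclimatic
raster layers and occurrence tables for several population groups, it
answers *how large is each group's realized niche, how much do the
niches overlap, along which axes do they differ, and where on the map
do matching climates occur?*  A built-in virtual-species simulator with
analytically known niche geometry makes every stage testable without
any data download.

## Method

1. **Orthogonal climate space.** Environmental variables are
   standardized and decomposed by a correlation-matrix PCA; components
   with eigenvalue > 1 (Kaiser criterion) are retained.  The PCA is
   fitted on the *available* climate (all cells of the analysis extent,
   by default the union of 200-km buffers around the groups' records),
   so the axes describe background climate space, not just occupied
   space.
2. **Hypervolume delineation.** Each group's records are scored on the
   retained axes and its niche support is delineated two ways:
   - `bdw` — the union of fixed-bandwidth hyperboxes (Chebyshev balls of
     half-width 0.5 PC units) around the records; volume by
     multiplicity-weighted Monte Carlo with a reported standard error;
   - `mcp` — the minimum convex polytope (convex hull) of the records;
     volume exact, by simplicial decomposition.
   Both carry a cloud of points exactly uniform over the support.
3. **Overlap statistics.** For hypervolumes A and B the intersection is
   estimated symmetrically from cross-membership of the uniform clouds,
   and similarity is the Soerensen index

       S = 2 |A ∩ B| / (|A| + |B|),     0 ≤ S ≤ 1,

   complemented by unique parts, centroid distances and per-axis
   contributions (axis spans normalized to PC 1).
4. **Projection & evaluation.** A hypervolume is projected into
   geography by testing every raster cell's scored environment for
   membership (a binary suitability map) and evaluated against
   presences and 1,000 random background points from the 200-km buffer
   with AUC (tie-corrected rank form), point-biserial correlation (COR)
   and Cohen's kappa.  For binary predictions, AUC =
   (sensitivity + specificity) / 2 exactly.

Rasters are exchanged as plain-text ESRI ASCII grids (`.asc`);
occurrences as CSV (`id,lon,lat,group`).

## Worked example

`examples/03_hypervolume_overlap.py` builds both hypervolume types for
the default synthetic invasion world, whose "invaded" niche is a known
shrunken, shifted copy of the native niche:

```
[bdw] |native| = 79.96  |invaded| = 29.31  intersection = 29.37  Soerensen = 0.538  centroid distance = 0.37 PC units
[mcp] |native| = 35.78  |invaded| = 8.70  intersection = 8.71  Soerensen = 0.392  centroid distance = 0.38 PC units
analytic truth in PC space: |native| = 39.12, |invaded| = 10.74, Soerensen = 0.431
```

Volumes are in PC-units³ (three axes are retained here).  The mcp
estimates sit a little below the analytic truth — a convex hull of
finitely many records cannot reach the support boundary — while bdw
sits above it, since the 0.5-unit kernel pads every record.  The
Soerensen index brackets the analytic 0.431 the same way.  The other
example scripts cover world generation (`01`), the PCA table (`02`),
projection and AUC/COR/kappa evaluation (`04`, printing
`AUC = 0.968  COR = 0.878  Kappa = 0.871` for a truth-matched model of
a rare niche), and the full pipeline with its report (`05`).

## Command line

```bash
hyperniche run --out runs/demo --seed 11          # synthetic world, all stages
hyperniche run --rasters layers/*.asc --occurrences occ.csv --out runs/real
hyperniche report runs/demo
```

`run` emits PCA tables, hypervolume files, comparison/centroid/
contribution matrices, crosswise suitability rasters, an evaluation
table and a manifest with every seed; reruns with the same seed are
byte-identical.

## Layout

- `src/hyperniche/` — library modules: `synthetic` (virtual worlds +
  analytic oracles), `raster`/`occurrences` (I/O), `envspace` (PCA),
  `background` (buffers), `hypervolume` (bdw/mcp), `compare` (overlap
  statistics, density profiles), `project` (maps + evaluation),
  `pipeline`/`cli` (orchestration).
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and known limitations.
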