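"""Quantify the native and invaded niches as hypervolumes and compare.

Builds both delineations (fixed-bandwidth kernel union `bdw` and the
minimum convex polytope `mcp`) from occurrence scores, then reports
volumes, the intersection, the Soerensen similarity and the centroid
distance — and checks the mcp overlap against the analytic truth of the
generating niche boxes mapped into PC space.
"""

from hyperniche import (build_bdw, build_mcp, compare_pair, default_world,
                        extract_env, fit_pca, pc_image_intersection_volume,
                        pc_image_volume, pc_scores)

world = default_world()
cells, _, _ = world.stack.cell_matrix()
pca = fit_pca(cells)

scores = {}
for group, occ in world.occurrences.items():
    matrix, _ = extract_env(world.stack, occ)
    scores[group] = pc_scores(pca, matrix)

for method, build in (("bdw", lambda s, i: build_bdw(s, bandwidth=0.5, seed=i)),
                      ("mcp", lambda s, i: build_mcp(s, seed=i))):
    hvs = {g: build(s, i) for i, (g, s) in enumerate(sorted(scores.items()))}
    cmp_ = compare_pair("native", hvs["native"], "invaded", hvs["invaded"])
    print(f"[{method}] |native| = {cmp_.volume_a:.2f}  "
          f"|invaded| = {cmp_.volume_b:.2f}  "
          f"intersection = {cmp_.intersection:.2f}  "
          f"Soerensen = {cmp_.soerensen:.3f}  "
          f"centroid distance = {cmp_.centroid_dist:.2f} PC units")

v_n = pc_image_volume(world.truths["native"], pca, world.stack)
v_i = pc_image_volume(world.truths["invaded"], pca, world.stack)
inter = pc_image_intersection_volume(world.truths["native"],
                                     world.truths["invaded"], pca,
                                     world.stack)
print(f"analytic truth in PC space: |native| = {v_n:.2f}, "
      f"|invaded| = {v_i:.2f}, Soerensen = {2 * inter / (v_n + v_i):.3f}")
print("(mcp volumes sit a little below the truth because a convex hull "
      "of finitely many records cannot reach the support boundary; the "
      "bdw volumes sit above it because the 0.5-unit kernel pads every "
      "record)")
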