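"""Fit the orthogonal climate space: correlation-matrix PCA with the
eigenvalue > 1 retention rule.

Prints a loadings table in the conventional layout: Pearson correlation
of each variable with each retained component, plus eigenvalues and
explained variance.  The default world's three layer pairs produce
exactly three eigenvalues near 2 (one per latent climate axis).
"""

from hyperniche import default_world, fit_pca, loadings

world = default_world()
cells, _, _ = world.stack.cell_matrix()
pca = fit_pca(cells)

print(f"retained components (eigenvalue > 1): k = {pca.k}")
print(loadings(pca, cells).round(3).to_string())
print("\nEach loading is the correlation between a climate variable and "
      "a component score; paired variables load together because they "
      "share a latent field.")
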