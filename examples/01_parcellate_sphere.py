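"""Divide a synthetic cortical sphere into labels with double-radius dividing.

Builds an icosphere, runs the dividing sweep, and prints the geometry of
the resulting label space: how many labels, how evenly the vertices are
shared, how far apart neighbouring label centers sit, and how many labels
a searchlight holds.
"""

import numpy as np

import sfmvpa as m

mesh = m.make_icosphere(subdivisions=4, radius=50.0)
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces")
print(f"mean nearest-vertex distance: {m.mean_nearest_vertex_distance(mesh):.3f} mm")

parc = m.double_radius_divide(mesh, r=7.5)  # R defaults to 2r
sizes = np.bincount(parc.assignment)
print(f"\ndouble-radius dividing (r={parc.r} mm, R={parc.R} mm):")
print(f"  {parc.n_labels} labels, {mesh.n_vertices / parc.n_labels:.1f} vertices/label "
      f"(sizes {sizes.min()}-{sizes.max()})")
print(f"  mean nearest-label center distance: {m.mean_nearest_label_distance(parc):.2f} mm")

# seeds are guaranteed >= R apart: the inner balls cannot overlap
seed_xyz = mesh.vertices[parc.seeds]
d = np.linalg.norm(seed_xyz[:, None] - seed_xyz[None], axis=-1)
np.fill_diagonal(d, np.inf)
print(f"  closest seed pair: {d.min():.2f} mm (>= R guarantees disjoint inner balls)")

searchlights = m.build_searchlights(parc.centers, radius=20.0)
counts = [len(s) for s in searchlights]
print(f"\nsearchlights (20 mm): {min(counts)}-{max(counts)} member labels")
print("each label's searchlight feeds one local classifier in the decoding stage")
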