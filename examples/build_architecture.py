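"""Construct the default 12-area architecture and inspect its structure.

Prints the cell counts, the realized between-area edge list, and basic
sparseness statistics of the topographic excitatory projections.
"""

import numpy as np

from hebbnet import build_architecture

conn = build_architecture(rng=0)
print(f"areas: {conn.n_areas} x ({conn.grid}x{conn.grid} excitatory "
      f"+ {conn.grid}x{conn.grid} inhibitory) = {conn.n_cells} cells")
print(f"between-area edges ({len(conn.edges)}):")
for a, b in conn.edges:
    print(f"  {a} <-> {b}")

W = conn.W_ee
in_deg = np.diff(W.indptr)
print(f"\nexcitatory synapses: {W.nnz}  (in-degree mean {in_deg.mean():.1f}, "
      f"max {in_deg.max()})")
print(f"initial weights: uniform on [{W.data.min():.4f}, {W.data.max():.4f}]")

# primaries are only indirectly connected
v1a1 = conn.W_ee[conn.area_slice('A1'), conn.area_slice('V1')].nnz
print(f"direct V1->A1 synapses: {v1a1} (primary areas connect only via hubs)")
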