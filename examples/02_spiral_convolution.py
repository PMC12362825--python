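"""Spiral neighbourhoods and spiral convolution on a mesh.

Shows the ring decomposition around a vertex, the ordered spiral sequence
a convolution consumes, and a spiral-conv layer acting on vertex features.
"""

import numpy as np

from genoface.autodiff import Tensor
from genoface.networks import SpiralConv
from genoface.simulate import template_mesh
from genoface.spiral import build_spirals, ring_structure

mesh = template_mesh(level=2)  # 162-vertex face template
v = int(mesh.metadata["landmarks"]["pronasale"])

rings = ring_structure(mesh, v, k_max=2)
print(f"vertex {v} (nose tip): 0-ring {sorted(rings[0])}, "
      f"1-ring has {len(rings[1])} vertices, 2-ring has {len(rings[2])}")

table = build_spirals(mesh, length=9)
print(f"spiral sequence at the nose tip: {[int(x) for x in table.sequences[v]]}")
# the row starts with the centre vertex, then walks the 1-ring counter-
# clockwise, then the 2-ring, giving the conv a fixed gather order.

conv = SpiralConv(3, 8, table, np.random.default_rng(0))
features = conv(Tensor(mesh.vertices[None])).data
print(f"conv output: {features.shape} (V x 8 channels), "
      f"finite: {np.all(np.isfinite(features))}")
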