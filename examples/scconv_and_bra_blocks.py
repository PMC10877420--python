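"""Push a random feature map through the SCConv block and the bi-level
routing attention layer and inspect their internal diagnostics.
"""

import numpy as np

from micropest import nn
from micropest.bra import BRAConfig, BiLevelRoutingAttention
from micropest.scconv import SCConvBlock

rng = np.random.default_rng(0)
x = nn.Tensor(rng.normal(size=(1, 32, 16, 16)))

blk = SCConvBlock(32, rng=rng)
# pretend training has already shaped the GN scales: spread the gammas so
# the gate has something to separate
blk.sru.gn.gamma.data[:] = rng.uniform(0.1, 2.0, blk.sru.gn.num_channels)
out = blk(x)
gate = blk.sru.gate()
_, state = blk.cru(blk.sru(blk.compress(x)), return_state=True)
print(f"SCConv: {x.shape} -> {out.shape}")
print(f"  informative channels: {gate.informative_mask.sum()}/{gate.informative_mask.size}"
      f" (gate threshold {gate.threshold} x mean weight)")
print(f"  CRU fusion weights beta1+beta2 deviate from 1 by "
      f"{np.abs(state.beta1 + state.beta2 - 1).max():.2e}")

bra = BiLevelRoutingAttention(32, BRAConfig(S=4, topk=4, heads=2), rng=rng)
out, st = bra(x, return_state=True)
print(f"BRA:    {x.shape} -> {out.shape}")
print(f"  each of the {st['Ir'].shape[-2]} regions routes to its top-"
      f"{st['Ir'].shape[-1]} most affine regions (of {st['Ar'].shape[-1]})")
# With topk = S^2 the routing keeps every region and the layer reduces to
# dense global attention; smaller topk restricts each query region's
# attention to its most related regions only.
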