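"""Walk through the SCF neighborhood self-attention algebra on a toy grid.

Shows the regional unfold R, the autocorrelation tensor D = R ⊙ X', the
concatenated feature G and the residual output A, with their shapes; and
demonstrates that zero-initialised projections make the module an exact
identity (so adding SCF cannot hurt a fresh model).
"""

import numpy as np

from pestdet._tensor import Tensor
from pestdet.scf_fpn import (SCFModule, autocorrelation, neighborhood_unfold)

H, W, C, U, V = 6, 6, 4, 3, 3
rng = np.random.default_rng(0)
x = Tensor(rng.standard_normal((H, W, C)).astype(np.float32))

R = neighborhood_unfold(x, U, V)
D = autocorrelation(R, x)
print(f"X:  {x.shape}   (reduced feature map)")
print(f"R:  {R.shape}  (each position's {U}x{V} neighborhood)")
print(f"D:  {D.shape}   (window self-similarity, C' = U*V*C = {U*V*C})")
print(f"G = [X; D] would have C + C' = {C + U*V*C} channels")

scf = SCFModule(in_channels=C, neck_channels=C, window=(U, V),
                rng=np.random.default_rng(1))
A = scf.fuse(x, D)
print(f"A:  {A.shape}   max |A - X| = {np.abs(A.data - x.data).max()}")
print("zero-initialised projections: the attention branch starts as a no-op.")

# one D entry, spelled out
i, j, u, v, c = 2, 3, 0, 1, 1
du, dv = u - U // 2, v - V // 2
val = D.data[i, j, (u * V + v) * C + c]
expect = x.data[i + du, j + dv, c] * x.data[i, j, c]
print(f"D[{i},{j},(u={u},v={v},c={c})] = X[{i + du},{j + dv},{c}] * "
      f"X[{i},{j},{c}]: {val:.6f} == {expect:.6f}")
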