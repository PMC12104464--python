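"""The six loss components on hand-sized tensors.

Evaluates each training objective on tiny fixtures whose expected
values can be checked by hand, then sums them into the total objective.
"""

import numpy as np

from mpdc import losses as L
from mpdc.autodiff import Tensor
from mpdc.decoupling import decouple, split_confidence
from mpdc.synthetic import tiny_tensor_fixtures

fx = tiny_tensor_fixtures()

# supervised Dice: uniform prediction of a single foreground pixel
p = Tensor(np.full((1, 2, 1, 1), 0.5, dtype=np.float32))
gt = L.one_hot(np.ones((1, 1, 1), dtype=np.int64), 2)
print(f"Dice loss, uniform prediction vs foreground pixel: {L.dice_loss(p, gt).item():.4f}"
      " (hand value 2/3: foreground term 2*0.5/1.5, background term ~1)")

# decoupling on the worked 2x2 example, then the direction-consistency loss
pos, rev = Tensor(fx["decouple_pos"]), Tensor(fx["decouple_rev"])
masks = decouple(pos.data, rev.data, gamma=0.65)
dc = L.direction_consistency_loss(*split_confidence(pos, rev, masks), masks)
print(f"direction consistency on the worked example: {dc.item():.4f}"
      " (squared pull of each branch's losing pixels toward the other's detached winners)")

# channel compression: mean of squared magnitudes over channels
f = Tensor(np.array([3.0, -4.0], dtype=np.float32).reshape(1, 2, 1, 1))
print(f"channel compression of (3, -4), p=2: {L.channel_compress(f).item():.1f} (= (9+16)/2)")

total, bundle = L.total_loss(Tensor(np.float32(0.1)), Tensor(np.float32(0.2)),
                             Tensor(np.float32(0.3)), Tensor(np.float32(0.05)),
                             Tensor(np.float32(0.02)), Tensor(np.float32(0.03)))
print(f"total objective is the plain sum of all six components: {total.item():.2f}")
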