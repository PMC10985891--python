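"""The compound loss and the evaluation metrics on a controlled pair.

Evaluates the weighted cross-entropy + Dice loss on hand-checkable
tensors, then scores a deliberately shifted mask with Dice/IoU/Hausdorff.
"""

import numpy as np

import vessel3 as v
from vessel3.losses import ClassWeights, ce_loss, dice_loss, total_loss
from vessel3.metrics import evaluate_batch

# hand-checkable loss values -------------------------------------------------
p = np.array([[[0.5, 0.9]]])                 # one channel, two pixels
g = np.array([[[1.0, 0.0]]])
w = ClassWeights(weights=np.array([2.0]), n_total=2, n_k=np.array([1]))
print(f"weighted CE for p=0.5 at the one positive pixel: {ce_loss(p, g, w):.4f}"
      f"  (= log 2 = {np.log(2):.4f})")

g = np.zeros((1, 3, 3))
g[0, 0, :3] = g[0, 1, 0] = 1
p = np.where(g > 0, 0.5, 0.0)
print(f"Dice loss for p=0.5 on all 4 positives: {dice_loss(p, g):.4f}  (= 1/3)")

v_ = total_loss(p, g, ClassWeights.uniform(1))
print(f"total = 0.5*dice + 0.5*ce = {v_.total:.4f} "
      f"(dice {v_.dice:.4f}, ce {v_.ce:.4f})")

# metrics on a shifted prediction --------------------------------------------
s = v.generate_phantom(v.PhantomSpec(), seed=2)
shifted = np.roll(s.mask, (2, 1), axis=(0, 1))   # 2 px down, 1 px right
report = evaluate_batch([shifted], [s.mask])
print("\nscoring a mask shifted by (2, 1) px against itself:")
for name, d, i, h in report.to_rows():
    print(f"  {name:>4}: Dice {d:6.2f}%  IoU {i:6.2f}%  HD {h:5.2f} px")
print("-> small vessels (SVC) lose the most overlap from the same shift,")
print("   while the Hausdorff distance stays near the shift magnitude.")
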