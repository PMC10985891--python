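"""Generate synthetic 3VV phantoms and inspect the class geometry.

Creates a small dataset of speckle-corrupted phantom images with three
vessel cross-sections (PA, Ao, SVC), writes them to disk, and prints the
per-class pixel statistics that drive the cross-entropy class weights.
"""

import numpy as np

import vessel3 as v
from vessel3.losses import compute_class_weights

spec = v.PhantomSpec()                      # 256x256, clinical-like hierarchy
samples = v.make_dataset(spec, n=20, seed=0, out_dir="scratch/phantoms")

areas = {k: np.mean([(s.mask == k).sum() for s in samples]) for k in (1, 2, 3)}
weights = compute_class_weights([s.mask for s in samples])

print("mean lumen area [px]: PA %.0f  Ao %.0f  SVC %.0f" %
      (areas[1], areas[2], areas[3]))
print("CE class weights W_k = N_total/N_k: PA %.0f  Ao %.0f  SVC %.0f" %
      tuple(weights.weights))
print("-> the SVC is far smaller than the arteries, so its sparse pixels")
print("   receive a proportionally larger cross-entropy weight.")
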