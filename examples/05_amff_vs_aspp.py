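"""Head ablation: attentional multi-scale fusion (AMFF) vs plain ASPP.

Trains both heads on identical data, splits and seeds, and reports
per-vessel Dice deltas over three seeds.  The delta's sign at desk scale
is an experimental outcome; the harness guarantees only a fair,
like-for-like comparison.
"""

import vessel3 as v
from vessel3.presets import small_phantom_spec, small_train_config

samples = v.make_dataset(small_phantom_spec(), 40, seed=13)
report = v.ablation_run(samples, small_train_config(epochs=10), seeds=(0, 1, 2))

print("per-seed Dice deltas (AMFF - ASPP), percentage points:")
for run in report.runs:
    d = run["delta_dice"]
    print(f"  seed {run['seed']}:  PA {d['PA']:+6.2f}  Ao {d['Ao']:+6.2f}  "
          f"SVC {d['SVC']:+6.2f}")
print("\nsummary over seeds:")
for name in ("PA", "Ao", "SVC"):
    s = report.summary[name]
    print(f"  {name:>4}: {s['mean']:+6.2f} ± {s['std']:.2f}")
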