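"""Predict nasal-bone dimensions from surface traits with the BPNN.

Trains the back-propagation network on 2000 synthetic subjects whose surface
measurements are linked to their (hidden) bone dimensions, then scores the
held-out fit and prints one subject's predicted versus true dimensions.
"""

import numpy as np

from nasoform.metrics import r_squared
from nasoform.morphology import (BpnnConfig, design_matrices,
                                 predict_bone_morphology, train_bpnn)
from nasoform.synthetic import PopulationParams, sample_population

records = sample_population(PopulationParams(n=2500, seed=11))
train, test = records[:2000], records[2000:]

cfg = BpnnConfig(epochs=400, seed=0)
model, hist = train_bpnn(train, cfg)
print(f"trained {model.n_params()}-parameter BPNN, "
      f"final loss {hist['loss'][-1]:.4f}")

X, Y, _, _ = design_matrices(test, cfg)
pred = model.forward((X - model.x_mean) / model.x_sd)["regression"] \
    * model.y_sd + model.y_mean
print("\nheld-out R^2 per bone dimension:")
for i, t in enumerate(cfg.regression_targets):
    print(f"  {t:4s} {r_squared(Y[:, i], pred[:, i]):.3f}")

res = predict_bone_morphology(model, test[0])
print(f"\nsubject {test[0].subject_id} ({test[0].sex}, BMI {test[0].bmi:.1f}):")
for t in cfg.regression_targets:
    print(f"  {t:4s} predicted {res.bone_dims[t]:6.2f} mm   "
          f"true {test[0].bone[t]:6.2f} mm")
print(f"  lateral {res.lateral_shape} (p={res.lateral_probs[res.lateral_shape]:.2f}), "
      f"frontal {res.frontal_type}")
print("\nHigh R^2 on N-R reflects the strong surface-to-bone link; widths")
print("with weaker surface correlates recover less variance.")
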