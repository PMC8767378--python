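"""Train the keypoint CNN on a small rendered set and detect landmarks.

Uses 96x96 renders and the reduced-width 19-layer backbone so the example
runs in about a minute on a laptop CPU.  Prints the validation landmark MAE
per epoch and the per-landmark error on one held-out image.
"""

import dataclasses

import numpy as np

from nasoform.keypoint import (NetworkConfig, predict_landmarks,
                               train_keypoint_model)
from nasoform.synthetic import (PopulationParams, RenderConfig,
                                render_subject_views, sample_population)

SIZE = 96
recs = sample_population(PopulationParams(n=60, seed=4))
data = []
for i, rec in enumerate(recs):
    rv = render_subject_views(rec, RenderConfig(image_size=(SIZE, SIZE)),
                              seed=400 + i)["lateral"]
    data.append((rv.image, rv.landmarks))

cfg = dataclasses.replace(NetworkConfig(epochs=8, batch_size=12,
                                        input_shape=(SIZE, SIZE, 3)).reduced())
model, hist = train_keypoint_model(data[:-1], cfg, seed=0)
print("validation MAE (px) per epoch:",
      [round(v, 1) for v in hist.val_mae_px])

img, truth = data[-1]
pred = predict_landmarks(model, img)
errs = {c: float(np.hypot(pred.points[c][0] - truth.points[c][0],
                          pred.points[c][1] - truth.points[c][1]))
        for c in truth.points if c in pred.points}
print(f"\nheld-out image: mean landmark error {np.mean(list(errs.values())):.1f} px")
for c in ("n", "prn", "sn"):
    print(f"  {c:4s} error {errs[c]:5.1f} px")
print("\nFalling MAE shows the network learning the facial configuration;")
print("longer training on more renders drives the error toward a few px")
print("(about 1-2 mm at this render scale).")
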