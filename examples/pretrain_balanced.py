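"""Pre-train the CNN on imbalanced cell-line crops with balanced minibatches.

Emulates the pre-training data condition — roughly 1 tumor crop for every
3.4 healthy-cell crops — and shows why per-batch class balancing matters:
with plain sampling the minority (tumor) class is under-recalled.
"""

import numpy as np

import ctcvision as cv
from ctcvision.model_train import examples_to_arrays
from ctcvision.synthgen import class_counts

RATIO = 9106 / 30785  # tumor : healthy, the emulated pre-training imbalance

crops = cv.generate_dataset(cv.SceneSpec(seed=8), n_scenes=15, imbalance_ratio=RATIO)
n_tum, n_healthy = class_counts(crops)
print(f"pool: {n_tum} tumor / {n_healthy} healthy crops "
      f"(ratio {n_tum / n_healthy:.3f}, target {RATIO:.3f})")

x, y = examples_to_arrays(crops)
for mode in ("balanced_minibatch", "all_data"):
    model = cv.build_model(seed=0)
    cfg = cv.TrainConfig(epochs=10, sampling_mode=mode, seed=0)
    trained = cv.pretrain(model, crops, cfg)
    labels, _ = cv.predict(trained, x)
    recall_tumor = labels[y == 1].mean()
    recall_healthy = (labels[y == 0] == 0).mean()
    print(f"{mode:19s} tumor recall {recall_tumor:.3f}   "
          f"healthy recall {recall_healthy:.3f}   "
          f"accuracy {cv.accuracy(labels, y):.3f}")

# Balanced minibatches counter the imbalance: each batch holds exactly
# half tumor, half healthy, resampling the scarce class with replacement.
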