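"""Few-shot transfer: fine-tune a pre-trained model on a handful of images.

Pre-trains on cell-line-like crops, then fine-tunes on 1-10 clinical-like
crops drawn from a shifted population (larger, dimmer, noisier cells) and
compares accuracy on held-out clinical crops against (a) the untouched
pre-trained model and (b) a model trained from scratch on the same few
images.
"""

from dataclasses import replace

import ctcvision as cv
from ctcvision.model_train import examples_to_arrays

scene = cv.SceneSpec(seed=0)
shift = cv.ShiftSpec(radius_scale=1.3, intensity_scale=0.7, extra_noise=10.0)

cellline = cv.generate_dataset(scene, n_scenes=15, imbalance_ratio=1.0)
clinical = cv.generate_dataset(
    replace(scene, domain="clinical", shift=shift, seed=999),
    n_scenes=10, imbalance_ratio=1.0,
)
train_pool, test = clinical[: len(clinical) // 4], clinical[len(clinical) // 4 :]
x_test, y_test = examples_to_arrays(test)
print(f"pre-train on {len(cellline)} cell-line crops; "
      f"test on {len(test)} clinical-like crops")

pretrained = cv.pretrain(
    cv.build_model(seed=1), cellline, cv.TrainConfig(epochs=15, seed=1)
)
labels, _ = cv.predict(pretrained, x_test)
print(f"pretrain-only accuracy on shifted domain: {cv.accuracy(labels, y_test):.3f}")

ft_cfg = cv.TrainConfig(epochs=50, sampling_mode="all_data", seed=1)
for n in (1, 4, 10):
    few = train_pool[:n]
    tuned = cv.fine_tune(pretrained, few, ft_cfg)
    labels, _ = cv.predict(tuned, x_test)
    acc_t = cv.accuracy(labels, y_test)
    scratch = cv.fine_tune(cv.build_model(seed=2), few, ft_cfg)
    labels, _ = cv.predict(scratch, x_test)
    acc_s = cv.accuracy(labels, y_test)
    print(f"n_train={n:2d}   transfer {acc_t:.3f}   scratch {acc_s:.3f}")

# Even one clinical image is a valid fine-tuning set, though updating on a
# single class can pull the model off balance — the repeated-sampling
# protocol (examples/learning_curve.py) is what separates such single-split
# noise from the systematic transfer benefit.
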