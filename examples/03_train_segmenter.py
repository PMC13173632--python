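"""Train the tiny ResUNet preset on synthetic phantoms (CPU, ~2 min).

A short run on 60 small phantoms: split 75/15/10, flip-augment the
training pool, minimise BCE + log-Dice with Adam, then report the
Dice overlap on the held-out test phantoms.  Longer runs (200
phantoms, 40 epochs) reach Dice ~0.97.
"""

import numpy as np

from cervitrace import (
    LossConfig,
    ModelConfig,
    SplitConfig,
    TrainConfig,
    AugmentConfig,
    augment,
    build_model,
    dice_coefficient,
    generate_phantom,
    predict_mask,
    random_phantom_spec,
    split_dataset,
    train,
)

rng = np.random.default_rng(0)
pairs = []
for _ in range(60):
    image, mask, _ = generate_phantom(random_phantom_spec(rng))
    pairs.append((image, mask))

train_pairs, val_pairs, test_pairs = split_dataset(pairs, SplitConfig(seed=1))
train_pairs = augment(train_pairs, AugmentConfig(do_affine=False, seed=2))
print(f"train/val/test: {len(train_pairs)} (after flip augmentation) / "
      f"{len(val_pairs)} / {len(test_pairs)}")

model = build_model(ModelConfig.tiny(seed=3))
model, history = train(
    model, train_pairs, val_pairs, LossConfig(),
    TrainConfig(batch_size=16, max_epochs=25, early_stopping_patience=10, seed=4),
)
print(f"epochs run: {history.stopped_epoch}, "
      f"train loss {history.train_loss[0]:.3f} -> {history.train_loss[-1]:.3f}")

dices = []
for image, mask in test_pairs:
    _, predicted = predict_mask(model, image)
    dices.append(dice_coefficient(mask, predicted))
print(f"held-out Dice: mean {np.mean(dices):.3f}, min {np.min(dices):.3f}")
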