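import os

# pin BLAS to one thread before numpy loads: these tensors are small and
# threaded GEMM is counterproductive on one core
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest
from hypothesis import settings

from cervitrace.images import UltrasoundImage
from cervitrace.objectives import LossConfig, dice_coefficient
from cervitrace.phantoms import PhantomSpec, generate_phantom, random_phantom_spec
from cervitrace.resunet import ModelConfig, build_model, predict_mask
from cervitrace.trainer import (
    AugmentConfig,
    SplitConfig,
    TrainConfig,
    augment,
    split_dataset,
    train,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_bank():
    """200 random tiny curved-canal phantoms (64x128 px, 0.35 mm/px)."""
    rng = np.random.default_rng(123)
    bank = []
    for _ in range(200):
        spec = random_phantom_spec(rng)
        img, mask, truth = generate_phantom(spec)
        bank.append((img, mask, truth))
    return bank


@pytest.fixture(scope="session")
def trained_model(phantom_bank):
    """Segmentation model trained at desk scale on the phantom bank.

    75/15/10 split, horizontal-flip augmentation of the training pool,
    batch 32 Adam for up to 40 epochs — the scaled-down counterpart of
    the full training protocol, shared across tests because training
    is the expensive step.
    """
    pairs = [(img, mask) for img, mask, _ in phantom_bank]
    tr, va, te = split_dataset(pairs, SplitConfig(seed=7))
    tr_aug = augment(tr, AugmentConfig(do_affine=False, seed=3))
    model = build_model(ModelConfig.tiny(seed=1))
    model, history = train(
        model, tr_aug, va, LossConfig(),
        TrainConfig(batch_size=32, max_epochs=40,
                    early_stopping_patience=15, seed=2),
    )
    return {"model": model, "history": history,
            "train": tr, "val": va, "test": te}


@pytest.fixture(scope="session")
def heldout_dice(trained_model):
    model = trained_model["model"]
    dices = []
    for img, mask in trained_model["test"]:
        _, pred = predict_mask(model, img)
        dices.append(dice_coefficient(mask, pred))
    return np.asarray(dices)


def semicircle_spec(pixel_spacing_mm: float) -> PhantomSpec:
    """Semicircular canal of radius 15 mm (chord 30, arc 15*pi)."""
    shape = (int(40 / pixel_spacing_mm) + 20, int(45 / pixel_spacing_mm) + 20)
    return PhantomSpec(
        "circular_arc", [(30.0, 10.0), (15.0, 25.0), (30.0, 40.0)],
        image_shape_px=shape, pixel_spacing_mm=pixel_spacing_mm,
    )


@pytest.fixture(scope="session")
def semicircle_phantom():
    """Semicircle at 0.1 mm/px with its analytic ground truth."""
    return generate_phantom(semicircle_spec(0.1))


@pytest.fixture()
def tiny_image():
    rng = np.random.default_rng(0)
    return UltrasoundImage(rng.random((64, 128), dtype=np.float32), 0.35, "tiny")
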