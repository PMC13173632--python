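"""Modified ResUNet for endocervical-canal segmentation.

The network is a U-Net whose encoder is a ResNet-style backbone:

* stem: BN -> pad -> 7x7 stride-2 CONV -> ReLU -> pad -> pooling
  (one stride-2 max-pool, optionally followed by a stride-1 padded
  max-pool so the stem contains two pooling steps without changing
  resolution);
* four stages, each one CONV block (with spatial reduction, except
  stage 1) plus a run of Identity blocks — counts [2, 3, 5, 3] by
  default;
* BN -> ReLU after the last stage;
* decoder: four Upsample Block_1 units (transposed convolution ->
  ReLU -> concatenate the matching encoder skip -> CONV -> ReLU),
  whose skip partners are, in order, stages 3, 2, 1 and the stem's
  first CONV output; then one Upsample Block_2 (transposed conv ->
  ReLU -> CONV -> sigmoid) producing a per-pixel probability map.

CONV block: BN,ReLU,CONV,BN,ReLU,pad,pool,CONV,BN,ReLU with a 1x1
shortcut CONV applied to the first ReLU output and added to the final
ReLU output.  Identity block: the same without pad/pool and with the
first ReLU output added directly.

Input rows/cols must be divisible by 32 (five spatial halvings: two in
the stem, three in stages 2-4).  Filter counts are not prescribed by
the architecture description; the default follows the ResNet
convention of ``base_channels`` doubling per stage and is fully
configurable (a tiny preset supports CPU-scale experiments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .images import CanalMask, UltrasoundImage
from .nn.autodiff import Tensor


@dataclass
class ModelConfig:
    input_shape: tuple[int, int] = (256, 512)
    base_channels: int = 64
    channel_multipliers: tuple[int, int, int, int] = (1, 2, 4, 8)
    identity_block_counts: tuple[int, int, int, int] = (2, 3, 5, 3)
    binarization_threshold: float = 0.5
    double_stem_pool: bool = True
    seed: int = 0

    def __post_init__(self):
        r, c = self.input_shape
        if r % 32 or c % 32:
            raise ValueError(
                f"input shape {self.input_shape} must be divisible by 32 "
                "(five spatial halvings across stem and stages)"
            )
        if not (0.0 < self.binarization_threshold < 1.0):
            raise ValueError("binarization_threshold must lie in (0,1)")
        if len(self.channel_multipliers) != 4 or len(self.identity_block_counts) != 4:
            raise ValueError("need exactly 4 stage multipliers and block counts")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """64x128 input, 8 base channels — a CPU-friendly preset."""
        return cls(input_shape=(64, 128), base_channels=8, seed=seed)


_STAGE_STRIDES = (1, 2, 2, 2)


class ConvBlock(nn.Module):
    """Residual block with spatial reduction via an internal padded pool."""

    def __init__(self, cin, cout, stride, *, rng):
        super().__init__()
        self.stride = stride
        self.bn1 = nn.BatchNorm2d(cin)
        self.conv1 = nn.Conv2d(cin, cout, 3, 1, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.pool = nn.MaxPool2d(3, stride, 1)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        self.shortcut = nn.Conv2d(cin, cout, 1, stride, 0, rng=rng)

    def forward(self, x):
        r1 = nn.autodiff.relu(self.bn1(x))
        h = self.conv1(r1)
        h = nn.autodiff.relu(self.bn2(h))
        h = self.pool(h)
        h = self.conv2(h)
        h = nn.autodiff.relu(self.bn3(h))
        return nn.autodiff.add(h, self.shortcut(r1))


class IdentityBlock(nn.Module):
    """Residual block preserving shape; first ReLU output added directly."""

    def __init__(self, c, *, rng):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(c)
        self.conv1 = nn.Conv2d(c, c, 3, 1, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, 3, 1, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(c)

    def forward(self, x):
        r1 = nn.autodiff.relu(self.bn1(x))
        h = self.conv1(r1)
        h = nn.autodiff.relu(self.bn2(h))
        h = self.conv2(h)
        h = nn.autodiff.relu(self.bn3(h))
        return nn.autodiff.add(h, r1)


class UpsampleBlock1(nn.Module):
    """ConvTranspose -> ReLU -> concat skip -> CONV -> ReLU."""

    def __init__(self, cin, skip_c, *, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, skip_c, 2, rng=rng)
        self.conv = nn.Conv2d(2 * skip_c, skip_c, 3, 1, 1, rng=rng)

    def forward(self, x, skip):
        h = nn.autodiff.relu(self.up(x))
        h = nn.autodiff.concat_channels(h, skip)
        return nn.autodiff.relu(self.conv(h))


class UpsampleBlock2(nn.Module):
    """ConvTranspose -> ReLU -> CONV -> sigmoid head."""

    def __init__(self, cin, mid, *, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, mid, 2, rng=rng)
        self.conv = nn.Conv2d(mid, 1, 3, 1, 1, rng=rng)

    def forward(self, x):
        h = nn.autodiff.relu(self.up(x))
        return nn.autodiff.sigmoid(self.conv(h))


class ResUNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        chans = [b * m for m in config.channel_multipliers]

        self.stem_bn = nn.BatchNorm2d(1)
        self.stem_conv = nn.Conv2d(1, b, 7, 2, 3, rng=rng)
        self.stem_pool = nn.MaxPool2d(3, 2, 1)
        self.stem_pool2 = nn.MaxPool2d(3, 1, 1) if config.double_stem_pool else None

        self.stages = []
        cin = b
        for ci, stride, n_id in zip(chans, _STAGE_STRIDES, config.identity_block_counts):
            blocks = [ConvBlock(cin, ci, stride, rng=rng)]
            blocks += [IdentityBlock(ci, rng=rng) for _ in range(n_id)]
            self.stages.append(blocks)
            cin = ci
        # register for parameter discovery
        self._stage_blocks = [blk for stage in self.stages for blk in stage]

        self.post_bn = nn.BatchNorm2d(chans[3])

        self.up1 = UpsampleBlock1(chans[3], chans[2], rng=rng)
        self.up2 = UpsampleBlock1(chans[2], chans[1], rng=rng)
        self.up3 = UpsampleBlock1(chans[1], chans[0], rng=rng)
        self.up4 = UpsampleBlock1(chans[0], b, rng=rng)
        self.head = UpsampleBlock2(b, max(b // 2, 4), rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h = self.stem_bn(x)
        skip0 = nn.autodiff.relu(self.stem_conv(h))
        h = self.stem_pool(skip0)
        if self.stem_pool2 is not None:
            h = self.stem_pool2(h)
        skips = []
        for stage in self.stages:
            for blk in stage:
                h = blk(h)
            skips.append(h)
        h = nn.autodiff.relu(self.post_bn(h))
        h = self.up1(h, skips[2])
        h = self.up2(h, skips[1])
        h = self.up3(h, skips[0])
        h = self.up4(h, skip0)
        return self.head(h)


@dataclass
class SegmentationModel:
    """Trained-parameter container: the network, its config and the
    training metadata (epochs run, final losses)."""

    net: ResUNet
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    def forward_probability(self, batch: np.ndarray) -> np.ndarray:
        """Eval-mode forward of an (N,1,H,W) batch -> (N,H,W) map in [0,1]."""
        self.net.eval()
        out = self.net(np.asarray(batch, dtype=np.float32))
        return out.data[:, 0]


def build_model(config: ModelConfig | None = None) -> SegmentationModel:
    """Construct the network with seeded He-uniform initialization.

    Identical configs (including seed) produce bit-identical parameters.
    """
    config = config or ModelConfig()
    return SegmentationModel(net=ResUNet(config), config=config, metadata={})


def predict_mask(model: SegmentationModel, image: UltrasoundImage):
    """Segment one image: returns (probability map, thresholded mask).

    Pixels with probability >= the configured threshold map to 1.
    The image must already match the model's input shape (resize with
    :func:`cervitrace.trainer.resize_to_model` first).
    """
    expected = tuple(model.config.input_shape)
    if tuple(image.shape) != expected:
        raise ValueError(
            f"image shape {tuple(image.shape)} does not match model input {expected}; "
            "resize the image first"
        )
    prob = model.forward_probability(image.pixels[None, None])[0]
    mask = (prob >= model.config.binarization_threshold).astype(np.uint8)
    return prob, CanalMask(mask, image.pixel_spacing_mm, image_id=image.image_id)


def structure_report(config: ModelConfig | None = None) -> list[dict]:
    """Ordered layer list with output shapes, for inspection and tests."""
    config = config or ModelConfig()
    r, c = config.input_shape
    b = config.base_channels
    chans = [b * m for m in config.channel_multipliers]
    rows: list[dict] = []

    def emit(name, kind, shape):
        rows.append({"name": name, "kind": kind, "output_shape": list(shape)})

    emit("stem.bn", "BN", (1, r, c))
    emit("stem.pad", "Padding", (1, r + 6, c + 6))
    r2, c2 = r // 2, c // 2
    emit("stem.conv", "CONV", (b, r2, c2))
    emit("stem.relu", "RELU", (b, r2, c2))
    emit("stem.pad2", "Padding", (b, r2 + 2, c2 + 2))
    r4, c4 = r2 // 2, c2 // 2
    emit("stem.pool", "Pooling", (b, r4, c4))
    if config.double_stem_pool:
        emit("stem.pool2", "Pooling", (b, r4, c4))
    rr, cc = r4, c4
    for si, (ci, stride, n_id) in enumerate(
        zip(chans, _STAGE_STRIDES, config.identity_block_counts), start=1
    ):
        rr, cc = rr // stride, cc // stride
        emit(f"stage{si}.conv_block", "CONV block", (ci, rr, cc))
        for k in range(n_id):
            emit(f"stage{si}.identity_block{k + 1}", "Identity block", (ci, rr, cc))
    emit("post.bn", "BN", (chans[3], rr, cc))
    emit("post.relu", "RELU", (chans[3], rr, cc))
    up_specs = [
        (chans[2], "stage3"),
        (chans[1], "stage2"),
        (chans[0], "stage1"),
        (b, "stem.conv"),
    ]
    for k, (co, skip) in enumerate(up_specs, start=1):
        rr, cc = rr * 2, cc * 2
        emit(f"decoder.upsample_block_1[{k}]", "Upsample Block_1",
             (co, rr, cc))
        rows[-1]["skip"] = skip
    rr, cc = rr * 2, cc * 2
    emit("decoder.upsample_block_2", "Upsample Block_2", (1, rr, cc))
    rows[-1]["activation"] = "Sigmoid"
    return rows


def save_model(model: SegmentationModel, path) -> None:
    """Write parameters (npz) plus a JSON sidecar of config/metadata."""
    path = Path(path)
    arrays = model.net.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrays)
    sidecar = {"config": asdict(model.config), "metadata": model.metadata}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> SegmentationModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["config"]
    for key in ("input_shape", "channel_multipliers", "identity_block_counts"):
        cfg_d[key] = tuple(cfg_d[key])
    config = ModelConfig(**cfg_d)
    model = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[k] for k in data.files]
    targets = model.net.state_arrays()
    if len(arrays) != len(targets):
        raise ValueError("checkpoint does not match model architecture")
    for tgt, src in zip(targets, arrays):
        tgt[...] = src
    model.metadata = sidecar["metadata"]
    return model
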