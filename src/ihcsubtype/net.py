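"""Dual encoder–decoder segmentation network with multi-level skip fusion.

The model is a ladder of two U-Net-style encoder–decoder pairs connected
serially. Feature blocks are residual convolution blocks (two 3x3
convolutions, each followed by ReLU then batch normalization, plus an
identity shortcut with a 1x1 projection when channel counts change).
Downsampling uses stride-2 convolutions; filters double per level
(``base_filters * 2**level``).

Each decoder block at level ``l`` fuses a concatenation of four sources:

1. a stride-2-downsampled output of the level ``l-1`` encoder block,
2. the level ``l`` encoder output,
3. a nearest-neighbour-upsampled output of the level ``l+1`` encoder block,
4. a 2x2 transposed-convolution upsampling of the level ``l+1`` decoder
   output.

Sources that do not exist at the boundary levels (no ``l-1`` encoder at the
top level 0, no ``l+1`` encoder above the bottleneck) are simply omitted
from the concatenation. The second encoder starts from the first decoder's
full-resolution output and additionally receives the first decoder's
feature map at every level by channel-wise addition, so learning paths can
route through either or both U-Net halves. Dropout is applied in decoder
blocks only; the head is a 1x1 convolution to ``n_classes`` with softmax.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .types import ClassMask, ClassSet, ValidationError


@dataclass
class NetConfig:
    depth: int = 4
    base_filters: int = 16
    n_classes: int = 3
    input_shape: tuple[int, int, int] = (240, 240, 3)
    dropout_rate: float = 0.1
    l2_coefficient: float = 1e-5

    def __post_init__(self) -> None:
        self.input_shape = tuple(self.input_shape)  # type: ignore[assignment]
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValidationError("base_filters must be >= 1")
        if self.n_classes not in (3, 4):
            raise ValidationError("n_classes must be 3 or 4")
        h, w, c = self.input_shape
        if c != 3:
            raise ValidationError("input must be RGB")
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValidationError(
                f"input spatial size {h}x{w} must be divisible by 2^depth"
            )

    @property
    def filters(self) -> list[int]:
        """Filter count per level 0..depth (bottleneck at index depth)."""
        return [self.base_filters * 2**l for l in range(self.depth + 1)]


class _ResBlock(nn.Module):
    """conv3x3 -> ReLU -> BN, twice, with an identity/projection shortcut."""

    def __init__(self, cin: int, cout: int, rng, name: str):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng=rng, name=f"{name}.c1")
        self.bn1 = nn.BatchNorm(cout, name=f"{name}.bn1")
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng, name=f"{name}.c2")
        self.bn2 = nn.BatchNorm(cout, name=f"{name}.bn2")
        self.proj = (
            nn.Conv2d(cin, cout, 1, rng=rng, name=f"{name}.proj") if cin != cout else None
        )

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.bn1(nn.relu(self.conv1(x)))
        h = self.bn2(nn.relu(self.conv2(h)))
        shortcut = self.proj(x) if self.proj is not None else x
        return nn.add(h, shortcut)


class _DownBlock(nn.Module):
    """Stride-2 convolution downsampling: conv3x3/s2 -> ReLU -> BN."""

    def __init__(self, cin: int, cout: int, rng, name: str):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, stride=2, rng=rng, name=f"{name}.c")
        self.bn = nn.BatchNorm(cout, name=f"{name}.bn")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.bn(nn.relu(self.conv(x)))


class _UpBlock(nn.Module):
    """2x2 stride-2 transposed convolution: deconv -> ReLU -> BN."""

    def __init__(self, cin: int, cout: int, rng, name: str):
        super().__init__()
        self.deconv = nn.ConvTranspose2d(cin, cout, rng=rng, name=f"{name}.d")
        self.bn = nn.BatchNorm(cout, name=f"{name}.bn")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.bn(nn.relu(self.deconv(x)))


class _Encoder(nn.Module):
    def __init__(self, cin: int, filters: list[int], rng, name: str):
        super().__init__()
        self.entry = _ResBlock(cin, filters[0], rng, f"{name}.l0")
        self.downs = [
            _DownBlock(filters[l - 1], filters[l], rng, f"{name}.down{l}")
            for l in range(1, len(filters))
        ]
        self.blocks = [
            _ResBlock(filters[l], filters[l], rng, f"{name}.l{l}")
            for l in range(1, len(filters))
        ]

    def __call__(
        self, x: nn.Tensor, lateral: list[nn.Tensor] | None = None
    ) -> list[nn.Tensor]:
        """Return features per level; ``lateral`` adds per-level features
        (the serial junction with the previous decoder)."""
        feats = []
        h = self.entry(x)
        if lateral is not None:
            h = nn.add(h, lateral[0])
        feats.append(h)
        for l, (down, block) in enumerate(zip(self.downs, self.blocks), start=1):
            h = block(down(h))
            if lateral is not None and l < len(lateral):
                h = nn.add(h, lateral[l])
            feats.append(h)
        return feats


class _Decoder(nn.Module):
    def __init__(self, filters: list[int], dropout_rate: float, rng, drop_rng, name: str):
        super().__init__()
        depth = len(filters) - 1
        self.depth = depth
        self.skip_downs = [
            _DownBlock(filters[l - 1], filters[l], rng, f"{name}.skipdown{l}")
            if l >= 1
            else None
            for l in range(depth)
        ]
        self.ups = [
            _UpBlock(filters[l + 1], filters[l], rng, f"{name}.up{l}")
            for l in range(depth)
        ]
        cat_channels = []
        for l in range(depth):
            ch = filters[l] + filters[l]  # encoder level l + deconv source
            if l >= 1:
                ch += filters[l]  # downsampled (l-1) encoder source
            ch += filters[l + 1]  # upsampled (l+1) encoder source
            cat_channels.append(ch)
        self.blocks = [
            _ResBlock(cat_channels[l], filters[l], rng, f"{name}.l{l}")
            for l in range(depth)
        ]
        self.dropouts = [nn.Dropout(dropout_rate, drop_rng) for _ in range(depth)]

    def __call__(self, enc_feats: list[nn.Tensor]) -> list[nn.Tensor]:
        """Return decoder features per level 0..depth (bottleneck passthrough)."""
        dec: list[nn.Tensor | None] = [None] * (self.depth + 1)
        dec[self.depth] = enc_feats[self.depth]
        for l in range(self.depth - 1, -1, -1):
            sources = []
            if l >= 1:
                sources.append(self.skip_downs[l](enc_feats[l - 1]))
            sources.append(enc_feats[l])
            if l + 1 <= self.depth:
                sources.append(nn.upsample_nearest2(enc_feats[l + 1]))
            sources.append(self.ups[l](dec[l + 1]))
            h = nn.concat(sources, axis=-1)
            h = self.dropouts[l](h)
            dec[l] = self.blocks[l](h)
        return dec  # type: ignore[return-value]


class _LadderNet(nn.Module):
    def __init__(self, config: NetConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator):
        super().__init__()
        f = config.filters
        self.encoder1 = _Encoder(config.input_shape[2], f, rng, "enc1")
        self.decoder1 = _Decoder(f, config.dropout_rate, rng, drop_rng, "dec1")
        self.encoder2 = _Encoder(f[0], f, rng, "enc2")
        self.decoder2 = _Decoder(f, config.dropout_rate, rng, drop_rng, "dec2")
        self.head = nn.Conv2d(f[0], config.n_classes, 1, rng=rng, name="head")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        e1 = self.encoder1(x)
        d1 = self.decoder1(e1)
        e2 = self.encoder2(d1[0], lateral=d1)
        d2 = self.decoder2(e2)
        return nn.softmax(self.head(d2[0]), axis=-1)


class SegModel:
    """A built (and possibly trained) segmentation network plus its config."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        self.network = _LadderNet(config, rng, drop_rng)

    @property
    def parameter_count(self) -> int:
        return self.network.parameter_count

    def forward(self, batch: np.ndarray, training: bool = False) -> nn.Tensor:
        """Run a float batch (N, H, W, 3) through the network."""
        h, w, c = self.config.input_shape
        if batch.ndim != 4 or batch.shape[1:] != (h, w, c):
            raise ValidationError(
                f"batch shape {batch.shape} incompatible with input {self.config.input_shape}"
            )
        self.network.train(training)
        return self.network(nn.Tensor(batch))

    def predict_probs(self, patches: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Per-pixel class probabilities for a stack of model-size patches.

        Inference mode: dropout off, batch norm on running statistics, so the
        output is deterministic for a fixed parameter set.
        """
        patches = np.asarray(patches)
        if patches.ndim == 3:
            patches = patches[None]
        x = patches.astype(np.float32)
        if x.max() > 1.5:  # uint8-range input
            x = x / 255.0
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], training=False).data)
        return np.concatenate(outs, axis=0)

    def predict_mask(self, patch: np.ndarray, class_set: ClassSet) -> ClassMask:
        probs = self.predict_probs(patch[None] if patch.ndim == 3 else patch)
        return ClassMask(np.argmax(probs[0], axis=-1).astype(np.int64), class_set)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        params = self.network.parameters()
        arrays = {f"p{i}": p.data for i, p in enumerate(params)}
        bns = [m for m in self.network.modules() if isinstance(m, nn.BatchNorm)]
        for i, bn in enumerate(bns):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        meta = dict(asdict(self.config))
        np.savez(path, __config__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__config__"]))
            meta["input_shape"] = tuple(meta["input_shape"])
            model = cls(NetConfig(**meta))
            for i, p in enumerate(model.network.parameters()):
                p.data = data[f"p{i}"].astype(np.float32)
            bns = [
                m
                for m in model.network.modules()
                if isinstance(m, nn.BatchNorm)
            ]
            for i, bn in enumerate(bns):
                bn.running_mean = data[f"rm{i}"]
                bn.running_var = data[f"rv{i}"]
        return model


def build_model(config: NetConfig, seed: int = 0) -> SegModel:
    """Build the segmentation network with He-normal initialization."""
    return SegModel(config, seed=seed)
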