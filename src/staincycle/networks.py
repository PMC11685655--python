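"""Generator and discriminator graphs, checkpointing, and Grad-CAM.

The generator is a residual-network image translator: a stride-1 3x3 entry
convolution lifting the image to 64 channels, two strided
Convolution-InstanceNorm-ReLU layers that halve the spatial size and double
the channels (64 -> 128 -> 256), a chain of residual blocks at the bottleneck,
and an upsampling path that bilinearly doubles the tensor twice, halving the
channels each time, with skip connections from the matching downsampling
level (merged by channel concatenation + 1x1 fusion convolution). A final
convolution restores 3 channels and a tanh maps to [-1, 1]. Reflection
padding keeps spatial sizes exact throughout.

The discriminator stacks five blocks of two 3x3 convolutions with leaky-ReLU
(slope 0.2) that double the channel count, each followed by stride-2 average
pooling; two fully connected layers (hidden width 512) reduce to a single
unbounded score per (sub)tile — no terminal squashing, per the least-squares
adversarial convention. The input may be subdivided into subtiles scored
independently; the image score is the mean over subtiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, InstanceNorm2d, Linear, Module, Tensor, concat, no_grad

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "ResNetGenerator", "TileDiscriminator",
           "TranslationModel", "generator_forward", "discriminator_forward",
           "gradcam_heatmap", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 3
    base_channels: int = 64
    n_downsampling: int = 2
    n_residual_blocks: int = 9
    skip_connections: bool = True
    out_channels: int = 3

    def __post_init__(self):
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.n_downsampling != 2:
            raise ValueError("the architecture is defined for two strided downsampling layers")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 3
    base_channels: int = 64
    n_blocks: int = 5
    fc_hidden: int = 512
    input_size: int = 256
    subtile_size: int | None = None  # None: score the whole input as one tile
    leaky_slope: float = 0.2

    def __post_init__(self):
        tile = self.subtile_size or self.input_size
        if tile % (2 ** self.n_blocks):
            raise ValueError(f"(sub)tile size {tile} must be divisible by 2^{self.n_blocks} "
                             f"for {self.n_blocks} pooling stages")
        if self.subtile_size and self.input_size % self.subtile_size:
            raise ValueError("input_size must be a multiple of subtile_size")


class _ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng, padding=1, pad_mode="reflect")
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, rng, padding=1, pad_mode="reflect")
        self.norm2 = InstanceNorm2d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y))
        out = x + y
        if out.shape != x.shape:
            raise AssertionError("residual block changed the activation shape")
        return out


class ResNetGenerator(Module):
    """Downsampling path, residual bottleneck, skip-connected upsampling path."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        c = spec.base_channels
        self.entry = Conv2d(spec.in_channels, c, 3, rng, padding=1, pad_mode="reflect")
        self.entry_norm = InstanceNorm2d(c)
        self.down1 = Conv2d(c, 2 * c, 3, rng, stride=2, padding=1, pad_mode="reflect")
        self.down1_norm = InstanceNorm2d(2 * c)
        self.down2 = Conv2d(2 * c, 4 * c, 3, rng, stride=2, padding=1, pad_mode="reflect")
        self.down2_norm = InstanceNorm2d(4 * c)
        self.res_blocks = [_ResidualBlock(4 * c, rng) for _ in range(spec.n_residual_blocks)]
        self.up1 = Conv2d(4 * c, 2 * c, 3, rng, padding=1, pad_mode="reflect")
        self.up1_norm = InstanceNorm2d(2 * c)
        self.up2 = Conv2d(2 * c, c, 3, rng, padding=1, pad_mode="reflect")
        self.up2_norm = InstanceNorm2d(c)
        if spec.skip_connections:
            self.fuse1 = Conv2d(4 * c, 2 * c, 1, rng)
            self.fuse2 = Conv2d(2 * c, c, 1, rng)
        self.final = Conv2d(c, spec.out_channels, 3, rng, padding=1, pad_mode="reflect")

    def __call__(self, x: Tensor, record: dict | None = None) -> Tensor:
        n, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels, got {c}")
        if h % 4 or w % 4:
            raise ValueError(f"spatial size {(h, w)} must be divisible by 4 "
                             "(two stride-2 layers); pad the input first")
        e = self.entry_norm(self.entry(x)).relu()
        d1 = self.down1_norm(self.down1(e)).relu()
        d2 = self.down2_norm(self.down2(d1)).relu()
        z = d2
        for i, block in enumerate(self.res_blocks):
            z = block(z)
            if record is not None:
                record[f"res{i + 1}"] = z
        if record is not None:
            record.update(entry=e, down1=d1, down2=d2)
        u1 = self.up1_norm(self.up1(z.upsample_bilinear2x())).relu()
        if self.spec.skip_connections:
            u1 = self.fuse1(concat([u1, d1], axis=1))
        u2 = self.up2_norm(self.up2(u1.upsample_bilinear2x())).relu()
        if self.spec.skip_connections:
            u2 = self.fuse2(concat([u2, e], axis=1))
        return self.final(u2).tanh()


class TileDiscriminator(Module):
    """Five doubling conv blocks with average pooling, then a two-layer head."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        tile = spec.subtile_size or spec.input_size
        self.blocks = []
        cin = spec.in_channels
        cout = spec.base_channels
        for _ in range(spec.n_blocks):
            self.blocks.append(Conv2d(cin, cout, 3, rng, padding=1, pad_mode="zero"))
            self.blocks.append(Conv2d(cout, cout, 3, rng, padding=1, pad_mode="zero"))
            cin = cout
            cout *= 2
        feat_size = tile // 2 ** spec.n_blocks
        self.fc1 = Linear(cin * feat_size * feat_size, spec.fc_hidden, rng)
        self.fc2 = Linear(spec.fc_hidden, 1, rng)

    def _score_tile(self, x: Tensor) -> Tensor:
        slope = self.spec.leaky_slope
        z = x
        for i in range(0, len(self.blocks), 2):
            z = self.blocks[i](z).leaky_relu(slope)
            z = self.blocks[i + 1](z).leaky_relu(slope)
            z = z.avg_pool2d(2)
        n = z.shape[0]
        flat = z.reshape(n, -1)
        return self.fc2(self.fc1(flat).leaky_relu(slope))  # (n, 1), unbounded

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, got {c}")
        tile = self.spec.subtile_size or min(h, w)
        if h % tile or w % tile:
            raise ValueError(f"input {(h, w)} not divisible into {tile}-px subtiles")
        if tile < 2 ** self.spec.n_blocks:
            raise ValueError(f"(sub)tile size {tile} too small for {self.spec.n_blocks} "
                             "stride-2 pooling stages")
        scores = []
        for i in range(h // tile):
            for j in range(w // tile):
                sub = x[:, :, i * tile:(i + 1) * tile, j * tile:(j + 1) * tile]
                scores.append(self._score_tile(sub))
        total = scores[0]
        for s in scores[1:]:
            total = total + s
        return (total * (1.0 / len(scores))).reshape(n)


@dataclass
class TranslationModel:
    """The two generators and two discriminators of one translation task."""

    G_A: ResNetGenerator  # A -> B
    G_B: ResNetGenerator  # B -> A
    D_A: TileDiscriminator  # scores domain-A images
    D_B: TileDiscriminator  # scores domain-B images
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    seed: int | None = None

    @classmethod
    def create(cls, gen_spec: GeneratorSpec | None = None,
               disc_spec: DiscriminatorSpec | None = None,
               seed: int = 0) -> "TranslationModel":
        gen_spec = gen_spec or GeneratorSpec()
        disc_spec = disc_spec or DiscriminatorSpec()
        rng = np.random.default_rng(seed)
        return cls(G_A=ResNetGenerator(gen_spec, rng), G_B=ResNetGenerator(gen_spec, rng),
                   D_A=TileDiscriminator(disc_spec, rng), D_B=TileDiscriminator(disc_spec, rng),
                   gen_spec=gen_spec, disc_spec=disc_spec, seed=seed)

    def parts(self) -> dict[str, Module]:
        return {"G_A": self.G_A, "G_B": self.G_B, "D_A": self.D_A, "D_B": self.D_B}


def generator_forward(generator: ResNetGenerator, x, record: dict | None = None,
                      inference: bool = True) -> np.ndarray | Tensor:
    """Run a generator on an NCHW batch (array in, array out when inferring)."""
    if isinstance(x, Tensor):
        return generator(x, record=record)
    batch = Tensor(np.asarray(x, dtype=np.float32))
    if inference and record is None:
        with no_grad():
            return generator(batch).data
    return generator(batch, record=record)


def discriminator_forward(discriminator: TileDiscriminator, x) -> np.ndarray | Tensor:
    """Score an NCHW batch; one unbounded scalar per image."""
    if isinstance(x, Tensor):
        return discriminator(x)
    with no_grad():
        return discriminator(Tensor(np.asarray(x, dtype=np.float32))).data


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def _bilinear_resize(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = arr.shape

    def mat(n_out, n_in):
        m = np.zeros((n_out, n_in))
        scale = n_in / n_out
        for o in range(n_out):
            centre = (o + 0.5) * scale - 0.5
            f = int(np.floor(centre))
            t = centre - f
            f0 = min(max(f, 0), n_in - 1)
            f1 = min(max(f + 1, 0), n_in - 1)
            m[o, f0] += 1.0 - t
            m[o, f1] += t
        return m

    return mat(out_h, h) @ arr @ mat(out_w, w).T


def gradcam_heatmap(generator: ResNetGenerator, x, target_layer: int,
                    target: str | None = "mean") -> np.ndarray:
    """Gradient-weighted activation map of one residual block.

    The scalar target (default: mean of the generator output) is
    backpropagated to the chosen residual block; per-channel weights are the
    spatially averaged gradients, the heatmap is the ReLU of the weighted
    activation sum, bilinearly resized to the input size and max-normalised
    to 1 when nonzero. ``target_layer`` is 1-based in [1, n_residual_blocks].
    """
    n_blocks = generator.spec.n_residual_blocks
    if not (1 <= target_layer <= n_blocks):
        raise ValueError(f"target_layer must be in [1, {n_blocks}], got {target_layer}")
    arr = np.asarray(x.pixels if hasattr(x, "pixels") else x, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[-1] in (1, 2, 3):  # HWC tile -> NCHW
        arr = arr.transpose(2, 0, 1)[None]
    elif arr.ndim == 2:
        arr = arr[None, None]
    if arr.ndim != 4:
        raise ValueError("expected a single image or an NCHW batch")
    if arr.shape[1] != generator.spec.in_channels:
        arr = np.repeat(arr, generator.spec.in_channels // arr.shape[1], axis=1)
    batch = Tensor(arr)
    record: dict = {}
    out = generator(batch, record=record)
    scalar = out.mean() if target == "mean" or target is None else target(out)
    generator.zero_grad()
    scalar.backward()
    act = record[f"res{target_layer}"]
    grads = act.grad  # (N, C, h, w)
    weights = grads.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * act.data).sum(axis=1), 0.0)  # (N, h, w)
    maps = []
    for m in cam:
        resized = np.maximum(_bilinear_resize(m, arr.shape[2], arr.shape[3]), 0.0)
        peak = resized.max()
        maps.append(resized / peak if peak > 0 else resized)
    generator.zero_grad()
    result = np.stack(maps)
    return result[0] if result.shape[0] == 1 else result


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TranslationModel, path: str | Path,
                    extra_meta: dict | None = None) -> None:
    """Serialise generators, discriminators, specs and the seed record."""
    path = Path(path)
    arrays = {}
    for part_name, part in model.parts().items():
        for key, val in part.state_dict().items():
            arrays[f"{part_name}::{key}"] = val
    meta = {"gen_spec": asdict(model.gen_spec), "disc_spec": asdict(model.disc_spec),
            "seed": model.seed, "extra": extra_meta or {}}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TranslationModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        gen_spec = GeneratorSpec(**meta["gen_spec"])
        disc_spec = DiscriminatorSpec(**meta["disc_spec"])
        model = TranslationModel.create(gen_spec, disc_spec, seed=meta["seed"] or 0)
        for part_name, part in model.parts().items():
            prefix = part_name + "::"
            state = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            part.load_state_dict(state)
    model.seed = meta["seed"]
    return model
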