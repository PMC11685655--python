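"""Training loop for the saliency-constrained cycle GAN and the two-stage
inter-domain transformation frameworks, plus inference-time translation.

The public surface follows the fitted-model convention: construct a
:class:`SaliencyCycleGAN` from the two unpaired domains and a
:class:`TrainingConfig`, call :meth:`~SaliencyCycleGAN.fit`, and receive a
:class:`CycleGANResults` holding the trained :class:`TranslationModel`, the
per-iteration loss trajectory and a ``summary()`` table. The lower-level
:class:`CycleGANTrainer` exposes single optimisation steps and a complete
serialisable training state for exact resumption.

Each iteration updates the generators first (adversarial + cycle + SSIM +
saliency terms, jointly for both directions), then both discriminators on
real images and a 50-image history pool of past fakes. Pairing information
is never consulted: the trainer receives only the two tile sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .imaging_io import DomainDataset, ImageTile
from .losses import (LossBreakdown, LossConfig, SSIMLossParams, cycle_loss,
                     lsgan_losses, otsu_threshold, saliency_loss, ssim_loss,
                     total_loss)
from .networks import (DiscriminatorSpec, GeneratorSpec, TranslationModel,
                       load_checkpoint, save_checkpoint)
from .nn import Adam, Tensor, no_grad

log = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "UIDTFramework", "IdentityTranslator",
           "SaliencyCycleGAN", "CycleGANTrainer", "CycleGANResults",
           "train_xcyclegan", "translate_tiles", "run_uidt",
           "tiles_to_batch", "batch_to_tiles"]


@dataclass
class TrainingConfig:
    loss_config: LossConfig = field(default_factory=LossConfig)
    learning_rate: float = 2e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    n_iterations: int = 2000
    batch_size: int = 1
    seed: int = 0
    checkpoint_interval: int = 0      # 0: only final checkpoint
    deterministic_mode: bool = True   # numpy backend: always bit-reproducible
    auto_thresholds: bool = True      # Otsu over training tiles at startup
    lr_linear_decay: bool = True      # constant, then linear decay over 2nd half
    fake_pool_size: int = 50

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# tile <-> network-range batch conversion
# ---------------------------------------------------------------------------

def tiles_to_batch(tiles: list[ImageTile]) -> np.ndarray:
    """Stack tiles into an NCHW float32 batch in the network range [-1, 1].

    Grayscale tiles are replicated to 3 channels; two-channel stained tiles
    become RGB with the red plane zeroed (blue and green in their native
    positions), keeping both generators shape-symmetric.
    """
    arrs = []
    for t in tiles:
        px = t.pixels
        if t.channels == "gray1":
            chw = np.repeat(px.transpose(2, 0, 1), 3, axis=0)
        elif t.channels == "stain2":
            chw = np.zeros((3,) + px.shape[:2], dtype=px.dtype)
            chw[2] = px[:, :, 0]  # blue
            chw[1] = px[:, :, 1]  # green
        else:  # rgb3
            chw = px.transpose(2, 0, 1)
        arrs.append(chw)
    batch = np.stack(arrs).astype(np.float32)
    return batch * 2.0 - 1.0


def batch_to_tiles(batch: np.ndarray, layout: str, template: ImageTile | None = None) -> list[ImageTile]:
    """Map a [-1, 1] NCHW batch back to [0, 1] tiles of the given layout."""
    px01 = np.clip((np.asarray(batch) + 1.0) / 2.0, 0.0, 1.0)
    pixel_size = template.pixel_size_um if template is not None else 0.31
    tiles = []
    for chw in px01:
        if layout == "gray1":
            hwc = chw.mean(axis=0)[:, :, None]
        elif layout == "stain2":
            hwc = np.stack([chw[2], chw[1]], axis=-1)  # (blue, green)
        elif layout == "rgb3":
            hwc = chw.transpose(1, 2, 0)
        else:
            raise ValueError(f"unknown layout {layout!r}")
        tiles.append(ImageTile(hwc.astype(np.float32), channels=layout,
                               value_range=(0.0, 1.0), pixel_size_um=pixel_size))
    return tiles


# ---------------------------------------------------------------------------
# trainer
# ---------------------------------------------------------------------------

class _EpochSampler:
    """Yields batches from an index permutation reshuffled every epoch."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = batch_size
        self.rng = rng
        self._perm = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos + self.batch_size > self.n:
            self._perm = self.rng.permutation(self.n)
            self._pos = 0
        out = self._perm[self._pos:self._pos + self.batch_size]
        self._pos += self.batch_size
        return out


class _FakePool:
    """History buffer of past generated images for discriminator updates."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, fakes: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return fakes
        out = []
        for img in fakes:
            if len(self.images) < self.size:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(0, self.size))
                out.append(self.images[idx].copy())
                self.images[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


class CycleGANTrainer:
    """Stateful optimisation driver: one `step()` = one full G + D update."""

    def __init__(self, batch_a: np.ndarray, batch_b: np.ndarray, config: TrainingConfig,
                 gen_spec: GeneratorSpec | None = None,
                 disc_spec: DiscriminatorSpec | None = None):
        self.config = config
        self.data_a = np.asarray(batch_a, dtype=np.float32)  # NCHW, [-1, 1]
        self.data_b = np.asarray(batch_b, dtype=np.float32)
        if self.data_a.ndim != 4 or self.data_b.ndim != 4:
            raise ValueError("training data must be NCHW batches")
        h, w = self.data_a.shape[2:]
        if h % 4 or w % 4:
            raise ValueError(f"tile size {(h, w)} incompatible with the generator "
                             "(must be divisible by 4)")
        gen_spec = gen_spec or GeneratorSpec()
        disc_spec = disc_spec or DiscriminatorSpec(input_size=h)
        self.model = TranslationModel.create(gen_spec, disc_spec, seed=config.seed)
        self.rng = np.random.default_rng(config.seed)
        lr, betas = config.learning_rate, config.adam_betas
        g_params = self.model.G_A.parameters() + self.model.G_B.parameters()
        d_params = self.model.D_A.parameters() + self.model.D_B.parameters()
        self.opt_g = Adam(g_params, lr=lr, betas=betas)
        self.opt_d = Adam(d_params, lr=lr, betas=betas)
        self.pool_a = _FakePool(config.fake_pool_size, self.rng)
        self.pool_b = _FakePool(config.fake_pool_size, self.rng)
        self.sampler_a = _EpochSampler(len(self.data_a), config.batch_size, self.rng)
        self.sampler_b = _EpochSampler(len(self.data_b), config.batch_size, self.rng)
        self.iteration = 0
        self.ssim_params = SSIMLossParams(dynamic_range=1.0, mode="global")

    # -- one optimisation step -------------------------------------------
    def step(self) -> dict:
        cfg = self.config
        lc = cfg.loss_config
        if cfg.lr_linear_decay:
            self.opt_g.set_linear_decay(self.iteration, cfg.n_iterations)
            self.opt_d.set_linear_decay(self.iteration, cfg.n_iterations)
        a = Tensor(self.data_a[self.sampler_a.next_batch()])
        b = Tensor(self.data_b[self.sampler_b.next_batch()])

        m = self.model
        # ---- generator update (both directions jointly) ----
        fake_b = m.G_A(a)
        rec_a = m.G_B(fake_b)
        fake_a = m.G_B(b)
        rec_b = m.G_A(fake_a)
        g_gan_fwd = ((m.D_B(fake_b) - 1.0) ** 2).mean()  # LSGAN generator target
        g_gan_bwd = ((m.D_A(fake_a) - 1.0) ** 2).mean()
        cyc = cycle_loss(a, rec_a, b, rec_b)
        # structural terms operate in the [0, 1] image range
        a01, b01 = (a + 1.0) * 0.5, (b + 1.0) * 0.5
        ra01, rb01 = (rec_a + 1.0) * 0.5, (rec_b + 1.0) * 0.5
        fb01, fa01 = (fake_b + 1.0) * 0.5, (fake_a + 1.0) * 0.5
        ssim = ssim_loss(a01, ra01, b01, rb01, self.ssim_params)
        sal = saliency_loss(a01, fb01, b01, fa01, lc)
        g_total = (g_gan_fwd + g_gan_bwd + lc.lambda_cyc * cyc
                   + lc.xi_ssim * ssim + lc.rho_saliency * sal)
        self.opt_g.zero_grad()
        self.opt_d.zero_grad()
        g_total.backward()
        self.opt_g.step()

        # ---- discriminator updates on detached fakes + history pool ----
        self.opt_d.zero_grad()
        fake_b_pool = Tensor(self.pool_b.query(fake_b.data))
        fake_a_pool = Tensor(self.pool_a.query(fake_a.data))
        d_b_loss, _ = lsgan_losses(m.D_B(b), m.D_B(fake_b_pool))
        d_a_loss, _ = lsgan_losses(m.D_A(a), m.D_A(fake_a_pool))
        d_total = d_b_loss + d_a_loss
        d_total.backward()
        self.opt_d.step()

        self.iteration += 1
        breakdown = total_loss(g_gan_fwd, g_gan_bwd, cyc, ssim, sal, lc)
        rec = breakdown.to_dict()
        rec.update(iteration=self.iteration, d_loss_A=d_a_loss.item(), d_loss_B=d_b_loss.item())
        return rec

    # -- exact state serialisation ----------------------------------------
    def save_state(self, path: str | Path) -> None:
        arrays = {}
        for part_name, part in self.model.parts().items():
            for k, v in part.state_dict().items():
                arrays[f"model::{part_name}::{k}"] = v
        for name, opt in (("opt_g", self.opt_g), ("opt_d", self.opt_d)):
            st = opt.state_dict()
            for i, (mm, vv) in enumerate(zip(st["m"], st["v"])):
                arrays[f"{name}::m{i}"] = mm
                arrays[f"{name}::v{i}"] = vv
        for name, pool in (("pool_a", self.pool_a), ("pool_b", self.pool_b)):
            for i, img in enumerate(pool.images):
                arrays[f"{name}::{i}"] = img
        meta = {"iteration": self.iteration,
                "opt_g": {"t": self.opt_g.t, "lr": self.opt_g.lr},
                "opt_d": {"t": self.opt_d.t, "lr": self.opt_d.lr},
                "rng_state": self.rng.bit_generator.state,
                "sampler_a": {"perm": self.sampler_a._perm.tolist(), "pos": self.sampler_a._pos},
                "sampler_b": {"perm": self.sampler_b._perm.tolist(), "pos": self.sampler_b._pos}}
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(Path(path), **arrays)

    def load_state(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            for part_name, part in self.model.parts().items():
                prefix = f"model::{part_name}::"
                part.load_state_dict({k[len(prefix):]: data[k]
                                      for k in data.files if k.startswith(prefix)})
            for name, opt in (("opt_g", self.opt_g), ("opt_d", self.opt_d)):
                ms, vs, i = [], [], 0
                while f"{name}::m{i}" in data.files:
                    ms.append(data[f"{name}::m{i}"])
                    vs.append(data[f"{name}::v{i}"])
                    i += 1
                opt.load_state_dict({"t": meta[name]["t"], "lr": meta[name]["lr"],
                                     "m": ms, "v": vs})
            for name, pool in (("pool_a", self.pool_a), ("pool_b", self.pool_b)):
                pool.images = []
                i = 0
                while f"{name}::{i}" in data.files:
                    pool.images.append(data[f"{name}::{i}"].copy())
                    i += 1
        self.iteration = meta["iteration"]
        self.rng.bit_generator.state = meta["rng_state"]
        self.sampler_a._perm = np.asarray(meta["sampler_a"]["perm"])
        self.sampler_a._pos = meta["sampler_a"]["pos"]
        self.sampler_b._perm = np.asarray(meta["sampler_b"]["perm"])
        self.sampler_b._pos = meta["sampler_b"]["pos"]


# ---------------------------------------------------------------------------
# fitted-model interface
# ---------------------------------------------------------------------------

class CycleGANResults:
    """Trained model, loss trajectory and summary of one fit."""

    def __init__(self, model: TranslationModel, log_records: list[dict],
                 config: TrainingConfig):
        self.model = model
        self.log_records = log_records
        self.config = config

    @property
    def log_df(self):
        import pandas as pd
        return pd.DataFrame(self.log_records)

    def translate(self, tiles: list[ImageTile], direction: str = "A2B",
                  out_layout: str | None = None) -> list[ImageTile]:
        return translate_tiles(self.model, direction, tiles, out_layout=out_layout)

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.model, path, extra_meta={"n_iterations": len(self.log_records)})

    def summary(self) -> str:
        first, last = self.log_records[0], self.log_records[-1]
        lc = self.config.loss_config
        lines = [
            "Saliency-constrained cycle GAN - fit summary",
            "=" * 52,
            f"iterations            {len(self.log_records)}",
            f"batch size            {self.config.batch_size}",
            f"generator params      {self.model.G_A.n_parameters():,} (x2)",
            f"discriminator params  {self.model.D_A.n_parameters():,} (x2)",
            f"weights               lambda={lc.lambda_cyc} xi={lc.xi_ssim} rho={lc.rho_saliency}",
            f"thresholds            T_A={lc.threshold_A:.3f} T_B={lc.threshold_B:.3f}",
            "-" * 52,
            f"{'term':<14}{'first':>12}{'last':>12}",
        ]
        for term in ("gan_forward", "gan_backward", "cycle", "ssim", "saliency", "total"):
            lines.append(f"{term:<14}{first[term]:>12.4f}{last[term]:>12.4f}")
        return "\n".join(lines)


class SaliencyCycleGAN:
    """Unpaired image-to-image translation model over two tile domains.

    Parameters
    ----------
    domain_a, domain_b
        The unpaired training domains (source and target). Only the tiles
        are consumed; any pairing metadata is structurally inaccessible to
        the trainer.
    config
        Optimisation settings and loss weights.
    """

    def __init__(self, domain_a: DomainDataset, domain_b: DomainDataset,
                 config: TrainingConfig | None = None,
                 gen_spec: GeneratorSpec | None = None,
                 disc_spec: DiscriminatorSpec | None = None):
        if len(domain_a) == 0 or len(domain_b) == 0:
            raise ValueError("both domains must be non-empty")
        self.config = config or TrainingConfig()
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec
        self.domain_a = domain_a
        self.domain_b = domain_b
        self.batch_a = tiles_to_batch(domain_a.tiles)
        self.batch_b = tiles_to_batch(domain_b.tiles)
        if self.config.auto_thresholds:
            t_a = otsu_threshold(domain_a.tiles)
            t_b = otsu_threshold(domain_b.tiles)
            self.config = replace(self.config,
                                  loss_config=replace(self.config.loss_config,
                                                      threshold_A=t_a, threshold_B=t_b))
            log.info("Otsu thresholds: T_A=%.4f T_B=%.4f", t_a, t_b)

    def fit(self, checkpoint_dir: str | Path | None = None,
            log_path: str | Path | None = None) -> CycleGANResults:
        cfg = self.config
        trainer = CycleGANTrainer(self.batch_a, self.batch_b, cfg,
                                  self.gen_spec, self.disc_spec)
        records = []
        log_file = open(log_path, "w") if log_path else None
        try:
            for it in range(cfg.n_iterations):
                rec = trainer.step()
                records.append(rec)
                if log_file:
                    log_file.write(json.dumps(rec) + "\n")
                if (checkpoint_dir and cfg.checkpoint_interval
                        and (it + 1) % cfg.checkpoint_interval == 0):
                    save_checkpoint(trainer.model,
                                    Path(checkpoint_dir) / f"checkpoint_{it + 1:06d}.npz")
        finally:
            if log_file:
                log_file.close()
        if checkpoint_dir:
            save_checkpoint(trainer.model, Path(checkpoint_dir) / "checkpoint_final.npz")
        return CycleGANResults(trainer.model, records, cfg)


def train_xcyclegan(domain_a: DomainDataset, domain_b: DomainDataset,
                    config: TrainingConfig | None = None,
                    gen_spec: GeneratorSpec | None = None,
                    disc_spec: DiscriminatorSpec | None = None,
                    checkpoint_dir=None, log_path=None) -> tuple[TranslationModel, list[dict]]:
    """Functional wrapper: train and return ``(model, per-iteration log)``."""
    res = SaliencyCycleGAN(domain_a, domain_b, config, gen_spec, disc_spec).fit(
        checkpoint_dir=checkpoint_dir, log_path=log_path)
    return res.model, res.log_records


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

_DIRECTIONS = ("A2B", "B2A")


def translate_tiles(model: TranslationModel, direction: str, tiles: list[ImageTile],
                    out_layout: str | None = None, batch_size: int = 4) -> list[ImageTile]:
    """Translate tiles with a trained model, deterministically, in order.

    ``direction`` is ``"A2B"`` (source to target, generator G_A) or
    ``"B2A"``. The output layout defaults to ``stain2`` for A2B and
    ``gray1`` for B2A; pass ``out_layout`` explicitly for grayscale-to-
    grayscale stages such as resolution enhancement.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if not tiles:
        return []
    gen = model.G_A if direction == "A2B" else model.G_B
    if out_layout is None:
        out_layout = "stain2" if direction == "A2B" else "gray1"
    outs = []
    with no_grad():
        for i in range(0, len(tiles), batch_size):
            chunk = tiles[i:i + batch_size]
            batch = tiles_to_batch(chunk)
            out = gen(Tensor(batch)).data
            outs.extend(batch_to_tiles(out, out_layout, template=chunk[0]))
    return outs


class IdentityTranslator:
    """A stub stage that passes images through the range remaps unchanged."""

    def translate(self, tiles: list[ImageTile], out_layout: str | None = None) -> list[ImageTile]:
        layout = out_layout or tiles[0].channels
        return batch_to_tiles(tiles_to_batch(tiles), layout, template=tiles[0])


@dataclass
class UIDTFramework:
    """End-to-end (one model) or pipeline (resolution enhancement then
    virtual staining) configuration of the inter-domain transformation."""

    kind: str  # "end_to_end" | "pipeline"
    stages: list
    stage_out_layouts: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("end_to_end", "pipeline"):
            raise ValueError("kind must be 'end_to_end' or 'pipeline'")
        expected = 1 if self.kind == "end_to_end" else 2
        if len(self.stages) != expected:
            raise ValueError(f"{self.kind} framework needs {expected} stage(s), "
                             f"got {len(self.stages)}")
        if not self.stage_out_layouts:
            self.stage_out_layouts = (["stain2"] if self.kind == "end_to_end"
                                      else ["gray1", "stain2"])


def _apply_stage(stage, tiles: list[ImageTile], out_layout: str, stage_name: str) -> list[ImageTile]:
    if isinstance(stage, TranslationModel):
        return translate_tiles(stage, "A2B", tiles, out_layout=out_layout)
    if hasattr(stage, "translate"):
        return stage.translate(tiles, out_layout=out_layout)
    raise TypeError(f"stage {stage_name}: expected a TranslationModel or a translator "
                    f"object, got {type(stage).__name__}")


def run_uidt(framework: UIDTFramework, lr_tiles: list[ImageTile]) -> list[ImageTile]:
    """Apply the framework to low-resolution unlabeled tiles.

    End-to-end: a single source-to-target translation. Pipeline: the first
    stage enhances resolution (grayscale to grayscale); its output is
    re-normalised to [0, 1] and fed to the second stage, which stains it.
    The composition is exactly two `translate_tiles` calls, so the manual
    two-stage path is bit-identical.
    """
    tiles = lr_tiles
    for idx, (stage, layout) in enumerate(zip(framework.stages, framework.stage_out_layouts)):
        name = ("stage1 (resolution enhancement)" if framework.kind == "pipeline" and idx == 0
                else "stage2 (virtual staining)" if framework.kind == "pipeline"
                else "end-to-end stage")
        try:
            tiles = _apply_stage(stage, tiles, layout, name)
        except ValueError as e:
            raise ValueError(f"{name}: interface mismatch: {e}") from e
    return tiles
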