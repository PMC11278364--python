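"""Mask-preserving CycleGAN for synthetic-to-real translation.

The source domain S is *annotated*: its samples are 4-channel tensors, the
RGB image concatenated with its binary segmentation mask.  The target
domain R is unannotated 3-channel imagery.  G_S→R maps 4→3 channels
(dropping the annotation to produce a realistic image); G_R→S maps 3→4
(hallucinating an image *and* a mask).  Because the S-side cycle loss is an
L1 distance over all four channels, the mask must be recreated at the end
of the S→R→S cycle — this is what forces the translation to keep wheat
heads where the annotation says they are.  D_S judges 4-channel
image⊕mask samples; D_R judges 3-channel images.

Translating a dataset never rewrites its annotations: the output dataset
reuses each source mask file byte for byte.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, no_grad
from .nn import autograd as ag
from .imgio import read_image, read_mask, require_binary, write_image
from .manifest import DatasetManifest


# -- domain samples --------------------------------------------------------

def to_domain_s(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(uint8 image, {0,1} mask) -> float32 (4,H,W) in [-1,1]; mask {0,1}->{-1,+1}."""
    mask = require_binary(mask)
    img = np.asarray(image, dtype=np.float32).transpose(2, 0, 1) / 127.5 - 1.0
    m = mask.astype(np.float32)[None] * 2.0 - 1.0
    return np.concatenate([img, m], axis=0)


def to_domain_r(image: np.ndarray) -> np.ndarray:
    """uint8 image -> float32 (3,H,W) in [-1,1]."""
    return np.asarray(image, dtype=np.float32).transpose(2, 0, 1) / 127.5 - 1.0


def image_from_channels(channels: np.ndarray) -> np.ndarray:
    """First three channels in [-1,1] -> uint8 H×W×3."""
    img = (np.asarray(channels[:3]).transpose(1, 2, 0) + 1.0) * 127.5
    return np.round(np.clip(img, 0, 255)).astype(np.uint8)


def mask_from_channel(channel: np.ndarray) -> np.ndarray:
    """Mask channel in [-1,1] -> {0,1}; threshold 0, ties to foreground."""
    return (np.asarray(channel) >= 0.0).astype(np.uint8)


def _check_arity(arr: np.ndarray, channels: int, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1] != channels:
        raise ValueError(f"{name} must have {channels} channels (got shape {arr.shape})")
    return arr


# -- configuration and state ----------------------------------------------

@dataclass(frozen=True)
class GanConfig:
    epochs: int = 60
    learning_rate: float = 2e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    lambda_cycle: float = 10.0
    replay_buffer_size: int = 50
    crop_size: int = 256
    seed: int = 0
    base_channels: int = 64
    n_res_blocks: int | None = None   # None -> 9 at crop>=256 else 6
    disc_layers: int = 3
    batch_size: int = 1

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.lambda_cycle < 0:
            raise ValueError("lambda_cycle must be >= 0")
        if self.epochs < 0 or self.replay_buffer_size < 0:
            raise ValueError("counts must be >= 0")

    @property
    def resolved_res_blocks(self) -> int:
        if self.n_res_blocks is not None:
            return self.n_res_blocks
        return 9 if self.crop_size >= 256 else 6


class ReplayBuffer:
    """Pool of past generated samples for discriminator updates.

    Each incoming sample is stored until the pool is full; afterwards, with
    probability 1/2 it is swapped with a random stored sample and the old
    one is returned instead.  Stabilizes the discriminators by keeping them
    honest against the generator's history, not just its latest output.
    """

    def __init__(self, size: int):
        self.size = size
        self.items: list[np.ndarray] = []

    def query(self, batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.items) < self.size:
                self.items.append(img.copy())
                out.append(img)
            elif rng.random() < 0.5:
                i = int(rng.integers(0, self.size))
                out.append(self.items[i].copy())
                self.items[i] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


@dataclass
class GanState:
    config: GanConfig
    g_s2r: nn.ResnetGenerator
    g_r2s: nn.ResnetGenerator
    d_s: nn.PatchDiscriminator
    d_r: nn.PatchDiscriminator
    opt_g: nn.Adam
    opt_d: nn.Adam
    pool_s: ReplayBuffer
    pool_r: ReplayBuffer
    epoch: int = 0
    history: list[dict] = field(default_factory=list)


def init_gan(config: GanConfig) -> GanState:
    """Fresh networks and optimizers, seeded from config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nb = config.resolved_res_blocks
    g_s2r = nn.ResnetGenerator(4, 3, rng, config.base_channels, nb)
    g_r2s = nn.ResnetGenerator(3, 4, rng, config.base_channels, nb)
    d_s = nn.PatchDiscriminator(4, rng, config.base_channels, config.disc_layers)
    d_r = nn.PatchDiscriminator(3, rng, config.base_channels, config.disc_layers)
    opt_g = nn.Adam(list(g_s2r.parameters()) + list(g_r2s.parameters()),
                    lr=config.learning_rate, betas=config.adam_betas)
    opt_d = nn.Adam(list(d_s.parameters()) + list(d_r.parameters()),
                    lr=config.learning_rate, betas=config.adam_betas)
    return GanState(config, g_s2r, g_r2s, d_s, d_r, opt_g, opt_d,
                    ReplayBuffer(config.replay_buffer_size),
                    ReplayBuffer(config.replay_buffer_size))


# -- losses ----------------------------------------------------------------

def adversarial_loss(disc_map, target_is_real: bool) -> Tensor:
    """Least-squares adversarial loss: mean (score - target)^2, target 1/0."""
    t = disc_map if isinstance(disc_map, Tensor) else Tensor(disc_map)
    if not np.isfinite(t.data).all():
        raise FloatingPointError("discriminator scores contain non-finite values")
    target = np.float32(1.0 if target_is_real else 0.0)
    diff = t - Tensor(target)
    return ag.tmean(ag.mul(diff, diff))


def _l1(a, b, channels: int, name: str) -> Tensor:
    ta = a if isinstance(a, Tensor) else Tensor(a)
    tb = b if isinstance(b, Tensor) else Tensor(b)
    da = _check_arity(ta.data, channels, name)
    db = _check_arity(tb.data, channels, name)
    if da.shape != db.shape:
        raise ValueError(f"{name}: shape mismatch {da.shape} vs {db.shape}")
    return ag.tmean(ag.absolute(ta - tb))


def cycle_loss_s(original, reconstructed) -> Tensor:
    """Mean |orig - rec| over all 4 channels; the mask weighs like a channel."""
    return _l1(original, reconstructed, 4, "cycle_loss_s")


def cycle_loss_r(original, reconstructed) -> Tensor:
    """Mean |orig - rec| over the 3 image channels."""
    return _l1(original, reconstructed, 3, "cycle_loss_r")


# -- training --------------------------------------------------------------

def training_step(state: GanState, batch_s: np.ndarray, batch_r: np.ndarray,
                  rng: np.random.Generator) -> tuple[GanState, dict[str, float]]:
    """One optimization step over both cycles (S→R→S and R→S→R).

    Generators are updated on the adversarial terms plus lambda_cycle times
    the two cycle losses; discriminators are then updated against replay
    buffers of past generated samples.
    """
    xs = Tensor(_check_arity(batch_s, 4, "batch_s"))
    yr = Tensor(_check_arity(batch_r, 3, "batch_r"))
    cfg = state.config

    # generator update
    fake_r = state.g_s2r(xs)
    rec_s = state.g_r2s(fake_r)
    fake_s = state.g_r2s(yr)
    rec_r = state.g_s2r(fake_s)
    adv_s2r = adversarial_loss(state.d_r(fake_r), True)
    adv_r2s = adversarial_loss(state.d_s(fake_s), True)
    cyc_s = cycle_loss_s(xs, rec_s)
    cyc_r = cycle_loss_r(yr, rec_r)
    loss_g = adv_s2r + adv_r2s + Tensor(np.float32(cfg.lambda_cycle)) * (cyc_s + cyc_r)
    state.opt_g.zero_grad()
    state.opt_d.zero_grad()
    loss_g.backward()
    state.opt_g.step()

    # discriminator updates against replay buffers
    pooled_r = state.pool_r.query(fake_r.data, rng)
    pooled_s = state.pool_s.query(fake_s.data, rng)
    loss_d_r = Tensor(np.float32(0.5)) * (
        adversarial_loss(state.d_r(yr), True)
        + adversarial_loss(state.d_r(Tensor(pooled_r)), False))
    loss_d_s = Tensor(np.float32(0.5)) * (
        adversarial_loss(state.d_s(xs), True)
        + adversarial_loss(state.d_s(Tensor(pooled_s)), False))
    state.opt_d.zero_grad()
    (loss_d_r + loss_d_s).backward()
    state.opt_d.step()

    losses = {
        "adv_s2r": float(adv_s2r.data), "adv_r2s": float(adv_r2s.data),
        "cycle_s": float(cyc_s.data), "cycle_r": float(cyc_r.data),
        "gen_total": float(loss_g.data),
        "disc_s": float(loss_d_s.data), "disc_r": float(loss_d_r.data),
    }
    for v in losses.values():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite training loss: {losses}")
    state.history.append(losses)
    return state, losses


def _random_crop(arr: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    _, H, W = arr.shape
    if H <= size and W <= size:
        return arr
    top = int(rng.integers(0, H - size + 1)) if H > size else 0
    left = int(rng.integers(0, W - size + 1)) if W > size else 0
    return arr[:, top:top + min(size, H), left:left + min(size, W)]


def train_gan(config: GanConfig, manifest_s: DatasetManifest,
              manifest_r: DatasetManifest,
              checkpoint_dir=None) -> GanState:
    """Train on paired random draws from the two manifests.

    S rows must carry masks (the annotation is half the sample).  One epoch
    is max(|S|, |R|) steps of randomly paired samples.  A checkpoint is
    written per epoch when ``checkpoint_dir`` is given.
    """
    config.validate()
    if len(manifest_s) == 0 or len(manifest_r) == 0:
        raise ValueError("both manifests must be non-empty")
    for row in manifest_s:
        if not row.has_mask:
            raise ValueError(f"S-domain row without mask: {row.image_path}")
    state = init_gan(config)
    rng = np.random.default_rng(config.seed)
    xs_all = [to_domain_s(read_image(r.image_path), read_mask(r.mask_path))
              for r in manifest_s]
    yr_all = [to_domain_r(read_image(r.image_path)) for r in manifest_r]
    if checkpoint_dir is not None:
        Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
    steps_per_epoch = max(len(xs_all), len(yr_all))
    for epoch in range(config.epochs):
        order_s = rng.permutation(len(xs_all))
        order_r = rng.permutation(len(yr_all))
        for i in range(steps_per_epoch):
            xs = _random_crop(xs_all[order_s[i % len(xs_all)]], config.crop_size, rng)
            yr = _random_crop(yr_all[order_r[i % len(yr_all)]], config.crop_size, rng)
            training_step(state, xs[None], yr[None], rng)
        state.epoch = epoch + 1
        if checkpoint_dir is not None:
            save_checkpoint(state, Path(checkpoint_dir) / f"gan_epoch{epoch + 1}.ckpt")
    return state


# -- inference -------------------------------------------------------------

def translate_sample(state: GanState, sample: np.ndarray) -> np.ndarray:
    """S-domain (4,H,W) sample -> realistic (3,H,W) image in [-1,1]."""
    x = _check_arity(sample, 4, "sample")
    with no_grad():
        out = state.g_s2r(Tensor(x))
    res = out.data
    return res[0] if np.asarray(sample).ndim == 3 else res


def recreate_s(state: GanState, sample: np.ndarray,
               binarize_mask: bool = False) -> np.ndarray:
    """R-domain (3,H,W) image -> (4,H,W) image+mask estimate.

    With ``binarize_mask=True`` the mask channel is snapped to {-1,+1} at
    threshold 0, ties to foreground.
    """
    y = _check_arity(sample, 3, "sample")
    with no_grad():
        out = state.g_r2s(Tensor(y))
    res = out.data.copy()
    if binarize_mask:
        res[:, 3] = np.where(res[:, 3] >= 0.0, 1.0, -1.0)
    return res[0] if np.asarray(sample).ndim == 3 else res


def build_gan_dataset(state: GanState, manifest_s: DatasetManifest,
                      out_dir) -> DatasetManifest:
    """Translate every S row; copy its mask file byte for byte.

    The output manifest has the same row count and splits as the input —
    the architecture never rewrites the annotation of a translated sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest()
    for i, row in enumerate(manifest_s):
        image = read_image(row.image_path)
        mask = read_mask(row.mask_path)
        fake = translate_sample(state, to_domain_s(image, mask))
        ipath = out_dir / f"gan_{i:05d}.png"
        mpath = out_dir / f"gan_{i:05d}_mask.png"
        write_image(ipath, image_from_channels(fake))
        mpath.write_bytes(Path(row.mask_path).read_bytes())
        manifest.append(ipath, mpath, row.split)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(state: GanState, path) -> None:
    """Serialize network parameters + config (not optimizer moments)."""
    payload = {
        "config": asdict(state.config),
        "epoch": state.epoch,
        "history": state.history,
        "params": {name: getattr(state, name).state_arrays()
                   for name in ("g_s2r", "g_r2s", "d_s", "d_r")},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> GanState:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg_dict = payload["config"]
    cfg_dict["adam_betas"] = tuple(cfg_dict["adam_betas"])
    config = GanConfig(**cfg_dict)
    state = init_gan(config)
    for name, arrays in payload["params"].items():
        getattr(state, name).load_state_arrays(arrays)
    state.epoch = payload["epoch"]
    state.history = payload["history"]
    return state
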