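"""Alternating GAN optimisation with Adam, checkpointing and logging.

One discriminator step and one generator step per mini-batch; Adam with
the reference hyperparameters (lr 1e-4, betas (0.5, 0.999)); all
convolution weights initialised i.i.d. N(0, 0.02^2) from the run seed.
The log records, per epoch, the discriminator loss, the generator's
adversarial and L2 terms, the hybrid objective and the fraction of
batches in which the discriminator had saturated (mean D(fake) below
1e-3) — the quantity that makes the edge-channel ablation comparison
observable.

Loss variants (the objective ablation axes):

* ``mse_jsd`` (default) — non-saturating adversarial + weighted L2;
* ``kl``      — the original saturating minimax generator term + L2;
* ``mse``     — L2 only (no discriminator updates).

Checkpoints are single ``.npz`` archives holding generator,
discriminator and optimiser state, the epoch counter and the RNG state,
so training is resumable with an identical random stream.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor
from .config import TrainConfig
from .encoder import EncoderConfig
from .gan import Discriminator, Generator, edge_channel
from .losses import LossWeights, adversarial_losses, l2_loss, saturating_generator_loss
from .volume import PairedSample

SATURATION_THRESHOLD = 1e-3


@dataclass
class TrainLog:
    """Per-epoch training records plus run metadata."""

    records: list[dict]
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame.from_records(self.records)


def init_weights(module: nn.Module, std: float, rng: np.random.Generator):
    """Re-draw every convolution weight i.i.d. N(0, std^2); zero biases.

    BatchNorm scale/shift are reset to 1/0.  Deterministic in ``rng``.
    """
    if std <= 0:
        raise ValueError("std must be > 0")
    for name, p in module.named_parameters().items():
        leaf = name.rsplit(".", 1)[-1]
        if leaf == "weight":
            p.data[...] = rng.normal(0.0, std, size=p.shape).astype(p.data.dtype)
        elif leaf == "bias" or leaf == "beta":
            p.data[...] = 0.0
        elif leaf == "gamma":
            p.data[...] = 1.0
    return module


def build_models(cfg: TrainConfig, rng: np.random.Generator) -> tuple[Generator, Discriminator]:
    enc_cfg = EncoderConfig(
        volume_extent=cfg.extent,
        long_kernel=cfg.extent,
        local_kernel=cfg.extent // 2,
        branch_channels=cfg.branch_channels,
        channels_2d=cfg.channels_2d,
        eps=cfg.fusion_eps,
    )
    gen = Generator(
        enc_cfg, rng, decoder_channels=cfg.decoder_channels,
        std=cfg.init_std, use_sobel=cfg.use_sobel,
    )
    disc = Discriminator(rng, channels=cfg.disc_channels, std=cfg.init_std)
    return gen, disc


def _stack_batch(pairs: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    pet = np.stack([p.pet.data for p in pairs])[:, None].astype(nn.DTYPE)
    mri = np.stack([p.mri.data for p in pairs])[:, None].astype(nn.DTYPE)
    return pet, mri


def save_checkpoint(path, gen, disc, opt_g, opt_d, epoch: int,
                    rng: np.random.Generator, cfg: TrainConfig):
    arrays: dict[str, np.ndarray] = {}
    for k, v in gen.state_dict().items():
        arrays[f"gen/{k}"] = v
    for k, v in disc.state_dict().items():
        arrays[f"disc/{k}"] = v
    for tag, opt in (("optg", opt_g), ("optd", opt_d)):
        if opt is None:
            continue
        st = opt.state_dict()
        arrays[f"{tag}/t"] = np.array(st["t"])
        for i, a in enumerate(st["m"]):
            arrays[f"{tag}/m{i}"] = a
        for i, a in enumerate(st["v"]):
            arrays[f"{tag}/v{i}"] = a
    meta = {
        "epoch": epoch,
        "rng_state": rng.bit_generator.state,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.__dict__.items()},
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path):
    """Return (arrays, meta) from a checkpoint file."""
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    return arrays, meta


def restore_models_from_checkpoint(path) -> tuple[Generator, Discriminator, dict]:
    """Rebuild generator/discriminator at the state stored in a checkpoint."""
    arrays, meta = load_checkpoint(path)
    cfg_d = dict(meta["config"])
    for key in ("betas", "decoder_channels", "disc_channels"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = TrainConfig(**cfg_d)
    gen, disc = build_models(cfg, np.random.default_rng(cfg.seed))
    gen.load_state_dict({k[4:]: v for k, v in arrays.items() if k.startswith("gen/")})
    disc.load_state_dict({k[5:]: v for k, v in arrays.items() if k.startswith("disc/")})
    return gen, disc, meta


def _restore_opt(opt, arrays, tag):
    keys = [k for k in arrays if k.startswith(tag + "/")]
    if not keys:
        return
    n = len(opt.m)
    opt.load_state_dict({
        "t": int(arrays[f"{tag}/t"]),
        "m": [arrays[f"{tag}/m{i}"] for i in range(n)],
        "v": [arrays[f"{tag}/v{i}"] for i in range(n)],
    })


def train(
    dataset: list[PairedSample],
    cfg: TrainConfig,
    weights: LossWeights | None = None,
    out_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
    progress: bool = False,
) -> tuple[Generator, Discriminator, TrainLog]:
    """Train the translator on preprocessed pairs.

    All pairs must already be on the configured grid with intensities in
    [-1, 1].  Returns the trained networks and the epoch log.  A NaN in
    any loss aborts with a diagnostic naming the epoch and batch.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    weights = weights or LossWeights(alpha1=cfg.alpha1, alpha2=cfg.alpha2)
    e = cfg.extent
    for pair in dataset:
        if pair.pet.shape != (e, e, e):
            raise ValueError(
                f"pair {pair.subject_id!r} has shape {pair.pet.shape}, expected {(e, e, e)}"
            )

    # deterministic split: the tail fraction is held out for validation
    n_val = int(round(cfg.val_fraction * len(dataset)))
    train_pairs = dataset[: len(dataset) - n_val] if n_val else list(dataset)
    val_pairs = dataset[len(dataset) - n_val:] if n_val else []
    if not train_pairs:
        raise ValueError("validation split left no training pairs")

    init_rng = np.random.default_rng(cfg.seed)
    gen, disc = build_models(cfg, init_rng)
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    use_adversarial = cfg.loss_variant != "mse" and weights.alpha1 > 0
    opt_d = nn.Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas) if use_adversarial else None

    rng = np.random.default_rng(cfg.seed + 1)  # shuffling stream
    start_epoch = 0
    if resume_from is not None:
        arrays, meta = load_checkpoint(resume_from)
        gen.load_state_dict({k[4:]: v for k, v in arrays.items() if k.startswith("gen/")})
        disc.load_state_dict({k[5:]: v for k, v in arrays.items() if k.startswith("disc/")})
        _restore_opt(opt_g, arrays, "optg")
        if opt_d is not None:
            _restore_opt(opt_d, arrays, "optd")
        rng.bit_generator.state = meta["rng_state"]
        start_epoch = int(meta["epoch"])

    # Sobel edge channels are a fixed function of the input: compute once
    edges_cache = [edge_channel(p.pet.data[None, None].astype(nn.DTYPE))[0]
                   for p in train_pairs]

    records: list[dict] = []
    best_val = np.inf
    out_dir = Path(out_dir) if out_dir is not None else None
    n_train = len(train_pairs)

    for epoch in range(start_epoch, cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n_train)
        sums = {"loss_d": 0.0, "loss_g_adv": 0.0, "loss_g_l2": 0.0, "hybrid": 0.0}
        n_batches = 0
        n_saturated = 0
        gen.train()
        disc.train()
        for b0 in range(0, n_train, cfg.batch_size):
            idx = order[b0: b0 + cfg.batch_size]
            batch = [train_pairs[i] for i in idx]
            pet_np, mri_np = _stack_batch(batch)
            edges_np = np.stack([edges_cache[i] for i in idx])
            pet, mri = Tensor(pet_np), Tensor(mri_np)
            edges = Tensor(edges_np)

            # generator step
            gen.zero_grad()
            disc.zero_grad()
            fake = gen(pet, edges)
            loss_l2_t = l2_loss(fake, mri)
            if use_adversarial:
                d_fake = disc(pet, fake)
                if cfg.loss_variant == "kl":
                    adv_t = saturating_generator_loss(d_fake)
                else:
                    _, adv_t = adversarial_losses(Tensor(np.ones(1)), d_fake)
                hybrid_t = weights.alpha1 * adv_t + weights.alpha2 * loss_l2_t
            else:
                adv_t = Tensor(np.zeros(()))
                hybrid_t = weights.alpha2 * loss_l2_t
            hybrid_t.backward()
            opt_g.step()

            # discriminator step (on the pre-update fake, detached)
            loss_d_val = 0.0
            if use_adversarial:
                disc.zero_grad()
                d_real = disc(pet, mri)
                d_fake_det = disc(pet, fake.detach())
                loss_d_t, _ = adversarial_losses(d_real, d_fake_det)
                loss_d_t.backward()
                opt_d.step()
                loss_d_val = float(loss_d_t.data)
                if float(d_fake_det.data.mean()) < SATURATION_THRESHOLD:
                    n_saturated += 1

            vals = {
                "loss_d": loss_d_val,
                "loss_g_adv": float(adv_t.data),
                "loss_g_l2": float(loss_l2_t.data),
                "hybrid": float(hybrid_t.data),
            }
            for k, v in vals.items():
                if not np.isfinite(v):
                    raise RuntimeError(
                        f"non-finite {k}={v} at epoch {epoch + 1}, batch {n_batches + 1}"
                    )
                sums[k] += v
            n_batches += 1

        rec = {k: v / n_batches for k, v in sums.items()}
        rec.update(
            epoch=epoch + 1,
            saturated_frac=n_saturated / n_batches if use_adversarial else 0.0,
            wall_time=time.perf_counter() - t0,
        )
        if val_pairs and (
            (epoch + 1) % cfg.checkpoint_every == 0 or epoch + 1 == cfg.epochs
        ):
            rec["val_l2"] = validation_l2(gen, val_pairs)
        records.append(rec)
        if progress:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}  D {rec['loss_d']:.4f}  "
                f"G_adv {rec['loss_g_adv']:.4f}  L2 {rec['loss_g_l2']:.4f}"
            )

        if out_dir is not None and (
            (epoch + 1) % cfg.checkpoint_every == 0 or epoch + 1 == cfg.epochs
        ):
            save_checkpoint(out_dir / f"ckpt_epoch{epoch + 1:05d}.npz",
                            gen, disc, opt_g, opt_d, epoch + 1, rng, cfg)
            if "val_l2" in rec and rec["val_l2"] < best_val:
                best_val = rec["val_l2"]
                save_checkpoint(out_dir / "ckpt_best.npz",
                                gen, disc, opt_g, opt_d, epoch + 1, rng, cfg)

    log = TrainLog(records=records, seed=cfg.seed)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        log.to_frame().to_csv(out_dir / "train_log.tsv", sep="\t", index=False)
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
    return gen, disc, log


def validation_l2(gen: Generator, pairs: list[PairedSample]) -> float:
    """Mean voxelwise squared error of the translator on held-out pairs."""
    gen.eval()
    total = 0.0
    for p in pairs:
        x = p.pet.data[None, None].astype(nn.DTYPE)
        out = gen(Tensor(x), Tensor(edge_channel(x)))
        total += float(((out.data[0, 0] - p.mri.data) ** 2).mean())
    gen.train()
    return total / len(pairs)
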