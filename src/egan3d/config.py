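"""Run configuration and the built-in size profiles.

Two profiles ship with the package:

* ``paper`` — the reference configuration: 90^3 volumes, batch 12,
  1000 epochs, wide decoder/discriminator.  This preserves the method's
  published operating point verbatim.
* ``desk`` — a CPU-feasible configuration (32^3, batch 4, 200 epochs,
  narrow channels) for tests, demos and the scaled-down learning
  experiment.

All hyperparameters remain individually overridable from YAML or
keyword arguments; the profiles are just bundles of defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml


@dataclass
class TrainConfig:
    """Optimisation and architecture settings for one training run."""

    # optimisation (reference defaults)
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 12
    epochs: int = 1000
    init_std: float = 0.02
    seed: int = 0
    device: str = "cpu"
    # geometry / architecture
    extent: int = 90
    branch_channels: int = 8
    channels_2d: int = 16
    decoder_channels: tuple[int, ...] = (64, 32, 16)
    disc_channels: tuple[int, ...] = (64, 128, 256)
    fusion_eps: float = 1e-8
    use_sobel: bool = True
    # objective
    alpha1: float = 1.0
    alpha2: float = 0.5
    loss_variant: str = "mse_jsd"  # mse | kl | mse_jsd
    # bookkeeping
    checkpoint_every: int = 50
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not (0 <= self.betas[0] < 1 and 0 <= self.betas[1] < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_variant not in {"mse", "kl", "mse_jsd"}:
            raise ValueError(f"unknown loss_variant {self.loss_variant!r}")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")


PROFILES: dict[str, dict] = {
    "paper": {},
    "desk": {
        "extent": 32,
        "batch_size": 4,
        "epochs": 200,
        "branch_channels": 4,
        "channels_2d": 8,
        "decoder_channels": (8, 8, 4),
        "disc_channels": (8, 16, 32),
    },
}


def make_config(profile: str = "paper", **overrides) -> TrainConfig:
    """Build a TrainConfig from a named profile plus keyword overrides."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    merged = {**PROFILES[profile], **overrides}
    return TrainConfig(**merged)


def load_config(path: str | Path, profile: str = "paper", **overrides) -> TrainConfig:
    """Load YAML settings on top of a profile; explicit kwargs win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("betas", "decoder_channels", "disc_channels"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return make_config(profile, **{**data, **overrides})


def dump_config(cfg: TrainConfig, path: str | Path):
    """Write the resolved configuration (reproducibility record)."""
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.__dict__.items()}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def with_overrides(cfg: TrainConfig, **kw) -> TrainConfig:
    return replace(cfg, **kw)
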