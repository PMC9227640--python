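"""High-level Model/Results interface to the translator.

:class:`EGAN` is constructed from paired data plus a configuration and
``fit()`` runs the adversarial optimisation, returning
:class:`EGANResults` — the trained networks, the per-epoch history, and
methods to translate new volumes, evaluate against references and print
a summary table.  The lower-level modules (trainer, gan, metrics)
remain usable directly; this class only wires them together.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import TrainConfig, make_config, with_overrides
from .gan import Discriminator, Generator, generator_forward
from .losses import LossWeights
from .metrics import glcm_3d_average, haralick, metrics_report
from .trainer import TrainLog, restore_models_from_checkpoint, train
from .volume import PairedSample, Volume, load_pairs


class EGAN:
    """PET -> MRI translation model over a paired training corpus.

    Parameters
    ----------
    pairs : list of PairedSample
        Preprocessed, co-registered training pairs (values in [-1, 1],
        cubic grid matching ``config.extent``).
    config : TrainConfig, optional
        Architecture and optimisation settings; defaults to the
        reference configuration.
    weights : LossWeights, optional
        Hybrid-objective weights (default alpha1=1, alpha2=0.5).
    """

    def __init__(self, pairs: list[PairedSample], config: TrainConfig | None = None,
                 weights: LossWeights | None = None):
        self.pairs = list(pairs)
        self.config = config or make_config("paper")
        self.weights = weights or LossWeights(self.config.alpha1, self.config.alpha2)

    @classmethod
    def from_manifest(cls, manifest: str | Path, profile: str = "desk", **overrides) -> "EGAN":
        """Build the model from a TSV/CSV manifest of NIfTI paths."""
        cfg = make_config(profile, **overrides)
        return cls(load_pairs(manifest), config=cfg)

    def fit(self, seed: int | None = None, out_dir: str | Path | None = None,
            resume_from: str | Path | None = None, progress: bool = False) -> "EGANResults":
        cfg = self.config if seed is None else with_overrides(self.config, seed=seed)
        gen, disc, log = train(self.pairs, cfg, self.weights, out_dir=out_dir,
                               resume_from=resume_from, progress=progress)
        return EGANResults(self, gen, disc, log, cfg)


class EGANResults:
    """Fitted translator: trained parameters, history and evaluation."""

    def __init__(self, model: EGAN, generator: Generator, discriminator: Discriminator,
                 log: TrainLog, config: TrainConfig):
        self.model = model
        self.generator = generator
        self.discriminator = discriminator
        self.log = log
        self.config = config

    @classmethod
    def from_checkpoint(cls, path: str | Path) -> "EGANResults":
        gen, disc, meta = restore_models_from_checkpoint(path)
        cfg_d = dict(meta["config"])
        for key in ("betas", "decoder_channels", "disc_channels"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = TrainConfig(**cfg_d)
        return cls(model=None, generator=gen, discriminator=disc,
                   log=TrainLog(records=[], seed=cfg.seed), config=cfg)

    # -- inference -----------------------------------------------------------
    def predict(self, pet: Volume) -> Volume:
        """Translate one preprocessed PET volume to a synthetic MRI."""
        return generator_forward(pet, self.generator)

    # -- evaluation ------------------------------------------------------------
    def evaluate(self, pairs: list[PairedSample], texture: bool = False) -> pd.DataFrame:
        """Quality metrics per pair, on the common [0, 1] intensity scale.

        Inputs are preprocessed to [-1, 1] and the generator's tanh output
        lives there too, so the fixed affine map (x + 1) / 2 puts every
        volume on one scale with ``data_range = 1``.
        """
        from .experiments import to_unit_range

        rows = []
        for p in pairs:
            gen_v = self.predict(p.pet)
            g01 = to_unit_range(gen_v)
            r01 = to_unit_range(p.mri)
            rep = metrics_report(g01, r01, data_range=1.0).as_dict()
            rep["subject_id"] = p.subject_id
            if texture:
                hg = haralick(glcm_3d_average(g01))
                hr = haralick(glcm_3d_average(r01))
                for k, v in hg.as_dict().items():
                    rep[f"gen_{k}"] = v
                for k, v in hr.as_dict().items():
                    rep[f"real_{k}"] = v
            rows.append(rep)
        return pd.DataFrame.from_records(rows)

    @property
    def history(self) -> pd.DataFrame:
        return self.log.to_frame()

    def summary(self, eval_pairs: list[PairedSample] | None = None) -> str:
        """Human-readable fit summary (losses; metrics if pairs given)."""
        lines = ["E-GAN translation results", "=" * 41]
        lines.append(f"extent: {self.config.extent}^3   epochs: {self.config.epochs}   "
                     f"batch: {self.config.batch_size}")
        lines.append(f"objective: {self.config.loss_variant}  "
                     f"(alpha1={self.model.weights.alpha1 if self.model else self.config.alpha1}, "
                     f"alpha2={self.model.weights.alpha2 if self.model else self.config.alpha2})")
        hist = self.history
        if len(hist):
            first, last = hist.iloc[0], hist.iloc[-1]
            lines.append(f"generator L2:  epoch 1 = {first.loss_g_l2:.5f}   "
                         f"final = {last.loss_g_l2:.5f}")
            lines.append(f"discriminator loss (final): {last.loss_d:.5f}")
            lines.append(f"saturated-batch fraction (final): {last.saturated_frac:.3f}")
        if eval_pairs:
            df = self.evaluate(eval_pairs)
            lines.append("-" * 41)
            lines.append("held-out metrics (mean over pairs):")
            for k in ("psnr", "ssim", "mae", "xcorr"):
                lines.append(f"  {k:6s} {df[k].mean():8.4f}")
        return "\n".join(lines)

    def plot_history(self, path: str | Path | None = None):
        """Loss curves over epochs (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hist = self.history
        fig, ax = plt.subplots(figsize=(6, 4))
        for col in ("loss_d", "loss_g_adv", "loss_g_l2"):
            ax.plot(hist["epoch"], hist[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
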