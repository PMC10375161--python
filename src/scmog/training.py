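"""Two-phase optimisation of a translator model.

Phase 1 (pre-training) plays the encoder/decoder generator against a
Wasserstein critic on the target modality: the critic takes several RMSProp
steps (with weight clipping) per generator step.  The critic is then
discarded.  Pre-training gives the reconstruction phase a warm start that
already matches the target modality's gross distribution (e.g. peak
sparsity), helping it escape poor local optima.

Phase 2 (training) minimises the direction's reconstruction loss — focal for
rna2atac, negative-binomial NLL for atac2rna, MSE for rna2adt — with Adam
(batch 256, learning rate 0.01), early-stopping on the validation loss and
returning the best-validation checkpoint.

Only training-partition cells ever contribute to a gradient step; validation
cells are used solely for the early-stopping criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from scmog import nn
from scmog.io import SplitAssignment
from scmog.losses import (
    FocalParams,
    NBParamsBatch,
    focal_loss,
    focal_loss_grad,
    mse_grad,
    mse_loss,
    nb_nll,
    nb_nll_grad,
    wasserstein_critic_losses,
)
from scmog.networks import TranslatorModel, make_critic

logger = logging.getLogger(__name__)

LOSS_FOR_DIRECTION = {"rna2atac": "focal", "atac2rna": "nb", "rna2adt": "mse"}


class TrainingDivergence(RuntimeError):
    """A loss became non-finite; carries epoch/batch diagnostics."""


@dataclass
class PretrainConfig:
    optimizer: str = "rmsprop"
    lr: float = 2e-3
    epochs: int = 10
    critic_steps_per_generator_step: int = 5
    weight_clip: float = 0.01
    batch_size: int = 256


@dataclass
class FitConfig:
    optimizer: str = "adam"
    lr: float = 0.01
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 10
    min_rel_improvement: float = 1e-4


@dataclass
class TrainConfig:
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    train: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train.lr <= 0 or self.pretrain.lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.train.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.train.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses for both phases and the best-validation epoch."""

    phase: list[str] = field(default_factory=list)
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float | None] = field(default_factory=list)
    best_epoch: int | None = None

    def record(self, phase: str, epoch: int, train_loss: float, val_loss: float | None) -> None:
        self.phase.append(phase)
        self.epoch.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)

    def best_val_loss(self) -> float:
        vals = [v for p, v in zip(self.phase, self.val_loss) if p == "train" and v is not None]
        return min(vals)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "epoch": self.epoch,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "best_epoch": self.best_epoch,
        }


def _dense(values, idx) -> np.ndarray:
    rows = values[idx]
    if sp.issparse(rows):
        rows = np.asarray(rows.todense())
    return np.asarray(rows, dtype=float)


def _check_finite(loss: float, phase: str, epoch: int, batch: int) -> None:
    if not np.isfinite(loss):
        raise TrainingDivergence(
            f"non-finite loss in {phase} at epoch {epoch}, batch {batch}: {loss}"
        )


def _batches(idx: np.ndarray, batch_size: int, rng: np.random.Generator):
    """Shuffled minibatch index iterator; the last partial batch is kept."""
    order = rng.permutation(len(idx))
    for start in range(0, len(idx), batch_size):
        yield idx[order[start : start + batch_size]]


def _generator_output(model: TranslatorModel, xb: np.ndarray) -> np.ndarray:
    """What the critic sees from the generator: probabilities for ATAC,
    the NB mean for RNA, identity output for protein."""
    out = model.forward(xb)
    if model.direction == "atac2rna":
        return out[0]
    return out


def _generator_backward(model: TranslatorModel, g_out: np.ndarray) -> None:
    if model.direction == "atac2rna":
        g_latent = model.decoder.backward(g_out, np.zeros_like(g_out))
    else:
        g_latent = model.decoder.backward(g_out)
    model.encoder.backward(g_latent)


def pretrain(
    model: TranslatorModel,
    critic,
    source_values,
    target_values,
    split: SplitAssignment,
    cfg: TrainConfig,
) -> tuple[TranslatorModel, TrainHistory]:
    """Adversarial warm start on the training partition.

    ``source_values``/``target_values`` are the processed source and target
    matrices over all cells (cells x features, same cell order as ``split``).
    The critic scores real target rows against generated ones; after each of
    its RMSProp steps every critic weight is clipped to +-weight_clip.
    Returns the model (updated in place) and the pre-training history.
    ``epochs=0`` is an exact no-op.
    """
    pc = cfg.pretrain
    rng = np.random.default_rng(cfg.seed)
    train_idx = split.indices("train")
    if len(train_idx) == 0:
        raise ValueError("empty training partition")
    history = TrainHistory()
    gen_group = nn.ModuleGroup(model.encoder, model.decoder)
    opt_gen = nn.RMSProp(gen_group, lr=pc.lr)
    opt_critic = nn.RMSProp(critic, lr=pc.lr)

    for epoch in range(pc.epochs):
        batches = list(_batches(train_idx, pc.batch_size, rng))
        critic_losses, gen_losses = [], []
        b = 0
        while b < len(batches):
            # critic updates
            for _ in range(pc.critic_steps_per_generator_step):
                idx = batches[b % len(batches)]
                b += 1
                x_src = _dense(source_values, idx)
                x_real = _dense(target_values, idx)
                fake = _generator_output(model, x_src)
                both = np.concatenate([x_real, fake], axis=0)
                scores = critic.forward(both)
                n_r, n_f = len(x_real), len(fake)
                c_loss, _ = wasserstein_critic_losses(scores[:n_r], scores[n_r:])
                _check_finite(c_loss, "pretrain/critic", epoch, b)
                g = np.zeros_like(scores)
                g[:n_r] = -1.0 / n_r
                g[n_r:] = 1.0 / n_f
                critic.backward(g)
                opt_critic.step()
                nn.clip_weights(critic, pc.weight_clip)
                critic_losses.append(c_loss)
            # generator update
            idx = batches[b % len(batches)]
            b += 1
            x_src = _dense(source_values, idx)
            fake = _generator_output(model, x_src)
            scores = critic.forward(fake)
            _, g_loss = wasserstein_critic_losses(np.zeros(1), scores)
            _check_finite(g_loss, "pretrain/generator", epoch, b)
            g_fake = critic.backward(np.full_like(scores, -1.0 / scores.size))
            _generator_backward(model, g_fake)
            opt_gen.step()
            gen_losses.append(g_loss)
        history.record("pretrain", epoch, float(np.mean(critic_losses)), None)
        logger.info(
            "pretrain epoch %d: critic %.4f generator %.4f",
            epoch, np.mean(critic_losses), np.mean(gen_losses),
        )
    return model, history


def _recon_loss_and_grad(model: TranslatorModel, loss_kind: str, xb, yb,
                         focal_params: FocalParams):
    out = model.forward(xb)
    if loss_kind == "focal":
        loss = focal_loss(out, yb, focal_params)
        return loss, (focal_loss_grad(out, yb, focal_params),)
    if loss_kind == "nb":
        mu, theta = out
        params = NBParamsBatch(mu, theta)
        loss = nb_nll(yb, params)
        return loss, nb_nll_grad(yb, params)
    if loss_kind == "mse":
        return mse_loss(out, yb), (mse_grad(out, yb),)
    raise ValueError(f"unknown loss kind {loss_kind!r}")


def _eval_loss(model: TranslatorModel, loss_kind: str, values_src, values_tgt,
               idx: np.ndarray, batch_size: int, focal_params: FocalParams) -> float:
    total, n = 0.0, 0
    for start in range(0, len(idx), batch_size):
        sel = idx[start : start + batch_size]
        xb = _dense(values_src, sel)
        yb = _dense(values_tgt, sel)
        loss, _ = _recon_loss_and_grad(model, loss_kind, xb, yb, focal_params)
        total += loss * yb.size
        n += yb.size
    return total / n


def train(
    model: TranslatorModel,
    source_values,
    target_values,
    split: SplitAssignment,
    cfg: TrainConfig,
    loss_kind: str | None = None,
    focal_params: FocalParams = FocalParams(),
) -> tuple[TranslatorModel, TrainHistory]:
    """Reconstruction training with Adam and validation early stopping.

    ``loss_kind`` defaults to the direction's canonical loss (focal / nb /
    mse).  Stops when the validation loss has not improved (relatively, by
    ``min_rel_improvement``) for ``early_stop_patience`` epochs and restores
    the best-validation parameters before returning.
    """
    fc = cfg.train
    loss_kind = loss_kind or LOSS_FOR_DIRECTION[model.direction]
    rng = np.random.default_rng(cfg.seed + 1)
    train_idx = split.indices("train")
    val_idx = split.indices("validation")
    if len(train_idx) == 0:
        raise ValueError("empty training partition")
    if len(val_idx) == 0:
        raise ValueError("empty validation partition")

    gen_group = nn.ModuleGroup(model.encoder, model.decoder)
    opt = nn.Adam(gen_group, lr=fc.lr)
    history = model.history if isinstance(model.history, TrainHistory) else TrainHistory()

    best_val = np.inf
    best_state = (nn.get_state(model.encoder), nn.get_state(model.decoder))
    best_epoch = 0
    stale = 0
    for epoch in range(fc.max_epochs):
        epoch_losses = []
        for bi, idx in enumerate(_batches(train_idx, fc.batch_size, rng)):
            xb = _dense(source_values, idx)
            yb = _dense(target_values, idx)
            loss, grads = _recon_loss_and_grad(model, loss_kind, xb, yb, focal_params)
            _check_finite(loss, "train", epoch, bi)
            if loss_kind == "nb":
                g_latent = model.decoder.backward(*grads)
            else:
                g_latent = model.decoder.backward(grads[0])
            model.encoder.backward(g_latent)
            opt.step()
            epoch_losses.append(loss)
        val_loss = _eval_loss(
            model, loss_kind, source_values, target_values, val_idx,
            fc.batch_size, focal_params,
        )
        _check_finite(val_loss, "validation", epoch, -1)
        history.record("train", epoch, float(np.mean(epoch_losses)), val_loss)
        logger.info("epoch %d: train %.5f val %.5f", epoch, np.mean(epoch_losses), val_loss)
        if val_loss < best_val * (1.0 - fc.min_rel_improvement):
            best_val = val_loss
            best_state = (nn.get_state(model.encoder), nn.get_state(model.decoder))
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= fc.early_stop_patience:
                break

    nn.set_state(model.encoder, best_state[0])
    nn.set_state(model.decoder, best_state[1])
    history.best_epoch = best_epoch
    model.history = history
    return model, history


def train_no_pretrain(
    model: TranslatorModel,
    source_values,
    target_values,
    split: SplitAssignment,
    cfg: TrainConfig,
    loss_kind: str | None = None,
    focal_params: FocalParams = FocalParams(),
) -> tuple[TranslatorModel, TrainHistory]:
    """The pre-training ablation: reconstruction training from a fresh
    initialisation, identical to :func:`train` in every other respect."""
    return train(model, source_values, target_values, split, cfg,
                 loss_kind=loss_kind, focal_params=focal_params)


def fit_translator(
    model: TranslatorModel,
    source_values,
    target_values,
    split: SplitAssignment,
    cfg: TrainConfig | None = None,
    use_pretrain: bool = True,
) -> tuple[TranslatorModel, TrainHistory]:
    """Convenience wrapper running both phases for one direction."""
    cfg = cfg or TrainConfig()
    if use_pretrain and cfg.pretrain.epochs > 0:
        critic = make_critic(
            model.direction, len(model.target_features), seed=cfg.seed + 17
        )
        model, pre_hist = pretrain(model, critic, source_values, target_values, split, cfg)
        model.history = pre_hist
    return train(model, source_values, target_values, split, cfg)
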