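"""Peptide-disjoint splitting, dataset assembly and the training loop."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import chem, losses
from .encoding import EncodingConfig, encode_batch
from .model import SpectrumTCN
from .nn import Adam, no_grad, set_training

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainingConfig:
    learning_rate: float = 0.02
    epochs: int = 50
    batch_size: int = 32
    mae_weight: float = 1e-3
    aux_weights: dict = field(default_factory=lambda: {
        "tryptic": 0.1, "length": 0.1, "presence": 0.1,
        "composition": 0.1, "pairs": 0.1})
    optimizer: str = "radam"  # or "adam"
    grad_clip: float | None = 5.0
    early_stop_patience: int | None = None
    lr_plateau_factor: float | None = None  # halve-on-plateau style decay
    lr_plateau_patience: int = 1
    lr_decay_epochs: tuple = ()  # deterministic halving schedule (overrides plateau)
    # on-the-fly augmentation of binned intensities (regularization against
    # memorizing exact intensity patterns of the training peptides)
    augment_intensity_sigma: float = 0.0
    augment_noise_lambda: float = 0.0
    regularization_start_epoch: int = 0  # dropout/augmentation off before this
    swa_window: int = 0  # >0: also try averaging the last k epoch weights
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainingConfig":
        cfg = cls(learning_rate=4e-3, epochs=18, batch_size=48,
                  mae_weight=1e-4, early_stop_patience=4,
                  lr_plateau_factor=0.5, lr_plateau_patience=2,
                  augment_intensity_sigma=0.0, augment_noise_lambda=0.0,
                  swa_window=5)
        return replace(cfg, **overrides) if overrides else cfg


def split_by_peptide(peptides: list[str], fractions: tuple[float, ...],
                     seed: int) -> tuple[np.ndarray, ...]:
    """Partition record indices so no peptide string spans two splits.

    All spectra of one peptide land in the same split; split sizes honor
    ``fractions`` up to peptide-group granularity. Deterministic given seed.
    """
    total_frac = sum(fractions)
    if abs(total_frac - 1.0) > 0.01:
        raise ValueError(f"fractions must sum to ~1, got {fractions}")
    fractions = tuple(f / total_frac for f in fractions)
    groups: dict[str, list[int]] = {}
    for i, pep in enumerate(peptides):
        groups.setdefault(pep, []).append(i)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_total = len(peptides)
    counts = [0.0] * len(fractions)
    out: list[list[int]] = [[] for _ in fractions]
    for k in order:
        members = groups[keys[k]]
        # assign the group to the split with the largest remaining deficit
        deficits = [f * n_total - c for f, c in zip(fractions, counts)]
        j = int(np.argmax(deficits))
        out[j].extend(members)
        counts[j] += len(members)
    return tuple(np.array(sorted(ix), dtype=np.int64) for ix in out)


@dataclass
class TrainingData:
    """Encoded spectra with all supervision targets, ready for batching."""

    x: np.ndarray          # (N, L, 4)
    meta: np.ndarray       # (N, 10)
    targets: np.ndarray    # (N, 32) class indices
    mask: np.ndarray       # (N, 32)
    true_masses: np.ndarray
    aux: dict[str, np.ndarray]
    peptides: list[str]

    @classmethod
    def from_records(cls, spectra, peptides: list[str],
                     ecfg: EncodingConfig, n_positions: int = 32) -> "TrainingData":
        x, meta = encode_batch(spectra, ecfg)
        targets, mask = losses.encode_targets(peptides, n_positions)
        masses = np.array([chem.peptide_mono_mass(p) for p in peptides])
        return cls(x=x, meta=meta, targets=targets, mask=mask,
                   true_masses=masses, aux=losses.build_aux_targets(peptides),
                   peptides=list(peptides))

    def __len__(self) -> int:
        return self.x.shape[0]

    def subset(self, idx: np.ndarray) -> "TrainingData":
        return TrainingData(
            x=self.x[idx], meta=self.meta[idx], targets=self.targets[idx],
            mask=self.mask[idx], true_masses=self.true_masses[idx],
            aux={k: v[idx] for k, v in self.aux.items()},
            peptides=[self.peptides[i] for i in idx])


def augment_batch(x: np.ndarray, tcfg: TrainingConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Perturb binned intensities: log-normal jitter on occupied bins plus
    Poisson-count uniform noise bins, then re-normalize to unit maximum.

    Emulates re-drawing the stochastic parts of the fragment intensity
    model each epoch; the m/z channels are untouched and the reversed
    intensity channel is kept consistent.
    """
    if tcfg.augment_intensity_sigma <= 0 and tcfg.augment_noise_lambda <= 0:
        return x
    x = x.copy()
    inten = x[:, :, 0]
    B, L = inten.shape
    if tcfg.augment_intensity_sigma > 0:
        jitter = rng.lognormal(0.0, tcfg.augment_intensity_sigma,
                               inten.shape).astype(np.float32)
        inten *= jitter
    if tcfg.augment_noise_lambda > 0:
        counts = rng.poisson(tcfg.augment_noise_lambda, B)
        for i, k in enumerate(counts):
            if k:
                bins = rng.integers(0, L, k)
                inten[i, bins] = np.maximum(
                    inten[i, bins],
                    rng.uniform(0, 0.05, k).astype(np.float32))
    peak = inten.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    inten /= peak
    x[:, :, 0] = inten
    x[:, :, 2] = inten[:, ::-1]
    return x


@dataclass
class TrainingResult:
    history: list[dict]
    best_epoch: int
    best_val_accuracy: float


def _clip_gradients(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / (norm + 1e-12))
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def validation_accuracy(model: SpectrumTCN, data: TrainingData,
                        batch_size: int = 64) -> float:
    """Average per-position accuracy on non-padding positions."""
    correct, total = 0.0, 0.0
    with no_grad():
        for lo in range(0, len(data), batch_size):
            sl = slice(lo, lo + batch_size)
            probs = model.forward(data.x[sl], data.meta[sl])["probs"].data
            pred = probs.argmax(axis=-1)
            m = data.mask[sl] > 0
            correct += float(((pred == data.targets[sl]) & m).sum())
            total += float(m.sum())
    return correct / max(total, 1.0)


def train(model: SpectrumTCN, train_data: TrainingData, val_data: TrainingData,
          tcfg: TrainingConfig, log_path: str | Path | None = None
          ) -> TrainingResult:
    """Mini-batch training; returns history and restores best-epoch weights.

    The best epoch is chosen by the average accuracy on non-padding
    positions of the validation set.
    """
    rng = np.random.default_rng(tcfg.seed)
    params = model.parameters()
    opt = Adam(params, lr=tcfg.learning_rate,
               rectified=(tcfg.optimizer == "radam"))
    history: list[dict] = []
    best_epoch, best_acc = -1, -1.0
    best_state: list[np.ndarray] | None = None
    recent_states: list[list[np.ndarray]] = []
    n = len(train_data)
    try:
        for epoch in range(tcfg.epochs):
            if epoch in tcfg.lr_decay_epochs:
                opt.lr *= 0.5
                logger.info("scheduled decay: learning rate now %.2e", opt.lr)
            order = rng.permutation(n)
            epoch_components: dict[str, float] = {}
            n_batches = 0
            reg_on = epoch >= tcfg.regularization_start_epoch
            set_training(reg_on)
            for lo in range(0, n, tcfg.batch_size):
                idx = order[lo: lo + tcfg.batch_size]
                x = (augment_batch(train_data.x[idx], tcfg, rng)
                     if reg_on else train_data.x[idx])
                outputs = model.forward(x, train_data.meta[idx])
                loss, comps = losses.total_loss(
                    outputs, train_data.targets[idx], train_data.mask[idx],
                    train_data.true_masses[idx],
                    {k: v[idx] for k, v in train_data.aux.items()},
                    tcfg.mae_weight, tcfg.aux_weights,
                    warn_on_mae_share=(n_batches == 0))
                if not np.isfinite(comps["total"]):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}: {comps}")
                model.zero_grad()
                loss.backward()
                if tcfg.grad_clip is not None:
                    _clip_gradients(params, tcfg.grad_clip)
                opt.step()
                for k, v in comps.items():
                    epoch_components[k] = epoch_components.get(k, 0.0) + v
                n_batches += 1
            set_training(False)
            if tcfg.swa_window > 0:
                recent_states.append([p.copy() for p in model.state_arrays()])
                if len(recent_states) > tcfg.swa_window:
                    recent_states.pop(0)
            row = {k: v / n_batches for k, v in epoch_components.items()}
            row["epoch"] = epoch
            row["val_accuracy"] = validation_accuracy(model, val_data)
            row["lr"] = opt.lr
            history.append(row)
            logger.info("epoch %d: loss %.4f, val positional accuracy %.4f",
                        epoch, row["total"], row["val_accuracy"])
            if row["val_accuracy"] > best_acc:
                best_acc = row["val_accuracy"]
                best_epoch = epoch
                best_state = [p.copy() for p in model.state_arrays()]
            else:
                stale = epoch - best_epoch
                if (tcfg.lr_plateau_factor is not None
                        and not tcfg.lr_decay_epochs
                        and stale >= tcfg.lr_plateau_patience):
                    opt.lr *= tcfg.lr_plateau_factor
                    logger.info("plateau: learning rate reduced to %.2e", opt.lr)
                if (tcfg.early_stop_patience is not None
                        and stale >= tcfg.early_stop_patience):
                    logger.info("early stop at epoch %d (best %d)",
                                epoch, best_epoch)
                    break
    finally:
        set_training(False)
    if tcfg.swa_window > 1 and len(recent_states) > 1:
        # averaged weights of the last epochs sometimes generalize better;
        # keep them only if they win on the validation set
        swa_state = [np.mean([s[i] for s in recent_states], axis=0)
                     for i in range(len(recent_states[0]))]
        model.load_state_arrays(swa_state)
        swa_acc = validation_accuracy(model, val_data)
        logger.info("weight-averaged model (last %d epochs): val %.4f",
                    len(recent_states), swa_acc)
        if swa_acc > best_acc:
            best_acc = swa_acc
            best_state = swa_state
            best_epoch = len(history) - 1
    if best_state is not None:
        model.load_state_arrays(best_state)
    if log_path is not None:
        cols = ["epoch", "total", "masked_ce", "mass_mae", "mae_share",
                "val_accuracy", "lr"] + [
                    c for c in history[0] if c.startswith("aux_")]
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            writer.writeheader()
            writer.writerows(history)
    return TrainingResult(history=history, best_epoch=best_epoch,
                          best_val_accuracy=best_acc)

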