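"""Training targets and the composite loss.

The main objective is the average cross-entropy over non-padding positions
(residues plus the end symbol) of the 32 x 23 probability matrix, plus a
mass term: the mean absolute error between the expected peptide mass under
the predicted per-position distributions and the true peptide mass, with a
weight c kept small enough that c*MAE stays below 10% of the total loss.
Five auxiliary classification/regression heads (tryptic flag, length,
residue presence, composition, adjacent residue pairs) are trained jointly.
"""

from __future__ import annotations

import logging

import numpy as np

from . import chem
from .nn import Tensor, softmax

logger = logging.getLogger(__name__)

N_AA = len(chem.RESIDUES)
AA_INDEX = {a: i for i, a in enumerate(chem.RESIDUES)}


def encode_targets(peptides: list[str], n_positions: int = 32
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Class-index targets and the non-padding mask.

    Position layout per peptide of length n: residues at 0..n-1, the end
    symbol at n, padding beyond. The mask covers positions 0..n inclusive.
    """
    B = len(peptides)
    targets = np.full((B, n_positions), chem.PAD_IDX, dtype=np.int64)
    mask = np.zeros((B, n_positions), dtype=np.float32)
    for i, pep in enumerate(peptides):
        n = len(pep)
        if n + 1 > n_positions:
            raise ValueError(f"peptide {pep!r} too long for {n_positions} positions")
        for j, ch in enumerate(pep):
            targets[i, j] = chem.CLASS_INDEX[ch]
        targets[i, n] = chem.END_IDX
        mask[i, : n + 1] = 1.0
    return targets, mask


def one_hot(targets: np.ndarray, n_classes: int = chem.N_CLASSES) -> np.ndarray:
    out = np.zeros(targets.shape + (n_classes,), dtype=np.float32)
    np.put_along_axis(out, targets[..., None], 1.0, axis=-1)
    return out


def masked_ce_loss(probs: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean -log p(target) over non-padding positions."""
    oh = Tensor(one_hot(targets, probs.shape[-1]))
    p_target = (probs * oh).sum(axis=-1)
    masked = p_target.log() * Tensor(mask)
    return -masked.sum() / float(mask.sum())


def masked_accuracy(probs: np.ndarray, targets: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of non-padding positions whose argmax equals the target."""
    pred = probs.argmax(axis=-1)
    correct = (pred == targets) & (mask > 0)
    return float(correct.sum() / mask.sum())


def mass_mae_loss(probs: Tensor, true_masses: np.ndarray) -> Tensor:
    """MAE between expected peptide mass under ``probs`` and the true mass.

    The expectation sums residue masses weighted by their probabilities over
    all positions (specials carry zero mass) plus water; it is differentiable
    in the probabilities.
    """
    class_mass = Tensor(chem.CLASS_MASS.astype(np.float32))
    expected = (probs * class_mass).sum(axis=(1, 2)) + chem.WATER
    return (expected - Tensor(true_masses.astype(np.float32))).abs().mean()


def build_aux_targets(peptides: list[str]) -> dict[str, np.ndarray]:
    """Per-peptide targets for the five auxiliary tasks."""
    B = len(peptides)
    tryptic = np.zeros((B, 1), dtype=np.float32)
    length = np.zeros(B, dtype=np.int64)
    presence = np.zeros((B, N_AA), dtype=np.float32)
    composition = np.zeros((B, N_AA), dtype=np.float32)
    pairs = np.zeros((B, N_AA * N_AA), dtype=np.float32)
    for i, pep in enumerate(peptides):
        tryptic[i, 0] = 1.0 if pep.endswith(("K", "R")) else 0.0
        length[i] = len(pep) - 1  # classes 0..29 for lengths 1..30
        for ch in pep:
            composition[i, AA_INDEX[ch]] += 1.0
        presence[i] = (composition[i] > 0).astype(np.float32)
        composition[i] /= len(pep)  # normalized by length (scale-comparable)
        for a, b in zip(pep[:-1], pep[1:]):
            pairs[i, AA_INDEX[a] * N_AA + AA_INDEX[b]] = 1.0
    return {"tryptic": tryptic, "length": length,
            "presence": presence, "composition": composition, "pairs": pairs}


def _bce(logits: Tensor, target: np.ndarray) -> Tensor:
    p = logits.sigmoid()
    t = Tensor(target)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def auxiliary_losses(aux_logits: dict[str, Tensor],
                     aux_targets: dict[str, np.ndarray]) -> dict[str, Tensor]:
    """Binary CE for tryptic/presence/pairs, categorical CE for length,
    MSE for (length-normalized) composition."""
    length_oh = one_hot(aux_targets["length"], n_classes=30)
    length_probs = softmax(aux_logits["length"], axis=-1)
    return {
        "tryptic": _bce(aux_logits["tryptic"], aux_targets["tryptic"]),
        "length": -((length_probs * Tensor(length_oh)).sum(axis=-1).log()).mean(),
        "presence": _bce(aux_logits["presence"], aux_targets["presence"]),
        "composition": (aux_logits["composition"]
                        - Tensor(aux_targets["composition"])).square().mean(),
        "pairs": _bce(aux_logits["pairs"], aux_targets["pairs"]),
    }


def total_loss(outputs: dict[str, Tensor], targets: np.ndarray, mask: np.ndarray,
               true_masses: np.ndarray, aux_targets: dict[str, np.ndarray],
               mae_weight: float, aux_weights: dict[str, float],
               warn_on_mae_share: bool = False
               ) -> tuple[Tensor, dict[str, float]]:
    """masked_ce + c * MAE + sum of weighted auxiliary losses.

    Returns the scalar loss tensor and a float breakdown. When requested,
    warns if the mass term exceeds 10% of the total (the weight c should be
    chosen small enough that it never does).
    """
    ce = masked_ce_loss(outputs["probs"], targets, mask)
    mae = mass_mae_loss(outputs["probs"], true_masses)
    total = ce + float(mae_weight) * mae
    components = {"masked_ce": ce.item(), "mass_mae": mae.item()}
    if aux_weights:
        aux = auxiliary_losses(
            {t: outputs[t] for t in aux_weights}, aux_targets)
        for task, w in aux_weights.items():
            if w:
                total = total + float(w) * aux[task]
            components[f"aux_{task}"] = aux[task].item()
    components["total"] = total.item()
    mae_share = mae_weight * components["mass_mae"] / max(components["total"], 1e-12)
    components["mae_share"] = mae_share
    if warn_on_mae_share and mae_share > 0.10:
        logger.warning(
            "mass term is %.1f%% of the total loss (> 10%%); reduce mae_weight",
            100 * mae_share)
    return total, components
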