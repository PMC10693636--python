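"""Accuracy metrics for de novo sequencing results.

Positional accuracy counts predicted residues that match the ground truth
under the prefix-mass alignment convention (residue identity with Leu/Ile
collapsed AND agreement of the aligned prefix masses within a small Da
tolerance), the convention shared by the tools this class of model is
benchmarked against. Peptide-level accuracy requires the whole sequence to
match. Precision-coverage curves rank results by the quality score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .chem import residues_equivalent  # re-exported module surface

PREFIX_MASS_TOL = 0.5  # Da


def peptide_correct(pred: str, truth: str) -> bool:
    """Exact sequence match with I/L equivalence."""
    return len(pred) == len(truth) and all(
        residues_equivalent(a, b) for a, b in zip(pred, truth))


def positional_matches(pred: str, truth: str,
                       mass_tol: float = PREFIX_MASS_TOL,
                       by_index: bool = False) -> int:
    """Number of predicted residues matching the truth.

    Default: prefix-mass alignment — walk both sequences keeping cumulative
    residue masses; when the prefixes agree within ``mass_tol`` the aligned
    residues are compared (I/L collapsed). ``by_index=True`` switches to
    plain position-index comparison.
    """
    if by_index:
        return sum(residues_equivalent(a, b) for a, b in zip(pred, truth))
    i = j = 0
    pm_pred = pm_truth = 0.0
    matched = 0
    while i < len(pred) and j < len(truth):
        if abs(pm_pred - pm_truth) <= mass_tol:
            if residues_equivalent(pred[i], truth[j]):
                matched += 1
            pm_pred += chem.RESIDUE_MASS[pred[i]]
            pm_truth += chem.RESIDUE_MASS[truth[j]]
            i += 1
            j += 1
        elif pm_pred < pm_truth:
            pm_pred += chem.RESIDUE_MASS[pred[i]]
            i += 1
        else:
            pm_truth += chem.RESIDUE_MASS[truth[j]]
            j += 1
    return matched


def positional_accuracy(predictions: list[str], truths: list[str],
                        mass_tol: float = PREFIX_MASS_TOL) -> float:
    """Total matched residues over total ground-truth residues."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    total = sum(len(t) for t in truths)
    if total == 0:
        return 0.0
    matched = sum(positional_matches(p, t, mass_tol)
                  for p, t in zip(predictions, truths))
    return matched / total


def peptide_accuracy(predictions: list[str], truths: list[str]) -> float:
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if not truths:
        return 0.0
    return sum(peptide_correct(p, t)
               for p, t in zip(predictions, truths)) / len(truths)


def filtered_peptide_accuracy(results, truths: dict[str, str],
                              tol_ppm: float = chem.DEFAULT_PPM_TOLERANCE
                              ) -> tuple[float, int]:
    """Peptide accuracy restricted to results within the ppm filter.

    Returns (accuracy, n_filtered); an empty filtered set reports 0.0 with
    n_filtered = 0 rather than NaN.
    """
    kept = [r for r in results if r.ppm_to_precursor <= tol_ppm]
    if not kept:
        return 0.0, 0
    acc = peptide_accuracy([r.peptide for r in kept],
                           [truths[r.spectrum_id] for r in kept])
    return acc, len(kept)


def precision_coverage(results, truths: dict[str, str],
                       thresholds) -> list[tuple[float, float, float]]:
    """(threshold, precision, coverage) per quality-score threshold.

    coverage(t) = #correct with score >= t / #ground-truth spectra;
    precision(t) = #correct with score >= t / #results with score >= t.
    An empty above-threshold set reports precision 1.0 (with coverage 0),
    a documented convention rather than NaN.
    """
    n_truth = len(truths)
    scored = [(r.quality_score, peptide_correct(r.peptide, truths[r.spectrum_id]))
              for r in results]
    curve = []
    for t in sorted(thresholds):
        above = [ok for score, ok in scored if score >= t]
        n_correct = sum(above)
        precision = n_correct / len(above) if above else 1.0
        coverage = n_correct / n_truth if n_truth else 0.0
        curve.append((float(t), float(precision), float(coverage)))
    return curve


def choose_cutoff_for_precision(results, truths: dict[str, str],
                                target_precision: float,
                                thresholds=None) -> float | None:
    """Smallest quality-score cutoff reaching the target precision.

    Candidate cutoffs default to the observed scores. Returns None when no
    cutoff with a non-empty result set reaches the target (as happens for
    weaker models at high precision targets).
    """
    if thresholds is None:
        thresholds = sorted({r.quality_score for r in results})
    curve = precision_coverage(results, truths, thresholds)
    for t, precision, _ in curve:
        n_above = sum(1 for r in results if r.quality_score >= t)
        if n_above > 0 and precision >= target_precision:
            return t
    return None


@dataclass
class EvalReport:
    positional_accuracy: float
    peptide_accuracy: float
    filtered_peptide_accuracy: float
    n_spectra: int
    n_filtered: int
    precision_coverage: list = field(default_factory=list)
    by_length: dict = field(default_factory=dict)
    by_position: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def evaluate(results, truths: dict[str, str],
             thresholds=None,
             tol_ppm: float = chem.DEFAULT_PPM_TOLERANCE) -> EvalReport:
    """Compose the full evaluation report for a result set."""
    results = [r for r in results if r.spectrum_id in truths]
    preds = [r.peptide for r in results]
    trues = [truths[r.spectrum_id] for r in results]
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 21), 3)
    facc, n_filtered = filtered_peptide_accuracy(results, truths, tol_ppm)

    by_length: dict[int, float] = {}
    for n in sorted({len(t) for t in trues}):
        sel = [(p, t) for p, t in zip(preds, trues) if len(t) == n]
        by_length[n] = positional_accuracy([p for p, _ in sel],
                                           [t for _, t in sel])
    max_len = max((len(t) for t in trues), default=0)
    by_position = []
    for pos in range(max_len):
        pairs = [(p, t) for p, t in zip(preds, trues) if len(t) > pos]
        ok = sum(1 for p, t in pairs
                 if len(p) > pos and residues_equivalent(p[pos], t[pos]))
        by_position.append(ok / len(pairs) if pairs else 0.0)

    return EvalReport(
        positional_accuracy=positional_accuracy(preds, trues),
        peptide_accuracy=peptide_accuracy(preds, trues),
        filtered_peptide_accuracy=facc,
        n_spectra=len(results),
        n_filtered=n_filtered,
        precision_coverage=[list(row) for row in
                            precision_coverage(results, truths, thresholds)],
        by_length=by_length,
        by_position=by_position)


def curve_to_csv(curve, path: str | Path) -> None:
    pd.DataFrame(curve, columns=["threshold", "precision", "coverage"]).to_csv(
        path, index=False)


def peak_retention_experiment(spectra, truths: dict[str, str], predict_fn,
                              k_list) -> pd.DataFrame:
    """Re-sequence the same spectra keeping only the top-k peaks, per k.

    ``predict_fn(spectra, top_k)`` must return SequencingResults. k = None
    means all peaks (the baseline). Returns a table with one row per k.
    """
    rows = []
    for k in k_list:
        results = predict_fn(spectra, k)
        preds = [r.peptide for r in results]
        trues = [truths[r.spectrum_id] for r in results]
        rows.append({
            "top_k": "all" if k is None else int(k),
            "positional_accuracy": positional_accuracy(preds, trues),
            "peptide_accuracy": peptide_accuracy(preds, trues),
        })
    return pd.DataFrame(rows)
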