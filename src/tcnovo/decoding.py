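"""Turning a probability matrix into a peptide call.

Greedy decoding picks the argmax class per position until the end symbol
wins; the quality score is the product of the chosen residue probabilities;
and when the decoded peptide's mass disagrees with the precursor by more
than the ppm tolerance, a rescue pass tries replacing one position at a
time with its runner-up residue to recover a matching mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem


@dataclass
class DecodeOutcome:
    sequence: str
    probabilities: list[float]
    failed: bool = False      # START/PAD argmax before END
    truncated: bool = False   # no END within the matrix


@dataclass
class SequencingResult:
    spectrum_id: str
    peptide: str
    positional_probs: list[float] = field(default_factory=list)
    quality_score: float = 0.0
    theoretical_mass: float = 0.0
    ppm_to_precursor: float = float("inf")
    rescued: bool = False
    passed_mass_filter: bool = False
    failed: bool = False
    truncated: bool = False


def _validate_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] != chem.N_CLASSES:
        raise ValueError(f"expected (positions, {chem.N_CLASSES}) matrix, got {m.shape}")
    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-4) or np.any(m < -1e-9):
        raise ValueError("rows must be probability distributions")
    return m


def greedy_decode(matrix: np.ndarray) -> DecodeOutcome:
    """Left-to-right argmax decode, stopping before the first END argmax.

    Ties break toward the lowest class index (numpy argmax convention).
    A START or PAD argmax before END marks the decode as failed; absence of
    END within the matrix truncates the call at 30 residues.
    """
    m = _validate_matrix(matrix)
    seq: list[str] = []
    probs: list[float] = []
    for pos in range(m.shape[0]):
        cls = int(np.argmax(m[pos]))
        if cls == chem.END_IDX:
            return DecodeOutcome("".join(seq), probs)
        if cls in (chem.START_IDX, chem.PAD_IDX):
            return DecodeOutcome("".join(seq), probs, failed=True)
        if len(seq) >= chem.MAX_PEPTIDE_LENGTH:
            return DecodeOutcome("".join(seq), probs, truncated=True)
        seq.append(chem.CLASSES[cls])
        probs.append(float(m[pos, cls]))
    return DecodeOutcome("".join(seq), probs, truncated=True)


def quality_score(positional_probs: list[float]) -> float:
    """Product of the residue probabilities; 0 for an empty decode."""
    if not positional_probs:
        return 0.0
    return float(np.prod(positional_probs))


def _result_from_sequence(spectrum_id: str, seq: str, probs: list[float],
                          precursor_neutral: float, tol_ppm: float,
                          rescued: bool, outcome: DecodeOutcome
                          ) -> SequencingResult:
    mass = chem.peptide_mono_mass(seq) if seq else chem.WATER
    ppm = chem.ppm_difference(mass, precursor_neutral)
    return SequencingResult(
        spectrum_id=spectrum_id, peptide=seq, positional_probs=list(probs),
        quality_score=quality_score(probs), theoretical_mass=mass,
        ppm_to_precursor=ppm, rescued=rescued,
        passed_mass_filter=bool(ppm <= tol_ppm),
        failed=outcome.failed, truncated=outcome.truncated)


def precursor_mass_rescue(matrix: np.ndarray, spectrum_id: str,
                          precursor_neutral: float,
                          tol_ppm: float = chem.DEFAULT_PPM_TOLERANCE
                          ) -> SequencingResult:
    """Greedy decode with single-substitution precursor-mass rescue.

    If the greedy peptide's theoretical mass is within ``tol_ppm`` of the
    precursor neutral mass it is returned as-is. Otherwise each position in
    turn (left to right) is substituted with that column's second-highest
    residue class; the first candidate whose mass matches wins and its
    probability replaces that position's in the quality score. If none
    matches, the greedy peptide is reported with the mass filter flag unset.
    """
    m = _validate_matrix(matrix)
    outcome = greedy_decode(m)
    seq, probs = outcome.sequence, outcome.probabilities
    result = _result_from_sequence(spectrum_id, seq, probs, precursor_neutral,
                                   tol_ppm, rescued=False, outcome=outcome)
    if result.passed_mass_filter or not seq or outcome.failed:
        return result
    residue_block = m[:, : len(chem.RESIDUES)]
    for pos in range(len(seq)):
        col = residue_block[pos]
        order = np.argsort(-col, kind="stable")
        runner_up = int(order[1])  # second-highest residue class
        candidate = seq[:pos] + chem.CLASSES[runner_up] + seq[pos + 1:]
        cand_mass = chem.peptide_mono_mass(candidate)
        if chem.ppm_difference(cand_mass, precursor_neutral) <= tol_ppm:
            new_probs = list(probs)
            new_probs[pos] = float(col[runner_up])
            rescued = _result_from_sequence(
                spectrum_id, candidate, new_probs, precursor_neutral,
                tol_ppm, rescued=True, outcome=outcome)
            return rescued
    return result


def decode_spectrum(matrix: np.ndarray, spectrum_id: str, precursor_mz: float,
                    charge: int, tol_ppm: float = chem.DEFAULT_PPM_TOLERANCE
                    ) -> SequencingResult:
    """Full post-processing for one spectrum given its probability matrix."""
    neutral = chem.precursor_neutral_mass(precursor_mz, charge)
    return precursor_mass_rescue(matrix, spectrum_id, neutral, tol_ppm)
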