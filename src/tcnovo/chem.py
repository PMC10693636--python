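"""Amino-acid alphabet and monoisotopic mass arithmetic.

Everything downstream (spectrum simulation, the mass term of the training
loss, precursor-mass rescue, evaluation) is built on the small set of exact
mass relations defined here: residue masses, b/y fragment m/z, neutral
precursor mass and ppm comparisons.
"""

from __future__ import annotations

import numpy as np

# Monoisotopic constants (Da).
PROTON = 1.00727646688
WATER = 18.0105646863

#: The 20 standard residues, ordered; this order fixes the class indices of
#: the network output (classes 0..19).
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses (Da). Cysteine is unmodified.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Special symbols completing the 23-class output alphabet: a start symbol
# (reserved, never a target), an end-of-peptide symbol and padding.
START, END, PAD = "<", "$", "_"
SPECIALS = (START, END, PAD)

CLASSES = tuple(RESIDUES) + SPECIALS          # 23 classes
N_CLASSES = len(CLASSES)
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}
START_IDX, END_IDX, PAD_IDX = (CLASS_INDEX[s] for s in SPECIALS)

#: Residue mass per class index; specials carry zero mass so that expected
#: mass under a class distribution is well defined.
CLASS_MASS = np.array(
    [RESIDUE_MASS[c] for c in RESIDUES] + [0.0, 0.0, 0.0], dtype=np.float64
)

MAX_PEPTIDE_LENGTH = 30
CHARGE_RANGE = (1, 8)
DEFAULT_PPM_TOLERANCE = 10.0


class InvalidPeptideError(ValueError):
    """Raised for sequences outside the residue alphabet or length limit."""


def validate_peptide(sequence: str, max_length: int = MAX_PEPTIDE_LENGTH) -> str:
    if not isinstance(sequence, str) or len(sequence) == 0:
        raise InvalidPeptideError(f"empty or non-string peptide: {sequence!r}")
    if len(sequence) > max_length:
        raise InvalidPeptideError(
            f"peptide length {len(sequence)} exceeds maximum {max_length}"
        )
    for ch in sequence:
        if ch not in RESIDUE_MASS:
            raise InvalidPeptideError(f"unknown residue {ch!r} in {sequence!r}")
    return sequence


def is_valid_peptide(sequence: str, max_length: int = MAX_PEPTIDE_LENGTH) -> bool:
    try:
        validate_peptide(sequence, max_length)
        return True
    except InvalidPeptideError:
        return False


def peptide_mono_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of a peptide: sum of residues plus water.

    The empty string is accepted for internal prefix arithmetic and maps to
    the mass of water.
    """
    if sequence:
        for ch in sequence:
            if ch not in RESIDUE_MASS:
                raise InvalidPeptideError(f"unknown residue {ch!r}")
    return sum(RESIDUE_MASS[ch] for ch in sequence) + WATER


def prefix_masses(sequence: str) -> np.ndarray:
    """Cumulative residue masses; prefix_masses(p)[i] = mass of p[:i]."""
    masses = np.fromiter(
        (RESIDUE_MASS[ch] for ch in sequence), dtype=np.float64, count=len(sequence)
    )
    out = np.empty(len(sequence) + 1)
    out[0] = 0.0
    np.cumsum(masses, out=out[1:])
    return out


def precursor_neutral_mass(precursor_mz: float, charge: int) -> float:
    """Neutral (uncharged) mass from the observed precursor m/z and charge."""
    lo, hi = CHARGE_RANGE
    if not lo <= charge <= hi:
        raise ValueError(f"charge {charge} outside [{lo}, {hi}]")
    if precursor_mz <= 0:
        raise ValueError(f"non-positive precursor m/z: {precursor_mz}")
    return charge * (precursor_mz - PROTON)


def mz_from_neutral_mass(neutral_mass: float, charge: int) -> float:
    """Inverse of :func:`precursor_neutral_mass` (exact round trip)."""
    lo, hi = CHARGE_RANGE
    if not lo <= charge <= hi:
        raise ValueError(f"charge {charge} outside [{lo}, {hi}]")
    return neutral_mass / charge + PROTON


def ppm_difference(m1: float, m2: float) -> float:
    """Absolute relative mass difference of m1 vs reference m2, in ppm."""
    if m2 <= 0:
        raise ValueError(f"non-positive reference mass: {m2}")
    return abs(m1 - m2) / m2 * 1e6


def fragment_mz(sequence: str, ion_type: str, index: int, frag_charge: int = 1) -> float:
    """m/z of the b- or y-ion at the given cleavage index.

    b_i covers the first ``index`` residues, y_j the last ``index`` residues;
    valid indices are 1..len-1 (internal backbone cleavages).
    """
    n = len(sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} outside [1, {n - 1}]")
    if frag_charge < 1:
        raise ValueError(f"fragment charge must be >= 1, got {frag_charge}")
    if ion_type == "b":
        neutral = sum(RESIDUE_MASS[ch] for ch in sequence[:index])
    elif ion_type == "y":
        neutral = sum(RESIDUE_MASS[ch] for ch in sequence[n - index:]) + WATER
    else:
        raise ValueError(f"unsupported ion type {ion_type!r} (expected 'b' or 'y')")
    return (neutral + frag_charge * PROTON) / frag_charge


def by_ladder(sequence: str, frag_charge: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """All b- and y-ion m/z values (index 1..len-1) at the given charge."""
    pm = prefix_masses(sequence)
    total = pm[-1]
    b = (pm[1:-1] + frag_charge * PROTON) / frag_charge
    y = (total - pm[1:-1] + WATER + frag_charge * PROTON) / frag_charge
    return b, y[::-1]


def residues_equivalent(a: str, b: str) -> bool:
    """Residue identity with Leu and Ile collapsed (isomeric, equal mass)."""
    return a == b or {a, b} == {"I", "L"}
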