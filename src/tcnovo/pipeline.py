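"""High-level glue: run the model over spectra and produce peptide calls."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import chem
from .decoding import SequencingResult, decode_spectrum
from .encoding import EncodingConfig, encode_batch
from .model import SpectrumTCN
from .nn import no_grad


def predict_matrices(model: SpectrumTCN, spectra, ecfg: EncodingConfig,
                     batch_size: int = 64) -> np.ndarray:
    """Probability matrices (N, 32, 23) for a list of spectra."""
    out = []
    with no_grad():
        for lo in range(0, len(spectra), batch_size):
            x, meta = encode_batch(spectra[lo: lo + batch_size], ecfg)
            out.append(model.forward(x, meta)["probs"].data)
    if not out:
        return np.zeros((0, model.cfg.out_positions, model.cfg.n_classes),
                        dtype=np.float32)
    return np.concatenate(out, axis=0)


def sequence_spectra(model: SpectrumTCN, spectra, ecfg: EncodingConfig,
                     batch_size: int = 64,
                     tol_ppm: float = chem.DEFAULT_PPM_TOLERANCE,
                     top_k: int | None = None) -> list[SequencingResult]:
    """De novo sequence spectra: encode, forward, decode with mass rescue."""
    if top_k is not None:
        ecfg = replace(ecfg, top_k_peaks=top_k)
    matrices = predict_matrices(model, spectra, ecfg, batch_size)
    return [
        decode_spectrum(m, s.id, s.precursor_mz, s.charge, tol_ppm)
        for m, s in zip(matrices, spectra)
    ]
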