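"""Spectrum vectorization: the fixed-size input the network consumes.

A spectrum is binned onto a uniform m/z grid (default 0.1 Th over 0-2000,
i.e. 20,000 bins), normalized to unit maximum intensity, zero-padded to
20,480 bins so that five successive factor-2 down-samplings stay integral,
and stacked with a scaled bin-center m/z channel plus the reversed copies
of both channels into a (padded_length, 4) matrix. Precursor charge, m/z
and collision energy travel separately as a small meta vector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .msio import Spectrum

META_LENGTH = 10  # charge one-hot (8) + scaled precursor m/z + NCE/100


@dataclass(frozen=True)
class EncodingConfig:
    bin_width: float = 0.1
    mz_max: float = 2000.0
    padded_length: int = 20480
    precursor_removal_window: float = 1.5
    top_k_peaks: int | None = None
    bin_collision: str = "max"  # or "sum"

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.mz_max <= 0:
            raise ValueError("bin_width and mz_max must be positive")
        if self.padded_length < self.n_bins:
            raise ValueError(
                f"padded_length {self.padded_length} < number of bins {self.n_bins}"
            )
        if self.padded_length % 32 != 0:
            raise ValueError("padded_length must be divisible by 2^5")
        if self.bin_collision not in ("max", "sum"):
            raise ValueError(f"unknown bin_collision {self.bin_collision!r}")

    @property
    def n_bins(self) -> int:
        return int(round(self.mz_max / self.bin_width))

    @classmethod
    def desk_scale(cls, **overrides) -> "EncodingConfig":
        """Coarse 1 Th grid (2048-bin input) for CPU-scale experiments."""
        cfg = cls(bin_width=1.0, mz_max=2000.0, padded_length=2048)
        return replace(cfg, **overrides) if overrides else cfg


def remove_precursor_peaks(s: Spectrum, window: float) -> Spectrum:
    """Drop every peak within ``window`` Th of the precursor m/z."""
    if window <= 0:
        raise ValueError("window must be positive")
    keep = np.abs(s.mz - s.precursor_mz) > window
    return Spectrum(
        id=s.id, mz=s.mz[keep], intensity=s.intensity[keep],
        precursor_mz=s.precursor_mz, charge=s.charge,
        retention_time=s.retention_time, collision_energy=s.collision_energy,
    )


def retain_top_k(s: Spectrum, k: int) -> Spectrum:
    """Keep only the k most intense peaks (ties at rank k: lower m/z wins)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if s.n_peaks <= k:
        return s
    # sort by (-intensity, mz): stable deterministic tie-break at the cut
    order = np.lexsort((s.mz, -s.intensity))[:k]
    keep = np.sort(order)
    return Spectrum(
        id=s.id, mz=s.mz[keep], intensity=s.intensity[keep],
        precursor_mz=s.precursor_mz, charge=s.charge,
        retention_time=s.retention_time, collision_energy=s.collision_energy,
    )


def bin_and_normalize(s: Spectrum, cfg: EncodingConfig) -> np.ndarray:
    """Binned, max-normalized intensity vector of length ``padded_length``.

    Bins are half-open [i*w, (i+1)*w); peaks at or above mz_max are
    discarded; colliding peaks within a bin take the maximum (or sum,
    per config); the vector is divided by its global maximum. An empty
    spectrum yields the zero vector.
    """
    vec = np.zeros(cfg.padded_length, dtype=np.float32)
    keep = (s.mz >= 0) & (s.mz < cfg.mz_max)
    if not np.any(keep):
        return vec
    idx = np.floor(s.mz[keep] / cfg.bin_width).astype(np.int64)
    inten = s.intensity[keep].astype(np.float32)
    if cfg.bin_collision == "max":
        np.maximum.at(vec, idx, inten)
    else:
        np.add.at(vec, idx, inten)
    peak = vec.max()
    if peak > 0:
        vec /= peak
    return vec


def mz_channel(cfg: EncodingConfig) -> np.ndarray:
    """Bin-center m/z scaled to [0,1] by mz_max; zero in the padding tail."""
    ch = np.zeros(cfg.padded_length, dtype=np.float32)
    n = cfg.n_bins
    ch[:n] = (np.arange(n, dtype=np.float32) + 0.5) * cfg.bin_width / cfg.mz_max
    return ch


def build_input_matrix(intensities: np.ndarray, cfg: EncodingConfig) -> np.ndarray:
    """Stack intensity and m/z channels with their reversals: (P, 4)."""
    if intensities.shape != (cfg.padded_length,):
        raise ValueError(
            f"intensity vector shape {intensities.shape} != ({cfg.padded_length},)"
        )
    mz = mz_channel(cfg)
    return np.stack(
        [intensities, mz, intensities[::-1], mz[::-1]], axis=1
    ).astype(np.float32)


def build_meta_vector(s: Spectrum, cfg: EncodingConfig) -> np.ndarray:
    """Charge one-hot (1..8), scaled precursor m/z, NCE/100 (0 if unknown)."""
    meta = np.zeros(META_LENGTH, dtype=np.float32)
    meta[s.charge - 1] = 1.0
    meta[8] = s.precursor_mz / cfg.mz_max
    meta[9] = (s.collision_energy or 0.0) / 100.0
    return meta


def encode_spectrum(s: Spectrum, cfg: EncodingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: precursor removal, optional top-k, binning, stacking."""
    s = remove_precursor_peaks(s, cfg.precursor_removal_window)
    if cfg.top_k_peaks is not None:
        s = retain_top_k(s, cfg.top_k_peaks)
    vec = bin_and_normalize(s, cfg)
    return build_input_matrix(vec, cfg), build_meta_vector(s, cfg)


def encode_batch(spectra, cfg: EncodingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Encode a list of spectra into (N, P, 4) and (N, 10) arrays."""
    mats, metas = [], []
    for s in spectra:
        m, v = encode_spectrum(s, cfg)
        mats.append(m)
        metas.append(v)
    n = len(mats)
    if n == 0:
        return (np.zeros((0, cfg.padded_length, 4), dtype=np.float32),
                np.zeros((0, META_LENGTH), dtype=np.float32))
    return np.stack(mats), np.stack(metas)
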