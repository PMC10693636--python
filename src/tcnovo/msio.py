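"""Reading and writing spectra, ground truth and sequencing results.

MGF is the canonical interchange format; mzML is supported as a thin
read-only adapter. Ground truth is a two-column TSV mapping spectrum id to
peptide. All parsing of the standard formats is delegated to pyteomics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import base64
import struct
import zlib

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

from . import chem

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with its precursor information."""

    id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    charge: int
    retention_time: float | None = None
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.precursor_mz <= 0:
            raise ValueError(f"non-positive precursor m/z: {self.precursor_mz}")
        lo, hi = chem.CHARGE_RANGE
        if not lo <= self.charge <= hi:
            raise ValueError(f"charge {self.charge} outside [{lo}, {hi}]")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            # enforce the sorted-peaks invariant on ingest
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def precursor_neutral_mass(self) -> float:
        return chem.precursor_neutral_mass(self.precursor_mz, self.charge)


@dataclass
class IngestStats:
    """Counters for records dropped while reading a file."""

    read: int = 0
    skipped: int = 0
    reasons: dict = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def read_mgf(path: str | Path, stats: IngestStats | None = None) -> Iterator[Spectrum]:
    """Yield spectra from an MGF file in file order.

    Records missing PEPMASS or CHARGE, or with charge outside 1..8, are
    skipped with a logged warning and counted in ``stats``.
    """
    stats = stats if stats is not None else IngestStats()
    with _mgf.MGF(str(path)) as reader:
        for i, rec in enumerate(reader):
            params = rec.get("params", {})
            title = str(params.get("title", f"index={i}"))
            pepmass = params.get("pepmass")
            charge_list = params.get("charge")
            if pepmass is None or not pepmass or pepmass[0] in (None, 0):
                logger.warning("MGF record %s: missing PEPMASS, skipped", title)
                stats.skip("missing_pepmass")
                continue
            if not charge_list:
                logger.warning("MGF record %s: missing CHARGE, skipped", title)
                stats.skip("missing_charge")
                continue
            charge = int(charge_list[0])
            lo, hi = chem.CHARGE_RANGE
            if not lo <= charge <= hi:
                logger.warning("MGF record %s: charge %d out of range, skipped",
                               title, charge)
                stats.skip("charge_out_of_range")
                continue
            rt = params.get("rtinseconds")
            nce = params.get("nce") or params.get("collision_energy")
            try:
                spec = Spectrum(
                    id=title,
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    retention_time=float(rt) if rt is not None else None,
                    collision_energy=float(nce) if nce is not None else None,
                )
            except (ValueError, KeyError) as exc:
                logger.warning("MGF record %s: %s, skipped", title, exc)
                stats.skip("invalid_record")
                continue
            stats.read += 1
            yield spec


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (TITLE/PEPMASS/CHARGE/RTINSECONDS dialect)."""
    records = []
    for s in spectra:
        params = {
            "title": s.id,
            "pepmass": s.precursor_mz,
            "charge": f"{s.charge}+",
        }
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        if s.collision_energy is not None:
            params["nce"] = s.collision_energy
        records.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(path, "w") as fh:
        _mgf.write(records, fh, key_order=["title", "pepmass", "charge", "rtinseconds", "nce"])


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions for the narrow mzML subset this adapter reads
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv_accessions(element) -> dict[str, str]:
    return {cv.get("accession"): cv.get("value", "")
            for cv in element.iter(_MZML_NS + "cvParam")}


def _decode_binary_array(array_element) -> tuple[str | None, np.ndarray]:
    acc = _cv_accessions(array_element)
    binary = array_element.find(_MZML_NS + "binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _ACC_ZLIB in acc:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in acc else "<f8"
    kind = ("mz" if _ACC_MZ_ARRAY in acc
            else "intensity" if _ACC_INT_ARRAY in acc else None)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path: str | Path, stats: IngestStats | None = None) -> Iterator[Spectrum]:
    """Yield MS2 spectra from an mzML file (centroided peaks assumed).

    A deliberately narrow reader for the mzML subset de novo pipelines
    consume: MS-level-2 spectra with uncompressed or zlib float32/float64
    peak arrays and a selected-ion precursor with a charge state.
    """
    stats = stats if stats is not None else IngestStats()
    for _, elem in etree.iterparse(str(path), tag=_MZML_NS + "spectrum"):
        sid = str(elem.get("id", ""))
        acc = _cv_accessions(elem)
        if acc.get(_ACC_MS_LEVEL) != "2":
            elem.clear()
            continue
        if _ACC_PROFILE in acc:
            logger.warning("mzML spectrum %s is profile mode; passing through", sid)
        ion = elem.find(".//" + _MZML_NS + "selectedIon")
        ion_acc = _cv_accessions(ion) if ion is not None else {}
        if _ACC_SELECTED_MZ not in ion_acc or _ACC_CHARGE not in ion_acc:
            logger.warning("mzML spectrum %s: missing precursor info, skipped", sid)
            stats.skip("missing_precursor")
            elem.clear()
            continue
        pre_mz = float(ion_acc[_ACC_SELECTED_MZ])
        charge = int(ion_acc[_ACC_CHARGE])
        lo, hi = chem.CHARGE_RANGE
        if not lo <= charge <= hi:
            logger.warning("mzML spectrum %s: charge %d unusable, skipped", sid, charge)
            stats.skip("charge_out_of_range")
            elem.clear()
            continue
        arrays: dict[str, np.ndarray] = {}
        for arr in elem.iter(_MZML_NS + "binaryDataArray"):
            kind, values = _decode_binary_array(arr)
            if kind:
                arrays[kind] = values
        try:
            spec = Spectrum(
                id=sid, mz=arrays["mz"], intensity=arrays["intensity"],
                precursor_mz=pre_mz, charge=charge)
        except (ValueError, KeyError) as exc:
            logger.warning("mzML spectrum %s: %s, skipped", sid, exc)
            stats.skip("invalid_record")
            elem.clear()
            continue
        stats.read += 1
        elem.clear()
        yield spec


def read_ground_truth(path: str | Path, stats: IngestStats | None = None) -> dict[str, str]:
    """Read a ``spectrum_id<TAB>peptide`` table, validating every peptide.

    Rows whose peptide fails alphabet/length validation are dropped with a
    warning, mirroring the dataset construction (charges 1-8, length <= 30).
    """
    stats = stats if stats is not None else IngestStats()
    table: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["spectrum_id", "peptide"],
                     dtype=str, comment="#")
    for sid, pep in zip(df["spectrum_id"], df["peptide"]):
        if not chem.is_valid_peptide(str(pep)):
            logger.warning("ground truth %s: invalid peptide %r, dropped", sid, pep)
            stats.skip("invalid_peptide")
            continue
        table[str(sid)] = str(pep)
        stats.read += 1
    return table


def write_ground_truth(table: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, pep in table.items():
            fh.write(f"{sid}\t{pep}\n")


RESULT_COLUMNS = [
    "spectrum_id", "peptide", "quality_score", "theoretical_mass",
    "ppm_to_precursor", "rescued", "passed_mass_filter", "positional_probs",
]


def write_results(results: Iterable, path: str | Path) -> None:
    """Write sequencing results as TSV (one row per spectrum, input order)."""
    rows = []
    for r in results:
        rows.append({
            "spectrum_id": r.spectrum_id,
            "peptide": r.peptide,
            "quality_score": f"{r.quality_score:.6f}",
            "theoretical_mass": f"{r.theoretical_mass:.6f}",
            "ppm_to_precursor": f"{r.ppm_to_precursor:.6f}",
            "rescued": int(r.rescued),
            "passed_mass_filter": int(r.passed_mass_filter),
            "positional_probs": ";".join(f"{p:.6f}" for p in r.positional_probs),
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV; probabilities are parsed to float lists."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str})
    df["peptide"] = df["peptide"].fillna("")
    df["rescued"] = df["rescued"].astype(bool)
    df["passed_mass_filter"] = df["passed_mass_filter"].astype(bool)
    df["positional_probs"] = [
        [float(x) for x in str(s).split(";")] if isinstance(s, str) and s else []
        for s in df["positional_probs"].fillna("")
    ]
    return df
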