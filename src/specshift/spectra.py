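"""Reading spectra (MGF/mzML) and PSM tables; writing the result table.

Spectra are read through pyteomics.  A spectrum is identified by its MGF
TITLE (or mzML spectrum id); PSM tables referring to spectra by an integer
are resolved against the 0-based position of the spectrum in the file.
Intensities are carried along but never influence the alignment — they feed
only the explained-intensity report.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import base64
import struct
import zlib

import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

from specshift.masses import VALID_RESIDUES

logger = logging.getLogger(__name__)

#: Default PSM-table column names (configurable; the input format does not
#: standardize them).
DEFAULT_SPECTRUM_COLUMN = "spectrum"
DEFAULT_PEPTIDE_COLUMN = "peptide"
DEFAULT_DELTA_COLUMN = "deltaM"

RESULT_COLUMNS = [
    "spectrum",
    "peptide",
    "deltaM",
    "preAlignedPeptide",
    "alignedPeptide",
    "sharedPeaksBefore",
    "sharedPeaksAfter",
    "intensityExplained",
    "score",
]


@dataclass(frozen=True)
class Spectrum:
    """An experimental MS2 spectrum: precursor descriptor plus peak list.

    Peaks are sorted strictly ascending by m/z; duplicate m/z values are
    collapsed keeping the highest intensity.
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.precursor_charge}")

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def total_intensity(self) -> float:
        return sum(p[1] for p in self.peaks)


@dataclass(frozen=True)
class PSMRequest:
    """One peptide-to-spectrum match to align: spectrum id, peptide, optional ΔM."""

    spectrum_id: str
    peptide: str
    delta_m: float | None = None


@dataclass
class ResultRow:
    """One output line: the request plus both alignment strings and metrics."""

    spectrum_id: str
    peptide: str
    delta_m: float
    pre_aligned: str
    aligned: str
    shared_before: int
    shared_after: int
    intensity_explained: float
    score: int
    error: str | None = None


def _clean_peaks(mzs: Iterable[float], intensities: Iterable[float]) -> tuple[tuple[float, float], ...]:
    """Sort ascending and collapse duplicate m/z keeping the max intensity."""
    best: dict[float, float] = {}
    for mz, it in zip(mzs, intensities):
        if mz <= 0:
            continue
        mz = float(mz)
        it = float(it)
        if mz not in best or it > best[mz]:
            best[mz] = it
    return tuple(sorted(best.items()))


def _read_mgf(path: str) -> dict[str, Spectrum]:
    out: dict[str, Spectrum] = {}
    index = 0
    with _mgf.MGF(path) as reader:
        for entry in reader:
            params = entry.get("params", {})
            title = str(params.get("title", index))
            pepmass = params.get("pepmass")
            charge = params.get("charge")
            if pepmass is None or not pepmass or pepmass[0] is None or not charge:
                logger.warning("spectrum %r lacks precursor information; skipped", title)
                index += 1
                continue
            spec = Spectrum(
                id=title,
                precursor_mz=float(pepmass[0]),
                precursor_charge=abs(int(charge[0])),
                peaks=_clean_peaks(entry["m/z array"], entry["intensity array"]),
            )
            out[spec.id] = spec
            out.setdefault(str(index), spec)
            index += 1
    return out


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _decode_binary_array(node) -> list[float]:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or none)."""
    fmt = "d"
    compressed = False
    payload = b""
    for cv in node.iter():
        if _local(cv.tag) == "cvParam":
            acc = cv.get("accession", "")
            if acc == "MS:1000521":
                fmt = "f"
            elif acc == "MS:1000574":
                compressed = True
        elif _local(cv.tag) == "binary" and cv.text:
            payload = base64.b64decode(cv.text.strip())
    if compressed:
        payload = zlib.decompress(payload)
    width = struct.calcsize(fmt)
    count = len(payload) // width
    return list(struct.unpack(f"<{count}{fmt}", payload[: count * width]))


def _read_mzml(path: str) -> dict[str, Spectrum]:
    # parsed directly with lxml: the mzML cvParams used are ms level
    # (MS:1000511), selected ion m/z (MS:1000744), charge state (MS:1000041),
    # and the m/z / intensity binary arrays (MS:1000514 / MS:1000515)
    out: dict[str, Spectrum] = {}
    index = 0
    for _, node in etree.iterparse(path, events=("end",)):
        if _local(node.tag) != "spectrum":
            continue
        sid = node.get("id", str(index))
        ms_level = None
        mz = charge = None
        mzs: list[float] = []
        intensities: list[float] = []
        for child in node.iter():
            tag = _local(child.tag)
            if tag == "cvParam" and child.get("accession") == "MS:1000511":
                ms_level = int(child.get("value"))
            elif tag == "selectedIon":
                for cv in child:
                    if cv.get("accession") == "MS:1000744":
                        mz = float(cv.get("value"))
                    elif cv.get("accession") == "MS:1000041":
                        charge = int(cv.get("value"))
            elif tag == "binaryDataArray":
                accs = {cv.get("accession") for cv in child if _local(cv.tag) == "cvParam"}
                if "MS:1000514" in accs:
                    mzs = _decode_binary_array(child)
                elif "MS:1000515" in accs:
                    intensities = _decode_binary_array(child)
        if ms_level == 2:
            if mz is None or charge is None or charge < 1:
                logger.warning("MS2 spectrum %r lacks precursor information; skipped", sid)
            else:
                spec = Spectrum(
                    id=sid,
                    precursor_mz=mz,
                    precursor_charge=charge,
                    peaks=_clean_peaks(mzs, intensities or [0.0] * len(mzs)),
                )
                out[spec.id] = spec
                out.setdefault(str(index), spec)
        index += 1
        node.clear()
    return out


def read_spectra(path: str, format: str = "auto") -> dict[str, Spectrum]:
    """Read MS2 spectra from an MGF or mzML file.

    Returns a mapping from spectrum id to :class:`Spectrum`; each spectrum is
    additionally reachable under its 0-based position in the file (as a
    string) so PSM tables may refer to spectra by index.  Spectra without a
    usable precursor are skipped with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"spectra file not found: {path}")
    if format == "auto":
        lower = path.lower()
        format = "mzml" if lower.endswith(".mzml") else "mgf"
    if format == "mgf":
        return _read_mgf(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown spectra format {format!r} (expected mgf, mzml or auto)")


def read_psm_table(
    path: str,
    delimiter: str = ";",
    spectrum_column: str = DEFAULT_SPECTRUM_COLUMN,
    peptide_column: str = DEFAULT_PEPTIDE_COLUMN,
    delta_column: str = DEFAULT_DELTA_COLUMN,
) -> list[PSMRequest]:
    """Read a delimited PSM table into :class:`PSMRequest` rows, in file order.

    The header must name the spectrum-id and peptide columns; a ΔM column is
    optional (ΔM is recomputed from the precursor when absent).  Rows whose
    peptide contains a non-standard residue are rejected with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"PSM table not found: {path}")
    table = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in (spectrum_column, peptide_column):
        if col not in table.columns:
            raise ValueError(
                f"PSM table {path!r} is missing mandatory column {col!r} "
                f"(found: {list(table.columns)})"
            )
    has_delta = delta_column in table.columns
    requests: list[PSMRequest] = []
    for _, row in table.iterrows():
        peptide = str(row[peptide_column]).strip().upper()
        bad = set(peptide) - VALID_RESIDUES
        if not peptide or bad:
            logger.warning(
                "rejecting PSM for spectrum %r: peptide %r contains non-standard residues %s",
                row[spectrum_column], peptide, sorted(bad),
            )
            continue
        dm: float | None = None
        if has_delta and pd.notna(row[delta_column]) and str(row[delta_column]).strip():
            dm = float(row[delta_column])
        requests.append(PSMRequest(spectrum_id=str(row[spectrum_column]).strip(), peptide=peptide, delta_m=dm))
    return requests


def write_results(path: str, rows: Iterable[ResultRow]) -> None:
    """Write the result table as comma-delimited CSV, one line per PSM in order."""
    records = []
    for r in rows:
        records.append(
            {
                "spectrum": r.spectrum_id,
                "peptide": r.peptide,
                "deltaM": round(r.delta_m, 5),
                "preAlignedPeptide": r.pre_aligned,
                "alignedPeptide": r.aligned,
                "sharedPeaksBefore": r.shared_before,
                "sharedPeaksAfter": r.shared_after,
                "intensityExplained": round(r.intensity_explained, 5),
                "score": r.score,
                "error": r.error or "",
            }
        )
    frame = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS + ["error"])
    frame.to_csv(path, index=False)


def read_results(path: str) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    return pd.read_csv(path, keep_default_na=False, dtype={"preAlignedPeptide": str, "alignedPeptide": str})
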