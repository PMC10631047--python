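"""Spectrum completion: add complementary peaks so y-ion evidence appears in
b-ion coordinates.

Fragmentation of a doubly charged precursor splits each backbone bond into a
b-ion and a y-ion whose singly protonated masses sum to MH+ + proton.  Since
the aligner models a peptide only by its b-ions, every observed peak is also
hypothesized to be a y-ion: a "complementary" peak at ``MH+ + proton − mz`` is
added for it.  When both ions of a cleavage were observed, the complementary
image of one lands on the other and the two merge into a single peak flagged
``both`` — completion then adds nothing.  The evidence flag (both vs. single
ion) later selects the strong or weak alignment scores.

A virtual anchor peak at m/z = proton (the "b0" position) is prepended so the
first residue has a left partner to align from; a matching virtual peak at
MH+ minus water (the "bn" position implied by the precursor measurement) is
appended so the last residue has a right partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from specshift.masses import PROTON, WATER, precursor_mh
from specshift.spectra import Spectrum

logger = logging.getLogger(__name__)

DEFAULT_MERGE_TOL = 0.01


class Evidence(str, Enum):
    NATIVE = "native"
    COMPLEMENTARY = "complementary"
    BOTH = "both"


@dataclass(frozen=True)
class CompletedPeak:
    mz: float
    evidence: Evidence
    #: indices into the native peak list that support this peak (directly or
    #: through their complementary image); empty for the virtual anchor.
    source_indices: tuple[int, ...]
    is_anchor: bool = False


@dataclass(frozen=True)
class CompletedSpectrum:
    source: Spectrum
    mh: float
    peaks: tuple[CompletedPeak, ...]

    def __len__(self) -> int:
        return len(self.peaks)


def complementary_mass(peak_mz: float, mh: float) -> float:
    """Complementary fragment mass: ``mh + proton − peak_mz``.

    ``mh`` is the singly protonated precursor mass MH+.  The map is an
    involution: applying it twice returns the original m/z.
    """
    if peak_mz <= 0:
        raise ValueError(f"peak m/z must be positive, got {peak_mz}")
    return mh + PROTON - peak_mz


def complete_spectrum(spectrum: Spectrum, merge_tol: float = DEFAULT_MERGE_TOL) -> CompletedSpectrum:
    """Transform a spectrum into its completed form.

    Every native peak contributes itself plus its complementary image; pairs
    closer than ``merge_tol`` merge into one ``both``-evidence peak kept at
    the native m/z (experimental evidence preferred over inferred).
    Complementary masses that come out non-positive are dropped.
    """
    mh = precursor_mh(spectrum.precursor_mz, spectrum.precursor_charge)
    native_mzs = [p[0] for p in spectrum.peaks]

    # entries: mz -> (evidence, sources); start from native peaks + anchor
    entries: list[dict] = [
        {"mz": mz, "evidence": Evidence.NATIVE, "sources": {i}, "anchor": False}
        for i, mz in enumerate(native_mzs)
    ]
    # virtual b0 anchor and bn terminus (MH+ - water), both implied by the
    # precursor measurement alone and therefore flagged as dual evidence;
    # a native peak within merge_tol of either absorbs it
    bn = mh - WATER
    if not any(abs(mz - PROTON) <= merge_tol for mz in native_mzs):
        entries.append({"mz": PROTON, "evidence": Evidence.BOTH, "sources": set(), "anchor": True})
    else:
        for e in entries:
            if abs(e["mz"] - PROTON) <= merge_tol:
                e["anchor"] = True
                break
    for e in entries:
        if abs(e["mz"] - bn) <= merge_tol:
            e["evidence"] = Evidence.BOTH
            break
    else:
        entries.append({"mz": bn, "evidence": Evidence.BOTH, "sources": set(), "anchor": False})
    entries.sort(key=lambda e: e["mz"])

    def nearest(mz: float) -> dict | None:
        best, bestd = None, merge_tol
        for e in entries:
            d = abs(e["mz"] - mz)
            if d <= bestd:
                best, bestd = e, d
        return best

    comp_only: list[dict] = []
    for i, mz in enumerate(native_mzs):
        comp = complementary_mass(mz, mh)
        if comp <= 0:
            logger.debug("complementary mass of peak %.4f is non-positive; dropped", mz)
            continue
        hit = nearest(comp)
        if hit is not None:
            # complementary image lands on an existing peak: upgrade evidence
            if not hit["anchor"]:
                hit["evidence"] = Evidence.BOTH
            hit["sources"].add(i)
            continue
        # merge with an earlier complementary-only peak if within tolerance
        merged = False
        for e in comp_only:
            if abs(e["mz"] - comp) <= merge_tol:
                e["sources"].add(i)
                merged = True
                break
        if not merged:
            comp_only.append({"mz": comp, "evidence": Evidence.COMPLEMENTARY, "sources": {i}, "anchor": False})

    entries.extend(comp_only)
    entries.sort(key=lambda e: e["mz"])
    peaks = tuple(
        CompletedPeak(
            mz=e["mz"],
            evidence=e["evidence"],
            source_indices=tuple(sorted(e["sources"])),
            is_anchor=e["anchor"],
        )
        for e in entries
    )
    return CompletedSpectrum(source=spectrum, mh=mh, peaks=peaks)
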