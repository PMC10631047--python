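"""End-to-end alignment of one peptide-to-spectrum match."""

from __future__ import annotations

from dataclasses import dataclass

from specshift.align import (
    DEFAULT_FRAGMENT_TOL,
    RawAlignment,
    ScoringScheme,
    fill_matrix,
    format_alignment,
    traceback,
)
from specshift.completion import DEFAULT_MERGE_TOL, complete_spectrum
from specshift.masses import b_ion_series, delta_m
from specshift.postprocess import FinalAlignment, intensity_explained, refine
from specshift.spectra import ResultRow, Spectrum


@dataclass
class AlignmentOutcome:
    raw: RawAlignment
    final: FinalAlignment
    row: ResultRow


def align_psm(
    spectrum: Spectrum,
    peptide: str,
    scheme: ScoringScheme = ScoringScheme(),
    frag_tol: float = DEFAULT_FRAGMENT_TOL,
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> AlignmentOutcome:
    """Align a candidate peptide against a spectrum and refine the result.

    Runs completion, matrix fill, traceback and post-processing, and returns
    the raw and final alignments together with the formatted result row.
    """
    model = b_ion_series(peptide)
    dm = delta_m(spectrum.precursor_mz, spectrum.precursor_charge, model)
    sec = complete_spectrum(spectrum, merge_tol)
    matrix = fill_matrix(model, sec, scheme, frag_tol)
    raw = traceback(matrix)
    residual = dm - raw.shift_sum
    pre_aligned = format_alignment(raw, residual if abs(residual) > frag_tol else None)
    final = refine(raw, model, spectrum, frag_tol)
    final.intensity_explained = intensity_explained(model, final, spectrum, frag_tol)
    row = ResultRow(
        spectrum_id=spectrum.id,
        peptide=peptide,
        delta_m=dm,
        pre_aligned=pre_aligned,
        aligned=final.aligned_string,
        shared_before=final.shared_before,
        shared_after=final.shared_after,
        intensity_explained=final.intensity_explained,
        score=raw.score,
    )
    return AlignmentOutcome(raw=raw, final=final, row=row)
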