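"""Shared fixtures: programmatic spectrum builders and the two worked examples."""

from __future__ import annotations

import pytest

from specshift.masses import PROTON, b_ion_series
from specshift.spectra import Spectrum

DEAMIDATION = 0.984016
FORMYLATION = 27.99491


def fragment_spectrum(
    peptide: str,
    mods: list[tuple[int, float]] = (),
    neutral_loss: float = 0.0,
    keep_b: set[str] | None = None,
    keep_y: set[str] | None = None,
    extra_peaks: list[float] = (),
    charge: int = 2,
    truncate_last: int = 0,
    sid: str = "spec",
) -> Spectrum:
    """Build a fragment spectrum of ``peptide`` with the given modifications.

    ``keep_b``/``keep_y`` restrict which ion labels (e.g. ``"b2"``) are kept
    (None keeps all); ``neutral_loss`` inflates the precursor only;
    ``truncate_last`` drops C-terminal residues from the fragmented form
    (semi-tryptic) while the precursor follows the truncated form too.
    """
    frag = peptide[: len(peptide) - truncate_last] if truncate_last else peptide
    fmods = [(p, v) for p, v in mods if p < len(frag)]
    model = b_ion_series(frag, fmods)
    n = len(frag)
    ions: dict[str, float] = {}
    for i in range(n - 1):
        ions[f"b{i + 1}"] = model.b_masses[i]
    for j in range(1, n):
        ions[f"y{j}"] = model.mh + PROTON - model.b_masses[n - j - 1]
    mzs = [
        mz for label, mz in ions.items()
        if (label.startswith("b") and (keep_b is None or label in keep_b))
        or (label.startswith("y") and (keep_y is None or label in keep_y))
    ]
    mzs.extend(extra_peaks)
    precursor_mz = (model.peptide_neutral_mass + neutral_loss + charge * PROTON) / charge
    return Spectrum(sid, precursor_mz, charge,
                    tuple(sorted((mz, 1.0) for mz in mzs)))


@pytest.fixture
def fig1_spectrum() -> Spectrum:
    """HINATESVR with deamidated N3 and formylated S7: all y-ions, b2 and b8."""
    return fragment_spectrum(
        "HINATESVR",
        mods=[(2, DEAMIDATION), (6, FORMYLATION)],
        keep_b={"b2", "b8"},
        sid="fig1",
    )


@pytest.fixture
def fig2_spectrum() -> Spectrum:
    """The same fragments with the precursor inflated by a 301.99 Da loss."""
    return fragment_spectrum(
        "HINATESVR",
        mods=[(2, DEAMIDATION), (6, FORMYLATION)],
        neutral_loss=301.99,
        keep_b={"b2", "b8"},
        sid="fig2",
    )
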