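"""Monoisotopic mass arithmetic: residue masses, b-ion series, precursor masses, ΔM.

All masses are monoisotopic and expressed in daltons.  Fragment m/z values are
singly protonated throughout: a b-ion prefix mass is ``proton + sum(residues)``.
The proton mass (1.007276 Da) is used wherever a charge is added or removed;
the hydrogen atom mass is never used for that purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from pyteomics import mass as _pmass

#: Mass of a proton in Da (charge carrier).
PROTON = 1.007276
#: Mass of a water molecule in Da (added to residue sum for a neutral peptide).
WATER = 18.010565

#: Monoisotopic residue masses for the 20 standard amino acids, from the
#: published standards (I and L are isobaric and share one mass).
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

VALID_RESIDUES = frozenset(RESIDUE_MASSES)


@dataclass(frozen=True)
class MassConstants:
    """Bundle of physical constants and the residue mass table."""

    proton: float = PROTON
    water: float = WATER
    residues: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_MASSES))


@dataclass(frozen=True)
class TheoreticalModel:
    """The b-ion prefix-mass model of a candidate peptide.

    ``b_masses[i]`` is the singly protonated b-ion of the first ``i + 1``
    residues; ``peptide_neutral_mass`` is the uncharged peptide mass
    (residue sum plus water).
    """

    peptide: str
    b_masses: tuple[float, ...]
    peptide_neutral_mass: float

    def __len__(self) -> int:
        return len(self.peptide)

    @property
    def mh(self) -> float:
        """Singly protonated peptide mass MH+."""
        return self.peptide_neutral_mass + PROTON


def validate_peptide(peptide: str) -> None:
    """Raise ``ValueError`` naming the offending residue and position."""
    if not peptide:
        raise ValueError("peptide sequence is empty")
    for pos, aa in enumerate(peptide, start=1):
        if aa not in VALID_RESIDUES:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos} in peptide {peptide!r}"
            )


def b_ion_series(peptide: str, modifications: Sequence[tuple[int, float]] = ()) -> TheoreticalModel:
    """Build the b-ion prefix-mass series of ``peptide``.

    Parameters
    ----------
    peptide:
        Uppercase sequence over the 20 standard residues.
    modifications:
        Optional ``(position, delta)`` pairs (0-based residue index); each
        delta is added to that residue's mass, shifting b_i onward.  Used by
        the simulator to build modified ion ladders; candidate peptides in
        alignment are plain sequences.
    """
    validate_peptide(peptide)
    deltas = [0.0] * len(peptide)
    for pos, delta in modifications:
        if not 0 <= pos < len(peptide):
            raise ValueError(f"modification position {pos} outside peptide of length {len(peptide)}")
        deltas[pos] += delta
    b_masses: list[float] = []
    running = PROTON
    for aa, extra in zip(peptide, deltas):
        running += RESIDUE_MASSES[aa] + extra
        b_masses.append(running)
    neutral = running - PROTON + WATER
    return TheoreticalModel(peptide=peptide, b_masses=tuple(b_masses), peptide_neutral_mass=neutral)


def precursor_neutral_mass(mz: float, charge: int) -> float:
    """Neutral (uncharged) mass from an observed precursor m/z and charge."""
    if charge < 1:
        raise ValueError(f"precursor charge must be >= 1, got {charge}")
    return (mz - PROTON) * charge


def precursor_mh(mz: float, charge: int) -> float:
    """Singly protonated precursor mass MH+ from observed m/z and charge."""
    return precursor_neutral_mass(mz, charge) + PROTON


def delta_m(precursor_mz: float, precursor_charge: int, model: TheoreticalModel) -> float:
    """ΔM: observed precursor neutral mass minus candidate peptide neutral mass."""
    return precursor_neutral_mass(precursor_mz, precursor_charge) - model.peptide_neutral_mass
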