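"""Simulated-spectrum generation with ground truth, and scoring of alignment
output against that truth.

The generator emulates imperfect HCD spectra of tryptic peptides: doubly
charged precursors, deterministic modifications (a deamidation on every
asparagine, +0.984016 Da, and a sodium adduct on every aspartate,
+21.981943 Da), 20% of fragment peaks removed (two-thirds of them b-ions,
as b-ions dominate the missing peaks in HCD data), up to 60 uniform-random
noise peaks, and a 17.03 Da neutral loss applied to the precursor mass only
— fragments never carry it, so the aligner must report it as a non-aligned
mass.  Peptides therefore carry one to five modifications each, always
including the neutral loss.

Peak intensities are uniform (1.0): intensity plays no role in alignment and
no intensity model is claimed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics import parser as _parser

from specshift.masses import PROTON, b_ion_series
from specshift.spectra import Spectrum, _clean_peaks

logger = logging.getLogger(__name__)

DEAMIDATION = 0.984016      # on N
SODIUM_ADDUCT = 21.981943   # on D
NEUTRAL_LOSS = 17.03        # applied to the precursor mass


@dataclass(frozen=True)
class SimParams:
    deamidation_mass: float = DEAMIDATION
    sodium_adduct_mass: float = SODIUM_ADDUCT
    frac_peaks_removed: float = 0.20
    removed_b_fraction: float = 2.0 / 3.0
    max_noise_peaks: int = 60
    neutral_loss: float = NEUTRAL_LOSS
    charge: int = 2
    min_len: int = 12
    max_len: int = 25
    noise_mz_min: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_peaks_removed <= 1.0 and 0.0 <= self.removed_b_fraction <= 1.0):
            raise ValueError("removal fractions must lie in [0, 1]")


@dataclass
class SimTruth:
    peptide: str
    modifications: list[tuple[int, float]]  # (0-based residue position, Da)
    neutral_loss: float
    removed_peaks: list[str]                # ion labels, e.g. "b3", "y7"
    noise_count: int


@dataclass
class EvalReport:
    n_psms: int
    pct_neutral_loss_detected: float
    pct_all_mods_correct: float
    pct_mods_correct_of_expected: float
    #: secondary count giving credit for placement on an adjacent residue
    #: (adjacent modifications are genuinely indistinguishable)
    pct_mods_correct_lenient: float = 0.0


def tryptic_peptides(fasta_path: str, n: int, params: SimParams, rng: np.random.Generator) -> list[str]:
    """Sample unique fully tryptic peptides from a protein FASTA.

    Cleavage after K/R except before P, no missed cleavages; peptide lengths
    restricted to ``[min_len, max_len]``; sampled without replacement.
    """
    unique: set[str] = set()
    for _, seq in _fasta.read(fasta_path):
        seq = seq.upper().replace("*", "")
        for pep in _parser.cleave(seq, _parser.expasy_rules["trypsin"], missed_cleavages=0):
            if params.min_len <= len(pep) <= params.max_len and set(pep) <= set("ACDEFGHIKLMNPQRSTVWY"):
                unique.add(pep)
    pool = sorted(unique)
    if len(pool) < n:
        logger.warning("only %d eligible tryptic peptides available (requested %d)", len(pool), n)
        n = len(pool)
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in picked]


def simulate_spectrum(
    peptide: str,
    params: SimParams,
    rng: np.random.Generator,
    spectrum_id: str | None = None,
) -> tuple[Spectrum, SimTruth]:
    """Build one simulated spectrum plus its ground truth."""
    n = len(peptide)
    mods = [(i, params.deamidation_mass) for i, aa in enumerate(peptide) if aa == "N"]
    mods += [(i, params.sodium_adduct_mass) for i, aa in enumerate(peptide) if aa == "D"]
    mods.sort()
    model = b_ion_series(peptide, mods)

    b_ions = [(f"b{i + 1}", model.b_masses[i]) for i in range(n - 1)]
    y_ions = [(f"y{j}", model.mh + PROTON - model.b_masses[n - j - 1]) for j in range(1, n)]

    n_remove = round(params.frac_peaks_removed * (len(b_ions) + len(y_ions)))
    n_b = min(round(params.removed_b_fraction * n_remove), len(b_ions))
    n_y = min(n_remove - n_b, len(y_ions))
    n_b = min(n_b + (n_remove - n_b - n_y), len(b_ions))  # spill over if y exhausted
    removed = set()
    if n_b:
        removed |= {b_ions[i][0] for i in rng.choice(len(b_ions), size=n_b, replace=False)}
    if n_y:
        removed |= {y_ions[i][0] for i in rng.choice(len(y_ions), size=n_y, replace=False)}

    neutral = model.peptide_neutral_mass + params.neutral_loss
    precursor_mz = (neutral + params.charge * PROTON) / params.charge

    kept = [(mz, 1.0) for label, mz in b_ions + y_ions if label not in removed]
    noise_count = int(rng.integers(0, params.max_noise_peaks + 1))
    noise_mz = rng.uniform(params.noise_mz_min, neutral + PROTON, size=noise_count)
    kept += [(float(mz), 1.0) for mz in noise_mz]

    sid = spectrum_id or peptide
    spectrum = Spectrum(
        id=sid,
        precursor_mz=precursor_mz,
        precursor_charge=params.charge,
        peaks=_clean_peaks(*zip(*((mz, it) for mz, it in kept))) if kept else (),
    )
    truth = SimTruth(
        peptide=peptide,
        modifications=mods,
        neutral_loss=params.neutral_loss,
        removed_peaks=sorted(removed),
        noise_count=noise_count,
    )
    return spectrum, truth


def write_mgf(path: str, spectra: list[Spectrum]) -> None:
    """Write simulated spectra as MGF (deterministic, byte-stable output)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, it in s.peaks:
                fh.write(f"{mz:.6f} {it:.1f}\n")
            fh.write("END IONS\n")


def write_truth_table(path: str, truths: list[SimTruth], ids: list[str], delimiter: str = ";") -> None:
    """Write ground truth as delimited text (one row per spectrum)."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(["spectrum", "peptide", "modifications", "neutral_loss",
                                 "removed_peaks", "noise_count"]) + "\n")
        for sid, t in zip(ids, truths):
            mods = ",".join(f"{pos}:{mass:.6f}" for pos, mass in t.modifications)
            fh.write(delimiter.join([
                sid, t.peptide, mods, f"{t.neutral_loss:.6f}",
                ",".join(t.removed_peaks), str(t.noise_count),
            ]) + "\n")


def read_truth_table(path: str, delimiter: str = ";") -> tuple[list[str], list[SimTruth]]:
    """Read back a truth table written by :func:`write_truth_table`."""
    ids: list[str] = []
    truths: list[SimTruth] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        col = {name: k for k, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split(delimiter)
            mods = []
            if f[col["modifications"]]:
                for tok in f[col["modifications"]].split(","):
                    pos, mass = tok.split(":")
                    mods.append((int(pos), float(mass)))
            ids.append(f[col["spectrum"]])
            truths.append(SimTruth(
                peptide=f[col["peptide"]],
                modifications=mods,
                neutral_loss=float(f[col["neutral_loss"]]),
                removed_peaks=f[col["removed_peaks"]].split(",") if f[col["removed_peaks"]] else [],
                noise_count=int(f[col["noise_count"]]),
            ))
    return ids, truths


#: Average human/vertebrate proteome residue frequencies (UniProt averages),
#: so tryptic digests of the synthetic proteins resemble real ones in
#: peptide length and in N/D content.
_AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}


def write_synthetic_fasta(path: str, n_proteins: int, rng: np.random.Generator,
                          mean_len: int = 400) -> None:
    """Write a synthetic protein FASTA (random residues, for tests and demos).

    Residues are drawn i.i.d. at proteome-average frequencies; the sequences
    carry no biological meaning beyond realistic composition.
    """
    alphabet = np.array(list(_AA_FREQ))
    weights = np.array(list(_AA_FREQ.values()))
    weights = weights / weights.sum()
    with open(path, "w") as fh:
        for k in range(n_proteins):
            length = int(rng.integers(int(mean_len * 0.5), int(mean_len * 1.5)))
            seq = "".join(rng.choice(alphabet, size=length, p=weights))
            fh.write(f">synthetic_{k}\n")
            for off in range(0, len(seq), 60):
                fh.write(seq[off:off + 60] + "\n")


_BRACKET = re.compile(r"\[([^\]]+)\]|([A-Z])|_(-?\d+(?:\.\d+)?)$")


@dataclass
class AlignmentCall:
    """Shifts and non-aligned mass as claimed by an alignment (for evaluation)."""

    peptide: str
    shifts: list[tuple[int, float]]
    non_aligned_mass: float | None


def parse_alignment_string(s: str) -> AlignmentCall:
    """Parse the alignment-string grammar back into shifts and residues.

    A numeric bracket after a residue is a shift on that residue; a numeric
    bracket before any residue (a ladder offset) is attributed to the next
    residue.  A trailing ``_mass`` is the non-aligned mass.
    """
    peptide: list[str] = []
    shifts: list[tuple[int, float]] = []
    non_aligned: float | None = None
    pending_leading: list[float] = []
    for m in _BRACKET.finditer(s):
        bracket, residue, trailing = m.groups()
        if trailing is not None:
            non_aligned = float(trailing)
        elif residue is not None:
            peptide.append(residue)
            for v in pending_leading:
                shifts.append((len(peptide) - 1, v))
            pending_leading = []
        elif len(bracket) == 1 and bracket.isalpha():
            peptide.append(bracket)
            for v in pending_leading:
                shifts.append((len(peptide) - 1, v))
            pending_leading = []
        else:
            value = float(bracket)
            if peptide:
                shifts.append((len(peptide) - 1, value))
            else:
                pending_leading.append(value)
    return AlignmentCall(peptide="".join(peptide), shifts=shifts, non_aligned_mass=non_aligned)


def _match_mods(
    truth: SimTruth,
    shifts: list[tuple[int, float]],
    mass_tol: float,
    max_pos_slack: int,
) -> int:
    """Count true modifications matched by reported shifts (each shift used once)."""
    used: set[int] = set()
    matched = 0
    for pos, mass in truth.modifications:
        for k, (spos, sval) in enumerate(shifts):
            if k in used:
                continue
            if abs(sval - mass) <= mass_tol and abs(spos - pos) <= max_pos_slack:
                used.add(k)
                matched += 1
                break
    return matched


def evaluate(
    results: list,
    truths: list[SimTruth],
    mass_tol: float = 0.02,
    require_position: bool = True,
) -> EvalReport:
    """Score alignment calls against simulation ground truth.

    A neutral loss is detected when the non-aligned mass matches it within
    ``mass_tol``; a modification is correct when a reported shift matches its
    mass at the true residue position.  A peptide counts as fully correct
    when the neutral loss is detected and every incorporated modification is
    correctly placed.  The per-modification rate is computed over all
    incorporated modifications, the neutral losses included.
    """
    if len(results) != len(truths):
        raise ValueError(f"results ({len(results)}) and truths ({len(truths)}) differ in length")
    n = len(results)
    if n == 0:
        return EvalReport(0, 0.0, 0.0, 0.0, 0.0)
    slack = 0 if require_position else 10**6
    nl_hits = all_hits = 0
    mods_matched = mods_matched_lenient = mods_expected = 0
    for res, truth in zip(results, truths):
        nam = res.non_aligned_mass
        nl = nam is not None and abs(nam - truth.neutral_loss) <= mass_tol
        matched = _match_mods(truth, res.shifts, mass_tol, slack)
        lenient = _match_mods(truth, res.shifts, mass_tol, max(slack, 1))
        nl_hits += nl
        all_hits += nl and matched == len(truth.modifications)
        mods_matched += matched + nl
        mods_matched_lenient += lenient + nl
        mods_expected += len(truth.modifications) + 1
    return EvalReport(
        n_psms=n,
        pct_neutral_loss_detected=100.0 * nl_hits / n,
        pct_all_mods_correct=100.0 * all_hits / n,
        pct_mods_correct_of_expected=100.0 * mods_matched / mods_expected,
        pct_mods_correct_lenient=100.0 * mods_matched_lenient / mods_expected,
    )
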