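"""Dynamic-programming alignment of a b-ion peptide model against a completed
spectrum.

A matrix ``D`` of size N (residues) x M (completed peaks) is filled row by
row.  Cell (i, j) holds the best score of an alignment of the first i + 1
residues in which the path currently sits at peak j.  Residues the path
skips while waiting in a column accumulate a *pending* mass there.  Three
moves feed a cell:

* **alignment** (S_A, +10 when peak j carries both b- and y-ion evidence,
  +7 for a single ion): the gap from a predecessor column m, net of that
  column's pending mass, accounts for residue i exactly (within the
  fragment tolerance).  With no pending mass this is a plain extension of
  an in-frame ladder; with pending mass it bridges missing peaks — the
  realignment with a null shift that must score as an alignment;
* **realignment** (S_R, -8 / -6 by the same evidence rule): residue i lands
  on peak j with a recorded shift ``mz_j - mz_m - pending_m - aa_i``.  Only
  available when *aafound* holds — some peak pair (j, k) matches the raw
  residue mass — and only from columns m left of that matching peak k;
* **non-alignment** (S_N, -4): residue i joins column j's pending mass.
  Barred when the residue's mass is corroborated at j and a landing move is
  available.

The realignment penalty exceeds the non-alignment penalty so that a shift
must be repaid by at least two subsequently aligned residues.

Row 0 is seeded from a virtual anchor peak (b0, at the proton mass): the
first residue must land — it aligns when b1 matches a gap from the anchor
and realigns with the induced leading shift otherwise.  This is what turns
a constant offset of the complementary frame (a neutral loss) into a
leading shift.  The best cell of the last row starts the traceback.

Each shift spans the realigned residue plus the non-aligned run skipped just
before it; the shift is attributed to the first residue of that span (a
bracketed residue directly before a shift is where the modification lies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from specshift.completion import CompletedSpectrum, Evidence
from specshift.masses import RESIDUE_MASSES, TheoreticalModel

DEFAULT_FRAGMENT_TOL = 0.02

ALIGN, REALIGN, NONALIGN, NOMOVE = 0, 1, 2, 3

_MOVE_NAMES = {ALIGN: "align", REALIGN: "realign", NONALIGN: "nonalign"}


@dataclass(frozen=True)
class ScoringScheme:
    """Elementary alignment scores, by move and ion evidence of the landing peak."""

    s_align_both: int = 10
    s_align_single: int = 7
    s_realign_both: int = -8
    s_realign_single: int = -6
    s_nonalign: int = -4

    def __post_init__(self) -> None:
        if not (self.s_align_both > 0 and self.s_align_single > 0):
            raise ValueError("alignment scores must be positive")
        if not (self.s_realign_both < 0 and self.s_realign_single < 0):
            raise ValueError("realignment scores must be negative")
        if self.s_nonalign >= 0:
            raise ValueError("non-alignment score must be negative")
        if not (abs(self.s_realign_both) > abs(self.s_nonalign)
                and abs(self.s_realign_single) > abs(self.s_nonalign)):
            raise ValueError("a realignment must be penalized more than one non-aligned residue")


@dataclass
class Step:
    """One traceback step for one residue, N-terminal to C-terminal."""

    kind: str                 # "align" | "realign" | "nonalign"
    peak_index: int           # landing peak (align/realign) or waiting column
    shift: float = 0.0        # realign only
    span_start: int = -1      # first residue covered by the shift (realign only)


@dataclass
class ScoreMatrix:
    scores: np.ndarray        # (N, M) float, -inf for unreachable cells
    move: np.ndarray          # (N, M) uint8
    pred: np.ndarray          # (N, M) int32 predecessor column
    shift: np.ndarray         # (N, M) float recorded shift for realign moves
    pending: np.ndarray       # (N, M) float mass of the trailing skipped run
    run: np.ndarray           # (N, M) int32 length of the trailing skipped run
    model: TheoreticalModel
    sec: CompletedSpectrum


@dataclass
class RawAlignment:
    steps: list[Step]
    shifts: list[tuple[int, float]]   # (span-start residue position, Da), N-to-C
    score: int
    peptide: str = ""

    @property
    def shift_sum(self) -> float:
        return sum(s for _, s in self.shifts)


def aa_found(peak_j: float, peak_k: float, residue: str, tol: float = DEFAULT_FRAGMENT_TOL) -> bool:
    """True iff the residue mass fits the gap between two peaks within tol."""
    if peak_k >= peak_j:
        return False
    return abs((peak_j - peak_k) - RESIDUE_MASSES[residue]) <= tol


def fill_matrix(
    model: TheoreticalModel,
    sec: CompletedSpectrum,
    scheme: ScoringScheme = ScoringScheme(),
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> ScoreMatrix:
    """Fill the score matrix and backpointers for one peptide/spectrum pair."""
    n = len(model)
    if n == 0:
        raise ValueError("cannot align an empty peptide")
    mz = np.array([p.mz for p in sec.peaks])
    m = mz.size
    ev_both = np.array([p.evidence == Evidence.BOTH for p in sec.peaks])
    anchor = next((j for j, p in enumerate(sec.peaks) if p.is_anchor), None)
    if anchor is None:
        raise ValueError("completed spectrum has no anchor peak")

    aa_masses = np.array([RESIDUE_MASSES[aa] for aa in model.peptide])
    gap = mz[:, None] - mz[None, :]              # gap[j, m] = mz_j - mz_m
    lower = np.tril(np.ones((m, m), dtype=bool), k=-1)  # m < j
    idx = np.arange(m)
    neg = -np.inf

    s_a = np.where(ev_both, scheme.s_align_both, scheme.s_align_single).astype(float)
    s_r = np.where(ev_both, scheme.s_realign_both, scheme.s_realign_single).astype(float)

    scores = np.full((n, m), neg)
    move = np.full((n, m), NOMOVE, dtype=np.uint8)
    pred = np.full((n, m), -1, dtype=np.int32)
    shift = np.zeros((n, m))
    pending = np.zeros((n, m))
    run = np.zeros((n, m), dtype=np.int32)

    # ---- row 0: seeded from the anchor
    lead = mz - mz[anchor] - aa_masses[0]
    ok = mz > mz[anchor]
    is_align0 = ok & (np.abs(lead) <= tol)
    scores[0] = np.where(is_align0, s_a, np.where(ok, s_r, neg))
    move[0] = np.where(is_align0, ALIGN, np.where(ok, REALIGN, NOMOVE)).astype(np.uint8)
    shift[0] = np.where(move[0] == REALIGN, lead, 0.0)
    pred[0] = np.where(ok, anchor, -1)

    d_prev, p_prev, r_prev = scores[0], pending[0], run[0]

    for i in range(1, n):
        aa = aa_masses[i]
        finite = np.isfinite(d_prev)
        dp = np.where(finite, d_prev, neg)

        # alignment (S_A): the gap to the predecessor, net of that column's
        # pending skipped masses, accounts for the residue exactly — a plain
        # align when the predecessor has no pending, a bridge over missing
        # peaks otherwise
        sh_all = gap - p_prev[None, :] - aa
        amask = (np.abs(sh_all) <= tol) & lower & finite[None, :]
        akey = dp + 0.25 * ev_both + 1e-9 * idx  # score, then evidence, then m/z
        acand = np.where(amask, akey[None, :], neg)
        a_j = np.argmax(acand, axis=1)
        a_usable = np.isfinite(acand[idx, a_j])
        align_val = np.where(a_usable, d_prev[a_j] + s_a, neg)

        # aafound: a peak pair whose raw gap matches the residue mass;
        # the rightmost matching peak k bounds the realignment range
        mmask = (np.abs(gap - aa) <= tol) & lower
        any_match = mmask.any(axis=1)
        k_j = m - 1 - np.argmax(mmask[:, ::-1], axis=1)

        # realignment (S_R): only into aafound cells, from any column m < k
        pmax = np.maximum.accumulate(dp)
        parg = np.maximum.accumulate(np.where(dp >= pmax, idx, -1))  # rightmost prefix argmax
        km1 = np.maximum(k_j - 1, 0)
        r_usable = any_match & (k_j >= 1) & np.isfinite(pmax[km1])
        r_val = np.where(r_usable, pmax[km1] + s_r, neg)
        r_pred = parg[km1]

        # non-alignment (S_N): residue waits in its column; barred when the
        # residue's mass is corroborated and a landing move is available
        non_val = np.where(finite, d_prev + scheme.s_nonalign, neg)
        non_val = np.where(~any_match | ~(a_usable | r_usable), non_val, neg)

        best_v = np.maximum(np.maximum(align_val, r_val), non_val)
        use_a = a_usable & (align_val >= best_v)
        use_r = r_usable & (r_val >= best_v) & ~use_a
        use_n = np.isfinite(non_val) & (non_val >= best_v) & ~use_a & ~use_r

        scores[i] = best_v
        move[i] = np.select([use_a, use_r, use_n], [ALIGN, REALIGN, NONALIGN], NOMOVE)
        pred[i] = np.select([use_a, use_r, use_n], [a_j, r_pred, idx], -1)
        shift[i] = np.where(use_r, gap[idx, r_pred] - p_prev[r_pred] - aa, 0.0)
        pending[i] = np.where(use_n, p_prev + aa, 0.0)
        run[i] = np.where(use_n, r_prev + 1, 0)

        d_prev, p_prev, r_prev = scores[i], pending[i], run[i]

    return ScoreMatrix(scores=scores, move=move, pred=pred, shift=shift,
                       pending=pending, run=run, model=model, sec=sec)


def traceback(matrix: ScoreMatrix) -> RawAlignment:
    """Recover the best path from the maximum cell of the last row.

    Ties on the last row are broken toward the rightmost peak; within a cell
    the fill step already prefers align over realign over non-align.
    """
    n, m = matrix.scores.shape
    last = matrix.scores[-1]
    best = last.max()
    if not np.isfinite(best):
        raise ValueError("alignment matrix has no reachable final cell")
    j = int(m - 1 - np.argmax(last[::-1] == best))

    steps: list[Step] = []
    for i in range(n - 1, -1, -1):
        mv = int(matrix.move[i, j])
        pj = int(matrix.pred[i, j])
        sh = float(matrix.shift[i, j])
        span = -1
        if mv == REALIGN:
            span = i - (int(matrix.run[i - 1, pj]) if i > 0 else 0)
        steps.append(Step(kind=_MOVE_NAMES[mv], peak_index=j, shift=sh, span_start=span))
        j = pj
    steps.reverse()
    shifts = [(s.span_start, s.shift) for s in steps if s.kind == "realign"]
    return RawAlignment(steps=steps, shifts=shifts, score=int(best),
                        peptide=matrix.model.peptide)


def rescore_path(raw: RawAlignment, sec: CompletedSpectrum, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Re-score a traceback path move by move (independent of the matrix)."""
    total = 0
    for step in raw.steps:
        both = sec.peaks[step.peak_index].evidence == Evidence.BOTH
        if step.kind == "align":
            total += scheme.s_align_both if both else scheme.s_align_single
        elif step.kind == "realign":
            total += scheme.s_realign_both if both else scheme.s_realign_single
        else:
            total += scheme.s_nonalign
    return total


def format_alignment(raw: RawAlignment, non_aligned_mass: float | None = None) -> str:
    """Render an alignment as a string.

    Residues whose mass is corroborated by a pair of peaks (aligned or
    realigned) appear bare; non-aligned residues are bracketed; a
    realignment prints its shift in brackets (two decimals) just before the
    realigned residue — right after the bracketed residues its span skips.
    A non-aligned mass, if any, is appended after ``_``.
    """
    parts: list[str] = []
    for step, aa in zip(raw.steps, raw.peptide):
        if step.kind == "align":
            parts.append(aa)
        elif step.kind == "nonalign":
            parts.append(f"[{aa}]")
        else:
            parts.append(f"[{step.shift:.2f}]" + aa)
    out = "".join(parts)
    if non_aligned_mass is not None:
        out += f"_{non_aligned_mass:.2f}"
    return out
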