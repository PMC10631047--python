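"""Post-processing of a raw alignment: validate each mass shift against the
native spectrum, arbitrate C-terminal shifts against a non-aligned mass, and
trim residues that the spectrum shows were never part of the fragmented
peptide.

The dynamic program works in the completed-peak coordinate frame, where a
constant offset of all complementary peaks (a neutral loss, a dimer artifact,
a charge error) masquerades as a perfectly good leading shift.  The rules
here re-evaluate every shift against the *native* peaks only:

1. a shift survives only if it strictly increases the number of native peaks
   matched by the shifted b/y ladders; otherwise its mass is accumulated into
   the non-aligned mass printed after ``_``;
2. a remaining non-aligned mass is tested as a modification on each of the
   two C-terminal residues, and moved there when that explains more peaks
   (ties keep the non-aligned form, which claims less);
3. runs of non-aligned terminal residues whose summed mass cancels an
   adjacent negative shift (or the non-aligned mass) are deleted — the
   semi-tryptic case — when the deletion does not lose any matched peak.

Shared-peak counting matches native peaks against the shifted b-ions and
against y-ions anchored to the shifted peptide mass (peptide MH+ plus the sum
of the kept shifts): fragments never carry a neutral loss, so a genuine
non-aligned mass must not enter the y-ion frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from specshift.align import RawAlignment, DEFAULT_FRAGMENT_TOL
from specshift.masses import PROTON, RESIDUE_MASSES, TheoreticalModel, b_ion_series, delta_m
from specshift.spectra import Spectrum

logger = logging.getLogger(__name__)

_MAX_PASSES = 10


@dataclass
class FinalAlignment:
    """A refined alignment: string form, kept shifts, non-aligned mass, metrics."""

    peptide: str                       # possibly trimmed (semi-tryptic)
    aligned_string: str
    shifts: list[tuple[int, float]]    # (residue position in `peptide`, Da)
    non_aligned_mass: float | None
    shared_before: int
    shared_after: int
    intensity_explained: float
    score: int
    delta_m: float


def _fragment_targets(model: TheoreticalModel, shifts: list[tuple[int, float]]) -> np.ndarray:
    """Shifted b- and y-ion m/z targets (b_n and y_n are not observable)."""
    n = len(model)
    b = np.array(model.b_masses)
    cum = np.zeros(n)
    for pos, val in shifts:
        cum[pos:] += val
    shifted_b = b + cum
    total = cum[-1] if n else 0.0
    anchor = model.mh + total          # MH+ of the peptide as shifted
    if n < 2:
        return np.empty(0)
    obs_b = shifted_b[: n - 1]
    obs_y = anchor + PROTON - obs_b
    return np.concatenate([obs_b, obs_y])


def shared_peaks(
    model: TheoreticalModel,
    shifts: list[tuple[int, float]],
    spectrum: Spectrum,
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> int:
    """Number of native peaks matched by any shifted b- or y-ion (each once)."""
    if not spectrum.peaks:
        return 0
    targets = _fragment_targets(model, shifts)
    if targets.size == 0:
        return 0
    mzs = np.array(spectrum.mz_values)
    hit = np.abs(mzs[:, None] - targets[None, :]) <= tol
    return int(hit.any(axis=1).sum())


def matched_intensity(
    model: TheoreticalModel,
    shifts: list[tuple[int, float]],
    spectrum: Spectrum,
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> float:
    """Summed intensity of native peaks matched by the shifted b/y ladders."""
    if not spectrum.peaks:
        return 0.0
    targets = _fragment_targets(model, shifts)
    if targets.size == 0:
        return 0.0
    mzs = np.array(spectrum.mz_values)
    its = np.array([p[1] for p in spectrum.peaks])
    hit = (np.abs(mzs[:, None] - targets[None, :]) <= tol).any(axis=1)
    return float(its[hit].sum())


def intensity_explained(
    model: TheoreticalModel,
    final: "FinalAlignment",
    spectrum: Spectrum,
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> float:
    """Fraction of total native signal intensity explained by the alignment."""
    total = spectrum.total_intensity
    if total <= 0:
        logger.warning("spectrum %r has zero total intensity", spectrum.id)
        return 0.0
    fmodel = b_ion_series(final.peptide) if final.peptide != model.peptide else model
    return matched_intensity(fmodel, final.shifts, spectrum, tol) / total


@dataclass
class _RenderStep:
    aa: str
    kind: str            # "align" | "nonalign" | "realign"
    shift: float | None  # shift printed just before this residue (realign)
    span: int            # first residue position covered by the shift


@dataclass
class _State:
    model: TheoreticalModel
    renders: list[_RenderStep]
    residual: float      # delta_m minus the sum of kept shifts

    @property
    def shifts(self) -> list[tuple[int, float]]:
        return [(r.span, r.shift) for r in self.renders if r.shift is not None]


def _shift_candidates(
    state: _State,
    render_index: int,
    spectrum: Spectrum,
    tol: float,
) -> list[float]:
    """Candidate replacement values for one shift, implied by native peaks.

    A traceback shift can absorb a constant offset of the complementary
    frame (a neutral loss) on top of a true modification mass.  Every value
    between zero (pure non-aligned mass) and the full shift that would put
    a shifted b-ion — or a y-ion whose complement lies N-terminal of the
    shift — onto a native peak is a plausible split point.
    """
    renders = state.renders
    r = renders[render_index]
    s = r.shift
    p = r.span
    n = len(state.model)
    b = state.model.b_masses
    others = [(rr.span, rr.shift) for t, rr in enumerate(renders)
              if rr.shift is not None and t != render_index]
    lo, hi = sorted((0.0, s))
    lo -= tol
    hi += tol
    cum = np.zeros(n)
    for pos, val in others:
        cum[pos:] += val
    total_others = sum(v for _, v in others)
    mzs = np.array(spectrum.mz_values)

    cands: set[float] = {0.0, round(s, 6)}
    # b-ions downstream of the shift: b'_t = b_t + cum_t + s'
    for t in range(p, n - 1):
        base = b[t] + cum[t]
        for v in mzs[(mzs >= base + lo) & (mzs <= base + hi)]:
            cands.add(round(float(v) - base, 6))
    # y-ions whose b-complement is upstream of the shift: they move with the
    # total shifted peptide mass, hence with s'
    anchor0 = state.model.mh + total_others
    for t in range(0, p):
        base = anchor0 + PROTON - (b[t] + cum[t])
        for v in mzs[(mzs >= base + lo) & (mzs <= base + hi)]:
            cands.add(round(float(v) - base, 6))
    return sorted(cands)


def _rule1_prune_shifts(state: _State, spectrum: Spectrum, tol: float) -> bool:
    """Keep of each shift only the part the native peaks support.

    For every traceback shift the candidate values implied by the native
    peaks (including zero) are scored by shared-peak count; the rest of the
    shift is accumulated into the non-aligned mass.  A shift survives at its
    full value only if that strictly beats every smaller candidate — ties go
    to the smaller |shift|, so an unsupported shift is fully demoted to
    non-aligned mass, as required for a pure neutral loss.
    """
    changed = False
    for i, r in enumerate(state.renders):
        if r.shift is None:
            continue
        others = [(rr.span, rr.shift) for t, rr in enumerate(state.renders)
                  if rr.shift is not None and t != i]
        best_val, best_count, best_abs = None, -1, float("inf")
        for cand in _shift_candidates(state, i, spectrum, tol):
            trial = others + ([(r.span, cand)] if abs(cand) > tol else [])
            cnt = shared_peaks(state.model, trial, spectrum, tol)
            if cnt > best_count or (cnt == best_count and abs(cand) < best_abs):
                best_val, best_count, best_abs = cand, cnt, abs(cand)
        if best_val is None or abs(best_val - r.shift) <= tol:
            continue
        state.residual += r.shift - best_val
        if abs(best_val) <= tol:
            # nothing of the shift is supported: the realigned residue keeps
            # its corroboration in the shifted frame, the mass moves to the
            # non-aligned remainder
            state.renders[i] = replace(r, shift=None, kind="align")
        else:
            state.renders[i] = replace(r, shift=best_val)
        changed = True
    return changed


def _rule2_cterm_arbitration(state: _State, spectrum: Spectrum, tol: float) -> bool:
    """Prefer a C-terminal shift over a non-aligned mass when it explains more peaks."""
    n = len(state.model)
    if abs(state.residual) <= tol:
        return False
    base = shared_peaks(state.model, state.shifts, spectrum, tol)
    best_pos, best_count = None, base
    for pos in (n - 1, n - 2):
        if pos < 0 or state.renders[pos].shift is not None:
            continue
        trial = state.shifts + [(pos, state.residual)]
        cnt = shared_peaks(state.model, trial, spectrum, tol)
        if cnt > best_count:  # ties keep the non-aligned form / the later position
            best_pos, best_count = pos, cnt
    if best_pos is None:
        return False
    r = state.renders[best_pos]
    state.renders[best_pos] = replace(r, shift=state.residual, kind="realign", span=best_pos)
    state.residual = 0.0
    return True


def _truncate(state: _State, start: int, stop: int) -> _State:
    """State with residues [start, stop) of the current peptide only."""
    peptide = state.model.peptide[start:stop]
    renders = [replace(r, span=max(r.span - start, 0)) for r in state.renders[start:stop]]
    return _State(model=b_ion_series(peptide), renders=renders, residual=state.residual)


def _rule3_trim_nonaligned(state: _State, spectrum: Spectrum, tol: float) -> bool:
    """Delete terminal non-aligned runs cancelled by a negative mass.

    Covers the semi-tryptic case: missing terminal residues show up as
    non-aligned residues paired with a compensating negative mass (a leading
    negative shift, or a negative non-aligned mass at the C-terminus).
    """
    n = len(state.model)
    renders = state.renders
    base = shared_peaks(state.model, state.shifts, spectrum, tol)

    # trailing suffix of non-aligned residues (possibly carrying a negative
    # shift) whose mass cancels against the non-aligned mass and those shifts
    for q in range(n - 1, 0, -1):
        suffix = renders[q:]
        ok = all(
            (r.kind == "nonalign" and r.shift is None)
            or (r.shift is not None and r.shift < 0 and r.span >= q)
            for r in suffix
        )
        if not ok or all(r.kind != "nonalign" for r in suffix):
            continue
        suf_shift = sum(r.shift for r in suffix if r.shift is not None)
        run_mass = sum(RESIDUE_MASSES[r.aa] for r in suffix)
        if abs(state.residual + suf_shift + run_mass) > tol * (n - q + 1):
            continue
        trial = _truncate(state, 0, q)
        trial.residual += suf_shift + run_mass
        if shared_peaks(trial.model, trial.shifts, spectrum, tol) >= base:
            state.model = trial.model
            state.renders = trial.renders
            state.residual = trial.residual
            return True

    # leading run vs. an adjacent negative shift
    h = 0
    while h < n and renders[h].kind == "nonalign" and renders[h].shift is None:
        h += 1
    if 0 < h < n:
        run_mass = sum(RESIDUE_MASSES[r.aa] for r in renders[:h])
        # variant A: the run is cancelled by a negative non-aligned mass
        if abs(state.residual + run_mass) <= tol * (h + 1):
            trial = _truncate(state, h, n)
            trial.residual += run_mass
            if shared_peaks(trial.model, trial.shifts, spectrum, tol) >= base:
                state.model = trial.model
                state.renders = trial.renders
                state.residual = trial.residual
                return True
        # variant B: the run is cancelled by an adjacent negative shift
        if renders[h].shift is not None and abs(renders[h].shift + run_mass) <= tol * (h + 1):
            trial = _truncate(state, h, n)
            trial.renders[0] = replace(trial.renders[0], shift=None, kind="align")
            if shared_peaks(trial.model, trial.shifts, spectrum, tol) >= base:
                state.model = trial.model
                state.renders = trial.renders
                return True
    return False


def _refine_pass(state: _State, spectrum: Spectrum, tol: float) -> bool:
    changed = _rule1_prune_shifts(state, spectrum, tol)
    changed = _rule2_cterm_arbitration(state, spectrum, tol) or changed
    changed = _rule3_trim_nonaligned(state, spectrum, tol) or changed
    return changed


def _render_string(state: _State, tol: float) -> tuple[str, float | None]:
    parts: list[str] = []
    for r in state.renders:
        if r.shift is not None:
            parts.append(f"[{r.shift:.2f}]" + r.aa)
        elif r.kind == "nonalign":
            parts.append(f"[{r.aa}]")
        else:
            parts.append(r.aa)
    non_aligned = state.residual if abs(state.residual) > tol else None
    out = "".join(parts)
    if non_aligned is not None:
        out += f"_{non_aligned:.2f}"
    return out, non_aligned


def _state_from_raw(raw: RawAlignment, dm: float) -> _State:
    renders = []
    for i, (step, aa) in enumerate(zip(raw.steps, raw.peptide)):
        if step.kind == "realign":
            renders.append(_RenderStep(aa=aa, kind="realign", shift=step.shift, span=step.span_start))
        else:
            renders.append(_RenderStep(aa=aa, kind=step.kind, shift=None, span=i))
    return _State(model=b_ion_series(raw.peptide), renders=renders, residual=dm - raw.shift_sum)


def refine(
    raw: RawAlignment,
    model: TheoreticalModel,
    spectrum: Spectrum,
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> FinalAlignment:
    """Apply the post-processing rules (prune, C-terminal arbitration, trim)
    until the alignment is stable, and assemble the final report."""
    dm = delta_m(spectrum.precursor_mz, spectrum.precursor_charge, model)
    state = _state_from_raw(raw, dm)
    for _ in range(_MAX_PASSES):
        if not _refine_pass(state, spectrum, tol):
            break
    aligned, non_aligned = _render_string(state, tol)
    fmodel = state.model
    return FinalAlignment(
        peptide=fmodel.peptide,
        aligned_string=aligned,
        shifts=state.shifts,
        non_aligned_mass=non_aligned,
        shared_before=shared_peaks(model, [], spectrum, tol),
        shared_after=shared_peaks(fmodel, state.shifts, spectrum, tol),
        intensity_explained=0.0,  # filled by the pipeline
        score=raw.score,
        delta_m=dm,
    )
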