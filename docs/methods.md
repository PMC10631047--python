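# Methods

## Problem setting

An open modification search (OMS) engine produces peptide-spectrum matches
(St, Se, ΔM): a candidate peptide's theoretical spectrum St, an experimental
MS/MS spectrum Se, and the difference ΔM between the observed precursor
neutral mass and the peptide's neutral mass. When |ΔM| exceeds the
instrument accuracy, the match is only credible if ΔM can be explained.
`specshift` splits ΔM into (i) mass shifts localized on residues —
candidate modifications — and (ii) a residual *non-aligned mass* that no
fragment supports, which arises from neutral losses of labile groups,
peptide dimers, or precursor charge misassignment. No modification database
is consulted; any shift value is admissible.

## Mass model

Monoisotopic arithmetic throughout. Residue masses come from the published
monoisotopic standards (pyteomics' table); isoleucine and leucine share one
mass and are never distinguished. The proton (1.007276 Da) is the charge
carrier everywhere; a peptide's b-ion prefix series is
bᵢ = proton + Σ residues₁..ᵢ, its neutral mass Σ residues + water
(18.010565 Da), and MH⁺ = neutral + proton. The observed precursor neutral
mass is (m/z − proton) × z. Candidate peptides are plain sequences over the
20 standard residues; fixed modifications of the candidate are out of scope.

## Spectrum completion

St is modeled by b-ions only, so the aligner must see y-ion evidence in
b-ion coordinates. For every observed peak at m, a complementary peak at
MH⁺ + proton − m is added (MH⁺ being the singly protonated observed
precursor; the b- and y-ions of one backbone cleavage sum to MH⁺ + proton).
A complementary image landing within the merge tolerance (0.01 Da) of an
existing peak merges into it and flags it as carrying *both* ion species;
such peaks earn the stronger alignment scores. Two virtual peaks complete
the frame: an anchor at the proton mass (the b₀ position, so the first
residue has a left partner) and a terminus at MH⁺ − water (the bₙ position
implied by the precursor measurement, so the last residue has a right
partner). Both carry dual evidence, being direct consequences of the
precursor measurement. Noise peaks are completed like any other peak; the
scoring absorbs the extra columns. No intensity-based pre-filtering is
applied: intensities are carried through untouched and only feed the
explained-intensity report.

A consequence worth noting: when the precursor carries a mass that the
fragments do not (a neutral loss Mloss), every complementary peak — and the
virtual bₙ terminus — is displaced by exactly Mloss relative to the b-ion
frame of the fragmented peptide. The aligner therefore sees the loss as a
coherent ladder offset, which is what makes it detectable.

## Alignment recurrence

A matrix D of size N (residues) × M (completed peaks) is filled row by row;
cell (i, j) is the best score with the path sitting at peak j after
considering residue i. Residues skipped while the path waits in a column
accumulate a *pending* mass there. Moves into (i, j):

* **align, S_A** (+10 when peak j has both-ion evidence, +7 otherwise): the
  gap from a predecessor column m, minus that column's pending mass, equals
  the residue mass within the fragment tolerance. With zero pending this
  extends an in-frame ladder; with pending it bridges missing peaks — a
  realignment with a null shift, which must score positively because the
  skipped masses fully account for the gap;
* **realign, S_R** (−8 / −6 by the same evidence rule): residue i lands on
  peak j with a recorded shift (gap − pending − residue mass). Available
  only where some raw peak pair (j, k) matches the residue mass, and only
  from columns left of that matching peak k;
* **non-align, S_N** (−4): the residue joins the column's pending mass.
  Barred where a landing move is available.

Row 0 is seeded from the anchor and the first residue must land: it aligns
if b₁ matches a gap from the anchor and otherwise realigns with the induced
leading shift — a precursor-level offset such as a neutral loss thus
surfaces as a leading shift. The penalties satisfy |S_R| > |S_N| so that a
shift is only introduced when at least two subsequently aligned residues
repay it; this guards against realigning onto noise. The traceback starts
at the best last-row cell (ties: rightmost peak; within a cell, align is
preferred over realign over non-align) and yields the raw alignment. Each
shift is attributed to the first residue of its span (the realigned residue
plus the non-aligned run directly before it), which is where the
modification lies when a single modified residue broke the ladder.

Scores are plain integers with no length normalization. All tolerances are
absolute daltons; there is no ppm mode. The scoring constants are
configurable (and validated: alignment rewards positive, realignment
penalties strictly exceeding the non-alignment penalty).

The fill is vectorized over peaks per row (numpy); a naive loop
transcription of the same recurrence serves as the reference in tests.
Typical cost is a few milliseconds per PSM at tryptic peptide lengths.

## Post-processing

The dynamic program works in completed-peak coordinates, where a constant
complementary-frame offset looks like a perfectly good shift. Three rules
re-validate the result against the native peaks only. Shared-peak counting
matches native peaks (each at most once) against the shifted b-ions and
against y-ions anchored at the peptide MH⁺ *plus the kept shifts* — the
non-aligned mass is deliberately excluded from the y-frame, because
fragments never carry it.

1. **Shift validation.** For each shift, candidate replacement values are
   enumerated: zero, the full value, and every value that would place a
   downstream b-ion (or a y-ion whose complement lies N-terminal of the
   shift) onto a native peak. The candidate with the highest shared-peak
   count wins; ties go to the smaller absolute value, so an unsupported
   shift is demoted entirely to non-aligned mass. This generalizes plain
   keep-or-drop validation: the optimal traceback merges a ladder offset
   (e.g. a 17 Da neutral loss) into the first modification's shift, since
   one realignment is cheaper than two, and only a partial-value search can
   pull the two apart. The remainder always accumulates into the
   non-aligned mass, so mass closure (Σ shifts + residual = ΔM) is
   preserved exactly.
2. **C-terminal arbitration.** A shift on the last residues cannot repay
   its penalty within the alignment, so genuine C-terminal modifications
   surface as non-aligned mass. The residual is therefore tested as a shift
   on each of the last two residues and moved there only if strictly more
   native peaks match; ties keep the non-aligned form, which claims less.
3. **Terminal trimming.** A terminal run of non-aligned residues whose
   summed mass cancels the non-aligned mass (or an adjacent negative
   shift) is deleted when the deletion does not lose any matched peak —
   the semi-tryptic case, where the spectrum stems from a truncated form
   of the candidate.

The rules run in this order and repeat until a full pass changes nothing
(convergence is reached in one or two passes in practice; a hard cap of 10
guards the loop). A final non-aligned mass below the fragment tolerance is
dropped. Both the raw (pre-processed) and final alignment strings are
reported.

## Simulated benchmark

The generator emulates imperfect higher-energy collisional dissociation
(HCD) spectra of tryptic peptides. Defaults, which are the benchmark's
defining conditions: fully tryptic peptides (cleavage after K/R except
before P, no missed cleavages) of length 12–25; every asparagine deamidated
(+0.984016 Da) and every aspartate given a sodium adduct (+21.981943 Da);
all b₁..b_{N−1} and y₁..y_{N−1} ions of the modified peptide at uniform
intensity 1.0; 20% of fragment peaks removed, two thirds of them b-ions
(b-ions dominate the missing peaks in real HCD data); a noise-peak count
drawn uniformly in [0, 60] with m/z uniform in [50, MH⁺]; and a 17.03 Da
neutral loss added to each doubly charged precursor but to no fragment.
Each simulated peptide thus carries one to five modifications, always
including the neutral loss. A synthetic proteome generator (residues i.i.d.
at proteome-average frequencies) supplies the peptide pool; sequences carry
no biological meaning beyond composition, which is what fixes the
modification-count distribution.

What the simulation does not emulate: intensity structure (no fragment
intensity model — the aligner ignores intensities by design), mass error on
fragment positions (peaks sit at exact theoretical values; real spectra add
~5 mDa jitter well inside the 0.02 Da tolerance), co-fragmentation, and
isotope envelopes. Passing benchmarks therefore speak to the alignment and
post-processing logic under missing peaks, noise, and compound ΔM — not to
robustness against calibration error.

Evaluation counts a neutral loss as detected when the final non-aligned
mass matches it within 0.02 Da; a modification as correct when a reported
shift matches its mass within 0.02 Da at the true residue position (a
secondary lenient count credits adjacent positions, since modifications on
adjacent residues are indistinguishable in principle); a peptide as fully
correct when the neutral loss is detected and every incorporated
modification is correctly placed. The per-modification rate is computed
over all incorporated modifications, neutral losses included. At the
benchmark scale used in the tests (2,000 peptides, one fixed seed) the
sampling standard error of the percentages is about one point.

Known limitation, measured and accepted: the partial-value shift validation
recovers neutral losses more often than the keep-or-drop variant would, so
the neutral-loss detection rate at the benchmark conditions (~87%) sits
above the mid-60s that plain keep-or-drop reasoning would suggest, while
modifications on the two C-terminal residues remain the dominant
irreducible failure mode (the residual then accumulates loss + modification
and matches neither).

## Degenerate inputs and numerical choices

Duplicate m/z values within a spectrum keep the highest intensity; peaks
with non-positive complementary mass are dropped from completion; spectra
without a usable precursor are skipped with a warning; PSM rows with
non-standard residues are rejected with a warning; a missing spectrum id
produces an error-marked output row rather than aborting the batch. A
zero-intensity spectrum reports explained intensity 0 with a warning.
Fragment tolerance defaults to 0.02 Da and the completion merge tolerance
to 0.01 Da, both configurable. All randomness flows through a single seeded
generator per run; batch alignment output is byte-identical across runs and
thread counts.
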