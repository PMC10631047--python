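# specshift

Spectral alignment of peptide-spectrum matches (PSMs) for open modification
search, with no a-priori modification list.

In bottom-up proteomics, an open modification search pairs an experimental
MS/MS spectrum *Se* with a candidate peptide whose theoretical spectrum *St*
may differ in precursor mass by some ΔM. When the peptide carries one or
several unanticipated modifications, ΔM has to be split into localized mass
shifts — and part of it may not be localizable at all (a neutral loss, a
dimer artifact, a charge-assignment error). `specshift` aligns each PSM by
dynamic programming and reports, for every peptide:

* an alignment string such as `HI[N][0.98]ATE[S][27.99]VR_301.99` — aligned
  residues bare, non-aligned residues bracketed, localized shifts in
  brackets at two decimals, and the non-aligned mass after `_`;
* the localized shifts with their residue positions;
* the numbers of peaks shared between *Se* and *St* before and after the
  alignment, and the fraction of total signal intensity explained.

## Method

A peptide of residues a₁…a_N is modeled by its b-ion prefix masses
(bᵢ = proton + Σ₁..ᵢ residues). Because experimental spectra mix b- and
y-ions, every observed peak is first *completed*: a complementary peak at
MH⁺ + proton − m/z is added, mapping y-ion evidence into b-ion coordinates
(peaks whose complement coincides with another observed peak are flagged as
carrying dual ion evidence). A dynamic program over (residues × completed
peaks) then assigns each residue one of three moves:

* **align** (+10 with dual ion evidence, +7 otherwise): the gap between two
  peaks, net of the mass of any residues skipped in between, equals the
  residue mass within the fragment tolerance (0.02 Da by default);
* **realign** (−8 / −6): the residue lands on a peak pair that matches its
  mass, but displaced — recording a mass shift;
* **non-align** (−4): the residue is skipped.

A realignment costs more than a skipped residue, so a shift must be repaid
by at least two subsequently aligned residues. The traceback from the best
last-row score yields the raw alignment. Post-processing then re-validates
every shift against the *native* peaks only: each shift keeps only the part
that increases the number of matched native b/y ions (the remainder
accumulates into the non-aligned mass), a residual mass is tested as a
modification of the two C-terminal residues, and non-aligned terminal
residues cancelled by a negative mass are trimmed (the semi-tryptic case).

The package also ships the simulation protocol used to benchmark the
aligner: doubly charged spectra of tryptic peptides with deterministic
deamidation (N, +0.984016 Da) and sodium adduct (D, +21.981943 Da), 20% of
fragment peaks removed (two thirds b-ions), up to 60 random noise peaks, and
a 17.03 Da neutral loss applied to each precursor — plus the evaluation
harness that scores alignments against the simulation ground truth.

## Worked example

```python
from specshift import b_ion_series, Spectrum, align_psm
from specshift.masses import PROTON

# simulate the spectrum of HINATESVR carrying a deamidation on N3 and a
# formylation on S7; all y-ions but only b2 and b8 survive
model = b_ion_series("HINATESVR", [(2, 0.984016), (6, 27.99491)])
peaks = [model.b_masses[1], model.b_masses[7]]
peaks += [model.mh + PROTON - b for b in model.b_masses[:-1]]
mz = (model.peptide_neutral_mass + 2 * PROTON) / 2
spectrum = Spectrum("demo", mz, 2, tuple(sorted((p, 1.0) for p in peaks)))

out = align_psm(spectrum, "HINATESVR")
print(out.row.aligned)        # HI[N][0.98]ATE[S][27.99]VR
print(out.final.shifts)       # [(2, 0.984016...), (6, 27.99491...)]
print(out.row.shared_after)   # 10
```

The alignment string says: H and I are corroborated by peak pairs, N is not
explained directly but a +0.98 Da shift (a deamidation on N) re-aligns the
following residues, and a further +27.99 Da shift (a formylation) is
introduced at S. All ten native peaks are matched once both shifts are
applied. Inflating the same precursor by 301.99 Da (a neutral loss) yields
`HI[N][0.98]ATE[S][27.99]VR_301.99`: the shifts stay localized and the
301.99 Da that no fragment supports is reported as non-aligned mass.

## Command line

```bash
specshift simulate --fasta proteome.fasta --n 1000 --seed 7 --out-prefix dsim
specshift align    --spectra dsim.mgf --psms dsim_psms.csv --out results.csv
specshift evaluate --results results.csv --truth dsim_truth.csv
```

`align` reads MGF or mzML spectra and a delimited PSM table (default
delimiter `;`, columns `spectrum` and `peptide`), and writes a CSV with the
`preAlignedPeptide` / `alignedPeptide` strings and the shared-peak and
intensity metrics. Scores and tolerances can be overridden with a
`key=value` file passed via `--scores`.

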