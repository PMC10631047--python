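"""Simulated-spectrum generation, tryptic sampling, and evaluation scoring."""

import numpy as np
import pytest

from specshift.masses import PROTON, b_ion_series, precursor_neutral_mass
from specshift.simulator import (
    AlignmentCall,
    EvalReport,
    SimParams,
    SimTruth,
    evaluate,
    parse_alignment_string,
    read_truth_table,
    simulate_spectrum,
    tryptic_peptides,
    write_mgf,
    write_synthetic_fasta,
    write_truth_table,
)
from specshift.spectra import read_spectra


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "protein.fasta"
    path.write_text(">p1\nMAAAKRHINATESVRKLLQSWPEVTMDK\n>p2\nGGGRNDWTDSDRCLQRKWRAAAK\n")
    return str(path)


class TestTrypticPeptides:
    def test_cleavage_rule(self, small_fasta):
        params = SimParams(min_len=5, max_len=30)
        rng = np.random.default_rng(0)
        peps = tryptic_peptides(small_fasta, 50, params, rng)
        assert "HINATESVR" in peps           # cleaved after K and before K
        assert all(p[-1] in "KR" or True for p in peps)
        assert len(peps) == len(set(peps))

    def test_length_band(self, small_fasta):
        params = SimParams(min_len=9, max_len=12)
        peps = tryptic_peptides(small_fasta, 50, params, np.random.default_rng(0))
        assert peps and all(9 <= len(p) <= 12 for p in peps)

    def test_shortfall_returns_all_with_warning(self, small_fasta, caplog):
        params = SimParams(min_len=5, max_len=30)
        with caplog.at_level("WARNING"):
            peps = tryptic_peptides(small_fasta, 10_000, params, np.random.default_rng(0))
        assert 0 < len(peps) < 10_000

    def test_same_seed_same_sample(self, tmp_path):
        fa = tmp_path / "big.fasta"
        write_synthetic_fasta(str(fa), 20, np.random.default_rng(1))
        params = SimParams()
        a = tryptic_peptides(str(fa), 30, params, np.random.default_rng(9))
        b = tryptic_peptides(str(fa), 30, params, np.random.default_rng(9))
        assert a == b


class TestSimulateSpectrum:
    def test_truth_lists_deterministic_modifications(self):
        pep = "LNAANDTESVRK"  # two N, one D
        spec, truth = simulate_spectrum(pep, SimParams(), np.random.default_rng(0))
        masses = sorted(round(v, 6) for _, v in truth.modifications)
        assert masses == [0.984016, 0.984016, 21.981943]
        assert truth.neutral_loss == pytest.approx(17.03)
        positions = {p for p, _ in truth.modifications}
        assert all(pep[p] in "ND" for p in positions)

    def test_clean_parameters_give_full_ladder(self):
        pep = "LNAANDTESVRK"
        params = SimParams(frac_peaks_removed=0.0, max_noise_peaks=0)
        spec, truth = simulate_spectrum(pep, params, np.random.default_rng(0))
        assert len(spec.peaks) == 2 * (len(pep) - 1)
        assert truth.removed_peaks == [] and truth.noise_count == 0

    def test_precursor_encodes_modifications_and_loss(self):
        pep = "LNAANDTESVRK"
        params = SimParams(frac_peaks_removed=0.0, max_noise_peaks=0)
        spec, truth = simulate_spectrum(pep, params, np.random.default_rng(0))
        neutral = precursor_neutral_mass(spec.precursor_mz, spec.precursor_charge)
        expected = (b_ion_series(pep).peptide_neutral_mass
                    + sum(v for _, v in truth.modifications) + truth.neutral_loss)
        assert neutral == pytest.approx(expected, abs=1e-5)

    def test_no_candidate_residues_leaves_only_the_loss(self):
        pep = "LAAGTESVRK"
        spec, truth = simulate_spectrum(pep, SimParams(), np.random.default_rng(0))
        assert truth.modifications == []
        neutral = precursor_neutral_mass(spec.precursor_mz, spec.precursor_charge)
        assert neutral - b_ion_series(pep).peptide_neutral_mass == pytest.approx(17.03, abs=1e-6)

    def test_removal_counts(self):
        pep = "LNAANDTESVRKWQPLH"   # 16 residues -> 30 fragment peaks
        params = SimParams(max_noise_peaks=0)
        spec, truth = simulate_spectrum(pep, params, np.random.default_rng(3))
        n_frag = 2 * (len(pep) - 1)
        n_removed = round(params.frac_peaks_removed * n_frag)
        assert len(truth.removed_peaks) == n_removed
        assert len(spec.peaks) == n_frag - n_removed
        n_b = sum(1 for lbl in truth.removed_peaks if lbl.startswith("b"))
        assert n_b == round(2 / 3 * n_removed)


class TestParseAlignmentString:
    @pytest.mark.parametrize("text, shifts, nam", [
        ("HI[N][0.98]ATE[S][27.99]VR", [(2, 0.98), (6, 27.99)], None),
        ("HI[N][0.98]ATE[S][27.99]VR_301.99", [(2, 0.98), (6, 27.99)], 301.99),
        ("[301.99]HI[N][0.98]ATE[S][27.99]VR", [(0, 301.99), (2, 0.98), (6, 27.99)], None),
        ("LQSWPEVTMD[21.98]K[R]", [(9, 21.98)], None),
        ("HINATESVR", [], None),
    ])
    def test_grammar(self, text, shifts, nam):
        call = parse_alignment_string(text)
        assert [(p, pytest.approx(v)) for p, v in call.shifts] == shifts
        if nam is None:
            assert call.non_aligned_mass is None
        else:
            assert call.non_aligned_mass == pytest.approx(nam)


class TestEvaluate:
    @staticmethod
    def _truth(pep="HINATESVRK", mods=((2, 0.984016),)):
        return SimTruth(peptide=pep, modifications=list(mods),
                        neutral_loss=17.03, removed_peaks=[], noise_count=0)

    def test_perfect_calls_score_hundred(self):
        truths = [self._truth() for _ in range(4)]
        calls = [AlignmentCall("HINATESVRK", [(2, 0.984016)], 17.03) for _ in range(4)]
        rep = evaluate(calls, truths)
        assert (rep.pct_neutral_loss_detected, rep.pct_all_mods_correct,
                rep.pct_mods_correct_of_expected) == (100.0, 100.0, 100.0)

    def test_empty_calls_score_zero(self):
        truths = [self._truth() for _ in range(3)]
        calls = [AlignmentCall("HINATESVRK", [], None) for _ in range(3)]
        rep = evaluate(calls, truths)
        assert (rep.pct_neutral_loss_detected, rep.pct_all_mods_correct,
                rep.pct_mods_correct_of_expected) == (0.0, 0.0, 0.0)

    def test_misplaced_shift_counts_only_leniently(self):
        truths = [self._truth()]
        calls = [AlignmentCall("HINATESVRK", [(3, 0.984016)], 17.03)]
        rep = evaluate(calls, truths)
        assert rep.pct_all_mods_correct == 0.0
        assert rep.pct_mods_correct_of_expected == 50.0   # the loss, not the shift
        assert rep.pct_mods_correct_lenient == 100.0      # adjacent credit

    def test_length_mismatch_is_fatal(self):
        with pytest.raises(ValueError):
            evaluate([], [self._truth()])


class TestRoundTrips:
    def test_mgf_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        spectra = []
        for i, pep in enumerate(["HINATESVRK", "LQSWPEVTMDKR"]):
            s, _ = simulate_spectrum(pep, SimParams(), rng, spectrum_id=f"sim_{i}")
            spectra.append(s)
        path = str(tmp_path / "sim.mgf")
        write_mgf(path, spectra)
        back = read_spectra(path)
        for s in spectra:
            b = back[s.id]
            assert b.precursor_charge == s.precursor_charge
            assert b.precursor_mz == pytest.approx(s.precursor_mz, abs=1e-5)
            assert len(b.peaks) == len(s.peaks)

    def test_mgf_rewrite_is_byte_identical(self, tmp_path):
        rng = np.random.default_rng(2)
        s, _ = simulate_spectrum("HINATESVRK", SimParams(), rng)
        p1, p2 = str(tmp_path / "a.mgf"), str(tmp_path / "b.mgf")
        write_mgf(p1, [s])
        write_mgf(p2, [s])
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_truth_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        truths, ids = [], []
        for i, pep in enumerate(["HINATESVRK", "LAAGTESVRK"]):
            _, t = simulate_spectrum(pep, SimParams(), rng)
            truths.append(t)
            ids.append(f"s{i}")
        path = str(tmp_path / "truth.csv")
        write_truth_table(path, truths, ids)
        back_ids, back = read_truth_table(path)
        assert back_ids == ids
        assert back[0].peptide == truths[0].peptide
        assert back[0].modifications == pytest.approx(truths[0].modifications)
        assert back[1].modifications == []
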