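"""Decoy generation, peak matching, scoring and the full search loop."""

import numpy as np
import pytest

from phosid.chem import ModifiedPeptide, fragment_ions, peptide_mass
from phosid.proteolysis import ProteinEntry
from phosid.search import (DECOY_PREFIX, SearchParams, build_candidate_index,
                           detect_diagnostic_ions, make_decoys, match_peaks,
                           psm_table, score_psm, search_run)
from phosid.spectra import Ms2Spectrum
from phosid.synthetic import (BENCHMARK_DIGEST, make_proteome,
                              make_search_benchmark, synthesize_spectrum)


def spectrum_with(mzs, intensities=None, precursor_mz=500.0, charge=2):
    mzs = np.asarray(mzs, float)
    if intensities is None:
        intensities = np.ones_like(mzs)
    return Ms2Spectrum("s1", precursor_mz, charge, 0.0, mzs, intensities)


class TestDecoys:
    def test_full_reversal_with_prefix(self):
        (decoy,) = make_decoys([ProteinEntry("P1", "", "ACDK")])
        assert decoy.sequence == "KDCA"
        assert decoy.id == DECOY_PREFIX + "P1"

    def test_palindrome_decoy_equals_target_and_is_logged(self, caplog):
        with caplog.at_level("INFO"):
            (decoy,) = make_decoys([ProteinEntry("P1", "", "ACA")])
        assert decoy.sequence == "ACA"
        assert "palindromic" in caplog.text

    def test_database_size_preserved(self, proteome):
        assert len(make_decoys(proteome)) == len(proteome)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            make_decoys([])


class TestMatchPeaks:
    def frag(self, mz):
        from phosid.chem import TheoreticalFragment
        return TheoreticalFragment("b", 1, 1, "", mz)

    def test_within_tolerance_matches(self):
        s = spectrum_with([500.0010])
        assert match_peaks(s, [self.frag(500.0)], tol_ppm=20) == [(0, "b1")]

    def test_outside_tolerance_unmatched(self):
        s = spectrum_with([500.0150])
        assert match_peaks(s, [self.frag(500.0)], tol_ppm=20) == []

    def test_equidistant_tie_goes_to_lower_mz(self):
        s = spectrum_with([499.9990, 500.0010])
        assert match_peaks(s, [self.frag(500.0)], tol_ppm=20) == [(0, "b1")]

    def test_peak_used_once_per_class(self):
        s = spectrum_with([500.0000])
        frags = [self.frag(500.0), self.frag(500.0)]
        assert len(match_peaks(s, frags, tol_ppm=20)) == 1


class TestDiagnosticIons:
    def test_trigger_ion_detected(self, probe):
        s = spectrum_with([194.05822, 800.0])
        evidence = detect_diagnostic_ions(s, probe)
        assert any(theo == 194.05822 for theo, _o, _i, _e in evidence)

    def test_clean_spectrum_gives_no_evidence(self, probe):
        s = spectrum_with([800.0, 900.0, 1000.0])
        assert detect_diagnostic_ions(s, probe) == []

    def test_all_checked_ions_present(self, probe):
        s = spectrum_with(sorted(probe.checked_diagnostic_ions))
        evidence = detect_diagnostic_ions(s, probe)
        found = {theo for theo, _o, _i, _e in evidence}
        assert set(probe.checked_diagnostic_ions) <= found


class TestScore:
    def test_no_matching_peaks_scores_zero(self, probe):
        pep = ModifiedPeptide("PEPTIDEK")
        s = spectrum_with([100.0, 150.0], precursor_mz=0.0)
        assert score_psm(s, pep, probe).score == 0.0

    def test_deterministic(self, probe, rng):
        pep = ModifiedPeptide("PEPTIDEK")
        frags = fragment_ions(pep)
        s = spectrum_with([f.mz for f in frags[:4]] + [333.3, 444.4])
        a = score_psm(s, pep, probe).score
        b = score_psm(s, pep, probe).score
        assert a == b > 0

    def test_probe_evidence_raises_score_when_nl_di_present(self, probe, rng):
        pep = ModifiedPeptide(
            "ACDEFGHIK",
            modifications=((2, probe.name, probe.adduct_mass),))
        s = synthesize_spectrum(pep, probe, rng, "x", frag_detect_prob=0.5,
                                nl_yield=0.9, di_yield=1.0)
        aware = score_psm(s, pep, probe,
                          SearchParams(use_probe_evidence=True)).score
        blind = score_psm(s, pep, probe,
                          SearchParams(use_probe_evidence=False)).score
        assert aware > blind

    def test_score_monotone_under_matched_peak_addition(self, probe, rng):
        """Replacing a noise peak by a matching fragment never lowers the
        score (peak count held fixed)."""
        pep = ModifiedPeptide("LMNPQRSTVWK")
        frags = fragment_ions(pep)
        for _ in range(25):
            k = int(rng.integers(1, len(frags) - 1))
            chosen = rng.choice(len(frags), size=k, replace=False)
            noise = list(rng.uniform(1900, 2000, size=6))
            mzs = [frags[i].mz for i in chosen] + noise
            base = score_psm(spectrum_with(sorted(mzs)), pep, probe).score
            extra = [i for i in range(len(frags)) if i not in chosen]
            mzs2 = ([frags[i].mz for i in chosen]
                    + [frags[int(rng.choice(extra))].mz] + noise[:-1])
            more = score_psm(spectrum_with(sorted(mzs2)), pep, probe).score
            assert more >= base


class TestSearchRun:
    def test_empty_inputs_warn_and_return_empty(self, probe, proteome,
                                                caplog):
        with caplog.at_level("WARNING"):
            assert search_run([], proteome, probe) == []
        s = spectrum_with([100.0])
        with caplog.at_level("WARNING"):
            assert search_run([s], [], probe) == []

    def test_exhaustive_oracle_on_tiny_database(self, probe, rng):
        """search_run's top hit equals brute-force rescoring of every
        candidate within the precursor window."""
        proteins = [ProteinEntry("T1", "", "ACDEFGKLMNPQRK"),
                    ProteinEntry("T2", "", "WYVHGSTKAAACDK")]
        index = build_candidate_index(proteins, probe, BENCHMARK_DIGEST)
        source = ModifiedPeptide("ACDEFGK")
        s = synthesize_spectrum(source, probe, rng, "t", charge=2,
                                frag_detect_prob=0.95, noise_peaks=5)
        params = SearchParams()
        accepted = search_run([s], index, probe, BENCHMARK_DIGEST,
                              params=params)
        mass = s.precursor_mz * 2 - 2 * probe.charge_carrier_mass
        pool = index.lookup(mass, params.precursor_tol_ppm)
        assert pool, "oracle needs candidates in the window"
        best = max(pool, key=lambda c: score_psm(s, c, probe, params).score)
        assert accepted and accepted[0].candidate.sequence == best.sequence

    def test_decoy_spectra_rejected_at_fdr(self, probe, rng):
        """Spectra generated from decoy sequences yield ~no accepted PSMs."""
        proteome = make_proteome(10, seed=50)
        decoys = make_decoys(proteome)
        index = build_candidate_index(proteome, probe, BENCHMARK_DIGEST)
        spectra = []
        from phosid.proteolysis import digest_tryptic
        peps = [p for d in decoys for p in
                digest_tryptic(d, BENCHMARK_DIGEST)][:60]
        for i, pep in enumerate(peps):
            spectra.append(synthesize_spectrum(
                ModifiedPeptide(pep.sequence), probe, rng, f"d{i}"))
        accepted = search_run(spectra, index, probe, BENCHMARK_DIGEST)
        assert len(accepted) <= max(2, 0.05 * len(spectra))

    def test_decoy_scores_dominated_by_target_scores(self, probe, rng):
        """Median best-match score against a decoy-only database is below
        the target-database median for target-generated spectra."""
        proteome = make_proteome(10, seed=51)
        spectra, _truth = make_search_benchmark(
            proteome, probe, n_spectra=60, foreign_fraction=0.0, seed=51)
        target_idx = build_candidate_index(proteome, probe, BENCHMARK_DIGEST,
                                           with_decoys=False)
        decoy_idx = build_candidate_index(make_decoys(proteome), probe,
                                          BENCHMARK_DIGEST,
                                          with_decoys=False)
        params = SearchParams()

        def best_scores(index):
            out = []
            for s in spectra:
                mass = (s.precursor_mz * s.precursor_charge
                        - s.precursor_charge * probe.charge_carrier_mass)
                pool = index.lookup(mass, params.precursor_tol_ppm)
                out.append(max((score_psm(s, c, probe, params).score
                                for c in pool), default=0.0))
            return np.array(out)

        assert (np.median(best_scores(target_idx))
                > np.median(best_scores(decoy_idx)))

    def test_same_seed_gives_byte_identical_table(self, probe, proteome):
        results = []
        for _ in range(2):
            spectra, _t = make_search_benchmark(proteome, probe,
                                                n_spectra=80, seed=7)
            accepted = search_run(spectra, proteome, probe, BENCHMARK_DIGEST)
            results.append(psm_table(accepted).to_csv(index=False))
        assert results[0] == results[1]

    def test_q_values_in_unit_interval_and_no_decoys_reported(
            self, probe, proteome):
        spectra, _t = make_search_benchmark(proteome, probe, n_spectra=80,
                                            seed=8)
        accepted = search_run(spectra, proteome, probe, BENCHMARK_DIGEST)
        assert accepted
        for psm in accepted:
            assert 0.0 <= psm.q_value <= 1.0
            assert not psm.is_decoy
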