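"""Screening criteria: isotope-fit score, blank thresholds, per-well matching
and replicate consensus."""

import numpy as np
import pytest

from maldiscreen.chem import apply_species, parse_formula, parse_species, theoretical_mz
from maldiscreen.isotopes import IsotopePattern, isotope_pattern
from maldiscreen.plate import CompoundRecord, PlateManifest, WellInfo
from maldiscreen.screening import (
    Detection,
    ScreeningCriteria,
    blank_threshold,
    consensus,
    iso_fit_score,
    screen_well,
)

from .conftest import make_spectrum


def spectrum_from_pattern(pattern, scale=1000.0, polarity="negative", well_id="W", shift=0.0):
    return make_spectrum(
        [(mz + shift, rel * scale) for mz, rel in pattern.peaks()], polarity, well_id
    )


class TestIsoFitScore:
    def test_exact_agreement_scores_zero(self):
        pat = isotope_pattern(parse_formula("C15H11Br4O2"))
        s = spectrum_from_pattern(pat, scale=5000.0)
        score = iso_fit_score(pat, s, anchor_mz=pat.monoisotopic_mz, tol=0.005)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        pat = isotope_pattern(parse_formula("C6H2Br3O"))
        for scale in (1.0, 1e3, 1e7):
            s = spectrum_from_pattern(pat, scale=scale)
            assert iso_fit_score(pat, s, pat.monoisotopic_mz, 0.005) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_peak_case(self):
        # theoretical (0.5, 0.5), measured (1, 0):
        # 1000 * sqrt((0.25 + 0.25)/2) = 500
        pat = IsotopePattern((100.0, 101.0), (0.5, 0.5))
        s = make_spectrum([(100.0, 123.0)])
        assert iso_fit_score(pat, s, 100.0, 0.005) == pytest.approx(500.0)

    def test_monotone_under_single_peak_perturbation(self):
        pat = isotope_pattern(parse_formula("C6H2Br3O"))
        base = [(mz, rel * 1000.0) for mz, rel in pat.peaks()]
        rng = np.random.default_rng(42)
        prev_scores = {}
        for eps in (0.0, 0.1, 0.2, 0.4, 0.8):
            for idx in range(3):
                peaks = list(base)
                mz, h = peaks[idx]
                peaks[idx] = (mz, h * (1.0 + eps))
                s = make_spectrum(peaks)
                score = iso_fit_score(pat, s, pat.monoisotopic_mz, 0.005)
                key = idx
                if key in prev_scores:
                    assert score >= prev_scores[key] - 1e-9
                prev_scores[key] = score

    def test_anchor_shift_alignment(self):
        # whole measured envelope offset by +3 mDa still scores ~0 when
        # anchored on the observed monoisotopic peak
        pat = isotope_pattern(parse_formula("C15H11Br4O2"))
        s = spectrum_from_pattern(pat, shift=0.003)
        score = iso_fit_score(pat, s, anchor_mz=pat.monoisotopic_mz + 0.003, tol=0.005)
        assert score < 1.0


class TestBlankThreshold:
    def test_three_times_highest_blank(self):
        blanks = [make_spectrum([(250.0, h)]) for h in (10.0, 20.0, 15.0)]
        assert blank_threshold(blanks, 250.0, 0.005, 3.0) == pytest.approx(60.0)

    def test_empty_blanks_give_zero_threshold(self):
        blanks = [make_spectrum([]) for _ in range(3)]
        assert blank_threshold(blanks, 250.0, 0.005, 3.0) == 0.0

    def test_noise_floor_used_when_no_peak_near_target(self):
        blank = make_spectrum([(100.0, 10.0), (200.0, 30.0), (300.0, 20.0)])
        # median intensity = 20 -> threshold 60
        assert blank_threshold([blank], 500.0, 0.005, 3.0) == pytest.approx(60.0)

    def test_boundary_equality_fails_strictly(self):
        # a sample peak exactly at 3x the highest blank must NOT pass
        tbbpa = parse_formula("C15H12Br4O2")
        sp = parse_species("M-H", "negative")
        mz = theoretical_mz(tbbpa, sp)
        pat = isotope_pattern(apply_species(tbbpa, sp))
        blanks = [make_spectrum([(mz, 50.0)], "negative") for _ in range(3)]
        peaks = [(m, rel / pat.rel_intensity[0] * 150.0) for m, rel in pat.peaks()]
        s = make_spectrum(peaks, "negative", "W05")
        db = [CompoundRecord("TBBPA", "79-94-7", tbbpa, "BFR", None, (sp,))]
        results = screen_well(s, db, ScreeningCriteria(), blanks)
        (r,) = [r for r in results if r.species == "M-H"]
        assert r.peak_height == pytest.approx(150.0)
        assert r.blank_threshold == pytest.approx(150.0)
        assert not r.blank_ok
        assert not r.passed_all


def tbbpa_record():
    return CompoundRecord(
        "TBBPA", "79-94-7", parse_formula("C15H12Br4O2"), "BFR",
        None, (parse_species("M-H", "negative"),),
    )


class TestScreenWell:
    def test_spiked_envelope_passes_all_criteria(self):
        rec = tbbpa_record()
        ion = apply_species(rec.formula, rec.neg_species[0])
        pat = isotope_pattern(ion)
        s = spectrum_from_pattern(pat, scale=1000.0, well_id="W05")
        blanks = [make_spectrum([(400.0, 10.0)], "negative") for _ in range(3)]
        results = screen_well(s, [rec], ScreeningCriteria(), blanks)
        assert len(results) == 1
        r = results[0]
        assert r.passed_all
        assert r.species == "M-H"
        assert abs(r.mass_error_mda) < 1e-6
        assert r.iso_fit_score == pytest.approx(0.0, abs=1e-9)

    def test_absent_compound_not_matched(self):
        rec = tbbpa_record()
        s = make_spectrum([(300.0, 1000.0)], "negative", "W05")
        assert screen_well(s, [rec], ScreeningCriteria(), []) == []

    def test_empty_spectrum_gives_empty_list(self):
        s = make_spectrum([], "negative")
        assert screen_well(s, [tbbpa_record()], ScreeningCriteria(), []) == []

    def test_tolerance_monotonicity(self):
        # shrinking mass_tol or sigma_max, or raising blank_factor,
        # never adds passing matches
        rec = tbbpa_record()
        ion = apply_species(rec.formula, rec.neg_species[0])
        pat = isotope_pattern(ion)
        peaks = [(mz + 0.003, rel * 100.0) for mz, rel in pat.peaks()]
        s = make_spectrum(peaks, "negative", "W05")
        blanks = [make_spectrum([(ion and 400.0, 30.0)], "negative")]

        def n_pass(**kw):
            res = screen_well(s, [rec], ScreeningCriteria(**kw), blanks)
            return sum(r.passed_all for r in res)

        assert n_pass(mass_tol=0.005) >= n_pass(mass_tol=0.002)
        assert n_pass(sigma_max=100.0) >= n_pass(sigma_max=1e-6)
        assert n_pass(blank_factor=3.0) >= n_pass(blank_factor=30.0)


def triplicate_manifest():
    wells = [WellInfo(f"W{i:02d}", "sample", "S1", i) for i in (1, 2, 3)]
    return PlateManifest(wells)


def passing_result(well_id, compound="TBBPA", species="M-H", ion="C15H11Br4O2"):
    from maldiscreen.screening import MatchResult

    return MatchResult(
        compound=compound, species=species, polarity="negative", well_id=well_id,
        theoretical_mz=542.7446, observed_mz=542.7446, mass_error_mda=0.0,
        peak_height=1000.0, iso_fit_score=5.0, blank_threshold=100.0,
        ion_formula=ion, mass_ok=True, sigma_ok=True, blank_ok=True,
    )


class TestConsensus:
    def test_three_of_three_validates_at_level_4(self):
        results = {f"W{i:02d}": [passing_result(f"W{i:02d}")] for i in (1, 2, 3)}
        dets = consensus(results, triplicate_manifest(), ScreeningCriteria())
        (d,) = dets
        assert d.validated
        assert d.times_detected == "3/3"
        assert d.confidence_level == 4

    def test_two_of_three_reported_not_validated(self):
        results = {
            "W01": [passing_result("W01")],
            "W02": [passing_result("W02")],
            "W03": [],
        }
        (d,) = consensus(results, triplicate_manifest(), ScreeningCriteria())
        assert d.times_detected == "2/3"
        assert not d.validated

    def test_isobaric_compounds_share_group_and_both_listed(self):
        # same post-species molecular formula -> indistinguishable by exact
        # mass + isotope pattern
        results = {
            f"W{i:02d}": [
                passing_result(f"W{i:02d}", "DEHP", "M+K", "C24H38KO4"),
                passing_result(f"W{i:02d}", "DNOP", "M+K", "C24H38KO4"),
            ]
            for i in (1, 2, 3)
        }
        dets = consensus(results, triplicate_manifest(), ScreeningCriteria())
        assert {d.compound for d in dets} == {"DEHP", "DNOP"}
        groups = {d.isobar_group for d in dets}
        assert len(groups) == 1 and "" not in groups
        assert all(d.validated for d in dets)

    def test_missing_replicate_well_is_an_error(self):
        results = {"W01": [passing_result("W01")], "W02": []}
        with pytest.raises(ValueError, match="replicate"):
            consensus(results, triplicate_manifest(), ScreeningCriteria())
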