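"""Frequency selection, type assignment, leveling and diagnostics."""

import pytest

from ptm_integrator.classify import (
    LocalizationGate,
    assign_ptm_type,
    classify_level,
    exclude_isotope_confusable,
    flag_misassignment,
    high_frequency_ptms,
)
from ptm_integrator.core import Level, MassShift, MatchConfig, PTMDefinition, TypedMassShift
from ptm_integrator.ptms import NTA_NAME

CFG = MatchConfig()


def _s(mass, a, b, protein="P1", score=None, rid="x"):
    return MassShift(mass=mass, protein=protein, region_start=a, region_end=b, record_id=rid, score=score)


class TestHighFrequencySelection:
    def _run(self, n_matched, total, ptm_table):
        seqs = {"P1": "AAMAAAAA"}
        psms = [(f"psm{i}", _s(15.995, 1, 8, rid=f"psm{i}.s0")) for i in range(n_matched)]
        return high_frequency_ptms(psms, ptm_table, total, seqs, cfg=CFG)

    def test_above_threshold_selected(self, ptm_table):
        freq, selected = self._run(20, 10_000, ptm_table)
        assert freq.frequency("Oxidation") == pytest.approx(0.002)
        assert "Oxidation" in {p.name for p in selected}

    def test_exact_threshold_not_selected(self, ptm_table):
        _, selected = self._run(15, 10_000, ptm_table)
        assert "Oxidation" not in {p.name for p in selected}

    def test_psm_counted_once_per_ptm(self, ptm_table):
        seqs = {"P1": "AAMAAAAA"}
        psms = [("psm0", _s(15.995, 1, 8)), ("psm0", _s(15.996, 1, 8))]
        freq, _ = high_frequency_ptms(psms, ptm_table, 10, seqs, cfg=CFG)
        assert freq.counts["Oxidation"] == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            high_frequency_ptms([], [], 10, {})


class TestIsotopeConfusableExclusion:
    def test_default_table_drops_exactly_deamidation(self, ptm_table):
        out = exclude_isotope_confusable(ptm_table, CFG)
        assert {p.name for p in ptm_table} - {p.name for p in out} == {"Deamidation"}

    def test_without_deamidation_unchanged(self, ptm_table):
        rest = [p for p in ptm_table if p.name != "Deamidation"]
        assert exclude_isotope_confusable(rest, CFG) == rest

    def test_artificial_near_neutron_mass_removed(self):
        fake = PTMDefinition("fake", 1.05, frozenset("A"))
        assert exclude_isotope_confusable([fake], CFG) == []


class TestAssignType:
    def test_acetyl_trimethyl_ambiguity_ordered_by_error(self, ptm_table):
        selected = exclude_isotope_confusable(ptm_table, CFG)
        cands = assign_ptm_type(_s(42.02, 5, 10), selected, "AAAAKAAAAA", CFG)
        # acetylation and trimethylation compete at offset 0, smaller error
        # first; carbamylation only qualifies through a -1 neutron offset
        # and therefore ranks last
        assert [c.ptm.name for c in cands] == ["Acetylation", "Trimethylation", "Carbamylation"]
        assert cands[0].mass_error == pytest.approx(0.00943, abs=1e-5)
        assert cands[1].mass_error == pytest.approx(0.02695, abs=1e-5)
        assert cands[2].isotope_offset == -1

    def test_no_eligible_residue_empty(self, ptm_table):
        assert assign_ptm_type(_s(79.97, 1, 8), ptm_table, "AAAAAAAA", CFG) == []

    def test_negative_mass_no_candidate(self, ptm_table):
        selected = exclude_isotope_confusable(ptm_table, CFG)
        assert assign_ptm_type(_s(-43.01, 1, 8), selected, "ACAAAAAA", CFG) == []

    def test_missing_sequence_fails_loudly(self, ptm_table):
        with pytest.raises(ValueError):
            assign_ptm_type(_s(15.995, 1, 8), ptm_table, None, CFG)


class TestClassifyLevel:
    def test_nta_is_level1(self, ptm):
        s = _s(42.01057, 1, 1)
        label = classify_level(s, [TypedMassShift(s, ptm[NTA_NAME])], LocalizationGate(), "MAAA")
        assert label.value is Level.L1 and label.is_nta

    def test_ambiguous_low_score_is_level2a(self, ptm):
        seq = "A" * 9 + "M" + "A" * 4 + "M" + "A" * 4 + "M" + "A" * 5 + "M" + "A" * 8
        s = _s(15.995, 10, 30, score=0.3)
        label = classify_level(s, [TypedMassShift(s, ptm["Oxidation"])], LocalizationGate(), seq)
        assert label.value is Level.L2A and not label.is_nta

    def test_unique_site_is_level1_without_score(self, ptm):
        seq = "A" * 14 + "S" + "A" * 20  # single Ser in the region
        s = _s(79.966, 10, 30)
        label = classify_level(s, [TypedMassShift(s, ptm["Phosphorylation"])], LocalizationGate(), seq)
        assert label.value is Level.L1

    def test_score_gate(self, ptm):
        seq = "A" * 9 + "MM" + "A" * 25
        s_hi = _s(15.995, 10, 30, score=0.61)
        s_lo = _s(15.995, 10, 30, score=0.59)
        cand = lambda s: [TypedMassShift(s, ptm["Oxidation"])]
        assert classify_level(s_hi, cand(s_hi), LocalizationGate(), seq).value is Level.L1
        assert classify_level(s_lo, cand(s_lo), LocalizationGate(), seq).value is Level.L2A

    def test_no_candidates_level3(self):
        assert classify_level(_s(123.4, 1, 10), [], LocalizationGate(), "A" * 10).value is Level.L3


class TestMisassignmentDiagnostic:
    def test_minus_43_with_cys_flagged(self, ptm_table):
        diag = flag_misassignment(_s(-43.006, 3, 8), "AACAAAAA", ptm_table, CFG)
        assert diag is not None and "methyl" in diag.explanation

    def test_no_cys_not_flagged(self, ptm_table):
        assert flag_misassignment(_s(-43.006, 3, 8), "AAAAAAAA", ptm_table, CFG) is None

    def test_positive_43_not_flagged(self, ptm_table):
        assert flag_misassignment(_s(43.006, 3, 8), "AACAAAAA", ptm_table, CFG) is None
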