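"""Verification passes, overlap accounting, histograms, pipeline behavior."""

import copy

import pytest

from ptm_integrator.classify import ClassifiedShift, LocalizationGate, classify_level
from ptm_integrator.core import Level, LevelLabel, MassShift, MatchConfig, Source, TypedMassShift
from ptm_integrator.ingest import AnnotationRecord
from ptm_integrator.ptms import NTA_NAME
from ptm_integrator.verify import (
    VerificationResult,
    histogram,
    overlap_partition,
    verify_by_annotation,
    verify_by_bottomup,
)

CFG = MatchConfig()


def _s(mass, a, b, protein="P1", rid="x", source=Source.TOPDOWN):
    return MassShift(mass=mass, protein=protein, region_start=a, region_end=b,
                     source=source, record_id=rid)


def _classified(shift, ptm=None, level=Level.L3, is_nta=False):
    cands = [TypedMassShift(shift, ptm)] if ptm else []
    return ClassifiedShift(shift, cands, LevelLabel(level, is_nta))


class TestBottomupVerification:
    def test_typed_match_verifies(self, ptm):
        seq = "A" * 14 + "M" + "A" * 10
        td = _classified(_s(15.995, 10, 20, rid="td"), ptm["Oxidation"], Level.L2A)
        bu = TypedMassShift(_s(15.995, 15, 15, rid="bu", source=Source.BOTTOMUP), ptm["Oxidation"])
        (res,) = verify_by_bottomup([td], [bu.shift], [bu], {"P1": seq}, CFG)
        assert res.verified_by_bottomup and res.bottomup_ids == ["bu"]

    def test_level3_uses_untyped_rule(self, ptm):
        td = _classified(_s(15.995, 10, 20, rid="td"))  # L3, no type
        bu = TypedMassShift(_s(15.996, 12, 18, rid="bu", source=Source.BOTTOMUP), ptm["Oxidation"])
        (res,) = verify_by_bottomup([td], [bu.shift], [bu], {"P1": "A" * 30}, CFG)
        assert res.verified_by_bottomup  # type ignored for level 3

    def test_nta_verifies_at_position_one(self, ptm):
        nta = ptm[NTA_NAME]
        td = _classified(_s(nta.mass, 1, 1, rid="td"), nta, Level.L1, is_nta=True)
        bu = TypedMassShift(_s(nta.mass, 1, 1, rid="bu", source=Source.BOTTOMUP), nta)
        (res,) = verify_by_bottomup([td], [bu.shift], [bu], {"P1": "MAAK"}, CFG)
        assert res.verified_by_bottomup

    def test_typed_mismatch_not_verified(self, ptm):
        seq = "A" * 14 + "M" + "A" * 10
        td = _classified(_s(15.995, 10, 20, rid="td"), ptm["Oxidation"], Level.L2A)
        bu = TypedMassShift(_s(14.016, 15, 15, rid="bu", source=Source.BOTTOMUP), ptm["Methylation"])
        (res,) = verify_by_bottomup([td], [bu.shift], [bu], {"P1": seq}, CFG)
        assert not res.verified_by_bottomup


class TestAnnotationVerification:
    def _result(self, shift, ptm=None, level=Level.L3):
        return VerificationResult(_classified(shift, ptm, level))

    def test_site_in_region_verifies(self, ptm):
        res = self._result(_s(42.01, 1, 5), ptm["Acetylation"], Level.L2A)
        ann = AnnotationRecord("P1", 2, "N6-acetyllysine", "Acetylation", "uniprot")
        verify_by_annotation([res], [ann], list(ptm.values()), CFG)
        assert res.verified_by_annotation("uniprot")

    def test_site_outside_region_no_match(self, ptm):
        res = self._result(_s(79.97, 10, 20), ptm["Phosphorylation"], Level.L2A)
        ann = AnnotationRecord("P1", 50, "Phosphoserine", "Phosphorylation", "uniprot")
        verify_by_annotation([res], [ann], list(ptm.values()), CFG)
        assert not res.verified_by_annotation()

    def test_isotope_corrected_mass_matches(self, ptm):
        res = self._result(_s(80.968, 10, 20), ptm["Phosphorylation"], Level.L2A)
        ann = AnnotationRecord("P1", 15, "Phosphoserine", "Phosphorylation", "dbptm")
        verify_by_annotation([res], [ann], list(ptm.values()), CFG)
        assert res.verified_by_annotation("dbptm")

    def test_typed_requires_name_equality(self, ptm):
        res = self._result(_s(42.03, 10, 20), ptm["Trimethylation"], Level.L2A)
        ann = AnnotationRecord("P1", 15, "N6-acetyllysine", "Acetylation", "uniprot")
        verify_by_annotation([res], [ann], list(ptm.values()), CFG)
        assert not res.verified_by_annotation()

    def test_unresolvable_never_matches(self, ptm):
        res = self._result(_s(42.01, 1, 5), ptm["Acetylation"], Level.L2A)
        ann = AnnotationRecord("P1", 2, "weird mod", None, "uniprot")
        verify_by_annotation([res], [ann], list(ptm.values()), CFG)
        assert not res.verified_by_annotation()


class TestOverlapPartition:
    def _mk(self, bu, uni):
        r = VerificationResult(_classified(_s(10.0, 1, 5)))
        if bu:
            r.bottomup_ids = ["b"]
        if uni:
            r.annotation_ids = {"uniprot": ["a"]}
        return r

    def test_partition_counts(self):
        results = [self._mk(True, False)] * 3 + [self._mk(False, True)] * 2 + [self._mk(True, True)]
        part = overlap_partition(results)["overall"]
        assert (part["bottomup_only"], part["annotation_only"], part["both"]) == (3, 2, 1)
        assert part["union"] == 6
        assert part["bottomup_only_pct"] == pytest.approx(50.0)

    def test_nothing_verified(self):
        part = overlap_partition([self._mk(False, False)])["overall"]
        assert (part["bottomup_only"], part["annotation_only"], part["both"]) == (0, 0, 0)

    def test_partition_sums_to_union(self):
        results = [self._mk(b, u) for b in (0, 1) for u in (0, 1) for _ in range(3)]
        part = overlap_partition(results)["overall"]
        assert part["bottomup_only"] + part["annotation_only"] + part["both"] == part["union"]


class TestHistogram:
    def test_binning(self):
        table, overflow = histogram([15.99, 15.995, 16.00, 79.97], 0.0, 200.0, 1.0)
        counts = dict(zip(table["bin_start"], table["count"]))
        # half-open bins: 16.00 belongs to [16, 17), not [15, 16)
        assert counts[15.0] == 2 and counts[16.0] == 1 and counts[79.0] == 1
        assert overflow == 0

    def test_empty(self):
        table, overflow = histogram([], 0.0, 10.0, 1.0)
        assert table["count"].sum() == 0 and overflow == 0

    def test_half_open_upper_edge(self):
        table, overflow = histogram([200.0], 0.0, 200.0, 1.0)
        assert table["count"].sum() == 0 and overflow == 1

    def test_conservation(self):
        masses = [-600.0, -12.3, 0.0, 5.5, 499.999, 500.0, 777.0]
        table, overflow = histogram(masses, -500.0, 500.0, 1.0)
        assert table["count"].sum() + overflow == len(masses)


class TestPipeline:
    def test_empty_bottomup_completes(self, e2e_paths, tmp_path):
        import yaml
        from ptm_integrator import run_pipeline

        base = e2e_paths["config"].parent
        cfg = yaml.safe_load(e2e_paths["config"].read_text())
        cfg["fasta"] = str(base / cfg["fasta"])
        cfg["topdown"]["path"] = str(base / cfg["topdown"]["path"])
        cfg["annotations"] = [{**a, "path": str(base / a["path"])} for a in cfg["annotations"]]
        empty = tmp_path / "empty_bu.tsv"
        empty.write_text(
            "Spectrum\tPeptide\tProtein ID\tProtein Start\tDelta Mass\tAssigned Modifications\n"
            "S1\tNOPE\tSYN000\t1\t\t\n"  # skipped: peptide does not map
        )
        cfg["bottomup"]["path"] = str(empty)
        res = run_pipeline(cfg)
        assert res.summary.n_topdown_kept > 0
        assert all(not r.verified_by_bottomup for r in res.results)

    def test_typed_verification_implies_untyped(self, e2e_run):
        """Typed bottom-up evidence is a subset of untyped evidence."""
        from ptm_integrator.core import match_shift

        result, _ = e2e_run
        bu_shifts = [c.shift for c in result.bottomup_classified]
        for r in result.results:
            if r.item.level.value is not Level.L3 and r.verified_by_bottomup:
                assert any(match_shift(r.item.shift, b, CFG) for b in bu_shifts)

    def test_level_partition_sums(self, e2e_run):
        result, _ = e2e_run
        counts = result.summary.level_counts
        assert sum(counts.values()) == result.summary.n_topdown_kept
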