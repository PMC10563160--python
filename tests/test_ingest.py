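"""Readers, coordinate lifting and candidate-region extension."""

import numpy as np
import pytest

from ptm_integrator.core import MassShift, Source
from ptm_integrator.ingest import (
    PeptideRecord,
    extend_region,
    peptide_shift_to_protein,
    peptide_typed_shifts,
    read_annotations,
    read_bottomup,
    read_shifts_tsv,
    read_topdown,
    write_shifts_tsv,
)
from ptm_integrator.ptms import NTA_NAME


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


TD_HEADER = "Prsm ID\tProtein accession\tFirst residue\tLast residue\tUnexpected modifications\tVariable PTMs\tMatched fragment positions\n"


class TestReadTopdown:
    def test_count_preservation(self, tmp_path):
        p = _write(
            tmp_path,
            "td.tsv",
            TD_HEADER
            + "R1\tP1\t1\t100\t15.995:10-20:0.7\t\t8,9,21,22\n"
            + "R2\tP1\t1\t100\t79.966:30-45:0.2\t\t28,29,46,47\n"
            + "R3\tP2\t5\t90\t42.011:50-60:0.9\t\t48,49,61,62\n",
        )
        res = read_topdown(p, "toppic")
        assert len(res.records) == 3 and res.n_skipped == 0
        assert res.records[0].shifts == [(15.995, 10, 20, 0.7)]

    def test_region_outside_span_skipped(self, tmp_path):
        p = _write(
            tmp_path,
            "td.tsv",
            TD_HEADER + "R1\tP1\t10\t100\t15.995:5-20:0.7\t\t\n",
        )
        res = read_topdown(p, "toppic")
        assert len(res.records) == 0 and res.n_skipped == 1

    def test_nta_plus_unexpected_shift(self, tmp_path):
        p = _write(
            tmp_path,
            "td.tsv",
            TD_HEADER + f"R1\tP1\t1\t100\t15.995:10-20:0.7\t{NTA_NAME}:1\t8,9,21,22\n",
        )
        res = read_topdown(p, "toppic")
        (rec,) = res.records
        assert len(rec.shifts) == 1 and rec.variable_ptms == [(NTA_NAME, 1)]

    def test_unknown_dialect(self, tmp_path):
        p = _write(tmp_path, "td.tsv", TD_HEADER)
        with pytest.raises(ValueError, match="dialect"):
            read_topdown(p, "prosight")

    def test_missing_column(self, tmp_path):
        p = _write(tmp_path, "td.tsv", "Prsm ID\tFirst residue\n")
        with pytest.raises(ValueError, match="Protein accession"):
            read_topdown(p, "toppic")


BU_HEADER = "Spectrum\tPeptide\tProtein ID\tProtein Start\tDelta Mass\tAssigned Modifications\n"


class TestReadBottomup:
    def test_repeat_psms(self, tmp_path):
        rows = "".join(f"S{i}\tPEPTIDEK\tP1\t10\t15.995\t\n" for i in range(5))
        res = read_bottomup(_write(tmp_path, "bu.tsv", BU_HEADER + rows), "msfragger")
        assert len(res.records) == 5
        assert res.records[0].shifts == [15.995]

    def test_peptide_protein_mismatch_skipped(self, tmp_path):
        seqs = {"P1": "A" * 9 + "PEPTIDEK" + "A" * 10}
        p = _write(
            tmp_path,
            "bu.tsv",
            BU_HEADER + "S1\tPEPTIDEK\tP1\t10\t\t\nS2\tWRONGPEP\tP1\t10\t\t\n",
        )
        res = read_bottomup(p, "msfragger", sequences=seqs)
        assert len(res.records) == 1 and res.n_skipped == 1

    def test_maxquant_nterm_acetyl_normalized(self, tmp_path):
        p = _write(
            tmp_path,
            "mq.tsv",
            "id\tSequence\tProteins\tStart position\tModifications\n"
            "1\tMDPEPTIDEK\tP1\t1\tAcetyl (Protein N-term)\n",
        )
        res = read_bottomup(p, "maxquant")
        (rec,) = res.records
        assert rec.assigned_mods == [(NTA_NAME, 1)]


class TestCoordinateLifting:
    def test_unlocalized_shift_spans_peptide(self):
        rec = PeptideRecord("S1", "A" * 12, "P", 100, shifts=[15.995])
        (s,) = peptide_shift_to_protein(rec)
        assert (s.region_start, s.region_end) == (100, 111)
        assert s.mass == 15.995 and s.source is Source.BOTTOMUP

    def test_assigned_mod_single_site(self, ptm):
        rec = PeptideRecord("S1", "A" * 12, "P", 100, assigned_mods=[("Oxidation", 3)])
        (s,) = peptide_shift_to_protein(rec)
        assert (s.region_start, s.region_end) == (102, 102)
        assert s.mass == pytest.approx(ptm["Oxidation"].mass)
        (t,) = peptide_typed_shifts(rec)
        assert t.ptm.name == "Oxidation" and t.isotope_offset == 0

    def test_two_shifts_two_records(self):
        rec = PeptideRecord("S1", "A" * 12, "P", 100, shifts=[15.995, 79.966])
        assert len(peptide_shift_to_protein(rec)) == 2


def _shift(a, b, protein="P", span=(1, 50)):
    return MassShift(mass=10.0, protein=protein, region_start=a, region_end=b, record_id="x")


class TestExtendRegion:
    def test_left_extension_two_fragments(self):
        s = extend_region(_shift(10, 12), [4, 7, 9, 14, 16], (1, 50))
        assert s.region_start == 7  # covers fragments 9 and 7

    def test_left_reaches_nterm(self):
        s = extend_region(_shift(3, 12), [14, 16, 20], (1, 50))
        assert s.region_start == 1

    def test_right_extension_two_fragments(self):
        s = extend_region(_shift(10, 12), [8, 9, 14, 16, 20], (1, 50))
        assert s.region_end == 16  # covers fragments 14 and 16

    def test_no_fragments_unchanged(self):
        s = _shift(10, 12)
        assert extend_region(s, None, (1, 50)) is s

    def test_monotone_and_idempotent_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            first, last = 1, int(rng.integers(30, 80))
            a = int(rng.integers(first, last + 1))
            b = int(rng.integers(a, last + 1))
            frags = sorted(
                int(x) for x in rng.choice(np.arange(first, last + 1), size=rng.integers(0, 10), replace=False)
            )
            s = _shift(a, b, span=(first, last))
            e1 = extend_region(s, frags, (first, last))
            assert e1.region_start <= a and e1.region_end >= b
            e2 = extend_region(e1, frags, (first, last))
            assert (e2.region_start, e2.region_end) == (e1.region_start, e1.region_end)


class TestAnnotations:
    def test_dedup_and_unresolvable(self, tmp_path):
        p = _write(
            tmp_path,
            "ann.tsv",
            "Accession\tPosition\tDescription\n"
            "P1\t2\tN-acetylalanine\n"
            "P1\t2\tN-acetylalanine\n"
            "P1\t30\tPhosphoserine\n"
            "P1\t40\tGPI-anchor amidated serine\n",
        )
        res = read_annotations(p, "uniprot")
        assert len(res.records) == 3  # duplicate triple collapsed
        by_site = {r.site: r for r in res.records}
        assert by_site[2].ptm == NTA_NAME
        assert by_site[30].ptm == "Phosphorylation"
        assert by_site[40].ptm is None and not by_site[40].resolvable


def test_shift_table_round_trip(tmp_path):
    shifts = [
        MassShift(15.995, "P1", 10, 20, Source.TOPDOWN, "a", 0.7),
        MassShift(-43.006, "P2", 3, 9, Source.BOTTOMUP, "b", None),
    ]
    path = tmp_path / "shifts.tsv"
    write_shifts_tsv(shifts, path)
    back = read_shifts_tsv(path)
    assert [(s.protein, s.region, s.record_id, s.score) for s in back] == [
        (s.protein, s.region, s.record_id, s.score) for s in shifts
    ]
    assert all(abs(x.mass - y.mass) < 1e-6 for x, y in zip(back, shifts))
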