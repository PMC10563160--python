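"""Duplicate removal and PTM type assignment.

Overlapping proteoform identifications report the same modification many
times; clustering by mass followed by a greedy sweep over region-ranked
members keeps one record per event.  Surviving shifts are then matched
against the high-frequency modification table to propose PTM types.
"""

from ptm_integrator import MassShift, MatchConfig, assign_ptm_type, builtin_ptm_table, dedup_all
from ptm_integrator.classify import exclude_isotope_confusable

cfg = MatchConfig()

print("-- duplicate removal (two proteoforms of one protein) --")
shifts = [
    MassShift(14.016, "P", 5, 15, record_id="A.green"),
    MassShift(15.995, "P", 30, 45, record_id="A.orange"),
    MassShift(15.999, "P", 40, 60, record_id="B.yellow"),  # same event as A.orange
]
kept, audit = dedup_all(shifts)
print("kept:   ", [s.record_id for s in kept])
print("removed:", audit[["removed_record_id", "kept_record_id"]].to_dict("records"))
# B.yellow overlaps A.orange with a 0.004 Da mass difference: one event,
# one surviving record.

print("\n-- type assignment for an ambiguous +42 Da shift --")
table = exclude_isotope_confusable(builtin_ptm_table(), cfg)
shift = MassShift(42.02, "P", 5, 10, record_id="x")
for cand in assign_ptm_type(shift, table, "AAAAKAAAAA", cfg):
    print(f"{cand.ptm.name:15s} error={cand.mass_error:.5f} Da  offset={cand.isotope_offset:+d}")
# Acetylation (42.011) and trimethylation (42.047) both fit a lysine within
# 0.1 Da; the smaller mass error ranks acetylation first, and carbamylation
# only qualifies through a -1 neutron offset, so it ranks last.
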