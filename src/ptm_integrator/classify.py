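"""PTM frequency selection, type assignment, and level classification.

Mass shifts only become interpretable once compared against a restricted set
of candidate modifications: the ones observed at high frequency in the
bottom-up data (strictly more than 0.15% of all identified PSMs carrying a
matching shift on an eligible residue).  Modifications whose mass is
indistinguishable from the +/-1 neutron deconvolution error (deamidation,
0.984 Da) are excluded from that set.  Typed shifts are then classified:

* level 1  - type identified and site localized (localization score at or
  above the gate, a unique eligible site, or a fixed-terminus PTM);
* level 2A - type identified, site ambiguous;
* level 3  - no type identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    Level,
    LevelLabel,
    MassShift,
    MatchConfig,
    PTMDefinition,
    TypedMassShift,
    mass_match,
    modifiable_positions,
    region_has_modifiable,
)

HIGH_FREQUENCY_THRESHOLD = 0.0015  # fraction of all identified PSMs, strict >
DEFAULT_SCORE_THRESHOLD = 0.6  # localization-confidence gate (MIScore scale)


@dataclass(frozen=True)
class LocalizationGate:
    score_threshold: float = DEFAULT_SCORE_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")


@dataclass
class PTMFrequencyTable:
    """PSM-level observation counts per candidate modification."""

    counts: dict[str, int]
    total_psms: int

    def frequency(self, name: str) -> float:
        return self.counts.get(name, 0) / self.total_psms


def high_frequency_ptms(
    psm_shifts: Sequence[tuple[str, MassShift]],
    ptm_table: Sequence[PTMDefinition],
    total_psms: int,
    sequences: dict[str, str],
    threshold: float = HIGH_FREQUENCY_THRESHOLD,
    cfg: MatchConfig = MatchConfig(),
) -> tuple[PTMFrequencyTable, list[PTMDefinition]]:
    """Select modifications observed in strictly more than ``threshold`` of
    all identified PSMs.

    A PSM counts toward a modification when any of its shifts mass-matches
    it and the shift's candidate region contains an eligible residue.
    Counting happens at the PSM level, before duplicate removal.  The
    selection excludes isotope-confusable modifications.
    """
    if not ptm_table:
        raise ValueError("empty PTM table")
    if total_psms <= 0:
        raise ValueError("total_psms must be positive")
    seen: set[tuple[str, str]] = set()  # (psm_id, ptm name) counted once
    counts: dict[str, int] = {p.name: 0 for p in ptm_table}
    for psm_id, shift in psm_shifts:
        seq = sequences.get(shift.protein)
        if seq is None:
            continue
        for ptm in ptm_table:
            if (psm_id, ptm.name) in seen:
                continue
            if not mass_match(shift.mass, ptm.mass, cfg).matched:
                continue
            if not region_has_modifiable(seq, shift.region_start, shift.region_end, ptm):
                continue
            seen.add((psm_id, ptm.name))
            counts[ptm.name] += 1
    freq = PTMFrequencyTable(counts, total_psms)
    selected = [p for p in ptm_table if freq.frequency(p.name) > threshold]
    return freq, exclude_isotope_confusable(selected, cfg)


def exclude_isotope_confusable(
    ptms: Iterable[PTMDefinition], cfg: MatchConfig = MatchConfig()
) -> list[PTMDefinition]:
    """Drop modifications whose mass is within the match tolerance of one
    neutron (1.00235 Da): their shifts cannot be told apart from common
    deconvolution errors.  On the built-in table this removes deamidation."""
    return [p for p in ptms if abs(abs(p.mass) - cfg.isotope_mass) >= cfg.mass_tol]


def assign_ptm_type(
    shift: MassShift,
    selected_ptms: Sequence[PTMDefinition],
    protein_seq: Optional[str],
    cfg: MatchConfig = MatchConfig(),
) -> list[TypedMassShift]:
    """All candidate types for a shift, best first.

    A modification qualifies when its mass matches the shift (isotope offset
    allowed) and the candidate region contains at least one eligible residue.
    Candidates order by |isotope offset| then residual mass error, so a
    0 Da interpretation always precedes a neutron-corrected one.
    """
    if protein_seq is None:
        raise ValueError(
            f"protein sequence for {shift.protein!r} required for residue eligibility"
        )
    candidates = []
    for ptm in selected_ptms:
        matched, offset, err = mass_match(shift.mass, ptm.mass, cfg)
        if not matched:
            continue
        if not region_has_modifiable(protein_seq, shift.region_start, shift.region_end, ptm):
            continue
        candidates.append(TypedMassShift(shift, ptm, mass_error=err, isotope_offset=offset))
    candidates.sort(key=lambda t: (abs(t.isotope_offset), t.mass_error, t.ptm.name))
    return candidates


def classify_level(
    shift: MassShift,
    candidates: Sequence[TypedMassShift],
    gate: LocalizationGate = LocalizationGate(),
    protein_seq: Optional[str] = None,
) -> LevelLabel:
    """Classify a shift as level 1 / 2A / 3.

    No candidate type -> level 3.  A typed shift is localized (level 1) when
    its upstream localization score clears the gate, when the region offers
    exactly one eligible residue for the best candidate, or when the best
    candidate is a fixed-terminus PTM with the N-terminal site in the region.
    Otherwise level 2A.
    """
    if not candidates:
        return LevelLabel(Level.L3)
    best = candidates[0]
    is_nta = best.ptm.nterm_only
    if is_nta and shift.region_start <= 1 <= shift.region_end:
        return LevelLabel(Level.L1, is_nta=True)
    if shift.score is not None and shift.score >= gate.score_threshold:
        return LevelLabel(Level.L1)
    if protein_seq is not None:
        sites = modifiable_positions(protein_seq, shift.region_start, shift.region_end, best.ptm)
        if len(sites) == 1:
            return LevelLabel(Level.L1)
    return LevelLabel(Level.L2A)


@dataclass
class MisassignmentDiagnostic:
    """A shift explainable as a fixed-modification bookkeeping error."""

    record_id: str
    observed_mass: float
    explanation: str


def flag_misassignment(
    shift: MassShift,
    protein_seq: Optional[str],
    ptm_table: Sequence[PTMDefinition],
    cfg: MatchConfig = MatchConfig(),
) -> Optional[MisassignmentDiagnostic]:
    """Diagnose shifts near -43 Da on cysteine-containing regions.

    When every cysteine is assumed carbamidomethylated (+57.021 Da fixed), a
    cysteine that actually carries methylation (+14.016 Da) shows up as an
    unexplained shift of 14.016 - 57.021 = -43.006 Da.  The diagnostic is
    advisory; the shift itself is never mutated.
    """
    by_name = {p.name: p for p in ptm_table}
    try:
        delta = by_name["Methylation"].mass - by_name["Carbamidomethylation"].mass
    except KeyError:
        return None
    if not mass_match(shift.mass, delta, cfg).matched:
        return None
    if protein_seq is None:
        return None
    end = min(shift.region_end, len(protein_seq))
    if not any(protein_seq[p - 1] == "C" for p in range(shift.region_start, end + 1)):
        return None
    return MisassignmentDiagnostic(
        record_id=shift.record_id,
        observed_mass=shift.mass,
        explanation=(
            "shift near -43.006 Da on a Cys-containing region: likely a "
            "methylated cysteine misbooked as carbamidomethylated"
        ),
    )


@dataclass
class ClassifiedShift:
    """A deduplicated shift with its type candidates and level."""

    shift: MassShift
    candidates: list[TypedMassShift] = field(default_factory=list)
    level: LevelLabel = field(default_factory=lambda: LevelLabel(Level.L3))
    diagnostics: list[MisassignmentDiagnostic] = field(default_factory=list)

    @property
    def best(self) -> Optional[TypedMassShift]:
        return self.candidates[0] if self.candidates else None

    @property
    def level_group(self) -> str:
        """Reporting group: NTA, L1 (excluding NTA), L2A or L3."""
        if self.level.is_nta:
            return "NTA"
        return self.level.value.value


def classify_shifts(
    shifts: Iterable[MassShift],
    selected_ptms: Sequence[PTMDefinition],
    sequences: dict[str, str],
    pre_typed: Optional[dict[str, TypedMassShift]] = None,
    gate: LocalizationGate = LocalizationGate(),
    ptm_table: Optional[Sequence[PTMDefinition]] = None,
    cfg: MatchConfig = MatchConfig(),
) -> list[ClassifiedShift]:
    """Type and level every shift.

    ``pre_typed`` maps record ids of shifts whose type was assigned upstream
    (engine variable modifications such as N-terminal acetylation); these
    keep their assignment instead of being re-typed against the selected set.
    """
    pre_typed = pre_typed or {}
    out = []
    for s in shifts:
        seq = sequences.get(s.protein)
        if s.record_id in pre_typed:
            cands = [pre_typed[s.record_id]]
        else:
            cands = assign_ptm_type(s, selected_ptms, seq, cfg)
        item = ClassifiedShift(s, cands, classify_level(s, cands, gate, seq))
        if ptm_table is not None:
            diag = flag_misassignment(s, seq, ptm_table, cfg)
            if diag is not None:
                item.diagnostics.append(diag)
        out.append(item)
    return out
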