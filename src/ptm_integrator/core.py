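"""Domain types and matching primitives for mass-shift integration.

A mass shift observed on a proteoform or peptide is represented by the
quadruple (mass, protein, region_start, region_end): the signed monoisotopic
shift in Da plus the protein region that may contain the modification site.
Once a PTM type is assigned the shift becomes a quintuple (the quadruple plus
the type).  Two shifts are *matched* when they can be explained by a single
modification event: same protein, overlapping candidate regions, and masses
equal up to a tolerance, optionally allowing a +/-1.00235 Da offset for the
off-by-one-neutron error common in deconvoluted precursor masses.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

#: Mass of the neutron-count error seen in deconvoluted monoisotopic masses (Da).
ISOTOPE_MASS = 1.00235

#: Default mass-match tolerance (Da); matching is strict ("smaller than").
DEFAULT_MASS_TOL = 0.1


class Source(str, enum.Enum):
    """Origin of an identification: intact proteoforms or digested peptides."""

    TOPDOWN = "topdown"
    BOTTOMUP = "bottomup"


class Level(str, enum.Enum):
    """Confidence class of a mass shift.

    L1: PTM type identified and site localized.
    L2A: PTM type identified, site not localized.
    L3: no PTM type identified.
    """

    L1 = "L1"
    L2A = "L2A"
    L3 = "L3"


@dataclass(frozen=True)
class LevelLabel:
    value: Level
    is_nta: bool = False  # N-terminal acetylation is reported separately

    def __post_init__(self) -> None:
        if self.is_nta and self.value is not Level.L1:
            raise ValueError("N-terminal acetylation implies a localized (L1) site")


@dataclass(frozen=True)
class PTMDefinition:
    """A named modification with its monoisotopic mass and specificity.

    ``residues`` is the set of one-letter codes of amino acids that can carry
    the modification.  ``nterm_only`` marks modifications fixed to the protein
    N-terminus (N-terminal acetylation); such entries may have an empty
    residue set.
    """

    name: str
    mass: float
    residues: frozenset[str] = frozenset()
    nterm_only: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.mass) or self.mass == 0.0:
            raise ValueError(f"PTM {self.name!r}: mass must be finite and nonzero")
        if not self.residues and not self.nterm_only:
            raise ValueError(f"PTM {self.name!r}: residue set empty for a non-terminal PTM")


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances governing every mass comparison in the pipeline."""

    mass_tol: float = DEFAULT_MASS_TOL
    isotope_mass: float = ISOTOPE_MASS
    allow_isotope: bool = True

    def __post_init__(self) -> None:
        if not (self.mass_tol > 0 and self.isotope_mass > 0):
            raise ValueError("mass_tol and isotope_mass must be positive")


@dataclass(frozen=True)
class MassShift:
    """An unexplained mass shift and its candidate site region.

    Coordinates are 1-based closed intervals in protein numbering (UniProt
    convention).  ``score`` optionally carries an upstream site-localization
    confidence (e.g. MIScore) and is consumed, never computed, here.
    """

    mass: float
    protein: str
    region_start: int
    region_end: int
    source: Source = Source.TOPDOWN
    record_id: str = ""
    score: Optional[float] = None
    #: set once the candidate region has been widened against matched
    #: fragments; the extension is a one-shot normalization
    extended: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.mass):
            raise ValueError("mass shift must be finite")
        if self.region_start < 1 or self.region_end < self.region_start:
            raise ValueError(
                f"invalid region [{self.region_start}, {self.region_end}] "
                f"for record {self.record_id!r}"
            )

    @property
    def region(self) -> tuple[int, int]:
        return (self.region_start, self.region_end)


@dataclass(frozen=True)
class TypedMassShift:
    """A mass shift with an assigned PTM type.

    ``isotope_offset`` records how many 1.00235 Da units were applied to
    reconcile the observed mass with the PTM's theoretical mass;
    ``mass_error`` is the residual |observed - corrected theoretical| in Da.
    """

    shift: MassShift
    ptm: PTMDefinition
    mass_error: float = 0.0
    isotope_offset: int = 0

    def __post_init__(self) -> None:
        if self.isotope_offset not in (-1, 0, 1):
            raise ValueError("isotope_offset must be in {-1, 0, +1}")
        if self.mass_error < 0 or not math.isfinite(self.mass_error):
            raise ValueError("mass_error must be a finite non-negative value")


class MassMatch(NamedTuple):
    matched: bool
    isotope_offset: int
    error: float


def mass_match(m1: float, m2: float, cfg: MatchConfig = MatchConfig()) -> MassMatch:
    """Compare two shift masses, optionally allowing a +/-1 neutron offset.

    The minimum of |m1 - (m2 + k * isotope_mass)| over k in {-1, 0, +1}
    (k = 0 only when ``allow_isotope`` is off) decides the match; a match
    requires the minimum to be strictly below ``cfg.mass_tol``.  Ties in
    error are broken toward k = 0, the parsimonious interpretation.
    """
    if not (math.isfinite(m1) and math.isfinite(m2)):
        raise ValueError("non-finite mass in comparison")
    offsets = (0, -1, 1) if cfg.allow_isotope else (0,)
    best_k = 0
    best_err = math.inf
    for k in offsets:
        err = abs(m1 - (m2 + k * cfg.isotope_mass))
        if err < best_err or (err == best_err and abs(k) < abs(best_k)):
            best_k, best_err = k, err
    # compare at nanodalton resolution so a difference of exactly the
    # tolerance never sneaks under it through float representation
    return MassMatch(round(best_err, 9) < cfg.mass_tol, best_k, best_err)


def regions_overlap(s1: MassShift, s2: MassShift) -> bool:
    """True iff both shifts sit on the same protein and their closed
    candidate-site intervals share at least one position."""
    return s1.protein == s2.protein and max(s1.region_start, s2.region_start) <= min(
        s1.region_end, s2.region_end
    )


def match_shift(s1: MassShift, s2: MassShift, cfg: MatchConfig = MatchConfig()) -> bool:
    """Untyped shift matching: same protein, overlapping regions, masses
    equal within tolerance (isotope offset allowed).  Symmetric."""
    return regions_overlap(s1, s2) and mass_match(s1.mass, s2.mass, cfg).matched


def modifiable_positions(
    seq: str, start: int, end: int, ptm: PTMDefinition
) -> list[int]:
    """1-based positions in [start, end] that can carry ``ptm`` on ``seq``.

    For N-terminus-only PTMs the only eligible position is 1.
    """
    if ptm.nterm_only:
        return [1] if start <= 1 <= end else []
    end = min(end, len(seq))
    return [p for p in range(start, end + 1) if seq[p - 1] in ptm.residues]


def region_has_modifiable(seq: str, start: int, end: int, ptm: PTMDefinition) -> bool:
    if ptm.nterm_only:
        return start <= 1 <= end
    end = min(end, len(seq))
    return any(seq[p - 1] in ptm.residues for p in range(start, end + 1))


def match_typed_shift(
    t1: TypedMassShift,
    t2: TypedMassShift,
    seq: Optional[str],
    cfg: MatchConfig = MatchConfig(),
) -> bool:
    """Typed shift matching.

    Requires (1) the underlying untyped shifts to match, (2) equal PTM
    names, and (3) at least one residue modifiable by the PTM inside the
    overlap of the two candidate regions (position 1 for N-terminal PTMs).
    The protein sequence is mandatory: condition (3) cannot be evaluated
    without it.
    """
    if not match_shift(t1.shift, t2.shift, cfg):
        return False
    if t1.ptm.name != t2.ptm.name:
        return False
    if seq is None:
        raise ValueError(
            f"protein sequence for {t1.shift.protein!r} required to test "
            "residue eligibility in the overlap region"
        )
    lo = max(t1.shift.region_start, t2.shift.region_start)
    hi = min(t1.shift.region_end, t2.shift.region_end)
    return region_has_modifiable(seq, lo, hi, t1.ptm)
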