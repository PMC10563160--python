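"""Readers for search-engine result tables, annotation tables and FASTA.

Every reader normalizes to 1-based closed protein coordinates and skips (with
a logged reason) rows that violate basic invariants, so that downstream stages
can assume well-formed records.  Column maps for the supported tool dialects
live in ``data/dialects.yaml`` and can be overridden per call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from pyteomics import fasta as _fasta

from .core import MassShift, PTMDefinition, Source, TypedMassShift
from .ptms import resolve_ptm_name

log = logging.getLogger(__name__)


def load_dialects(path: str | Path | None = None) -> dict:
    """Dialect column maps (built-in unless a custom YAML is given)."""
    if path is None:
        ref = resources.files("ptm_integrator.data").joinpath("dialects.yaml")
        with resources.as_file(ref) as p:
            return yaml.safe_load(Path(p).read_text())
    return yaml.safe_load(Path(path).read_text())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by the first token of the defline."""
    seqs: dict[str, str] = {}
    with _fasta.read(str(path)) as reader:
        for header, seq in reader:
            seqs[header.split()[0]] = seq
    return seqs


# ---------------------------------------------------------------------------
# record types


@dataclass
class ProteoformRecord:
    """One proteoform identification from a top-down search."""

    record_id: str
    protein: str
    first: int  # first residue of the proteoform in the protein
    last: int
    # unexpected shifts: (mass, region_start, region_end, localization score)
    shifts: list[tuple[float, int, int, Optional[float]]] = field(default_factory=list)
    # variable PTMs assigned by the engine: (canonical name, protein site)
    variable_ptms: list[tuple[str, int]] = field(default_factory=list)
    fragments: Optional[list[int]] = None  # matched fragment positions


@dataclass
class PeptideRecord:
    """One PSM from a bottom-up search."""

    record_id: str
    peptide: str
    protein: str
    start: int  # 1-based position of the peptide in the protein
    shifts: list[float] = field(default_factory=list)  # open-search delta masses
    assigned_mods: list[tuple[str, int]] = field(default_factory=list)  # (name, peptide pos)

    @property
    def end(self) -> int:
        return self.start + len(self.peptide) - 1


@dataclass(frozen=True)
class AnnotationRecord:
    """A curated PTM at one site of one protein."""

    protein: str
    site: int
    ptm_raw: str
    ptm: Optional[str]  # canonical name, None when unresolvable
    source: str  # "uniprot" | "dbptm"

    @property
    def resolvable(self) -> bool:
        return self.ptm is not None


@dataclass
class ReadResult:
    """Parsed records plus an account of the rows that were skipped."""

    records: list
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


# ---------------------------------------------------------------------------
# cell parsers


def _parse_td_shifts(cell) -> list[tuple[float, int, int, Optional[float]]]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return []
    out = []
    for entry in str(cell).split(";"):
        entry = entry.strip()
        if not entry:
            continue
        parts = entry.split(":")
        mass = float(parts[0])
        a, b = (int(x) for x in parts[1].split("-"))
        score = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
        out.append((mass, a, b, score))
    return out


def _parse_variable_ptms(cell, table: Iterable[PTMDefinition]) -> tuple[list, list]:
    """Returns (resolved (name, site) pairs, unresolved raw names)."""
    ok, bad = [], []
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return ok, bad
    for entry in str(cell).split(";"):
        entry = entry.strip()
        if not entry:
            continue
        name, _, site = entry.rpartition(":")
        ptm = resolve_ptm_name(name, table)
        if ptm is None:
            bad.append(name)
        else:
            ok.append((ptm.name, int(site)))
    return ok, bad


def _parse_int_list(cell) -> Optional[list[int]]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return None
    return sorted(int(x) for x in str(cell).replace(";", ",").split(",") if x.strip())


def _require_columns(df: pd.DataFrame, colmap: dict, needed: Iterable[str], where: str) -> None:
    for key in needed:
        col = colmap.get(key)
        if col is None:
            continue
        if col not in df.columns:
            raise ValueError(f"{where}: required column {col!r} (field {key!r}) is missing")


# ---------------------------------------------------------------------------
# top-down reader


def read_topdown(
    path: str | Path,
    dialect: str = "toppic",
    ptm_table: Optional[Iterable[PTMDefinition]] = None,
    dialects: Optional[dict] = None,
) -> ReadResult:
    """Read a proteoform identification table (TopPIC- or MSPathFinder-style).

    Rows whose shift regions or fragment positions fall outside the
    proteoform span are skipped and counted, not silently accepted.
    """
    from .ptms import builtin_ptm_table

    table = list(ptm_table) if ptm_table is not None else builtin_ptm_table()
    maps = (dialects or load_dialects())["topdown"]
    if dialect not in maps:
        raise ValueError(f"unknown top-down dialect {dialect!r}; know {sorted(maps)}")
    cm = maps[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, cm, ("record_id", "protein", "first", "last"), f"{path} ({dialect})")

    records: list[ProteoformRecord] = []
    skipped: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            first, last = int(row[cm["first"]]), int(row[cm["last"]])
            rec = ProteoformRecord(
                record_id=str(row[cm["record_id"]]),
                protein=str(row[cm["protein"]]),
                first=first,
                last=last,
            )
            if "shifts" in cm and cm["shifts"] in df.columns:
                rec.shifts = _parse_td_shifts(row[cm["shifts"]])
            if "variable_ptms" in cm and cm["variable_ptms"] in df.columns:
                rec.variable_ptms, bad = _parse_variable_ptms(row[cm["variable_ptms"]], table)
                for name in bad:
                    log.warning("row %d: unresolvable variable PTM %r kept out", idx, name)
            if "fragments" in cm and cm["fragments"] in df.columns:
                rec.fragments = _parse_int_list(row[cm["fragments"]])
            if first < 1 or last < first:
                raise ValueError(f"invalid proteoform span [{first}, {last}]")
            for mass, a, b, _ in rec.shifts:
                if a < first or b > last or a > b:
                    raise ValueError(f"shift region [{a}, {b}] outside span [{first}, {last}]")
            for _, site in rec.variable_ptms:
                if site < first or site > last:
                    raise ValueError(f"variable PTM site {site} outside span")
            if rec.fragments and (rec.fragments[0] < first or rec.fragments[-1] > last):
                raise ValueError("fragment position outside proteoform span")
            records.append(rec)
        except (ValueError, KeyError) as exc:
            log.warning("skipping top-down row %d: %s", idx, exc)
            skipped.append((int(idx), str(exc)))
    return ReadResult(records, skipped)


# ---------------------------------------------------------------------------
# bottom-up reader


def read_bottomup(
    path: str | Path,
    dialect: str = "msfragger",
    sequences: Optional[dict[str, str]] = None,
    ptm_table: Optional[Iterable[PTMDefinition]] = None,
    dialects: Optional[dict] = None,
) -> ReadResult:
    """Read a PSM table (MSFragger/MetaMorpheus/MaxQuant-style).

    When ``sequences`` is given, rows whose peptide does not map onto the
    protein at the stated start are skipped.
    """
    from .ptms import builtin_ptm_table

    table = list(ptm_table) if ptm_table is not None else builtin_ptm_table()
    maps = (dialects or load_dialects())["bottomup"]
    if dialect not in maps:
        raise ValueError(f"unknown bottom-up dialect {dialect!r}; know {sorted(maps)}")
    cm = maps[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, cm, ("record_id", "peptide", "protein", "start"), f"{path} ({dialect})")

    records: list[PeptideRecord] = []
    skipped: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            rec = PeptideRecord(
                record_id=str(row[cm["record_id"]]),
                peptide=str(row[cm["peptide"]]).strip(),
                protein=str(row[cm["protein"]]),
                start=int(row[cm["start"]]),
            )
            if "shifts" in cm and cm["shifts"] in df.columns:
                cell = row[cm["shifts"]]
                if cell is not None and not (isinstance(cell, float) and math.isnan(cell)):
                    rec.shifts = [float(x) for x in str(cell).split(";") if x.strip()]
            if "assigned" in cm and cm["assigned"] in df.columns:
                rec.assigned_mods = _parse_assigned(row[cm["assigned"]], table)
            if rec.start < 1:
                raise ValueError(f"start {rec.start} < 1")
            if sequences is not None:
                seq = sequences.get(rec.protein)
                if seq is None:
                    raise ValueError(f"unknown protein {rec.protein!r}")
                if seq[rec.start - 1 : rec.start - 1 + len(rec.peptide)] != rec.peptide:
                    raise ValueError(
                        f"peptide does not match protein {rec.protein} at {rec.start}"
                    )
            records.append(rec)
        except (ValueError, KeyError) as exc:
            log.warning("skipping bottom-up row %d: %s", idx, exc)
            skipped.append((int(idx), str(exc)))
    return ReadResult(records, skipped)


def _parse_assigned(cell, table: Iterable[PTMDefinition]) -> list[tuple[str, int]]:
    """Assigned-modification cell -> (canonical name, peptide position).

    Entries are "pos:Name"; a bare engine-style name such as
    "Acetyl (Protein N-term)" is taken to sit at peptide position 1.
    """
    out: list[tuple[str, int]] = []
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return out
    for entry in str(cell).split(";"):
        entry = entry.strip()
        if not entry:
            continue
        if ":" in entry and entry.split(":", 1)[0].strip().isdigit():
            pos_s, name = entry.split(":", 1)
            pos = int(pos_s)
        else:
            name, pos = entry, 1
        ptm = resolve_ptm_name(name, table)
        if ptm is None:
            raise ValueError(f"unresolvable assigned modification {name!r}")
        out.append((ptm.name, pos))
    return out


# ---------------------------------------------------------------------------
# coordinate lifting and region extension


def peptide_shift_to_protein(rec: PeptideRecord, ptm_table=None) -> list[MassShift]:
    """Lift a PSM's shifts into protein coordinates.

    Open-search shifts have no site, so their candidate region is the whole
    peptide span; engine-assigned modifications collapse to a single site.
    """
    from .ptms import builtin_ptm_table, table_by_name

    by_name = table_by_name(ptm_table if ptm_table is not None else builtin_ptm_table())
    out: list[MassShift] = []
    for i, mass in enumerate(rec.shifts):
        out.append(
            MassShift(
                mass=mass,
                protein=rec.protein,
                region_start=rec.start,
                region_end=rec.end,
                source=Source.BOTTOMUP,
                record_id=f"{rec.record_id}.s{i}",
            )
        )
    for i, (name, pep_pos) in enumerate(rec.assigned_mods):
        site = rec.start + pep_pos - 1
        out.append(
            MassShift(
                mass=by_name[name].mass,
                protein=rec.protein,
                region_start=site,
                region_end=site,
                source=Source.BOTTOMUP,
                record_id=f"{rec.record_id}.v{i}",
            )
        )
    return out


def peptide_typed_shifts(rec: PeptideRecord, ptm_table=None) -> list[TypedMassShift]:
    """Engine-assigned modifications as typed shifts (exact mass, offset 0)."""
    from .ptms import builtin_ptm_table, table_by_name

    by_name = table_by_name(ptm_table if ptm_table is not None else builtin_ptm_table())
    out = []
    for i, (name, pep_pos) in enumerate(rec.assigned_mods):
        site = rec.start + pep_pos - 1
        ptm = by_name[name]
        out.append(
            TypedMassShift(
                shift=MassShift(
                    mass=ptm.mass,
                    protein=rec.protein,
                    region_start=site,
                    region_end=site,
                    source=Source.BOTTOMUP,
                    record_id=f"{rec.record_id}.v{i}",
                ),
                ptm=ptm,
            )
        )
    return out


def extend_region(
    shift: MassShift,
    fragment_positions: Optional[list[int]],
    protein_span: tuple[int, int],
) -> MassShift:
    """Widen a top-down candidate region to absorb boundary errors caused by
    randomly matched fragment masses.

    The left boundary a moves left until the newly covered part [a', a-1]
    contains two matched fragment positions, or to the proteoform's first
    residue when fewer than two exist on that side; the right boundary moves
    symmetrically.  Without fragment information the region is unchanged.

    Extension is a one-shot normalization of the tool-reported region:
    already-extended shifts pass through untouched (absorbed fragments sit
    inside the region, so re-running the walk would not be meaningful).
    """
    first, last = protein_span
    if shift.extended:
        return shift
    if not fragment_positions:
        log.warning(
            "no matched-fragment positions for %s; region not extended", shift.record_id
        )
        return shift
    left = sorted(p for p in fragment_positions if p < shift.region_start)
    right = sorted(p for p in fragment_positions if p > shift.region_end)
    new_a = left[-2] if len(left) >= 2 else first
    new_b = right[1] if len(right) >= 2 else last
    return MassShift(
        mass=shift.mass,
        protein=shift.protein,
        region_start=new_a,
        region_end=new_b,
        source=shift.source,
        record_id=shift.record_id,
        score=shift.score,
        extended=True,
    )


# ---------------------------------------------------------------------------
# annotations


def read_annotations(
    path: str | Path,
    source: str = "uniprot",
    ptm_table: Optional[Iterable[PTMDefinition]] = None,
    dialects: Optional[dict] = None,
) -> ReadResult:
    """Read a curated-PTM table; identical (protein, site, PTM) triples
    collapse to one record, unresolvable PTM names are kept but flagged."""
    from .ptms import builtin_ptm_table

    table = list(ptm_table) if ptm_table is not None else builtin_ptm_table()
    maps = (dialects or load_dialects())["annotations"]
    if source not in maps:
        raise ValueError(f"unknown annotation source {source!r}; know {sorted(maps)}")
    cm = maps[source]
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, cm, ("protein", "site", "ptm"), f"{path} ({source})")

    seen: dict[tuple[str, int, str], AnnotationRecord] = {}
    skipped: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            raw = str(row[cm["ptm"]]).strip()
            site = int(row[cm["site"]])
            if site < 1:
                raise ValueError(f"site {site} < 1")
            ptm = resolve_ptm_name(raw, table)
            if ptm is None:
                log.warning("annotation row %d: unresolvable PTM name %r", idx, raw)
            rec = AnnotationRecord(
                protein=str(row[cm["protein"]]),
                site=site,
                ptm_raw=raw,
                ptm=ptm.name if ptm else None,
                source=source,
            )
            seen.setdefault((rec.protein, rec.site, rec.ptm or rec.ptm_raw), rec)
        except (ValueError, KeyError) as exc:
            log.warning("skipping annotation row %d: %s", idx, exc)
            skipped.append((int(idx), str(exc)))
    return ReadResult(list(seen.values()), skipped)


# ---------------------------------------------------------------------------
# normalized shift tables (round-trippable)

_SHIFT_COLS = ["record_id", "protein", "mass", "region_start", "region_end", "source", "score"]


def shifts_to_frame(shifts: Iterable[MassShift]) -> pd.DataFrame:
    rows = [
        {
            "record_id": s.record_id,
            "protein": s.protein,
            "mass": s.mass,
            "region_start": s.region_start,
            "region_end": s.region_end,
            "source": s.source.value,
            "score": s.score,
        }
        for s in shifts
    ]
    return pd.DataFrame(rows, columns=_SHIFT_COLS)


def write_shifts_tsv(shifts: Iterable[MassShift], path: str | Path) -> None:
    shifts_to_frame(shifts).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_shifts_tsv(path: str | Path) -> list[MassShift]:
    """Read a normalized shift table; also accepts the pipeline's richer
    per-shift output (missing source/score columns default sensibly)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        raw_score = r.get("score", r.get("localization_score"))
        score = None if raw_score is None or pd.isna(raw_score) else float(raw_score)
        out.append(
            MassShift(
                mass=float(r["mass"]),
                protein=str(r["protein"]),
                region_start=int(r["region_start"]),
                region_end=int(r["region_end"]),
                source=Source(r["source"]) if "source" in df.columns else Source.TOPDOWN,
                record_id=str(r["record_id"]),
                score=score,
            )
        )
    return out
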