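"""Cross-verification of top-down shifts and end-to-end pipeline driver.

A mass shift seen on an intact proteoform gains credibility when the same
modification event is independently observed on a digested peptide, or when
a curated database annotates a matching PTM inside the shift's candidate
region.  Typed shifts (level 1/2A) are verified with the typed matching rule
(name equality plus an eligible residue in the overlap); untyped level 3
shifts are verified on mass and region alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    ClassifiedShift,
    LocalizationGate,
    classify_shifts,
    high_frequency_ptms,
)
from .core import (
    Level,
    MassShift,
    MatchConfig,
    PTMDefinition,
    TypedMassShift,
    mass_match,
    match_shift,
    match_typed_shift,
)
from .dedup import dedup_all
from .ingest import (
    AnnotationRecord,
    extend_region,
    peptide_shift_to_protein,
    peptide_typed_shifts,
    read_annotations,
    read_bottomup,
    read_fasta,
    read_topdown,
)
from .ptms import builtin_ptm_table, load_ptm_table, table_by_name

log = logging.getLogger(__name__)

LEVEL_GROUPS = ("NTA", "L1", "L2A", "L3")


@dataclass
class VerificationResult:
    """Evidence collected for one classified top-down shift."""

    item: ClassifiedShift
    bottomup_ids: list[str] = field(default_factory=list)
    annotation_ids: dict[str, list[str]] = field(default_factory=dict)  # source -> ids

    @property
    def verified_by_bottomup(self) -> bool:
        return bool(self.bottomup_ids)

    def verified_by_annotation(self, source: Optional[str] = None) -> bool:
        if source is not None:
            return bool(self.annotation_ids.get(source))
        return any(self.annotation_ids.values())

    @property
    def verified(self) -> bool:
        return self.verified_by_bottomup or self.verified_by_annotation()


def verify_by_bottomup(
    td: Sequence[ClassifiedShift],
    bu_all: Sequence[MassShift],
    bu_typed: Sequence[TypedMassShift],
    sequences: dict[str, str],
    cfg: MatchConfig = MatchConfig(),
) -> list[VerificationResult]:
    """Verify classified top-down shifts against deduplicated bottom-up ones.

    Level 3 shifts are compared with *all* bottom-up shifts using the
    untyped rule; level 1/2A shifts are compared with typed bottom-up shifts
    only, requiring the same PTM type on an eligible overlap residue.
    """
    results = []
    for item in td:
        res = VerificationResult(item)
        if item.level.value is Level.L3:
            res.bottomup_ids = [
                b.record_id for b in bu_all if match_shift(item.shift, b, cfg)
            ]
        else:
            t1 = item.best
            seq = sequences.get(item.shift.protein)
            for b in bu_typed:
                if b.shift.protein != item.shift.protein:
                    continue
                if seq is None:
                    log.warning(
                        "no sequence for %s; typed comparison with %s skipped",
                        item.shift.protein,
                        b.shift.record_id,
                    )
                    continue
                if match_typed_shift(t1, b, seq, cfg):
                    res.bottomup_ids.append(b.shift.record_id)
        results.append(res)
    return results


def verify_by_annotation(
    results: Sequence[VerificationResult],
    annotations: Sequence[AnnotationRecord],
    ptm_table: Sequence[PTMDefinition],
    cfg: MatchConfig = MatchConfig(),
) -> list[VerificationResult]:
    """Add curated-annotation evidence to verification results (in place).

    An annotation matches a shift when its site falls inside the candidate
    region, the annotated PTM's mass matches the shift mass (isotope offset
    allowed), and - for typed shifts - the annotated PTM is the assigned
    type.  Sources (uniprot/dbptm) are recorded separately.
    """
    by_name = table_by_name(ptm_table)
    by_protein: dict[str, list[AnnotationRecord]] = {}
    for a in annotations:
        if a.resolvable:
            by_protein.setdefault(a.protein, []).append(a)

    for res in results:
        s = res.item.shift
        for a in by_protein.get(s.protein, []):
            if not (s.region_start <= a.site <= s.region_end):
                continue
            ptm = by_name.get(a.ptm)
            if ptm is None or not mass_match(s.mass, ptm.mass, cfg).matched:
                continue
            if res.item.best is not None and a.ptm != res.item.best.ptm.name:
                continue
            res.annotation_ids.setdefault(a.source, []).append(
                f"{a.protein}:{a.site}:{a.ptm}"
            )
    return list(results)


def overlap_partition(results: Sequence[VerificationResult]) -> dict:
    """Partition verified shifts by evidence source, overall and per level
    group (NTA / level 1 excluding NTA / level 2A / level 3)."""

    def tally(items: Iterable[VerificationResult]) -> dict:
        bu_only = ann_only = both = 0
        for r in items:
            if r.verified_by_bottomup and r.verified_by_annotation():
                both += 1
            elif r.verified_by_bottomup:
                bu_only += 1
            elif r.verified_by_annotation():
                ann_only += 1
        union = bu_only + ann_only + both
        return {
            "bottomup_only": bu_only,
            "annotation_only": ann_only,
            "both": both,
            "union": union,
            "bottomup_only_pct": 100.0 * bu_only / union if union else 0.0,
            "annotation_only_pct": 100.0 * ann_only / union if union else 0.0,
        }

    out = {"overall": tally(results)}
    for group in LEVEL_GROUPS:
        out[group] = tally(r for r in results if r.item.level_group == group)
    return out


def histogram(
    masses: Iterable[float], lo: float = -500.0, hi: float = 500.0, bin_width: float = 1.0
) -> tuple[pd.DataFrame, int]:
    """Bin shift masses into half-open bins [lo + k*w, lo + (k+1)*w).

    Returns the bin table and the count of masses outside [lo, hi).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    masses = np.asarray(list(masses), dtype=float)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    overflow = 0
    for m in masses:
        if lo <= m < hi:
            counts[int((m - lo) // bin_width)] += 1
        else:
            overflow += 1
    starts = lo + bin_width * np.arange(n_bins)
    df = pd.DataFrame(
        {"bin_start": starts, "bin_end": starts + bin_width, "count": counts}
    )
    return df, overflow


def replicate_intersection(
    runs: Sequence[Sequence[ClassifiedShift]], cfg: MatchConfig = MatchConfig()
) -> dict:
    """Count first-run shifts also found (by shift matching, not record
    identity) in every other run, per level group."""
    out = {}
    first, rest = runs[0], runs[1:]
    for group in LEVEL_GROUPS:
        items = [c for c in first if c.level_group == group]
        n_shared = sum(
            1
            for c in items
            if all(
                any(match_shift(c.shift, o.shift, cfg) for o in other) for other in rest
            )
        )
        out[group] = {"first_run": len(items), "in_all_runs": n_shared}
    return out


# ---------------------------------------------------------------------------
# summary and pipeline


@dataclass
class SummaryReport:
    level_counts: dict[str, int]
    bottomup_verified: dict[str, int]
    annotation_verified: dict[str, dict[str, int]]  # source -> group -> n
    partition: dict
    n_topdown_kept: int
    n_bottomup_kept: int
    stage_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "level_counts": self.level_counts,
            "bottomup_verified": self.bottomup_verified,
            "annotation_verified": self.annotation_verified,
            "partition": self.partition,
            "n_topdown_kept": self.n_topdown_kept,
            "n_bottomup_kept": self.n_bottomup_kept,
            "stage_counts": self.stage_counts,
        }


@dataclass
class PipelineResult:
    summary: SummaryReport
    results: list[VerificationResult]
    bottomup_classified: list[ClassifiedShift]
    shifts_table: pd.DataFrame
    audit_table: pd.DataFrame
    histogram_table: pd.DataFrame
    selected_ptms: list[PTMDefinition]
    frequency_table: "pd.DataFrame"


def _summarize(results: Sequence[VerificationResult]) -> tuple[dict, dict, dict]:
    levels = {g: 0 for g in LEVEL_GROUPS}
    bu = {g: 0 for g in LEVEL_GROUPS}
    ann: dict[str, dict[str, int]] = {}
    for r in results:
        g = r.item.level_group
        levels[g] += 1
        if r.verified_by_bottomup:
            bu[g] += 1
        for source in r.annotation_ids:
            if r.annotation_ids[source]:
                ann.setdefault(source, {gg: 0 for gg in LEVEL_GROUPS})[g] += 1
    return levels, bu, ann


def _shifts_table(results: Sequence[VerificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.item
        best = c.best
        rows.append(
            {
                "record_id": c.shift.record_id,
                "protein": c.shift.protein,
                "mass": round(c.shift.mass, 6),
                "region_start": c.shift.region_start,
                "region_end": c.shift.region_end,
                "level": c.level.value.value,
                "is_nta": int(c.level.is_nta),
                "best_ptm": best.ptm.name if best else "",
                "all_candidates": ";".join(t.ptm.name for t in c.candidates),
                "mass_error": round(best.mass_error, 6) if best else "",
                "isotope_offset": best.isotope_offset if best else "",
                "localization_score": "" if c.shift.score is None else c.shift.score,
                "verified_bottomup": int(r.verified_by_bottomup),
                "verified_uniprot": int(r.verified_by_annotation("uniprot")),
                "verified_dbptm": int(r.verified_by_annotation("dbptm")),
                "diagnostics": ";".join(d.explanation for d in c.diagnostics),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full integration: ingest, region extension, duplicate
    removal on both sides, frequency-based PTM selection, typing and level
    classification of the top-down shifts, then bottom-up and annotation
    verification.  Deterministic given identical inputs.

    ``config`` is a mapping (or path to a YAML file) with keys:
    fasta, topdown {path, dialect}, bottomup {path, dialect},
    annotations [{path, source}], options {mass_tol, cluster_tol,
    allow_isotope, frequency_threshold, score_threshold, ptm_table}.
    """
    import yaml

    if not isinstance(config, dict):
        cfg_path = Path(config)
        config = yaml.safe_load(cfg_path.read_text())
        # relative input paths are taken relative to the config file
        base = cfg_path.parent

        def _resolve(p):
            return str(p) if Path(p).is_absolute() else str(base / p)

        config = dict(config)
        config["fasta"] = _resolve(config["fasta"])
        for section in ("topdown", "bottomup"):
            config[section] = {**config[section], "path": _resolve(config[section]["path"])}
        config["annotations"] = [
            {**a, "path": _resolve(a["path"])} for a in config.get("annotations", [])
        ]
    opts = config.get("options", {})
    cfg = MatchConfig(
        mass_tol=float(opts.get("mass_tol", 0.1)),
        allow_isotope=bool(opts.get("allow_isotope", True)),
    )
    cluster_tol = float(opts.get("cluster_tol", 0.1))
    gate = LocalizationGate(float(opts.get("score_threshold", 0.6)))
    freq_threshold = float(opts.get("frequency_threshold", 0.0015))
    table = (
        load_ptm_table(opts["ptm_table"]) if "ptm_table" in opts else builtin_ptm_table()
    )
    by_name = table_by_name(table)
    stage: dict[str, int] = {}

    sequences = read_fasta(config["fasta"])

    # --- top-down side ------------------------------------------------
    td_res = read_topdown(config["topdown"]["path"], config["topdown"].get("dialect", "toppic"), table)
    stage["topdown_records"] = len(td_res.records)
    stage["topdown_skipped"] = td_res.n_skipped
    td_shifts: list[MassShift] = []
    td_pre_typed: dict[str, TypedMassShift] = {}
    for rec in td_res.records:
        span = (rec.first, rec.last)
        for i, (mass, a, b, score) in enumerate(rec.shifts):
            s = MassShift(
                mass=mass,
                protein=rec.protein,
                region_start=a,
                region_end=b,
                record_id=f"{rec.record_id}.s{i}",
                score=score,
            )
            td_shifts.append(extend_region(s, rec.fragments, span))
        for i, (name, site) in enumerate(rec.variable_ptms):
            ptm = by_name[name]
            s = MassShift(
                mass=ptm.mass,
                protein=rec.protein,
                region_start=site,
                region_end=site,
                record_id=f"{rec.record_id}.v{i}",
            )
            td_shifts.append(s)
            td_pre_typed[s.record_id] = TypedMassShift(s, ptm)
    stage["topdown_shifts"] = len(td_shifts)
    td_kept, td_audit = dedup_all(td_shifts, cluster_tol, cfg)
    stage["topdown_kept"] = len(td_kept)

    # --- bottom-up side ----------------------------------------------
    bu_res = read_bottomup(
        config["bottomup"]["path"], config["bottomup"].get("dialect", "msfragger"), sequences, table
    )
    stage["bottomup_psms"] = len(bu_res.records)
    stage["bottomup_skipped"] = bu_res.n_skipped
    bu_shifts: list[MassShift] = []
    bu_pre_typed: dict[str, TypedMassShift] = {}
    psm_shifts: list[tuple[str, MassShift]] = []
    for rec in bu_res.records:
        lifted = peptide_shift_to_protein(rec, table)
        bu_shifts.extend(lifted)
        psm_shifts.extend((rec.record_id, s) for s in lifted)
        for t in peptide_typed_shifts(rec, table):
            bu_pre_typed[t.shift.record_id] = t
    stage["bottomup_shifts"] = len(bu_shifts)

    if bu_res.records:
        freq, selected = high_frequency_ptms(
            psm_shifts, table, total_psms=len(bu_res.records), sequences=sequences,
            threshold=freq_threshold, cfg=cfg,
        )
    else:  # no bottom-up evidence: nothing selected, nothing verified by it
        from .classify import PTMFrequencyTable

        freq, selected = PTMFrequencyTable({p.name: 0 for p in table}, 1), []
    stage["selected_ptms"] = len(selected)

    bu_kept, bu_audit = dedup_all(bu_shifts, cluster_tol, cfg)
    stage["bottomup_kept"] = len(bu_kept)

    # --- classification ----------------------------------------------
    td_classified = classify_shifts(
        td_kept, selected, sequences, pre_typed=td_pre_typed, gate=gate,
        ptm_table=table, cfg=cfg,
    )
    bu_classified = classify_shifts(
        bu_kept, selected, sequences, pre_typed=bu_pre_typed, gate=gate, cfg=cfg
    )
    bu_typed = [c.best for c in bu_classified if c.best is not None]

    # --- verification -------------------------------------------------
    results = verify_by_bottomup(td_classified, bu_kept, bu_typed, sequences, cfg)
    annotations: list[AnnotationRecord] = []
    for spec in config.get("annotations", []):
        ann_res = read_annotations(spec["path"], spec.get("source", "uniprot"), table)
        stage[f"annotations_{spec.get('source', 'uniprot')}"] = len(ann_res.records)
        annotations.extend(ann_res.records)
    verify_by_annotation(results, annotations, table, cfg)

    levels, bu_counts, ann_counts = _summarize(results)
    partition = overlap_partition(results)
    hist_all, overflow = histogram((c.shift.mass for c in td_classified), -500.0, 500.0, 1.0)
    hist_all.attrs["overflow"] = overflow

    summary = SummaryReport(
        level_counts=levels,
        bottomup_verified=bu_counts,
        annotation_verified=ann_counts,
        partition=partition,
        n_topdown_kept=len(td_kept),
        n_bottomup_kept=len(bu_kept),
        stage_counts=stage,
    )
    for name, n in stage.items():
        log.info("stage %s: %d", name, n)

    freq_df = pd.DataFrame(
        sorted(
            ({"ptm": k, "psm_count": v, "frequency": freq.frequency(k)} for k, v in freq.counts.items()),
            key=lambda r: r["ptm"],
        )
    )
    result = PipelineResult(
        summary=summary,
        results=results,
        bottomup_classified=bu_classified,
        shifts_table=_shifts_table(results),
        audit_table=_concat_audits(td_audit, bu_audit),
        histogram_table=hist_all,
        selected_ptms=selected,
        frequency_table=freq_df,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _concat_audits(td_audit: pd.DataFrame, bu_audit: pd.DataFrame) -> pd.DataFrame:
    frames = [td_audit.assign(side="topdown"), bu_audit.assign(side="bottomup")]
    nonempty = [f for f in frames if not f.empty]
    return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write shifts.tsv, audit.tsv, summary.json, histogram.tsv, overlap.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "shifts": out / "shifts.tsv",
        "audit": out / "audit.tsv",
        "summary": out / "summary.json",
        "histogram": out / "histogram.tsv",
        "overlap": out / "overlap.tsv",
    }
    result.shifts_table.to_csv(paths["shifts"], sep="\t", index=False)
    result.audit_table.to_csv(paths["audit"], sep="\t", index=False, float_format="%.6f")
    paths["summary"].write_text(json.dumps(result.summary.to_dict(), indent=2, sort_keys=True))
    result.histogram_table.to_csv(paths["histogram"], sep="\t", index=False)
    rows = []
    for group, tally in result.summary.partition.items():
        rows.append({"group": group, **tally})
    pd.DataFrame(rows).to_csv(paths["overlap"], sep="\t", index=False, float_format="%.4f")
    return paths
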