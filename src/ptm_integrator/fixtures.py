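"""Synthetic proteome and identification-table generator with ground truth.

The generator emulates the statistical structure of open-search results:
ambiguous candidate-site intervals, duplicated reports across overlapping
proteoforms and repeated PSMs, +/-1.00235 Da deconvolution errors, partial
bottom-up sequence coverage, partial database annotation, and decoy shifts
whose masses match no known modification.  Every planted event is recorded
in ``truth.tsv`` together with the level, PTM type and verification flags a
correct integration must recover, so the whole pipeline is testable without
any external data.

Construction guarantees that make the ground truth well-defined:

* at most one site per PTM type per protein, and disjoint ambiguity slots,
  so duplicate removal can never legitimately merge two distinct events;
* isotope errors are injected only for PTM types whose +/-1 neutron images
  stay clear of every other table mass - otherwise the nearest-candidate
  type after the error would genuinely be a different PTM;
* decoy masses keep >=0.25 Da away from all table masses and their isotope
  images, so decoys are unambiguously level 3;
* every PTM type retains enough bottom-up PSMs to clear the high-frequency
  selection threshold (under-represented types get one forced covered site,
  reflected in the truth flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import ISOTOPE_MASS, PTMDefinition
from .ptms import NTA_NAME, builtin_ptm_table, table_by_name

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Roughly human-proteome-like residue weights (arbitrary units).
AA_WEIGHTS = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.6, 7.1, 2.3, 4.4, 5.8, 9.7, 2.4, 3.6, 6.3, 4.4, 5.5, 8.1, 5.6, 6.9, 1.1, 2.7]
)

UNIPROT_TYPES = {
    NTA_NAME,
    "Acetylation",
    "Phosphorylation",
    "Methylation",
    "Dimethylation",
    "Trimethylation",
    "Oxidation",
}
DBPTM_TYPES = {NTA_NAME, "Acetylation", "Phosphorylation", "Methylation", "Oxidation"}

# UniProt-style "Modified residue" descriptions, keyed by (type, residue).
_UNIPROT_DESC = {
    ("Acetylation", "K"): "N6-acetyllysine",
    ("Methylation", "K"): "N6-methyllysine",
    ("Methylation", "R"): "Omega-N-methylarginine",
    ("Methylation", "C"): "S-methylcysteine",
    ("Dimethylation", "K"): "N6,N6-dimethyllysine",
    ("Dimethylation", "R"): "Omega-N,omega-N-dimethylarginine",
    ("Trimethylation", "K"): "N6,N6,N6-trimethyllysine",
    ("Phosphorylation", "S"): "Phosphoserine",
    ("Phosphorylation", "T"): "Phosphothreonine",
    ("Phosphorylation", "Y"): "Phosphotyrosine",
}


class FixtureError(ValueError):
    """Raised when a fixture specification cannot be satisfied."""


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    seed: int = 7
    n_proteins: int = 30
    length_range: tuple[int, int] = (140, 260)
    sites_per_protein: tuple[int, int] = (4, 7)  # typed (non-NTA) sites
    decoys_per_protein: tuple[int, int] = (1, 3)
    p_nta: float = 0.7
    p_level1: float = 0.35  # localization score planted above the 0.6 gate
    coverage: float = 0.6  # chance a planted site is seen bottom-up
    p_uniprot: float = 0.5
    p_dbptm: float = 0.4
    ambiguity_width: tuple[int, int] = (0, 5)  # candidate-region halfwidths
    duplicates: tuple[int, int] = (1, 3)  # top-down records per shift
    psm_multiplicity: tuple[int, int] = (1, 3)
    isotope_error_prob: float = 0.15
    n_unmodified_psms: int = 300
    mass_jitter: float = 0.004

    def __post_init__(self) -> None:
        for name in ("p_nta", "p_level1", "coverage", "p_uniprot", "p_dbptm", "isotope_error_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureError(f"{name} must lie in [0, 1], got {v}")
        if self.mass_jitter < 0 or self.mass_jitter >= 0.015:
            raise FixtureError("mass_jitter must stay well below half the smallest table mass gap")


@dataclass
class _Planted:
    item_id: str
    protein: str
    site: int
    kind: str  # "typed" | "nta" | "decoy"
    ptm: Optional[PTMDefinition]
    region: tuple[int, int]  # emitted (pre-extension) region
    observed_mass: float  # theoretical + isotope error, before jitter
    isotope_offset: int
    score: Optional[float]
    level: str
    is_nta: bool
    covered: bool = False
    uniprot: bool = False
    dbptm: bool = False
    peptide: Optional[tuple[int, str]] = None  # (start, sequence)


def tryptic_peptides(
    seq: str, max_missed: int = 2, min_len: int = 5, max_len: int = 50
) -> list[tuple[int, str]]:
    """In-silico tryptic digestion: cleave after K/R except before P.

    Returns (1-based start, peptide) for every peptide with at most
    ``max_missed`` missed cleavages and length within [min_len, max_len].
    """
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(len(seq))
    out = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            pep = seq[cuts[i] : cuts[j]]
            if min_len <= len(pep) <= max_len:
                out.append((cuts[i] + 1, pep))
    return out


def isotope_safe_types(
    table: list[PTMDefinition], jitter: float = 0.004
) -> set[str]:
    """PTM types for which a +/-1 neutron error still leaves the type the
    best-ranked candidate against the rest of the table."""
    safe = set()
    for t in table:
        if t.nterm_only:
            continue
        ok = True
        for k in (-1, 1):
            obs = t.mass + k * ISOTOPE_MASS
            for u in table:
                if u.name == t.name or abs(u.mass - t.mass) < 1e-9:
                    continue
                if abs(obs - u.mass) < 0.11:  # rival at offset 0 would outrank
                    ok = False
                for j in (-1, 1):  # rival at |offset| 1 with a smaller error
                    if abs(obs - u.mass - j * ISOTOPE_MASS) < 3 * jitter + 0.003:
                        ok = False
        if ok:
            safe.add(t.name)
    return safe


def _draw_decoy_mass(rng: np.random.Generator, table, used: list[float]) -> float:
    """A shift mass guaranteed not to match any table PTM (or its isotope
    images) nor any previously drawn decoy."""
    forbidden = [p.mass + k * ISOTOPE_MASS for p in table for k in (-1, 0, 1)]
    for _ in range(10_000):
        m = float(rng.uniform(-120.0, 220.0))
        if abs(m) < 0.5:
            continue
        if any(abs(m - f) < 0.25 for f in forbidden):
            continue
        if any(abs(m - u - k * ISOTOPE_MASS) < 0.35 for u in used for k in (-1, 0, 1)):
            continue
        return m
    raise FixtureError("could not draw a decoy mass away from all PTM masses")


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write fasta, topdown.tsv, bottomup.tsv, uniprot.tsv, dbptm.tsv,
    truth.tsv and a ready-to-run config.yaml; returns the paths.

    Identical specs produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    table = builtin_ptm_table()
    by_name = table_by_name(table)
    nta = by_name[NTA_NAME]
    plantable = [
        p for p in table if not p.nterm_only and p.name != "Deamidation"
    ]
    safe = isotope_safe_types(table, spec.mass_jitter)
    weights = AA_WEIGHTS / AA_WEIGHTS.sum()

    # ---- plan proteins and planted events ---------------------------
    sequences: dict[str, str] = {}
    planted: list[_Planted] = []
    item_counter = 0
    type_site_count = {p.name: 0 for p in plantable}

    # Types whose masses sit within the cluster tolerance of each other
    # (acetylation vs trimethylation on the built-in table) must not share a
    # protein: a bottom-up peptide spanning both sites would legitimately be
    # deduplicated across them and the truth flags would stop being unique.
    def _conflicts(a: PTMDefinition, b: PTMDefinition) -> bool:
        return a.name != b.name and abs(a.mass - b.mass) < 0.12

    nta_flags = [bool(rng.random() < spec.p_nta) for _ in range(spec.n_proteins)]

    plans: list[list[PTMDefinition]] = []
    for pi in range(spec.n_proteins):
        n_typed = int(rng.integers(spec.sites_per_protein[0], spec.sites_per_protein[1] + 1))
        order = rng.permutation(len(plantable))
        plan: list[PTMDefinition] = []
        for i in order[:n_typed]:
            cand = plantable[i]
            if any(_conflicts(cand, q) for q in plan):
                continue
            plan.append(cand)
        plans.append(plan)
    # make sure every type is planted somewhere
    for ptm in plantable:
        if not any(ptm.name in {q.name for q in plan} for plan in plans):
            hosts = [p for p in plans if not any(_conflicts(ptm, q) for q in p)]
            if not hosts:
                raise FixtureError(f"cannot host {ptm.name} on any protein")
            hosts[int(rng.integers(len(hosts)))].append(ptm)

    decoy_masses: list[float] = []
    for pi, plan in enumerate(plans):
        acc = f"SYN{pi:03d}"
        target_len = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        n_decoys = int(rng.integers(spec.decoys_per_protein[0], spec.decoys_per_protein[1] + 1))
        items: list[tuple[str, Optional[PTMDefinition]]] = [("typed", p) for p in plan]
        items += [("decoy", None)] * n_decoys
        items = [items[i] for i in rng.permutation(len(items))]

        seq = list(rng.choice(list(AMINO_ACIDS), size=3, p=weights))
        seq[0] = "M"
        cursor = 4  # 1-based start of the next ambiguity slot
        for kind, ptm in items:
            w_l = int(rng.integers(spec.ambiguity_width[0], spec.ambiguity_width[1] + 1))
            w_r = int(rng.integers(spec.ambiguity_width[0], spec.ambiguity_width[1] + 1))
            site = cursor + w_l + 2
            slot_end = site + w_r + 2
            while len(seq) < slot_end:
                seq.append(str(rng.choice(list(AMINO_ACIDS), p=weights)))
            item_counter += 1
            iid = f"E{item_counter:04d}"
            if kind == "typed":
                residues = sorted(ptm.residues)
                seq[site - 1] = str(rng.choice(residues))
                seq[site] = str(rng.choice(residues))  # second eligible site
                level1 = bool(rng.random() < spec.p_level1)
                score = float(rng.uniform(0.65, 0.98)) if level1 else float(rng.uniform(0.05, 0.55))
                offset = 0
                if ptm.name in safe and rng.random() < spec.isotope_error_prob:
                    offset = int(rng.choice([-1, 1]))
                planted.append(
                    _Planted(
                        item_id=iid, protein=acc, site=site, kind="typed", ptm=ptm,
                        region=(site - w_l, site + w_r),
                        observed_mass=ptm.mass + offset * ISOTOPE_MASS,
                        isotope_offset=offset, score=round(score, 3),
                        level="L1" if level1 else "L2A", is_nta=False,
                    )
                )
                type_site_count[ptm.name] += 1
            else:
                m = _draw_decoy_mass(rng, table, decoy_masses)
                decoy_masses.append(m)
                offset = int(rng.choice([-1, 1])) if rng.random() < spec.isotope_error_prob else 0
                planted.append(
                    _Planted(
                        item_id=iid, protein=acc, site=site, kind="decoy", ptm=None,
                        region=(site - w_l, site + w_r),
                        observed_mass=m + offset * ISOTOPE_MASS,
                        isotope_offset=offset, score=round(float(rng.uniform(0.0, 1.0)), 3),
                        level="L3", is_nta=False,
                    )
                )
            cursor = slot_end + 4  # 3 background residues between slots
        while len(seq) < max(target_len, cursor + 5):
            seq.append(str(rng.choice(list(AMINO_ACIDS), p=weights)))
        sequences[acc] = "".join(seq)

        if nta_flags[pi]:
            item_counter += 1
            planted.append(
                _Planted(
                    item_id=f"E{item_counter:04d}", protein=acc, site=1, kind="nta",
                    ptm=nta, region=(1, 1), observed_mass=nta.mass, isotope_offset=0,
                    score=None, level="L1", is_nta=True,
                )
            )

    # ---- bottom-up coverage -----------------------------------------
    digests = {acc: tryptic_peptides(s) for acc, s in sequences.items()}
    nta_proteins = {i.protein for i in planted if i.kind == "nta"}

    def _peptide_candidates(item: _Planted) -> list[tuple[int, str]]:
        seq = sequences[item.protein]
        cands = [
            (start, pep)
            for start, pep in digests[item.protein]
            if start <= item.site <= start + len(pep) - 1
        ]
        if item.kind == "nta":
            cands = [(s, p) for s, p in cands if s == 1]
            if not cands:  # semi-tryptic fallback so coverage stays possible
                cands = [(1, seq[: min(12, len(seq))])]
            return cands
        # a peptide covering both residue 1 and a near-NTA-mass site would
        # merge with the N-terminal acetylation shift during deduplication
        avoid_nterm = (
            item.kind == "typed"
            and item.protein in nta_proteins
            and abs(item.ptm.mass - nta.mass) < 0.12
        )
        if avoid_nterm:
            cands = [(s, p) for s, p in cands if s > 1]
        if not cands:
            # K/R-dense neighborhoods can leave no fully tryptic peptide of
            # length >=5 around the site; fall back to a semi-tryptic window
            lo = max(2 if avoid_nterm else 1, item.site - 7)
            hi = min(len(seq), item.site + 7)
            cands = [(lo, seq[lo - 1 : hi])]
        return cands

    for item in planted:
        cands = _peptide_candidates(item)
        if cands and rng.random() < spec.coverage:
            item.covered = True
            item.peptide = cands[int(rng.integers(len(cands)))]
    # every plantable type must keep bottom-up support (high-frequency gate)
    for ptm in plantable:
        typed = [i for i in planted if i.kind == "typed" and i.ptm.name == ptm.name]
        if not any(i.covered for i in typed):
            coverable = []
            for i in typed:
                cands = _peptide_candidates(i)
                if cands:
                    coverable.append((i, cands))
            if not coverable:
                raise FixtureError(f"no coverable site for {ptm.name}; spec infeasible")
            i, cands = coverable[0]
            i.covered = True
            i.peptide = cands[int(rng.integers(len(cands)))]

    # ---- annotations -------------------------------------------------
    for item in planted:
        if item.kind == "decoy":
            continue
        if item.ptm.name in UNIPROT_TYPES and rng.random() < spec.p_uniprot:
            item.uniprot = True
        if item.ptm.name in DBPTM_TYPES and rng.random() < spec.p_dbptm:
            item.dbptm = True

    # ---- top-down table ---------------------------------------------
    td_rows = []
    rec_counter = 0

    def jitter() -> float:
        return float(rng.uniform(-spec.mass_jitter, spec.mass_jitter))

    nta_attach: dict[str, int] = {}  # protein -> NTA records still to place
    for item in planted:
        if item.kind == "nta":
            nta_attach[item.protein] = int(rng.integers(1, 4))
    for item in planted:
        if item.kind == "nta":
            continue
        n_records = int(rng.integers(spec.duplicates[0], spec.duplicates[1] + 1))
        w_l0 = item.site - item.region[0]
        w_r0 = item.region[1] - item.site
        for _ in range(max(1, n_records)):
            rec_counter += 1
            w_l = int(rng.integers(0, w_l0 + 1))
            w_r = int(rng.integers(0, w_r0 + 1))
            a, b = item.site - w_l, item.site + w_r
            row = {
                "Prsm ID": f"TD{rec_counter:05d}",
                "Protein accession": item.protein,
                "First residue": 1,
                "Last residue": len(sequences[item.protein]),
                "Unexpected modifications": f"{item.observed_mass + jitter():.5f}:{a}-{b}:{item.score:.3f}",
                "Variable PTMs": "",
                "Matched fragment positions": f"{a-2},{a-1},{b+1},{b+2}",
            }
            if nta_attach.get(item.protein, 0) > 0:
                row["Variable PTMs"] = f"{NTA_NAME}:1"
                nta_attach[item.protein] -= 1
            td_rows.append(row)
    # leftover N-terminal acetylations on proteins with no other shift records
    for acc, remaining in sorted(nta_attach.items()):
        for _ in range(remaining):
            rec_counter += 1
            td_rows.append(
                {
                    "Prsm ID": f"TD{rec_counter:05d}",
                    "Protein accession": acc,
                    "First residue": 1,
                    "Last residue": len(sequences[acc]),
                    "Unexpected modifications": "",
                    "Variable PTMs": f"{NTA_NAME}:1",
                    "Matched fragment positions": "",
                }
            )

    # ---- bottom-up table --------------------------------------------
    bu_rows: list[dict] = []
    psm_counter = 0

    def add_psm(peptide: tuple[int, str], protein: str, delta: str, assigned: str) -> None:
        nonlocal psm_counter
        psm_counter += 1
        bu_rows.append(
            {
                "Spectrum": f"PSM{psm_counter:06d}",
                "Peptide": peptide[1],
                "Protein ID": protein,
                "Protein Start": peptide[0],
                "Delta Mass": delta,
                "Assigned Modifications": assigned,
            }
        )

    type_psm_rows: dict[str, list[_Planted]] = {p.name: [] for p in plantable}
    for item in planted:
        if not item.covered:
            continue
        mult = int(rng.integers(spec.psm_multiplicity[0], spec.psm_multiplicity[1] + 1))
        for _ in range(max(1, mult)):
            if item.kind == "nta":
                add_psm(item.peptide, item.protein, "", f"1:{NTA_NAME}")
            elif item.kind == "typed":
                add_psm(item.peptide, item.protein, f"{item.ptm.mass + jitter():.5f}", "")
                type_psm_rows[item.ptm.name].append(item)
            else:
                # bottom-up open search sees the true mass, no neutron error
                base = item.observed_mass - item.isotope_offset * ISOTOPE_MASS
                add_psm(item.peptide, item.protein, f"{base + jitter():.5f}", "")

    accs = sorted(sequences)
    for _ in range(spec.n_unmodified_psms):
        acc = accs[int(rng.integers(len(accs)))]
        peps = digests[acc]
        if peps:
            add_psm(peps[int(rng.integers(len(peps)))], acc, "", "")
    # a sprinkle of deamidation, later excluded as isotope-confusable
    deam = by_name["Deamidation"]
    n_deam = 0
    for _ in range(400):
        if n_deam >= 20:
            break
        acc = accs[int(rng.integers(len(accs)))]
        peps = [e for e in digests[acc] if ("N" in e[1] or "Q" in e[1])]
        if peps:
            add_psm(peps[int(rng.integers(len(peps)))], acc, f"{deam.mass + jitter():.5f}", "")
            n_deam += 1

    # top up any under-represented type so selection is never starved
    threshold = 0.0015
    while True:
        total = len(bu_rows)
        need = int(np.ceil(threshold * total * 1.5)) + 2
        lacking = {
            name: need - len(rows_)
            for name, rows_ in type_psm_rows.items()
            if need - len(rows_) > 0
        }
        if not lacking:
            break
        for name, d in sorted(lacking.items()):
            donors = [i for i in planted if i.kind == "typed" and i.ptm.name == name and i.covered]
            donor = donors[0]
            for _ in range(d):
                add_psm(donor.peptide, donor.protein, f"{donor.ptm.mass + jitter():.5f}", "")
                type_psm_rows[name].append(donor)

    # ---- annotation tables ------------------------------------------
    uni_rows, db_rows = [], []
    for item in planted:
        if item.kind == "decoy":
            continue
        res = sequences[item.protein][item.site - 1]
        if item.uniprot:
            if item.kind == "nta":
                desc = "N-acetylmethionine"
            else:
                desc = _UNIPROT_DESC.get((item.ptm.name, res), item.ptm.name)
            uni_rows.append({"Accession": item.protein, "Position": item.site, "Description": desc})
        if item.dbptm:
            db_rows.append({"Accession": item.protein, "Site": item.site, "PTM": item.ptm.name})
    if uni_rows:  # exercise duplicate collapsing and unresolvable names
        uni_rows.append(dict(uni_rows[0]))
        uni_rows.append({"Accession": accs[0], "Position": 2, "Description": "GPI-anchor amidated serine"})

    # ---- write everything -------------------------------------------
    paths = {
        "fasta": out / "proteome.fasta",
        "topdown": out / "topdown.tsv",
        "bottomup": out / "bottomup.tsv",
        "uniprot": out / "uniprot.tsv",
        "dbptm": out / "dbptm.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    with open(paths["fasta"], "w") as fh:
        for acc in accs:
            fh.write(f">{acc} synthetic protein\n")
            s = sequences[acc]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    pd.DataFrame(td_rows).to_csv(paths["topdown"], sep="\t", index=False)
    pd.DataFrame(bu_rows).to_csv(paths["bottomup"], sep="\t", index=False)
    pd.DataFrame(uni_rows, columns=["Accession", "Position", "Description"]).to_csv(
        paths["uniprot"], sep="\t", index=False
    )
    pd.DataFrame(db_rows, columns=["Accession", "Site", "PTM"]).to_csv(
        paths["dbptm"], sep="\t", index=False
    )
    truth = pd.DataFrame(
        [
            {
                "item_id": i.item_id,
                "protein": i.protein,
                "site": i.site,
                "kind": i.kind,
                "ptm": i.ptm.name if i.ptm else "",
                "observed_mass": round(i.observed_mass, 5),
                "isotope_offset": i.isotope_offset,
                "score": "" if i.score is None else i.score,
                "level": i.level,
                "is_nta": int(i.is_nta),
                "verified_bottomup": int(i.covered),
                "verified_uniprot": int(i.uniprot),
                "verified_dbptm": int(i.dbptm),
            }
            for i in planted
        ]
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    # paths are relative to the config file so the directory is relocatable
    # (and regeneration is byte-identical)
    config = {
        "fasta": paths["fasta"].name,
        "topdown": {"path": paths["topdown"].name, "dialect": "toppic"},
        "bottomup": {"path": paths["bottomup"].name, "dialect": "msfragger"},
        "annotations": [
            {"path": paths["uniprot"].name, "source": "uniprot"},
            {"path": paths["dbptm"].name, "source": "dbptm"},
        ],
        "options": {"mass_tol": 0.1, "cluster_tol": 0.1, "score_threshold": 0.6},
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# truth comparison


def compare_to_truth(pipeline_result, truth: pd.DataFrame) -> dict:
    """Match pipeline output against a fixture's truth table.

    Each verified/classified shift is assigned to the unique truth row whose
    site lies in its candidate region on the same protein with a compatible
    mass.  Returns recovery rates for levels, PTM types and all three
    verification flags (1.0 means exact reproduction).
    """
    results = pipeline_result.results
    mism: list[str] = []
    n_matched = 0
    ok_level = ok_type = ok_bu = ok_uni = ok_db = 0
    claimed: set[int] = set()
    for r in results:
        s = r.item.shift
        hits = truth[
            (truth["protein"] == s.protein)
            & (truth["site"] >= s.region_start)
            & (truth["site"] <= s.region_end)
            & ((truth["observed_mass"] - s.mass).abs() < 0.05)
        ]
        if len(hits) != 1:
            mism.append(f"{s.record_id}: {len(hits)} truth rows match")
            continue
        row = hits.iloc[0]
        idx = int(hits.index[0])
        if idx in claimed:
            mism.append(f"{s.record_id}: truth row {row['item_id']} claimed twice")
            continue
        claimed.add(idx)
        n_matched += 1
        group = "NTA" if row["is_nta"] else row["level"]
        ok_level += int(r.item.level_group == group)
        best = r.item.best
        want_type = "" if pd.isna(row["ptm"]) else row["ptm"]
        got_type = best.ptm.name if best else ""
        ok_type += int(got_type == want_type)
        ok_bu += int(int(r.verified_by_bottomup) == int(row["verified_bottomup"]))
        ok_uni += int(int(r.verified_by_annotation("uniprot")) == int(row["verified_uniprot"]))
        ok_db += int(int(r.verified_by_annotation("dbptm")) == int(row["verified_dbptm"]))
        if r.item.level_group != group or got_type != want_type:
            mism.append(
                f"{s.record_id}: level {r.item.level_group} vs {group}, type {got_type!r} vs {want_type!r}"
            )
    n = max(n_matched, 1)
    return {
        "n_truth": len(truth),
        "n_pipeline": len(results),
        "n_matched": n_matched,
        "level_recovery": ok_level / n,
        "type_recovery": ok_type / n,
        "bottomup_flag_recovery": ok_bu / n,
        "uniprot_flag_recovery": ok_uni / n,
        "dbptm_flag_recovery": ok_db / n,
        "mismatches": mism,
    }
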