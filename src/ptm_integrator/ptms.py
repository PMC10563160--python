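"""The modification table: built-in high-frequency PTMs and name resolution.

The package ships a default table of the twelve modifications that dominate
open-search results on human samples (oxidation, methyl/dimethyl/trimethyl,
lysine and N-terminal acetylation, phosphorylation, carbamylation,
carbamidomethylation, sodium and potassium adducts, deamidation), with
monoisotopic masses and residue specificities.  Search engines and annotation
databases name the same chemistry in many ways ("Acetyl (Protein N-term)",
"N-acetylalanine", "Phosphoserine", ...); ``resolve_ptm_name`` maps those
spellings onto the table's canonical names.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .core import PTMDefinition

NTA_NAME = "N-terminal acetylation"

# Lower-cased alias -> canonical table name.  Covers the spellings used by
# MSFragger/MetaMorpheus/MaxQuant output and UniProt/dbPTM annotation rows.
NAME_ALIASES: dict[str, str] = {
    "oxidation": "Oxidation",
    "oxidation (m)": "Oxidation",
    "hydroxylation": "Oxidation",
    "methyl": "Methylation",
    "methylation": "Methylation",
    "n6-methyllysine": "Methylation",
    "omega-n-methylarginine": "Methylation",
    "s-methylcysteine": "Methylation",
    "dimethyl": "Dimethylation",
    "dimethylation": "Dimethylation",
    "n6,n6-dimethyllysine": "Dimethylation",
    "omega-n,omega-n-dimethylarginine": "Dimethylation",
    "trimethyl": "Trimethylation",
    "trimethylation": "Trimethylation",
    "n6,n6,n6-trimethyllysine": "Trimethylation",
    "acetyl": "Acetylation",
    "acetyl (k)": "Acetylation",
    "acetylation": "Acetylation",
    "n6-acetyllysine": "Acetylation",
    "acetyl (protein n-term)": NTA_NAME,
    "n-term acetylation": NTA_NAME,
    "n-terminal acetylation": NTA_NAME,
    "nta": NTA_NAME,
    "phospho": "Phosphorylation",
    "phospho (sty)": "Phosphorylation",
    "phosphorylation": "Phosphorylation",
    "phosphoserine": "Phosphorylation",
    "phosphothreonine": "Phosphorylation",
    "phosphotyrosine": "Phosphorylation",
    "carbamyl": "Carbamylation",
    "carbamylation": "Carbamylation",
    "carbamidomethyl": "Carbamidomethylation",
    "carbamidomethylation": "Carbamidomethylation",
    "cation:na": "Sodium adduct",
    "sodium adduct": "Sodium adduct",
    "cation:k": "Potassium adduct",
    "potassium adduct": "Potassium adduct",
    "deamidated": "Deamidation",
    "deamidation": "Deamidation",
}


def load_ptm_table(path: str | Path) -> list[PTMDefinition]:
    """Read a modification table (TSV: name, mass, residues, nterm_only).

    ``residues`` is a concatenation of one-letter codes; "-" (or empty)
    means no side-chain specificity, which is only legal for terminal PTMs.
    """
    out: list[PTMDefinition] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            res = row["residues"].strip()
            out.append(
                PTMDefinition(
                    name=row["name"].strip(),
                    mass=float(row["mass"]),
                    residues=frozenset() if res in ("", "-") else frozenset(res),
                    nterm_only=row["nterm_only"].strip() in ("1", "true", "True"),
                )
            )
    return out


def builtin_ptm_table() -> list[PTMDefinition]:
    """The default twelve-entry high-frequency modification table."""
    with resources.as_file(
        resources.files("ptm_integrator.data").joinpath("ptm_table.tsv")
    ) as p:
        return load_ptm_table(p)


def table_by_name(table: Iterable[PTMDefinition]) -> dict[str, PTMDefinition]:
    return {p.name: p for p in table}


def resolve_ptm_name(
    raw: str, table: Iterable[PTMDefinition]
) -> Optional[PTMDefinition]:
    """Map a search-engine or annotation-database PTM spelling onto the
    table, or None when it cannot be resolved.

    UniProt "Modified residue" descriptions of the form "N-acetyl<residue>"
    (N-acetylalanine, N-acetylmethionine, ...) denote protein N-terminal
    acetylation and resolve to the terminal entry.
    """
    by_name = table_by_name(table)
    key = raw.strip()
    # UniProt prefixes descriptions with "Modified residue N: "
    if ":" in key and key.lower().startswith("modified residue"):
        key = key.split(":", 1)[1].strip()
    if key in by_name:
        return by_name[key]
    low = key.lower()
    if low in NAME_ALIASES:
        return by_name.get(NAME_ALIASES[low])
    if low.startswith("n-acetyl"):
        return by_name.get(NTA_NAME)
    return None
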