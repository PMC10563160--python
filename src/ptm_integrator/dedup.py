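"""Duplicate removal for mass shifts reported across identifications.

The same modification is typically reported many times: by several PSMs of
one modified peptide, or by overlapping proteoforms of one protein.  Removal
runs in two stages: shifts of a protein are first clustered by mass alone
(single-linkage, strict tolerance, no isotope allowance), then each cluster
is swept greedily in order of the left region boundary, removing every member
that matches an already-kept one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core import MassShift, MatchConfig, match_shift

DEFAULT_CLUSTER_TOL = 0.1


@dataclass
class ShiftCluster:
    protein: str
    members: list[MassShift] = field(default_factory=list)

    @property
    def representative_mass(self) -> float:
        return sum(m.mass for m in self.members) / len(self.members)


def cluster_shifts(
    shifts: Iterable[MassShift], cluster_tol: float = DEFAULT_CLUSTER_TOL
) -> list[ShiftCluster]:
    """Group shifts of the same protein whose masses chain together.

    Two shifts join a cluster when they share the protein and their masses
    differ by strictly less than ``cluster_tol``; the relation is closed
    transitively (on sorted masses this is chaining of consecutive gaps).
    Isotope offsets are deliberately not considered at this stage.
    """
    by_protein: dict[str, list[MassShift]] = {}
    for s in shifts:
        by_protein.setdefault(s.protein, []).append(s)

    clusters: list[ShiftCluster] = []
    for protein in sorted(by_protein):
        members = sorted(by_protein[protein], key=lambda s: (s.mass, s.record_id))
        current = ShiftCluster(protein, [members[0]])
        for prev, cur in zip(members, members[1:]):
            if cur.mass - prev.mass < cluster_tol:
                current.members.append(cur)
            else:
                clusters.append(current)
                current = ShiftCluster(protein, [cur])
        clusters.append(current)
    return clusters


def _rank_key(s: MassShift):
    return (s.region_start, s.region_end, s.record_id)


def dedup_cluster(
    cluster: ShiftCluster, cfg: MatchConfig = MatchConfig()
) -> tuple[list[MassShift], list[tuple[MassShift, MassShift]]]:
    """Greedy sweep over a cluster ranked by left region boundary.

    The first-ranked member is kept; each later member is compared against
    every kept member and removed on the first match (mapped to that kept
    shift), otherwise kept itself.  Ties in rank break on region end and
    record id so the outcome is deterministic.
    """
    kept: list[MassShift] = []
    removed: list[tuple[MassShift, MassShift]] = []
    for s in sorted(cluster.members, key=_rank_key):
        partner = next((k for k in kept if match_shift(s, k, cfg)), None)
        if partner is None:
            kept.append(s)
        else:
            removed.append((s, partner))
    return kept, removed


def dedup_all(
    shifts: Iterable[MassShift],
    cluster_tol: float = DEFAULT_CLUSTER_TOL,
    cfg: MatchConfig = MatchConfig(),
) -> tuple[list[MassShift], pd.DataFrame]:
    """Cluster then deduplicate; returns kept shifts plus an audit table
    recording every removal with its kept partner."""
    kept_all: list[MassShift] = []
    audit_rows = []
    for cluster in cluster_shifts(shifts, cluster_tol):
        kept, removed = dedup_cluster(cluster, cfg)
        kept_all.extend(kept)
        for gone, partner in removed:
            audit_rows.append(
                {
                    "removed_record_id": gone.record_id,
                    "kept_record_id": partner.record_id,
                    "mass_delta": gone.mass - partner.mass,
                    "overlap_start": max(gone.region_start, partner.region_start),
                    "overlap_end": min(gone.region_end, partner.region_end),
                }
            )
    audit = pd.DataFrame(
        audit_rows,
        columns=["removed_record_id", "kept_record_id", "mass_delta", "overlap_start", "overlap_end"],
    )
    kept_all.sort(key=lambda s: (s.protein, _rank_key(s)))
    return kept_all, audit
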