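"""Mismatch-threshold species assignment of query insert sequences.

A query (the 126 bp insert recovered from a scat sample) is assigned to the
species whose reference haplotype it matches within a maximum number of
mismatches (default 2, strict Hamming).  References from the survey region
are preferred when a region tag is given — regional references are searched
first and the global set is only consulted when no regional hit falls
within the threshold — reflecting that intraspecific geographic divergence
can push a query past the threshold against far-away references while a
local reference matches exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .refdb import ReferenceDB, Haplotype
from .seqcore import BarcodeSeq, hamming

__all__ = [
    "AssignmentStatus",
    "AssignmentResult",
    "assign",
    "batch_assign",
    "BatchSummary",
]

INSERT_LENGTH = 126


class AssignmentStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"
    FAILED_TO_AMPLIFY = "failed_to_amplify"


@dataclass
class AssignmentResult:
    query_id: str
    status: AssignmentStatus
    best_species: Optional[str] = None
    best_distance: Optional[int] = None
    runner_up_species: Optional[str] = None
    runner_up_distance: Optional[int] = None
    #: haplotype representative ids at the best distance
    references_hit: tuple[str, ...] = ()
    #: species tying at the best distance (≥2 only when ambiguous)
    tied_species: tuple[str, ...] = ()
    regional_match: bool = False

    def to_row(self) -> dict:
        return {
            "query_id": self.query_id,
            "status": self.status.value,
            "best_species": self.best_species or "",
            "best_distance": ""
            if self.best_distance is None
            else self.best_distance,
            "runner_up_species": self.runner_up_species or "",
            "runner_up_distance": ""
            if self.runner_up_distance is None
            else self.runner_up_distance,
            "references_hit": ",".join(self.references_hit),
            "tied_species": ",".join(self.tied_species),
            "regional_match": self.regional_match,
        }


def _candidates(
    db: ReferenceDB, region: Optional[str]
) -> tuple[list[Haplotype], list[Haplotype]]:
    """Split haplotypes into (regional, all); regional by member record tag."""
    all_haps = [h for sp in sorted(db.haplotypes) for h in db.haplotypes[sp]]
    if not region:
        return [], all_haps
    regions = {r.id: r.region for r in db.records}
    regional = [
        h
        for h in all_haps
        if any(regions.get(mid, "") == region for mid in h.member_ids)
    ]
    return regional, all_haps


def _scan(
    query: BarcodeSeq, haps: Sequence[Haplotype], policy: str
) -> tuple[int, list[Haplotype], Optional[str], Optional[int]]:
    """Min distance, arg-min haplotypes, and runner-up species/distance."""
    dists = [hamming(query.residues, h.sequence, policy) for h in haps]
    best = min(dists)
    winners = [h for h, d in zip(haps, dists) if d == best]
    best_species = {h.species for h in winners}
    runner_sp, runner_d = None, None
    for h, d in sorted(zip(haps, dists), key=lambda t: (t[1], t[0].species)):
        if h.species not in best_species:
            runner_sp, runner_d = h.species, d
            break
    return best, winners, runner_sp, runner_d


def assign(
    query: BarcodeSeq,
    db: ReferenceDB,
    threshold: int = 2,
    region: Optional[str] = None,
    ambiguity_policy: str = "strict",
) -> AssignmentResult:
    """Assign one query to a species by minimum Hamming distance.

    ``ambiguity_policy`` is "strict" by default (an N counts as a
    mismatch, conservative); "compatible" treats intersecting IUPAC sets
    as matches, appropriate for noisy Sanger base calls.

    Assigned when a single species is strictly unique at the minimum
    distance and that distance is within ``threshold``; ambiguous when two
    or more species tie within the threshold; unassigned otherwise.  The
    per-species distance is the minimum over that species' haplotypes.
    """
    if query.length != INSERT_LENGTH:
        raise ValueError(
            f"query {query.id!r} has length {query.length}; expected "
            f"{INSERT_LENGTH} (run extract_insert first)"
        )
    if not db.haplotypes:
        raise ValueError("reference database is empty or not deduplicated")
    regional, all_haps = _candidates(db, region)

    used_regional = False
    best, winners, runner_sp, runner_d = _scan(query, all_haps, ambiguity_policy)
    if regional:
        rbest, rwinners, rrunner_sp, rrunner_d = _scan(
            query, regional, ambiguity_policy
        )
        if rbest <= threshold:
            best, winners, runner_sp, runner_d = (
                rbest,
                rwinners,
                rrunner_sp,
                rrunner_d,
            )
            used_regional = True

    species = sorted({h.species for h in winners})
    refs = tuple(sorted(h.representative_id for h in winners))
    if best > threshold:
        return AssignmentResult(
            query_id=query.id,
            status=AssignmentStatus.UNASSIGNED,
            best_species=None,
            best_distance=best,
            references_hit=refs,
            tied_species=tuple(species),
        )
    if len(species) > 1:
        return AssignmentResult(
            query_id=query.id,
            status=AssignmentStatus.AMBIGUOUS,
            best_species=None,
            best_distance=best,
            runner_up_species=runner_sp,
            runner_up_distance=runner_d,
            references_hit=refs,
            tied_species=tuple(species),
            regional_match=used_regional,
        )
    return AssignmentResult(
        query_id=query.id,
        status=AssignmentStatus.ASSIGNED,
        best_species=species[0],
        best_distance=best,
        runner_up_species=runner_sp,
        runner_up_distance=runner_d,
        references_hit=refs,
        tied_species=tuple(species),
        regional_match=used_regional,
    )


@dataclass
class BatchSummary:
    n_total: int
    n_assigned: int
    n_ambiguous: int
    n_unassigned: int
    n_failed: int
    per_species: dict[str, int] = field(default_factory=dict)

    @property
    def percent_assigned(self) -> float:
        return 100.0 * self.n_assigned / self.n_total if self.n_total else 0.0


def batch_assign(
    queries: Iterable[BarcodeSeq],
    db: ReferenceDB,
    threshold: int = 2,
    region: Optional[str] = None,
    failed_ids: Iterable[str] = (),
    ambiguity_policy: str = "strict",
) -> tuple[list[AssignmentResult], BatchSummary]:
    """Assign a cohort; amplification failures pass through unassessed.

    ``failed_ids`` names samples whose amplification failed upstream (no
    sequence was obtained); they are recorded as ``failed_to_amplify`` and
    counted in the denominator of the summary percentages.
    """
    results = [
        AssignmentResult(query_id=qid, status=AssignmentStatus.FAILED_TO_AMPLIFY)
        for qid in failed_ids
    ]
    for q in queries:
        results.append(
            assign(q, db, threshold=threshold, region=region,
                   ambiguity_policy=ambiguity_policy)
        )
    per_species: dict[str, int] = {}
    counts = {s: 0 for s in AssignmentStatus}
    for r in results:
        counts[r.status] += 1
        if r.status is AssignmentStatus.ASSIGNED:
            per_species[r.best_species] = per_species.get(r.best_species, 0) + 1
    summary = BatchSummary(
        n_total=len(results),
        n_assigned=counts[AssignmentStatus.ASSIGNED],
        n_ambiguous=counts[AssignmentStatus.AMBIGUOUS],
        n_unassigned=counts[AssignmentStatus.UNASSIGNED],
        n_failed=counts[AssignmentStatus.FAILED_TO_AMPLIFY],
        per_species=dict(sorted(per_species.items())),
    )
    return results, summary


def results_table(results: Iterable[AssignmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
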