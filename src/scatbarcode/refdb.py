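"""Curation and haplotype reduction of the barcode reference database.

Reference records carry provenance flags mirroring the curation rules used
to assemble carnivore reference panels from public repositories: reviewed
(``NC_``) entries are dropped in favour of their original submissions;
historical and withdrawn records are dropped unconditionally; non-African,
captive-origin or unknown-origin records are kept only as a species' last
resort; records with insufficient insert coverage are moved to a
binding-assessment-only set; and per-species exact-string haplotype
deduplication yields the representative identification panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .seqcore import BarcodeSeq, write_fasta, read_fasta

__all__ = [
    "ReferenceRecord",
    "Haplotype",
    "ReferenceDB",
    "CurationResult",
    "CrossSpeciesHaplotypeWarning",
    "VALID_FLAGS",
    "apply_curation_filters",
    "dedup_haplotypes",
    "export_representative_set",
    "load_reference_db",
]

VALID_FLAGS = frozenset(
    {
        "reviewed_refseq",
        "historical",
        "non_african",
        "captive",
        "unknown_origin",
        "withdrawn",
        "insufficient_coverage",
        "ambiguous_redundant",
    }
)

#: flags marking provenance that is acceptable only as a last resort
_LAST_RESORT = frozenset({"non_african", "captive", "unknown_origin"})


class CrossSpeciesHaplotypeWarning(UserWarning):
    """Two different species share an identical insert string."""


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    species: str
    insert: Optional[BarcodeSeq] = None
    common_name: str = ""
    provenance_flags: frozenset[str] = frozenset()
    region: str = ""
    source: str = "genbank"

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"record {self.id!r} lacks a species label")
        bad = set(self.provenance_flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"record {self.id!r}: unknown flags {sorted(bad)}")
        object.__setattr__(
            self, "provenance_flags", frozenset(self.provenance_flags)
        )


@dataclass(frozen=True)
class Haplotype:
    species: str
    sequence: str
    member_ids: tuple[str, ...]

    @property
    def representative_id(self) -> str:
        """Deterministic representative: lexicographically smallest member id."""
        return min(self.member_ids)


@dataclass
class ReferenceDB:
    records: list[ReferenceRecord]
    haplotypes: dict[str, list[Haplotype]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def haplotype_count(self) -> int:
        return sum(len(v) for v in self.haplotypes.values())

    def region_of(self, record_id: str) -> str:
        for r in self.records:
            if r.id == record_id:
                return r.region
        raise KeyError(record_id)


@dataclass
class CurationResult:
    kept: list[ReferenceRecord]
    #: records usable for primer-binding assessment but not sequence comparison
    binding_only: list[ReferenceRecord]
    dropped: list[tuple[ReferenceRecord, str]]

    @property
    def drop_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.id, r.species, reason) for r, reason in self.dropped],
            columns=["id", "species", "reason"],
        )


def apply_curation_filters(
    records: Iterable[ReferenceRecord],
) -> CurationResult:
    """Apply the provenance-driven curation rules.

    Every dropped record carries a reason code; ``kept + binding_only +
    dropped`` partitions the input, and the filter is idempotent.
    """
    records = list(records)
    by_species: dict[str, list[ReferenceRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)

    def has_unflagged(sp: str, *, ignoring: ReferenceRecord) -> bool:
        for other in by_species[sp]:
            if other.id == ignoring.id:
                continue
            if other.provenance_flags & {
                "historical",
                "withdrawn",
                "reviewed_refseq",
                "insufficient_coverage",
            }:
                continue
            if not (other.provenance_flags & _LAST_RESORT):
                return True
        return False

    kept: list[ReferenceRecord] = []
    binding_only: list[ReferenceRecord] = []
    dropped: list[tuple[ReferenceRecord, str]] = []
    for r in records:
        flags = r.provenance_flags
        if "withdrawn" in flags:
            dropped.append((r, "withdrawn"))
        elif "historical" in flags:
            dropped.append((r, "historical"))
        elif "reviewed_refseq" in flags and any(
            o.id != r.id and "reviewed_refseq" not in o.provenance_flags
            and not (o.provenance_flags & {"historical", "withdrawn"})
            for o in by_species[r.species]
        ):
            dropped.append((r, "reviewed_refseq"))
        elif "insufficient_coverage" in flags:
            binding_only.append(r)
        elif flags & _LAST_RESORT and has_unflagged(r.species, ignoring=r):
            reason = sorted(flags & _LAST_RESORT)[0]
            dropped.append((r, reason))
        elif "ambiguous_redundant" in flags and any(
            o.id != r.id
            and "ambiguous_redundant" not in o.provenance_flags
            and not (
                o.provenance_flags
                & {"historical", "withdrawn", "insufficient_coverage"}
            )
            for o in by_species[r.species]
        ):
            dropped.append((r, "ambiguous_redundant"))
        else:
            kept.append(r)
    return CurationResult(kept=kept, binding_only=binding_only, dropped=dropped)


def dedup_haplotypes(
    records: Iterable[ReferenceRecord] | ReferenceDB,
) -> ReferenceDB:
    """Species-wise exact-string deduplication of insert sequences.

    Deduplication is *within* species: two species sharing an identical
    insert are both retained, with a :class:`CrossSpeciesHaplotypeWarning`
    (such a marker would not be diagnostic between them).
    """
    if isinstance(records, ReferenceDB):
        records = records.records
    records = list(records)
    for r in records:
        if r.insert is None:
            raise ValueError(
                f"record {r.id!r} has no insert sequence; run curation first"
            )
    haplotypes: dict[str, list[Haplotype]] = {}
    for sp in sorted({r.species for r in records}):
        members: dict[str, list[str]] = {}
        for r in records:
            if r.species != sp:
                continue
            members.setdefault(r.insert.residues, []).append(r.id)
        haplotypes[sp] = [
            Haplotype(species=sp, sequence=seq, member_ids=tuple(sorted(ids)))
            for seq, ids in sorted(members.items())
        ]
    seen: dict[str, str] = {}
    for sp, haps in haplotypes.items():
        for h in haps:
            if h.sequence in seen and seen[h.sequence] != sp:
                warnings.warn(
                    f"species {sp!r} and {seen[h.sequence]!r} share an "
                    "identical insert haplotype",
                    CrossSpeciesHaplotypeWarning,
                )
            seen.setdefault(h.sequence, sp)
    return ReferenceDB(records=records, haplotypes=haplotypes)


def export_representative_set(
    db: ReferenceDB, fasta_path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write one record per haplotype, deterministically ordered.

    Header: ``species|h<index>|<representative id>`` with spaces in the
    species name replaced by underscores; species alphabetical, haplotypes
    by index.  Re-export of an unchanged database is byte-identical.
    """
    if not db.haplotypes:
        raise ValueError("database has no haplotypes; run dedup_haplotypes first")
    seqs: list[BarcodeSeq] = []
    meta_rows = []
    for sp in sorted(db.haplotypes):
        for idx, h in enumerate(db.haplotypes[sp], start=1):
            header = f"{sp.replace(' ', '_')}|h{idx}|{h.representative_id}"
            seqs.append(BarcodeSeq(id=header, residues=h.sequence))
            meta_rows.append(
                {
                    "id": header,
                    "species": sp,
                    "haplotype": idx,
                    "representative_id": h.representative_id,
                    "member_ids": ",".join(h.member_ids),
                }
            )
    write_fasta(seqs, fasta_path)
    if meta_path is not None:
        pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def load_reference_db(
    fasta_path: str | Path,
    meta_path: str | Path,
    auto_flag_reviewed: bool = True,
) -> list[ReferenceRecord]:
    """Load records from FASTA plus a TSV metadata sidecar keyed by id.

    Sidecar columns: ``id, species`` required; ``common_name, flags
    (comma-separated), region, source`` optional.  ``NC_``-prefixed ids are
    auto-flagged ``reviewed_refseq`` unless disabled (other provenance flags
    are human annotations and never inferred).
    """
    seqs = {s.id: s for s in read_fasta(fasta_path)}
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    if not {"id", "species"} <= set(meta.columns):
        raise ValueError("metadata sidecar needs 'id' and 'species' columns")
    records = []
    for row in meta.itertuples(index=False):
        flags = {f for f in str(getattr(row, "flags", "")).split(",") if f}
        if auto_flag_reviewed and row.id.startswith("NC_"):
            flags.add("reviewed_refseq")
        seq = seqs.get(row.id)
        records.append(
            ReferenceRecord(
                id=row.id,
                species=row.species,
                insert=seq,
                common_name=str(getattr(row, "common_name", "")),
                provenance_flags=frozenset(flags),
                region=str(getattr(row, "region", "")),
                source=str(getattr(row, "source", "genbank")) or "genbank",
            )
        )
    return records
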