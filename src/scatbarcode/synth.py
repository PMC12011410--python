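"""Synthetic reference panels and query cohorts with known ground truth.

The generator emulates the regime in which a short diagnostic marker works:
between-species divergence on the 126 bp insert far exceeding within-species
variation, so that a 2-mismatch assignment rule separates species cleanly.
It builds a random ancestral 172 bp amplicon carrying the exact default
primer binding sites, derives species founders by planting substitutions in
the insert, optionally plants primer-site substitutions per species (to
exercise the in silico binding assessment), spawns within-species haplotype
variants, and simulates error-bearing queries.

All randomness flows through an explicit seeded generator; identical specs
reproduce byte-identical panels.  Mutations are substitutions only: the
marker's diagnostic logic and the assignment rule are substitution-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .primer_eval import DEFAULT_PRIMERS, PrimerPair
from .refdb import ReferenceDB, ReferenceRecord, dedup_haplotypes
from .seqcore import BarcodeSeq, reverse_complement

__all__ = ["PanelSpec", "Panel", "generate_panel", "generate_queries"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for a synthetic panel.

    Defaults mirror a small carnivore-guild survey: six species, two
    haplotypes each, between-species p-distance 0.10 on the insert versus
    0.01 within species, and a query error rate of 1/126 (about one
    expected substitution per insert).
    """

    n_species: int = 6
    haplotypes_per_species: int = 2
    inter_species_p: float = 0.10
    intra_species_p: float = 0.01
    #: per-species planted primer-site substitutions:
    #: species name -> list of (1-based amplicon position, new sense base)
    primer_mutation_plan: dict[str, list[tuple[int, str]]] = field(
        default_factory=dict
    )
    query_error_rate: float = 1 / 126
    ambiguity_rate: float = 0.01
    region: str = "synthetic-region"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("inter_species_p", self.inter_species_p),
            ("intra_species_p", self.intra_species_p),
            ("query_error_rate", self.query_error_rate),
            ("ambiguity_rate", self.ambiguity_rate),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.inter_species_p <= self.intra_species_p:
            raise ValueError(
                "inter_species_p must exceed intra_species_p: species would "
                "not be diagnosable with this marker"
            )
        if self.n_species < 1 or self.haplotypes_per_species < 1:
            raise ValueError("need at least one species and one haplotype")

    def species_names(self) -> list[str]:
        return [f"species_{i+1:02d}" for i in range(self.n_species)]


@dataclass
class Panel:
    """Generated panel: full-length templates, curated records, and truth."""

    templates: list[BarcodeSeq]  # 172 nt sense amplicons, one per record
    records: list[ReferenceRecord]
    db: ReferenceDB  # deduplicated
    truth: pd.DataFrame  # id, species, haplotype, insert/primer substitutions
    ancestral_amplicon: BarcodeSeq
    spec: PanelSpec


def _mutate(
    seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        choices = _BASES[_BASES != out[s]]
        out[s] = rng.choice(choices)
    return out


def generate_panel(
    spec: PanelSpec, primers: PrimerPair = DEFAULT_PRIMERS
) -> Panel:
    """Generate a reference panel under ``spec``; fully seeded.

    Each species founder differs from the ancestral insert at
    Binomial(126, inter_species_p / 2) sites, so pairwise between-species
    Hamming distances centre on inter_species_p * 126.  Additional
    haplotypes differ from their founder at Binomial(126, intra_species_p)
    sites.  Primer-site substitutions are planted on the sense amplicon at
    the requested positions.
    """
    rng = np.random.default_rng(spec.seed)
    L = primers.insert_length
    insert0 = rng.choice(_BASES, size=L)
    fwd = np.array(list(primers.forward.residues))
    rev_site = np.array(list(reverse_complement(primers.reverse).residues))
    for name, plan in spec.primer_mutation_plan.items():
        if name not in spec.species_names():
            raise ValueError(f"primer_mutation_plan names unknown species {name!r}")
        for pos, base in plan:
            if not 1 <= pos <= primers.amplicon_length:
                raise ValueError(f"amplicon position {pos} out of range")

    templates: list[BarcodeSeq] = []
    records: list[ReferenceRecord] = []
    truth_rows = []
    ins_start = primers.forward.length  # 0-based insert offset in amplicon
    for sp in spec.species_names():
        k = rng.binomial(L, spec.inter_species_p / 2)
        sites = rng.choice(L, size=k, replace=False)
        founder = _mutate(insert0, sites, rng)
        for h in range(spec.haplotypes_per_species):
            if h == 0 or spec.intra_species_p == 0:
                hap = founder.copy()
                hap_sites = np.array([], dtype=int)
            else:
                kh = rng.binomial(L, spec.intra_species_p)
                hap_sites = rng.choice(L, size=kh, replace=False)
                hap = _mutate(founder, hap_sites, rng)
            amplicon = np.concatenate([fwd, hap, rev_site])
            planted_primer = []
            for pos, base in spec.primer_mutation_plan.get(sp, []):
                amplicon[pos - 1] = base
                planted_primer.append((pos, base))
            rec_id = f"{sp}_h{h+1}"
            templates.append(
                BarcodeSeq(id=rec_id, residues="".join(amplicon.tolist()))
            )
            records.append(
                ReferenceRecord(
                    id=rec_id,
                    species=sp,
                    insert=BarcodeSeq(
                        id=rec_id,
                        residues="".join(
                            amplicon[ins_start : ins_start + L].tolist()
                        ),
                    ),
                    region=spec.region,
                    source="this_study",
                )
            )
            truth_rows.append(
                {
                    "id": rec_id,
                    "species": sp,
                    "haplotype": h + 1,
                    "founder_substitutions": ",".join(map(str, sorted(sites))),
                    "haplotype_substitutions": ",".join(
                        map(str, sorted(hap_sites))
                    ),
                    "primer_substitutions": ";".join(
                        f"{p}:{b}" for p, b in planted_primer
                    ),
                }
            )
    db = dedup_haplotypes(records)
    amp0 = np.concatenate([fwd, insert0, rev_site])
    return Panel(
        templates=templates,
        records=records,
        db=db,
        truth=pd.DataFrame(truth_rows),
        ancestral_amplicon=BarcodeSeq("ancestor", "".join(amp0.tolist())),
        spec=spec,
    )


def generate_queries(
    db: ReferenceDB,
    n_per_species: int,
    query_error_rate: float = 1 / 126,
    ambiguity_rate: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[BarcodeSeq], pd.DataFrame]:
    """Simulate error-bearing query inserts from a deduplicated panel.

    Each query samples one of its species' haplotypes uniformly, applies
    per-base substitution noise at ``query_error_rate`` and then N-masking
    at ``ambiguity_rate``; the truth table records the source species and
    haplotype.
    """
    if not db.haplotypes:
        raise ValueError("database has no haplotypes; run dedup_haplotypes first")
    if rng is None:
        rng = np.random.default_rng(seed)
    queries: list[BarcodeSeq] = []
    truth_rows = []
    q = 0
    for sp in sorted(db.haplotypes):
        haps = db.haplotypes[sp]
        for _ in range(n_per_species):
            q += 1
            hap = haps[rng.integers(len(haps))]
            arr = np.array(list(hap.sequence))
            err_sites = np.flatnonzero(rng.random(len(arr)) < query_error_rate)
            arr = _mutate(arr, err_sites, rng)
            n_sites = np.flatnonzero(rng.random(len(arr)) < ambiguity_rate)
            arr[n_sites] = "N"
            qid = f"query_{q:04d}"
            queries.append(BarcodeSeq(id=qid, residues="".join(arr.tolist())))
            truth_rows.append(
                {
                    "query_id": qid,
                    "species": sp,
                    "source_haplotype": hap.representative_id,
                    "n_substitutions": len(err_sites),
                    "n_masked": len(n_sites),
                }
            )
    return queries, pd.DataFrame(truth_rows)
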