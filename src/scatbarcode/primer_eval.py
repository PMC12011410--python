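"""In silico PCR for the ATP6 mini-barcode primer pair.

The marker is a 172 bp amplicon: a 21 nt forward primer site (ATP6-DF3), a
126 bp diagnostic insert, and a 25 nt reverse primer site (ATP6-DR1).  This
module locates the amplicon on a reference template (either strand), tallies
primer-template mismatches over the full primer and over the 3' pentamer —
the five bases nearest the 3' terminus, where mismatches most disrupt
polymerase extension — and classifies expected amplification success.

Coordinate frame (1-based, inclusive, amplicon sense strand):

* forward primer: positions 1-21, 3' pentamer 17-21
* insert: positions 22-147
* reverse primer: positions 148-172, 3' pentamer 148-152; the reverse
  primer's 3'-terminal base anneals at position 148.

Mismatch cells are reported primer base first, then the base the primer
would need to equal on its annealing-equivalent strand: the sense strand for
the forward primer, the antisense (reverse-complement) strand for the
reverse primer.  Under this convention a wild-dog-like template carries the
reverse-pentamer pattern T-G at the 3rd and G-T at the 4th position from the
3' terminus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from .seqcore import BarcodeSeq, hamming, reverse_complement

__all__ = [
    "ATP6_DF3",
    "ATP6_DR1",
    "PrimerPair",
    "AmpliconHit",
    "BindingAssessment",
    "Amplifiability",
    "AmpliconNotFoundError",
    "AmbiguousAmpliconError",
    "PartialInsertError",
    "locate_amplicon",
    "assess_binding",
    "classify_amplifiability",
    "extract_insert",
    "binding_report",
]

ATP6_DF3 = "AACGAAAATCTATTCGCCTCT"
ATP6_DR1 = "CCAGTATTTGTTTTGATGTTAGTTG"


class AmpliconNotFoundError(ValueError):
    """No window satisfied the per-primer mismatch cap."""


class AmbiguousAmpliconError(ValueError):
    """Multiple equally scoring candidate windows."""

    def __init__(self, hits):
        self.hits = hits
        super().__init__(
            "multiple equally scoring amplicon windows: "
            + ", ".join(f"{h.strand}({h.start},{h.end})" for h in hits)
        )


class PartialInsertError(ValueError):
    """The template covers only part of the 126 bp insert."""

    def __init__(self, record_id: str, covered: int, expected: int):
        self.covered = covered
        self.expected = expected
        super().__init__(
            f"record {record_id!r}: insert covers only {covered} of "
            f"{expected} positions; usable for binding assessment only"
        )


class Amplifiability(str, enum.Enum):
    ASSUMED_SUCCESSFUL = "assumed_successful"
    POTENTIALLY_PROBLEMATIC = "potentially_problematic"
    NO_REFERENCE = "no_reference"


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers and the amplicon coordinate frame they induce."""

    forward: BarcodeSeq = field(
        default_factory=lambda: BarcodeSeq("ATP6-DF3", ATP6_DF3)
    )
    reverse: BarcodeSeq = field(
        default_factory=lambda: BarcodeSeq("ATP6-DR1", ATP6_DR1)
    )
    insert_length: int = 126

    @property
    def amplicon_length(self) -> int:
        return self.forward.length + self.insert_length + self.reverse.length

    @property
    def insert_span(self) -> tuple[int, int]:
        """1-based inclusive insert coordinates on the amplicon."""
        return (self.forward.length + 1, self.forward.length + self.insert_length)

    @property
    def reverse_span(self) -> tuple[int, int]:
        start = self.forward.length + self.insert_length + 1
        return (start, self.amplicon_length)


DEFAULT_PRIMERS = PrimerPair()


@dataclass(frozen=True)
class AmpliconHit:
    """Located amplicon window, 1-based inclusive on the carrying strand."""

    start: int
    end: int
    strand: str  # '+' as supplied, '-' found on the reverse complement
    mismatches_forward: int
    mismatches_reverse: int
    amplicon: BarcodeSeq  # sense-oriented (forward primer first)

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_forward + self.mismatches_reverse


@dataclass
class BindingAssessment:
    """Per-species primer-template mismatch profile (Table-2-style)."""

    species: str
    mismatches_forward_total: int
    mismatches_reverse_total: int
    mismatches_forward_3prime: int
    mismatches_reverse_3prime: int
    #: (amplicon position, primer base, annealing-strand template base)
    mismatch_details: list[tuple[int, str, str]]
    classification: Amplifiability

    @property
    def mismatches_cumulative(self) -> int:
        return self.mismatches_forward_total + self.mismatches_reverse_total


def _site_mismatches(primer: str, site: str) -> int:
    return hamming(primer, site, "strict")


def locate_amplicon(
    template: BarcodeSeq,
    primers: PrimerPair = DEFAULT_PRIMERS,
    max_mismatch_per_primer: int = 6,
) -> AmpliconHit:
    """Locate the amplicon window on either strand of ``template``.

    Exhaustive sliding comparison of both primer sites at every offset on
    the template and its reverse complement; returns the window minimising
    the summed mismatch count.  ``max_mismatch_per_primer`` defaults to 6,
    the largest full-primer tally seen across the southern African carnivore
    panel.  Distinct windows tying at the minimum raise
    :class:`AmbiguousAmpliconError`.
    """
    amp_len = primers.amplicon_length
    if template.length < amp_len:
        raise AmpliconNotFoundError(
            f"template {template.id!r} ({template.length} nt) shorter than "
            f"amplicon ({amp_len} nt)"
        )
    fwd = primers.forward.residues
    rev_site_expected = reverse_complement(primers.reverse).residues
    rstart = primers.reverse_span[0] - 1  # 0-based offset inside window

    hits: list[AmpliconHit] = []
    strands = [("+", template.residues)]
    rc = reverse_complement(template).residues
    if rc != template.residues:
        strands.append(("-", rc))
    for strand, seq in strands:
        for i in range(template.length - amp_len + 1):
            mf = _site_mismatches(fwd, seq[i : i + len(fwd)])
            if mf > max_mismatch_per_primer:
                continue
            site = seq[i + rstart : i + amp_len]
            mr = _site_mismatches(rev_site_expected, site)
            if mr > max_mismatch_per_primer:
                continue
            hits.append(
                AmpliconHit(
                    start=i + 1,
                    end=i + amp_len,
                    strand=strand,
                    mismatches_forward=mf,
                    mismatches_reverse=mr,
                    amplicon=BarcodeSeq(template.id, seq[i : i + amp_len]),
                )
            )
    if not hits:
        raise AmpliconNotFoundError(
            f"no amplicon window within {max_mismatch_per_primer} mismatches "
            f"per primer on template {template.id!r}"
        )
    best = min(h.total_mismatches for h in hits)
    winners = [h for h in hits if h.total_mismatches == best]
    distinct = {(h.strand, h.start, h.amplicon.residues) for h in winners}
    if len({(s, st) for s, st, _ in distinct}) > 1 and len(
        {a for _, _, a in distinct}
    ) > 1:
        raise AmbiguousAmpliconError(winners)
    return winners[0]


def assess_binding(
    template: BarcodeSeq,
    primers: PrimerPair = DEFAULT_PRIMERS,
    species: str = "",
    max_mismatch_per_primer: int = 6,
) -> BindingAssessment:
    """Tally primer-template mismatches position by position.

    The forward primer is compared directly to sense-strand amplicon
    positions 1-21.  The reverse primer (written 5'->3') is compared to the
    reverse complement of sense positions 148-172, so its 3'-terminal base
    maps to amplicon position 148 and its 3' pentamer to positions 148-152.
    """
    hit = locate_amplicon(template, primers, max_mismatch_per_primer)
    amp = hit.amplicon.residues
    flen = primers.forward.length
    details: list[tuple[int, str, str]] = []

    fwd = primers.forward.residues
    f3 = 0
    for p in range(flen):  # 0-based over primer = amplicon positions 1..flen
        tb = amp[p]
        pb = fwd[p]
        if pb != tb:
            details.append((p + 1, pb, tb))
            if p >= flen - 5:
                f3 += 1

    rev = primers.reverse.residues
    rlen = primers.reverse.length
    rstart, rend = primers.reverse_span
    # annealing-equivalent strand for the reverse primer: revcomp of the
    # sense-strand reverse site, aligned 5'->3' with the primer
    anneal = reverse_complement(
        BarcodeSeq("_site", amp[rstart - 1 : rend])
    ).residues
    r3 = 0
    rdetails: list[tuple[int, str, str]] = []
    for j in range(rlen):  # primer 5'->3'; position j maps to rend - j
        pb = rev[j]
        tb = anneal[j]
        if pb != tb:
            pos = rend - j
            rdetails.append((pos, pb, tb))
            if j >= rlen - 5:
                r3 += 1
    details.extend(sorted(rdetails))

    assessment = BindingAssessment(
        species=species or template.id,
        mismatches_forward_total=hit.mismatches_forward,
        mismatches_reverse_total=hit.mismatches_reverse,
        mismatches_forward_3prime=f3,
        mismatches_reverse_3prime=r3,
        mismatch_details=details,
        classification=Amplifiability.ASSUMED_SUCCESSFUL,
    )
    assessment.classification = classify_amplifiability(assessment)
    return assessment


def classify_amplifiability(b: BindingAssessment) -> Amplifiability:
    """Two-level classification from the 3' pentamer tallies.

    The rule is per primer, not summed: a species is *assumed successful*
    when neither primer carries more than one pentamer mismatch, and
    *potentially problematic* when either primer carries two.  Three or more
    pentamer mismatches in one primer (outside the range observed in the
    carnivore panel) are conservatively folded into the problematic class.
    """
    worst = max(b.mismatches_forward_3prime, b.mismatches_reverse_3prime)
    if worst <= 1:
        return Amplifiability.ASSUMED_SUCCESSFUL
    return Amplifiability.POTENTIALLY_PROBLEMATIC


def extract_insert(
    template: BarcodeSeq,
    primers: PrimerPair = DEFAULT_PRIMERS,
    max_mismatch_per_primer: int = 6,
) -> BarcodeSeq:
    """Extract the 126 bp insert (primer-binding segments removed).

    Raises :class:`PartialInsertError` when the template covers only part
    of the insert (alignment gaps inside the insert span).
    """
    hit = locate_amplicon(template, primers, max_mismatch_per_primer)
    s, e = primers.insert_span
    insert = hit.amplicon.residues[s - 1 : e]
    covered = sum(1 for c in insert if c != "-")
    if covered < primers.insert_length:
        raise PartialInsertError(template.id, covered, primers.insert_length)
    return BarcodeSeq(id=template.id, residues=insert)


def binding_report(assessments: list[BindingAssessment]) -> pd.DataFrame:
    """Per-species mismatch table mirroring the published report layout.

    Columns: species, the five forward 3'-pentamer cells (amplicon
    positions 17-21), forward/cumulative/reverse full-primer totals, the
    five reverse 3'-pentamer cells (positions 148-152), classification.
    """
    fcols = list(range(17, 22))
    rcols = list(range(148, 153))
    rows = []
    for b in assessments:
        cells = {pos: f"{pb}-{tb}" for pos, pb, tb in b.mismatch_details}
        row: dict[str, object] = {"species": b.species}
        for pos in fcols:
            row[f"F{pos}"] = cells.get(pos, "")
        row["F_total"] = b.mismatches_forward_total
        row["cumulative"] = b.mismatches_cumulative
        row["R_total"] = b.mismatches_reverse_total
        for pos in rcols:
            row[f"R{pos}"] = cells.get(pos, "")
        row["classification"] = b.classification.value
        rows.append(row)
    return pd.DataFrame(rows)


def write_binding_report(
    assessments: list[BindingAssessment], path: str | Path
) -> None:
    binding_report(assessments).to_csv(path, sep="\t", index=False)
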