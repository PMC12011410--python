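"""Sequence primitives shared by every other module.

A :class:`BarcodeSeq` is a validated, uppercase DNA string over the IUPAC
alphabet (plus ``-`` for alignment gaps).  The module provides FASTA I/O,
reverse complementation with full ambiguity-code support, and the Hamming
distance that underlies both the primer-mismatch screen and the
mismatch-threshold species assignment rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "BarcodeSeq",
    "ParseError",
    "DuplicateIdWarning",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "hamming",
    "IUPAC_SETS",
]


class ParseError(ValueError):
    """Raised for malformed FASTA input or non-IUPAC residues."""


class DuplicateIdWarning(UserWarning):
    """Two FASTA records share an identifier; the parser keeps both."""


#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_VALID = set(IUPAC_SETS) | {"-"}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)


@dataclass(frozen=True)
class BarcodeSeq:
    """A named DNA sequence over the IUPAC alphabet.

    Residues are canonicalised to uppercase on construction; ``U`` is mapped
    to ``T`` with a warning.  ``-`` is accepted so that records taken from
    alignments (e.g. references with incomplete insert coverage) can be
    carried through, but curated reference inserts should be gap-free.
    """

    id: str
    residues: str = field(compare=True)

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if "U" in res:
            warnings.warn(
                f"record {self.id!r}: RNA residue 'U' mapped to 'T'", UserWarning
            )
            res = res.replace("U", "T")
        bad = set(res) - _VALID
        if bad:
            raise ParseError(
                f"record {self.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]


def read_fasta(path: str | Path) -> list[BarcodeSeq]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Order is preserved and duplicate ids are kept, with a
    :class:`DuplicateIdWarning`.  Residues failing the IUPAC alphabet raise
    :class:`ParseError` naming the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not FASTA-formatted")
    seen: set[str] = set()
    out: list[BarcodeSeq] = []
    for rec in records:
        if rec.id in seen:
            warnings.warn(
                f"{path}: duplicate record id {rec.id!r}", DuplicateIdWarning
            )
        seen.add(rec.id)
        out.append(BarcodeSeq(id=rec.id, residues=str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[BarcodeSeq], path: str | Path, wrap: int = 70) -> None:
    """Write records to FASTA; round-trips through :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def reverse_complement(s: BarcodeSeq) -> BarcodeSeq:
    """Reverse complement with IUPAC ambiguity codes (R<->Y, K<->M, ...)."""
    return BarcodeSeq(id=s.id, residues=s.residues.translate(_COMPLEMENT)[::-1])


def hamming(
    a: BarcodeSeq | str,
    b: BarcodeSeq | str,
    ambiguity_policy: Literal["strict", "compatible"] = "strict",
) -> int:
    """Count mismatching positions between two equal-length sequences.

    strict
        Positions with unequal symbols count 1 (``N`` vs ``A`` mismatches).
    compatible
        A position counts 0 whenever the two IUPAC sets intersect
        (``N`` matches anything, ``R`` matches ``A``/``G``/``R``...).

    A position where either symbol is the gap ``-`` always counts 1,
    including the gap-vs-gap corner case.
    """
    sa = a.residues if isinstance(a, BarcodeSeq) else a.upper()
    sb = b.residues if isinstance(b, BarcodeSeq) else b.upper()
    if len(sa) != len(sb):
        raise ValueError(
            f"hamming requires equal lengths, got {len(sa)} and {len(sb)}"
        )
    if ambiguity_policy == "strict":
        return sum(
            1 for x, y in zip(sa, sb) if x != y or x == "-"
        )
    if ambiguity_policy == "compatible":
        n = 0
        for x, y in zip(sa, sb):
            if x == "-" or y == "-":
                n += 1
            elif not (IUPAC_SETS[x] & IUPAC_SETS[y]):
                n += 1
        return n
    raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")
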