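"""Core sequence and interval data model, plus readers/writers for external formats.

Internal coordinates are 0-based, half-open throughout.  GFF3 output follows
the GFF3 standard (1-based, closed); BED output is 0-based, half-open.
Soft-masked (lower-case) genome bases are upper-cased and treated as normal
sequence.  ``U`` is mapped to ``T`` so RNA-style reference files are accepted.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL = frozenset("ACGTN")
# IUPAC ambiguity codes other than N are accepted on input but collapsed to N.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Upper-case, map U->T and non-N ambiguity codes to N; reject junk.

    Raises ``ValueError`` naming the offending record for characters outside
    the IUPAC nucleotide alphabet.
    """
    seq = raw.upper().replace("U", "T")
    letters = set(seq)
    bad = letters - CANONICAL - IUPAC_AMBIGUOUS
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-nucleotide characters: "
            f"{''.join(sorted(bad))}"
        )
    ambiguous = letters & IUPAC_AMBIGUOUS
    if ambiguous:
        logger.warning(
            "record %r: IUPAC ambiguity codes %s mapped to N",
            record_id,
            "".join(sorted(ambiguous)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in ambiguous}))
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - CANONICAL
        if bad:
            raise ValueError(
                f"record {self.id!r}: un-normalized characters "
                f"{''.join(sorted(bad))}; use normalize_sequence() first"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReferenceRNA:
    """The query small-RNA gene sequence (e.g. a U6 snRNA, ~100-200 nt).

    References shorter than 26 nt are rejected: they would make the
    minimum-hit-length filter vacuous.
    """

    record: SequenceRecord
    name: str = ""

    def __post_init__(self) -> None:
        if self.record.length < 26:
            raise ValueError(
                f"reference {self.record.id!r} is {self.record.length} nt; "
                "references must be at least 26 nt"
            )
        if not self.name:
            object.__setattr__(self, "name", self.record.id)

    @property
    def seq(self) -> str:
        return self.record.seq

    @property
    def length(self) -> int:
        return self.record.length


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized SequenceRecords (file order kept)."""
    records = [
        SequenceRecord(id=rec.id, seq=normalize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - CANONICAL
    if bad:
        raise ValueError(
            f"cannot reverse-complement characters {''.join(sorted(bad))}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GFF3 / BED export of classified copies
# ---------------------------------------------------------------------------

GFF3_SOURCE = "pseudoscan"
GFF3_TYPE = "processed_pseudogene"


def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :/().'-_")


def write_gff3(copies: Iterable, path: str | Path) -> None:
    """Write classified copies as GFF3 (1-based, closed coordinates).

    Each item must expose ``interval`` (GenomicInterval) and
    ``gff_attributes()`` returning an ordered mapping of attribute fields.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for copy in copies:
            iv = copy.interval
            attrs = ";".join(
                f"{k}={_gff3_escape(v)}" for k, v in copy.gff_attributes().items()
            )
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        GFF3_SOURCE,
                        GFF3_TYPE,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3_intervals(path: str | Path) -> list[tuple[GenomicInterval, dict]]:
    """Parse a GFF3 file written by :func:`write_gff3` back into intervals."""
    out: list[tuple[GenomicInterval, dict]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    key, _, val = item.partition("=")
                    attrs[key] = urllib.parse.unquote(val)
            out.append(
                (
                    GenomicInterval(
                        seq_id=cols[0],
                        start=int(cols[3]) - 1,
                        end=int(cols[4]),
                        strand=cols[6],
                    ),
                    attrs,
                )
            )
    return out


def write_bed(copies: Iterable, path: str | Path) -> None:
    """Write classified copies as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        for copy in copies:
            iv = copy.interval
            fh.write(
                "\t".join(
                    [iv.seq_id, str(iv.start), str(iv.end), copy.bed_name(), "0", iv.strand]
                )
                + "\n"
            )
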