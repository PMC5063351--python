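"""Sequence and annotation I/O.

Reads and writes FASTA, GFF3 and BED6, and loads the packaged catalogue of
the 13 AfuSINE elements annotated in the Aspergillus fumigatus Af293 genome
(5 elements derived from 5S rRNA, 8 from tRNAs of various isotypes).

Coordinate conventions: all intervals are 0-based half-open internally.
GFF3 output converts to 1-based inclusive; BED output stays 0-based
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ElementRecord",
    "Catalogue",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "write_bed",
    "load_fixture_catalogue",
]

_VALID = set("ACGTN")
_NONACGT = re.compile(r"[^ACGT]")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into valid records."""


@dataclass
class ElementRecord:
    """One candidate or annotated SINE element.

    seq is an uppercase nucleotide string over {A,C,G,T,N}; characters
    outside ACGT are coerced to N on construction. origin_label is the
    ancestral-gene call ("tRNA/<isotype>", "5S rRNA", or "unknown").
    source_interval optionally records where the record was lifted from a
    genome (set by de-novo discovery).
    """

    id: str
    seq: str
    origin_label: str = "unknown"
    chromosome_tag: Optional[str] = None
    source_interval: Optional[object] = None  # a genome_scan Locus, if any

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("element record with empty id")
        if not self.seq:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        seq = _NONACGT.sub("N", self.seq.upper())
        object.__setattr__(self, "seq", seq)

    @property
    def length_bp(self) -> int:
        return len(self.seq)


@dataclass
class Catalogue:
    """An ordered collection of ElementRecords with pairwise-distinct ids."""

    records: list[ElementRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ParseError(f"duplicate record ids: {sorted(dup)}")
        self._index = {r.id: r for r in self.records}

    def __iter__(self) -> Iterator[ElementRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: str | int) -> ElementRecord:
        if isinstance(key, int):
            return self.records[key]
        return self._index[key]

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | Path) -> Catalogue:
    """Read a FASTA file into a Catalogue.

    Lowercase is normalised to uppercase and non-ACGT characters to N.
    The description after the first whitespace is kept as chromosome_tag.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() or None
        records.append(ElementRecord(id=rec.id, seq=str(rec.seq), chromosome_tag=desc))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return Catalogue(records)


def write_fasta(catalogue: Iterable[ElementRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    seqrecs = []
    for r in catalogue:
        desc = r.chromosome_tag or ""
        seqrecs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecs)


def _check_locus(loc) -> None:
    if loc.end <= loc.start:
        raise ValueError(
            f"locus on {loc.contig} has end {loc.end} <= start {loc.start}"
        )


def write_gff3(loci: Iterable, path: str | Path, source: str = "sinescout") -> None:
    """Write mapped loci as GFF3 (1-based inclusive), type dispersed_repeat.

    Each locus needs contig/start/end/strand/identity_pct and an
    element_id attribute; identity is carried in the attribute column.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, loc in enumerate(loci, 1):
            _check_locus(loc)
            ident = getattr(loc, "identity_pct", None)
            eid = getattr(loc, "element_id", None) or f"locus{i}"
            attrs = [f"ID={eid}.{i}", f"element={eid}"]
            score = "."
            if ident is not None:
                attrs.append(f"identity={ident:.1f}")
                score = f"{ident:.1f}"
            fh.write(
                "\t".join(
                    [
                        loc.contig,
                        source,
                        "dispersed_repeat",
                        str(loc.start + 1),
                        str(loc.end),
                        score,
                        loc.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_bed(loci: Iterable, path: str | Path) -> None:
    """Write loci as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for loc in loci:
            _check_locus(loc)
            ident = getattr(loc, "identity_pct", 0.0) or 0.0
            name = getattr(loc, "element_id", None) or "locus"
            score = min(1000, int(round(ident * 10)))
            fh.write(
                f"{loc.contig}\t{loc.start}\t{loc.end}\t{name}\t{score}\t{loc.strand}\n"
            )


def load_fixture_catalogue() -> Catalogue:
    """Load the packaged catalogue of the 13 AfuSINE elements.

    Sequences are stored verbatim as annotated for Af293 (flanking TSD
    copies are part of each printed element). Headers carry the ancestral
    origin and source chromosome, which are decoded into origin_label and
    chromosome_tag.
    """
    ref = resources.files("sinescout").joinpath("data/afusine_catalogue.fasta")
    records = []
    with resources.as_file(ref) as p:
        for rec in SeqIO.parse(str(p), "fasta"):
            fieldmap = dict(
                tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
            )
            origin = fieldmap.get("origin", "unknown").replace("_", " ")
            records.append(
                ElementRecord(
                    id=rec.id,
                    seq=str(rec.seq),
                    origin_label=origin,
                    chromosome_tag=fieldmap.get("chr"),
                )
            )
    return Catalogue(records)
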