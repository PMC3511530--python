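"""Core gene/replicon data model shared by all analysis stages.

Coordinates are 1-based and inclusive at both ends (GenBank/GFF3 native).
Conversion to 0-based half-open (BED) happens only at write time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated coding feature on a replicon.

    ``start``/``end`` are 1-based inclusive with ``end >= start`` regardless
    of strand; ``strand`` records the coding direction.
    """

    replicon_id: str
    locus_tag: str
    strand: str
    start: int
    end: int
    feature_kind: str = "CDS"
    product_text: str = ""

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError("locus_tag must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.locus_tag}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Replicon:
    """A chromosome or plasmid: ordered genes plus optional sequence.

    ``topology`` is ``linear`` (streptomycete chromosomes) or ``circular``.
    Genes are kept sorted by start coordinate; ties break on locus tag so
    every downstream traversal is deterministic.
    """

    replicon_id: str
    length: int
    topology: str = "linear"
    sequence: Optional[str] = None
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        if self.length < 1:
            raise ValueError("replicon length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.replicon_id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.locus_tag))
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"{g.locus_tag}: end {g.end} beyond replicon length {self.length}"
                )

    def gene(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(f"locus tag {locus_tag!r} not on replicon {self.replicon_id}")

    def mirror(self) -> "Replicon":
        """Reverse-complement the replicon, remapping every gene.

        A gene spanning [s, e] maps to [L-e+1, L-s+1] with its strand
        flipped; classification results must be invariant under this
        transformation.
        """
        L = self.length
        genes = [
            replace(
                g,
                strand="-" if g.strand == "+" else "+",
                start=L - g.end + 1,
                end=L - g.start + 1,
            )
            for g in self.genes
        ]
        seq = reverse_complement(self.sequence) if self.sequence is not None else None
        return Replicon(self.replicon_id, L, self.topology, seq, genes)


@dataclass
class AnnotationBundle:
    """All replicons of one genome; locus tags are unique bundle-wide."""

    replicons: list[Replicon] = field(default_factory=list)
    source_path: str = ""
    source_checksum: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rep in self.replicons:
            for g in rep.genes:
                if g.locus_tag in seen:
                    raise ValueError(
                        f"duplicate locus tag {g.locus_tag!r} on "
                        f"{seen[g.locus_tag]} and {rep.replicon_id}"
                    )
                seen[g.locus_tag] = rep.replicon_id

    def all_genes(self) -> Iterator[GeneRecord]:
        for rep in self.replicons:
            yield from rep.genes

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise KeyError(f"no replicon {replicon_id!r} in bundle")

    def find(self, locus_tag: str) -> tuple[Replicon, GeneRecord]:
        for rep in self.replicons:
            for g in rep.genes:
                if g.locus_tag == locus_tag:
                    return rep, g
        raise KeyError(f"locus tag {locus_tag!r} not found in bundle")

    def mirror(self) -> "AnnotationBundle":
        return AnnotationBundle(
            [rep.mirror() for rep in self.replicons],
            self.source_path,
            self.source_checksum,
        )


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain assignment for a protein, as consumed from a
    CD-Search / HMMER style hit table (the tool never computes these itself)."""

    locus_tag: str
    domain_accession: str
    domain_name: str = ""
    score: Optional[float] = None
    evalue: Optional[float] = None
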