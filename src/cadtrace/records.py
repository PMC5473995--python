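"""Core domain types shared by every pipeline stage.

Coordinate convention: every public field that carries sequence or genomic
coordinates is 1-based inclusive (the FASTA/GFF3 convention).  Internal
interval arithmetic is done 0-based half-open and converted at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
GAP = "-"

#: labels a domain segment may carry
DOMAIN_CLASSES = ("Nt", "EC", "NC", "CE", "LG", "TM", "CP")

#: cadherin type categories used throughout
CADHERIN_TYPES = ("III", "IVa", "IVb", "non_categorized")


class ValidationError(ValueError):
    """An object violated one of its documented invariants."""


def _check_alphabet(sequence: str, alphabet: frozenset, what: str) -> None:
    bad = set(sequence) - alphabet
    if bad:
        offender = sorted(bad)[0]
        raise ValidationError(
            f"{what}: illegal character {offender!r} "
            f"(allowed: {''.join(sorted(alphabet))})"
        )


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence with taxon/group metadata.

    ``group`` is a taxon-group label such as ``"chelicerate"``, ``"insect"``,
    ``"malacostracan"`` or ``"non-arthropod"``; it drives the conservation
    classifiers downstream.
    """

    id: str
    sequence: str
    taxon: str = ""
    group: str = ""
    accession: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.id:
            raise ValidationError("ProteinRecord requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"ProteinRecord {self.id}: empty sequence")
        _check_alphabet(self.sequence, PROTEIN_ALPHABET, f"ProteinRecord {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class NucleotideRecord:
    """A genomic or transcript nucleotide sequence."""

    id: str
    sequence: str
    kind: str = "genomic"  # {"genomic", "transcript"}
    accession: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.kind not in ("genomic", "transcript"):
            raise ValidationError(
                f"NucleotideRecord {self.id}: kind must be 'genomic' or "
                f"'transcript', got {self.kind!r}"
            )
        if not self.sequence:
            raise ValidationError(f"NucleotideRecord {self.id}: empty sequence")
        _check_alphabet(self.sequence, NUCLEOTIDE_ALPHABET, f"NucleotideRecord {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """Exon coordinates of one gene on a genomic sequence.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted along the
    genome.  ``cds_start_offset`` is the 0-based offset of the first coding
    base within the *spliced transcript* (i.e. the 5' UTR length);
    ``cds_length`` is the coding length including the stop codon, or ``None``
    when the CDS runs to the transcript end.  ``partial`` flags models with
    incomplete 5'/3' ends, which downstream stages refuse unless asked.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_offset: int = 0
    cds_length: int | None = None
    partial: bool = False

    MIN_INTRON = 30

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"GeneModel {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"GeneModel {self.gene_id}: no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        prev_end = None
        for s, e in self.exons:
            if s > e or s < 1:
                raise ValidationError(
                    f"GeneModel {self.gene_id}: bad exon ({s},{e})"
                )
            if prev_end is not None:
                if s <= prev_end:
                    raise ValidationError(
                        f"GeneModel {self.gene_id}: exons out of order or "
                        f"overlapping at ({s},{e})"
                    )
                if s - prev_end - 1 < self.MIN_INTRON:
                    raise ValidationError(
                        f"GeneModel {self.gene_id}: intron shorter than "
                        f"{self.MIN_INTRON} nt before exon ({s},{e})"
                    )
            prev_end = e
        if self.cds_start_offset < 0:
            raise ValidationError(f"GeneModel {self.gene_id}: negative CDS offset")

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of each intron, 1-based inclusive."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def spliced_sequence(self, genomic: str | NucleotideRecord) -> str:
        """Concatenate the exons in transcript orientation."""
        seq = genomic.sequence if isinstance(genomic, NucleotideRecord) else genomic
        parts = [seq[s - 1 : e] for s, e in self.exons]
        spliced = "".join(parts)
        if self.strand == "-":
            spliced = reverse_complement(spliced)
        return spliced

    def coding_sequence(self, genomic: str | NucleotideRecord) -> str:
        spliced = self.spliced_sequence(genomic)
        end = (
            self.cds_start_offset + self.cds_length
            if self.cds_length is not None
            else len(spliced)
        )
        cds = spliced[self.cds_start_offset : end]
        if not self.partial and len(cds) % 3 != 0:
            raise ValidationError(
                f"GeneModel {self.gene_id}: CDS length {len(cds)} not a "
                f"multiple of 3 (flag the model partial if it is incomplete)"
            )
        return cds

    def to_transcript_orientation(
        self, genomic: NucleotideRecord
    ) -> tuple["GeneModel", NucleotideRecord]:
        """Return an equivalent plus-strand model on the (possibly
        reverse-complemented) genomic sequence.

        Minus-strand models are normalized here once so that all downstream
        logic can assume transcript orientation.
        """
        if self.strand == "+":
            return self, genomic
        n = len(genomic.sequence)
        flipped = NucleotideRecord(
            id=genomic.id + "_rc",
            sequence=reverse_complement(genomic.sequence),
            kind=genomic.kind,
            accession=genomic.accession,
        )
        new_exons = sorted((n - e + 1, n - s + 1) for s, e in self.exons)
        model = GeneModel(
            gene_id=self.gene_id,
            seq_id=flipped.id,
            strand="+",
            exons=new_exons,
            cds_start_offset=self.cds_start_offset,
            cds_length=self.cds_length,
            partial=self.partial,
        )
        return model, flipped


class ColumnMap:
    """Bijection between the non-gap columns of one alignment row and the
    residue indices of its ungapped sequence (both sides 1-based)."""

    def __init__(self, gapped_row: str) -> None:
        self._col_of_res: list[int] = []  # residue i (1-based) -> column
        self._res_of_col: dict[int, int] = {}
        for col0, ch in enumerate(gapped_row):
            if ch != GAP:
                self._col_of_res.append(col0 + 1)
                self._res_of_col[col0 + 1] = len(self._col_of_res)

    def column_of(self, residue: int) -> int:
        if not 1 <= residue <= len(self._col_of_res):
            raise KeyError(f"residue index {residue} out of range")
        return self._col_of_res[residue - 1]

    def residue_of(self, column: int) -> int | None:
        """Residue at an alignment column, or ``None`` for a gap column."""
        return self._res_of_col.get(column)

    @property
    def n_residues(self) -> int:
        return len(self._col_of_res)


@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped rows (gap char '-')."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment has no rows")
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) != 1:
            detail = ", ".join(f"{rid}:{len(g)}" for rid, g in self.rows)
            raise ValidationError(f"ragged alignment rows ({detail})")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate record ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, record_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == record_id:
                return gapped
        raise KeyError(f"record {record_id!r} not in alignment")

    def ungapped(self, record_id: str) -> str:
        return self.row(record_id).replace(GAP, "")

    def column_map(self, record_id: str) -> ColumnMap:
        return ColumnMap(self.row(record_id))

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.rows)


@dataclass
class DomainSegment:
    """One typed segment of a protein (1-based inclusive coordinates)."""

    label: str  # e.g. "EC3", "NC", "CE1"
    klass: str  # one of DOMAIN_CLASSES
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.klass not in DOMAIN_CLASSES:
            raise ValidationError(f"unknown domain class {self.klass!r}")
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"segment {self.label}: bad coordinates ({self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainAnnotation:
    """Ordered, typed, numbered domain segmentation of one protein."""

    record_id: str
    segments: list[DomainSegment]
    ec_numbers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValidationError(
                    f"{self.record_id}: segments overlap or out of order at "
                    f"{seg.label} ({seg.start},{seg.end})"
                )
            prev_end = seg.end
        if not self.ec_numbers:
            self.ec_numbers = {
                seg.label: int(seg.label[2:])
                for seg in self.segments
                if seg.klass == "EC"
            }
        indices = [self.ec_numbers[s.label] for s in self.segments if s.klass == "EC"]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError(
                f"{self.record_id}: EC indices not strictly increasing"
            )

    def of_class(self, klass: str) -> list[DomainSegment]:
        return [s for s in self.segments if s.klass == klass]

    @property
    def ec_count(self) -> int:
        return len(self.of_class("EC"))

    def has_label(self, label: str) -> bool:
        return any(s.label == label for s in self.segments)

    def domain_string(self) -> str:
        """Compact architecture string, e.g. ``EC×9-NC-CE1-LG1-TM-CP``."""
        parts: list[str] = []
        i = 0
        while i < len(self.segments):
            seg = self.segments[i]
            if seg.klass == "EC":
                j = i
                while j < len(self.segments) and self.segments[j].klass == "EC":
                    j += 1
                parts.append(f"EC×{j - i}")
                i = j
            else:
                parts.append(seg.label)
                i += 1
        return "-".join(parts)
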