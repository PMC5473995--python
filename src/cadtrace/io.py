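"""Readers and writers for the standard formats the pipeline touches.

FASTA (protein and nucleotide), aligned FASTA / Clustal, a GFF3 dialect for
gene models, and TSV taxon-group tables.  All external coordinates are
1-based inclusive.  Parsing of FASTA and alignments is delegated to
Biopython; GFF3 parsing to gffutils.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    GAP,
    NUCLEOTIDE_ALPHABET,
    PROTEIN_ALPHABET,
    DomainAnnotation,
    GeneModel,
    MultipleAlignment,
    NucleotideRecord,
    ProteinRecord,
    ValidationError,
)


class ParseError(ValueError):
    """A file could not be parsed under its expected grammar."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "protein", kind: str = "genomic"):
    """Read a FASTA file into ``ProteinRecord`` or ``NucleotideRecord`` lists.

    ``alphabet`` is ``"protein"`` or ``"nucleotide"``; for nucleotides,
    ``kind`` tags every record as genomic or transcript.  Record order is
    preserved; sequences are uppercased; alphabet violations raise
    ``ValidationError`` naming the record and offending character.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        # name the first offending line for the caller
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno} is not a FASTA header: "
                        f"{line!r}"
                    ) from exc
                break
        raise ParseError(f"{path}: {exc}") from exc
    out = []
    seen: set[str] = set()
    for sr in seq_records:
        if sr.id in seen:
            raise ValidationError(f"{path}: duplicate record id {sr.id!r}")
        seen.add(sr.id)
        seq = str(sr.seq).upper()
        if alphabet == "protein":
            out.append(ProteinRecord(id=sr.id, sequence=seq))
        elif alphabet == "nucleotide":
            out.append(NucleotideRecord(id=sr.id, sequence=seq, kind=kind))
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
    return out


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Multiple alignments

def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned-FASTA or Clustal file; gaps normalized to '-'.

    Ragged rows raise ``ValidationError`` listing the row lengths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    fmt = "clustal" if text.lstrip()[:7].upper().startswith("CLUSTAL") else "fasta"
    if fmt == "fasta":
        # tolerate ragged input so we can report lengths ourselves
        rows = [
            (sr.id, str(sr.seq).upper().replace(".", GAP))
            for sr in SeqIO.parse(str(path), "fasta")
        ]
    else:
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        rows = [(sr.id, str(sr.seq).upper().replace(".", GAP)) for sr in aln]
    if not rows:
        raise ParseError(f"{path}: no alignment rows found")
    return MultipleAlignment(rows=rows)


def write_alignment(alignment: MultipleAlignment, path: str | Path,
                    fmt: str = "fasta") -> None:
    seq_records = [
        SeqRecord(Seq(gapped), id=rid, description="")
        for rid, gapped in alignment.rows
    ]
    if fmt == "fasta":
        with open(path, "w") as fh:
            for sr in seq_records:
                fh.write(f">{sr.id}\n")
                s = str(sr.seq)
                for i in range(0, len(s), 60):
                    fh.write(s[i : i + 60] + "\n")
    elif fmt == "clustal":
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(seq_records), str(path), "clustal")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def column_map(alignment: MultipleAlignment, record_id: str):
    """Bidirectional residue↔column map for one alignment row."""
    return alignment.column_map(record_id)


# ---------------------------------------------------------------------------
# Gene models (GFF3 dialect: gene + exon features)

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (``gene`` parents with ``exon`` children).

    ``cds_start_offset`` / ``cds_length`` / ``partial`` round-trip through
    gene-level attributes of the same names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        attrs = gene.attributes
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_start_offset=int(attrs.get("cds_start_offset", ["0"])[0]),
                cds_length=(
                    int(attrs["cds_length"][0]) if "cds_length" in attrs else None
                ),
                partial=attrs.get("partial", ["false"])[0].lower() == "true",
            )
        )
    return models


def write_gene_models(models: list[GeneModel], path: str | Path,
                      source: str = "cadtrace") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (m.exons[0][0], m.exons[-1][1])
            attrs = [f"ID={m.gene_id}", f"cds_start_offset={m.cds_start_offset}"]
            if m.cds_length is not None:
                attrs.append(f"cds_length={m.cds_length}")
            if m.partial:
                attrs.append("partial=true")
            fh.write(
                f"{m.seq_id}\t{source}\tgene\t{span[0]}\t{span[1]}\t.\t"
                f"{m.strand}\t.\t{';'.join(attrs)}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.seq_id}\t{source}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Taxon-group tables

def read_groups(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV with columns record_id, taxon, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"record_id", "taxon", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return {
        row.record_id: {"taxon": row.taxon, "group": row.group}
        for row in df.itertuples()
    }


def write_groups(groups: dict[str, dict[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"record_id": rid, "taxon": meta.get("taxon", ""),
             "group": meta["group"]}
            for rid, meta in groups.items()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Domain annotations (GFF3 on protein coordinates + TSV summary)

def write_annotations_gff(annotations: list[DomainAnnotation],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            for seg in ann.segments:
                fh.write(
                    f"{ann.record_id}\tcadtrace\tprotein_domain\t{seg.start}\t"
                    f"{seg.end}\t.\t+\t.\tID={ann.record_id}.{seg.label};"
                    f"Name={seg.label};domain_class={seg.klass}\n"
                )


def read_annotations_gff(path: str | Path) -> list[DomainAnnotation]:
    per_record: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: bad GFF line: {line!r}")
            seqid, _src, ftype, start, end, _score, _strand, _phase, attrs = fields
            if ftype != "protein_domain":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            from .records import DomainSegment

            per_record.setdefault(seqid, []).append(
                DomainSegment(
                    label=attr["Name"],
                    klass=attr["domain_class"],
                    start=int(start),
                    end=int(end),
                )
            )
    return [
        DomainAnnotation(record_id=rid, segments=sorted(segs, key=lambda s: s.start))
        for rid, segs in per_record.items()
    ]
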