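"""Readers, writers and shared record types for the pipeline's file formats.

Everything here is plumbing: FASTA/FASTQ sequences, gene models (GFF3
subset or TSV), the locus registry that threads through every stage, and
probe FASTA/BED emission. All coordinates are 0-based half-open,
BED-compatible. No science lives in this module.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("skimprobe")

# IUPAC nucleotide codes. '-' is legal only inside alignments; 'U' is
# normalized to 'T' on input so RNA-alphabet transcriptomes round-trip.
IUPAC_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
UNAMBIGUOUS = set("ACGT")
VALID_CHARS = UNAMBIGUOUS | set(IUPAC_AMBIGUITY) | {"-"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file (message names the offending line/record)."""


class ConsistencyError(ValueError):
    """Cross-record invariant violated (dangling id, bad coordinates...)."""


@dataclass
class SequenceRecord:
    """One nucleotide sequence. ``seq`` is uppercase; '-' only in alignments."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _normalize_seq(raw: str, *, record_id: str, aligned: bool = False) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_CHARS
    if bad:
        raise FormatError(
            f"record {record_id!r}: invalid characters {sorted(bad)}"
        )
    if not aligned and "-" in seq:
        raise FormatError(f"record {record_id!r}: gap character in unaligned sequence")
    return seq


def read_fasta(path: str | Path, *, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into ordered :class:`SequenceRecord` objects.

    Duplicate ids, empty files and malformed headers raise
    :class:`FormatError` naming the offending line. CRLF endings and RNA
    ('U') alphabets are tolerated.
    """
    path = Path(path)
    with open(path, newline=None) as fh:
        text = fh.read()
    lines = text.splitlines()
    first_content = next((i for i, ln in enumerate(lines) if ln.strip()), None)
    if first_content is None:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    if not lines[first_content].startswith(">"):
        raise FormatError(
            f"{path}: line {first_content + 1}: expected FASTA header starting with '>'"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(rec.id, _normalize_seq(str(rec.seq), record_id=rec.id,
                                                  aligned=aligned), desc)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found (line 1)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(f"read {self.id!r}: sequence/quality length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


@dataclass
class GeneModel:
    """Exon/intron structure of one transcript.

    ``exon_lengths`` are the spliced pieces in transcript order;
    ``intron_lengths`` sit between consecutive exons, so a model with
    n exons carries exactly n-1 introns (single-exon models carry none).
    """

    transcript_id: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise FormatError(f"gene model {self.transcript_id!r}: no exons")
        if any(e <= 0 for e in self.exon_lengths):
            raise FormatError(f"gene model {self.transcript_id!r}: non-positive exon length")
        if any(i < 0 for i in self.intron_lengths):
            raise FormatError(f"gene model {self.transcript_id!r}: negative intron length")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise FormatError(
                f"gene model {self.transcript_id!r}: {len(self.exon_lengths)} exons "
                f"need {len(self.exon_lengths) - 1} introns, "
                f"got {len(self.intron_lengths)}"
            )

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)


def _parse_gff3_gene_models(lines: list[str], path: Path) -> dict[str, GeneModel]:
    # GFF3 subset: exon features grouped by Parent, 1-based inclusive coords.
    exons: dict[str, list[tuple[int, int]]] = {}
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
        if cols[2].lower() != "exon":
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        parent = attrs.get("Parent") or attrs.get("ID")
        if not parent:
            raise FormatError(f"{path}: line {lineno}: exon without Parent attribute")
        exons.setdefault(parent, []).append((start, end))
    models = {}
    for tid, ivs in exons.items():
        ivs.sort()
        exon_lengths = [e - s + 1 for s, e in ivs]
        intron_lengths = [ivs[i + 1][0] - ivs[i][1] - 1 for i in range(len(ivs) - 1)]
        if any(i < 0 for i in intron_lengths):
            raise FormatError(f"{path}: overlapping exons for transcript {tid!r}")
        models[tid] = GeneModel(tid, exon_lengths, intron_lengths)
    return models


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from a GFF3 subset or a 3/4-column TSV.

    TSV columns: transcript_id, comma-separated exon lengths,
    comma-separated intron lengths (empty for single-exon transcripts),
    optional taxon.
    """
    path = Path(path)
    with open(path, newline=None) as fh:
        lines = fh.read().splitlines()
    stripped = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not stripped:
        raise FormatError(f"{path}: empty gene-model file (line 1)")
    if len(stripped[0].split("\t")) == 9:
        return _parse_gff3_gene_models(lines, path)
    models: dict[str, GeneModel] = {}
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.rstrip("\n").split("\t")
        if len(cols) not in (3, 4):
            raise FormatError(f"{path}: line {lineno}: expected 3 or 4 TSV columns")
        tid = cols[0]
        if tid in models:
            raise FormatError(f"{path}: line {lineno}: duplicate transcript id {tid!r}")
        try:
            exon_lengths = [int(x) for x in cols[1].split(",") if x.strip()]
            intron_lengths = [int(x) for x in cols[2].split(",") if x.strip()]
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-integer length") from None
        taxon = cols[3] if len(cols) == 4 else ""
        try:
            models[tid] = GeneModel(tid, exon_lengths, intron_lengths, taxon)
        except FormatError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models.values():
            fh.write(
                f"{m.transcript_id}\t{','.join(map(str, m.exon_lengths))}\t"
                f"{','.join(map(str, m.intron_lengths))}\t{m.taxon}\n"
            )


SOURCE_METHODS = ("markerminer", "universal", "published", "functional")
GENOME_ORIGINS = ("genomeA", "genomeB", "both", "none")


@dataclass
class LocusRecord:
    """One locus in the design set with its representative sequence."""

    locus_id: str
    source_method: str
    genome_origin: str
    representative: SequenceRecord
    template_ids: list[str] = field(default_factory=list)
    representative_source: str = ""

    def __post_init__(self) -> None:
        if self.source_method not in SOURCE_METHODS:
            raise ConsistencyError(f"unknown source_method {self.source_method!r}")
        if self.genome_origin not in GENOME_ORIGINS:
            raise ConsistencyError(f"unknown genome_origin {self.genome_origin!r}")


REGISTRY_COLUMNS = [
    "locus_id", "source_method", "genome_origin",
    "representative_id", "representative_source", "template_ids",
]


class LocusRegistry:
    """Ordered, unique-keyed collection of :class:`LocusRecord`.

    Persisted as a fixed-column TSV plus a representative FASTA so every
    pipeline stage is independently resumable.
    """

    def __init__(self, records: Iterable[LocusRecord] = ()) -> None:
        self._records: dict[str, LocusRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: LocusRecord) -> None:
        if rec.locus_id in self._records:
            raise ConsistencyError(f"duplicate locus id {rec.locus_id!r} in registry")
        self._records[rec.locus_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._records

    def __getitem__(self, locus_id: str) -> LocusRecord:
        return self._records[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return list(self._records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": r.locus_id,
                "source_method": r.source_method,
                "genome_origin": r.genome_origin,
                "representative_id": r.representative.id,
                "representative_source": r.representative_source,
                "template_ids": ",".join(r.template_ids),
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)

    def write(self, tsv_path: str | Path, fasta_path: str | Path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        write_fasta(
            [SequenceRecord(r.locus_id, r.representative.seq,
                            f"rep={r.representative.id}") for r in self],
            fasta_path,
        )

    @classmethod
    def read(cls, tsv_path: str | Path, fasta_path: str | Path) -> "LocusRegistry":
        df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
        missing = set(REGISTRY_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{tsv_path}: missing registry columns {sorted(missing)}")
        seqs = {r.id: r.seq for r in read_fasta(fasta_path)}
        reg = cls()
        for _, row in df.iterrows():
            if row.locus_id not in seqs:
                raise ConsistencyError(
                    f"{tsv_path}: locus {row.locus_id!r} has no sequence in {fasta_path}"
                )
            reg.add(
                LocusRecord(
                    locus_id=row.locus_id,
                    source_method=row.source_method,
                    genome_origin=row.genome_origin,
                    representative=SequenceRecord(
                        row.representative_id or row.locus_id, seqs[row.locus_id]
                    ),
                    template_ids=[t for t in row.template_ids.split(",") if t],
                    representative_source=row.representative_source,
                )
            )
        return reg


def write_probes(
    probes: Sequence,
    fasta_path: str | Path,
    bed_path: str | Path,
    template_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write probes as FASTA (ids ``<template_id>|<start>-<end>``) and BED.

    BED coordinates are 0-based half-open on template coordinates. An
    empty probe set yields empty files. If ``template_lengths`` is given,
    probes extending past their template raise :class:`ConsistencyError`.
    """
    fasta_records = []
    bed_lines = []
    for p in probes:
        if p.end - p.start != len(p.seq):
            raise ConsistencyError(
                f"probe {p.probe_id}: interval [{p.start},{p.end}) "
                f"does not match sequence length {len(p.seq)}"
            )
        if template_lengths is not None:
            tlen = template_lengths.get(p.template_id)
            if tlen is None:
                raise ConsistencyError(f"probe {p.probe_id}: unknown template {p.template_id!r}")
            if p.start < 0 or p.end > tlen:
                raise ConsistencyError(
                    f"probe {p.probe_id}: interval [{p.start},{p.end}) outside "
                    f"template {p.template_id!r} of length {tlen}"
                )
        fasta_records.append(
            SequenceRecord(f"{p.template_id}|{p.start}-{p.end}", p.seq,
                           ",".join(sorted(p.flags)) if p.flags else "")
        )
        bed_lines.append(f"{p.template_id}\t{p.start}\t{p.end}\t{p.probe_id}")
    if fasta_records:
        write_fasta(fasta_records, fasta_path)
    else:
        Path(fasta_path).write_text("")
    Path(bed_path).write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))


def read_probe_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["template_id", "start", "end", "probe_id"],
    )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: invalid BED interval")
    return df
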