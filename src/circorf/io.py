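"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* Coordinates are 0-based half-open everywhere inside the package. GTF input
  is converted from the format's 1-based closed convention on read; emitted
  result tables carry 1-based closed coordinates and say so in their headers.
* Minus-strand sequence is reverse-complemented at extraction time, so
  downstream modules always see transcript-oriented (5'->3') sequence.
* Nucleotide records may contain N in the genome; a called circRNA whose
  spliced sequence contains N is dropped upstream with a logged reason, so
  translation never sees an undefined base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDES = set("ACGTN")


class FormatError(ValueError):
    """A file violated the format contract (duplicate ids, ragged rows, ...)."""


def get_logger(stage: str) -> logging.Logger:
    """Stage-tagged logger; stages mirror the pipeline steps."""
    return logging.getLogger(f"circorf.{stage}")


_log = get_logger("io")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptModel:
    """An exon/CDS model of one transcript.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic
    position regardless of strand. ``cds_start`` is the genomic coordinate of
    the first base of the annotated start codon (strand-aware: on the minus
    strand it is the numerically largest CDS base). ``cds_end`` is the genomic
    coordinate of the last CDS base in translation order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_transcript_seq(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Mature (exon-joined) transcript sequence in 5'->3' orientation."""
    chrom = genome[model.chrom]
    joined = "".join(chrom[s:e] for s, e in model.exons)
    return revcomp(joined) if model.strand == "-" else joined


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and line wrapping is collapsed. Duplicate ids
    and empty sequences raise :class:`FormatError` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap_width: int = 60
) -> None:
    """Write records as FASTA; round-trips through :func:`read_fasta`."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap_width):
                fh.write(rec.seq[i : i + wrap_width] + "\n")


def as_bio_records(records: Iterable[SequenceRecord]) -> list[_BioSeqRecord]:
    return [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF2.2 file into transcript models.

    Exons are grouped per transcript and sorted by genomic position.
    ``cds_start`` is taken from a ``start_codon`` feature when one exists,
    otherwise from the 5'-most (strand-aware) CDS base. Transcripts with zero
    exons are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"malformed GTF {path}: {exc}") from exc

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    start_codons: dict[str, tuple[int, int]] = {}

    def _tid(feat) -> str:
        try:
            return feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"feature at {feat.seqid}:{feat.start} lacks transcript_id"
            ) from exc

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in {"exon", "cds", "start_codon"}:
            continue
        tid = _tid(feat)
        gene = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> 0-based half-open
        if ftype == "exon":
            exons.setdefault(tid, []).append(iv)
        elif ftype == "cds":
            cds.setdefault(tid, []).append(iv)
        else:
            start_codons[tid] = iv

    models: list[TranscriptModel] = []
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in exons:
            _log.warning("transcript %s has zero exons; skipped", tid)
            continue
        tx_exons = tuple(sorted(exons[tid]))
        cds_start = cds_end = None
        if tid in start_codons:
            s, e = start_codons[tid]
            cds_start = s if strand == "+" else e - 1
        if tid in cds:
            ivs = sorted(cds[tid])
            if cds_start is None:
                cds_start = ivs[0][0] if strand == "+" else ivs[-1][1] - 1
            cds_end = ivs[-1][1] - 1 if strand == "+" else ivs[0][0]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tx_exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Emit transcript models as GTF2.2 (exon + CDS + start_codon features)."""
    with open(Path(path), "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tcircorf\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_start is not None and m.cds_end is not None:
                lo, hi = sorted((m.cds_start, m.cds_end))
                # clip the genomic CDS span to the exons it crosses
                for s, e in m.exons:
                    cs, ce = max(s, lo), min(e, hi + 1)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\tcircorf\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t{attrs}\n"
                        )
                if m.strand == "+":
                    sc = (m.cds_start, m.cds_start + 3)
                else:
                    sc = (m.cds_start - 2, m.cds_start + 1)
                fh.write(
                    f"{m.chrom}\tcircorf\tstart_codon\t{sc[0] + 1}\t{sc[1]}\t.\t{m.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Tables


def write_table(
    rows: Sequence[dict],
    path: str | Path,
    comment: str | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a list of homogeneous dict rows as a TSV file.

    Column order follows the first row (or ``columns``, which also lets an
    empty row list produce a header-only file). Ragged rows raise
    :class:`FormatError`. Genomic coordinates in emitted tables are 1-based
    closed; ``comment`` (written as a ``#`` line) should say so.
    """
    path = Path(path)
    rows = list(rows)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        if not rows:
            if columns:
                fh.write("\t".join(columns) + "\n")
            return
        cols = list(columns) if columns else list(rows[0].keys())
        for i, row in enumerate(rows):
            if list(row.keys()) != cols:
                raise FormatError(f"row {i} columns differ from header {cols}")
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
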