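"""Anchor-based back-splice junction detection and circRNA calling.

Reads that fail linear alignment are probed for circularity: 20-mer anchors
from both read ends are looked up in an exact k-mer genome index, and a pair
of same-chromosome, same-strand hits in inverted (head-to-tail) order is
extended toward a unique breakpoint at which the whole read reconstructs
from two genomic segments with zero mismatches. The genomic dinucleotides
flanking the junction are checked against the canonical splice signal
(donor GT / acceptor AG, strand-aware). Candidates are collapsed per
junction and kept when supported by at least two unique back-spliced reads
(distinct read sequences); calls are then classified by genomic origin
(exon incl. UTR/CDS sub-labels, intron, exon-intron, antisense, intergenic)
and summarized into per-sample expression and GM/DM fold-change tables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SequenceRecord, TranscriptModel, get_logger, revcomp

_log = get_logger("detect")

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MIN_SUPPORT = 2
SPLICE_POLICIES = ("enforce", "report", "ignore")


@dataclass(frozen=True)
class AnchorPair:
    read_id: str
    left_anchor: str
    right_anchor: str
    k: int


@dataclass(frozen=True)
class BackspliceCandidate:
    """A single read placed head-to-tail on the genome.

    ``acceptor_pos`` is the 0-based genomic coordinate of the first base of
    the circle (5' end in genomic orientation) and ``donor_pos`` the 0-based
    coordinate of its last base; ``acceptor_pos < donor_pos`` always
    (head-to-tail geometry).
    """

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    read_id: str
    read_seq: str
    breakpoint_offset: int
    splice_signal_ok: bool


@dataclass
class CircRNACall:
    circ_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open genomic span
    end: int
    supporting_read_ids: tuple[str, ...]
    n_unique_reads: int
    splice_signal_ok: bool = True
    spliced_seq: str | None = None
    exon_blocks: tuple[tuple[int, int], ...] | None = None
    origin_category: str | None = None
    host_gene_id: str | None = None


class GenomeIndex:
    """Exact k-mer position index over a genome (both strands on query)."""

    def __init__(self, genome: Mapping[str, str], k: int):
        if k < 1:
            raise ValueError("k must be positive")
        for chrom, seq in genome.items():
            if k > len(seq):
                raise ValueError(f"k={k} exceeds length of sequence {chrom!r}")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((chrom, i))

    def query(self, kmer: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``kmer``, including the reverse strand."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        hits = [(c, p, "+") for c, p in self._index.get(kmer, ())]
        rc = revcomp(kmer)
        hits += [(c, p, "-") for c, p in self._index.get(rc, ())]
        return hits

    def forward_hits(self, kmer: str) -> list[tuple[str, int]]:
        return list(self._index.get(kmer, ()))


def extract_anchors(read: SequenceRecord, k: int = DEFAULT_ANCHOR_LEN) -> AnchorPair | None:
    """Prefix/suffix k-mers of a read; short reads are skipped with a log line."""
    if len(read.seq) < 2 * k:
        _log.info("read %s shorter than 2x anchor length %d; skipped", read.id, k)
        return None
    return AnchorPair(read.id, read.seq[:k], read.seq[-k:], k)


def _reconstructions(read_seq: str, index: GenomeIndex, genome: Mapping[str, str], k: int):
    """All (chrom, hit_pair, breakpoint, acceptor, donor_end) placements of a
    plus-oriented read as two head-to-tail genomic segments."""
    n = len(read_seq)
    left_hits = index.forward_hits(read_seq[:k])
    right_hits = index.forward_hits(read_seq[-k:])
    out = []
    for c1, p1 in left_hits:
        seq = genome[c1]
        for c2, p2 in right_hits:
            if c2 != c1 or p2 >= p1:
                continue
            for b in range(k, n - k + 1):
                acc = p2 + k - (n - b)
                if acc < 0:
                    continue
                donor_end = p1 + b
                if acc >= donor_end or donor_end > len(seq):
                    continue
                if seq[p1:donor_end] == read_seq[:b] and seq[acc : acc + n - b] == read_seq[b:]:
                    out.append((c1, (p1, p2), b, acc, donor_end))
    return out


def _splice_ok(genome: Mapping[str, str], chrom: str, strand: str, acc: int, donor_end: int) -> bool:
    """Canonical GT/AG check in gene orientation, strand-aware.

    Plus strand: GT immediately after the donor, AG immediately before the
    acceptor. Minus strand: the gene-oriented donor/acceptor flanks are the
    reverse complements on the other genomic side (AC before the span start,
    CT after the span end).
    """
    seq = genome[chrom]
    if strand == "+":
        return (
            acc >= 2
            and donor_end + 2 <= len(seq)
            and seq[donor_end : donor_end + 2] == "GT"
            and seq[acc - 2 : acc] == "AG"
        )
    return (
        acc >= 2
        and donor_end + 2 <= len(seq)
        and seq[acc - 2 : acc] == "AC"
        and seq[donor_end : donor_end + 2] == "CT"
    )


def call_backsplice(
    read: SequenceRecord,
    index: GenomeIndex,
    genome: Mapping[str, str],
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    splice_check: str = "enforce",
) -> BackspliceCandidate | None:
    """Head-to-tail placement of one read, or None.

    A candidate is emitted iff the read reconstructs exactly (zero
    mismatches) from two genomic segments in inverted order at a unique
    junction. Junction-shift variants (repeat bases at both flanks of the
    same anchor-hit pair) are canonicalized by preferring splice-consistent
    breakpoints, then the 5'-most breakpoint in read coordinates; genuinely
    ambiguous reads (several distinct anchor-hit placements, or placements on
    both strands) yield no call.
    """
    if splice_check not in SPLICE_POLICIES:
        raise ValueError(f"splice_check must be one of {SPLICE_POLICIES}")
    anchors = extract_anchors(read, anchor_len)
    if anchors is None:
        return None

    placements: list[tuple[str, str, tuple, int, int, int]] = []
    for strand, oriented in (("+", read.seq), ("-", revcomp(read.seq))):
        for chrom, pair, b, acc, donor_end in _reconstructions(
            oriented, index, genome, anchor_len
        ):
            placements.append((chrom, strand, pair, b, acc, donor_end))

    if not placements:
        return None
    pairs = {(chrom, strand, pair) for chrom, strand, pair, *_ in placements}
    if len(pairs) > 1:
        _log.info("read %s is ambiguous (%d placements); no call", read.id, len(pairs))
        return None
    if len(placements) > 1:
        _log.info(
            "read %s: %d junction-shift breakpoints; canonicalizing", read.id, len(placements)
        )
    chrom, strand = placements[0][0], placements[0][1]
    scored = sorted(
        placements,
        key=lambda p: (not _splice_ok(genome, p[0], p[1], p[4], p[5]), p[3]),
    )
    _, _, _, b, acc, donor_end = scored[0]
    ok = _splice_ok(genome, chrom, strand, acc, donor_end)
    if splice_check == "enforce" and not ok:
        _log.info("read %s: non-canonical splice flanks; dropped (enforce)", read.id)
        return None
    return BackspliceCandidate(
        chrom=chrom,
        strand=strand,
        acceptor_pos=acc,
        donor_pos=donor_end - 1,
        read_id=read.id,
        read_seq=read.seq,
        breakpoint_offset=b,
        splice_signal_ok=ok,
    )


def collapse_candidates(
    candidates: Iterable[BackspliceCandidate],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[CircRNACall]:
    """Group candidates per junction and apply the unique-read support filter.

    "Unique back-spliced reads" counts distinct read sequences, so PCR
    duplicates of one fragment contribute a single unit of support. Collapsing
    is idempotent and independent of input order.
    """
    groups: dict[tuple, list[BackspliceCandidate]] = defaultdict(list)
    for cand in candidates:
        groups[(cand.chrom, cand.strand, cand.acceptor_pos, cand.donor_pos)].append(cand)
    calls: list[CircRNACall] = []
    for (chrom, strand, acc, donor), cands in sorted(groups.items()):
        unique_seqs = {c.read_seq for c in cands}
        if len(unique_seqs) < min_support:
            _log.info(
                "junction %s:%d-%d(%s) has %d unique reads < %d; discarded",
                chrom, acc, donor, strand, len(unique_seqs), min_support,
            )
            continue
        calls.append(
            CircRNACall(
                circ_id="",  # assigned after sorting all calls
                chrom=chrom,
                strand=strand,
                start=acc,
                end=donor + 1,
                supporting_read_ids=tuple(sorted({c.read_id for c in cands})),
                n_unique_reads=len(unique_seqs),
                splice_signal_ok=all(c.splice_signal_ok for c in cands),
            )
        )
    for i, call in enumerate(calls):
        call.circ_id = f"circ_{i + 1:06d}"
    return calls


def _matching_exon_run(
    call: CircRNACall, model: TranscriptModel
) -> tuple[int, int] | None:
    """Indices (i, j) of an exon run whose genomic span equals the call."""
    for i, (s, _) in enumerate(model.exons):
        if s != call.start:
            continue
        for j in range(i, len(model.exons)):
            if model.exons[j][1] == call.end:
                return i, j
            if model.exons[j][1] > call.end:
                break
    return None


def spliced_sequence(
    call: CircRNACall, genome: Mapping[str, str], models: Sequence[TranscriptModel]
) -> CircRNACall:
    """Attach the spliced sequence and exon blocks to a call.

    When the call's span coincides with an annotated exon run on the same
    strand, the sequence is the exon join (the exonic-circle case, e.g. a
    circle formed from three consecutive CDS exons); otherwise the genomic
    span is used. Sequence and block order are transcript-oriented (5'->3').
    """
    blocks: tuple[tuple[int, int], ...] | None = None
    for m in models:
        if m.chrom != call.chrom or m.strand != call.strand:
            continue
        run = _matching_exon_run(call, m)
        if run is not None:
            i, j = run
            blocks = tuple(m.exons[i : j + 1])
            break
    if blocks is None:
        blocks = ((call.start, call.end),)
    seq = "".join(genome[call.chrom][s:e] for s, e in blocks)
    if call.strand == "-":
        seq = revcomp(seq)
        blocks = tuple(reversed(blocks))
    call.spliced_seq = seq
    call.exon_blocks = blocks
    return call


def classify_origin(
    call: CircRNACall, models: Sequence[TranscriptModel]
) -> CircRNACall:
    """Assign a single origin category and host gene to a call.

    Precedence: exact exon-boundary join (exonic, with UTR/CDS sub-labels by
    base overlap) > exon-intron > intron > antisense > intergenic. Gene-derived
    labels require same-strand overlap; antisense means overlap only with an
    opposite-strand gene.
    """
    best: tuple[int, str, str | None] | None = None  # (rank, label, gene)
    for m in models:
        if m.chrom != call.chrom:
            continue
        overlap = max(0, min(call.end, m.end) - max(call.start, m.start))
        if overlap == 0:
            continue
        if m.strand != call.strand:
            cand = (4, "antisense", None)
        elif _matching_exon_run(call, m) is not None:
            cand = (1, _exonic_sublabel(call, m), m.gene_id)
        else:
            exonic = sum(
                max(0, min(call.end, e) - max(call.start, s)) for s, e in m.exons
            )
            if exonic == 0:
                # fully inside one intron?
                inside = any(
                    e1 <= call.start and call.end <= s2
                    for (_, e1), (s2, _) in zip(m.exons, m.exons[1:])
                )
                cand = (3, "intron", m.gene_id) if inside else (2, "exon-intron", m.gene_id)
            else:
                cand = (2, "exon-intron", m.gene_id)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        call.origin_category, call.host_gene_id = "intergenic", None
    else:
        call.origin_category, call.host_gene_id = best[1], best[2]
    return call


def _exonic_sublabel(call: CircRNACall, m: TranscriptModel) -> str:
    """UTR/CDS sub-label of an exact exon-join call, by base overlap."""
    if m.cds_start is None or m.cds_end is None:
        return "exon"
    # transcript coordinates of the CDS
    tx_len = m.exon_length()
    cds_t = sorted((_genomic_to_tx(m, m.cds_start), _genomic_to_tx(m, m.cds_end)))
    cds_lo, cds_hi = cds_t[0], cds_t[1] + 1
    run = _matching_exon_run(call, m)
    assert run is not None
    i, j = run
    offs = [0]
    for s, e in (m.exons if m.strand == "+" else tuple(reversed(m.exons))):
        offs.append(offs[-1] + (e - s))
    exon_order = list(range(len(m.exons)))
    if m.strand == "-":
        exon_order = exon_order[::-1]
    tx_pos = {orig: (offs[k], offs[k + 1]) for k, orig in enumerate(exon_order)}
    lo = min(tx_pos[x][0] for x in range(i, j + 1))
    hi = max(tx_pos[x][1] for x in range(i, j + 1))
    utr5 = max(0, min(hi, cds_lo) - lo)
    cds = max(0, min(hi, cds_hi) - max(lo, cds_lo))
    utr3 = max(0, hi - max(lo, cds_hi))
    if cds and utr5 and not utr3:
        return "CDS-5'UTR"
    if cds and utr3 and not utr5:
        return "CDS-3'UTR"
    if utr5 and not cds and not utr3:
        return "5'UTR"
    if utr3 and not cds and not utr5:
        return "3'UTR"
    return "exon"


def _genomic_to_tx(m: TranscriptModel, g: int) -> int:
    """Transcript coordinate of genomic base ``g`` (must lie in an exon)."""
    off = 0
    exons = m.exons if m.strand == "+" else tuple(reversed(m.exons))
    for s, e in exons:
        if s <= g < e:
            return off + (g - s if m.strand == "+" else e - 1 - g)
        off += e - s
    raise ValueError(f"genomic position {g} not exonic in {m.transcript_id}")


def expression_table(
    counts: Mapping[str, Mapping[str, int]],
    groups: Mapping[str, Sequence[str]],
    pseudocount: float = 0.5,
    fc_groups: tuple[str, str] = ("GM", "DM"),
) -> pd.DataFrame:
    """Per-circRNA unique-junction-read counts, group means and fold change.

    ``counts`` maps circ_id -> {sample: unique read count}. Fold change is
    (mean(second group) + c) / (mean(first group) + c) with pseudocount ``c``;
    circRNAs with fold change >= 2 or <= 0.5 are flagged as fold-change
    candidates (the dispersion/significance test of a differential-expression
    package is out of scope here).
    """
    for g, samples in groups.items():
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
    samples = [s for g in groups.values() for s in g]
    rows = []
    for circ_id in sorted(counts):
        row: dict = {"circ_id": circ_id}
        for s in samples:
            row[s] = int(counts[circ_id].get(s, 0))
        for g, ss in groups.items():
            row[f"mean_{g}"] = sum(row[s] for s in ss) / len(ss)
        g1, g2 = fc_groups
        fc = (row[f"mean_{g2}"] + pseudocount) / (row[f"mean_{g1}"] + pseudocount)
        row["fold_change"] = fc
        row["is_fc_candidate"] = fc >= 2 or fc <= 0.5
        rows.append(row)
    return pd.DataFrame(rows)
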