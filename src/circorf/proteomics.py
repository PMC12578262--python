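"""Junction-spanning peptide databases and smORF start-codon annotation.

Only a tryptic peptide whose residues cross the back-splice junction is
unambiguous evidence that a circRNA, and not its host mRNA, was translated.
This module builds the customized search database (junction-crossing cORF
proteins plus the reference proteome), digests proteins in silico (cleave
after K/R except before P), extracts junction-spanning peptides, labels
peptide novelty by exact substring search against the proteome, and
annotates smORFs: the start codon of a peptide-encoding frame is the 5'-most
upstream in-frame ATG, else the 5'-most near-cognate codon
(GTG/ACG/CTG/AGG/AAG/ATT/ATC) in a favorable Kozak context (purine at -3,
G at +4), else the codon following the upstream in-frame stop; a
stop-to-stop span under 150 codons marks a smORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corf import NEAR_COGNATE_CODONS, STOP_CODONS, translate
from .io import SequenceRecord, get_logger

_log = get_logger("pepdb")

SMORF_MAX_CODONS = 150
UPSTREAM_SCAN_CAP = 1000  # codons; bounds the scan on stop-free circular frames


@dataclass(frozen=True)
class Peptide:
    seq: str
    start: int  # residue indices, 0-based half-open on the parent protein
    end: int

    def contains_residue(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class JunctionPeptideRecord:
    circ_id: str
    protein_seq: str
    junction_aa_pos: int
    tryptic_peptides: tuple[Peptide, ...]
    junction_spanning: tuple[Peptide, ...]
    novelty: dict


@dataclass(frozen=True)
class SmorfAnnotation:
    peptide: str
    matched_rna_id: str | None
    frame: int | None
    start_codon: str | None
    start_source: str | None  # atg | near_cognate_kozak | upstream_stop
    kozak_ok: bool
    stop_to_stop_codons: int | None
    is_smorf: bool


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[Peptide]:
    """In-silico trypsin digestion with residue coordinates.

    Cleaves after K or R except when the next residue is P. Fragments tile
    the protein without gaps; with m missed cleavages every concatenation of
    up to m+1 adjacent fragments is also emitted.
    """
    if not protein:
        raise ValueError("empty protein")
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    frags = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    peptides: list[Peptide] = []
    for i in range(len(frags)):
        for m in range(missed_cleavages + 1):
            j = i + m
            if j >= len(frags):
                break
            s, e = frags[i][0], frags[j][1]
            peptides.append(Peptide(protein[s:e], s, e))
    return peptides


def junction_spanning_peptides(
    protein: str, junction_aa_pos: int, missed_cleavages: int = 0
) -> list[Peptide]:
    """Digestion products whose residue span contains the junction residue."""
    if not 0 <= junction_aa_pos < len(protein):
        raise ValueError(
            f"junction_aa_pos {junction_aa_pos} outside protein of length {len(protein)}"
        )
    return [
        p
        for p in tryptic_digest(protein, missed_cleavages)
        if p.contains_residue(junction_aa_pos)
    ]


def filter_known(
    peptides: Iterable[str],
    proteome: Sequence[SequenceRecord],
    il_equivalent: bool = False,
) -> dict[str, str]:
    """Label each peptide "known" (exact substring of a proteome entry) or "novel".

    ``il_equivalent=True`` folds isoleucine onto leucine on both sides before
    matching, since tandem MS cannot distinguish the two; the default is the
    plain string search.
    """
    proteome = list(proteome)
    if not proteome:
        _log.warning("empty proteome: every peptide is labeled novel")

    def _fold(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    targets = [_fold(rec.seq) for rec in proteome]
    labels: dict[str, str] = {}
    for pep in peptides:
        q = _fold(pep)
        labels[pep] = "known" if any(q in t for t in targets) else "novel"
    return labels


def database_protein(
    protein: str, is_moebius: bool, period_aa: int, context_aa: int = 40
) -> tuple[str, bool]:
    """Finite database entry for a cORF protein.

    A MOEBIUS product is theoretically infinite; its entry is one repeat unit
    plus ``context_aa`` residues of junction-overlapping context, flagged as
    a repeat unit. Other proteins pass through unchanged.
    """
    if not is_moebius:
        return protein, False
    return protein[: period_aa + context_aa], True


def build_junction_db(
    corf_proteins: Sequence[dict],
    proteome: Sequence[SequenceRecord],
    context_aa: int = 40,
) -> list[SequenceRecord]:
    """Combined FASTA records: junction-crossing cORF proteins + proteome.

    Each cORF entry carries parseable metadata in its description:
    ``circ_id=<id> junction_aa_pos=<i> frame=<f> repeat_unit=<0|1>``.
    ``corf_proteins`` rows need keys circ_id, protein_seq, junction_aa_pos,
    frame, is_moebius and period_aa; entries without a junction position are
    skipped with a warning.
    """
    records: list[SequenceRecord] = []
    for row in corf_proteins:
        if row.get("junction_aa_pos") is None:
            _log.warning(
                "cORF of %s lacks junction metadata; skipped", row.get("circ_id")
            )
            continue
        seq, repeat_unit = database_protein(
            row["protein_seq"], row.get("is_moebius", False),
            row.get("period_aa", len(row["protein_seq"])), context_aa,
        )
        desc = (
            f"circ_id={row['circ_id']} junction_aa_pos={row['junction_aa_pos']} "
            f"frame={row.get('frame', 0)} repeat_unit={int(repeat_unit)}"
        )
        records.append(
            SequenceRecord(
                id=f"{row['circ_id']}|cORF_f{row.get('frame', 0)}",
                seq=seq,
                description=desc,
            )
        )
    records.extend(proteome)
    return records


def parse_db_header(record: SequenceRecord) -> dict:
    """Round-trip the metadata written by :func:`build_junction_db`."""
    out: dict = {}
    for token in record.description.split():
        if "=" in token:
            key, val = token.split("=", 1)
            out[key] = int(val) if val.lstrip("-").isdigit() else val
    return out


def kozak_check(seq: str, codon_start: int) -> bool:
    """Minimal strong Kozak context: purine at -3 and G at +4.

    Positions are relative to the first base of the candidate start codon
    (+1); a context window truncated by the sequence end fails the check.
    """
    up = codon_start - 3
    down = codon_start + 3
    if up < 0 or down >= len(seq):
        return False
    return seq[up] in "AG" and seq[down] == "G"


def _find_peptide_frame(
    peptide: str, rna_sequences: Sequence[SequenceRecord]
) -> tuple[str, int, int] | None:
    """Locate a peptide in the 3-frame translations of the supplied RNAs.

    Returns (rna_id, frame, nt_start_of_peptide); deterministic: records are
    scanned in id order, frames in 0..2, positions 5'-most first.
    """
    for rec in sorted(rna_sequences, key=lambda r: r.id):
        for frame in range(3):
            prot = translate(rec.seq[frame:])
            pos = prot.find(peptide)
            if pos != -1:
                return rec.id, frame, frame + 3 * pos
    return None


def annotate_smorf(
    peptide: str,
    rna_sequences: Sequence[SequenceRecord],
    smorf_cutoff: int = SMORF_MAX_CODONS,
) -> SmorfAnnotation:
    """Start-codon and smORF annotation for one identified peptide.

    The peptide is located by exact match against 3-frame translations of the
    supplied RNA records. Scanning upstream in frame from the peptide (capped
    at 1,000 codons so stop-free circular frames terminate): the start is the
    5'-most in-frame ATG above the upstream stop; failing that, the 5'-most
    near-cognate codon passing the Kozak check; failing both, the codon after
    the upstream in-frame stop. ``stop_to_stop_codons`` counts the codons
    strictly between the upstream and downstream in-frame stops (sequence
    edges bound the count when a stop is absent); a span under
    ``smorf_cutoff`` codons marks a smORF.
    """
    loc = _find_peptide_frame(peptide, rna_sequences)
    if loc is None:
        return SmorfAnnotation(peptide, None, None, None, None, False, None, False)
    rna_id, frame, nt_start = loc
    seq = next(r.seq for r in rna_sequences if r.id == rna_id)

    # upstream in-frame stop (or scan cap / sequence start)
    upstream_stop_pos: int | None = None
    scanned = 0
    pos = nt_start - 3
    while pos >= frame and scanned < UPSTREAM_SCAN_CAP:
        if seq[pos : pos + 3] in STOP_CODONS:
            upstream_stop_pos = pos
            break
        pos -= 3
        scanned += 1
    window_lo = upstream_stop_pos + 3 if upstream_stop_pos is not None else max(frame, pos + 3)

    # candidate starts within [window_lo, nt_start], 5'-most first
    atg_pos = near_pos = None
    p = window_lo
    while p <= nt_start:
        codon = seq[p : p + 3]
        if codon == "ATG" and atg_pos is None:
            atg_pos = p
        elif codon in NEAR_COGNATE_CODONS and near_pos is None and kozak_check(seq, p):
            near_pos = p
        p += 3

    if atg_pos is not None:
        start_codon, start_source, kozak_ok = "ATG", "atg", kozak_check(seq, atg_pos)
    elif near_pos is not None:
        start_codon, start_source, kozak_ok = seq[near_pos : near_pos + 3], "near_cognate_kozak", True
    else:
        start_codon, start_source, kozak_ok = None, "upstream_stop", False

    # downstream in-frame stop (or sequence end / cap)
    downstream_stop_pos: int | None = None
    p = nt_start
    scanned = 0
    while p + 3 <= len(seq) and scanned < UPSTREAM_SCAN_CAP:
        if seq[p : p + 3] in STOP_CODONS:
            downstream_stop_pos = p
            break
        p += 3
        scanned += 1
    hi = downstream_stop_pos if downstream_stop_pos is not None else p
    lo = upstream_stop_pos + 3 if upstream_stop_pos is not None else window_lo
    stop_to_stop = (hi - lo) // 3
    return SmorfAnnotation(
        peptide=peptide,
        matched_rna_id=rna_id,
        frame=frame,
        start_codon=start_codon,
        start_source=start_source,
        kozak_ok=kozak_ok,
        stop_to_stop_codons=stop_to_stop,
        is_smorf=stop_to_stop < smorf_cutoff,
    )
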