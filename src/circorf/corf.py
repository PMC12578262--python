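"""Circular ORF (cORF) prediction on back-spliced RNAs.

A circRNA of length L is linearized by concatenating its spliced sequence
four times; in each of the three reading frames the longest ORF whose codon
span crosses a junction boundary (a multiple of L inside the concatenation)
is kept. ORFs are scored

    S = 100*KNOWN_START + 1000*HEAD_TO_TAIL + (len_aa / 1_010_000)*MOEBIUS_ORF

where KNOWN_START marks an ORF whose start codon sits exactly on the host
mRNA's annotated translation start, HEAD_TO_TAIL marks a junction-crossing
ORF, and MOEBIUS_ORF marks a frame with no stop codon around the circle
(possible only when L is a multiple of three), i.e. a template for
rolling-circle translation that in principle never terminates.

Attribute taxonomy: COMPLETE (the ORF covers every base of the circle),
MOEBIUS, HEAD_TO_TAIL, and MICROPEPTIDE (< 100 aa product).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from Bio.Seq import Seq

from .io import TranscriptModel, get_logger

_log = get_logger("corf")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NEAR_COGNATE_CODONS = ("GTG", "ACG", "CTG", "AGG", "AAG", "ATT", "ATC")
MICROPEPTIDE_MAX_AA = 100


@dataclass(frozen=True)
class CircularOrf:
    """One predicted ORF on the 4x concatenation of a circRNA."""

    circ_id: str
    frame: int
    start_idx: int
    end_idx: int  # half-open, includes the stop codon when has_stop
    len_aa: int
    spans_junction: bool
    start_codon: str | None
    has_stop: bool
    protein_seq: str
    junction_aa_pos: int | None


@dataclass(frozen=True)
class CorfAttributes:
    complete: bool
    moebius: bool
    head_to_tail: bool
    micropeptide: bool
    primary_label: str | None


def concatenate_4x(circ_seq: str) -> str:
    """Return the circRNA sequence repeated exactly four times."""
    if not circ_seq:
        raise ValueError("empty circRNA sequence")
    if set(circ_seq) - set("ACGT"):
        raise ValueError(
            f"circRNA sequence contains non-ACGT characters: "
            f"{sorted(set(circ_seq) - set('ACGT'))}"
        )
    return circ_seq * 4


def translate(nt: str) -> str:
    """Translate complete codons of ``nt`` (standard code, stops as '*')."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def is_moebius(circ_seq: str) -> tuple[bool, int | None]:
    """Whether any frame of the circle is stop-free (rolling-circle template).

    True iff ``len(circ_seq) % 3 == 0`` and at least one frame contains no
    stop codon anywhere around the circle; the check wraps the junction by
    scanning one period of codons on the doubled sequence. Returns the first
    stop-free frame, or None.
    """
    L = len(circ_seq)
    if L == 0 or L % 3 != 0:
        return False, None
    doubled = circ_seq * 2
    for frame in range(3):
        if all(
            doubled[frame + 3 * i : frame + 3 * i + 3] not in STOP_CODONS
            for i in range(L // 3)
        ):
            return True, frame
    return False, None


def _junction_boundary_in(start: int, end: int, L: int) -> int | None:
    """Smallest multiple of L strictly inside [start, end), if any."""
    for m in (1, 2, 3):
        if start < m * L < end:
            return m * L
    return None


def _make_orf(circ_id: str, search_seq: str, L: int, s: int, end: int,
              has_stop: bool, start_codon: str | None) -> CircularOrf:
    n_codons = (end - s) // 3
    len_aa = n_codons - 1 if has_stop else n_codons
    boundary = _junction_boundary_in(s, end, L)
    junction_aa_pos: int | None = None
    if boundary is not None:
        aa = (boundary - s) // 3  # codon containing (or starting at) boundary
        junction_aa_pos = aa if aa < len_aa else None
    coding_end = end - 3 if has_stop else end
    return CircularOrf(
        circ_id=circ_id,
        frame=s % 3,
        start_idx=s,
        end_idx=end,
        len_aa=len_aa,
        spans_junction=boundary is not None,
        start_codon=start_codon,
        has_stop=has_stop,
        protein_seq=translate(search_seq[s:coding_end]),
        junction_aa_pos=junction_aa_pos,
    )


def find_junction_orfs(
    search_seq: str,
    L: int,
    start_codon_policy: str = "ATG",
    circ_id: str = "circ",
) -> list[CircularOrf]:
    """Longest junction-spanning ORF per frame on the 4x concatenation.

    ORFs start at ATG (policy ``"ATG"``) or additionally at the near-cognate
    codons (policy ``"near_cognate"``) and run to the first in-frame stop, or
    to the end of the concatenation with ``has_stop=False`` (MOEBIUS
    candidates). Only ORFs whose codon span covers a junction boundary (L,
    2L or 3L) qualify; ties go to the 5'-most start. A stop-free frame of a
    length-divisible-by-three circle with no start codon is still reported,
    anchored at the frame offset with ``start_codon=None`` — the
    never-terminating frame exists regardless of initiation.
    """
    if len(search_seq) != 4 * L:
        raise ValueError("search_seq must be the 4x concatenation of the circRNA")
    if start_codon_policy == "ATG":
        start_set = {"ATG"}
    elif start_codon_policy == "near_cognate":
        start_set = {"ATG", *NEAR_COGNATE_CODONS}
    else:
        raise ValueError(f"unknown start_codon_policy {start_codon_policy!r}")

    n = len(search_seq)
    results: list[CircularOrf] = []
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        stops = [p for p in codon_starts if search_seq[p : p + 3] in STOP_CODONS]
        starts = [p for p in codon_starts if search_seq[p : p + 3] in start_set]
        last_codon_end = frame + 3 * ((n - frame) // 3)
        best: CircularOrf | None = None
        for s in starts:
            i = bisect_right(stops, s)
            if i < len(stops):
                end, has_stop = stops[i] + 3, True
            else:
                end, has_stop = last_codon_end, False
            if _junction_boundary_in(s, end, L) is None:
                continue
            orf = _make_orf(circ_id, search_seq, L, s, end, has_stop,
                            search_seq[s : s + 3])
            if best is None or (orf.len_aa, -orf.start_idx) > (best.len_aa, -best.start_idx):
                best = orf
        if best is None and L % 3 == 0 and not stops:
            # stop-free frame with no start codon: report the frame itself
            best = _make_orf(circ_id, search_seq, L, frame, last_codon_end,
                             False, None)
        if best is not None:
            results.append(best)
    return results


def known_start(
    orf: CircularOrf,
    call,
    models: list[TranscriptModel],
) -> int:
    """1 iff the ORF's first base maps to the host mRNA's annotated start.

    The ORF start is mapped back to genomic coordinates through the circRNA's
    exon structure (``call.exon_blocks``, transcript-ordered genomic
    intervals); intergenic calls and calls without a host gene score 0.
    """
    if call.host_gene_id is None or call.exon_blocks is None or orf.start_idx is None:
        return 0
    L = sum(e - s for s, e in call.exon_blocks)
    pos = orf.start_idx % L
    genomic = _circ_to_genomic(pos, call.exon_blocks, call.strand)
    for m in models:
        if (
            m.gene_id == call.host_gene_id
            and m.strand == call.strand
            and m.cds_start is not None
            and m.cds_start == genomic
        ):
            return 1
    return 0


def _circ_to_genomic(pos: int, blocks, strand: str) -> int:
    """Map a position on the spliced circle to a genomic coordinate."""
    for s, e in blocks:
        n = e - s
        if pos < n:
            return s + pos if strand == "+" else e - 1 - pos
        pos -= n
    raise ValueError("position outside circRNA exon blocks")


def score_corf(
    known_start: int,
    head_to_tail: int,
    moebius_orf: int,
    len_aa: int = 0,
    variant: str = "printed",
) -> float:
    """Score of a cORF.

    ``variant="printed"`` is S = 100*K + 1000*H + (len_aa/1,010,000)*M (the
    length term contributes only for MOEBIUS ORFs, left-to-right arithmetic).
    ``variant="additive_len"`` is the alternative parse with a standalone
    length term plus a bare MOEBIUS flag.
    """
    for name, flag in (("known_start", known_start), ("head_to_tail", head_to_tail),
                       ("moebius_orf", moebius_orf)):
        if flag not in (0, 1):
            raise ValueError(f"{name} must be 0 or 1, got {flag!r}")
    if len_aa < 0:
        raise ValueError("len_aa must be >= 0")
    if variant == "printed":
        return 100.0 * known_start + 1000.0 * head_to_tail + (len_aa / 1_010_000) * moebius_orf
    if variant == "additive_len":
        return 100.0 * known_start + 1000.0 * head_to_tail + len_aa / 1_010_000 + moebius_orf
    raise ValueError(f"unknown score variant {variant!r}")


def classify_corf(orf: CircularOrf, circ_len: int) -> CorfAttributes:
    """Attribute flags and primary label for one cORF.

    Flags are not mutually exclusive; the primary label follows the
    precedence MOEBIUS > COMPLETE > HEAD_TO_TAIL > MICROPEPTIDE.
    """
    complete = (orf.end_idx - orf.start_idx) >= circ_len
    moebius = circ_len % 3 == 0 and not orf.has_stop
    head_to_tail = orf.spans_junction
    micropeptide = orf.len_aa < MICROPEPTIDE_MAX_AA
    primary = None
    for label, flag in (
        ("MOEBIUS", moebius),
        ("COMPLETE", complete),
        ("HEAD_TO_TAIL", head_to_tail),
        ("MICROPEPTIDE", micropeptide),
    ):
        if flag:
            primary = label
            break
    return CorfAttributes(
        complete=complete,
        moebius=moebius,
        head_to_tail=head_to_tail,
        micropeptide=micropeptide,
        primary_label=primary,
    )
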