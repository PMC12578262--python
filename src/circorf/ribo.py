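"""Ribosome-footprint processing for circRNA junctions.

Ribosome-protected fragments (RPFs) are filtered to the 27-32 nt window,
then placed on per-circRNA junction windows (the last ``flank`` bases of the
circle joined to its first ``flank`` bases, junction at the center) with
zero mismatches, a minimum overhang on each side of the back-splice point,
a uniqueness requirement across the junction database, and an exclusion of
reads that occur exactly in the linear transcriptome/genome (a desk-scale
stand-in for cross-referencing genomic rearrangements and repeats). A
circRNA supported by at least ``min_unique`` distinct junction-spanning RPF
sequences is flagged as a ribo-circRNA. Translation efficiency is the ratio
of ribosome-level to transcript-level junction expression, and the conjoint
GM/DM classification combines the fold-change direction at both levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SequenceRecord, get_logger

_log = get_logger("ribo")

RPF_MIN_LEN = 27
RPF_MAX_LEN = 32
DEFAULT_MIN_OVERHANG = 6
DEFAULT_WINDOW_FLANK = 31


@dataclass(frozen=True)
class RpfJunctionAssignment:
    read_id: str
    circ_id: str
    offset: int  # placement start within the junction window
    left_overhang: int
    right_overhang: int
    mismatches: int  # always 0 for accepted assignments
    is_unique: bool
    read_seq: str


def filter_rpf_length(
    reads: Iterable[SequenceRecord], lo: int = RPF_MIN_LEN, hi: int = RPF_MAX_LEN
) -> list[SequenceRecord]:
    """Keep exactly the reads with lo <= length <= hi, order preserved."""
    if lo > hi:
        raise ValueError(f"lo={lo} > hi={hi}")
    return [r for r in reads if lo <= len(r.seq) <= hi]


def build_junction_windows(
    circ_seqs: Mapping[str, str], window_flank: int = DEFAULT_WINDOW_FLANK
) -> dict[str, str]:
    """Junction window per circRNA: tail ``flank`` + head ``flank`` bases.

    The back-splice point sits at the window center (index ``flank``); the
    center dinucleotide is seq[L-1] + seq[0]. Circles shorter than the flank
    are wrapped as many times as needed; circles shorter than 2 nt are
    skipped.
    """
    windows: dict[str, str] = {}
    for circ_id, seq in circ_seqs.items():
        L = len(seq)
        if L < 2:
            _log.info("circ %s shorter than 2 nt; no junction window", circ_id)
            continue
        reps = math.ceil(window_flank / L)
        tiled = seq * reps
        windows[circ_id] = tiled[-window_flank:] + tiled[:window_flank]
    return windows


def assign_rpf(
    read: SequenceRecord,
    windows: Mapping[str, str],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    linear_decoys: Sequence[str] = (),
) -> RpfJunctionAssignment | None:
    """Zero-mismatch junction-spanning placement of one footprint, or None.

    Accepted iff exactly one circRNA window admits an exact placement whose
    span covers the junction center with at least ``min_overhang`` bases on
    each side, and the read does not occur exactly in any of the supplied
    linear decoy sequences (transcriptome/genome). Within one window the
    5'-most qualifying offset is reported (a wrapped window of a short circle
    may contain the junction more than once).
    """
    n = len(read.seq)
    hits: list[tuple[str, int, int]] = []  # (circ_id, offset, flank)
    for circ_id, window in windows.items():
        flank = len(window) // 2
        start = window.find(read.seq)
        while start != -1:
            left = flank - start
            right = start + n - flank
            if left >= min_overhang and right >= min_overhang:
                hits.append((circ_id, start, flank))
                break  # one qualifying placement per circle is enough
            start = window.find(read.seq, start + 1)
    if not hits:
        return None
    unique = len({h[0] for h in hits}) == 1
    if not unique:
        _log.info("RPF %s matches %d junctions; rejected", read.id, len(hits))
        return None
    for decoy in linear_decoys:
        if read.seq in decoy:
            _log.info("RPF %s occurs in a linear decoy sequence; rejected", read.id)
            return None
    circ_id, offset, flank = hits[0]
    return RpfJunctionAssignment(
        read_id=read.id,
        circ_id=circ_id,
        offset=offset,
        left_overhang=flank - offset,
        right_overhang=offset + n - flank,
        mismatches=0,
        is_unique=True,
        read_seq=read.seq,
    )


def count_junction_rpfs(
    assignments: Iterable[RpfJunctionAssignment], min_unique: int = 1
) -> pd.DataFrame:
    """Unique (deduplicated by sequence) junction RPF support per circRNA.

    ``min_unique`` defaults to 1 ("at least one specific RPF read"); the
    stricter published criterion of >= 20 unique junction-spanning reads is a
    configuration choice.
    """
    per_circ: dict[str, set[str]] = {}
    for a in assignments:
        per_circ.setdefault(a.circ_id, set()).add(a.read_seq)
    rows = [
        {
            "circ_id": circ_id,
            "n_unique_rpfs": len(seqs),
            "is_ribo_circ": len(seqs) >= min_unique,
        }
        for circ_id, seqs in sorted(per_circ.items())
    ]
    return pd.DataFrame(rows, columns=["circ_id", "n_unique_rpfs", "is_ribo_circ"])


def translation_efficiency(
    ribo_counts: Mapping[str, Mapping[str, int]],
    circ_counts: Mapping[str, Mapping[str, int]],
    groups: Mapping[str, Sequence[str]],
    norm: str = "cpm",
    pseudocount: float = 0.5,
    fc_groups: tuple[str, str] = ("GM", "DM"),
) -> pd.DataFrame:
    """Per-circRNA translation efficiency and its DM/GM fold change.

    TE = (ribo expression + c) / (circRNA expression + c) per group, with
    expressions either raw unique junction read counts (``norm="raw"``) or
    counts per million junction reads per sample library (``norm="cpm"``,
    invariant to joint library rescaling). The TE fold change compares the
    second group of ``fc_groups`` to the first.
    """
    if norm not in ("cpm", "raw"):
        raise ValueError(f"norm must be 'cpm' or 'raw', got {norm!r}")
    samples = [s for g in groups.values() for s in g]
    circ_ids = sorted(set(ribo_counts) | set(circ_counts))

    def _norm(counts: Mapping[str, Mapping[str, int]]) -> dict[str, dict[str, float]]:
        table = {
            cid: {s: float(counts.get(cid, {}).get(s, 0)) for s in samples}
            for cid in circ_ids
        }
        if norm == "raw":
            return table
        lib = {s: sum(table[cid][s] for cid in circ_ids) for s in samples}
        for s in samples:
            if lib[s] == 0:
                raise ValueError(f"empty library for sample {s!r}")
        return {
            cid: {s: table[cid][s] * 1e6 / lib[s] for s in samples} for cid in circ_ids
        }

    ribo = _norm(ribo_counts)
    circ = _norm(circ_counts)
    rows = []
    for cid in circ_ids:
        row: dict = {"circ_id": cid}
        for g, ss in groups.items():
            r = sum(ribo[cid][s] for s in ss) / len(ss)
            c = sum(circ[cid][s] for s in ss) / len(ss)
            row[f"ribo_expr_{g}"] = r
            row[f"circ_expr_{g}"] = c
            row[f"TE_{g}"] = (r + pseudocount) / (c + pseudocount)
        g1, g2 = fc_groups
        row["te_fold_change"] = row[f"TE_{g2}"] / row[f"TE_{g1}"]
        rows.append(row)
    return pd.DataFrame(rows)


def conjoint_classify(
    transcript_fc: Mapping[str, float],
    ribo_fc: Mapping[str, float],
    fc_threshold: float = 2.0,
) -> dict[str, str]:
    """Conjoint GM-vs-DM class from transcript- and ribosome-level fold change.

    Fold changes are GM/DM oriented: a level is "up" when fc >= threshold,
    "down" when fc <= 1/threshold, otherwise unchanged. Classes: up_up,
    down_down, up_down, down_up, unchanged (any level unchanged collapses to
    "unchanged").
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")

    def _dir(fc: float) -> str:
        if fc >= fc_threshold:
            return "up"
        if fc <= 1 / fc_threshold:
            return "down"
        return "flat"

    out: dict[str, str] = {}
    for cid in sorted(set(transcript_fc) & set(ribo_fc)):
        t, r = _dir(transcript_fc[cid]), _dir(ribo_fc[cid])
        out[cid] = "unchanged" if "flat" in (t, r) else f"{t}_{r}"
    return out
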