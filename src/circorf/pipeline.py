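"""End-to-end orchestration: simulate -> detect -> cORF -> ribo -> pepdb.

Single-process execution with per-stage output files under one run
directory; the summary mirrors the discovery funnel (circRNAs called, with
cORF, MOEBIUS, ribosome-associated, MOEBIUS-and-ribosome-associated, novel
junction peptides), whose subset relations hold on every run. One structured
log line is emitted for every discarded item so each filter is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import corf as corf_mod
from . import detect as detect_mod
from . import proteomics as pep_mod
from . import ribo as ribo_mod
from .io import (
    SequenceRecord,
    get_logger,
    write_fasta,
    write_gtf,
    write_table,
)
from .simulate import (
    FixtureConfig,
    make_genome,
    make_proteome,
    simulate_backsplice_reads,
    simulate_rpf_reads,
)

_log = get_logger("pipeline")

COORD_NOTE = "coordinates are 1-based closed"


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, at their study defaults.

    20-mer anchors, >= 2 unique back-spliced reads, 27-32 nt footprints,
    6 nt minimum junction overhang, >= 1 unique footprint for a
    ribo-circRNA, fold-change threshold 2, < 100 aa micropeptides, < 150
    codon smORFs.
    """

    seed: int = 0
    outdir: str = "circorf_run"
    anchor_len: int = 20
    min_support: int = 2
    splice_check: str = "enforce"
    rpf_min_len: int = 27
    rpf_max_len: int = 32
    min_overhang: int = 6
    window_flank: int = 31
    min_unique: int = 1
    fc_threshold: float = 2.0
    pseudocount: float = 0.5
    norm: str = "cpm"
    micropeptide_cutoff: int = 100
    smorf_cutoff: int = 150
    score_variant: str = "printed"
    start_codon_policy: str = "ATG"
    missed_cleavages: int = 2  # the usual MS search allowance
    fixture: FixtureConfig = field(default_factory=FixtureConfig)

    def __post_init__(self) -> None:
        self.fixture.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # paths do not change the science
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


FUNNEL_KEYS = (
    "n_circRNAs",
    "n_with_cORF",
    "n_moebius",
    "n_ribo_circ",
    "n_moebius_ribo",
    "n_novel_junction_peptides",
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a fresh synthetic fixture and write all outputs.

    Returns the summary dict (funnel counts plus config hash and seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # --- simulate ----------------------------------------------------------
    fixture = config.fixture
    genome_records, models, truth = make_genome(fixture)
    genome = {r.id: r.seq for r in genome_records}
    reads_by_sample = simulate_backsplice_reads(truth, fixture)
    rpfs_by_sample = simulate_rpf_reads(truth, fixture)
    proteome = make_proteome(models, genome)
    write_fasta(genome_records, outdir / "genome.fa")
    write_gtf(models, outdir / "annotation.gtf")
    write_fasta(proteome, outdir / "proteome.fa")
    for sample, reads in reads_by_sample.items():
        write_fasta(reads, outdir / f"reads_{sample}.fa")
    for sample, reads in rpfs_by_sample.items():
        write_fasta(reads, outdir / f"rpf_{sample}.fa")
    write_table(
        [
            {
                "circ_id": c.circ_id,
                "gene_id": c.gene_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start + 1,
                "end": c.end,
                "length": len(c.spliced_seq),
                "is_moebius": c.is_moebius,
                "is_translated": c.is_translated,
                "junction_peptide": c.junction_peptide or "",
            }
            for c in truth.circs
        ],
        outdir / "truth.tsv",
        comment=f"planted circRNAs; {COORD_NOTE}",
    )

    # --- detect ------------------------------------------------------------
    index = detect_mod.GenomeIndex(genome, config.anchor_len)
    candidates_by_sample: dict[str, list] = {}
    for sample, reads in reads_by_sample.items():
        cands = []
        for read in reads:
            cand = detect_mod.call_backsplice(
                read, index, genome, config.anchor_len, config.splice_check
            )
            if cand is not None:
                cands.append(cand)
        candidates_by_sample[sample] = cands
    all_cands = [c for cc in candidates_by_sample.values() for c in cc]
    calls = detect_mod.collapse_candidates(all_cands, config.min_support)
    kept_calls = []
    for call in calls:
        detect_mod.spliced_sequence(call, genome, models)
        if "N" in call.spliced_seq:
            _log.info("call %s spliced sequence contains N; dropped", call.circ_id)
            continue
        detect_mod.classify_origin(call, models)
        kept_calls.append(call)
    calls = kept_calls
    write_table(
        [
            {
                "circ_id": c.circ_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start + 1,
                "end": c.end,
                "n_unique_reads": c.n_unique_reads,
                "splice_signal_ok": c.splice_signal_ok,
                "origin_category": c.origin_category,
                "host_gene_id": c.host_gene_id or "",
            }
            for c in calls
        ],
        outdir / "circ_calls.tsv",
        comment=f"called circRNAs; {COORD_NOTE}",
        columns=[
            "circ_id", "chrom", "strand", "start", "end", "n_unique_reads",
            "splice_signal_ok", "origin_category", "host_gene_id",
        ],
    )
    write_fasta(
        [SequenceRecord(c.circ_id, c.spliced_seq) for c in calls],
        outdir / "circ_seqs.fa",
    )

    # per-sample unique junction-read counts for expression
    junction_key = {(c.chrom, c.strand, c.start, c.end): c.circ_id for c in calls}
    circ_counts: dict[str, dict[str, int]] = {c.circ_id: {} for c in calls}
    for sample, cands in candidates_by_sample.items():
        per_junction: dict[str, set[str]] = {}
        for cand in cands:
            key = (cand.chrom, cand.strand, cand.acceptor_pos, cand.donor_pos + 1)
            circ_id = junction_key.get(key)
            if circ_id is not None:
                per_junction.setdefault(circ_id, set()).add(cand.read_seq)
        for circ_id, seqs in per_junction.items():
            circ_counts[circ_id][sample] = len(seqs)
    groups = fixture.samples
    expr = detect_mod.expression_table(
        circ_counts, groups, config.pseudocount
    ) if calls else None
    if expr is not None:
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    # --- cORF --------------------------------------------------------------
    corf_rows: list[dict] = []
    corf_proteins: list[dict] = []
    circs_with_corf: set[str] = set()
    per_circ_best: dict[str, tuple] = {}
    for call in calls:
        L = len(call.spliced_seq)
        search = corf_mod.concatenate_4x(call.spliced_seq)
        orfs = corf_mod.find_junction_orfs(
            search, L, config.start_codon_policy, circ_id=call.circ_id
        )
        if orfs:
            circs_with_corf.add(call.circ_id)
        for orf in orfs:
            attrs = corf_mod.classify_corf(orf, L)
            k = corf_mod.known_start(orf, call, models)
            score = corf_mod.score_corf(
                k, int(attrs.head_to_tail), int(attrs.moebius), orf.len_aa,
                config.score_variant,
            )
            corf_rows.append(
                {
                    "circ_id": call.circ_id,
                    "frame": orf.frame,
                    "start_idx": orf.start_idx,
                    "len_aa": orf.len_aa,
                    "start_codon": orf.start_codon or "",
                    "known_start": k,
                    "head_to_tail": int(attrs.head_to_tail),
                    "moebius": int(attrs.moebius),
                    "complete": int(attrs.complete),
                    "micropeptide": int(attrs.micropeptide),
                    "primary_label": attrs.primary_label or "",
                    "score": score,
                    "junction_aa_pos": orf.junction_aa_pos
                    if orf.junction_aa_pos is not None
                    else "",
                }
            )
            if orf.junction_aa_pos is not None:
                cur = per_circ_best.get(call.circ_id)
                cand = (score, orf.len_aa, -orf.start_idx, orf, attrs)
                if cur is None or cand[:3] > cur[:3]:
                    per_circ_best[call.circ_id] = cand
    circ_len = {c.circ_id: len(c.spliced_seq) for c in calls}
    for circ_id, (score, _, _, orf, attrs) in sorted(per_circ_best.items()):
        corf_proteins.append(
            {
                "circ_id": circ_id,
                "protein_seq": orf.protein_seq,
                "junction_aa_pos": orf.junction_aa_pos,
                "frame": orf.frame,
                "is_moebius": attrs.moebius,
                "period_aa": circ_len[circ_id] // 3,
            }
        )
    write_table(
        corf_rows, outdir / "corfs.tsv", comment="predicted cORFs",
        columns=[
            "circ_id", "frame", "start_idx", "len_aa", "start_codon",
            "known_start", "head_to_tail", "moebius", "complete",
            "micropeptide", "primary_label", "score", "junction_aa_pos",
        ],
    )

    # --- ribo --------------------------------------------------------------
    windows = ribo_mod.build_junction_windows(
        {c.circ_id: c.spliced_seq for c in calls}, config.window_flank
    )
    linear_decoys = list(truth.transcript_seqs.values()) + list(genome.values())
    ribo_counts: dict[str, dict[str, int]] = {c.circ_id: {} for c in calls}
    all_assignments = []
    for sample, rpf_reads in rpfs_by_sample.items():
        kept = ribo_mod.filter_rpf_length(
            rpf_reads, config.rpf_min_len, config.rpf_max_len
        )
        per_circ: dict[str, set[str]] = {}
        for read in kept:
            a = ribo_mod.assign_rpf(read, windows, config.min_overhang, linear_decoys)
            if a is not None:
                all_assignments.append(a)
                per_circ.setdefault(a.circ_id, set()).add(a.read_seq)
        for circ_id, seqs in per_circ.items():
            ribo_counts[circ_id][sample] = len(seqs)
    support = ribo_mod.count_junction_rpfs(all_assignments, config.min_unique)
    support.to_csv(outdir / "ribo_circ.tsv", sep="\t", index=False)
    ribo_flagged = set(support[support["is_ribo_circ"]]["circ_id"])
    if calls:
        te = ribo_mod.translation_efficiency(
            ribo_counts, circ_counts, groups, config.norm, config.pseudocount
        )
        gm, dm = list(groups)[0], list(groups)[1]
        t_fc = {
            cid: (cnt_mean(circ_counts[cid], groups[gm]) + config.pseudocount)
            / (cnt_mean(circ_counts[cid], groups[dm]) + config.pseudocount)
            for cid in ribo_flagged
        }
        r_fc = {
            cid: (cnt_mean(ribo_counts[cid], groups[gm]) + config.pseudocount)
            / (cnt_mean(ribo_counts[cid], groups[dm]) + config.pseudocount)
            for cid in ribo_flagged
        }
        conjoint = ribo_mod.conjoint_classify(t_fc, r_fc, config.fc_threshold)
        te["conjoint_class"] = te["circ_id"].map(conjoint).fillna("")
        te.to_csv(outdir / "te.tsv", sep="\t", index=False)

    # --- pepdb -------------------------------------------------------------
    db = pep_mod.build_junction_db(corf_proteins, proteome)
    write_fasta(db, outdir / "junction_db.fa")
    junction_peptides: dict[str, str] = {}  # peptide -> circ_id
    for row in corf_proteins:
        protein, _ = pep_mod.database_protein(
            row["protein_seq"], row["is_moebius"], row["period_aa"]
        )
        if row["junction_aa_pos"] >= len(protein):
            continue
        for pep in pep_mod.junction_spanning_peptides(
            protein, row["junction_aa_pos"], config.missed_cleavages
        ):
            junction_peptides.setdefault(pep.seq, row["circ_id"])
    novelty = pep_mod.filter_known(junction_peptides, proteome)
    write_table(
        [
            {"peptide": p, "circ_id": junction_peptides[p], "novelty": novelty[p]}
            for p in sorted(junction_peptides)
        ],
        outdir / "novelty.tsv",
        comment="junction-spanning peptides vs reference proteome",
        columns=["peptide", "circ_id", "novelty"],
    )

    # MS-identified peptides: in fixture mode, the planted junction peptides
    identified = list(truth.expected_peptides)
    novel_identified = [
        p for p in identified if p in junction_peptides and novelty.get(p) == "novel"
    ]
    circ_rnas = [
        SequenceRecord(c.circ_id, corf_mod.concatenate_4x(c.spliced_seq))
        for c in calls
    ]
    smorfs = [
        pep_mod.annotate_smorf(p, circ_rnas, config.smorf_cutoff)
        for p in novel_identified
    ]
    write_table(
        [
            {
                "peptide": s.peptide,
                "matched_rna_id": s.matched_rna_id or "",
                "frame": s.frame if s.frame is not None else "",
                "start_codon": s.start_codon or "none",
                "start_source": s.start_source or "",
                "kozak_ok": s.kozak_ok,
                "stop_to_stop_codons": s.stop_to_stop_codons
                if s.stop_to_stop_codons is not None
                else "",
                "is_smorf": s.is_smorf,
            }
            for s in smorfs
        ],
        outdir / "smorf_annotations.tsv",
        comment="smORF start-codon annotation of identified novel peptides",
        columns=[
            "peptide", "matched_rna_id", "frame", "start_codon", "start_source",
            "kozak_ok", "stop_to_stop_codons", "is_smorf",
        ],
    )

    # --- summary -----------------------------------------------------------
    moebius_ids = {
        c.circ_id for c in calls if corf_mod.is_moebius(c.spliced_seq)[0]
    }
    summary = {
        "n_circRNAs": len(calls),
        "n_with_cORF": len(circs_with_corf),
        "n_moebius": len(moebius_ids),
        "n_ribo_circ": len(ribo_flagged),
        "n_moebius_ribo": len(moebius_ids & ribo_flagged),
        "n_novel_junction_peptides": len(novel_identified),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    report(summary, outdir)
    return summary


def cnt_mean(counts: dict[str, int], samples) -> float:
    return sum(counts.get(s, 0) for s in samples) / len(samples)


def report(summary: dict, outdir: str | Path) -> str:
    """Human-readable funnel report plus a machine-readable TSV."""
    outdir = Path(outdir)
    write_table([summary], outdir / "summary.tsv", columns=list(summary))
    lines = ["circRNA coding-discovery funnel", "=" * 31]
    for k in FUNNEL_KEYS:
        lines.append(f"{k:30s} {summary[k]}")
    lines.append(f"{'config_hash':30s} {summary['config_hash']}")
    lines.append(f"{'seed':30s} {summary['seed']}")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


def read_summary(outdir: str | Path) -> dict:
    """Parse a written summary back to its numbers."""
    import pandas as pd

    df = pd.read_csv(Path(outdir) / "summary.tsv", sep="\t")
    return df.iloc[0].to_dict()
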