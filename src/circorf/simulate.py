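"""Synthetic genomes with planted circRNAs, reads, footprints and proteomes.

The generator emulates the data structure of a paired myoblast (GM) /
myotube (DM) study: multi-exon genes with canonical GT/AG introns, planted
exonic circRNAs spanning contiguous internal exon runs, back-spliced
circRNA-seq reads, ribosome-protected fragments across junctions of the
translated circRNAs, and a proteome of the linear host proteins. Every
planted fact (junction coordinates, MOEBIUS status, cORF proteins, the
junction-spanning tryptic peptides) is recorded as ground truth so each
downstream stage can be scored for recall and false positives.

Construction guarantees, per gene hosting a circRNA:

* the host CDS starts at the first base of the circle's first exon, so the
  circle reads ATG + stop-free codons in frame 0 across one period — every
  planted circRNA therefore carries a junction-crossing ORF, and its ORF
  start coincides with the annotated mRNA start (KNOWN_START);
* a MOEBIUS circle spans a single exon whose length is a multiple of three,
  making frame 0 stop-free around the wrap; non-MOEBIUS circles get a run
  length that is not a multiple of three;
* the circle's first exon is preceded by an AG-terminated intron and its
  last exon followed by a GT-initiated intron, so the back-splice flanks
  carry the canonical splice signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import corf as _corf
from . import proteomics as _pep
from .io import SequenceRecord, TranscriptModel, get_logger, revcomp

_log = get_logger("simulate")

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _corf.STOP_CODONS
)
_STOPS = ("TAA", "TAG", "TGA")


class ConfigError(ValueError):
    """The fixture configuration is infeasible."""


@dataclass
class FixtureConfig:
    """Study-shaped defaults: 20 genes, 10 planted circRNAs of which 2 are
    MOEBIUS, back-splice depth 5, footprints on 5 translated circles."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (100, 160)
    intron_len: tuple[int, int] = (60, 120)
    n_circ_genes: int = 10
    n_circ_per_gene: int = 1
    n_moebius: int = 2
    n_translated: int = 5
    read_len: int = 100
    circ_read_depth: int = 5
    rpf_len: tuple[int, int] = (27, 32)
    rpf_depth: int = 8
    n_decoy_reads: int = 30
    n_decoy_rpfs: int = 12
    mutation_rate: float = 0.02
    anchor_len: int = 20
    min_overhang: int = 6
    flank_len: int = 150  # intergenic sequence on each side of a gene
    samples: dict[str, list[str]] = field(
        default_factory=lambda: {
            "GM": ["GM_1", "GM_2", "GM_3"],
            "DM": ["DM_1", "DM_2", "DM_3"],
        }
    )

    def validate(self) -> None:
        if self.exon_len[0] < 3:
            raise ConfigError("exon_len must allow at least one codon")
        if self.exon_len[0] < self.read_len:
            raise ConfigError(
                "minimum exon length must reach read_len so a back-splice read "
                "stays within the circle's terminal exons"
            )
        if self.read_len < 2 * self.anchor_len:
            raise ConfigError("read_len must be at least 2x anchor_len")
        if self.exons_per_gene[0] < 4:
            raise ConfigError("genes need >= 4 exons to host internal circles")
        if not (20 <= self.rpf_len[0] <= self.rpf_len[1] <= 40):
            raise ConfigError("rpf_len range must lie within [20, 40]")
        if self.n_moebius > self.n_circ_genes * self.n_circ_per_gene:
            raise ConfigError("more MOEBIUS circles requested than circles")
        if self.intron_len[0] < 8:
            raise ConfigError("introns need room for GT...AG signals")
        for v in (
            self.n_genes, self.n_circ_genes, self.n_translated,
            self.circ_read_depth, self.rpf_depth, self.n_decoy_reads,
        ):
            if v < 0:
                raise ConfigError("counts must be >= 0")


@dataclass
class PlantedCirc:
    circ_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int  # genomic span, 0-based half-open
    end: int
    exon_blocks: tuple[tuple[int, int], ...]  # transcript-ordered
    spliced_seq: str
    is_moebius: bool
    is_translated: bool
    known_start: bool
    junction_aa_pos: int | None = None
    corf_protein: str | None = None
    junction_peptide: str | None = None


@dataclass
class PlantedTruth:
    circs: list[PlantedCirc]
    junction_strings: dict[str, str]  # circ_id -> 20+20 nt junction string
    expected_peptides: list[str]
    transcript_seqs: dict[str, str]  # mature mRNA per transcript
    genome: dict[str, str]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def plant_moebius_circ(length_nt: int, seed: int) -> str:
    """A circular sequence whose wrapped frame 0 contains no stop codon.

    Starts with ATG and continues with random non-stop codons; because the
    length is a multiple of three the wrapped reading frame re-reads the same
    codons forever. Verified by an exhaustive codon scan of the doubled
    sequence.
    """
    if length_nt % 3 != 0:
        raise ValueError(f"length {length_nt} is not divisible by 3")
    if length_nt < 30:
        raise ValueError("length must be >= 30")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + list(rng.choice(_NONSTOP_CODONS, size=length_nt // 3 - 1))
    seq = "".join(codons)
    doubled = seq * 2
    assert all(
        doubled[i : i + 3] not in _corf.STOP_CODONS for i in range(0, len(doubled) - 2, 3)
    )
    return seq


def _build_gene(
    rng: np.random.Generator, cfg: FixtureConfig, gene_idx: int, hosts_circ: bool,
    circ_specs: list[dict],
):
    """One gene in transcript orientation plus its circle bookkeeping.

    ``circ_specs`` entries: {"run": (i, j), "moebius": bool}. Circles start at
    exon 1 (the CDS start) for the first spec; later specs (multiple circles
    per gene) start where the previous run ended + 1.
    """
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    need = 2 + sum(spec["run"][1] - spec["run"][0] + 1 for spec in circ_specs)
    if n_exons < need:
        n_exons = need
    exon_lens = [
        int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1)) for _ in range(n_exons)
    ]
    # adjust run lengths: MOEBIUS runs sum to a multiple of 3, others must not
    for spec in circ_specs:
        i, j = spec["run"]
        total = sum(exon_lens[i : j + 1])
        if spec["moebius"]:
            target = total - total % 3
            while target < cfg.read_len:  # circle must hold a whole read
                target += 3
            exon_lens[j] += target - total
        elif total % 3 == 0:
            exon_lens[j] += 1

    # transcript layout: exon 0 = 5'UTR, CDS from the start of exon 1 to an
    # in-frame stop near the transcript end
    tx_len = sum(exon_lens)
    cds_start_t = exon_lens[0]
    cds_len = ((tx_len - 3 - cds_start_t) // 3) * 3
    n_codons = cds_len // 3
    codons = ["ATG"] + list(rng.choice(_NONSTOP_CODONS, size=n_codons - 2)) + [
        str(rng.choice(_STOPS))
    ]
    utr5 = _random_seq(rng, cds_start_t)
    utr3 = _random_seq(rng, tx_len - cds_start_t - cds_len)
    transcript = utr5 + "".join(codons) + utr3
    assert len(transcript) == tx_len

    # split into exons, insert GT...AG introns
    exon_seqs = []
    off = 0
    exon_offsets_t = []
    for ln in exon_lens:
        exon_offsets_t.append(off)
        exon_seqs.append(transcript[off : off + ln])
        off += ln
    intron_seqs = [
        "GT" + _random_seq(rng, int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1)) - 4) + "AG"
        for _ in range(n_exons - 1)
    ]
    gene_parts = []
    gene_offsets = []  # exon offsets within the gene sequence
    pos = 0
    for k in range(n_exons):
        gene_offsets.append(pos)
        gene_parts.append(exon_seqs[k])
        pos += exon_lens[k]
        if k < n_exons - 1:
            gene_parts.append(intron_seqs[k])
            pos += len(intron_seqs[k])
    gene_seq = "".join(gene_parts)
    return {
        "gene_seq": gene_seq,
        "exon_lens": exon_lens,
        "gene_offsets": gene_offsets,
        "exon_offsets_t": exon_offsets_t,
        "cds_start_t": cds_start_t,
        "cds_len": cds_len,
        "transcript": transcript,
    }


def make_genome(
    config: FixtureConfig,
) -> tuple[list[SequenceRecord], list[TranscriptModel], PlantedTruth]:
    """Genome, annotation and planted truth; fully deterministic per seed."""
    config.validate()
    genome_records: list[SequenceRecord] = []
    models: list[TranscriptModel] = []
    circs: list[PlantedCirc] = []
    transcript_seqs: dict[str, str] = {}
    genome: dict[str, str] = {}

    circ_counter = 0
    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1:03d}"
        tid = f"tx_{g + 1:03d}"
        chrom = f"chr{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        hosts = g < config.n_circ_genes
        # A gene hosting a translated circle must actually yield a detectable
        # junction peptide (novel, >= MIN_PLANTED_PEPTIDE_LEN aa); the gene is
        # resampled from its own seed substream until it does.
        for attempt in range(_MAX_GENE_ATTEMPTS):
            result = _build_gene_bundle(
                config, g, gene_id, tid, chrom, strand, hosts, circ_counter, attempt
            )
            if result is not None:
                break
        else:
            raise ConfigError(
                f"could not plant a detectable junction peptide for {gene_id} "
                f"after {_MAX_GENE_ATTEMPTS} attempts"
            )
        chrom_seq, model, transcript, gene_circs = result
        genome[chrom] = chrom_seq
        genome_records.append(SequenceRecord(chrom, chrom_seq, f"synthetic {gene_id}"))
        models.append(model)
        transcript_seqs[tid] = transcript
        circs.extend(gene_circs)
        circ_counter += len(gene_circs)

    junction_strings = {
        c.circ_id: c.spliced_seq[-20:] + c.spliced_seq[:20] for c in circs
    }
    expected_peptides = [
        c.junction_peptide for c in circs if c.is_translated and c.junction_peptide
    ]
    truth = PlantedTruth(
        circs=circs,
        junction_strings=junction_strings,
        expected_peptides=expected_peptides,
        transcript_seqs=transcript_seqs,
        genome=genome,
    )
    _log.info(
        "planted %d circRNAs (%d MOEBIUS, %d translated) across %d genes",
        len(circs), config.n_moebius, config.n_translated, config.n_genes,
    )
    return genome_records, models, truth


_MAX_GENE_ATTEMPTS = 50


def _build_gene_bundle(
    config: FixtureConfig,
    g: int,
    gene_id: str,
    tid: str,
    chrom: str,
    strand: str,
    hosts: bool,
    circ_base: int,
    attempt: int,
):
    """One complete gene: chromosome sequence, model, circles with truth.

    Returns None when a translated circle fails to yield a detectable
    junction peptide, signalling the caller to resample.
    """
    rng = np.random.default_rng([config.seed, 0, g, attempt])
    specs: list[dict] = []
    if hosts:
        exon_cursor = 1
        for c in range(config.n_circ_per_gene):
            run_len = 1 if (circ_base + c) < config.n_moebius else int(
                rng.integers(1, 3)
            )
            specs.append(
                {
                    "run": (exon_cursor, exon_cursor + run_len - 1),
                    "moebius": (circ_base + c) < config.n_moebius,
                }
            )
            exon_cursor += run_len
    built = _build_gene(rng, config, g, hosts, specs)

    flank5 = _random_seq(rng, config.flank_len)
    flank3 = _random_seq(rng, config.flank_len)
    glen = len(built["gene_seq"])
    if strand == "+":
        chrom_seq = flank5 + built["gene_seq"] + flank3
        exon_iv = [
            (config.flank_len + o, config.flank_len + o + ln)
            for o, ln in zip(built["gene_offsets"], built["exon_lens"])
        ]
    else:
        chrom_seq = flank5 + revcomp(built["gene_seq"]) + flank3
        exon_iv = [
            (
                config.flank_len + glen - (o + ln),
                config.flank_len + glen - o,
            )
            for o, ln in zip(built["gene_offsets"], built["exon_lens"])
        ]

    # exon_iv index k is transcript exon k (genomic interval), regardless of
    # strand; map transcript offsets exon-by-exon
    tx_blocks = exon_iv

    def t2g(t_off: int) -> int:
        for k, (ln, o) in enumerate(zip(built["exon_lens"], built["exon_offsets_t"])):
            if o <= t_off < o + ln:
                s, e = tx_blocks[k]
                return s + (t_off - o) if strand == "+" else e - 1 - (t_off - o)
        raise ValueError("offset not exonic")

    cds_start_g = t2g(built["cds_start_t"])
    cds_end_g = t2g(built["cds_start_t"] + built["cds_len"] - 1)
    model = TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(sorted(tx_blocks)),
        cds_start=cds_start_g,
        cds_end=cds_end_g,
    )

    cds = built["transcript"][
        built["cds_start_t"] : built["cds_start_t"] + built["cds_len"]
    ]
    host_protein = _corf.translate(cds).rstrip("*")

    gene_circs: list[PlantedCirc] = []
    for local, spec in enumerate(specs):
        i, j = spec["run"]
        blocks = tuple(tx_blocks[i : j + 1])
        lo = min(s for s, _ in blocks)
        hi = max(e for _, e in blocks)
        t_lo = built["exon_offsets_t"][i]
        t_hi = built["exon_offsets_t"][j] + built["exon_lens"][j]
        spliced = built["transcript"][t_lo:t_hi]
        idx = circ_base + local
        circ = PlantedCirc(
            circ_id=f"planted_{idx + 1:03d}",
            gene_id=gene_id,
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            start=lo,
            end=hi,
            exon_blocks=blocks,
            spliced_seq=spliced,
            is_moebius=spec["moebius"],
            is_translated=idx < config.n_translated,
            known_start=(i == 1),
        )
        peptide_ok = _attach_corf_truth(circ, [host_protein])
        if circ.is_translated and not peptide_ok:
            return None  # resample this gene
        gene_circs.append(circ)
    return chrom_seq, model, built["transcript"], gene_circs


MIN_PLANTED_PEPTIDE_LEN = 7  # below ~7 aa a tryptic peptide is rarely unique
PLANTED_MISSED_CLEAVAGES = 2  # the usual MS search allowance


def _attach_corf_truth(circ: PlantedCirc, proteome_seqs: list[str]) -> bool:
    """Record the expected junction-crossing ORF product and tryptic peptide.

    The ORF is chosen exactly as the discovery side does (highest score, then
    longest, then 5'-most). The planted peptide is the shortest junction-
    spanning digestion product (up to the usual missed-cleavage allowance)
    that is at least MIN_PLANTED_PEPTIDE_LEN residues and absent from the
    linear proteome — the peptides an MS search could actually attribute to
    the circle.
    """
    L = len(circ.spliced_seq)
    orfs = _corf.find_junction_orfs(
        _corf.concatenate_4x(circ.spliced_seq), L, circ_id=circ.circ_id
    )
    scored = []
    for orf in orfs:
        if orf.junction_aa_pos is None:
            continue
        attrs = _corf.classify_corf(orf, L)
        k = 1 if circ.known_start and orf.start_idx % L == 0 else 0
        s = _corf.score_corf(k, int(attrs.head_to_tail), int(attrs.moebius), orf.len_aa)
        scored.append((s, orf.len_aa, -orf.start_idx, orf, attrs))
    if not scored:
        return False
    _, _, _, best, attrs = max(scored, key=lambda t: t[:3])
    protein, _ = _pep.database_protein(best.protein_seq, attrs.moebius, L // 3)
    if best.junction_aa_pos >= len(protein):
        return False
    circ.junction_aa_pos = best.junction_aa_pos
    circ.corf_protein = protein
    candidates = sorted(
        _pep.junction_spanning_peptides(
            protein, best.junction_aa_pos, PLANTED_MISSED_CLEAVAGES
        ),
        key=lambda p: (len(p.seq), p.start),
    )
    for pep in candidates:
        if len(pep.seq) >= MIN_PLANTED_PEPTIDE_LEN and not any(
            pep.seq in prot for prot in proteome_seqs
        ):
            circ.junction_peptide = pep.seq
            return True
    if candidates:
        # acceptable for untranslated circles; translated genes are resampled
        circ.junction_peptide = candidates[-1].seq
    return False


def _occurs_linear(seq: str, truth: PlantedTruth) -> bool:
    """Exact occurrence of a read in the linear transcriptome or genome."""
    return any(seq in tx for tx in truth.transcript_seqs.values()) or any(
        seq in chrom for chrom in truth.genome.values()
    )


def _mutate(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(n_sites, len(seq)), replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(out)


def simulate_backsplice_reads(
    truth: PlantedTruth, config: FixtureConfig
) -> dict[str, list[SequenceRecord]]:
    """Per-sample circRNA-seq reads: junction reads + linear/mutated decoys.

    Each planted junction yields ``circ_read_depth`` reads per sample whose
    sequence crosses the back-splice point; the split offset keeps at least
    ``anchor_len`` bases on each side and each half within the circle's
    terminal exon, so the read reconstructs as exactly two genomic segments.
    Decoys are contiguous mature-mRNA fragments (linear reads) and
    point-mutated junction reads.
    """
    config.validate()
    R = config.read_len
    out: dict[str, list[SequenceRecord]] = {}
    all_samples = [s for ss in config.samples.values() for s in ss]
    for s_idx, sample in enumerate(all_samples):
        rng = np.random.default_rng([config.seed, 1, s_idx])
        reads: list[SequenceRecord] = []
        for circ in truth.circs:
            S = circ.spliced_seq
            L = len(S)
            if L < R:
                raise ConfigError(
                    f"planted circle {circ.circ_id} shorter than read_len"
                )
            first_len = circ.exon_blocks[0][1] - circ.exon_blocks[0][0]
            last_len = circ.exon_blocks[-1][1] - circ.exon_blocks[-1][0]
            a_lo = max(config.anchor_len, R - first_len)
            a_hi = min(R - config.anchor_len, last_len)
            if a_lo > a_hi:
                raise ConfigError(
                    f"no feasible junction offset for {circ.circ_id}: "
                    "terminal exons shorter than required read halves"
                )
            for d in range(config.circ_read_depth):
                a = int(rng.integers(a_lo, a_hi + 1))
                seq = S[L - a :] + S[: R - a]
                reads.append(
                    SequenceRecord(
                        f"{sample}|bsj|{circ.circ_id}|{d}|off{a}", seq,
                        f"junction read of {circ.circ_id}",
                    )
                )
        # linear decoys from mature transcripts
        tids = sorted(truth.transcript_seqs)
        for d in range(config.n_decoy_reads):
            tid = tids[int(rng.integers(len(tids)))]
            tx = truth.transcript_seqs[tid]
            if len(tx) <= R:
                continue
            p = int(rng.integers(0, len(tx) - R))
            reads.append(
                SequenceRecord(f"{sample}|linear|{tid}|{d}", tx[p : p + R],
                               "linear mRNA decoy")
            )
        # mutated junction decoys
        n_mut = max(1, int(round(config.mutation_rate * R)))
        for d, circ in enumerate(truth.circs[: max(1, len(truth.circs) // 2)]):
            S = circ.spliced_seq
            a = R // 2
            seq = _mutate(rng, S[len(S) - a :] + S[: R - a], n_mut)
            reads.append(
                SequenceRecord(f"{sample}|mutdecoy|{circ.circ_id}|{d}", seq,
                               "point-mutated junction decoy")
            )
        out[sample] = reads
    return out


def simulate_rpf_reads(
    truth: PlantedTruth, config: FixtureConfig
) -> dict[str, list[SequenceRecord]]:
    """Per-sample ribosome-protected fragments.

    Translated circles get ``rpf_depth`` junction-crossing footprints with
    lengths uniform in ``rpf_len`` and at least ``min_overhang`` bases on
    each side of the back-splice point; decoys are off-junction transcript
    fragments, out-of-length-range fragments, and point-mutated junction
    footprints (exercising the zero-mismatch rule).
    """
    config.validate()
    out: dict[str, list[SequenceRecord]] = {}
    all_samples = [s for ss in config.samples.values() for s in ss]
    translated = [c for c in truth.circs if c.is_translated]
    for s_idx, sample in enumerate(all_samples):
        rng = np.random.default_rng([config.seed, 2, s_idx])
        reads: list[SequenceRecord] = []
        for circ in translated:
            S = circ.spliced_seq
            L = len(S)
            for d in range(config.rpf_depth):
                # a footprint whose short overhang happens to match the host
                # mRNA past the junction is linear-indistinguishable and would
                # rightly be rejected downstream; redraw such offsets
                for _ in range(30):
                    n = int(rng.integers(config.rpf_len[0], config.rpf_len[1] + 1))
                    a = int(
                        rng.integers(config.min_overhang, n - config.min_overhang + 1)
                    )
                    seq = (S * 2)[L - a : L - a + n]
                    if not _occurs_linear(seq, truth):
                        break
                else:
                    _log.warning(
                        "%s: every drawn footprint occurs in the linear "
                        "transcriptome; emitting the last one", circ.circ_id,
                    )
                reads.append(
                    SequenceRecord(f"{sample}|rpf|{circ.circ_id}|{d}|len{n}", seq,
                                   f"junction RPF of {circ.circ_id}")
                )
        tids = sorted(truth.transcript_seqs)
        for d in range(config.n_decoy_rpfs):
            tid = tids[int(rng.integers(len(tids)))]
            tx = truth.transcript_seqs[tid]
            n = int(rng.integers(config.rpf_len[0], config.rpf_len[1] + 1))
            p = int(rng.integers(0, len(tx) - n))
            reads.append(
                SequenceRecord(f"{sample}|rpfdecoy|{tid}|{d}", tx[p : p + n],
                               "off-junction RPF decoy")
            )
        # out-of-range lengths flanking the retention window
        for d, n in enumerate((config.rpf_len[0] - 1, config.rpf_len[1] + 1)):
            tid = tids[int(rng.integers(len(tids)))]
            tx = truth.transcript_seqs[tid]
            p = int(rng.integers(0, len(tx) - n))
            reads.append(
                SequenceRecord(f"{sample}|rpflen|{d}|len{n}", tx[p : p + n],
                               "length-window RPF decoy")
            )
        # mutated junction footprints
        for d, circ in enumerate(translated):
            S = circ.spliced_seq
            n = config.rpf_len[1]
            a = n // 2
            seq = _mutate(rng, (S * 2)[len(S) - a : len(S) - a + n], 1)
            reads.append(
                SequenceRecord(f"{sample}|rpfmut|{circ.circ_id}|{d}", seq,
                               "point-mutated junction RPF decoy")
            )
        out[sample] = reads
    return out


def make_proteome(
    models: list[TranscriptModel], genome: dict[str, str] | list[SequenceRecord]
) -> list[SequenceRecord]:
    """One translated protein per CDS-bearing transcript (stops trimmed).

    A CDS whose length is not a multiple of three is truncated to the last
    complete codon with a warning.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r.seq for r in genome}
    from .io import extract_transcript_seq

    proteins: list[SequenceRecord] = []
    for m in models:
        if m.cds_start is None or m.cds_end is None:
            continue
        tx = extract_transcript_seq(m, genome)
        t_start = _tx_offset(m, m.cds_start)
        t_end = _tx_offset(m, m.cds_end)
        cds = tx[t_start : t_end + 1]
        if len(cds) % 3:
            _log.warning(
                "CDS of %s has length %d not divisible by 3; truncating",
                m.transcript_id, len(cds),
            )
            cds = cds[: len(cds) - len(cds) % 3]
        prot = _corf.translate(cds).rstrip("*")
        if prot:
            proteins.append(
                SequenceRecord(f"prot_{m.transcript_id}", prot,
                               f"translation of {m.transcript_id}")
            )
    return proteins


def _tx_offset(m: TranscriptModel, g: int) -> int:
    off = 0
    exons = m.exons if m.strand == "+" else tuple(reversed(m.exons))
    for s, e in exons:
        if s <= g < e:
            return off + (g - s if m.strand == "+" else e - 1 - g)
        off += e - s
    raise ValueError(f"genomic position {g} not exonic in {m.transcript_id}")
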