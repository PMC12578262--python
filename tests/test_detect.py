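"""Back-splice detection: anchors, head-to-tail calling, collapsing, origin."""

import random

import pytest

from circorf.detect import (
    GenomeIndex,
    call_backsplice,
    classify_origin,
    collapse_candidates,
    expression_table,
    extract_anchors,
    spliced_sequence,
)
from circorf.io import SequenceRecord, TranscriptModel, revcomp


@pytest.fixture(scope="module")
def detected(bundle, bs_reads):
    """All candidates from every sample's reads, splice check enforced."""
    index = GenomeIndex(bundle.genome, 20)
    cands = {}
    for sample, reads in bs_reads.items():
        cands[sample] = [
            c
            for r in reads
            if (c := call_backsplice(r, index, bundle.genome)) is not None
        ]
    return index, cands


class TestGenomeIndex:
    def test_unique_kmer_single_hit(self):
        idx = GenomeIndex({"c": "ACGTACGTTTGCAGGCATTA"}, 12)
        assert idx.query("ACGTACGTTTGC") == [("c", 0, "+")]

    def test_absent_kmer_empty(self):
        idx = GenomeIndex({"c": "ACGTACGTTTGCAGGCATTA"}, 12)
        assert idx.query("A" * 12) == []

    def test_palindromic_kmer_hits_both_strands_vs_brute_force(self):
        rng = random.Random(4)
        genome = "".join(rng.choice("ACGT") for _ in range(60))
        pal = "GAATTC"  # revcomp(GAATTC) == GAATTC
        genome = genome[:20] + pal + genome[26:]
        idx = GenomeIndex({"c": genome}, 6)
        hits = idx.query(pal)
        fwd = [i for i in range(55) if genome[i : i + 6] == pal]
        rev = [i for i in range(55) if revcomp(genome[i : i + 6]) == pal]
        assert sorted(hits) == sorted(
            [("c", i, "+") for i in fwd] + [("c", i, "-") for i in rev]
        )
        assert {s for _, _, s in hits} == {"+", "-"}

    def test_k_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            GenomeIndex({"c": "ACGT"}, 5)


class TestAnchors:
    def test_hundred_nt_read_yields_20mers(self):
        read = SequenceRecord("r", "A" * 100)
        pair = extract_anchors(read)
        assert pair.left_anchor == "A" * 20 and pair.right_anchor == "A" * 20

    def test_forty_nt_read_partitions_exactly(self):
        read = SequenceRecord("r", "ACGT" * 10)
        pair = extract_anchors(read, 20)
        assert pair.left_anchor + pair.right_anchor == read.seq

    def test_short_read_skipped(self):
        assert extract_anchors(SequenceRecord("r", "A" * 39), 20) is None


class TestCallBacksplice:
    def test_planted_reads_recover_exact_coordinates(self, bundle, detected):
        _, cands = detected
        planted = {
            (c.chrom, c.strand, c.start, c.end - 1): c.circ_id
            for c in bundle.truth.circs
        }
        n_junction = 0
        for sample, cc in cands.items():
            for cand in cc:
                key = (cand.chrom, cand.strand, cand.acceptor_pos, cand.donor_pos)
                assert key in planted, f"false positive call from {cand.read_id}"
                n_junction += 1
        # every junction read of every sample was recovered (100% recall)
        expected = (
            len(bundle.truth.circs)
            * bundle.config.circ_read_depth
            * sum(len(s) for s in bundle.config.samples.values())
        )
        assert n_junction == expected

    def test_linear_decoys_yield_no_call(self, bundle, bs_reads, detected):
        index, _ = detected
        linear = [r for r in bs_reads["GM_1"] if "|linear|" in r.id]
        assert linear
        for read in linear:
            assert call_backsplice(read, index, bundle.genome) is None

    def test_reconstruction_identity(self, bundle, detected):
        # genome segments at the breakpoint re-concatenate to the read exactly
        _, cands = detected
        for cand in cands["GM_2"]:
            chrom = bundle.genome[cand.chrom]
            n = len(cand.read_seq)
            b = cand.breakpoint_offset
            oriented = cand.read_seq if cand.strand == "+" else revcomp(cand.read_seq)
            left = chrom[cand.donor_pos + 1 - b : cand.donor_pos + 1]
            right = chrom[cand.acceptor_pos : cand.acceptor_pos + n - b]
            assert left + right == oriented

    def test_splice_flank_mutation_drops_or_flags(self, bundle, bs_reads):
        # mutate the GT donor flank of one planted circle to CC and re-call
        circ = next(c for c in bundle.truth.circs if c.strand == "+")
        genome = dict(bundle.genome)
        chrom = genome[circ.chrom]
        genome[circ.chrom] = chrom[: circ.end] + "CC" + chrom[circ.end + 2 :]
        index = GenomeIndex(genome, 20)
        read = next(
            r for r in bs_reads["GM_1"] if f"|bsj|{circ.circ_id}|" in r.id
        )
        assert call_backsplice(read, index, genome, splice_check="enforce") is None
        cand = call_backsplice(read, index, genome, splice_check="report")
        assert cand is not None and cand.splice_signal_ok is False

    def test_mutated_junction_decoys_rejected(self, bundle, bs_reads, detected):
        _, cands = detected
        for cc in cands.values():
            assert all("|mutdecoy|" not in c.read_id for c in cc)


class TestCollapse:
    def _cand(self, read_id, seq, acc=100, donor=400):
        from circorf.detect import BackspliceCandidate

        return BackspliceCandidate(
            chrom="c", strand="+", acceptor_pos=acc, donor_pos=donor,
            read_id=read_id, read_seq=seq, breakpoint_offset=30,
            splice_signal_ok=True,
        )

    def test_two_unique_reads_retained_one_not(self):
        two = [self._cand("r1", "AAAA"), self._cand("r2", "CCCC")]
        assert len(collapse_candidates(two)) == 1
        one = [self._cand("r1", "AAAA")]
        assert collapse_candidates(one) == []

    def test_duplicate_sequences_count_once(self):
        cands = [
            self._cand("r1", "AAAA"),
            self._cand("r2", "AAAA"),  # PCR duplicate of r1
            self._cand("r3", "CCCC"),
        ]
        (call,) = collapse_candidates(cands)
        assert call.n_unique_reads == 2
        assert call.supporting_read_ids == ("r1", "r2", "r3")

    def test_idempotent_and_order_independent(self):
        cands = [
            self._cand("r1", "AAAA"),
            self._cand("r2", "CCCC"),
            self._cand("r3", "GGGG", acc=10, donor=50),
        ]
        a = collapse_candidates(cands)
        b = collapse_candidates(list(reversed(cands)))
        assert [(c.start, c.end, c.n_unique_reads) for c in a] == [
            (c.start, c.end, c.n_unique_reads) for c in b
        ]

    def test_raising_min_support_never_adds_calls(self, detected):
        _, cands = detected
        flat = [c for cc in cands.values() for c in cc]
        sizes = [len(collapse_candidates(flat, ms)) for ms in (1, 2, 5, 50)]
        assert sizes == sorted(sizes, reverse=True)


TOY_GENOME = {"t": "AG" + "ACGTTGCA" * 30 + "GT"}


def _toy_model(strand="+", exons=((20, 60), (100, 140), (180, 220)),
               cds_start=100, cds_end=210):
    return TranscriptModel("tx", "gene_t", "t", strand, exons, cds_start, cds_end)


class TestClassifyOrigin:
    def _call(self, start, end, strand="+"):
        from circorf.detect import CircRNACall

        return CircRNACall(
            circ_id="x", chrom="t", strand=strand, start=start, end=end,
            supporting_read_ids=("r",), n_unique_reads=2,
        )

    def test_exact_exon_run_inside_cds_is_exon(self, bundle, bs_reads):
        # planted circles span CDS-only exon runs
        for c in bundle.truth.circs[:3]:
            call = self._call(c.start, c.end, c.strand)
            call.chrom = c.chrom
            classify_origin(call, bundle.models)
            assert call.origin_category == "exon"
            assert call.host_gene_id == c.gene_id

    def test_fully_intronic_same_strand(self):
        call = self._call(65, 95)
        classify_origin(call, [_toy_model()])
        assert call.origin_category == "intron"
        assert call.host_gene_id == "gene_t"

    def test_partially_exonic_is_exon_intron(self):
        call = self._call(40, 120)
        classify_origin(call, [_toy_model()])
        assert call.origin_category == "exon-intron"

    def test_opposite_strand_overlap_is_antisense(self):
        call = self._call(30, 130, strand="-")
        classify_origin(call, [_toy_model("+")])
        assert call.origin_category == "antisense"
        assert call.host_gene_id is None

    def test_no_overlap_is_intergenic(self):
        call = self._call(230, 240)
        classify_origin(call, [_toy_model()])
        assert call.origin_category == "intergenic"

    def test_utr_sublabels(self):
        # CDS confined to the last exon: a first-exon circle is pure 5'UTR,
        # a two-exon circle crossing into the CDS is CDS-5'UTR
        m = _toy_model(cds_start=180, cds_end=219)
        call = self._call(20, 60)
        classify_origin(call, [m])
        assert call.origin_category == "5'UTR"
        call2 = self._call(100, 220)
        classify_origin(call2, [m])
        assert call2.origin_category == "CDS-5'UTR"


class TestSplicedSequence:
    def test_exon_join_used_for_annotated_runs(self, bundle):
        c = bundle.truth.circs[0]
        from circorf.detect import CircRNACall

        call = CircRNACall(
            circ_id="x", chrom=c.chrom, strand=c.strand, start=c.start,
            end=c.end, supporting_read_ids=("r",), n_unique_reads=2,
        )
        spliced_sequence(call, bundle.genome, bundle.models)
        assert call.spliced_seq == c.spliced_seq
        assert call.exon_blocks == c.exon_blocks

    def test_genomic_span_fallback(self, bundle):
        from circorf.detect import CircRNACall

        call = CircRNACall(
            circ_id="x", chrom="chr1", strand="+", start=5, end=25,
            supporting_read_ids=("r",), n_unique_reads=2,
        )
        spliced_sequence(call, bundle.genome, bundle.models)
        assert call.spliced_seq == bundle.genome["chr1"][5:25]


class TestExpressionTable:
    GROUPS = {"GM": ["GM_1", "GM_2"], "DM": ["DM_1", "DM_2"]}

    def test_fold_change_two_is_flagged(self):
        counts = {"c1": {"GM_1": 4, "GM_2": 4, "DM_1": 8, "DM_2": 8}}
        df = expression_table(counts, self.GROUPS, pseudocount=0)
        row = df.iloc[0]
        assert row.fold_change == 2 and bool(row.is_fc_candidate)

    def test_identical_counts_unflagged(self):
        counts = {"c1": {s: 5 for ss in self.GROUPS.values() for s in ss}}
        row = expression_table(counts, self.GROUPS, pseudocount=0).iloc[0]
        assert row.fold_change == 1 and not row.is_fc_candidate

    def test_pseudocount_rescues_zero_group(self):
        counts = {"c1": {"GM_1": 0, "GM_2": 0, "DM_1": 3, "DM_2": 3}}
        row = expression_table(counts, self.GROUPS, pseudocount=0.5).iloc[0]
        assert row.fold_change == pytest.approx(7.0)
        assert bool(row.is_fc_candidate)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            expression_table({}, {"GM": [], "DM": ["DM_1"]})
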