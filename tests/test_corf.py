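"""Circular ORF search, MOEBIUS detection, scoring and attributes."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circorf.corf import (
    STOP_CODONS,
    CircularOrf,
    classify_corf,
    concatenate_4x,
    find_junction_orfs,
    is_moebius,
    known_start,
    score_corf,
    translate,
)
from circorf.detect import CircRNACall


# --- independent brute-force oracle ---------------------------------------


def brute_force_junction_orfs(circ_seq: str) -> dict[int, tuple[int, int]]:
    """Naive enumerator: every ATG start on the 4x sequence, walked codon by
    codon, filtered for junction coverage; longest (then 5'-most) per frame.

    Returns frame -> (start, end) with end including the stop codon.
    """
    L = len(circ_seq)
    s4 = circ_seq * 4
    best: dict[int, tuple[int, int]] = {}
    for start in range(len(s4) - 2):
        if s4[start : start + 3] != "ATG":
            continue
        end = None
        has_stop = False
        p = start
        while p + 3 <= len(s4):
            if s4[p : p + 3] in STOP_CODONS:
                end = p + 3
                has_stop = True
                break
            p += 3
        if end is None:
            end = p
        if not any(start < m * L < end for m in (1, 2, 3)):
            continue
        n_aa = (end - start) // 3 - (1 if has_stop else 0)
        frame = start % 3
        cur = best.get(frame)
        if cur is None:
            best[frame] = (start, end)
        else:
            cur_aa = (cur[1] - cur[0]) // 3 - (
                1 if s4[cur[1] - 3 : cur[1]] in STOP_CODONS else 0
            )
            if (n_aa, -start) > (cur_aa, -cur[0]):
                best[frame] = (start, end)
    return best


def _random_circ(rng: random.Random, lo=6, hi=60) -> str:
    return "".join(rng.choice("ACGT") for _ in range(rng.randrange(lo, hi + 1)))


class TestFindJunctionOrfs:
    def test_matches_brute_force_oracle_on_small_circles(self):
        rng = random.Random(17)
        n_with_orfs = 0
        for _ in range(300):
            circ = _random_circ(rng)
            L = len(circ)
            got = {
                o.frame: (o.start_idx, o.end_idx)
                for o in find_junction_orfs(concatenate_4x(circ), L)
                if o.start_codon is not None  # oracle enumerates ATG starts only
            }
            assert got == brute_force_junction_orfs(circ), circ
            n_with_orfs += bool(got)
        assert n_with_orfs > 50  # the comparison was not vacuous

    def test_short_orf_terminating_before_junction_excluded(self):
        # frame-0 ORF of ATGAAATAG stops at its own junction-free period
        orfs = find_junction_orfs(concatenate_4x("ATGAAATAG"), 9)
        assert all(o.frame != 0 or o.start_codon is None for o in orfs)
        assert all(o.spans_junction for o in orfs)

    def test_planted_fixture_orf_crosses_junction_at_truth_position(self, bundle):
        for c in bundle.truth.circs:
            if c.junction_aa_pos is None:
                continue
            L = len(c.spliced_seq)
            orfs = find_junction_orfs(concatenate_4x(c.spliced_seq), L)
            assert any(o.junction_aa_pos == c.junction_aa_pos for o in orfs)

    def test_moebius_fixture_orf_runs_to_concatenation_end(self, bundle):
        c = next(c for c in bundle.truth.circs if c.is_moebius)
        L = len(c.spliced_seq)
        orfs = find_junction_orfs(concatenate_4x(c.spliced_seq), L)
        frame0 = next(o for o in orfs if o.frame == 0)
        assert frame0.has_stop is False
        assert frame0.end_idx == 4 * L

    def test_stop_free_frame_without_atg_still_reported(self):
        # 30-nt stop-free circle in every frame, ATG removed
        circ = ("GGC" * 10)
        orfs = find_junction_orfs(concatenate_4x(circ), 30)
        assert orfs and all(o.start_codon is None for o in orfs)
        assert all(not o.has_stop for o in orfs)

    def test_protein_matches_translation_of_reported_span(self, bundle):
        for c in bundle.truth.circs[:4]:
            L = len(c.spliced_seq)
            s4 = concatenate_4x(c.spliced_seq)
            for o in find_junction_orfs(s4, L):
                coding_end = o.end_idx - 3 if o.has_stop else o.end_idx
                assert o.protein_seq == translate(s4[o.start_idx : coding_end])


class TestConcatenate4x:
    def test_typical_exonic_circle_scale(self):
        # a 539-nt three-exon circle yields a 2156-nt search sequence
        assert len(concatenate_4x("A" * 539)) == 2156

    def test_small_example(self):
        assert concatenate_4x("ACG") == "ACGACGACGACG"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            concatenate_4x("")
        with pytest.raises(ValueError):
            concatenate_4x("ACGN")


class TestIsMoebius:
    def test_multiple_of_three_stop_free(self):
        from circorf.simulate import plant_moebius_circ

        flag, frame = is_moebius(plant_moebius_circ(1041, seed=2))
        assert flag and frame == 0

    def test_non_multiple_of_three_always_false(self):
        rng = random.Random(9)
        seq = "".join(rng.choice("ACGT") for _ in range(539))
        assert is_moebius(seq) == (False, None)

    def test_stop_in_every_frame(self):
        # frame 0: AAT GAA TGA; frame 1: ATG AAT GAG TGA; frame 2 wraps
        # straight into TGA — every circular frame terminates
        assert is_moebius("AATGAATGAGTG") == (False, None)

    def test_single_stop_free_frame_suffices(self):
        # TAA TAA TAA in frame 0, but circular frame 1 reads AAT forever
        assert is_moebius("TAATAATAA") == (True, 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 59))
    def test_rotation_invariance(self, seed, k):
        rng = random.Random(seed)
        n = 3 * rng.randrange(4, 20)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        rotated = seq[k % n :] + seq[: k % n]
        assert is_moebius(seq)[0] == is_moebius(rotated)[0]


class TestScore:
    def test_known_start_coefficient(self):
        assert score_corf(1, 0, 0, 50) == 100.0

    def test_head_to_tail_coefficient(self):
        assert score_corf(0, 1, 0, 50) == 1000.0

    def test_all_flags_zero(self):
        assert score_corf(0, 0, 0, 999) == 0.0

    def test_moebius_length_term(self):
        assert score_corf(1, 1, 1, 1_010_000) == pytest.approx(1101.0)

    def test_length_term_gated_by_moebius_in_printed_parse(self):
        assert score_corf(0, 0, 0, 1_010_000) == 0.0
        assert score_corf(0, 0, 0, 1_010_000, variant="additive_len") == pytest.approx(1.0)

    def test_non_binary_flag_rejected(self):
        with pytest.raises(ValueError):
            score_corf(2, 0, 0, 10)

    def test_monotone_in_flags_and_moebius_length(self):
        base = score_corf(0, 0, 0, 10)
        assert score_corf(1, 0, 0, 10) > base
        assert score_corf(0, 1, 0, 10) > base
        assert score_corf(0, 0, 1, 10) >= base
        assert score_corf(0, 0, 1, 20) > score_corf(0, 0, 1, 10)


def _orf(len_aa, spans=True, has_stop=True, start=0, end=None):
    end = end if end is not None else start + 3 * (len_aa + int(has_stop))
    return CircularOrf(
        circ_id="c", frame=start % 3, start_idx=start, end_idx=end,
        len_aa=len_aa, spans_junction=spans, start_codon="ATG",
        has_stop=has_stop, protein_seq="M" * len_aa, junction_aa_pos=1,
    )


class TestClassify:
    def test_99_aa_is_micropeptide_100_is_not(self):
        a = classify_corf(_orf(99), circ_len=500)
        b = classify_corf(_orf(100), circ_len=500)
        assert a.micropeptide and a.head_to_tail
        assert not b.micropeptide

    def test_moebius_primary_label(self):
        orf = _orf(40, has_stop=False, start=0, end=120)
        attrs = classify_corf(orf, circ_len=30)
        assert attrs.moebius and attrs.primary_label == "MOEBIUS"

    def test_complete_requires_full_circle_coverage(self):
        covers = classify_corf(_orf(20, start=0), circ_len=60)
        assert covers.complete
        partial = classify_corf(_orf(10, start=0), circ_len=60)
        assert not partial.complete


class TestKnownStart:
    def _call(self, c):
        return CircRNACall(
            circ_id=c.circ_id, chrom=c.chrom, strand=c.strand, start=c.start,
            end=c.end, supporting_read_ids=("r",), n_unique_reads=2,
            exon_blocks=c.exon_blocks, host_gene_id=c.gene_id,
        )

    def test_orf_at_circ_start_on_cds_start_scores_one(self, bundle):
        # planted circles begin exactly at the host's annotated start codon
        for c in bundle.truth.circs[:4]:
            L = len(c.spliced_seq)
            orfs = find_junction_orfs(concatenate_4x(c.spliced_seq), L)
            frame0 = next(o for o in orfs if o.start_idx % L == 0)
            assert known_start(frame0, self._call(c), bundle.models) == 1

    def test_shifted_start_scores_zero(self, bundle):
        c = bundle.truth.circs[0]
        L = len(c.spliced_seq)
        orfs = find_junction_orfs(concatenate_4x(c.spliced_seq), L)
        frame0 = next(o for o in orfs if o.start_idx % L == 0)
        shifted = CircularOrf(
            **{**frame0.__dict__, "start_idx": frame0.start_idx + 9}
        )
        assert known_start(shifted, self._call(c), bundle.models) == 0

    def test_intergenic_call_scores_zero(self, bundle):
        c = bundle.truth.circs[0]
        L = len(c.spliced_seq)
        orf = find_junction_orfs(concatenate_4x(c.spliced_seq), L)[0]
        call = self._call(c)
        call.host_gene_id = None
        assert known_start(orf, call, bundle.models) == 0
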