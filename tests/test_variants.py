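"""Affine-gap alignment, indel normalisation, variant calling, aggregation."""

import numpy as np
import pytest

import nickedit as ne
from nickedit import variants as V
from nickedit.errors import DataError
from oracles import glocal_affine_score, random_alignment_instance


class TestAlignToAmplicon:
    def test_exact_substring_scores_five_per_base(self, amplicon):
        read = amplicon.sequence[100:260]
        aln = ne.align_to_amplicon(read, amplicon)
        assert aln.score == 5 * len(read)
        assert [op.kind for op in aln.ops] == ["match"]

    def test_internal_three_base_deletion_cost(self, amplicon):
        # score = 5*(L-3) - (25 + 3*1) under cost(k) = open + k*extend
        read = amplicon.sequence[100:200] + amplicon.sequence[203:300]
        aln = ne.align_to_amplicon(read, amplicon)
        assert aln.score == 5 * len(read) - 28

    def test_empty_read_is_an_error(self, amplicon):
        with pytest.raises(DataError, match="empty"):
            ne.align_to_amplicon("", amplicon)

    def test_reconstruction_reproduces_read(self, amplicon):
        rng = np.random.default_rng(2)
        for _ in range(30):
            ref = amplicon.sequence
            lo = int(rng.integers(0, 300))
            read = list(ref[lo:lo + 200])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(5, len(read) - 5))
                r = rng.random()
                if r < 0.4:
                    read[p] = str(rng.choice(list("ACGT")))
                elif r < 0.7:
                    del read[p:p + int(rng.integers(1, 8))]
                else:
                    read[p:p] = rng.choice(list("ACGT"),
                                           size=int(rng.integers(1, 8))).tolist()
            read = "".join(read)
            aln = ne.align_to_amplicon(read, amplicon)
            assert aln.reconstruct(amplicon) == read
            norm = ne.normalize_ops(aln, amplicon)
            assert norm.reconstruct(amplicon) == read
            assert norm.score == aln.score

    def test_scores_match_bruteforce_dp_sample(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            ref, read = random_alignment_instance(rng, max_len=120)
            amp = ne.AmpliconRef("r", ref)
            aln = ne.align_to_amplicon(read, amp)
            assert aln.score == glocal_affine_score(ref, read)


class TestNormalizeOps:
    def test_ambiguous_deletion_reported_leftmost(self):
        # deleting any one ACT of the triple repeat gives the same read;
        # the normalised call must use the smallest reference start (20)
        ref = ne.AmpliconRef(
            "r", "GGCCGTTGAACCGGTTGGCA" + "ACTACTACT" + "TTGGCCAAGGTTCCGGAATTGGCCAA")
        read = ref.sequence[:23] + ref.sequence[26:]  # delete the middle ACT
        norm = ne.normalize_ops(ne.align_to_amplicon(read, ref), ref)
        dels = [op for op in norm.ops if op.kind == "deletion"]
        assert [(d.ref_start, d.length) for d in dels] == [(20, 3)]
        assert norm.reconstruct(ref) == read

    def test_homopolymer_single_deletion_leftmost(self):
        ref = ne.AmpliconRef("r", "CCGTTGGCAAAAATCGGATCGGCCATTGCCAGGACCATTGCA")
        run = ref.sequence.index("AAAAA")
        read = ref.sequence[:run + 2] + ref.sequence[run + 3:]
        norm = ne.normalize_ops(ne.align_to_amplicon(read, ref), ref)
        dels = [op for op in norm.ops if op.kind == "deletion"]
        assert [(d.ref_start, d.length) for d in dels] == [(run, 1)]

    def test_insertion_left_aligned(self):
        ref = ne.AmpliconRef("r", "GGCCATTGACGGTTCACCAGGTGGCCATTAACCAGGTTACCG")
        # insert "ACG" after the TGACG context: equivalent placements reach
        # back to reference position 7 (read ...ATT[GAC]GACG... == ...ATTGAC[GAC]G...)
        pos = ref.sequence.index("ACG", 5) + 3
        assert pos == 11
        read = ref.sequence[:pos] + "ACG" + ref.sequence[pos:]
        norm = ne.normalize_ops(ne.align_to_amplicon(read, ref), ref)
        ins = [op for op in norm.ops if op.kind == "insertion"]
        assert [(op.ref_start, op.seq) for op in ins] == [(7, "GAC")]
        assert norm.reconstruct(ref) == read

    def test_idempotent(self, amplicon):
        read = amplicon.sequence[100:200] + amplicon.sequence[210:300]
        once = ne.normalize_ops(ne.align_to_amplicon(read, amplicon), amplicon)
        twice = ne.normalize_ops(once, amplicon)
        assert once == twice


class TestCallVariant:
    def _aln(self, read, amplicon):
        return ne.normalize_ops(ne.align_to_amplicon(read, amplicon), amplicon)

    def test_exact_reference_read_is_unedited(self, amplicon):
        call = ne.call_variant(self._aln(amplicon.sequence[100:350], amplicon),
                               amplicon.quant_window)
        assert (call.vtype, call.edited) == ("none", False)

    def test_perfect_internick_deletion(self, amplicon, pair):
        n1, n2 = pair.nicks
        read = amplicon.sequence[n1 - 100:n1] + amplicon.sequence[n2:n2 + 100]
        call = ne.call_variant(self._aln(read, amplicon), amplicon.quant_window)
        assert call.vtype == "deletion"
        assert call.net_size == -pair.inter_nick_distance == -64
        assert call.edited

    def test_deletion_plus_insertion_is_complex(self, amplicon, pair):
        n1, n2 = pair.nicks
        seq = amplicon.sequence
        read = (seq[n1 - 80:n1 - 4] + seq[n1:n2] + "TTAACC" + seq[n2:n2 + 80])
        call = ne.call_variant(self._aln(read, amplicon), amplicon.quant_window)
        assert call.vtype == "complex"
        assert call.edited

    def test_substitutions_never_count_as_edits(self, amplicon, pair):
        n1 = pair.nicks[0]
        seq = list(amplicon.sequence[n1 - 100:n1 + 100])
        seq[100] = {"A": "C"}.get(seq[100], "A")
        call = ne.call_variant(self._aln("".join(seq), amplicon),
                               amplicon.quant_window)
        assert (call.vtype, call.edited) == ("none", False)

    def test_indel_outside_window_flagged_unedited(self, amplicon):
        lo = amplicon.quant_window[0]
        read = amplicon.sequence[lo - 240:lo - 140] + amplicon.sequence[lo - 135:lo - 40]
        call = ne.call_variant(self._aln(read, amplicon), amplicon.quant_window)
        assert not call.edited
        assert call.outside_window


class _Event:
    def __init__(self, left_bp, vstart, vend, strand="+"):
        self.left_bp, self.right_bp = left_bp, left_bp
        self.vstart, self.vend, self.strand = vstart, vend, strand


class TestAggregate:
    def test_textbook_frequencies(self):
        calls = ([("w%d" % i, ne.VariantCall("WT", "none", 0, None, False, False))
                  for i in range(50)]
                 + [("d%d" % i, ne.VariantCall("D10+5", "deletion", -5, 10, True,
                                               False, (V.Op("deletion", 10, 5),)))
                    for i in range(40)])
        events = [_Event(300, 0, 60) for _ in range(10)]
        table, rep = ne.aggregate(calls, events)
        assert rep.indel_frequency == 0.50
        assert rep.integration_frequency_reads == 0.10
        assert rep.integration_frequency_indels == 0.20
        vec_rows = table[table["type"] == "vector_insertion"]
        assert vec_rows["support"].sum() == 10

    def test_zero_chimeric_gives_zero_integration(self):
        calls = [("r", ne.VariantCall("WT", "none", 0, None, False, False))]
        _, rep = ne.aggregate(calls, [])
        assert rep.integration_frequency_reads == 0.0
        assert rep.integration_frequency_indels == 0.0

    def test_supports_sum_to_classified_reads(self, mix_bundle, tmp_path, run_pipeline_on):
        res = run_pipeline_on(mix_bundle, tmp_path / "out")
        assert res.variant_table["support"].sum() == res.summary.n_classified

    def test_denominator_identity(self, mix_bundle, tmp_path, run_pipeline_on):
        rep = run_pipeline_on(mix_bundle, tmp_path / "out").summary
        assert rep.integration_frequency_indels * rep.indel_frequency == \
            pytest.approx(rep.integration_frequency_reads)


class TestDeletionProfile:
    def test_wildtype_reads_give_zero_profile(self, amplicon):
        alns = [ne.align_to_amplicon(amplicon.sequence[s:s + 200], amplicon)
                for s in (0, 100, 200)]
        prof = ne.deletion_coverage_profile(alns, amplicon)
        covered = ~np.isnan(prof)
        assert covered.any()
        assert np.all(prof[covered] == 0.0)

    def test_pure_internick_deletion_profile_is_one_on_interval(self, amplicon, pair):
        n1, n2 = pair.nicks
        read = amplicon.sequence[n1 - 100:n1] + amplicon.sequence[n2:n2 + 100]
        alns = [ne.normalize_ops(ne.align_to_amplicon(read, amplicon), amplicon)
                for _ in range(5)]
        prof = ne.deletion_coverage_profile(alns, amplicon)
        assert np.all(prof[n1:n2] == 1.0)
        assert np.all(prof[n1 - 100:n1] == 0.0)
        assert np.all(prof[n2:n2 + 100] == 0.0)
        assert np.all(np.isnan(prof[:n1 - 100]))

    def test_uncovered_positions_are_missing(self, amplicon):
        prof = ne.deletion_coverage_profile([], amplicon)
        assert np.all(np.isnan(prof))
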