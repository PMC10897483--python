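"""Read preprocessing and amplicon/vector partitioning."""

import numpy as np
import pytest

import nickedit as ne
from nickedit import classify as C
from nickedit.errors import DataError
from nickedit.refio import revcomp


@pytest.fixture(scope="module")
def tools(vector):
    return C.build_vector_index(vector), C.make_local_aligner()


def _classify(seq, amplicon, vector, tools, **params):
    idx, la = tools
    return ne.classify_read("r", seq, amplicon, vector,
                            ne.ClassifyParams(**params), idx, la)


class TestPreprocess:
    def test_high_quality_read_unchanged(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\n" + "ACGT" * 20 + "\n+\n" + "I" * 80 + "\n")
        reads, log = ne.preprocess_reads(p, min_length=50)
        assert reads == [("r1", "ACGT" * 20)]
        assert log == {"input": 1, "passed": 1, "filtered_short": 0,
                       "unmerged_dropped": 0}

    def test_low_quality_tail_cut_at_first_failing_window(self):
        # quals 30x6 then 10x4; window 4, threshold 20:
        # windows starting at 0..4 average 30,30,30,25,20; the first window
        # below 20 starts at index 5 (30,10,10,10 -> 15), so keep 5 bases
        quals = [30] * 6 + [10] * 4
        cut = C.sliding_window_trim("ACGTACGTAC", quals, threshold=20, window=4)
        assert cut == 5

    def test_reads_trimmed_below_min_length_are_filtered(self, tmp_path):
        p = tmp_path / "r.fastq"
        qual = "I" * 30 + "#" * 50  # long low-quality tail
        p.write_text(f"@r1\n{'A' * 80}\n+\n{qual}\n")
        reads, log = ne.preprocess_reads(p, min_length=50)
        assert reads == []
        assert log["filtered_short"] == 1

    def test_truncated_fastq_reports_record_index(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n@r2\nACGT\n")
        with pytest.raises(DataError, match="record 2"):
            ne.preprocess_reads(p)

    def test_pair_merging_reconstructs_fragment(self):
        rng = np.random.default_rng(0)
        frag = "".join(rng.choice(list("ACGT"), size=250))
        r1, r2 = frag[:150], revcomp(frag[-150:])
        merged = C.merge_pair(r1, [35] * 150, r2, [35] * 150)
        assert merged is not None
        assert merged[0] == frag

    def test_gzipped_input(self, tmp_path):
        import gzip
        p = tmp_path / "r.fastq.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("@r1\n" + "ACGT" * 20 + "\n+\n" + "I" * 80 + "\n")
        reads, _ = ne.preprocess_reads(p)
        assert reads[0][1] == "ACGT" * 20


class TestClassifyRead:
    def test_exact_amplicon_substring_is_amplicon_only(self, amplicon, vector, tools):
        call = _classify(amplicon.sequence[200:420], amplicon, vector, tools)
        assert call.cls == "amplicon_only"

    def test_flanked_itr_fragment_is_chimeric_inside_itr(self, amplicon, vector, pair, tools):
        cut = pair.nicks[0]
        read = (amplicon.sequence[cut - 60:cut]
                + vector.sequence[0:40]
                + amplicon.sequence[cut:cut + 50])
        call = _classify(read, amplicon, vector, tools)
        assert call.cls == "chimeric"
        hit = call.vector_hit
        itr5 = [(s, e) for lab, s, e, _ in vector.itr_features()]
        assert any(hit.vstart < e and hit.vend > s for s, e in itr5)

    def test_random_read_sharing_no_kmer_is_unaligned(self, amplicon, vector, tools):
        rng = np.random.default_rng(1)
        k = 15
        refs = amplicon.sequence, vector.sequence
        kmers = {r[i:i + k] for r in refs for i in range(len(r) - k + 1)}
        kmers |= {revcomp(m) for m in kmers}
        while True:
            read = "".join(rng.choice(list("ACGT"), size=120))
            if not any(read[i:i + k] in kmers for i in range(len(read) - k + 1)):
                break
        call = _classify(read, amplicon, vector, tools)
        assert call.cls == "unaligned"

    def test_bare_vector_fragment_is_vector_only(self, amplicon, vector, tools):
        call = _classify(vector.sequence[100:220], amplicon, vector, tools)
        assert call.cls == "vector_only"


@pytest.fixture(scope="module")
def calls(mix_bundle, tools):
    reads, log = ne.preprocess_reads(mix_bundle["paths"]["reads"])
    idx, la = tools
    out = [ne.classify_read(r, s, mix_bundle["amplicon"],
                            mix_bundle["vector"], ne.ClassifyParams(), idx, la)
           for r, s in reads]
    return reads, log, out


class TestPartitionInvariants:
    def test_every_read_in_exactly_one_class(self, calls, mix_bundle):
        reads, log, cls = calls
        n = mix_bundle["cfg"].n_reads
        assert log["input"] == n
        assert len(cls) + (log["input"] - log["passed"]) == n
        valid = {"amplicon_only", "chimeric", "vector_only", "unaligned"}
        assert all(c.cls in valid for c in cls)

    def test_error_free_truth_classes_recovered_exactly(self, clean_bundle, tools):
        reads, _ = ne.preprocess_reads(clean_bundle["paths"]["reads"])
        idx, la = tools
        truth = dict(zip(clean_bundle["result"].truth.read_id,
                         clean_bundle["result"].truth["class"]))
        expected = {"wildtype": "amplicon_only",
                    "internick_deletion": "amplicon_only",
                    "vector_insertion": "chimeric"}
        for rid, seq in reads:
            want = expected.get(truth[rid])
            if want is None:
                continue
            call = ne.classify_read(rid, seq, clean_bundle["amplicon"],
                                    clean_bundle["vector"], ne.ClassifyParams(), idx, la)
            assert call.cls == want, (rid, truth[rid], call.cls)

    def test_raising_vector_min_len_only_removes_vector_classes(
            self, calls, mix_bundle, tools):
        reads, _, _ = calls
        idx, la = tools

        def vector_reads(min_len):
            p = ne.ClassifyParams(vector_min_len=min_len)
            return {
                r for r, s in reads
                if ne.classify_read(r, s, mix_bundle["amplicon"],
                                    mix_bundle["vector"], p, idx, la).cls
                in ("chimeric", "vector_only")
            }

        low, mid, high = (vector_reads(n) for n in (15, 30, 50))
        assert high <= mid <= low
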