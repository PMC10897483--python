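"""Junction resolution, vector coverage and ITR breakpoint statistics."""

import numpy as np
import pytest

import nickedit as ne
from nickedit import classify as C
from nickedit import variants as V
from nickedit.integration import IntegrationEvent
from nickedit.simulate import decode_ops


@pytest.fixture(scope="module")
def tools(vector):
    return C.build_vector_index(vector), C.make_local_aligner(), V.make_glocal_aligner()


def _event(vstart, vend, strand="+", left=300, right=300, ambiguous=False,
           alts=(), boundary_hit=False, rid="r"):
    return IntegrationEvent(rid, left, right, vstart, vend, strand, (),
                            boundary_hit, ambiguous, alts)


class TestResolveJunctions:
    def test_error_free_truth_intervals_recovered_exactly(self, clean_bundle, tools):
        idx, la, ga = tools
        amp, vec = clean_bundle["amplicon"], clean_bundle["vector"]
        truth = clean_bundle["result"].truth
        reads = dict(ne.preprocess_reads(clean_bundle["paths"]["reads"])[0])
        checked = 0
        for row in truth[truth["class"] == "vector_insertion"].itertuples(index=False):
            call = ne.classify_read(row.read_id, reads[row.read_id], amp, vec,
                                    ne.ClassifyParams(), idx, la)
            assert call.cls == "chimeric"
            ev = ne.resolve_junctions(call, amp, vec, aligner=ga)
            assert ev is not None
            op = decode_ops(row.ops)[0]
            _, s, dlen, strand, vs, ve = op
            assert (vs, ve, strand) in [(ev.vstart, ev.vend, ev.strand), *ev.alts]
            assert ev.left_bp == s
            assert ev.right_bp == s + dlen
            checked += 1
        assert checked > 10

    def test_vector_at_read_end_gives_single_sided_event(self, amplicon, vector,
                                                         pair, tools):
        idx, la, ga = tools
        cut = pair.nicks[1]
        read = amplicon.sequence[cut - 150:cut] + vector.sequence[:80]
        call = ne.classify_read("r", read, amplicon, vector,
                                ne.ClassifyParams(), idx, la)
        assert call.cls == "chimeric"
        ev = ne.resolve_junctions(call, amplicon, vector, aligner=ga)
        assert ev.left_bp == cut
        assert ev.right_bp is None

    def test_palindromic_itr_fragment_is_ambiguous(self, amplicon, vector, pair, tools):
        idx, la, ga = tools
        cut = pair.nicks[0]
        # a 5' ITR prefix equals the reverse complement of the 3' ITR suffix
        read = (amplicon.sequence[cut - 90:cut] + vector.sequence[:60]
                + amplicon.sequence[cut:cut + 90])
        call = ne.classify_read("r", read, amplicon, vector,
                                ne.ClassifyParams(), idx, la)
        ev = ne.resolve_junctions(call, amplicon, vector, aligner=ga)
        assert ev.ambiguous
        placements = {(p[0], p[1], p[2]) for p in ev.weight_placements}
        V_len = len(vector)
        assert (0, 60, "+") in placements
        assert (V_len - 60, V_len, "-") in placements


class TestVectorCoverage:
    def test_single_event_coverage_mass(self, vector):
        cov = ne.vector_coverage([_event(10, 50)], vector)
        assert cov.coverage[10:50].sum() == 40
        assert cov.coverage.sum() == 40
        assert np.all(cov.coverage[:10] == 0) and np.all(cov.coverage[50:] == 0)

    def test_two_way_ambiguous_events_restore_unit_weight(self, vector):
        V_len = len(vector)
        ev = [
            _event(0, 60, "+", ambiguous=True, alts=((V_len - 60, V_len, "-"),),
                   rid="a"),
            _event(0, 60, "+", ambiguous=True, alts=((V_len - 60, V_len, "-"),),
                   rid="b"),
        ]
        cov = ne.vector_coverage(ev, vector)
        assert np.all(cov.coverage[0:60] == 1.0)
        assert np.all(cov.coverage[V_len - 60:V_len] == 1.0)

    def test_coverage_conservation_on_simulated_events(self, clean_bundle, tools):
        idx, la, ga = tools
        amp, vec = clean_bundle["amplicon"], clean_bundle["vector"]
        reads, _ = ne.preprocess_reads(clean_bundle["paths"]["reads"])
        events = []
        for rid, seq in reads:
            call = ne.classify_read(rid, seq, amp, vec, ne.ClassifyParams(), idx, la)
            if call.cls == "chimeric":
                ev = ne.resolve_junctions(call, amp, vec, aligner=ga)
                if ev is not None:
                    events.append(ev)
        assert events
        cov = ne.vector_coverage(events, vec)
        expected = sum(
            (ve - vs) / len(ev.weight_placements)
            for ev in events for vs, ve, _ in ev.weight_placements
        )
        assert cov.coverage.sum() == pytest.approx(expected)

    def test_breakpoint_histogram_mass_bounded_by_two_per_event(self, clean_bundle,
                                                                vector, tools):
        events = [_event(0, 60), _event(100, 200), _event(30, 620)]
        cov = ne.vector_coverage(events, vector)
        assert sum(cov.breakpoint_hist.values()) <= 2 * len(events)

    def test_hotspot_bias_recovered(self, amplicon, vector, pair, tmp_path, tools):
        idx, la, ga = tools
        n = 600
        cfg = ne.SimConfig(n_reads=n, seed=12, sub_error_rate=0.0,
                           class_mix={"vector_insertion": 1.0},
                           itr_breakpoint_bias=0.8)
        res = ne.simulate_dataset(cfg, amplicon, vector, pair, tmp_path)
        reads, _ = ne.preprocess_reads(res.fastq[0])
        events = []
        for rid, seq in reads:
            call = ne.classify_read(rid, seq, amplicon, vector,
                                    ne.ClassifyParams(), idx, la)
            assert call.cls == "chimeric"
            events.append(ne.resolve_junctions(call, amplicon, vector, aligner=ga))
        cov = ne.vector_coverage(events, vector)
        sd = np.sqrt(0.8 * 0.2 / n)
        assert abs(cov.boundary_fraction - 0.8) <= 3 * sd


class TestITRFraction:
    def test_all_itr_insertions_fraction_one(self, vector):
        events = [_event(0, 50), _event(len(vector) - 40, len(vector), "-")]
        assert ne.itr_fraction(events, vector) == 1.0

    def test_half_from_stuffer(self, vector):
        stuffer = next(f for f in vector.features if f[0] == "stuffer")
        events = [_event(0, 50), _event(stuffer[1] + 10, stuffer[1] + 60)]
        assert ne.itr_fraction(events, vector) == 0.5

    def test_no_events_is_missing(self, vector):
        assert ne.itr_fraction([], vector) is None
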