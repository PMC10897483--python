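"""Read preprocessing and amplicon/vector read partitioning.

Reads are classified with a two-pass rule mirroring the genome-then-vector
mapping strategy of amplicon pipelines that must retain long vector
insertions: (1) find the best local alignment of the read to the amplicon;
(2) scan the unaligned portions (soft clips and large internal insertions)
against a k-mer index of the vector genome and extend seed clusters to
scored hits; (3) a read is *chimeric* when it has both a qualifying amplicon
anchor and a qualifying vector hit, *amplicon_only* when the anchor covers
the read with no vector hit, *vector_only* when only the vector hit
qualifies, and *unaligned* otherwise. Every read receives exactly one class.

Vector hits are searched on both strands; palindromic ITRs make some hits
placeable at several locations with identical score — those are flagged
ambiguous and downweighted in coverage summaries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from collections import defaultdict

from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import DataError
from .refio import AmpliconRef, VectorRef, revcomp


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the partitioning rule.

    A 15 nt vector hit at 90% identity keeps the chance false-hit
    probability per read far below one for kb-scale vectors; the 25 nt
    amplicon anchor requirement plays the role genome-filtering plays at
    genome scale.
    """

    anchor_min: int = 25
    anchor_min_ident: float = 0.85
    vector_min_len: int = 15
    vector_min_ident: float = 0.90
    seed_k: int = 12
    min_read_cover: float = 0.5


@dataclass
class VectorHit:
    """A candidate vector-derived segment of a read."""

    vstart: int
    vend: int
    strand: str
    read_span: tuple[int, int]
    matched_length: int
    identity: float
    score: int
    ambiguous: bool = False
    alts: tuple = ()


@dataclass
class ReadCall:
    read_id: str
    cls: str
    seq: str
    anchor: dict | None = None
    vector_hit: VectorHit | None = None


# ---------------------------------------------------------------------------
# FASTQ preprocessing


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path):
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise DataError(f"{path}: truncated or malformed FASTQ at record {index + 1}: {exc}") from None
            index += 1
            yield rec


def sliding_window_trim(seq: str, quals: list[int], threshold: int, window: int) -> int:
    """Index at which to cut the read: start of the first window whose mean
    quality drops below ``threshold`` (the whole read if none does)."""
    n = len(seq)
    if n < window:
        return n if (not quals or sum(quals) / len(quals) >= threshold) else 0
    running = sum(quals[:window])
    if running / window < threshold:
        return 0
    for i in range(1, n - window + 1):
        running += quals[i + window - 1] - quals[i - 1]
        if running / window < threshold:
            return i
    return n


def merge_pair(seq1: str, q1: list, seq2: str, q2: list,
               min_overlap: int = 15, max_mismatch_frac: float = 0.1):
    """Merge mates by overlap; ``seq2`` is reverse-complemented first.

    Returns ``(merged_seq, merged_quals)`` or ``None`` if no acceptable
    overlap exists. At overlap conflicts the higher-quality base wins.
    """
    s2 = revcomp(seq2)
    q2r = q2[::-1]
    best = None
    for shift in range(0, len(seq1) - min_overlap + 1):
        ov = min(len(seq1) - shift, len(s2))
        mism = sum(1 for a, b in zip(seq1[shift:shift + ov], s2[:ov]) if a != b)
        if mism <= max_mismatch_frac * ov:
            if best is None or mism / ov < best[0]:
                best = (mism / ov if ov else 1.0, shift, ov)
    if best is None:
        return None
    _, shift, ov = best
    merged = list(seq1[:shift])
    mq = list(q1[:shift])
    for i in range(ov):
        a, qa = seq1[shift + i], q1[shift + i]
        b, qb = s2[i], q2r[i]
        if a == b or qa >= qb:
            merged.append(a)
            mq.append(max(qa, qb) if a == b else qa)
        else:
            merged.append(b)
            mq.append(qb)
    merged += list(s2[ov:])
    mq += q2r[ov:]
    return "".join(merged), mq


def preprocess_reads(
    fastq,
    fastq2=None,
    qual_threshold: int = 20,
    trim_window: int = 4,
    min_length: int = 50,
    merge_pairs: bool | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Quality-trim, length-filter and optionally merge paired reads.

    Returns ``(reads, log)`` where ``reads`` is a list of ``(id, sequence)``
    and ``log`` counts input, passed and dropped reads. Dropped reads are
    assigned the ``filtered`` class downstream so that partition counts stay
    conserved.
    """
    if merge_pairs is None:
        merge_pairs = fastq2 is not None
    log = {"input": 0, "passed": 0, "filtered_short": 0, "unmerged_dropped": 0}
    reads = []

    def quals(qstr):
        return [ord(c) - 33 for c in qstr]

    if fastq2 is None:
        for rid, seq, qual in _iter_fastq(fastq):
            log["input"] += 1
            cut = sliding_window_trim(seq, quals(qual), qual_threshold, trim_window)
            trimmed = seq[:cut].upper()
            if len(trimmed) < min_length:
                log["filtered_short"] += 1
                continue
            reads.append((rid.split()[0], trimmed))
            log["passed"] += 1
        return reads, log

    it2 = _iter_fastq(fastq2)
    for rec1 in _iter_fastq(fastq):
        try:
            rec2 = next(it2)
        except StopIteration:
            raise DataError(f"{fastq2}: fewer records than {fastq}") from None
        log["input"] += 1
        rid = rec1[0].split()[0]
        c1 = sliding_window_trim(rec1[1], quals(rec1[2]), qual_threshold, trim_window)
        c2 = sliding_window_trim(rec2[1], quals(rec2[2]), qual_threshold, trim_window)
        s1, ql1 = rec1[1][:c1].upper(), quals(rec1[2])[:c1]
        s2, ql2 = rec2[1][:c2].upper(), quals(rec2[2])[:c2]
        if merge_pairs:
            merged = merge_pair(s1, ql1, s2, ql2) if s1 and s2 else None
            if merged is None:
                log["unmerged_dropped"] += 1
                continue
            seq = merged[0]
        else:
            seq = s1
        if len(seq) < min_length:
            log["filtered_short"] += 1
            continue
        reads.append((rid, seq))
        log["passed"] += 1
    if next(it2, None) is not None:
        raise DataError(f"{fastq2}: more records than {fastq}")
    return reads, log


# ---------------------------------------------------------------------------
# Vector k-mer scan


def build_vector_index(vector: VectorRef, k: int = 12) -> dict:
    index = defaultdict(list)
    seq = vector.sequence
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return dict(index)


def _cluster_hits(scan_seq: str, vec_seq: str, index: dict, k: int):
    """Group exact k-mer seeds by (strand-local) diagonal; score each group
    by ungapped base agreement over its seed span."""
    clusters = {}
    for i in range(len(scan_seq) - k + 1):
        for vp in index.get(scan_seq[i:i + k], ()):
            key = vp - i
            lo, hi = clusters.get(key, (i, i))
            clusters[key] = (min(lo, i), max(hi, i))
    out = []
    for diag, (lo, hi) in clusters.items():
        span = (lo, hi + k)
        vlo, vhi = lo + diag, hi + k + diag
        seg = scan_seq[span[0]:span[1]]
        ref = vec_seq[vlo:vhi]
        matches = sum(1 for a, b in zip(seg, ref) if a == b)
        out.append((matches, span, (vlo, vhi)))
    return out


def find_vector_hit(segment: str, seg_offset: int, vector: VectorRef,
                    index: dict, k: int) -> VectorHit | None:
    """Best vector placement of ``segment`` over both strands.

    Distinct placements tying at the best score (e.g. a fragment of one
    palindromic ITR matching the other ITR in reverse orientation) mark the
    hit ambiguous, with the alternatives recorded.
    """
    if len(segment) < k:
        return None
    vec = vector.sequence
    candidates = []
    for matches, span, (vlo, vhi) in _cluster_hits(segment, vec, index, k):
        rs = (seg_offset + span[0], seg_offset + span[1])
        candidates.append((matches, span[1] - span[0], vlo, vhi, "+", rs))
    rc = revcomp(segment)
    n = len(segment)
    for matches, span, (vlo, vhi) in _cluster_hits(rc, vec, index, k):
        rs = (seg_offset + n - span[1], seg_offset + n - span[0])
        candidates.append((matches, span[1] - span[0], vlo, vhi, "-", rs))
    if not candidates:
        return None
    best_score = max(c[0] for c in candidates)
    top = sorted(
        (c for c in candidates if c[0] == best_score),
        key=lambda c: (c[2], c[4]),
    )
    matches, mlen, vlo, vhi, strand, rs = top[0]
    alts = tuple((c[2], c[3], c[4]) for c in top[1:])
    return VectorHit(
        vstart=vlo, vend=vhi, strand=strand, read_span=rs,
        matched_length=mlen, identity=matches / mlen if mlen else 0.0,
        score=matches, ambiguous=len(top) > 1, alts=alts,
    )


# ---------------------------------------------------------------------------
# Classification


def make_local_aligner(match: int = 5, mismatch: int = 4,
                       gap_open: int = 25, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = -mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _anchor_info(alignment) -> dict:
    blocks_t, blocks_q = alignment.aligned
    if len(blocks_q) == 0:
        return {"q_start": 0, "q_end": 0, "t_start": 0, "t_end": 0,
                "aligned_len": 0, "identity": 0.0}
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    return {
        "q_start": int(blocks_q[0][0]), "q_end": int(blocks_q[-1][1]),
        "t_start": int(blocks_t[0][0]), "t_end": int(blocks_t[-1][1]),
        "aligned_len": int(aligned),
        "identity": counts.identities / aligned if aligned else 0.0,
        "internal_gaps": [
            (int(blocks_q[i][1]), int(blocks_q[i + 1][0]))
            for i in range(len(blocks_q) - 1)
            if blocks_q[i + 1][0] > blocks_q[i][1]
        ],
    }


def classify_read(
    read_id: str,
    seq: str,
    amplicon: AmpliconRef,
    vector: VectorRef,
    params: ClassifyParams = ClassifyParams(),
    vec_index: dict | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> ReadCall:
    """Assign one of {amplicon_only, chimeric, vector_only, unaligned}."""
    if vec_index is None:
        vec_index = build_vector_index(vector, params.seed_k)
    if aligner is None:
        aligner = make_local_aligner()
    seq = seq.upper()
    anchor = _anchor_info(aligner.align(amplicon.sequence, seq)[0])
    anchor_ok = (anchor["aligned_len"] >= params.anchor_min
                 and anchor["identity"] >= params.anchor_min_ident)

    def qualifying_hit(segments):
        best = None
        for off, sub in segments:
            hit = find_vector_hit(sub, off, vector, vec_index, params.seed_k)
            if hit and (best is None or hit.score > best.score):
                best = hit
        if (best and best.matched_length >= params.vector_min_len
                and best.identity >= params.vector_min_ident):
            return best
        return None

    if anchor_ok:
        # candidate vector segments: soft clips plus large internal
        # insertions; the anchor alignment can split one insert into nearby
        # gaps (or absorb junction bases as mismatches), so pad each gap and
        # merge gaps separated by only a few aligned columns
        pad = 6
        intervals = []
        if anchor["q_start"] > 0:
            intervals.append((0, anchor["q_start"]))
        for gs, ge in anchor.get("internal_gaps", []):
            intervals.append((max(0, gs - pad), min(len(seq), ge + pad)))
        if anchor["q_end"] < len(seq):
            intervals.append((anchor["q_end"], len(seq)))
        merged = []
        for lo, hi in sorted(intervals):
            if merged and lo - merged[-1][1] <= 8:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        segments = [(lo, seq[lo:hi]) for lo, hi in merged
                    if hi - lo >= params.seed_k]
        hit = qualifying_hit(segments)
        if hit is not None:
            return ReadCall(read_id, "chimeric", seq, anchor, hit)
        covered = (anchor["q_end"] - anchor["q_start"]) / len(seq) if seq else 0.0
        if covered >= params.min_read_cover:
            return ReadCall(read_id, "amplicon_only", seq, anchor, None)
        return ReadCall(read_id, "unaligned", seq, anchor, None)

    hit = qualifying_hit([(0, seq)])
    if hit is not None:
        return ReadCall(read_id, "vector_only", seq, anchor, hit)
    return ReadCall(read_id, "unaligned", seq, anchor, None)
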