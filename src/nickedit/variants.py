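"""Amplicon alignment, indel normalisation, variant tables and summaries.

Amplicon-only reads are aligned *glocally* (read global, reference local —
reads are subfragments of the amplicon) under an affine gap model with
score = 5·matches − 4·mismatches − Σ_gaps (25 + length·1), the scoring used
by the minimap2-style parameters -A5 -B4 -O25 -E1. The gap cost convention
is ``cost(k) = gap_open + k·gap_extend``; conventions differ between tools,
so it is stated here explicitly.

Alignment operations are normalised by left-aligning every indel to its
minimal reference start among sequence-equivalent placements, giving stable
variant signatures across reads. A read counts as *edited* when at least one
indel overlaps the quantification window; substitutions never count.
Chimeric reads enter the aggregation as vector-insertion variants and are
counted as edited, so editing and integration frequencies share a consistent
read universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align

from .errors import DataError
from .refio import AmpliconRef


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring parameters (positive magnitudes)."""

    match: int = 5
    mismatch: int = 4
    gap_open: int = 25
    gap_extend: int = 1


@dataclass(frozen=True)
class Op:
    """One alignment operation.

    ``kind`` is one of match/substitution/insertion/deletion; ``ref_start``
    is the amplicon coordinate (insertion point for insertions); ``seq``
    holds the read bases for substitutions and insertions. Concatenating, in
    order, the reference slice for matches, ``seq`` for substitutions and
    insertions and nothing for deletions reproduces the read.
    """

    kind: str
    ref_start: int
    length: int
    seq: str = ""


@dataclass(frozen=True)
class AlignmentResult:
    ops: tuple[Op, ...]
    score: float
    ref_start: int
    ref_end: int
    read_length: int

    def reconstruct(self, amplicon: AmpliconRef | str) -> str:
        seq = amplicon if isinstance(amplicon, str) else amplicon.sequence
        parts = []
        for op in self.ops:
            if op.kind == "match":
                parts.append(seq[op.ref_start:op.ref_start + op.length])
            elif op.kind in ("substitution", "insertion"):
                parts.append(op.seq)
        return "".join(parts)


def make_glocal_aligner(scoring: Scoring = Scoring()) -> Align.PairwiseAligner:
    """Read-global / reference-local affine aligner (free reference flanks)."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = -scoring.mismatch
    a.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    a.extend_gap_score = -scoring.gap_extend
    a.end_deletion_score = 0  # reference overhangs beyond the read are free
    return a


def _block_ops(ref: str, read: str, t0: int, te: int, q0: int, qe: int) -> list[Op]:
    """Split one gapless aligned block into match/substitution runs."""
    ops = []
    run_kind, run_start = None, 0
    for i in range(te - t0):
        kind = "match" if ref[t0 + i] == read[q0 + i] else "substitution"
        if kind != run_kind:
            if run_kind is not None:
                ops.append(Op(run_kind, t0 + run_start, i - run_start,
                              "" if run_kind == "match" else read[q0 + run_start:q0 + i]))
            run_kind, run_start = kind, i
    if run_kind is not None:
        n = te - t0
        ops.append(Op(run_kind, t0 + run_start, n - run_start,
                      "" if run_kind == "match" else read[q0 + run_start:q0 + n]))
    return ops


def align_to_amplicon(
    read: str,
    amplicon: AmpliconRef,
    scoring: Scoring = Scoring(),
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal glocal affine-gap alignment of a read to the amplicon."""
    if not read:
        raise DataError("cannot align an empty read")
    read = read.upper()
    if aligner is None:
        aligner = make_glocal_aligner(scoring)
    ref = amplicon.sequence
    aln = aligner.align(ref, read)[0]
    blocks_t, blocks_q = (b.tolist() for b in aln.aligned)
    ops: list[Op] = []
    if not blocks_t:
        raise DataError("alignment produced no aligned block")
    t0 = blocks_t[0][0]
    if blocks_q[0][0] > 0:  # leading read bases inserted before the anchor
        ops.append(Op("insertion", t0, blocks_q[0][0], read[:blocks_q[0][0]]))
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            if ts > prev_t:
                ops.append(Op("deletion", prev_t, ts - prev_t))
            if qs > prev_q:
                ops.append(Op("insertion", ts, qs - prev_q, read[prev_q:qs]))
        ops.extend(_block_ops(ref, read, ts, te, qs, qe))
        prev_t, prev_q = te, qe
    if prev_q < len(read):  # trailing read bases beyond the anchor
        ops.append(Op("insertion", prev_t, len(read) - prev_q, read[prev_q:]))
    return AlignmentResult(tuple(ops), float(aln.score), t0, prev_t, len(read))


# ---------------------------------------------------------------------------
# Indel normalisation


def _merge_adjacent(ops: list[Op]) -> list[Op]:
    out: list[Op] = []
    for op in ops:
        if op.length == 0:
            continue
        if out:
            prev = out[-1]
            if prev.kind == op.kind == "match" and prev.ref_start + prev.length == op.ref_start:
                out[-1] = replace(prev, length=prev.length + op.length)
                continue
            if prev.kind == op.kind == "deletion" and prev.ref_start + prev.length == op.ref_start:
                out[-1] = replace(prev, length=prev.length + op.length)
                continue
            if prev.kind == op.kind == "insertion" and prev.ref_start == op.ref_start:
                out[-1] = replace(prev, length=prev.length + op.length, seq=prev.seq + op.seq)
                continue
            if (prev.kind == op.kind == "substitution"
                    and prev.ref_start + prev.length == op.ref_start):
                out[-1] = replace(prev, length=prev.length + op.length, seq=prev.seq + op.seq)
                continue
            # canonical order: deletion before insertion at a shared point
            if prev.kind == "insertion" and op.kind == "deletion" and op.ref_start == prev.ref_start:
                out[-1] = op
                out.append(prev)
                continue
        out.append(op)
    return out


def normalize_ops(aln: AlignmentResult, amplicon: AmpliconRef | str) -> AlignmentResult:
    """Left-align every indel to its minimal reference start; idempotent."""
    ref = amplicon if isinstance(amplicon, str) else amplicon.sequence
    ops = _merge_adjacent(list(aln.ops))
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(ops):
            op = ops[i]
            prev = ops[i - 1] if i > 0 else None
            if (op.kind in ("insertion", "deletion") and prev is not None
                    and prev.kind == "match" and prev.length >= 1):
                s = op.ref_start
                if op.kind == "deletion" and ref[s - 1] == ref[s + op.length - 1]:
                    ops[i - 1] = replace(prev, length=prev.length - 1)
                    ops[i] = replace(op, ref_start=s - 1)
                    ops.insert(i + 1, Op("match", s + op.length - 1, 1))
                    changed = True
                elif op.kind == "insertion" and op.seq and ref[s - 1] == op.seq[-1]:
                    ops[i - 1] = replace(prev, length=prev.length - 1)
                    ops[i] = replace(op, ref_start=s - 1, seq=ref[s - 1] + op.seq[:-1])
                    ops.insert(i + 1, Op("match", s - 1, 1))
                    changed = True
            i += 1
        if changed:
            ops = _merge_adjacent(ops)
    ops = _merge_adjacent(ops)
    ref_start = min((o.ref_start for o in ops if o.kind != "insertion"),
                    default=aln.ref_start)
    ref_end = max((o.ref_start + o.length for o in ops if o.kind not in ("insertion",)),
                  default=aln.ref_end)
    return AlignmentResult(tuple(ops), aln.score, ref_start, ref_end, aln.read_length)


# ---------------------------------------------------------------------------
# Variant calling


@dataclass(frozen=True)
class VariantCall:
    """Per-read variant contribution derived from a normalised alignment."""

    signature: str
    vtype: str        # none | deletion | insertion | complex
    net_size: int
    start: int | None
    edited: bool
    outside_window: bool
    indels: tuple[Op, ...] = field(default=())


def _overlaps_window(op: Op, lo: int, hi: int) -> bool:
    if op.kind == "deletion":
        return op.ref_start < hi and op.ref_start + op.length > lo
    return lo <= op.ref_start <= hi  # insertion point


def call_variant(aln: AlignmentResult, quant_window: tuple[int, int]) -> VariantCall:
    lo, hi = quant_window
    indels = tuple(op for op in aln.ops if op.kind in ("insertion", "deletion"))
    if not indels:
        return VariantCall("WT", "none", 0, None, False, False)
    edited = any(_overlaps_window(op, lo, hi) for op in indels)
    toks = []
    net = 0
    for op in indels:
        if op.kind == "deletion":
            toks.append(f"D{op.ref_start}+{op.length}")
            net -= op.length
        else:
            toks.append(f"I{op.ref_start}+{op.seq}")
            net += op.length
    vtype = ("deletion" if indels[0].kind == "deletion" else "insertion") \
        if len(indels) == 1 else "complex"
    return VariantCall(";".join(toks), vtype, net, indels[0].ref_start,
                       edited, not edited, indels)


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class SummaryReport:
    """Headline quantities of one sample.

    Frequencies are fractions in [0, 1]; the two integration denominators
    follow the convention of reporting vector-bearing reads both as a share
    of all classified reads and as a share of edited reads.
    """

    n_classified: int
    n_edited: int
    n_chimeric: int
    indel_frequency: float
    integration_frequency_reads: float
    integration_frequency_indels: float
    size_histograms: dict
    class_counts: dict
    mh_fraction_gt_threshold: float | None = None
    mh_threshold: int = 2
    junction_warnings: int = 0

    def to_dict(self) -> dict:
        return {
            "n_classified": self.n_classified,
            "n_edited": self.n_edited,
            "n_chimeric": self.n_chimeric,
            "indel_frequency": self.indel_frequency,
            "integration_frequency_reads": self.integration_frequency_reads,
            "integration_frequency_indels": self.integration_frequency_indels,
            "size_histograms": self.size_histograms,
            "class_counts": self.class_counts,
            "mh_fraction_gt_threshold": self.mh_fraction_gt_threshold,
            "mh_threshold": self.mh_threshold,
            "junction_warnings": self.junction_warnings,
        }


def _event_signature(ev) -> str:
    left = ev.left_bp if ev.left_bp is not None else "."
    right = ev.right_bp if ev.right_bp is not None else "."
    return f"V{left}-{right}+{ev.vstart}-{ev.vend}{ev.strand}"


def aggregate(
    variant_calls: list[tuple[str, VariantCall]],
    events: list,
    class_counts: dict | None = None,
) -> tuple[pd.DataFrame, SummaryReport]:
    """Build the variant table and summary from per-read calls plus
    integration events (chimeric reads, one event per read)."""
    n_amp = len(variant_calls)
    n_chim = len(events)
    total = n_amp + n_chim
    n_edited = sum(1 for _, c in variant_calls if c.edited) + n_chim

    groups: dict[str, dict] = {}
    for _, call in variant_calls:
        g = groups.setdefault(call.signature, {
            "signature": call.signature, "type": call.vtype,
            "size": call.net_size, "start": call.start, "support": 0,
            "outside_window": call.outside_window,
        })
        g["support"] += 1
    for ev in events:
        sig = _event_signature(ev)
        g = groups.setdefault(sig, {
            "signature": sig, "type": "vector_insertion",
            "size": ev.vend - ev.vstart, "start": ev.left_bp, "support": 0,
            "outside_window": False,
        })
        g["support"] += 1

    table = pd.DataFrame(
        sorted(groups.values(), key=lambda g: (-g["support"], g["signature"])),
        columns=["signature", "type", "size", "start", "support", "outside_window"],
    )
    if total:
        table["freq_total"] = table["support"] / total
    else:
        table["freq_total"] = np.nan
    edited_mask = (table["type"] != "none") & ~table["outside_window"]
    table["freq_edited"] = np.where(
        edited_mask & (n_edited > 0), table["support"] / max(n_edited, 1), np.nan,
    )

    del_hist: dict[int, int] = {}
    ins_hist: dict[int, int] = {}
    vec_hist: dict[int, int] = {}
    for _, call in variant_calls:
        if not call.edited:
            continue
        for op in call.indels:
            hist = del_hist if op.kind == "deletion" else ins_hist
            hist[op.length] = hist.get(op.length, 0) + 1
    for ev in events:
        size = ev.vend - ev.vstart
        vec_hist[size] = vec_hist.get(size, 0) + 1

    report = SummaryReport(
        n_classified=total,
        n_edited=n_edited,
        n_chimeric=n_chim,
        indel_frequency=n_edited / total if total else 0.0,
        integration_frequency_reads=n_chim / total if total else 0.0,
        integration_frequency_indels=n_chim / n_edited if n_edited else 0.0,
        size_histograms={
            "deletion": dict(sorted(del_hist.items())),
            "insertion": dict(sorted(ins_hist.items())),
            "vector": dict(sorted(vec_hist.items())),
        },
        class_counts=dict(class_counts or {}),
    )
    return table, report


def deletion_coverage_profile(
    alignments: list[AlignmentResult], amplicon: AmpliconRef,
) -> np.ndarray:
    """Per-position fraction of covering reads that carry a deletion there.

    A read covers every reference position inside its aligned span,
    including positions it deletes. Positions with zero coverage are NaN.
    """
    n = len(amplicon)
    cov = np.zeros(n)
    dele = np.zeros(n)
    for aln in alignments:
        cov[aln.ref_start:aln.ref_end] += 1
        for op in aln.ops:
            if op.kind == "deletion":
                dele[op.ref_start:op.ref_start + op.length] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(cov > 0, dele / np.maximum(cov, 1), np.nan)
    return profile
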