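"""Vector-amplicon junction resolution and integration summaries.

A chimeric read is split into an amplicon prefix, a vector-derived middle
and an amplicon suffix. Junctions are canonicalised by *maximal vector
extension*: a base that matches both the amplicon flank and the adjacent
vector base is attributed to the vector, the same convention the simulator
uses when recording truth, so on error-free data resolved intervals equal
the generating ones. Reads whose vector segment reaches a read end yield a
single-sided event contributing one breakpoint instead of two — short reads
truncate long insertions, so double-sided evidence cannot be required.

Each chimeric read is one integration event; events (not base pairs) are the
unit of the integration frequencies reported upstream. Ambiguous hits
(palindromic ITRs make some placements score-equivalent) spread unit weight
over their co-optimal placements in coverage and breakpoint histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ReadCall
from .refio import AmpliconRef, VectorRef, arm_boundaries
from .variants import Scoring, align_to_amplicon, make_glocal_aligner

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class IntegrationEvent:
    """One resolved vector integration junction on the amplicon."""

    read_id: str
    left_bp: int | None          # amplicon coordinate left of the insert
    right_bp: int | None         # amplicon coordinate right of the insert
    vstart: int
    vend: int
    strand: str
    itr_arms: tuple[str, ...]
    arm_boundary_hit: bool
    ambiguous: bool = False
    alts: tuple = ()             # alternative (vstart, vend, strand) placements

    @property
    def weight_placements(self) -> list[tuple[int, int, str]]:
        return [(self.vstart, self.vend, self.strand), *self.alts]


def _extend_vector_span(seq: str, rs: int, re: int, vstart: int, vend: int,
                        strand: str, vec: str) -> tuple[int, int, int, int]:
    """Grow the vector-matched read span while read bases continue the
    vector sequence exactly (maximal-vector canonicalisation)."""
    V = len(vec)
    if strand == "+":
        while rs > 0 and vstart > 0 and seq[rs - 1] == vec[vstart - 1]:
            rs -= 1
            vstart -= 1
        while re < len(seq) and vend < V and seq[re] == vec[vend]:
            re += 1
            vend += 1
    else:
        while rs > 0 and vend < V and seq[rs - 1] == _COMP[vec[vend]]:
            rs -= 1
            vend += 1
        while re < len(seq) and vstart > 0 and seq[re] == _COMP[vec[vstart - 1]]:
            re += 1
            vstart -= 1
    return rs, re, vstart, vend


def _mirror_placement(vstart: int, vend: int, strand: str, shift_s: int,
                      shift_e: int, vec_len: int) -> tuple[int, int, str]:
    """Apply the same canonical extension to an alternative placement.

    An alternative placement is the reverse-complement image of the primary
    one, so growing the primary by ``shift_s``/``shift_e`` grows the mirror
    on the opposite ends.
    """
    if strand == "+":
        return (max(0, vstart - shift_s), min(vec_len, vend + shift_e), strand)
    return (max(0, vstart - shift_e), min(vec_len, vend + shift_s), strand)


def resolve_junctions(
    call: ReadCall,
    amplicon: AmpliconRef,
    vector: VectorRef,
    tol: int = 3,
    min_flank: int = 10,
    min_flank_identity: float = 0.6,
    min_match_run: int = 5,
    scoring: Scoring = Scoring(),
    aligner=None,
    boundaries: list[int] | None = None,
) -> IntegrationEvent | None:
    """Resolve the amplicon/vector/amplicon split of a chimeric read.

    Returns ``None`` when no consistent split exists (flank alignments
    crossing each other); the caller then reclassifies the read as
    amplicon-only and counts a warning.
    """
    hit = call.vector_hit
    if hit is None:
        raise ValueError(f"read {call.read_id} has no vector hit to resolve")
    if aligner is None:
        aligner = make_glocal_aligner(scoring)
    if boundaries is None:
        boundaries = arm_boundaries(vector)
    seq = call.seq
    vec = vector.sequence
    rs0, re0 = hit.read_span
    rs, re, vstart, vend = _extend_vector_span(
        seq, rs0, re0, hit.vstart, hit.vend, hit.strand, vec)
    grow_s = (hit.vstart - vstart) if hit.strand == "+" else (vend - hit.vend)
    grow_e = (vend - hit.vend) if hit.strand == "+" else (hit.vstart - vstart)
    alts = tuple(
        _mirror_placement(a, b, s, grow_s, grow_e, len(vec))
        for a, b, s in hit.alts
    )

    def flank_bp(sub: str, side: str) -> int | None:
        if len(sub) < min_flank:
            return None
        aln = align_to_amplicon(sub, amplicon, scoring, aligner=aligner)
        aligned = sum(o.length for o in aln.ops if o.kind in ("match", "substitution"))
        matches = sum(o.length for o in aln.ops if o.kind == "match")
        if aligned == 0 or matches / aligned < min_flank_identity:
            return None
        # anchor the breakpoint on solid sequence: an undetected vector stump
        # (e.g. seeds broken by an error at the junction) can be absorbed
        # into the flank alignment as a mismatch tail, so walk back to the
        # innermost confident match run
        ops = aln.ops if side == "right" else tuple(reversed(aln.ops))
        for op in ops:
            if op.kind == "match" and op.length >= min_match_run:
                return op.ref_start if side == "right" else op.ref_start + op.length
        return None

    left_bp = flank_bp(seq[:rs], "left")
    right_bp = flank_bp(seq[re:], "right")
    if left_bp is None and right_bp is None:
        return None
    if left_bp is not None and right_bp is not None and right_bp < left_bp:
        return None  # flanks cross: no consistent amplicon/vector split

    arms = tuple(
        label for label, fs, fe, _ in vector.itr_features()
        if fs < vend and fe > vstart
    )
    internal = [p for placement in ((vstart, vend, hit.strand), *alts)
                for p in placement[:2] if 0 < p < len(vec)]
    boundary_hit = any(abs(p - b) <= tol for p in internal for b in boundaries)
    return IntegrationEvent(
        read_id=call.read_id, left_bp=left_bp, right_bp=right_bp,
        vstart=vstart, vend=vend, strand=hit.strand, itr_arms=arms,
        arm_boundary_hit=boundary_hit, ambiguous=hit.ambiguous, alts=alts,
    )


# ---------------------------------------------------------------------------
# Summaries over events


@dataclass
class VectorCoverage:
    coverage: np.ndarray
    per_arm: dict
    boundary_fraction: float | None
    breakpoint_hist: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(len(self.coverage)),
            "coverage": self.coverage,
        })


def vector_coverage(
    events: list[IntegrationEvent],
    vector: VectorRef,
    tol: int = 3,
    boundaries: list[int] | None = None,
) -> VectorCoverage:
    """Read-weighted per-position coverage of the vector genome by
    integrated fragments, per-arm totals and arm-boundary breakpoint usage.

    Ambiguous events spread unit weight across their co-optimal placements
    (half weight each for a two-way tie), so total coverage mass equals
    Σ weight·interval length.
    """
    if boundaries is None:
        boundaries = arm_boundaries(vector)
    V = len(vector.sequence)
    cov = np.zeros(V)
    hist = {b: 0.0 for b in boundaries}
    n_hit = 0
    for ev in events:
        placements = ev.weight_placements
        w = 1.0 / len(placements)
        for vs, ve, _ in placements:
            cov[vs:ve] += w
            for p in (vs, ve):
                if 0 < p < V:
                    for b in boundaries:
                        if abs(p - b) <= tol:
                            hist[b] += w
        if ev.arm_boundary_hit:
            n_hit += 1
    per_arm = {
        label: float(cov[fs:fe].sum())
        for label, fs, fe, _ in vector.itr_features()
    }
    return VectorCoverage(
        coverage=cov,
        per_arm=per_arm,
        boundary_fraction=n_hit / len(events) if events else None,
        breakpoint_hist=hist,
    )


def itr_fraction(events: list[IntegrationEvent], vector: VectorRef) -> float | None:
    """Fraction of events whose vector interval overlaps any ITR feature;
    ``None`` when there are no events."""
    if not events:
        return None
    itr = vector.itr_features()
    n = sum(
        1 for ev in events
        if any(fs < ev.vend and fe > ev.vstart for _, fs, fe, _ in itr)
    )
    return n / len(events)


def events_to_frame(events: list[IntegrationEvent]) -> pd.DataFrame:
    rows = [{
        "read_id": ev.read_id,
        "left_bp": ev.left_bp if ev.left_bp is not None else "",
        "right_bp": ev.right_bp if ev.right_bp is not None else "",
        "vector_start": ev.vstart, "vector_end": ev.vend, "strand": ev.strand,
        "itr_arms": ",".join(ev.itr_arms),
        "arm_boundary_hit": int(ev.arm_boundary_hit),
        "ambiguous": int(ev.ambiguous),
    } for ev in events]
    return pd.DataFrame(rows, columns=[
        "read_id", "left_bp", "right_bp", "vector_start", "vector_end",
        "strand", "itr_arms", "arm_boundary_hit", "ambiguous",
    ])
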