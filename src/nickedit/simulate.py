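"""Truth-tagged synthetic amplicon-sequencing datasets.

The generator emulates the editing-outcome spectrum of a paired-nickase (or
nuclease) amplicon experiment with AAV delivery: wildtype reads, small NHEJ
indels at the nick sites, clean inter-nick deletions, MMEJ deletions with
defined flanking microhomology, locus-templated insertions copied from the
inter-nick segment, and truncated-ITR vector insertions whose breakpoint
falls at the ITR arm boundary with configurable probability. Sequencing
noise is substitution-only by default (amplicon platforms are
substitution-dominated, and it keeps the truth records unambiguous).

Every read carries a TruthRecord: re-applying the recorded operations to the
reference, windowing, and re-applying the recorded substitution errors
reproduces the emitted read byte for byte.

Coordinate conventions follow :mod:`nickedit.refio`; recorded indels are
left-aligned and vector junctions are canonicalised by maximal vector-interval
extension, the same conventions the analysis modules normalise to, so truth
and pipeline output are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .microhomology import scan_mh
from .refio import AmpliconRef, GuidePair, GuideSpec, VectorRef, revcomp

READ_CLASSES = (
    "wildtype", "nhej_indel", "internick_deletion", "mmej_deletion",
    "templated_insertion", "vector_insertion", "combined",
)

#: Default outcome mix: 60% edited alleles of which one sixth carry a vector
#: insertion, mirroring an efficient paired-nickase editing experiment.
DEFAULT_CLASS_MIX = {
    "wildtype": 0.40,
    "nhej_indel": 0.10,
    "internick_deletion": 0.10,
    "mmej_deletion": 0.15,
    "templated_insertion": 0.10,
    "vector_insertion": 0.10,
    "combined": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset; ``seed`` is mandatory."""

    n_reads: int
    seed: int
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    sub_error_rate: float = 0.001
    read_length: int = 250
    paired: bool = False
    pair_read_length: int = 150
    itr_breakpoint_bias: float = 0.8
    boundary_tol: int = 3
    mmej_mh_mix: dict = field(default_factory=lambda: {0: 1 / 3, 4: 1 / 3, 5: 1 / 3})
    vector_rc_prob: float = 0.5
    base_quality: int = 35
    min_flank: int = 30

    def __post_init__(self):
        unknown = set(self.class_mix) - set(READ_CLASSES)
        if unknown:
            raise ConfigError(f"unknown read classes in class_mix: {sorted(unknown)}")
        probs = list(self.class_mix.values()) + [
            self.sub_error_rate, self.itr_breakpoint_bias, self.vector_rc_prob,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"class_mix sums to {sum(self.class_mix.values())}, expected 1")
        if abs(sum(self.mmej_mh_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("mmej_mh_mix must sum to 1")


@dataclass
class SimResult:
    fastq: list
    truth_path: Path
    truth: pd.DataFrame
    class_counts: dict


# ---------------------------------------------------------------------------
# Synthetic references

_BASES = np.array(list("ACGT"))


def _rand_dna(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def build_synthetic_vector(
    arm_lengths: tuple[int, int, int, int] = (20, 10, 10, 10),
    stuffer_length: int = 500,
    seed: int = 0,
    name: str = "synthetic_vector",
) -> VectorRef:
    """A synthetic AAV-like vector with two palindromic ITRs and a stuffer.

    Each ITR is laid out A C C' B B' A' D (primes are reverse complements),
    so the B/B' palindrome abuts the A' stem; the 3' ITR is the reverse
    complement of the 5' ITR. ``arm_lengths`` gives the A, B, C and D arm
    lengths, so each ITR spans ``2a + 2b + 2c + d`` bases.
    """
    a, b, c, d = arm_lengths
    if min(a, b, c, d) <= 0:
        raise ConfigError("ITR arm lengths must be positive")
    rng = np.random.default_rng(seed)
    A, B, C, D = (_rand_dna(rng, n) for n in (a, b, c, d))
    itr5 = A + C + revcomp(C) + B + revcomp(B) + revcomp(A) + D
    stuffer = _rand_dna(rng, stuffer_length)
    seq = itr5 + stuffer + revcomp(itr5)
    ilen = len(itr5)
    total = len(seq)

    arms5 = [("A", a), ("C", c), ("Cp", c), ("B", b), ("Bp", b), ("Ap", a), ("D", d)]
    arms3 = [("D", d), ("A", a), ("B", b), ("Bp", b), ("C", c), ("Cp", c), ("Ap", a)]
    feats = []
    pos = 0
    for label, n in arms5:
        feats.append((f"ITR5_{label}", pos, pos + n, "+"))
        pos += n
    if stuffer_length:
        feats.append(("stuffer", ilen, ilen + stuffer_length, "+"))
    pos = total - ilen
    for label, n in arms3:
        feats.append((f"ITR3_{label}", pos, pos + n, "-"))
        pos += n
    return VectorRef(name, seq, tuple(feats))


def _set(seq: list, i: int, base: str):
    seq[i] = base


def _force_diff(seq: list, keep: int, change: int, rng):
    """Make ``seq[change]`` differ from ``seq[keep]``."""
    if seq[change] == seq[keep]:
        seq[change] = rng.choice([b for b in "ACGT" if b != seq[keep]])


def build_synthetic_locus(
    seed: int = 0,
    length: int = 646,
    inter_nick: int = 64,
    protospacer_length: int = 21,
    nick_offset: int = 3,
    quant_pad: int = 5,
    name: str = "synthetic_amplicon",
) -> tuple[AmpliconRef, GuidePair]:
    """A synthetic on-target amplicon with a PAM-out paired-nickase design.

    Two guide sites on opposite strands nick ``inter_nick`` bp apart around
    the amplicon centre, each with an NNGRRT-compatible PAM facing outward.
    The sequence is engineered to contain one 23 bp deletion site with an
    exact 4 bp flanking microhomology and one 10 bp deletion site with an
    exact 5 bp microhomology inside the quantification window, and the
    inter-nick "perfect" deletion is made non-shiftable so that truth records
    coincide with left-aligned variant calls.
    """
    L = protospacer_length
    pam_len = 6
    center = length // 2
    n1 = center - inter_nick // 2
    n2 = n1 + inter_nick
    rng = np.random.default_rng(seed)
    seq = list(_rand_dna(rng, length))

    # plus-strand guide 3' of the right nick: nick = start + L - offset
    sp = n2 - L + nick_offset
    for off, base in ((2, "G"), (3, "A"), (4, "G"), (5, "T")):
        _set(seq, sp + L + off, base)
    # minus-strand guide 5' of the left nick: nick = start + offset
    sm = n1 - nick_offset
    for off, base in ((-3, "C"), (-4, "T"), (-5, "C"), (-6, "A")):
        _set(seq, sm + off, base)

    # 4 bp microhomology flanking a 23 bp deletion spanning the left nick
    # (copied after the PAMs are fixed so the repeat survives)
    p4 = n1 - 10
    seq[p4 + 23:p4 + 27] = seq[p4:p4 + 4]
    # 5 bp microhomology flanking a 10 bp deletion just left of the right nick
    q5 = n2 - 12
    seq[q5 + 10:q5 + 15] = seq[q5:q5 + 5]

    # make the engineered microhomologies exact and left-aligned
    _force_diff(seq, p4 + 4, p4 + 27, rng)
    _force_diff(seq, p4 - 1, p4 + 22, rng)
    _force_diff(seq, q5 + 5, q5 + 15, rng)
    _force_diff(seq, q5 - 1, q5 + 9, rng)
    # make the inter-nick deletion non-shiftable in either direction
    _force_diff(seq, n2 - 1, n1 - 1, rng)
    _force_diff(seq, n2, n1, rng)

    sequence = "".join(seq)
    g_minus = GuideSpec(
        name="g1", protospacer=revcomp(sequence[sm:sm + L]),
        pam=revcomp(sequence[sm - pam_len:sm]), strand="-",
        protospacer_start=sm, nick_offset=nick_offset,
    )
    g_plus = GuideSpec(
        name="g2", protospacer=sequence[sp:sp + L],
        pam=sequence[sp + L:sp + L + pam_len], strand="+",
        protospacer_start=sp, nick_offset=nick_offset,
    )
    pair = GuidePair(g_minus, g_plus)
    assert pair.orientation == "PAM-out" and pair.inter_nick_distance == inter_nick
    window = (max(0, n1 - quant_pad), min(length, n2 + quant_pad))
    amplicon = AmpliconRef(name, sequence, cut_sites=(n1, n2), quant_window=window)
    g_minus.validate_on(amplicon)
    g_plus.validate_on(amplicon)
    return amplicon, pair


def enumerate_mh_sites(
    amplicon: AmpliconRef,
    mh_length: int,
    window: tuple[int, int] | None = None,
    size_range: tuple[int, int] = (8, 30),
) -> list[tuple[int, int]]:
    """All left-aligned deletions ``(start, size)`` with exactly the requested
    flanking microhomology that overlap ``window`` (default: quant window)."""
    seq = amplicon.sequence
    lo, hi = window or amplicon.quant_window or (0, len(seq))
    sites = []
    for size in range(size_range[0], size_range[1] + 1):
        for s in range(max(0, lo - size), min(hi, len(seq) - size)):
            e = s + size
            if e + mh_length > len(seq):
                continue
            if s > 0 and seq[s - 1] == seq[e - 1]:
                continue  # not left-aligned
            if scan_mh(s, e, seq).mh_length == mh_length:
                sites.append((s, size))
    return sites


# ---------------------------------------------------------------------------
# Applying operations

def _op_sort_key(op):
    return (op[1], 0 if op[0] == "del" else 1)


def apply_ops(amplicon_seq: str, ops, vector_seq: str | None = None) -> tuple[str, int, int]:
    """Apply truth operations to the reference.

    Returns ``(edited_sequence, edit_lo, edit_hi)`` where the ``edit`` span
    brackets every modified position in edited coordinates.
    """
    parts = []
    cur = 0
    elen = 0
    lo, hi = None, None
    for op in sorted(ops, key=_op_sort_key):
        kind, s = op[0], op[1]
        if s < cur:
            raise DataError(f"overlapping truth ops at {s}")
        parts.append(amplicon_seq[cur:s])
        elen += s - cur
        start_e = elen
        if kind == "del":
            cur = s + op[2]
        elif kind == "ins":
            parts.append(op[2])
            elen += len(op[2])
            cur = s
        elif kind == "vec":
            _, s, dlen, strand, vs, ve = op
            frag = vector_seq[vs:ve]
            if strand == "-":
                frag = revcomp(frag)
            parts.append(frag)
            elen += len(frag)
            cur = s + dlen
        else:
            raise DataError(f"unknown op {kind!r}")
        lo = start_e if lo is None else min(lo, start_e)
        hi = elen if hi is None else max(hi, elen)
    parts.append(amplicon_seq[cur:])
    edited = "".join(parts)
    if lo is None:
        lo = hi = len(edited) // 2
    return edited, lo, hi


def _to_edited_coord(x: int, ops) -> int:
    off = 0
    for op in sorted(ops, key=_op_sort_key):
        kind, s = op[0], op[1]
        if kind == "del":
            k = op[2]
            if x >= s + k:
                off -= k
            elif x > s:
                return s + off
        elif kind == "ins":
            if x > s:
                off += len(op[2])
        elif kind == "vec":
            _, s, dlen, strand, vs, ve = op
            if x >= s + dlen:
                off += (ve - vs) - dlen
            elif x > s:
                return s + off
    return x + off


# ---------------------------------------------------------------------------
# Left-alignment / junction canonicalisation (same conventions as analysis)

def _left_align_del(seq: str, s: int, k: int) -> int:
    while s > 0 and seq[s - 1] == seq[s + k - 1]:
        s -= 1
    return s


def _left_align_ins(seq: str, s: int, ins: str) -> tuple[int, str]:
    while s > 0 and ins and ins[-1] == seq[s - 1]:
        ins = seq[s - 1] + ins[:-1]
        s -= 1
    return s, ins


def canonicalize_vector_op(op, amplicon_seq: str, vector_seq: str):
    """Maximal-vector-interval canonical form of a vector insertion op.

    When a base at a vector/amplicon junction could be attributed to either
    sequence the description is ambiguous; both the simulator and the
    junction resolver give contested bases to the vector, so truth records
    and resolved events agree on error-free data.
    """
    _, s, dlen, strand, vs, ve = op
    left, right = s, s + dlen
    V = len(vector_seq)
    if strand == "+":
        while vs > 0 and left > 0 and amplicon_seq[left - 1] == vector_seq[vs - 1]:
            left -= 1
            vs -= 1
        while ve < V and right < len(amplicon_seq) and amplicon_seq[right] == vector_seq[ve]:
            right += 1
            ve += 1
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        while ve < V and left > 0 and amplicon_seq[left - 1] == comp[vector_seq[ve]]:
            left -= 1
            ve += 1
        while vs > 0 and right < len(amplicon_seq) and amplicon_seq[right] == comp[vector_seq[vs - 1]]:
            right += 1
            vs -= 1
    return ("vec", left, right - left, strand, vs, ve)


# ---------------------------------------------------------------------------
# Per-class op generators

def _gen_nhej(rng, pair: GuidePair, amp: str):
    n = int(rng.choice(pair.nicks))
    if rng.random() < 0.5:
        k = int(rng.integers(1, 11))
        s = n - int(rng.integers(0, k + 1))
        s = max(0, s)
        return [("del", _left_align_del(amp, s, k), k)]
    k = int(rng.integers(1, 6))
    s = n + int(rng.integers(-2, 3))
    ins = _rand_dna(rng, k)
    s, ins = _left_align_ins(amp, s, ins)
    return [("ins", s, ins)]


def _gen_mmej(rng, cfg: SimConfig, site_cache: dict):
    lengths = sorted(cfg.mmej_mh_mix)
    weights = np.array([cfg.mmej_mh_mix[m] for m in lengths])
    mh = int(lengths[rng.choice(len(lengths), p=weights / weights.sum())])
    sites = site_cache[mh]
    s, k = sites[int(rng.integers(len(sites)))]
    return [("del", s, k)], mh


def _gen_templated(rng, pair: GuidePair, amp: str):
    n1, n2 = pair.nicks
    k = int(rng.integers(5, 26))
    k = min(k, n2 - n1)
    s0 = int(rng.integers(n1, n2 - k + 1))
    ins = amp[s0:s0 + k]
    if rng.random() < 0.5:
        ins = revcomp(ins)
    s = int(rng.choice([n1, n2]))
    s, ins = _left_align_ins(amp, s, ins)
    return [("ins", s, ins)]


def _itr_intervals(vector: VectorRef) -> tuple[tuple[int, int], tuple[int, int]]:
    itr = vector.itr_features()
    starts5 = [f[1] for f in itr if f[0].startswith("ITR5")]
    ends5 = [f[2] for f in itr if f[0].startswith("ITR5")]
    starts3 = [f[1] for f in itr if f[0].startswith("ITR3")]
    ends3 = [f[2] for f in itr if f[0].startswith("ITR3")]
    if not starts5 or not starts3:
        raise DataError(f"vector {vector.name!r} lacks annotated ITR5/ITR3 features")
    return (min(starts5), max(ends5)), (min(starts3), max(ends3))


def _gen_vector_ins(rng, cfg: SimConfig, pair: GuidePair, amp: str, vector: VectorRef,
                    boundaries: list[int], min_frag: int = 25):
    (i5lo, i5hi), (i3lo, i3hi) = _itr_intervals(vector)
    V = len(vector.sequence)
    use5 = rng.random() < 0.5
    b5 = min(boundaries)          # breakpoint offset from the 5' terminus
    b3 = max(boundaries)
    hotspot = rng.random() < cfg.itr_breakpoint_bias
    tol = cfg.boundary_tol
    if use5:
        if hotspot:
            b = b5
        else:
            while True:
                b = int(rng.integers(i5lo + min_frag, i5hi + 1))
                if abs(b - b5) > tol:
                    break
        vs, ve = 0, b
    else:
        if hotspot:
            b = b3
        else:
            while True:
                b = int(rng.integers(i3lo, i3hi - min_frag + 1))
                if abs(b - b3) > tol:
                    break
        vs, ve = b, V
    strand = "-" if rng.random() < cfg.vector_rc_prob else "+"
    n = int(rng.choice(pair.nicks))
    dl, dr = int(rng.integers(0, 4)), int(rng.integers(0, 4))
    op = ("vec", max(0, n - dl), dl + dr, strand, vs, ve)
    return [canonicalize_vector_op(op, amp, vector.sequence)], hotspot


def _gen_combined(rng, pair: GuidePair, amp: str):
    n1, n2 = pair.nicks
    k1 = int(rng.integers(2, 9))
    s1 = max(0, n1 - int(rng.integers(0, k1 + 1)))
    s1 = _left_align_del(amp, s1, k1)
    k2 = int(rng.integers(2, 7))
    s2, ins = _left_align_ins(amp, n2, _rand_dna(rng, k2))
    if s2 < s1 + k1:  # keep ops disjoint (pathological shift)
        s2 = s1 + k1
        ins = _rand_dna(rng, k2)
    return [("del", s1, k1), ("ins", s2, ins)]


# ---------------------------------------------------------------------------
# Truth encoding

def encode_ops(ops) -> str:
    toks = []
    for op in ops:
        if op[0] == "del":
            toks.append(f"del:{op[1]}:{op[2]}")
        elif op[0] == "ins":
            toks.append(f"ins:{op[1]}:{op[2]}")
        else:
            _, s, dlen, strand, vs, ve = op
            toks.append(f"vec:{s}:{dlen}:{strand}:{vs}:{ve}")
    return ";".join(toks)


def decode_ops(text: str) -> list:
    if not text:
        return []
    ops = []
    for tok in text.split(";"):
        parts = tok.split(":")
        if parts[0] == "del":
            ops.append(("del", int(parts[1]), int(parts[2])))
        elif parts[0] == "ins":
            ops.append(("ins", int(parts[1]), parts[2]))
        elif parts[0] == "vec":
            ops.append(("vec", int(parts[1]), int(parts[2]), parts[3],
                        int(parts[4]), int(parts[5])))
        else:
            raise DataError(f"bad truth op token {tok!r}")
    return ops


def reconstruct_from_truth(row, amplicon: AmpliconRef, vector: VectorRef,
                           read_length: int) -> str:
    """Rebuild the emitted (single-end) read from a truth record."""
    ops = decode_ops(row["ops"] if isinstance(row, dict) else row.ops)
    edited, _, _ = apply_ops(amplicon.sequence, ops, vector.sequence)
    start = int(row["read_start"] if isinstance(row, dict) else row.read_start)
    read = list(edited[start:start + read_length])
    subs = row["subs"] if isinstance(row, dict) else row.subs
    if isinstance(subs, str) and subs:
        for tok in subs.split(","):
            mate, pos, base = tok.split(":")
            if mate == "0":
                read[int(pos)] = base
    return "".join(read)


# ---------------------------------------------------------------------------
# Main entry point

def simulate_dataset(
    cfg: SimConfig,
    amplicon: AmpliconRef,
    vector: VectorRef,
    pair: GuidePair,
    out_dir,
    prefix: str = "sim",
) -> SimResult:
    """Write FASTQ read(s) and a truth TSV for one simulated dataset."""
    from .refio import arm_boundaries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    amp = amplicon.sequence
    window = amplicon.quant_window or (0, len(amp))
    n1, n2 = pair.nicks
    boundaries = arm_boundaries(vector)

    # cache MMEJ-compatible deletion sites, failing early if a requested
    # microhomology length has no genuine site on this reference
    site_cache = {}
    if cfg.class_mix.get("mmej_deletion", 0) > 0:
        for m in cfg.mmej_mh_mix:
            sites = enumerate_mh_sites(amplicon, int(m))
            if not sites:
                avail = {
                    k: len(enumerate_mh_sites(amplicon, k)) for k in range(0, 9)
                }
                raise DataError(
                    f"no deletion site with a {m} bp flanking microhomology "
                    f"overlaps the quantification window; available site "
                    f"counts by MH length: { {k: v for k, v in avail.items() if v} }"
                )
            site_cache[int(m)] = sites

    classes = np.array(sorted(cfg.class_mix))
    probs = np.array([cfg.class_mix[c] for c in classes])
    counts = rng.multinomial(cfg.n_reads, probs / probs.sum())
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    rl = cfg.read_length
    rows = []
    fastq_records = [[], []] if cfg.paired else [[]]
    qual_full = chr(cfg.base_quality + 33)
    for i, cls in enumerate(labels):
        mh = ""
        hotspot = ""
        if cls == "wildtype":
            ops = []
        elif cls == "nhej_indel":
            ops = _gen_nhej(rng, pair, amp)
        elif cls == "internick_deletion":
            ops = [("del", n1, n2 - n1)]
        elif cls == "mmej_deletion":
            ops, mh = _gen_mmej(rng, cfg, site_cache)
        elif cls == "templated_insertion":
            ops = _gen_templated(rng, pair, amp)
        elif cls == "vector_insertion":
            ops, hot = _gen_vector_ins(rng, cfg, pair, amp, vector, boundaries)
            hotspot = int(hot)
        else:
            ops = _gen_combined(rng, pair, amp)

        edited, e_lo, e_hi = apply_ops(amp, ops, vector.sequence)
        w_lo = _to_edited_coord(window[0], ops)
        w_hi = _to_edited_coord(window[1], ops)
        span_lo, span_hi = min(e_lo, w_lo), max(e_hi, w_hi)
        lo_min = max(0, span_hi + cfg.min_flank - rl)
        lo_max = min(span_lo - cfg.min_flank, len(edited) - rl)
        if lo_max < lo_min:  # span + flanks exceed the read: centre instead
            start = max(0, min((span_lo + span_hi) // 2 - rl // 2, len(edited) - rl))
        else:
            start = int(rng.integers(lo_min, lo_max + 1))
        fragment = edited[start:start + rl]

        read_id = f"{prefix}_{i:06d}"
        subs = []
        if cfg.paired:
            prl = cfg.pair_read_length
            mates = [fragment[:prl], revcomp(fragment[-prl:])]
        else:
            mates = [fragment]
        emitted = []
        for mate_idx, seq in enumerate(mates):
            seq = list(seq)
            if cfg.sub_error_rate > 0:
                hits = np.flatnonzero(rng.random(len(seq)) < cfg.sub_error_rate)
                for p in hits:
                    new = rng.choice([b for b in "ACGT" if b != seq[p]])
                    seq[p] = new
                    subs.append(f"{mate_idx}:{p}:{new}")
            emitted.append("".join(seq))
        for mate_idx, seq in enumerate(emitted):
            fastq_records[mate_idx].append(
                f"@{read_id}\n{seq}\n+\n{qual_full * len(seq)}\n"
            )
        rows.append({
            "read_id": read_id, "class": cls, "ops": encode_ops(ops),
            "mh_length": mh, "read_start": start, "subs": ",".join(subs),
            "hotspot": hotspot,
        })

    if cfg.paired:
        paths = [out / f"{prefix}_R1.fastq", out / f"{prefix}_R2.fastq"]
    else:
        paths = [out / f"{prefix}.fastq"]
    for path, records in zip(paths, fastq_records):
        path.write_text("".join(records))
    truth = pd.DataFrame(rows, columns=[
        "read_id", "class", "ops", "mh_length", "read_start", "subs", "hotspot",
    ])
    truth_path = out / f"{prefix}_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    class_counts = dict(zip(classes.tolist(), (int(c) for c in counts)))
    return SimResult(paths, truth_path, truth, class_counts)
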