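"""Paired-nickase geometry and guide-level sequence analyses.

A D10A nickase pair on opposite strands converts two single-strand nicks
into one staggered double-strand break. With PAMs facing outward (PAM-out)
the nicks leave 5' overhangs spanning the inter-nick segment; PAM-in pairs
leave 3' overhangs; a same-strand (tandem) pair nicks only one strand and
produces no DSB. Clean excision of the inter-nick segment is the signature
"perfect" deletion, so its expected length equals the nick-to-nick distance.
The distance is measured nick to nick; the protospacer inner-edge gap is
also reported since design tools sometimes quote that instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .errors import DataError
from .refio import AmpliconRef, GuidePair, GuideSpec, VectorRef, iupac_match, revcomp


@dataclass(frozen=True)
class OverhangPrediction:
    polarity: str                 # "5'" | "3'" | "blunt" | "none"
    length: int
    span: tuple[int, int]         # amplicon interval between the nicks


@dataclass(frozen=True)
class GeometryReport:
    orientation: str
    enzyme_mode: str
    inter_nick_distance: int
    protospacer_gap: int
    overhang: OverhangPrediction
    expected_deletion_length: int | None
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "enzyme_mode": self.enzyme_mode,
            "inter_nick_distance": self.inter_nick_distance,
            "protospacer_gap": self.protospacer_gap,
            "overhang_polarity": self.overhang.polarity,
            "overhang_length": self.overhang.length,
            "overhang_span": list(self.overhang.span),
            "expected_deletion_length": self.expected_deletion_length,
            "warning": self.warning,
        }


def _protospacer_gap(pair: GuidePair) -> int:
    """Gap between the two protospacer footprints on the amplicon."""
    iv = sorted(
        (g.protospacer_start, g.protospacer_start + len(g.protospacer))
        for g in (pair.g1, pair.g2)
    )
    return max(0, iv[1][0] - iv[0][1])


def predict_cut_geometry(pair: GuidePair, enzyme_mode: str = "D10A_nickase") -> GeometryReport:
    """Overhang polarity/length and expected perfect-deletion span."""
    if enzyme_mode not in ("nuclease", "D10A_nickase"):
        raise DataError(f"unknown enzyme_mode {enzyme_mode!r}")
    dist = pair.inter_nick_distance
    span = pair.nicks
    warning = None
    if enzyme_mode == "nuclease":
        overhang = OverhangPrediction("blunt", 0, span)
        expected = dist
    elif pair.orientation == "tandem":
        overhang = OverhangPrediction("none", 0, span)
        expected = None
        warning = ("tandem same-strand pair in nickase mode: both nicks fall "
                   "on one strand, no DSB expected")
    elif dist == 0:
        overhang = OverhangPrediction("blunt", 0, span)
        expected = 0
    else:
        polarity = "5'" if pair.orientation == "PAM-out" else "3'"
        overhang = OverhangPrediction(polarity, dist, span)
        expected = dist
    return GeometryReport(
        orientation=pair.orientation, enzyme_mode=enzyme_mode,
        inter_nick_distance=dist, protospacer_gap=_protospacer_gap(pair),
        overhang=overhang, expected_deletion_length=expected, warning=warning,
    )


# ---------------------------------------------------------------------------
# Insertion origin


def _best_infix_identity(query: str, target: str) -> tuple[float, tuple[int, int] | None]:
    """Best identity of ``query`` placed anywhere inside ``target``."""
    if not query or len(target) < 1:
        return 0.0, None
    res = edlib.align(query, target, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or not res["locations"]:
        return 0.0, None
    s, e = res["locations"][0]
    return 1.0 - dist / len(query), (s, e + 1)


def classify_insertion_origin(
    inserted_seq: str,
    amplicon: AmpliconRef,
    pair: GuidePair,
    vector: VectorRef | None = None,
    min_ident: float = 0.90,
) -> tuple[str, tuple[int, int] | None, str]:
    """Attribute an inserted sequence to the inter-nick segment, the vector,
    or neither.

    Insertions shorter than 10 bp must match exactly (short random matches
    are too likely otherwise); longer ones qualify at >= ``min_ident``
    identity. Locus-templated origin takes precedence over vector on ties.
    Returns ``(origin, matched_interval, strand)`` with the interval in
    amplicon coordinates for locus hits and vector coordinates otherwise.
    """
    if not inserted_seq:
        raise DataError("empty insertion")
    ins = inserted_seq.upper()
    n1, n2 = pair.nicks
    region = amplicon.sequence[n1:n2]

    def search(target: str, offset: int):
        exact = len(ins) < 10
        for strand, q in (("+", ins), ("-", revcomp(ins))):
            if exact:
                idx = target.find(q)
                if idx >= 0:
                    return (offset + idx, offset + idx + len(q)), strand
            else:
                ident, loc = _best_infix_identity(q, target)
                if loc is not None and ident >= min_ident:
                    return (offset + loc[0], offset + loc[1]), strand
        return None

    found = search(region, n1)
    if found:
        return "locus_templated", found[0], found[1]
    if vector is not None:
        found = search(vector.sequence, 0)
        if found:
            return "vector", found[0], found[1]
    return "other", None, "+"


# ---------------------------------------------------------------------------
# Off-target identity with degenerate PAMs


def offtarget_identity(site_seq: str, guide: GuideSpec,
                       pam_pattern: str = "NNGRRT") -> float:
    """Percent identity between a candidate site and guide + degenerate PAM.

    Every position weighs equally. A protospacer position matches when the
    bases are identical; a PAM position matches when the site base falls in
    the IUPAC class of the pattern character (R = {A,G}, N = any base), so a
    fully degenerate position can never mismatch.
    """
    pattern = guide.protospacer + pam_pattern.upper()
    site = site_seq.upper()
    if len(site) != len(pattern):
        raise DataError(
            f"site length {len(site)} != protospacer+PAM length {len(pattern)}"
        )
    matches = sum(1 for s, p in zip(site, pattern) if iupac_match(s, p))
    return 100.0 * matches / len(pattern)
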