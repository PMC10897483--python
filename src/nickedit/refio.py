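"""Reference loading, validation and coordinate conventions.

All coordinates are 0-based, half-open. Cut/nick sites are *between-base*
integers: a nick at position ``p`` falls between ``sequence[p-1]`` and
``sequence[p]``, so a clean excision of the inter-nick segment removes
``sequence[n1:n2]``.

A guide is described by its protospacer on the protospacer strand, its PAM,
the strand relative to the amplicon, and the amplicon coordinate of the
leftmost protospacer base. The single-strand nick introduced by a D10A
nickase sits ``nick_offset`` nucleotides 5' of the PAM-proximal protospacer
end (default 3, the canonical Cas9 blunt-cut position; configurable because
the exact SaCas9 offset is a convention, not a measurement).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DataError

DNA_REF = set("ACGT")

#: IUPAC degenerate-base classes used for PAM matching.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def iupac_match(base: str, pattern_char: str) -> bool:
    """True if ``base`` is compatible with the degenerate ``pattern_char``.

    Uses the subset rule: the IUPAC class of the observed base must be
    contained in the class of the pattern character, so an ``N`` in the
    observed sequence matches only an ``N`` in the pattern.
    """
    try:
        return IUPAC[base.upper()] <= IUPAC[pattern_char.upper()]
    except KeyError as exc:
        raise DataError(f"not an IUPAC base code: {exc}") from None


@dataclass(frozen=True)
class AmpliconRef:
    """An amplicon-scale reference with cut-site annotation."""

    name: str
    sequence: str
    cut_sites: tuple[int, ...] = ()
    quant_window: tuple[int, int] | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise DataError(f"amplicon {self.name!r}: empty sequence")
        bad = set(seq) - DNA_REF
        if bad:
            raise DataError(
                f"amplicon {self.name!r}: non-ACGT characters {sorted(bad)} "
                "(ambiguity codes are not allowed in references)"
            )
        for c in self.cut_sites:
            if not 0 <= c <= len(seq):
                raise DataError(f"amplicon {self.name!r}: cut site {c} outside [0, {len(seq)}]")
        if self.quant_window is not None:
            lo, hi = self.quant_window
            if not (0 <= lo <= hi <= len(seq)):
                raise DataError(f"amplicon {self.name!r}: quant_window {self.quant_window} outside sequence")
            for c in self.cut_sites:
                if not lo <= c <= hi:
                    raise DataError(f"amplicon {self.name!r}: cut site {c} outside quant_window")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideSpec:
    """One protospacer/PAM record placed on an amplicon."""

    name: str
    protospacer: str
    pam: str
    strand: str
    protospacer_start: int
    nick_offset: int = 3

    def __post_init__(self):
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())
        if self.strand not in {"+", "-"}:
            raise DataError(f"guide {self.name!r}: strand must be '+' or '-'")
        if not 0 <= self.nick_offset <= len(self.protospacer):
            raise DataError(f"guide {self.name!r}: nick_offset outside protospacer")

    def validate_on(self, amplicon: AmpliconRef) -> None:
        """Check that the protospacer and PAM map exactly where declared."""
        s, L, P = self.protospacer_start, len(self.protospacer), len(self.pam)
        seq = amplicon.sequence
        if self.strand == "+":
            found = seq[s:s + L]
            pam_obs = seq[s + L:s + L + P]
        else:
            found = revcomp(seq[s:s + L])
            pam_obs = revcomp(seq[max(0, s - P):s])
        if found != self.protospacer:
            raise DataError(
                f"guide {self.name!r}: protospacer not found on amplicon "
                f"{amplicon.name!r} at {self.strand}{s} (expected "
                f"{self.protospacer}, reference has {found})"
            )
        if len(pam_obs) != P or not all(iupac_match(b, p) for b, p in zip(pam_obs, self.pam)):
            raise DataError(
                f"guide {self.name!r}: PAM mismatch at declared position "
                f"(pattern {self.pam}, reference has {pam_obs or 'nothing'})"
            )
        n = nick_position(self)
        if not 0 <= n <= len(amplicon):
            raise DataError(f"guide {self.name!r}: nick position {n} outside amplicon")


def nick_position(g: GuideSpec) -> int:
    """Between-base coordinate of the single-strand nick on the amplicon.

    The nick sits ``nick_offset`` nt 5' of the PAM-proximal protospacer end
    on the protospacer strand; on the minus strand the coordinate mirrors.
    """
    if g.strand == "+":
        return g.protospacer_start + len(g.protospacer) - g.nick_offset
    return g.protospacer_start + g.nick_offset


def classify_orientation(g1: GuideSpec, g2: GuideSpec) -> str:
    """Derive PAM layout class from strands and protospacer placement."""
    if g1.strand == g2.strand:
        return "tandem"
    plus = g1 if g1.strand == "+" else g2
    minus = g2 if plus is g1 else g1
    mid = lambda g: g.protospacer_start + len(g.protospacer) / 2  # noqa: E731
    # plus-strand PAM points right, minus-strand PAM points left:
    # minus guide left of plus guide -> PAMs face away from each other.
    return "PAM-out" if mid(minus) < mid(plus) else "PAM-in"


@dataclass(frozen=True)
class GuidePair:
    g1: GuideSpec
    g2: GuideSpec
    orientation: str = field(init=False)
    inter_nick_distance: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "orientation", classify_orientation(self.g1, self.g2))
        object.__setattr__(
            self, "inter_nick_distance",
            abs(nick_position(self.g2) - nick_position(self.g1)),
        )

    @property
    def nicks(self) -> tuple[int, int]:
        """Nick positions in ascending order."""
        a, b = nick_position(self.g1), nick_position(self.g2)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class VectorRef:
    """A vector genome with feature annotation including ITR arm intervals."""

    name: str
    sequence: str
    features: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise DataError(f"vector {self.name!r}: empty sequence")
        bad = set(self.sequence) - DNA_REF
        if bad:
            raise DataError(f"vector {self.name!r}: non-ACGT characters {sorted(bad)}")
        for label, start, end, strand in self.features:
            if not 0 <= start < end <= len(self.sequence):
                raise DataError(
                    f"vector {self.name!r}: feature {label!r} interval "
                    f"[{start}, {end}) outside sequence bounds"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def itr_features(self) -> list[tuple[str, int, int, str]]:
        return [f for f in self.features if "ITR" in f[0].upper()]


def _arm_letter(label: str) -> str | None:
    """Extract the ITR arm letter from a feature label like ``ITR5_Bp``."""
    if "ITR" not in label.upper():
        return None
    token = label.rsplit("_", 1)[-1].rstrip("p'′").upper()
    return token if token in {"A", "B", "C", "D"} else None


def arm_boundaries(vector: VectorRef) -> list[int]:
    """Positions where an A/A' arm abuts a B/B' arm, one per ITR.

    These are the junctions between the ITR stem (A-A') and the internal
    palindrome (B-B'), the region where truncated-ITR integration breakpoints
    concentrate.
    """
    feats = sorted(vector.itr_features(), key=lambda f: f[1])
    out = []
    for f, g in zip(feats, feats[1:]):
        if f[2] != g[1]:
            continue
        a, b = _arm_letter(f[0]), _arm_letter(g[0])
        if a and b and {a, b} == {"A", "B"}:
            out.append(f[2])
    return out


# ---------------------------------------------------------------------------
# File I/O


def _read_single_fasta(path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise DataError(f"{path}: duplicate sequence names {names}")
    if len(records) > 1:
        raise DataError(f"{path}: expected a single sequence, found {names}")
    return records[0].id, str(records[0].seq).upper()


def load_guides_tsv(path, default_nick_offset: int = 3) -> list[GuideSpec]:
    """Parse a guide TSV with columns name, protospacer, pam, strand, start[, nick_offset]."""
    required = {"name", "protospacer", "pam", "strand", "start"}
    guides = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(
                f"{path}: guide TSV must have columns {sorted(required)}; "
                f"found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                guides.append(GuideSpec(
                    name=row["name"],
                    protospacer=row["protospacer"],
                    pam=row["pam"],
                    strand=row["strand"],
                    protospacer_start=int(row["start"]),
                    nick_offset=int(row.get("nick_offset") or default_nick_offset),
                ))
            except (KeyError, ValueError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
    return guides


def load_features_tsv(path) -> list[tuple[str, int, int, str]]:
    """Parse a 4-column BED-like feature TSV (label, start, end, strand)."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}")
            label, start, end, strand = parts
            try:
                feats.append((label, int(start), int(end), strand))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
    return feats


def load_references(
    amplicon_path,
    vector_path,
    guides_path,
    vector_features_path=None,
    default_nick_offset: int = 3,
    quant_pad: int = 5,
) -> tuple[AmpliconRef, VectorRef, GuidePair]:
    """Load and validate the amplicon, vector and guide-pair design.

    Cut sites are derived from the guides via ``nick_offset`` and the quant
    window defaults to the cut sites padded by ``quant_pad`` on each side.
    """
    amp_name, amp_seq = _read_single_fasta(amplicon_path)
    vec_name, vec_seq = _read_single_fasta(vector_path)
    if amp_name == vec_name:
        raise DataError(f"amplicon and vector share the name {amp_name!r}")
    guides = load_guides_tsv(guides_path, default_nick_offset)
    if len(guides) != 2:
        raise DataError(f"{guides_path}: expected exactly 2 guides for a pair, found {len(guides)}")
    feats = load_features_tsv(vector_features_path) if vector_features_path else []
    vector = VectorRef(vec_name, vec_seq, tuple(feats))
    amplicon = AmpliconRef(amp_name, amp_seq)
    for g in guides:
        g.validate_on(amplicon)
    pair = GuidePair(*guides)
    cuts = tuple(sorted(pair.nicks))
    window = (max(0, cuts[0] - quant_pad), min(len(amp_seq), cuts[-1] + quant_pad))
    amplicon = replace(amplicon, cut_sites=cuts, quant_window=window)
    return amplicon, vector, pair


def write_fasta(path, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def write_guides_tsv(path, pair: GuidePair) -> None:
    with open(path, "w") as fh:
        fh.write("name\tprotospacer\tpam\tstrand\tstart\tnick_offset\n")
        for g in (pair.g1, pair.g2):
            fh.write(f"{g.name}\t{g.protospacer}\t{g.pam}\t{g.strand}\t"
                     f"{g.protospacer_start}\t{g.nick_offset}\n")


def write_features_tsv(path, vector: VectorRef) -> None:
    with open(path, "w") as fh:
        for label, start, end, strand in vector.features:
            fh.write(f"{label}\t{start}\t{end}\t{strand}\n")


def write_references(out_dir, amplicon: AmpliconRef, vector: VectorRef, pair: GuidePair) -> dict:
    """Write the reference bundle; returns the path map used by ``load_references``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "amplicon": out / "amplicon.fa",
        "vector": out / "vector.fa",
        "guides": out / "guides.tsv",
        "features": out / "vector_features.tsv",
    }
    write_fasta(paths["amplicon"], amplicon.name, amplicon.sequence)
    write_fasta(paths["vector"], vector.name, vector.sequence)
    write_guides_tsv(paths["guides"], pair)
    write_features_tsv(paths["features"], vector)
    return paths
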