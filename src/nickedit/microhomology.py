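"""Microhomology scoring at deletion junctions.

MMEJ (microhomology-mediated end joining) anneals short identical sequences
flanking a double-strand break, so the deletions it produces carry a
characteristic junction microhomology. We define the microhomology length of
a deletion as its *placement ambiguity*: for a left-aligned deletion of
``[s, e)`` it is the largest ``m`` with
``amplicon[s:s+m] == amplicon[e:e+m]``, i.e. the number of alternative
sequence-equivalent placements of the same deletion. The microhomology is a
property of the reference deletion, computed after left-normalisation, and
therefore robust to read errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DataError
from .refio import AmpliconRef


@dataclass(frozen=True)
class MHCall:
    """Microhomology call for one deletion interval."""

    start: int
    end: int
    mh_length: int
    mh_sequence: str


def scan_mh(start: int, end: int, amplicon: AmpliconRef | str) -> MHCall:
    """Length of the microhomology flanking the deletion ``[start, end)``.

    The deletion must be normalised (left-aligned); the scan never reads past
    the end of the reference, so ``mh_length`` is capped at ``len - end``.
    """
    seq = amplicon if isinstance(amplicon, str) else amplicon.sequence
    if not 0 <= start < end <= len(seq):
        raise DataError(f"deletion interval [{start}, {end}) out of bounds for length {len(seq)}")
    m = 0
    while end + m < len(seq) and seq[start + m] == seq[end + m]:
        m += 1
    return MHCall(start, end, m, seq[start:start + m])


def mh_summary(
    deletions: pd.DataFrame,
    amplicon: AmpliconRef,
    mh_threshold: int = 2,
    top_n: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Score and summarise junction microhomology over a deletion table.

    ``deletions`` needs columns ``start``, ``size`` and ``support`` (read
    counts); one row per distinct deletion. Returns the per-deletion MH table
    and a summary dict with the support-weighted fraction of deletions whose
    MH exceeds ``mh_threshold`` (strictly greater, the conventional MMEJ
    cutoff), a histogram of deletion read counts by MH-length class
    (0,1,2,3,4,>=5) and the most supported recurrent MH deletions.
    """
    if len(deletions) == 0:
        return (
            pd.DataFrame(columns=["start", "size", "mh_length", "mh_sequence", "support"]),
            {"fraction_mh_gt_threshold": None, "mh_threshold": mh_threshold,
             "histogram": {}, "top": []},
        )
    rows = []
    for rec in deletions.itertuples(index=False):
        call = scan_mh(int(rec.start), int(rec.start) + int(rec.size), amplicon)
        rows.append({
            "start": int(rec.start), "size": int(rec.size),
            "mh_length": call.mh_length, "mh_sequence": call.mh_sequence,
            "support": int(rec.support),
        })
    table = pd.DataFrame(rows)
    total = table["support"].sum()
    frac = table.loc[table["mh_length"] > mh_threshold, "support"].sum() / total
    bins = table["mh_length"].clip(upper=5)
    hist = {
        ("5+" if k == 5 else str(k)): int(v)
        for k, v in table.groupby(bins)["support"].sum().items()
    }
    top = (
        table[table["mh_length"] > 0]
        .sort_values(["support", "mh_length"], ascending=False)
        .head(top_n)
        .to_dict("records")
    )
    summary = {
        "fraction_mh_gt_threshold": float(frac),
        "mh_threshold": mh_threshold,
        "histogram": hist,
        "top": top,
    }
    return table, summary
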