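"""Microhomology at deletion junctions.

The microhomology length of a deletion is its placement ambiguity: the
longest stretch for which the bases at the deletion start equal the bases
immediately after its end. MMEJ repair preferentially produces deletions
with MH > 2 bp.
"""

import nickedit as ne

# toy example: deleting "ACT" from GGG[ACT]ACTTTT is placeable 4 ways
call = ne.scan_mh(3, 6, "GGGACTACTTTT")
print(f"toy deletion [3,6) of GGGACTACTTTT: MH length {call.mh_length}, "
      f"sequence {call.mh_sequence!r}")

# on the synthetic locus, list deletion sites with genuine 4 bp and 5 bp MH
amplicon, pair = ne.build_synthetic_locus(seed=101)
for m in (4, 5):
    sites = ne.enumerate_mh_sites(amplicon, m)
    s, k = sites[0]
    print(f"{len(sites):3d} deletion sites with exactly {m} bp MH in the "
          f"quantification window; e.g. a {k} bp deletion at {s} "
          f"(MH {ne.scan_mh(s, s + k, amplicon).mh_sequence!r})")
# The engineered locus carries a 23 bp deletion site with a 4 bp MH and a
# 10 bp site with a 5 bp MH, the two recurrent MMEJ signatures the
# simulator reproduces.
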