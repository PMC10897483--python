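"""Off-target site identity with a degenerate PAM.

Candidate off-target sites are scored as the fraction of matching positions
over protospacer + PAM, where degenerate PAM positions (pattern NNGRRT for
SaCas9) match any base of their IUPAC class.
"""

import nickedit as ne

_, pair = ne.build_synthetic_locus(seed=101)
g = pair.g1

perfect = g.protospacer + "AAGAAT"          # PAM fits NNGRRT
pam_mut = g.protospacer + "AACAAT"          # G position violated
flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
body = list(g.protospacer)
body[0], body[1] = flip[body[0]], flip[body[1]]  # two real mismatches
body_mut = "".join(body) + "AAGAAT"

for label, site in (("perfect site", perfect),
                    ("PAM G>C", pam_mut),
                    ("2 protospacer mismatches", body_mut)):
    print(f"{label:28s}: {ne.offtarget_identity(site, g):5.1f} % identity")
# 100% requires every non-degenerate position to match; each mismatch
# removes 1/27 of the score for a 21 nt protospacer + 6 nt PAM.
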