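"""Paired-guide cut-site geometry.

For a D10A nickase pair the PAM layout decides the overhang: PAM-out pairs
leave 5' overhangs spanning the inter-nick segment, whose clean excision is
the signature "perfect" deletion; the same guides with wildtype nuclease
give blunt cuts.
"""

import json

import nickedit as ne

_, pair = ne.build_synthetic_locus(seed=101)

for mode in ("D10A_nickase", "nuclease"):
    rep = ne.predict_cut_geometry(pair, enzyme_mode=mode)
    print(f"--- {mode} ---")
    print(json.dumps(rep.to_dict(), indent=2))

# The 64 bp inter-nick distance with PAM-out orientation means simultaneous
# nicking leaves a 64 nt 5' overhang; the expected perfect deletion removes
# exactly those 64 bp.
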