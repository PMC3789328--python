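"""Scan a miRNA against an EST for binding sites (miRanda-style scoring)."""

import numpy as np

from sharkmir.target_scan import ScanParams, scan
from sharkmir.util import revcomp

rng = np.random.default_rng(2)
mirna = "UGGAGUGUGACAAUGGUGUUUG"
est = (
    "".join(rng.choice(list("ACGU"), size=60))
    + revcomp(mirna)
    + "".join(rng.choice(list("ACGU"), size=60))
)

params = ScanParams()  # gap open -8, extend -2, score >= 50, energy <= -20
for hit in scan(mirna, est, params, mirna_id="miR-x", target_id="est1"):
    print(f"site {hit.target_start + 1}-{hit.target_end} on {hit.target_id}: "
          f"score {hit.score:.1f}, energy {hit.energy:.1f} kcal/mol, "
          f"{hit.n_pairs} pairs")
    print(hit.render())
# The query line is the miRNA 3'->5'; '|' marks Watson-Crick pairs, ':' G:U
# wobbles.  Positions 2-8 from the miRNA 5' end (the seed) score double,
# and a site must clear both the score and the energy threshold.
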