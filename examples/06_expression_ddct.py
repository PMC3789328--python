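"""Quantify expression: log2 read ratios and qPCR 2^-ddCt fold changes."""

import numpy as np
import pandas as pd

from sharkmir.quantify import CtTable, ddct_table, expression_table
from sharkmir.synthetic_fixtures import simulate_ct_table

# --- sequencing side: RPM + log2 ratio ---------------------------------
counts = pd.DataFrame(
    {"LN": [520, 40, 310], "LR24": [1450, 38, 95]},
    index=["miR-a", "miR-b", "miR-c"],
)
totals = {"LN": 1_000_000, "LR24": 1_200_000}
expr = expression_table(counts, totals, treated="LR24", control="LN")
print(expr[["LN_rpm", "LR24_rpm", "log2_ratio", "differential"]].round(2))
# |log2 ratio| > 1 (strict) marks a miRNA as differentially expressed.

# --- qPCR side: 2^-ddCt -------------------------------------------------
rng = np.random.default_rng(1)
ct = simulate_ct_table(
    rng, {"miR-a": {"LR6": 4.2, "LR12": 2.2, "LR24": 0.7}},
    reference_gene="18S", control_group="LN", replicates=3, noise_sd=0.1,
)
table = CtTable(ct, reference_gene="18S", control_group="LN")
print()
print(ddct_table(table).round(3).to_string(index=False))
# dCt = Ct(target)-Ct(reference) on replicate means; ddCt subtracts the
# control group; 2^-ddCt is the relative expression (control = 1 exactly).
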