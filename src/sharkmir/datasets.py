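"""Bundled reference numbers used by examples and reproduction scripts.

``GROUP_READ_COUNTS`` is the published distribution of clean small-RNA
reads among the ten mapping groups for the two bamboo-shark liver
libraries: LN (normal liver, 0 h) and LR24 (regenerating liver, 24 h after
partial hepatectomy).  The per-group counts are the printed values; totals
and percentages are recomputed from them by the package.
"""

from __future__ import annotations

from typing import Dict

GROUP_READ_COUNTS: Dict[str, Dict[str, int]] = {
    "LN": {
        "1a": 0,
        "1b": 1_600_835,
        "2a": 56_020,
        "2b": 25_388,
        "3a": 2_300_528,
        "3b": 72_334,
        "4a": 310_150,
        "4b": 301_238,
        "5": 6_032_607,
        "6": 4_662_701,
    },
    "LR24": {
        "1a": 0,
        "1b": 985_411,
        "2a": 39_787,
        "2b": 12_569,
        "3a": 1_113_914,
        "3b": 40_956,
        "4a": 153_216,
        "4b": 195_545,
        "5": 4_341_986,
        "6": 3_263_199,
    },
}

#: published library totals the group counts must add up to
LIBRARY_TOTALS: Dict[str, int] = {"LN": 15_361_801, "LR24": 10_146_583}

#: published one-decimal group percentages, for cross-checking
GROUP_PERCENTAGES: Dict[str, Dict[str, float]] = {
    "LN": {
        "1a": 0.0, "1b": 10.4, "2a": 0.4, "2b": 0.2, "3a": 15.0,
        "3b": 0.5, "4a": 2.0, "4b": 2.0, "5": 39.3, "6": 30.4,
    },
    "LR24": {
        "1a": 0.0, "1b": 9.7, "2a": 0.4, "2b": 0.1, "3a": 11.0,
        "3b": 0.4, "4a": 1.5, "4b": 1.9, "5": 42.8, "6": 32.2,
    },
}
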