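"""Reference descriptive statistics for the four Mediterranean sheep breeds.

Total run counts and post-QC sample sizes per breed and mode, used as
desk-scale inputs for validating the breed-summary arithmetic (mean runs
per individual = total runs / individuals).
"""

from __future__ import annotations

__all__ = ["REFERENCE_RUN_TOTALS", "REFERENCE_BREEDS"]

REFERENCE_BREEDS = ("BAR", "NOT", "SAR", "VDB")

# mode -> breed -> (total runs, post-QC individuals)
REFERENCE_RUN_TOTALS: dict[str, dict[str, tuple[int, int]]] = {
    "HOM": {
        "BAR": (4018, 48),
        "NOT": (4434, 48),
        "SAR": (8453, 140),
        "VDB": (7545, 136),
    },
    "HET": {
        "BAR": (214, 48),
        "NOT": (274, 48),
        "SAR": (790, 140),
        "VDB": (884, 136),
    },
}
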