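"""Published summary tables for the barley InDel marker panel this
pipeline emulates (Morex x Barke, 1140 InDel markers integrated with SSR,
DArT and SNP panels into a single POPSEQ-anchored map).

These constants are worked-example inputs: feeding them through
:func:`indelmark.integrate.summarize`-style arithmetic reproduces the
published per-chromosome densities and totals, which serves as an exact
cross-check of the summary code on real numbers.
"""

from __future__ import annotations

CHROMOSOMES = ["1H", "2H", "3H", "4H", "5H", "6H", "7H"]

# Per-chromosome InDel marker counts by length class (bp).
INDEL_LENGTH_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "1-2":   {"1H": 12, "2H": 4,  "3H": 0,  "4H": 6,   "5H": 31,  "6H": 2,   "7H": 0},
    "3-10":  {"1H": 107, "2H": 92, "3H": 84, "4H": 101, "5H": 136, "6H": 57,  "7H": 70},
    "11-20": {"1H": 33, "2H": 26, "3H": 37, "4H": 29,  "5H": 36,  "6H": 16,  "7H": 35},
    "21-30": {"1H": 12, "2H": 13, "3H": 16, "4H": 14,  "5H": 9,   "6H": 9,   "7H": 8},
    "31-40": {"1H": 6,  "2H": 7,  "3H": 6,  "4H": 3,   "5H": 10,  "6H": 7,   "7H": 10},
    "41-50": {"1H": 4,  "2H": 4,  "3H": 4,  "4H": 2,   "5H": 2,   "6H": 2,   "7H": 5},
    ">50":   {"1H": 13, "2H": 12, "3H": 6,  "4H": 4,   "5H": 17,  "6H": 13,  "7H": 8},
}

# Per-chromosome genetic map lengths (cM) and total as printed.
CHROMOSOME_LENGTH_CM: dict[str, float] = {
    "1H": 142.2, "2H": 149.2, "3H": 155.0, "4H": 115.2,
    "5H": 169.4, "6H": 126.6, "7H": 140.9,
}
TOTAL_LENGTH_CM = 998.4  # printed total (per-chromosome values sum to 998.5)

# Integrated single-map marker counts per chromosome and marker system.
INTEGRATED_MARKER_COUNTS: dict[str, dict[str, int]] = {
    "1H": {"SNP": 481, "DArT": 182, "SSR": 41, "InDel": 187},
    "2H": {"SNP": 644, "DArT": 285, "SSR": 66, "InDel": 158},
    "3H": {"SNP": 597, "DArT": 256, "SSR": 58, "InDel": 153},
    "4H": {"SNP": 450, "DArT": 140, "SSR": 45, "InDel": 159},
    "5H": {"SNP": 713, "DArT": 214, "SSR": 55, "InDel": 241},
    "6H": {"SNP": 463, "DArT": 207, "SSR": 51, "InDel": 106},
    "7H": {"SNP": 561, "DArT": 260, "SSR": 67, "InDel": 136},
}

# HRM survey: 55 markers assayed, 36 with delta-Tm > 0.3 C; PAGE survey:
# 43 markers tested, 2 monomorphic; map drawing: 436 duplicate-position
# InDel markers collapsed out of 1140.
HRM_MARKERS_TESTED = 55
HRM_MARKERS_GENOTYPABLE = 36
PAGE_MARKERS_TESTED = 43
PAGE_MARKERS_MONOMORPHIC = 2
INDEL_MARKERS_TOTAL = 1140
DUPLICATE_POSITION_MARKERS = 436


def indel_counts_per_chromosome() -> dict[str, int]:
    """Total InDel markers per chromosome (sum over length classes)."""
    return {
        ch: sum(row[ch] for row in INDEL_LENGTH_CLASS_COUNTS.values())
        for ch in CHROMOSOMES
    }
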