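"""Published input tables for the OGDH mutually-exclusive-exon analyses.

These are the printed clone counts and codon counts that the statistical
re-analyses take as input: Sanger clone counts of distant branch-point (dBP)
usage in human and chicken *OGDH* intron 4a under three cellular conditions
(DBR1-deficient cells additionally lacking TIA-1/TIAR, overexpressing PUF60,
or untreated), and the aspartate/glutamate codon counts over the reference
exonic splicing enhancer (ESE, n=1182 hexamers) and silencer (ESS, n=1090)
sets, 4 overlapping codon windows per hexamer (totals 4728 and 4360).
"""

from __future__ import annotations

import pandas as pd

from .lariat import UsageTable
from .splicecode import CodonCountTable

__all__ = [
    "HUMAN_DBP_BINS",
    "CHICKEN_DBP_BINS",
    "human_usage_table",
    "chicken_usage_table",
    "ESE_N_HEXAMERS",
    "ESS_N_HEXAMERS",
    "ESE_CODON_TOTAL",
    "ESS_CODON_TOTAL",
    "DE_CODON_COUNTS",
    "de_codon_count_tables",
    "U2_CORE_BOX",
]

#: Human dBP adenine positions, nt downstream of the intron 4a 5'ss.
HUMAN_DBP_BINS: tuple[int, ...] = (25, 31, 36, 41)

#: Chicken orthologue positions and their human-orthologous bins:
#: 23~25, 29~31, 34~36, 39~41.
CHICKEN_DBP_BINS: tuple[int, ...] = (23, 29, 34, 39)

#: DNA form of the U2 snRNA GUAGUA branch-point-interacting box.
U2_CORE_BOX = "GTAGTA"

_CONDITIONS = ("TIA1/TIAR depleted", "PUF60 overexpressing", "control")

_HUMAN_COUNTS = {
    "TIA1/TIAR depleted": (14, 12, 10, 3),
    "PUF60 overexpressing": (18, 15, 10, 0),
    "control": (14, 23, 12, 1),
}

_CHICKEN_COUNTS = {
    "TIA1/TIAR depleted": (0, 0, 5, 7),
    "PUF60 overexpressing": (0, 0, 2, 12),
    "control": (1, 1, 2, 10),
}


def human_usage_table() -> UsageTable:
    """Informative Sanger clone counts per human dBP bin (rows: conditions)."""
    return UsageTable.from_dict(_HUMAN_COUNTS, HUMAN_DBP_BINS)


def chicken_usage_table(human_bins: bool = False) -> UsageTable:
    """Informative clone counts per chicken dBP bin.

    With ``human_bins`` the columns are relabelled to the orthologous human
    positions so human and chicken rows can be stacked into one table.
    """
    bins = HUMAN_DBP_BINS if human_bins else CHICKEN_DBP_BINS
    return UsageTable.from_dict(_CHICKEN_COUNTS, bins)


# --- splicing-regulatory codon counts --------------------------------------

ESE_N_HEXAMERS = 1182
ESS_N_HEXAMERS = 1090
ESE_CODON_TOTAL = 4 * ESE_N_HEXAMERS  # 4728
ESS_CODON_TOTAL = 4 * ESS_N_HEXAMERS  # 4360

#: (ESE count, ESS count) of the D/E codons over the reference hexamer sets.
DE_CODON_COUNTS: dict[str, tuple[int, int]] = {
    "GAA": (146, 10),
    "GAG": (105, 32),
    "GAC": (177, 7),
    "GAT": (113, 23),
}


def de_codon_count_tables() -> tuple[CodonCountTable, CodonCountTable]:
    """Partial codon-count tables holding the published D/E codon counts.

    Only the four aspartate/glutamate codons carry counts; the totals are the
    full published window totals, so frequencies and fold excesses for these
    codons are exact.
    """
    ese = CodonCountTable(
        {c: n for c, (n, _) in DE_CODON_COUNTS.items()},
        total=ESE_CODON_TOTAL,
        set_label="ESE",
    )
    ess = CodonCountTable(
        {c: n for c, (_, n) in DE_CODON_COUNTS.items()},
        total=ESS_CODON_TOTAL,
        set_label="ESS",
    )
    return ese, ess
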