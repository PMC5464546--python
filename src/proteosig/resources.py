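"""Shipped fixtures: the screened-protein reference list, named reduced
predictors, and the UniProt accession -> gene symbol map they rely on.

These are editable data tables, not derived quantities; the pipeline only
reads them when asked to score one of the named predictors.
"""

from __future__ import annotations

# accession -> (gene symbol, univariate HR, p) for the 18 screened proteins
SCREENED_PROTEINS: dict[str, tuple[str, float, float]] = {
    "O43175": ("PHGDH", 0.689, 0.001),
    "O75323": ("GBAS", 1.830, 0.001),
    "P05091": ("ALDH2", 0.423, 0.002),
    "P05161": ("ISG15", 0.500, 0.002),
    "P07996": ("THBS1", 0.649, 0.002),
    "P14317": ("HCLS1", 0.379, 0.003),
    "P15153": ("RAC2", 0.423, 0.003),
    "P18085": ("ARF4", 3.754, 0.003),
    "P20340": ("RAB6A", 0.493, 0.004),
    "P28065": ("PSMB9", 0.758, 0.005),
    "P53004": ("BLVRA", 0.674, 0.006),
    "P62873": ("GNB1", 0.703, 0.006),
    "Q09666": ("AHNAK", 1.614, 0.006),
    "Q15046": ("KARS", 0.672, 0.008),
    "Q15181": ("PPA1", 2.184, 0.008),
    "Q9BUP0": ("EFHD1", 0.265, 0.009),
    "Q9GZZ9": ("UBA5", 0.316, 0.009),
    "Q9NR31": ("SAR1A", 0.222, 0.009),
}

PROTEIN_TO_GENE: dict[str, str] = {
    acc: gene for acc, (gene, _hr, _p) in SCREENED_PROTEINS.items()
}

# Named reduced predictors (accession sets)
PREDICTOR_P1: list[str] = ["P53004", "P05161", "P28065", "O75323"]
PREDICTOR_P5: list[str] = ["P15153", "P20340", "P53004", "Q15181"]

NAMED_PREDICTORS: dict[str, list[str]] = {
    "P1": PREDICTOR_P1,
    "P5": PREDICTOR_P5,
}
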