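"""The published per-class competition score table (precision, recall,
F1, support for 27 classes, n = 585), used as printed input data for
metric-identity checks."""

# class: (precision, recall, f1, support)
TABLE = {
    "ACRU": (0.15625, 0.147059, 0.151515, 34),
    "ACSA3": (0.0, 0.0, 0.0, 3),
    "AMLA": (0.0, 0.0, 0.0, 0),
    "CAGL8": (0.0, 0.0, 0.0, 19),
    "CATO6": (0.0, 0.0, 0.0, 0),
    "FAGR": (0.0, 0.0, 0.0, 3),
    "LITU": (0.0, 0.0, 0.0, 14),
    "NYBI": (0.0, 0.0, 0.0, 0),
    "NYSY": (0.0, 0.0, 0.0, 12),
    "OXYDE": (0.0, 0.0, 0.0, 0),
    "Other": (0.259259, 0.185841, 0.216495, 113),
    "PIEL": (0.0, 0.0, 0.0, 0),
    "PINUS": (0.0, 0.0, 0.0, 5),
    "PIPA2": (0.65, 0.80791, 0.720403, 177),
    "PITA": (0.0, 0.0, 0.0, 30),
    "PRSE2": (0.0, 0.0, 0.0, 0),
    "QUAL": (0.076923, 0.043478, 0.055556, 23),
    "QUCO2": (0.0, 0.0, 0.0, 0),
    "QUERC": (0.0, 0.0, 0.0, 23),
    "QUGE2": (0.153846, 0.1, 0.121212, 20),
    "QUHE2": (0.0, 0.0, 0.0, 3),
    "QULA2": (0.40625, 0.371429, 0.38806, 35),
    "QUMO4": (0.0, 0.0, 0.0, 15),
    "QUNI": (0.0, 0.0, 0.0, 22),
    "QURU": (0.384615, 0.208333, 0.27027, 24),
    "ROPS": (0.0, 0.0, 0.0, 5),
    "TSCA": (0.0, 0.0, 0.0, 5),
}

MACRO_F1 = 0.071241
WEIGHTED_F1 = 0.309226
TOTAL_SUPPORT = 585
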