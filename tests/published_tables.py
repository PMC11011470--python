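"""Published derived-metric cells (percent, printed rounding) from the
source study's per-entity and combined-reading tables.  The counts they
derive from live in :mod:`triagecut.reference`; the strings here preserve
the printed precision so tests can compare at half-ulp tolerance."""

from triagecut.reference import EXPLORATORY_COUNTS, YOUDEN_COUNTS

YOUDEN_PRINTED = {
    "sensitivity": dict(zip(YOUDEN_COUNTS, ["100", "82.4", "69.7", "86.4", "87.1", "83.3", "88.4"])),
    "specificity": dict(zip(YOUDEN_COUNTS, ["58.0", "80.6", "82.0", "86.4", "73.5", "88.1", "57.1"])),
    "ppv": dict(zip(YOUDEN_COUNTS, ["6.25", "24.56", "22.33", "50.44", "18.62", "8.20", "16.96"])),
    "npv": dict(zip(YOUDEN_COUNTS, ["100", "98.35", "97.33", "97.53", "98.80", "99.76", "98.02"])),
    "fpr": dict(zip(YOUDEN_COUNTS, ["42.03", "19.41", "18.02", "13.63", "26.46", "11.89", "42.86"])),
    # fracture TP prints "23 (4.87)" at source, but 23/477 = 4.82%: the
    # percentage cell is a typo; the count-derived value is asserted.
    "tp_fraction": dict(zip(YOUDEN_COUNTS, ["2.73", "5.87", "4.82", "11.95", "5.66", "1.05", "7.97"])),
    "fn_fraction": dict(zip(YOUDEN_COUNTS, ["0", "1.26", "2.10", "1.89", "0.84", "0.21", "1.05"])),
}
EXPLORATORY_PRINTED = {
    "sensitivity": dict(zip(EXPLORATORY_COUNTS, ["100", "97.1", "97.0", "95.5", "96.8", "100", "95.3"])),
    "specificity": dict(zip(EXPLORATORY_COUNTS, ["58.0", "55.3", "20.0", "63.0", "44.2", "30.1", "40.6"])),
    "ppv": dict(zip(EXPLORATORY_COUNTS, ["6.25", "14.29", "8.27", "29.30", "10.75", "1.79", "13.71"])),
    "npv": dict(zip(EXPLORATORY_COUNTS, ["100", "99.59", "98.89", "98.85", "99.49", "100", "98.88"])),
    "fpr": dict(zip(EXPLORATORY_COUNTS, ["42.03", "44.70", "79.95", "36.98", "55.83", "69.85", "59.45"])),
    "tp_fraction": dict(zip(EXPLORATORY_COUNTS, ["2.73", "6.92", "6.71", "13.21", "6.29", "1.26", "8.6"])),
    "fn_fraction": dict(zip(EXPLORATORY_COUNTS, ["0", "0.21", "0.21", "0.63", "0.21", "0", "0.42"])),
}
COMBINED_PRINTED = {
    "youden": {"sensitivity": "31.37", "specificity": "14.55",
               "ppv": "4.21", "npv": "63.92", "fpr": "85.45",
               "tp_fraction": "3.35", "tn_fraction": "13",
               "fp_fraction": "76.31", "fn_fraction": "7.34"},
    "min_sensitivity": {"sensitivity": "27.27", "specificity": "1.07",
                        "ppv": "0.65", "npv": "38.46", "fpr": "98.93",
                        "tp_fraction": "0.63", "tn_fraction": "1.05",
                        "fp_fraction": "96.65", "fn_fraction": "1.68"},
}
# Average rows: (metric, printed value, convention that reproduces it)
YOUDEN_AVERAGE_PRINTED = [
    ("sensitivity", "85.3", "arithmetic"),
    ("specificity", "75.1", "arithmetic"),
    ("ppv", "21.05", "arithmetic"),
    ("npv", "98.54", "arithmetic"),
    ("fpr", "24.96", "pooled"),
]
EXPLORATORY_AVERAGE_PRINTED = [
    ("sensitivity", "97.4", "arithmetic"),
    ("specificity", "44.5", "arithmetic"),
    ("ppv", "11.16", "pooled"),
    ("npv", "99.42", "pooled"),
    ("fpr", "55.77", "pooled"),
]
# Averaged counts: (value, pct-of-477) pairs, always arithmetic means.
YOUDEN_AVERAGE_COUNTS = {
    "tp": ("27.29", "5.72"), "tn": ("333.71", "69.96"),
    "fp": ("111", "23.27"), "fn": ("5", "1.05"),
}
EXPLORATORY_AVERAGE_COUNTS = {
    "tp": ("31.14", "6.53"), "tn": ("196.71", "41.24"),
    "fp": ("248", "51.99"), "fn": ("1.14", "0.24"),
}
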