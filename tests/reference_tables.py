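"""Reference results of the three-hospital chart-review validation study.

Each row: (algorithm, possible cases, tp, fp, fn, PPV, PPV CI low/high,
sensitivity, sensitivity CI low/high), percentages as published (2
decimals).  The APC screening row anchors the denominator, so its
sensitivity is 100% by design and carries no interval.  The pooled 4x4
reviewer-agreement table (rows: one reviewer, columns: the other; category
order True A, True B, Suspected, Other) is the published cross-
classification of all 348 sampled cases.
"""

AGREEMENT_MATRIX = [
    [57, 4, 1, 3],
    [3, 16, 2, 1],
    [0, 1, 6, 1],
    [0, 3, 2, 248],
]

# primary analysis: Suspected counted as not true
PRIMARY_ROWS = [
    ("APC", 348, 86, 262, 0, 24.71, 20.27, 29.59, 100.00, None, None),
    ("ALG1", 160, 68, 92, 18, 42.50, 34.73, 50.55, 79.07, 68.95, 87.10),
    ("ALG2", 166, 69, 97, 17, 41.57, 33.98, 49.46, 80.23, 70.25, 88.04),
    ("ALG3", 157, 67, 90, 19, 42.68, 34.83, 50.81, 77.91, 67.67, 86.14),
    ("ALG4", 119, 58, 61, 28, 48.74, 39.47, 58.07, 67.44, 56.48, 77.16),
    ("ALG5", 97, 45, 52, 41, 46.39, 36.20, 56.81, 52.33, 41.27, 63.21),
    ("ALG6", 88, 43, 45, 43, 48.86, 38.05, 59.75, 50.00, 39.02, 60.98),
    ("ALG7", 94, 54, 40, 32, 57.45, 46.82, 67.59, 62.79, 51.70, 72.98),
    ("ALG8", 27, 21, 6, 65, 77.78, 57.74, 91.38, 24.42, 15.80, 34.87),
    ("ALG9", 189, 77, 112, 9, 40.74, 33.67, 48.11, 89.53, 81.06, 95.10),
    ("ALG10", 157, 70, 87, 16, 44.59, 36.66, 52.72, 81.40, 71.55, 88.98),
    ("ALG11", 141, 64, 77, 22, 45.39, 36.99, 53.98, 74.42, 63.87, 83.22),
    ("ALG12", 111, 59, 52, 27, 53.15, 43.45, 62.69, 68.60, 57.70, 78.19),
    ("ALG13", 151, 67, 84, 19, 44.37, 36.30, 52.67, 77.91, 67.67, 86.14),
    ("ALG14", 29, 17, 12, 69, 58.62, 38.94, 76.48, 19.77, 11.96, 29.75),
    ("ALG15", 86, 42, 44, 44, 48.84, 37.90, 59.86, 48.84, 37.90, 59.86),
    ("ALG16", 80, 40, 40, 46, 50.00, 38.60, 61.40, 46.51, 35.68, 57.59),
    ("ALG17", 95, 55, 40, 31, 57.89, 47.33, 67.96, 63.95, 52.88, 74.03),
    ("ALG18", 29, 22, 7, 64, 75.86, 56.46, 89.70, 25.58, 16.78, 36.13),
]

# sensitivity analysis: Suspected counted as true
SENSITIVITY_ROWS = [
    ("APC", 348, 95, 253, 0, 27.30, 22.69, 32.30, 100.00, None, None),
    ("ALG1", 160, 75, 85, 20, 46.88, 38.95, 54.92, 78.95, 69.38, 86.64),
    ("ALG2", 166, 76, 90, 19, 45.78, 38.04, 53.68, 80.00, 70.54, 87.51),
    ("ALG3", 157, 73, 84, 22, 46.50, 38.51, 54.62, 76.84, 67.06, 84.88),
    ("ALG4", 119, 64, 55, 31, 53.78, 44.41, 62.96, 67.37, 56.98, 76.64),
    ("ALG5", 97, 50, 47, 45, 51.55, 41.18, 61.82, 52.63, 42.12, 62.97),
    ("ALG6", 88, 47, 41, 48, 53.41, 42.46, 64.12, 49.47, 39.05, 59.93),
    ("ALG7", 94, 58, 36, 37, 61.70, 51.10, 71.54, 61.05, 50.50, 70.89),
    ("ALG8", 27, 22, 5, 73, 81.48, 61.92, 93.70, 23.16, 15.12, 32.94),
    ("ALG9", 189, 84, 105, 11, 44.44, 37.23, 51.83, 88.42, 80.23, 94.08),
    ("ALG10", 157, 76, 81, 19, 48.41, 40.37, 56.51, 80.00, 70.54, 87.51),
    ("ALG11", 141, 68, 73, 27, 48.23, 39.74, 56.79, 71.58, 61.40, 80.36),
    ("ALG12", 111, 64, 47, 31, 57.66, 47.92, 66.98, 67.37, 56.98, 76.64),
    ("ALG13", 151, 72, 79, 23, 47.68, 39.50, 55.96, 75.79, 65.92, 83.99),
    ("ALG14", 29, 17, 12, 78, 58.62, 38.94, 76.48, 17.89, 10.78, 27.10),
    ("ALG15", 86, 47, 39, 48, 54.65, 43.55, 65.42, 49.47, 39.05, 59.93),
    ("ALG16", 80, 44, 36, 51, 55.00, 43.47, 66.15, 46.32, 36.02, 56.85),
    ("ALG17", 95, 58, 37, 37, 61.05, 50.50, 70.89, 61.05, 50.50, 70.89),
    ("ALG18", 29, 23, 6, 72, 79.31, 60.28, 92.01, 24.21, 16.01, 34.08),
]
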