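"""Packaged summary of the reference sepsis cohort.

The packaged table records, for each social-determinant category of the 5,783
Sepsis-3 patients of the source ICU cohort: the category size ``n``, its printed
percentage of the cohort, the number of in-hospital deaths, the printed
in-hospital mortality percentage, and the train/test counts under the study's
7:3 random split. It is the calibration target for the synthetic-cohort
generator and the fixture for the summary-arithmetic checks.
"""

from __future__ import annotations

import pandas as pd

COHORT_TOTAL = 5783

# (determinant, category, n, pct_cohort, deaths, pct_deaths, n_train, n_test)
_ROWS = [
    ("race", "Asian", 179, 3.10, 26, 14.53, 129, 50),
    ("race", "Black or African American", 501, 8.66, 52, 10.38, 348, 153),
    ("race", "Hispanic or Latino", 188, 3.25, 18, 9.57, 132, 56),
    ("race", "Other", 714, 12.35, 165, 23.11, 527, 187),
    ("race", "White", 4201, 72.64, 575, 13.69, 2912, 1289),
    ("sex", "Female", 2562, 44.30, 384, 14.99, 1798, 764),
    ("sex", "Male", 3221, 55.70, 452, 14.03, 2250, 971),
    ("marital", "Separated", 398, 6.88, 52, 13.07, 287, 111),
    ("marital", "Significant other", 2559, 44.25, 363, 14.19, 1788, 771),
    ("marital", "Single", 1638, 28.32, 174, 10.62, 1157, 481),
    ("marital", "Unknown", 332, 5.74, 102, 30.72, 248, 84),
    ("marital", "Widowed", 856, 14.80, 145, 16.94, 568, 288),
    ("insurance", "Government", 166, 2.87, 13, 7.83, 115, 51),
    ("insurance", "Medicaid", 570, 9.86, 67, 11.75, 395, 175),
    ("insurance", "Medicare", 3358, 58.07, 560, 16.68, 2335, 1023),
    ("insurance", "Private", 1639, 28.34, 185, 11.29, 1168, 471),
    ("insurance", "Self-pay", 50, 0.86, 11, 22.00, 35, 15),
    ("language", "English", 5167, 89.35, 727, 14.07, 3631, 1536),
    ("language", "Other", 499, 8.63, 94, 18.84, 339, 160),
    ("language", "Spanish", 117, 2.02, 15, 12.82, 78, 39),
]

_COLUMNS = [
    "determinant",
    "category",
    "n",
    "pct_cohort",
    "deaths",
    "pct_deaths",
    "n_train",
    "n_test",
]


def reference_summary() -> pd.DataFrame:
    """Return the packaged cohort summary as a long-format DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
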