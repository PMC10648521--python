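"""Published reference statistics for the breast-CT screening cohort.

These are the printed summary numbers of the 517-woman photon-counting
breast-CT density study this package models: per-age-group counts, mean ages,
and mean ± SD of breast tissue volume (BTV, cm^3), mammary gland volume
(MGV, cm^3) and percent breast density (PBD, %), plus the quadrant table and
the published age-regression models. They are the inputs for reproduction
runs (the raw scans are confidential and not deposited).

Note: the age-group counts sum to 1033 while the study text reports 1027
examinations; both constants are kept and the discrepancy is surfaced here
rather than resolved.
"""

from __future__ import annotations

import pandas as pd

#: Examinations reported in the study text.
N_EXAMINATIONS = 1027
#: Sum of the per-age-group counts in the demographics table (differs from
#: N_EXAMINATIONS by 6; unexplained in the source).
N_GROUPED = 1033
#: Number of women.
N_WOMEN = 517

#: Seven five-year age bins, 40-74 years.
AGE_BINS = [(40, 44), (45, 49), (50, 54), (55, 59), (60, 64), (65, 69), (70, 74)]
AGE_BIN_LABELS = [f"{lo}–{hi}" for lo, hi in AGE_BINS]


def age_group_table() -> pd.DataFrame:
    """Per-age-group demographics and composition features (mean, SD).

    Columns: bin, n, age_mean, age_sd, btv_mean, btv_sd, mgv_mean, mgv_sd,
    pbd_mean, pbd_sd. Volumes in cm^3, PBD in percent.
    """
    return pd.DataFrame(
        {
            "bin": AGE_BIN_LABELS,
            "n": [62, 120, 292, 190, 176, 123, 70],
            "age_mean": [42, 47, 52, 57, 62, 67, 72],
            "age_sd": [1, 1, 1, 1, 2, 1, 1],
            "btv_mean": [545, 539, 589, 657, 627, 663, 676],
            "btv_sd": [345, 314, 365, 416, 401, 424, 412],
            "mgv_mean": [111, 77, 64, 56, 51, 50, 57],
            "mgv_sd": [164, 64, 59, 55, 43, 57, 43],
            "pbd_mean": [24, 17, 14, 13, 13, 10, 11],
            "pbd_sd": [21, 15, 12, 14, 13, 9, 9],
        }
    )


def quadrant_table() -> pd.DataFrame:
    """Quadrant composition features and shares over all ages.

    Rows: entire breast plus UOQ/UIQ/LOQ/LIQ. Shares are percentages of the
    entire breast; the PBD ratio is quadrant PBD as a percentage of
    whole-breast PBD. Missing entries (shares of the entire breast) are NaN.
    """
    return pd.DataFrame(
        {
            "region": ["entire", "UOQ", "UIQ", "LOQ", "LIQ"],
            "btv_mean": [614, 208, 164, 126, 117],
            "btv_sd": [388, 135, 107, 17, 12],
            "btv_share_mean": [None, 34, 28, 19, 19],
            "btv_share_sd": [None, 9, 8, 7, 7],
            "mgv_mean": [62, 21, 13, 17, 12],
            "mgv_sd": [68, 23, 15, 24, 17],
            "mgv_share_mean": [None, 34, 21, 26, 18],
            "mgv_share_sd": [None, 14, 11, 13, 10],
            "pbd_mean": [14, 13, 11, 19, 13],
            "pbd_sd": [13, 13, 13, 17, 14],
            "pbd_ratio_mean": [None, 99, 75, 142, 92],
            "pbd_ratio_sd": [None, 31, 27, 47, 37],
        }
    )


#: Published age-regression models: feature -> (family, a, b, RSE).
#: BTV(age) = 290 ln(age) - 554 (RSE 386 cm^3); MGV = 4885/age - 26
#: (RSE 67 cm^3); PBD = 1237/age - 8.4 (RSE 13 %).
PUBLISHED_MODELS = {
    "btv": {"family": "log", "a": 290.0, "b": -554.0, "rse": 386.0},
    "mgv": {"family": "inverse", "a": 4885.0, "b": -26.0, "rse": 67.0},
    "pbd": {"family": "inverse", "a": 1237.0, "b": -8.4, "rse": 13.0},
}

#: Printed uncertainties of (a, b) for the three models, kept for display
#: only: they cannot be reconstructed from the grouped statistics. The 822 on
#: a=4885 alongside p<0.05 is internally surprising in the source and is
#: recorded as printed.
PUBLISHED_COEF_UNCERTAINTY = {
    "btv": (86.0, 345.0),
    "mgv": (822.0, 15.0),
    "pbd": (160.0, 2.9),
}

#: Whole-cohort averages: (mean, SD) per feature.
PUBLISHED_OVERALL = {"btv": (614.0, 388.0), "mgv": (62.0, 68.0), "pbd": (14.0, 13.0)}
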