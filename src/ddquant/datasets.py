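"""Bundled reference measurements for a chicken-in-sheep adulteration assay.

Published wet-lab measurements from a QX200 ddPCR / TaqMan qPCR study of
chicken adulteration in sheep meat, included as validation inputs: the
calibration and performance routines must reproduce the summary
statistics reported alongside them.  All concentrations are copies/uL
as read off the instrument; fractions are mass percentages.
"""

from __future__ import annotations

import pandas as pd

from .types import SpeciesPair

__all__ = [
    "equal_mass_parallels",
    "k_mixture_series",
    "method_comparison",
    "repeatability_replicates",
    "standard_curve_coefficients",
]


def equal_mass_parallels() -> list[SpeciesPair]:
    """Six parallel 50/50 (w/w) sheep/chicken reference extractions.

    Mean copy concentrations per parallel; used to calibrate the
    multiplication factor k = Qs/Qc on the equal-mass reference
    (reported summary: k ~ 0.8, RSD 3.1%).
    """
    sheep = [265.0, 336.0, 324.0, 373.3, 379.3, 327.0]
    chicken = [335.33, 406.0, 395.3, 471.7, 480.0, 384.7]
    return [SpeciesPair(q_adulterant=c, q_base=s) for c, s in zip(chicken, sheep)]


def k_mixture_series() -> pd.DataFrame:
    """Triplicate concentrations across five known chicken fractions.

    Columns: chicken_percent, chicken_1..3, sheep_1..3 (copies/uL) and
    the k value reported for the row.  The 1% row's reported k is not
    consistent with its printed triplicates (recomputing gives ~0.63);
    it is retained verbatim but excluded from validation checks.
    """
    rows = [
        (80.0, 770.0, 769.0, 768.0, 160.0, 159.0, 160.0, 0.8),
        (50.0, 375.0, 378.0, 376.0, 292.0, 295.0, 305.0, 0.8),
        (20.0, 163.0, 157.0, 161.0, 484.0, 472.0, 476.0, 0.7),
        (10.0, 103.0, 100.0, 99.0, 714.0, 718.0, 721.0, 0.8),
        (1.0, 9.7, 9.1, 7.6, 556.0, 536.0, 547.0, 0.8),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chicken_percent",
            "chicken_1", "chicken_2", "chicken_3",
            "sheep_1", "sheep_2", "sheep_3",
            "k_reported",
        ],
    )


def method_comparison() -> pd.DataFrame:
    """Measured chicken fractions by ddPCR and qPCR across six levels.

    Mean measured percentage, RSD and bias per method, as reported for
    mixtures of 1-80% chicken in sheep.
    """
    rows = [
        (80.0, 79.1, 68.1, 0.4, 2.5, -1.2, -14.9),
        (50.0, 49.8, 34.9, 1.3, 4.8, -0.4, -30.2),
        (20.0, 20.8, 12.7, 1.9, 1.9, 4.2, -36.5),
        (10.0, 9.9, 5.4, 2.0, 9.1, -1.0, -45.8),
        (5.0, 4.8, 2.9, 0.5, 8.7, -3.4, -41.1),
        (1.0, 1.3, 0.6, 13.8, 8.6, 24.8, -35.8),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "true_percent",
            "ddpcr_mean", "qpcr_mean",
            "ddpcr_rsd", "qpcr_rsd",
            "ddpcr_bias", "qpcr_bias",
        ],
    )


def repeatability_replicates() -> dict[str, dict[float, list[float]]]:
    """Six-replicate measured fractions per level for two operators.

    Levels 1-10% chicken; used for LOQ determination and repeatability
    summaries (mean, sample RSD, bias).
    """
    return {
        "A": {
            10.0: [9.22, 9.26, 9.03, 9.19, 9.39, 9.01],
            5.0: [5.08, 4.75, 4.74, 5.03, 4.87, 5.31],
            4.0: [4.24, 3.72, 3.85, 4.10, 3.80, 4.23],
            3.0: [2.72, 3.02, 2.89, 2.70, 2.82, 3.12],
            2.0: [2.14, 2.22, 2.10, 2.13, 2.33, 2.11],
            1.0: [1.30, 1.32, 1.14, 1.13, 1.08, 1.36],
        },
        "B": {
            10.0: [9.24, 9.49, 9.01, 9.14, 9.25, 9.84],
            5.0: [5.19, 5.20, 4.89, 4.80, 4.77, 5.04],
            4.0: [4.23, 4.32, 3.87, 3.75, 4.10, 4.11],
            3.0: [2.79, 2.91, 3.07, 2.72, 2.86, 2.80],
            2.0: [2.34, 2.11, 2.28, 2.12, 2.29, 2.27],
            1.0: [1.15, 1.34, 1.28, 1.12, 1.23, 1.20],
        },
    }


def standard_curve_coefficients() -> pd.DataFrame:
    """Reported qPCR standard-curve coefficients per species.

    Ct = slope * log10(copies) + intercept, fitted on six 4-fold
    dilutions of an equal-mass standard declared at 1e5 copies/uL.
    """
    rows = [
        ("chicken", -3.449, 39.57, 0.999),
        ("sheep", -3.480, 40.52, 0.997),
    ]
    return pd.DataFrame(rows, columns=["target", "slope", "intercept", "r_squared"])
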