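"""Assay-validation metrics: bias, RSD, linearity, LOQ and LOD.

Conventions (used throughout and in all reports):

* RSD is the sample (n-1) relative standard deviation, 100*SD/mean.
* Bias is 100*(measured - true)/true.
* The limit of quantification (LOQ) is the smallest adulterant level
  that — together with every larger tested level — stays within the
  RSD and |bias| acceptance limits (default 25%, the FAO-style rule
  for DNA-based food quantification).
* The limit of detection (LOD) is the smallest level at which every
  replicate well still shows at least ``min_positives`` positive
  droplets, a guard against calling isolated false-positive droplets.
"""

from __future__ import annotations

import statistics
from typing import Optional, Sequence

from scipy import stats

from .types import (
    InvalidInputError,
    LevelSummary,
    PartitionCount,
    bias_percent,
    sample_rsd_percent,
)

__all__ = [
    "summarize_level",
    "linearity",
    "determine_loq",
    "determine_lod",
]


def summarize_level(
    true_fraction: float,
    measured_values: Sequence[float],
) -> LevelSummary:
    """Summarise replicate fraction measurements at one known level."""
    vals = tuple(float(v) for v in measured_values)
    if len(vals) < 2:
        raise InvalidInputError(
            "level summary needs >=2 replicates for a sample RSD"
        )
    mean = statistics.fmean(vals)
    return LevelSummary(
        true_fraction_percent=float(true_fraction),
        measured_values=vals,
        mean_percent=mean,
        rsd_percent=sample_rsd_percent(vals),
        bias_percent=bias_percent(mean, true_fraction),
    )


def linearity(levels: Sequence[LevelSummary]) -> tuple[float, float]:
    """OLS of mean measured fraction on true fraction: (slope, r_squared).

    The r-squared over the dynamic range is the standard check that the
    assay responds linearly from trace to dominant adulterant levels.
    """
    levels = list(levels)
    if len(levels) < 3:
        raise InvalidInputError("linearity needs >=3 levels")
    xs = [s.true_fraction_percent for s in levels]
    ys = [s.mean_percent for s in levels]
    if len(set(xs)) < 2:
        raise InvalidInputError("true fractions must vary")
    fit = stats.linregress(xs, ys)
    return fit.slope, fit.rvalue**2


def _passes(s: LevelSummary, rsd_limit: float,
            bias_limit: Optional[float]) -> bool:
    if s.rsd_percent > rsd_limit:
        return False
    return bias_limit is None or abs(s.bias_percent) <= bias_limit


def determine_loq(
    levels: Sequence[LevelSummary],
    rsd_limit: float = 25.0,
    bias_limit: Optional[float] = 25.0,
) -> Optional[float]:
    """Smallest level passing the precision/accuracy gates contiguously.

    Levels are scanned from the largest true fraction downward; the LOQ
    is the smallest level of the unbroken passing run — once a level
    fails, everything below it is excluded even if it would pass in
    isolation.  ``bias_limit=None`` disables the accuracy gate (an
    RSD-only rule).

    Returns None when even the largest level fails.
    """
    levels = list(levels)
    if not levels:
        raise InvalidInputError("determine_loq needs >=1 level")
    ordered = sorted(levels, key=lambda s: s.true_fraction_percent,
                     reverse=True)
    loq: Optional[float] = None
    for s in ordered:
        if _passes(s, rsd_limit, bias_limit):
            loq = s.true_fraction_percent
        else:
            break
    return loq


def determine_lod(
    levels: Sequence[tuple[float, Sequence[PartitionCount]]],
    min_positives: int = 3,
) -> Optional[float]:
    """Smallest level at which every replicate well is reliably positive.

    Parameters
    ----------
    levels : sequence of (true_fraction_percent, wells)
        Adulterant-target wells per dilution level.
    min_positives : int
        Minimum positive droplets required in *every* replicate well; the
        default of 3 rejects levels where a single stray droplet would
        otherwise be called a detection.

    Returns
    -------
    float or None
        The smallest qualifying level of the unbroken run from the top,
        or None when no level qualifies.
    """
    levels = list(levels)
    if not levels:
        raise InvalidInputError("determine_lod needs >=1 level")
    ordered = sorted(levels, key=lambda lv: lv[0], reverse=True)
    lod: Optional[float] = None
    for frac, wells in ordered:
        wells = list(wells)
        if not wells:
            raise InvalidInputError(f"level {frac}: no replicate wells")
        if all(w.positives >= min_positives for w in wells):
            lod = frac
        else:
            break
    return lod
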