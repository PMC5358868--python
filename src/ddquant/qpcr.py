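"""Real-time PCR standard curves and the qPCR-based fraction estimate.

The comparator method: the threshold cycle Ct is linear in log10 of
starting copies, Ct = slope * log10(copies) + intercept.  Fitting a
dilution series gives the curve; unknowns are interpolated back to
copies, and the adulterant fraction is the copy-number share

    P = 100 * C_adulterant / (C_adulterant + C_base).

Unlike the ddPCR route this carries the amplification-efficiency and
copies-per-unit-mass discrepancies of the two assays straight into the
fraction, which is why its bias is systematically larger.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Sequence

from scipy import stats

from .types import CtObservation, InvalidInputError, StandardCurve

__all__ = [
    "fit_standard_curve",
    "efficiency_from_slope",
    "ct_to_copies",
    "qpcr_fraction",
]

#: Slope of a perfectly doubling reaction, -1/log10(2).
PERFECT_DOUBLING_SLOPE = -1.0 / math.log10(2.0)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent, 100*(10^(-1/slope) - 1)."""
    if slope >= 0:
        raise InvalidInputError(
            f"slope must be negative for a dilution series, got {slope}"
        )
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(
    standards: Sequence[CtObservation],
    use_level_means: bool = True,
) -> StandardCurve:
    """Fit Ct = slope * log10(copies) + intercept by ordinary least squares.

    Parameters
    ----------
    standards : sequence of CtObservation
        Observations with ``log10_copies`` set.  Replicates at the same
        level are averaged before fitting by default, matching the
        convention of plotting mean Ct per dilution level.
    use_level_means : bool
        If False, fit the raw replicate Ct values instead.

    Raises
    ------
    InvalidInputError
        Fewer than three distinct levels, no spread in levels, or a
        non-negative fitted slope (a sign-flipped or degenerate series).
    """
    pts = [(o.log10_copies, o.ct) for o in standards if o.log10_copies is not None]
    if use_level_means:
        by_level: dict[float, list[float]] = defaultdict(list)
        for x, y in pts:
            by_level[x].append(y)
        pts = [(x, sum(ys) / len(ys)) for x, ys in sorted(by_level.items())]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise InvalidInputError(
            f"standard-curve fit needs >=3 distinct log10_copies levels, "
            f"got {len(levels)}"
        )
    xs = [x for x, _ in pts]
    ys = [y for _, y in pts]
    fit = stats.linregress(xs, ys)
    if fit.slope >= 0:
        raise InvalidInputError(
            f"fitted slope {fit.slope:.4g} is non-negative: Ct must "
            "decrease with template copies — curve flagged invalid"
        )
    return StandardCurve(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.rvalue**2,
        efficiency_percent=efficiency_from_slope(fit.slope),
        log10_range=(min(levels), max(levels)),
    )


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Interpolate a Ct back to copies: 10^((ct - intercept)/slope).

    Extrapolation beyond the fitted range is permitted; callers can
    compare ``(ct - intercept)/slope`` against ``curve.log10_range``.
    """
    if not math.isfinite(ct):
        raise InvalidInputError("ct must be finite")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def is_extrapolated(ct: float, curve: StandardCurve) -> bool:
    """True when the implied log10 copies fall outside the fitted range."""
    log10_c = (ct - curve.intercept) / curve.slope
    lo, hi = curve.log10_range
    return not lo <= log10_c <= hi


def qpcr_fraction(c_adulterant: float, c_base: float) -> float:
    """Copy-number share of the adulterant, in percent.

    100 * Ca / (Ca + Cb); scale-invariant in the pair of concentrations.
    """
    if c_adulterant < 0 or c_base < 0:
        raise InvalidInputError("concentrations must be non-negative")
    total = c_adulterant + c_base
    if total == 0:
        raise InvalidInputError(
            "fraction undefined when both concentrations are zero"
        )
    return 100.0 * c_adulterant / total
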