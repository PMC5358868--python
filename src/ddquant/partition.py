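"""Poisson partition statistics: droplet counts to copy concentrations.

Under random partitioning, the number of target copies per droplet is
Poisson with mean lambda, so the probability a droplet is positive is
p = 1 - exp(-lambda).  Inverting the observed positive fraction P/R
gives the maximum-likelihood estimate

    lambda_hat = -ln(1 - P/R)

which is the entire measurement model of droplet digital PCR: no
standard curve and no amplification-efficiency assumption enter.
Concentration in copies/uL follows by dividing by the droplet volume.
"""

from __future__ import annotations

import math
from typing import Sequence

from scipy import stats

from .types import (
    DEFAULT_DROPLET_VOLUME_NL,
    MERGED_REPLICATE,
    ConcentrationEstimate,
    InvalidInputError,
    PartitionCount,
    SaturationError,
)

__all__ = [
    "lambda_from_counts",
    "estimate_copies_per_partition",
    "concentration_interval",
    "pool_wells",
]


def lambda_from_counts(positives: int, total: int) -> float:
    """Mean copies per partition, -ln(1 - P/R).

    Raises
    ------
    SaturationError
        If every droplet is positive (the estimate diverges).
    InvalidInputError
        If counts are inconsistent.
    """
    if total <= 0:
        raise InvalidInputError(f"total must be positive, got {total}")
    if positives < 0 or positives > total:
        raise InvalidInputError(
            f"positives must lie in [0, {total}], got {positives}"
        )
    if positives == total:
        raise SaturationError(
            f"all {total} droplets positive: concentration unbounded; "
            "dilute the sample and re-run"
        )
    # log1p for accuracy at small positive fractions
    return -math.log1p(-positives / total)


def _droplet_volume_ul(droplet_volume_nl: float) -> float:
    if droplet_volume_nl <= 0:
        raise InvalidInputError("droplet volume must be positive")
    return droplet_volume_nl * 1e-3


def estimate_copies_per_partition(
    count: PartitionCount,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    level: float = 0.95,
) -> ConcentrationEstimate:
    """Point estimate and CI of concentration from one well's counts.

    Parameters
    ----------
    count : PartitionCount
        Positive/total droplet counts.
    droplet_volume_nl : float
        Droplet volume in nL; sets the copies/uL scale only.
    level : float
        Coverage probability of the confidence interval.

    Returns
    -------
    ConcentrationEstimate
        lambda, copies/uL (dilution-corrected) and the CI on copies/uL.
    """
    lam = lambda_from_counts(count.positives, count.total)
    vol = _droplet_volume_ul(droplet_volume_nl)
    scale = count.dilution_factor / vol
    low, high = _lambda_interval(count, level)
    return ConcentrationEstimate(
        lam=lam,
        conc=lam * scale,
        ci_low=low * scale,
        ci_high=high * scale,
        n_partitions=count.total,
    )


def _lambda_interval(count: PartitionCount, level: float) -> tuple[float, float]:
    """Delta-method interval on lambda; exact one-sided bound at P=0.

    SE(lambda_hat) = sqrt(p_hat / ((1 - p_hat) * R)) by the delta method
    applied to -ln(1-p) with binomial variance p(1-p)/R.
    """
    if not 0.0 < level < 1.0:
        raise InvalidInputError("level must lie in (0, 1)")
    P, R = count.positives, count.total
    if P == R:
        raise SaturationError("all droplets positive: interval unbounded")
    if P == 0:
        # exact one-sided binomial bound: largest p with
        # Pr(0 successes | p) >= 1 - level
        p_up = 1.0 - (1.0 - level) ** (1.0 / R)
        return 0.0, -math.log1p(-p_up)
    p_hat = P / R
    lam = -math.log1p(-p_hat)
    se = math.sqrt(p_hat / ((1.0 - p_hat) * R))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return max(0.0, lam - z * se), lam + z * se


def concentration_interval(
    count: PartitionCount,
    level: float = 0.95,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> tuple[float, float]:
    """Confidence interval on concentration (copies/uL) for one well."""
    vol = _droplet_volume_ul(droplet_volume_nl)
    scale = count.dilution_factor / vol
    low, high = _lambda_interval(count, level)
    return low * scale, high * scale


def pool_wells(counts: Sequence[PartitionCount]) -> PartitionCount:
    """Merge replicate wells of one sample/target by summing counts.

    Pooling counts before the Poisson inversion is the standard
    merged-well estimate; for small lambda it agrees with the
    precision-weighted average of per-well estimates.
    """
    counts = list(counts)
    if not counts:
        raise InvalidInputError("cannot pool an empty list of wells")
    first = counts[0]
    for c in counts[1:]:
        if c.sample_id != first.sample_id or c.target != first.target:
            raise InvalidInputError(
                "pooled wells must share sample_id and target: "
                f"({first.sample_id}, {first.target}) vs "
                f"({c.sample_id}, {c.target})"
            )
        if c.dilution_factor != first.dilution_factor:
            raise InvalidInputError("pooled wells must share dilution_factor")
    return PartitionCount(
        sample_id=first.sample_id,
        target=first.target,
        replicate=MERGED_REPLICATE,
        positives=sum(c.positives for c in counts),
        total=sum(c.total for c in counts),
        dilution_factor=first.dilution_factor,
    )
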