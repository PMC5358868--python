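"""Multiplication-factor calibration and copy-ratio -> mass-fraction conversion.

Equal masses of two meats do not yield equal target-gene copy numbers:
cell density, genome size and extraction behaviour differ by species.
For a fixed extraction procedure the copies-per-unit-mass constants Cc
(adulterant, chicken) and Cs (base species, sheep) are stable, so their
ratio

    k = Cs / Cc

is a single calibration constant.  Measured copy concentrations Qc, Qs
then convert to a mass ratio by

    Mc/Ms = (Qc/Cc) / (Qs/Cs) = k * (Qc/Qs)

and the adulterant mass fraction is 100 * (Mc/Ms) / (1 + Mc/Ms).
A single equal-mass (50/50 w/w) reference mixture suffices to estimate
k, because Mc/Ms = 1 forces k = Qs/Qc.
"""

from __future__ import annotations

import statistics
from typing import Optional, Sequence

from .types import (
    InvalidInputError,
    KFactor,
    QuantResult,
    SpeciesPair,
    bias_percent,
    sample_rsd_percent,
)

__all__ = [
    "k_from_equal_mass",
    "k_from_known_mixture",
    "mass_fraction",
    "quantify_replicates",
]


def k_from_equal_mass(pairs: Sequence[SpeciesPair]) -> KFactor:
    """Estimate k from replicate measurements of a 50/50 w/w reference.

    Each replicate gives k_i = Qs_i / Qc_i; the pooled k is the
    arithmetic mean of the per-replicate ratios (not the ratio of means)
    and the spread is their sample RSD.

    Parameters
    ----------
    pairs : sequence of SpeciesPair
        Paired adulterant/base concentrations, one per replicate
        extraction; at least two are required for an RSD.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise InvalidInputError(
            "equal-mass calibration needs >=2 replicate pairs"
        )
    reps = []
    for i, p in enumerate(pairs):
        if p.q_adulterant <= 0:
            raise InvalidInputError(
                f"replicate {i}: zero adulterant concentration in a 50/50 "
                "reference — check target assignment or well quality"
            )
        reps.append(p.q_base / p.q_adulterant)
    value = statistics.fmean(reps)
    return KFactor(
        value=value,
        replicate_values=tuple(reps),
        rsd_percent=sample_rsd_percent(reps),
    )


def k_from_known_mixture(mass_ratio_true: float, pair: SpeciesPair) -> float:
    """k implied by one measurement of a mixture with known mass ratio.

    Inverts Mc/Ms = k * (Qc/Qs):  k = (Mc/Ms) / (Qc/Qs).
    """
    if mass_ratio_true <= 0:
        raise InvalidInputError("true mass ratio must be positive")
    if pair.q_adulterant <= 0:
        raise InvalidInputError(
            "adulterant concentration must be positive to infer k"
        )
    return mass_ratio_true / pair.copy_ratio


def mass_fraction(pair: SpeciesPair, k: KFactor | float) -> QuantResult:
    """Convert one pair of copy concentrations into a mass fraction.

    mass_ratio = k * Qc/Qs; fraction = 100 * mass_ratio / (1 + mass_ratio).
    """
    k_value = k.value if isinstance(k, KFactor) else float(k)
    if k_value <= 0:
        raise InvalidInputError("k must be positive")
    ratio = k_value * pair.copy_ratio
    return QuantResult(
        fraction_percent=100.0 * ratio / (1.0 + ratio),
        mass_ratio=ratio,
    )


def quantify_replicates(
    pairs: Sequence[SpeciesPair],
    k: KFactor | float,
    true_fraction: Optional[float] = None,
) -> QuantResult:
    """Quantify a sample from replicate pairs; summarise mean, RSD, bias.

    Parameters
    ----------
    pairs : sequence of SpeciesPair
        One concentration pair per replicate.
    k : KFactor or float
        Calibrated multiplication factor.
    true_fraction : float, optional
        Known adulterant mass percentage; when given, the summary carries
        bias = 100 * (mean - true) / true.
    """
    pairs = list(pairs)
    if not pairs:
        raise InvalidInputError("quantify_replicates needs >=1 pair")
    fracs = [mass_fraction(p, k).fraction_percent for p in pairs]
    mean = statistics.fmean(fracs)
    ratio = mean / (100.0 - mean) if mean < 100.0 else float("inf")
    rsd = sample_rsd_percent(fracs) if len(fracs) >= 2 and mean > 0 else 0.0
    bias = bias_percent(mean, true_fraction) if true_fraction is not None else None
    return QuantResult(
        fraction_percent=mean,
        mass_ratio=ratio,
        replicate_fractions=tuple(fracs),
        rsd_percent=rsd,
        bias_percent=bias,
    )
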