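"""Core domain types for droplet-digital-PCR (ddPCR) quantification.

The measurement chain is: droplets (partitions) are scored positive or
negative for a species-specific target; Poisson statistics convert the
positive fraction into copies per partition; a multiplication factor *k*
(the ratio of copies-per-unit-mass between base species and adulterant)
converts the copy-number ratio of two species into a mass ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class SaturationError(ValueError):
    """All partitions positive: the Poisson estimate is unbounded."""


class InvalidInputError(ValueError):
    """Input violates a type invariant or an operation precondition."""


#: Sentinel replicate index used for wells merged across replicates.
MERGED_REPLICATE = -1

#: Droplet volume of a QX200-style droplet generator, in nanolitres.
#: Used only to place concentrations on a copies/uL scale; every
#: mass-fraction computation works on ratios and is volume-invariant.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Wells with fewer accepted droplets than this are flagged (not rejected).
LOW_DROPLET_WARNING_THRESHOLD = 10_000


@dataclass(frozen=True)
class PartitionCount:
    """Positive/total droplet counts for one well and one target.

    Parameters
    ----------
    sample_id : str
        Identifier of the meat-mixture sample.
    target : str
        Species label of the assay target (e.g. ``"chicken"``, ``"sheep"``).
    replicate : int
        Replicate well index; :data:`MERGED_REPLICATE` marks pooled wells.
    positives : int
        Number of FAM-positive droplets.
    total : int
        Total number of accepted droplets in the well.
    dilution_factor : float
        Multiplicative dilution applied before partitioning; reported
        concentrations are scaled back up by this factor.
    """

    sample_id: str
    target: str
    replicate: int
    positives: int
    total: int
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InvalidInputError(
                f"total droplets must be positive, got {self.total}"
            )
        if not 0 <= self.positives <= self.total:
            raise InvalidInputError(
                f"positives must lie in [0, total]={self.total}, "
                f"got {self.positives}"
            )
        if self.dilution_factor <= 0:
            raise InvalidInputError("dilution_factor must be positive")

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.total

    @property
    def low_droplet_count(self) -> bool:
        """True when the well has fewer accepted droplets than the QC flag."""
        return self.total < LOW_DROPLET_WARNING_THRESHOLD


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Copies-per-partition and copies/uL with a confidence interval.

    ``lam`` is the mean number of target copies per droplet inferred from
    the positive fraction under random (Poisson) partitioning.
    """

    lam: float
    conc: float
    ci_low: float
    ci_high: float
    n_partitions: int

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise InvalidInputError("lam must be non-negative")
        if not (self.ci_low <= self.conc <= self.ci_high):
            raise InvalidInputError(
                "interval must bracket the point estimate: "
                f"[{self.ci_low}, {self.ci_high}] vs {self.conc}"
            )


@dataclass(frozen=True)
class SpeciesPair:
    """Measured concentrations of adulterant and base-species targets.

    ``q_adulterant`` and ``q_base`` are copy-number concentrations (same
    units; the units cancel in every downstream ratio).
    """

    q_adulterant: float
    q_base: float

    def __post_init__(self) -> None:
        if self.q_adulterant < 0:
            raise InvalidInputError("q_adulterant must be non-negative")
        if self.q_base <= 0:
            raise InvalidInputError("q_base must be positive")

    @property
    def copy_ratio(self) -> float:
        """Qc/Qs — adulterant over base-species copy concentration."""
        return self.q_adulterant / self.q_base


@dataclass(frozen=True)
class KFactor:
    """Multiplication factor k = Cs/Cc with replicate spread.

    k is the ratio of copies-per-unit-mass between base species and
    adulterant; it converts a measured copy ratio Qc/Qs into a mass
    ratio Mc/Ms.  ``value`` is the arithmetic mean of the per-replicate
    estimates; ``rsd_percent`` their sample (n-1) relative SD.
    """

    value: float
    replicate_values: tuple[float, ...] = ()
    rsd_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise InvalidInputError("k must be positive")
        if self.rsd_percent < 0:
            raise InvalidInputError("rsd_percent must be non-negative")
        if self.replicate_values:
            mean = sum(self.replicate_values) / len(self.replicate_values)
            if not math.isclose(mean, self.value, rel_tol=1e-9):
                raise InvalidInputError(
                    "value must equal the mean of replicate_values"
                )

    @classmethod
    def fixed(cls, value: float) -> "KFactor":
        """A k supplied as a fixed constant (no replicate information)."""
        return cls(value=value)


@dataclass(frozen=True)
class QuantResult:
    """Estimated adulterant mass fraction with replicate spread.

    ``fraction_percent`` = 100 * Mc / (Mc + Ms) on the mass scale;
    ``bias_percent`` = 100 * (measured - true) / true when a true
    fraction was supplied.
    """

    fraction_percent: float
    mass_ratio: float
    replicate_fractions: tuple[float, ...] = ()
    rsd_percent: Optional[float] = None
    bias_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_percent <= 100.0:
            raise InvalidInputError("fraction_percent must lie in [0, 100]")
        expected = 100.0 * self.mass_ratio / (1.0 + self.mass_ratio)
        if not math.isclose(expected, self.fraction_percent,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise InvalidInputError(
                "fraction_percent inconsistent with mass_ratio"
            )


@dataclass(frozen=True)
class CtObservation:
    """One real-time-PCR observation: a threshold cycle for one target.

    ``log10_copies`` is set for standard-curve points (the declared,
    unitless nominal copy number of the standard) and ``None`` for
    unknowns.
    """

    sample_id: str
    target: str
    ct: float
    log10_copies: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise InvalidInputError(f"ct must be finite and positive, got {self.ct}")
        if self.log10_copies is not None and not math.isfinite(self.log10_copies):
            raise InvalidInputError("log10_copies must be finite")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR standard curve Ct = slope * log10(copies) + intercept.

    ``efficiency_percent`` is the per-cycle amplification gain,
    100 * (10^(-1/slope) - 1); 100% corresponds to perfect doubling
    (slope = -1/log10 2 ~ -3.3219).
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    log10_range: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise InvalidInputError(
                f"a valid standard curve has negative slope, got {self.slope}"
            )
        expected = 100.0 * (10.0 ** (-1.0 / self.slope) - 1.0)
        if not math.isclose(expected, self.efficiency_percent, rel_tol=1e-9):
            raise InvalidInputError(
                "efficiency_percent inconsistent with slope"
            )


@dataclass(frozen=True)
class LevelSummary:
    """Replicate summary of measured fractions at one true adulterant level."""

    true_fraction_percent: float
    measured_values: tuple[float, ...]
    mean_percent: float
    rsd_percent: float
    bias_percent: float


@dataclass
class ValidationReport:
    """Assay-validation bundle: per-level summaries, linearity, LOQ, LOD."""

    levels: list[LevelSummary] = field(default_factory=list)
    linearity_slope: Optional[float] = None
    linearity_r_squared: Optional[float] = None
    loq_percent: Optional[float] = None
    lod_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.loq_percent is not None and self.lod_percent is not None
                and self.loq_percent < self.lod_percent):
            raise InvalidInputError("LOQ cannot be below LOD")
        if (self.linearity_r_squared is not None
                and not 0.0 <= self.linearity_r_squared <= 1.0 + 1e-12):
            raise InvalidInputError("r_squared must lie in [0, 1]")


def sample_rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation, 100*SD/mean, sample (n-1) convention."""
    vals = list(values)
    if len(vals) < 2:
        raise InvalidInputError("RSD requires at least two values")
    mean = sum(vals) / len(vals)
    if mean == 0:
        raise InvalidInputError("RSD undefined for zero mean")
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return 100.0 * math.sqrt(var) / mean


def bias_percent(measured_mean: float, true_value: float) -> float:
    """Accuracy metric: 100 * (measured - true) / true."""
    if true_value == 0:
        raise InvalidInputError("bias undefined for a zero true value")
    return 100.0 * (measured_mean - true_value) / true_value
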