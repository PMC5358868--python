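"""Synthetic droplet-count and Ct data with the structure the analysis assumes.

The generator emulates a QX200-style workflow end to end:

* a binary meat mixture with adulterant mass fraction f contributes
  target copies in proportion f * Cc (adulterant) and (1-f) * k * Cc
  (base species), where Cc is the adulterant's copies-per-unit-mass and
  k = Cs/Cc is the multiplication factor the calibration stage must
  recover;
* each well partitions the reaction into ~20,000 droplets; the number of
  positive droplets is Binomial(R, 1 - exp(-lambda)), equivalent in
  distribution to placing Poisson-distributed molecules into droplets;
* optional per-droplet false-positive/false-negative rates, per-well
  pipetting noise, and per-species DNA-retention factors (an abstraction
  of differential degradation under harsh processing);
* matched qPCR tables: a 4-fold dilution series of an equal-mass
  standard declared at a virtual common concentration, plus unknown Ct
  values generated from configurable standard curves with Gaussian Ct
  noise.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import InvalidInputError, PartitionCount

__all__ = [
    "SimulationScenario",
    "QpcrSimConfig",
    "SimulatedDataset",
    "expected_concentrations",
    "simulate_well",
    "simulate_study",
]

#: Default copies-per-unit-mass of the adulterant target (copies/uL of
#: final reaction per unit mass fraction).  Chosen so simulated wells
#: land on the concentration scale typical of 50 ng meat-DNA ddPCR
#: inputs: hundreds of copies/uL at tens-of-percent adulterant levels,
#: ~10 copies/uL at 1%.
DEFAULT_C_UNIT_ADULTERANT = 1000.0


@dataclass(frozen=True)
class SimulationScenario:
    """One simulated mixture condition.

    Parameters
    ----------
    true_fraction_percent : float
        Adulterant mass percentage f of the binary mixture.
    c_unit_adulterant : float
        Copies-per-unit-mass constant Cc of the adulterant target.
    k_true : float
        Multiplication factor Cs/Cc; base-species copies-per-unit-mass
        is ``k_true * c_unit_adulterant``.
    total_mass : float
        Mass of mixture extracted (arbitrary units; cancels in ratios).
    extraction_yield : float
        Proportionality constant from mass*copies-per-mass to copies/uL.
    droplets_per_well, droplet_volume_nl : partitioning geometry.
    replicates : int
        Wells per target for this condition.
    pipetting_cv : float
        Per-well multiplicative concentration noise (coefficient of
        variation); models pipetting and droplet-volume variability.
    false_positive_rate, false_negative_rate : float
        Per-droplet misclassification probabilities.
    retention_adulterant, retention_base : float
        Multiplicative DNA-survival factors in (0, 1]; unequal values
        emulate species-differential degradation under processing.
    """

    true_fraction_percent: float
    c_unit_adulterant: float = DEFAULT_C_UNIT_ADULTERANT
    k_true: float = 0.8
    total_mass: float = 1.0
    extraction_yield: float = 1.0
    droplets_per_well: int = 20_000
    droplet_volume_nl: float = 0.85
    replicates: int = 3
    pipetting_cv: float = 0.02
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    retention_adulterant: float = 1.0
    retention_base: float = 1.0
    target_adulterant: str = "chicken"
    target_base: str = "sheep"
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction_percent <= 100.0:
            raise InvalidInputError("true_fraction_percent must be in [0, 100]")
        if self.k_true <= 0:
            raise InvalidInputError("k_true must be positive")
        if self.droplets_per_well <= 0:
            raise InvalidInputError("droplets_per_well must be positive")
        for name in ("false_positive_rate", "false_negative_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        for name in ("retention_adulterant", "retention_base"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidInputError(f"{name} must be in (0, 1]")
        if self.pipetting_cv < 0:
            raise InvalidInputError("pipetting_cv must be non-negative")

    @property
    def label(self) -> str:
        if self.sample_id is not None:
            return self.sample_id
        return f"mix_{self.true_fraction_percent:g}pct"


@dataclass(frozen=True)
class QpcrSimConfig:
    """Standard curves and noise for the matched qPCR tables.

    The simulated standard is an equal-mass binary mixture declared at a
    virtual common concentration for both species (``virtual_copies``),
    diluted ``n_levels`` times by ``dilution_step``; each level is run
    in ``standard_replicates``.  ``ct_shift_*`` add a constant Ct offset
    to unknown wells only, emulating matrix/efficiency discrepancies
    between standards and unknowns (0 = none).
    """

    slope_adulterant: float = -3.449
    intercept_adulterant: float = 39.57
    slope_base: float = -3.480
    intercept_base: float = 40.52
    ct_noise_sd: float = 0.15
    virtual_copies: float = 1e5
    dilution_step: float = 4.0
    n_levels: int = 6
    standard_replicates: int = 3
    ct_shift_adulterant: float = 0.0
    ct_shift_base: float = 0.0


@dataclass
class SimulatedDataset:
    """Bundle of simulated tables plus the ground truth to score against."""

    droplets: pd.DataFrame
    truth: pd.DataFrame
    qpcr_standards: Optional[pd.DataFrame] = None
    qpcr_unknowns: Optional[pd.DataFrame] = None


def expected_concentrations(scenario: SimulationScenario) -> tuple[float, float]:
    """Noise-free expected copies/uL of (adulterant, base) targets.

    conc_adulterant = yield * f * M * Cc * retention_adulterant
    conc_base       = yield * (1-f) * M * (k*Cc) * retention_base
    so with equal retentions conc_base/conc_adulterant = k * (1-f)/f.
    """
    f = scenario.true_fraction_percent / 100.0
    common = scenario.extraction_yield * scenario.total_mass * scenario.c_unit_adulterant
    conc_adu = common * f * scenario.retention_adulterant
    conc_base = common * (1.0 - f) * scenario.k_true * scenario.retention_base
    return conc_adu, conc_base


def simulate_well(
    conc: float,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    *,
    target: str = "target",
    replicate: int = 0,
    sample_id: Optional[str] = None,
) -> PartitionCount:
    """Draw one well's positive-droplet count at concentration ``conc``.

    lambda = conc * droplet volume; a droplet is truly positive with
    probability 1 - exp(-lambda) and observed positive with probability
    p*(1-fn) + (1-p)*fp; positives ~ Binomial(droplets_per_well, .).
    """
    if conc < 0:
        raise InvalidInputError("concentration must be non-negative")
    lam = conc * scenario.droplet_volume_nl * 1e-3
    p = -math.expm1(-lam)
    p_obs = (
        p * (1.0 - scenario.false_negative_rate)
        + (1.0 - p) * scenario.false_positive_rate
    )
    positives = int(rng.binomial(scenario.droplets_per_well, p_obs))
    return PartitionCount(
        sample_id=sample_id or scenario.label,
        target=target,
        replicate=replicate,
        positives=positives,
        total=scenario.droplets_per_well,
    )


def _simulate_scenario_wells(
    scenario: SimulationScenario, rng: np.random.Generator
) -> list[PartitionCount]:
    conc_adu, conc_base = expected_concentrations(scenario)
    wells = []
    for rep in range(scenario.replicates):
        for target, conc in (
            (scenario.target_adulterant, conc_adu),
            (scenario.target_base, conc_base),
        ):
            noisy = conc
            if scenario.pipetting_cv > 0:
                noisy = conc * max(0.0, rng.normal(1.0, scenario.pipetting_cv))
            wells.append(
                simulate_well(noisy, scenario, rng, target=target, replicate=rep)
            )
    return wells


def _standard_tables(
    scenarios: Sequence[SimulationScenario],
    qpcr: QpcrSimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    # standards: equal-mass mixture, both species declared at the same
    # virtual concentration, diluted in a geometric series
    rows = []
    for species, slope, intercept in (
        ("chicken", qpcr.slope_adulterant, qpcr.intercept_adulterant),
        ("sheep", qpcr.slope_base, qpcr.intercept_base),
    ):
        for lvl in range(qpcr.n_levels):
            declared = qpcr.virtual_copies / qpcr.dilution_step**lvl
            for rep in range(qpcr.standard_replicates):
                ct = slope * math.log10(declared) + intercept
                ct += rng.normal(0.0, qpcr.ct_noise_sd)
                rows.append(
                    {
                        "sample_id": f"std_L{lvl}_r{rep}",
                        "target": species,
                        "ct": ct,
                        "log10_copies": math.log10(declared),
                    }
                )
    standards = pd.DataFrame(rows)

    # unknowns: actual copies mapped to the declared scale through the
    # equal-mass standard (the virtual-concentration convention), so the
    # Ct of an unknown reflects its copies relative to the 50/50 standard
    ref = replace(
        scenarios[0],
        true_fraction_percent=50.0,
        retention_adulterant=1.0,
        retention_base=1.0,
    )
    q50_adu, q50_base = expected_concentrations(ref)
    rows = []
    for sc in scenarios:
        conc_adu, conc_base = expected_concentrations(sc)
        for rep in range(sc.replicates):
            for species, conc, q50, slope, intercept, shift in (
                (
                    sc.target_adulterant, conc_adu, q50_adu,
                    qpcr.slope_adulterant, qpcr.intercept_adulterant,
                    qpcr.ct_shift_adulterant,
                ),
                (
                    sc.target_base, conc_base, q50_base,
                    qpcr.slope_base, qpcr.intercept_base,
                    qpcr.ct_shift_base,
                ),
            ):
                if conc <= 0:
                    continue  # no template: no Ct is recorded
                declared_scale = conc / q50 * qpcr.virtual_copies
                ct = slope * math.log10(declared_scale) + intercept + shift
                ct += rng.normal(0.0, qpcr.ct_noise_sd)
                rows.append(
                    {
                        "sample_id": sc.label,
                        "target": species,
                        "ct": ct,
                        "log10_copies": np.nan,
                        "replicate": rep,
                    }
                )
    return standards, pd.DataFrame(rows)


def simulate_study(
    scenarios: Sequence[SimulationScenario],
    seed: int,
    qpcr: Optional[QpcrSimConfig] = None,
) -> SimulatedDataset:
    """Simulate a full mixture study: droplet counts, truth, qPCR tables.

    Parameters
    ----------
    scenarios : sequence of SimulationScenario
        One entry per mixture level/condition.
    seed : int
        Master seed; identical seeds give bit-identical datasets.
    qpcr : QpcrSimConfig, optional
        When given, matched qPCR standard/unknown Ct tables are emitted.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise InvalidInputError("simulate_study needs >=1 scenario")
    rng = np.random.default_rng(seed)

    droplet_rows = []
    truth_rows = []
    for sc in scenarios:
        conc_adu, conc_base = expected_concentrations(sc)
        for w in _simulate_scenario_wells(sc, rng):
            droplet_rows.append(
                {
                    "sample_id": w.sample_id,
                    "target": w.target,
                    "replicate": w.replicate,
                    "positives": w.positives,
                    "total_droplets": w.total,
                }
            )
        truth_rows.append(
            {
                "sample_id": sc.label,
                "true_fraction_percent": sc.true_fraction_percent,
                "k_true": sc.k_true,
                "expected_conc_adulterant": conc_adu,
                "expected_conc_base": conc_base,
                "target_adulterant": sc.target_adulterant,
                "target_base": sc.target_base,
            }
        )

    standards = unknowns = None
    if qpcr is not None:
        standards, unknowns = _standard_tables(scenarios, qpcr, rng)

    return SimulatedDataset(
        droplets=pd.DataFrame(droplet_rows),
        truth=pd.DataFrame(truth_rows),
        qpcr_standards=standards,
        qpcr_unknowns=unknowns,
    )
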