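"""End-to-end composition: droplet counts -> concentrations -> k -> fractions.

`run_pipeline` is the audit-friendly entry point: it logs every
assumption it uses (droplet volume, k and its source, thresholds), is a
pure function of (inputs, config), and degrades per sample — a sample
missing its base-species wells is reported as an error row while the
remaining samples are still quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .calibration import k_from_equal_mass, quantify_replicates
from .io import RunConfig, read_droplet_table
from .partition import estimate_copies_per_partition
from .performance import determine_lod, determine_loq, linearity, summarize_level
from .types import (
    InvalidInputError,
    KFactor,
    PartitionCount,
    QuantResult,
    SpeciesPair,
    ValidationReport,
)

logger = logging.getLogger("ddquant")

__all__ = ["PipelineReport", "pairs_from_counts", "resolve_k", "run_pipeline"]


@dataclass
class PipelineReport:
    """Per-sample quantification plus optional validation against truth."""

    quant: pd.DataFrame
    k: KFactor
    config: RunConfig
    validation: Optional[ValidationReport] = None
    errors: list[str] = field(default_factory=list)

    def validation_frame(self) -> Optional[pd.DataFrame]:
        """Per-level validation rows with the report rounding policy."""
        if self.validation is None:
            return None
        c = self.config
        rows = [
            {
                "true_percent": s.true_fraction_percent,
                "mean_percent": round(s.mean_percent, c.round_fraction),
                "rsd_percent": round(s.rsd_percent, c.round_rsd),
                "bias_percent": round(s.bias_percent, c.round_bias),
                "n_replicates": len(s.measured_values),
            }
            for s in self.validation.levels
        ]
        return pd.DataFrame(rows)


def pairs_from_counts(
    counts: Sequence[PartitionCount],
    config: RunConfig,
) -> dict[str, list[SpeciesPair]]:
    """Group wells by sample, pair targets by replicate, estimate copies.

    Replicate pairing assumes the adulterant and base wells sharing a
    replicate index come from the same DNA extraction; samples with
    unpaired replicate indices are rejected.
    """
    by_sample: dict[str, dict[str, dict[int, PartitionCount]]] = {}
    for c in counts:
        by_sample.setdefault(c.sample_id, {}).setdefault(c.target, {})[c.replicate] = c

    out: dict[str, list[SpeciesPair]] = {}
    for sample_id, targets in by_sample.items():
        adu = targets.get(config.target_adulterant)
        base = targets.get(config.target_base)
        if adu is None or base is None:
            missing = config.target_base if adu else config.target_adulterant
            raise InvalidInputError(
                f"sample {sample_id}: no wells for target '{missing}'"
            )
        if set(adu) != set(base):
            raise InvalidInputError(
                f"sample {sample_id}: unpaired replicate indices "
                f"{sorted(set(adu) ^ set(base))}"
            )
        pairs = []
        for rep in sorted(adu):
            est_a = estimate_copies_per_partition(
                adu[rep], droplet_volume_nl=config.droplet_volume_nl,
                level=config.ci_level,
            )
            est_b = estimate_copies_per_partition(
                base[rep], droplet_volume_nl=config.droplet_volume_nl,
                level=config.ci_level,
            )
            pairs.append(SpeciesPair(q_adulterant=est_a.conc, q_base=est_b.conc))
        out[sample_id] = pairs
    return out


def resolve_k(config: RunConfig) -> KFactor:
    """Obtain k from the config: fixed value or calibration-table path."""
    if config.k_value is not None:
        logger.info("k fixed by configuration: %.4g", config.k_value)
        return KFactor.fixed(config.k_value)
    counts = read_droplet_table(config.k_calibration_table)
    pairs_by_sample = pairs_from_counts(counts, config)
    pairs = [p for ps in pairs_by_sample.values() for p in ps]
    k = k_from_equal_mass(pairs)
    logger.info(
        "k calibrated from %s: %.4g (RSD %.3g%%, n=%d)",
        config.k_calibration_table, k.value, k.rsd_percent,
        len(k.replicate_values),
    )
    return k


def run_pipeline(
    config: RunConfig,
    droplet_table: Union[str, Sequence[PartitionCount]],
    truth: Optional[pd.DataFrame] = None,
) -> PipelineReport:
    """Quantify every sample of a droplet table; validate when truth given.

    Parameters
    ----------
    config : RunConfig
    droplet_table : path or sequence of PartitionCount
        Droplet-count CSV path or already-parsed records.
    truth : DataFrame, optional
        Columns ``sample_id`` and ``true_fraction_percent``; enables
        per-level bias/RSD summaries, linearity, LOQ and LOD.
    """
    counts = (
        read_droplet_table(droplet_table)
        if isinstance(droplet_table, (str,)) or hasattr(droplet_table, "__fspath__")
        else list(droplet_table)
    )
    k = resolve_k(config)
    logger.info(
        "pipeline assumptions: droplet volume %.3g nL, k=%.4g, "
        "LOQ limits RSD<=%s%%/|bias|<=%s%%, LOD min positives %d",
        config.droplet_volume_nl, k.value, config.loq_rsd_limit,
        config.loq_bias_limit, config.lod_min_positives,
    )

    truth_map: dict[str, float] = {}
    if truth is not None:
        truth_map = dict(
            zip(truth["sample_id"].astype(str), truth["true_fraction_percent"])
        )

    errors: list[str] = []
    rows = []
    results: dict[str, QuantResult] = {}
    by_sample: dict[str, list[PartitionCount]] = {}
    for c in counts:
        by_sample.setdefault(c.sample_id, []).append(c)

    for sample_id, sample_counts in by_sample.items():
        try:
            pairs = pairs_from_counts(sample_counts, config)[sample_id]
            res = quantify_replicates(pairs, k, truth_map.get(sample_id))
        except InvalidInputError as exc:
            errors.append(str(exc))
            logger.error("sample %s skipped: %s", sample_id, exc)
            continue
        results[sample_id] = res
        rows.append(
            {
                "sample_id": sample_id,
                "fraction_percent": round(res.fraction_percent, config.round_fraction),
                "rsd_percent": round(res.rsd_percent, config.round_rsd)
                if res.rsd_percent is not None else None,
                "bias_percent": round(res.bias_percent, config.round_bias)
                if res.bias_percent is not None else None,
                "n_replicates": len(res.replicate_fractions),
                "k_used": round(k.value, config.round_k),
            }
        )

    validation = None
    if truth_map:
        levels = []
        lod_levels = []
        for sample_id, res in results.items():
            if sample_id not in truth_map:
                continue
            if len(res.replicate_fractions) >= 2:
                levels.append(
                    summarize_level(truth_map[sample_id], res.replicate_fractions)
                )
            adu_wells = [
                c for c in by_sample[sample_id]
                if c.target == config.target_adulterant
            ]
            lod_levels.append((truth_map[sample_id], adu_wells))
        validation = ValidationReport(levels=sorted(
            levels, key=lambda s: s.true_fraction_percent))
        if len(levels) >= 3:
            slope, r2 = linearity(levels)
            validation.linearity_slope = slope
            validation.linearity_r_squared = r2
        if levels:
            validation.loq_percent = determine_loq(
                levels, rsd_limit=config.loq_rsd_limit,
                bias_limit=config.loq_bias_limit,
            )
        if lod_levels:
            validation.lod_percent = determine_lod(
                lod_levels, min_positives=config.lod_min_positives
            )

    return PipelineReport(
        quant=pd.DataFrame(rows), k=k, config=config,
        validation=validation, errors=errors,
    )
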