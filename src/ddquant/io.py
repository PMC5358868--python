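"""Table schemas, run configuration, and validated readers/writers.

Two delimited-text (CSV) schemas serve both instrument exports and the
simulator:

* droplet table — ``sample_id, target, replicate, positives,
  total_droplets`` with optional ``dilution_factor``;
* Ct table — ``sample_id, target, ct`` with optional ``log10_copies``
  (set only for standard-curve points).

Readers validate row by row and report offending line numbers (header
is line 1).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .types import (
    DEFAULT_DROPLET_VOLUME_NL,
    CtObservation,
    InvalidInputError,
    PartitionCount,
)

logger = logging.getLogger("ddquant")

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_droplet_table",
    "write_droplet_table",
    "read_ct_table",
    "write_ct_table",
]

DROPLET_COLUMNS = ["sample_id", "target", "replicate", "positives", "total_droplets"]
CT_COLUMNS = ["sample_id", "target", "ct"]


class SchemaError(InvalidInputError):
    """A table is missing required columns or has malformed rows."""


@dataclass(frozen=True)
class RunConfig:
    """Assay parameters for a quantification run.

    ``k_value`` supplies the multiplication factor directly;
    ``k_calibration_table`` instead points at a droplet table of an
    equal-mass reference from which k is derived.  Exactly one of the
    two must be set.
    """

    target_adulterant: str = "chicken"
    target_base: str = "sheep"
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    dilution_factor: float = 1.0
    k_value: Optional[float] = 0.8
    k_calibration_table: Optional[str] = None
    loq_rsd_limit: float = 25.0
    loq_bias_limit: Optional[float] = 25.0
    lod_min_positives: int = 3
    ci_level: float = 0.95
    seed: int = 0
    # rounding policy for report display (significance is never truncated
    # internally)
    round_fraction: int = 2
    round_rsd: int = 2
    round_bias: int = 2
    round_k: int = 1
    round_r_squared: int = 4

    def __post_init__(self) -> None:
        if (self.k_value is None) == (self.k_calibration_table is None):
            raise InvalidInputError(
                "exactly one of k_value and k_calibration_table must be set"
            )
        if self.k_value is not None and self.k_value <= 0:
            raise InvalidInputError("k_value must be positive")
        for name in ("droplet_volume_nl", "dilution_factor", "loq_rsd_limit"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_droplet_table(path: Union[str, Path]) -> list[PartitionCount]:
    """Read and validate a droplet-count CSV into PartitionCount records.

    Raises
    ------
    SchemaError
        On missing columns or malformed rows; the message names the
        1-based file line of the first offending row.
    """
    df = pd.read_csv(path)
    _require_columns(df, DROPLET_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header occupies line 1
        try:
            records.append(
                PartitionCount(
                    sample_id=str(row["sample_id"]),
                    target=str(row["target"]),
                    replicate=int(row["replicate"]),
                    positives=int(row["positives"]),
                    total=int(row["total_droplets"]),
                    dilution_factor=float(row.get("dilution_factor", 1.0))
                    if "dilution_factor" in df.columns
                    else 1.0,
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise SchemaError(f"{path}: invalid row at line {line_no}: {exc}") from exc
    n_low = sum(r.low_droplet_count for r in records)
    if n_low:
        logger.warning("%s: %d well(s) below the accepted-droplet QC flag", path, n_low)
    logger.info("%s: read %d droplet-count records", path, len(records))
    return records


def write_droplet_table(
    records: Sequence[PartitionCount], path: Union[str, Path]
) -> None:
    """Write PartitionCount records in the droplet-table schema."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "target": [r.target for r in records],
            "replicate": [r.replicate for r in records],
            "positives": [r.positives for r in records],
            "total_droplets": [r.total for r in records],
            "dilution_factor": [r.dilution_factor for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_ct_table(path: Union[str, Path]) -> list[CtObservation]:
    """Read and validate a Ct CSV into CtObservation records."""
    df = pd.read_csv(path)
    _require_columns(df, CT_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2
        log10 = None
        if "log10_copies" in df.columns and pd.notna(row["log10_copies"]):
            log10 = float(row["log10_copies"])
        try:
            records.append(
                CtObservation(
                    sample_id=str(row["sample_id"]),
                    target=str(row["target"]),
                    ct=float(row["ct"]),
                    log10_copies=log10,
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise SchemaError(f"{path}: invalid row at line {line_no}: {exc}") from exc
    logger.info("%s: read %d Ct records", path, len(records))
    return records


def write_ct_table(records: Sequence[CtObservation], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "target": [r.target for r in records],
            "ct": [r.ct for r in records],
            "log10_copies": [r.log10_copies for r in records],
        }
    )
    df.to_csv(path, index=False)
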