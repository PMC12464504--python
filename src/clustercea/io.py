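"""Readers, writers and validated configuration for the analysis pipeline.

The on-disk interchange formats are deliberately plain: comma-separated
UTF-8 CSV with '.' decimals and ISO-8601-style fractional-year times for
tabular data, JSON for nested results, YAML for configuration. Every
reader validates before returning and every writer produces a file whose
re-read equals the in-memory object.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

logger = logging.getLogger("clustercea")

ARMS = ("intervention", "control")

#: columns of the long-format trial CSV (one row per participant-wave)
TRIAL_COLUMNS = [
    "participant_id",
    "arm",
    "village",
    "township",
    "age",
    "sex",
    "death_time_years",
    "wave_time_years",
    "sbp",
    "utility",
]

#: columns of the itemized cost CSV (one row per cost item)
COST_COLUMNS = [
    "participant_id",
    "category",
    "amount",
    "source_year",
    "quantity",
    "unit_price",
    "adherence",
]


class SchemaError(ValueError):
    """A file does not match the documented schema."""


class ValidationError(ValueError):
    """Data are schema-conformant but violate an invariant."""


class RunConfig(BaseModel):
    """Analysis-level settings shared across pipeline stages.

    Parameters
    ----------
    reference_year
        Calendar year all monetary amounts are expressed in (USD).
    discount_rate_annual
        Annual discount rate applied to post-trial costs and QALYs.
    wtp_threshold
        Willingness-to-pay threshold in USD per QALY (1.5x per-capita
        GDP is a common rule for the setting this defaults to).
    n_bootstrap
        Number of bootstrap replications for uncertainty analysis.
    wtp_grid
        Ascending willingness-to-pay grid for the acceptability curve;
        defaults to 0 .. 2*wtp_threshold in 100 steps.
    cpi_table
        Rural consumer price index by calendar year, used to inflate
        historical local-currency amounts to the reference year.
    exchange_rate
        Local currency units per USD at the reference year.
    """

    model_config = ConfigDict(extra="forbid")

    reference_year: int = 2023
    discount_rate_annual: float = 0.05
    wtp_threshold: float = 18766.0
    n_bootstrap: int = 5000
    rng_seed: int = 0
    wtp_grid: list[float] | None = None
    cpi_table: dict[int, float] = field(default_factory=dict)  # type: ignore[assignment]
    exchange_rate: float = 7.08

    @field_validator("discount_rate_annual")
    @classmethod
    def _rate_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("discount_rate_annual must be >= 0")
        return v

    @field_validator("n_bootstrap")
    @classmethod
    def _boot_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_bootstrap must be >= 1")
        return v

    @field_validator("cpi_table")
    @classmethod
    def _cpi_positive(cls, v: dict[int, float]) -> dict[int, float]:
        if any(x <= 0 for x in v.values()):
            raise ValueError("cpi_table values must be > 0")
        return v

    @model_validator(mode="after")
    def _grid_ascending(self) -> "RunConfig":
        if self.wtp_grid is None:
            self.wtp_grid = list(np.linspace(0.0, 2.0 * self.wtp_threshold, 101))
        g = np.asarray(self.wtp_grid, dtype=float)
        if g.size and np.any(np.diff(g) <= 0):
            raise ValueError("wtp_grid must be strictly increasing")
        return self


def read_config(path: str | Path) -> RunConfig:
    """Read and fully validate a YAML run configuration.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    cfg = RunConfig(**raw)
    logger.info("read config from %s (seed=%d)", path, cfg.rng_seed)
    return cfg


@dataclass(frozen=True)
class TrialTable:
    """Validated long-format participant-level trial data.

    ``data`` has one row per participant-wave (:data:`TRIAL_COLUMNS`);
    participant attributes (arm, village, township, age, sex, death
    time) are repeated on every wave row and must be internally
    consistent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_trial(self.data)

    @property
    def participants(self) -> pd.DataFrame:
        """One row per participant with time-invariant attributes."""
        cols = [
            "participant_id",
            "arm",
            "village",
            "township",
            "age",
            "sex",
            "death_time_years",
        ]
        return self.data[cols].drop_duplicates("participant_id").reset_index(drop=True)

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    @property
    def villages(self) -> pd.DataFrame:
        return (
            self.data[["village", "township", "arm"]]
            .drop_duplicates("village")
            .reset_index(drop=True)
        )

    def wave(self, time_years: float, tol: float = 1e-9) -> pd.DataFrame:
        """Rows for the wave closest to ``time_years`` (within ``tol``)."""
        m = (self.data["wave_time_years"] - time_years).abs() <= tol
        return self.data[m].reset_index(drop=True)


def _validate_trial(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")

    bad_arm = set(df["arm"].unique()) - set(ARMS)
    if bad_arm:
        raise ValidationError(f"invalid arm value(s): {sorted(bad_arm)}")

    v2t = df.groupby("village")["township"].nunique()
    multi = v2t[v2t > 1]
    if len(multi):
        raise ValidationError(
            f"village(s) mapped to more than one township: {list(multi.index)}"
        )

    for col in ("arm", "village", "township", "age", "sex"):
        if df.groupby("participant_id")[col].nunique().max() > 1:
            raise ValidationError(f"participant attribute '{col}' varies across waves")

    if (df["wave_time_years"] < 0).any():
        raise ValidationError("wave times must be nonnegative")

    dup = df.duplicated(["participant_id", "wave_time_years"])
    if dup.any():
        raise ValidationError("duplicate (participant_id, wave_time_years) row(s)")

    dead = df.dropna(subset=["death_time_years"])
    late = dead[dead["wave_time_years"] > dead["death_time_years"]]
    if len(late):
        pids = late["participant_id"].unique()[:5]
        raise ValidationError(f"outcome waves recorded after death for: {list(pids)}")


def read_trial(path: str | Path) -> TrialTable:
    """Read and validate the long-format trial CSV."""
    df = pd.read_csv(path)
    table = TrialTable(df)
    logger.info(
        "read trial table from %s: %d rows, %d participants",
        path,
        len(df),
        table.n_participants,
    )
    return table


def write_trial(table: TrialTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_cost_items(path: str | Path) -> pd.DataFrame:
    """Read the itemized cost CSV (one row per cost item)."""
    df = pd.read_csv(path)
    missing = [c for c in COST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cost table missing column(s): {', '.join(missing)}")
    if (df["amount"] < 0).any():
        raise ValidationError("cost amounts must be >= 0")
    adh = df["adherence"].dropna()
    if ((adh < 0) | (adh > 1)).any():
        raise ValidationError("adherence must lie in [0, 1]")
    logger.info("read %d cost items from %s", len(df), path)
    return df


def write_cost_items(items: pd.DataFrame, path: str | Path) -> None:
    items.to_csv(path, index=False)


def write_results(result: Any, path: str | Path) -> None:
    """Serialize a result object to disk.

    ``CEResult``-like objects (anything with ``to_dict``) are written as
    JSON; DataFrames (budget-impact year tables, effect tables) as CSV.
    Incomplete results — e.g. a cost-effectiveness result with no
    bootstrap draws — are refused rather than written partially.
    """
    path = Path(path)
    if hasattr(result, "to_dict") and not isinstance(result, pd.DataFrame):
        d = result.to_dict()
        draws = d.get("draws")
        if draws is not None and len(draws.get("d_cost", [])) == 0:
            raise ValidationError("refusing to serialize result with empty bootstrap draws")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)
    elif isinstance(result, pd.DataFrame):
        if result.empty:
            raise ValidationError("refusing to serialize an empty result table")
        result.to_csv(path, index=False)
    else:
        raise TypeError(f"do not know how to serialize {type(result)!r}")
    logger.info("wrote results to %s", path)


def read_ce_result(path: str | Path):
    """Re-read a JSON cost-effectiveness result written by write_results."""
    from .cea import CEResult

    with open(path, "r", encoding="utf-8") as fh:
        return CEResult.from_dict(json.load(fh))
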