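"""Dataset reading/validation and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import DEFAULT_DAY, TimeSeriesDataset


@dataclass
class RunConfig:
    """Column mapping, covariate designations and run settings.

    ``pollutant_like`` lists the covariates whose effect curves are
    constrained to be non-decreasing; the rest (weather-like) are fitted
    unconstrained.  Defaults for the lag search follow the method's
    standard settings (grid gap 10, upper bound 200, refinement
    half-width 5) and Friday as the default day.
    """

    date_column: str = "date"
    outcome_column: str = "outcome"
    covariate_columns: list[str] = field(default_factory=list)
    pollutant_like: list[str] = field(default_factory=list)
    default_day: str = DEFAULT_DAY
    intervention_start: str | None = None
    intervention_end: str | None = None
    lags: list[int] | None = None
    lag_grid_gap: int = 10
    lag_upper_bound: int = 200
    lag_refine_halfwidth: int = 5
    tol: float = 1e-6
    max_iter: int = 100
    bootstrap_b: int = 500
    seed: int = 0
    log_offset: float = 0.0
    allow_gaps: bool = False
    output_dir: str = "casim-output"

    def __post_init__(self) -> None:
        if self.lag_grid_gap < 1 or self.lag_upper_bound < 1:
            raise ValueError("lag grid gap and upper bound must be >= 1")
        if self.lag_refine_halfwidth < 0:
            raise ValueError("lag refinement half-width must be >= 0")
        unknown = set(self.pollutant_like) - set(self.covariate_columns)
        if self.covariate_columns and unknown:
            raise ValueError(f"pollutant_like names not among covariates: {sorted(unknown)}")

    @property
    def intervention(self):
        if self.intervention_start is None or self.intervention_end is None:
            return None
        return (pd.Timestamp(self.intervention_start), pd.Timestamp(self.intervention_end))

    def monotone_flags(self) -> list[bool]:
        return [name in self.pollutant_like for name in self.covariate_columns]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_dataset(path, config: RunConfig) -> TimeSeriesDataset:
    """Read and validate a delimited daily time-series file.

    Rejects missing columns, unparseable/duplicate dates, non-positive
    counts (the model logs the outcome), non-numeric covariates and
    calendar gaps (permitted as segment breaks with ``allow_gaps``),
    naming the offending row in each message.
    """
    frame = pd.read_csv(path)
    needed = [config.date_column, config.outcome_column, *config.covariate_columns]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mapped columns in {path}: {missing}")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(frame[config.date_column], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable ISO-8601 date in {path}: {exc}") from exc
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise ValueError(f"duplicate date {dup.date()} in {path}")
    order = np.argsort(dates.to_numpy())
    frame = frame.iloc[order].reset_index(drop=True)
    dates = dates[order]
    if not config.allow_gaps:
        delta = np.diff(dates.to_numpy())
        gap = np.flatnonzero(delta != np.timedelta64(1, "D"))
        if gap.size:
            raise ValueError(
                f"calendar gap after {dates[gap[0]].date()} (set allow_gaps to treat "
                "gaps as segment breaks)"
            )
    outcome = pd.to_numeric(frame[config.outcome_column], errors="coerce").to_numpy()
    if np.any(~np.isfinite(outcome)):
        bad = dates[int(np.argmax(~np.isfinite(outcome)))]
        raise ValueError(f"non-numeric outcome on {bad.date()}")
    if np.any(outcome + config.log_offset <= 0):
        bad = dates[int(np.argmax(outcome + config.log_offset <= 0))]
        raise ValueError(
            f"non-positive outcome count on {bad.date()}: the log transform needs "
            "positive counts (set log_offset: 0.5 to offset zeros)"
        )
    covs = frame[config.covariate_columns].apply(pd.to_numeric, errors="coerce")
    if covs.isna().any().any():
        col = covs.columns[covs.isna().any()][0]
        bad = dates[int(covs[col].isna().to_numpy().argmax())]
        raise ValueError(f"non-numeric covariate {col!r} on {bad.date()}")
    return TimeSeriesDataset(
        dates=dates,
        outcome=outcome,
        covariates=covs.reset_index(drop=True),
        intervention=config.intervention,
        log_offset=config.log_offset,
    )


def write_dataset(dataset: TimeSeriesDataset, path, config: RunConfig | None = None) -> None:
    """Write a dataset back to CSV with ISO-8601 dates."""
    cfg = config or RunConfig(covariate_columns=dataset.covariate_names)
    frame = pd.DataFrame({cfg.date_column: dataset.dates.strftime("%Y-%m-%d")})
    frame[cfg.outcome_column] = dataset.outcome
    for name in dataset.covariate_names:
        frame[name] = dataset.covariates[name].to_numpy()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
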