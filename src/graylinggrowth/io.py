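"""CSV/JSON/YAML readers and writers plus run configuration.

Schemas (CSV, header required):

* daily series: ``date`` (ISO-8601), ``value``
* lengths: ``year, site, age_class, fork_length_mm, recapture``
* catches: ``species, year, site, cls, pass_idx, count`` (``pass`` accepted
  as an alias for ``pass_idx``; ``species`` optional)
* covariate table: ``year, site, stage, variable, raw_value, std_value``
* posterior draws: ``chain, iter, parameter, value``

Round trips are stable on canonical form.  Ingestion applies the study's
framing rules: grayling age-classes 7/8 (ages 6+/7+) are dropped with a
warning because growth is not estimated for them; anything outside 1..8
is an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import (
    DEFAULT_DROP_LIST,
    DEFAULT_STAGE_SETS,
    CovariateTable,
    DailySeries,
)
from .mcmc import McmcSettings, PosteriorResult

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_daily_series",
    "write_daily_series",
    "read_lengths",
    "write_lengths",
    "read_catches",
    "write_catches",
    "read_covariate_table",
    "write_covariate_table",
    "write_draws",
    "write_json",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_daily_series(path, kind: str = "temperature") -> DailySeries:
    df = pd.read_csv(path, parse_dates=["date"])
    _require_columns(df, ["date", "value"], path)
    s = pd.Series(df["value"].to_numpy(dtype=float), index=pd.DatetimeIndex(df["date"]))
    return DailySeries(s, kind=kind)


def write_daily_series(series: DailySeries, path) -> None:
    pd.DataFrame(
        {"date": series.values.index.strftime("%Y-%m-%d"), "value": series.values.to_numpy()}
    ).to_csv(path, index=False)


def read_lengths(path) -> pd.DataFrame:
    """Length records; drops age-classes 7/8 (ages 6+/7+) with a warning."""
    df = pd.read_csv(path)
    _require_columns(df, ["year", "site", "age_class", "fork_length_mm"], path)
    if "recapture" not in df.columns:
        df["recapture"] = False
    bad = ~df["age_class"].isin(range(1, 9))
    if bad.any():
        raise ValueError(
            f"{path}: age_class outside 1..8 at rows {df.index[bad].tolist()[:5]}"
        )
    old = df["age_class"].isin([7, 8])
    if old.any():
        log.warning(
            "%s: dropping %d records of age-classes 7/8 (ages 6+/7+): growth is "
            "not estimated for them",
            path,
            int(old.sum()),
        )
        df = df.loc[~old]
    if (df["fork_length_mm"] <= 0).any():
        raise ValueError(f"{path}: non-positive fork lengths")
    df["recapture"] = df["recapture"].astype(bool)
    return df.reset_index(drop=True)


def write_lengths(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_catches(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "pass" in df.columns and "pass_idx" not in df.columns:
        df = df.rename(columns={"pass": "pass_idx"})
    _require_columns(df, ["year", "site", "cls", "pass_idx", "count"], path)
    if (df["count"] < 0).any():
        rows = df.index[df["count"] < 0].tolist()[:5]
        raise ValueError(f"{path}: negative catch count at rows {rows}")
    if (df["count"] != df["count"].astype(int)).any():
        raise ValueError(f"{path}: non-integer catch counts")
    df["count"] = df["count"].astype(int)
    return df


def write_catches(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_covariate_table(table: CovariateTable, path, scales_path=None) -> None:
    table.data.to_csv(path, index=False)
    if scales_path is not None:
        payload = {
            "scales": {k: list(v) for k, v in table.scales.items()},
            "stage_sets": {str(l): v for l, v in table.stage_sets.items()},
        }
        Path(scales_path).write_text(json.dumps(payload, indent=2))


def read_covariate_table(path, scales_path=None) -> CovariateTable:
    df = pd.read_csv(path)
    _require_columns(
        df, ["year", "site", "stage", "variable", "raw_value", "std_value"], path
    )
    dup = df.duplicated(["year", "site", "stage", "variable"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (year, site, stage, variable) keys")
    scales: dict = {}
    stage_sets: dict = {}
    if scales_path is not None:
        payload = json.loads(Path(scales_path).read_text())
        scales = {k: tuple(v) for k, v in payload["scales"].items()}
        stage_sets = {int(l): v for l, v in payload["stage_sets"].items()}
    else:
        stage_sets = {
            int(l): sorted(df.loc[df["stage"] == l, "variable"].unique())
            for l in sorted(df["stage"].unique())
        }
    return CovariateTable(df, scales, stage_sets)


def write_draws(result: PosteriorResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


@dataclass
class RunConfig:
    """One place for a pipeline run's settings, loadable from YAML.

    Defaults mirror the study's fitting choices: 3 chains; growth MCMC
    30,000 iterations with 20,000 burn-in and thin 100; abundance MCMC
    30,000 / 10,000 / 100; collinearity threshold 0.7 with the
    hot-day count dropped in favour of mean temperature.  A master seed is
    mandatory for every stochastic command.
    """

    seed: int
    lengths_path: str | None = None
    catches_path: str | None = None
    temperature_path: str | None = None
    discharge_path: str | None = None
    habitat_path: str | None = None
    stage_sets: dict[int, list[str]] = field(
        default_factory=lambda: {l: list(v) for l, v in DEFAULT_STAGE_SETS.items()}
    )
    drop_list: list[str] = field(default_factory=lambda: list(DEFAULT_DROP_LIST))
    r_threshold: float = 0.7
    growth_mcmc: McmcSettings | None = None
    abundance_mcmc: McmcSettings | None = None
    literal_form: bool = False
    exclude_recaptures: bool = False
    batch_removal: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if self.growth_mcmc is None:
            self.growth_mcmc = McmcSettings(3, 30_000, 20_000, 100, self.seed)
        if self.abundance_mcmc is None:
            self.abundance_mcmc = McmcSettings(3, 30_000, 10_000, 100, self.seed + 1)
        for p in (
            self.lengths_path,
            self.catches_path,
            self.temperature_path,
            self.discharge_path,
            self.habitat_path,
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        for key in ("growth_mcmc", "abundance_mcmc"):
            if key in raw and raw[key] is not None:
                raw[key] = McmcSettings(**raw[key])
        if "stage_sets" in raw:
            raw["stage_sets"] = {int(k): list(v) for k, v in raw["stage_sets"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def digest(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
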