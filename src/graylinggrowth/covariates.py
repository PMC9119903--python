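"""Environmental and biotic covariate engineering.

Derives the annual explanatory variables used by the growth model from daily
air-temperature and mean-discharge series plus annual habitat monitoring
data:

* mean temperature over the main growing period (1 April -- 30 September,
  "spring--autumn") and over the preceding "autumn--winter" period
  (1 October of the previous year -- 31 March);
* counts of unusually hot days (air temperature strictly above a threshold,
  default 20 degC) and of low-/high-flow days (daily mean discharge at or
  below Q90, respectively at or above Q10, where Q90/Q10 are the 10th/90th
  empirical percentiles of daily discharge over the whole study period);
* summer macrophyte cover and a spring/autumn macroinvertebrate biomass
  index, accepted as supplied annual values;
* stage- and site-specific grayling and trout abundances estimated by the
  depletion N-mixture model (:mod:`graylinggrowth.abundance`).

All covariates are z-standardised before fitting and screened for pairwise
Pearson collinearity at |r| >= 0.7 within each life stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DailySeries",
    "CovariateTable",
    "SPRING_AUTUMN",
    "AUTUMN_WINTER",
    "DEFAULT_STAGE_SETS",
    "DEFAULT_DROP_LIST",
    "window_mean",
    "count_days_above",
    "flow_thresholds",
    "count_flow_days",
    "assemble",
    "z_standardise",
    "collinearity_screen",
]

SPRING_AUTUMN = "spring_autumn"
AUTUMN_WINTER = "autumn_winter"

#: Saturated stage-specific variable sets.  Stage 1 = juvenile (age 0+),
#: 2 = sub-adult (age 1+), 3 = adult (ages 2+..5+).  High-temperature days
#: are computed but dropped by the default collinearity configuration.
DEFAULT_STAGE_SETS: dict[int, list[str]] = {
    1: [
        "meanT_SA",
        "highT_days",
        "lowflow_days",
        "highflow_days",
        "macrophyte",
        "invert_biomass",
        "grayling_juv_abund",
        "trout_small_abund",
    ],
    2: [
        "meanT_SA",
        "meanT_AW",
        "lowflow_days",
        "highflow_days",
        "macrophyte",
        "invert_biomass",
        "grayling_subadult_abund",
        "trout_large_abund",
    ],
    3: [
        "meanT_SA",
        "meanT_AW",
        "lowflow_days",
        "invert_biomass",
        "grayling_adult_abund",
        "trout_large_abund",
    ],
}

#: Default resolution of the screen's flagged pairs: mean spring--autumn
#: temperature is retained over the count of hot days.
DEFAULT_DROP_LIST: tuple[str, ...] = ("highT_days",)

#: Variables that vary by site as well as year (abundance covariates).
SITE_VARYING = frozenset(
    {
        "grayling_juv_abund",
        "grayling_subadult_abund",
        "grayling_adult_abund",
        "trout_small_abund",
        "trout_large_abund",
    }
)


@dataclass
class DailySeries:
    """A daily environmental series (temperature degC or discharge m3/s).

    Dates must be strictly increasing with no duplicates; gaps are allowed
    but flagged via :meth:`missing_fraction`.
    """

    values: pd.Series  # DatetimeIndex -> float
    kind: str = "temperature"  # or "discharge"

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("DailySeries requires a DatetimeIndex")
        self.values = self.values.rename_axis("date")
        idx = self.values.index
        if idx.has_duplicates:
            raise ValueError("duplicate dates in daily series")
        if not idx.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if self.kind == "discharge" and (self.values.dropna() < 0).any():
            raise ValueError("discharge values must be >= 0")

    def window(self, year: int, window: str) -> pd.Series:
        """Daily values inside a closed seasonal date window.

        ``spring_autumn`` = 1 Apr -- 30 Sep of ``year``;
        ``autumn_winter`` = 1 Oct of ``year - 1`` -- 31 Mar of ``year``.
        """
        if window == SPRING_AUTUMN:
            lo, hi = pd.Timestamp(year, 4, 1), pd.Timestamp(year, 9, 30)
        elif window == AUTUMN_WINTER:
            lo, hi = pd.Timestamp(year - 1, 10, 1), pd.Timestamp(year, 3, 31)
        else:
            raise ValueError(f"unknown window {window!r}")
        out = self.values.loc[lo:hi].dropna()
        if out.empty:
            raise ValueError(f"no observations in {window} window of year {year}")
        return out

    def missing_fraction(self, year: int, window: str) -> float:
        obs = self.window(year, window)
        if window == SPRING_AUTUMN:
            total = (pd.Timestamp(year, 9, 30) - pd.Timestamp(year, 4, 1)).days + 1
        else:
            total = (pd.Timestamp(year, 3, 31) - pd.Timestamp(year - 1, 10, 1)).days + 1
        return 1.0 - len(obs) / total

    def impute_from(self, donor: "DailySeries") -> "DailySeries":
        """Fill missing days from a secondary (donor) series, joined by date."""
        filled = self.values.combine_first(donor.values)
        return DailySeries(filled.sort_index(), kind=self.kind)


def window_mean(
    series: DailySeries, year: int, window: str, max_missing: float = 0.2
) -> float:
    """Arithmetic mean of the daily values in the closed seasonal window."""
    obs = series.window(year, window)
    frac = series.missing_fraction(year, window)
    if frac > max_missing:
        log.warning(
            "window %s of %d is missing %.0f%% of days", window, year, 100 * frac
        )
    return float(obs.mean())


def count_days_above(series: DailySeries, threshold: float, year: int) -> int:
    """Days in the spring--autumn window strictly exceeding ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    obs = series.window(year, SPRING_AUTUMN)
    return int((obs > threshold).sum())


def flow_thresholds(
    series: DailySeries, period: tuple[int, int]
) -> tuple[float, float]:
    """Q90 and Q10 discharge values over a period of calendar years.

    Q90 (the flow exceeded 90% of the time) is the empirical 10th percentile
    of all daily discharges in the period; Q10 is the 90th percentile.
    Percentiles use linear interpolation between order statistics.

    Returns ``(q90_value, q10_value)`` with ``q90_value <= q10_value``.
    """
    y0, y1 = period
    if y1 < y0:
        raise ValueError("empty period")
    vals = series.values.loc[
        pd.Timestamp(y0, 1, 1) : pd.Timestamp(y1, 12, 31)
    ].dropna()
    if len(vals) < 100:
        raise ValueError(f"period {period} has only {len(vals)} daily values (<100)")
    q90, q10 = np.quantile(vals.to_numpy(), [0.10, 0.90])
    if q90 == q10:
        warnings.warn("constant discharge series: Q90 == Q10", stacklevel=2)
    return float(q90), float(q10)


def count_flow_days(
    series: DailySeries, year: int, threshold: float, direction: str
) -> int:
    """Spring--autumn days at or beyond a discharge threshold.

    ``direction='low'`` counts days with discharge <= threshold,
    ``direction='high'`` days with discharge >= threshold (both inclusive,
    matching the "equal to or less/greater than" definitions).
    """
    obs = series.window(year, SPRING_AUTUMN)
    if direction == "low":
        return int((obs <= threshold).sum())
    if direction == "high":
        return int((obs >= threshold).sum())
    raise ValueError("direction must be 'low' or 'high'")


@dataclass
class CovariateTable:
    """Stage-specific standardised design values chi[y, s, l, m].

    ``data`` is a long DataFrame with columns
    (year, site, stage, variable, raw_value, std_value); ``scales`` maps
    variable -> (mean, sd) used for standardisation (NaN before
    :func:`z_standardise` runs).
    """

    data: pd.DataFrame
    scales: dict[str, tuple[float, float]] = field(default_factory=dict)
    stage_sets: dict[int, list[str]] = field(default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    @property
    def sites(self) -> np.ndarray:
        return np.sort(self.data["site"].unique())

    def standardised(self) -> bool:
        return self.data["std_value"].notna().all()

    def drop_variables(self, names: list[str]) -> "CovariateTable":
        keep = ~self.data["variable"].isin(names)
        sets = {l: [v for v in vs if v not in names] for l, vs in self.stage_sets.items()}
        scales = {k: v for k, v in self.scales.items() if k not in names}
        return CovariateTable(self.data.loc[keep].reset_index(drop=True), scales, sets)

    def design_arrays(
        self, stage_vars: dict[int, list[str]] | None = None
    ) -> tuple[np.ndarray, np.ndarray, dict[int, list[str]]]:
        """Dense design array X[y, s, l, m] of standardised values.

        Returns ``(X, M, stage_vars)`` where ``X`` has shape
        (n_years, n_sites, 3, max_m), ``M[l-1]`` is the number of variables
        for stage ``l`` and unused trailing entries are zero.
        """
        if not self.standardised():
            raise ValueError("covariate table must be standardised first")
        stage_vars = stage_vars if stage_vars is not None else self.stage_sets
        years, sites = self.years, self.sites
        yidx = {y: i for i, y in enumerate(years)}
        sidx = {s: i for i, s in enumerate(sites)}
        M = np.array([len(stage_vars.get(l, [])) for l in (1, 2, 3)], dtype=np.int64)
        X = np.zeros((len(years), len(sites), 3, max(int(M.max()), 1)))
        piv = self.data.set_index(["stage", "variable", "year", "site"])[
            "std_value"
        ].sort_index()
        for l in (1, 2, 3):
            for m, var in enumerate(stage_vars.get(l, [])):
                if (l, var) not in piv.index.droplevel(["year", "site"]):
                    raise ValueError(
                        f"variable {var!r} is not present for stage {l} in this "
                        "covariate table (was it dropped by the collinearity screen?)"
                    )
                sub = piv.loc[(l, var)]
                missing = [
                    (y, s)
                    for y in years
                    for s in sites
                    if (y, s) not in sub.index
                ]
                if missing:
                    raise ValueError(
                        f"stage {l} variable {var!r} missing year x site combinations: "
                        f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
                    )
                for (y, s), v in sub.items():
                    X[yidx[y], sidx[s], l - 1, m] = v
        return X, M, stage_vars


def assemble(
    raw: pd.DataFrame,
    stage_sets: dict[int, list[str]] | None = None,
    sites: list | None = None,
) -> CovariateTable:
    """Assemble the stage-specific covariate table from raw annual values.

    ``raw`` is long-format with columns (year, site, variable, value).
    Year-level environmental variables (site = NA or missing) are replicated
    across all sites; abundance variables must be supplied per year x site.
    Each stage receives only its allowed variable set.
    """
    stage_sets = stage_sets if stage_sets is not None else DEFAULT_STAGE_SETS
    raw = raw.copy()
    if "site" not in raw.columns:
        raw["site"] = np.nan
    if sites is None:
        site_vals = raw["site"].dropna().unique()
        sites = sorted(site_vals) if len(site_vals) else [1, 2, 3, 4, 5, 6]
    years = np.sort(raw["year"].unique())

    rows = []
    gaps = []
    for l, var_list in stage_sets.items():
        for var in var_list:
            sub = raw.loc[raw["variable"] == var]
            if sub.empty:
                gaps.append((l, var, "all years"))
                continue
            per_site = sub["site"].notna().any()
            for y in years:
                suby = sub.loc[sub["year"] == y]
                if suby.empty:
                    gaps.append((l, var, y))
                    continue
                if per_site:
                    lookup = suby.set_index("site")["value"]
                    for s in sites:
                        if s not in lookup.index:
                            gaps.append((l, var, (y, s)))
                        else:
                            rows.append((y, s, l, var, float(lookup.loc[s])))
                else:
                    v = float(suby["value"].iloc[0])
                    for s in sites:
                        rows.append((y, s, l, var, v))
    if gaps:
        raise ValueError(f"missing year x variable combinations: {gaps[:10]}")
    data = pd.DataFrame(
        rows, columns=["year", "site", "stage", "variable", "raw_value"]
    ).sort_values(["stage", "variable", "year", "site"], ignore_index=True)
    data["std_value"] = np.nan
    return CovariateTable(data, scales={}, stage_sets={l: list(v) for l, v in stage_sets.items()})


def z_standardise(table: CovariateTable) -> CovariateTable:
    """z-standardise each variable over its full year x site support.

    Subtracts the mean and divides by the sample standard deviation (ddof=1)
    of the variable's distinct (year, site) values, so identical replicated
    site copies of a year-level variable are not over-weighted.  Stores the
    (mean, sd) per variable for back-transforming marginal-effect axes.
    Idempotent: standardising an already standardised table re-centres by
    ~0 and re-scales by ~1.
    """
    data = table.data.copy()
    scales: dict[str, tuple[float, float]] = {}
    for var in data["variable"].unique():
        mask = data["variable"] == var
        support = (
            data.loc[mask, ["year", "site", "raw_value"]]
            .drop_duplicates(["year", "site"])["raw_value"]
            .to_numpy(dtype=float)
        )
        if len(np.unique(support)) < 2:
            raise ValueError(f"zero variance: variable {var!r} is constant")
        mean, sd = float(support.mean()), float(support.std(ddof=1))
        scales[var] = (mean, sd)
        data.loc[mask, "std_value"] = (data.loc[mask, "raw_value"] - mean) / sd
    return CovariateTable(data, scales, {l: list(v) for l, v in table.stage_sets.items()})


def collinearity_screen(
    table: CovariateTable,
    r_threshold: float = 0.7,
    drop_list: tuple[str, ...] = DEFAULT_DROP_LIST,
    resolve: str | None = None,
) -> tuple[CovariateTable, dict]:
    """Pairwise Pearson screen of stage-specific covariates.

    Flags, within each life stage, variable pairs with |r| >= ``r_threshold``
    over the stage's (year, site) support.  A flagged pair must be resolved
    by ``drop_list`` (variables to remove); by default an unresolved pair
    raises, because which member to keep is an ecological judgement, not a
    rule.  ``resolve="drop_second"`` instead drops the later-listed member
    of any unresolved pair automatically -- meant for simulation studies
    where flagged pairs are sampling accidents, not ecology.

    Returns the screened table and a report dict with the flagged pairs,
    the drops applied and the kept member of each pair.
    """
    if not table.standardised():
        raise ValueError("standardise the table before screening")
    flagged = []
    for l, var_list in table.stage_sets.items():
        sub = table.data.loc[table.data["stage"] == l]
        wide = sub.pivot_table(
            index=["year", "site"], columns="variable", values="std_value"
        )[var_list]
        corr = wide.corr(method="pearson")
        for i, vi in enumerate(var_list):
            for vj in var_list[i + 1 :]:
                r = float(corr.loc[vi, vj])
                if abs(r) >= r_threshold:
                    flagged.append({"stage": l, "pair": (vi, vj), "r": r})
    drop_set = set(drop_list)
    unresolved = [
        f for f in flagged if not (f["pair"][0] in drop_set or f["pair"][1] in drop_set)
    ]
    if unresolved:
        if resolve == "drop_second":
            for f in unresolved:
                drop_set.add(f["pair"][1])
        else:
            raise ValueError(
                "collinear pairs with no configured resolution (add one member of "
                "each to the drop list): "
                f"{[(f['stage'], f['pair'], round(f['r'], 3)) for f in unresolved]}"
            )
    dropped = sorted(
        drop_set & {v for vs in table.stage_sets.values() for v in vs}
    )
    report = {
        "r_threshold": r_threshold,
        "flagged_pairs": [
            {
                "stage": f["stage"],
                "pair": list(f["pair"]),
                "r": f["r"],
                "kept": f["pair"][0] if f["pair"][1] in drop_set else f["pair"][1],
                "reason": (
                    "configured drop list"
                    if (f["pair"][0] in drop_list or f["pair"][1] in drop_list)
                    else "auto-resolved (drop_second)"
                ),
            }
            for f in flagged
        ],
        "dropped": dropped,
    }
    return table.drop_variables(dropped), report
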