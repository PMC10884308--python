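"""Ingest, validate, filter and normalize per-skater race-record tables.

A race record holds the variables published for every long-track result:
absolute final time (s), rink altitude (m), ice surface temperature (deg C),
race frequency index (ordinal race number within a season), ambient
temperature, humidity, race date and lane. The unit of analysis downstream
is one (skater, distance) pair, here a :class:`SkaterDataset`.

Career progression ("training years") shifts a skater's absolute times
between seasons. It is removed by the *relative final time*

    t_rel_i = t_abs_i / mean(t_abs over the same season)

so that every season's relative times average exactly 1 and all seasons can
be pooled when fitting a model.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

log = logging.getLogger(__name__)

#: Columns that must be present in an input CSV.
REQUIRED_COLUMNS = ("skater_id", "distance", "race_date", "t_abs", "altitude", "ice_temp")

#: Optional columns with their fill values when absent.
OPTIONAL_COLUMNS = {
    "race_index": np.nan,  # recomputed per (skater, season) when absent
    "air_temp": np.nan,
    "humidity": np.nan,
    "lane": np.nan,
    "anomaly_flag": False,
}

NUMERIC_COLUMNS = ("distance", "t_abs", "altitude", "ice_temp", "race_index", "air_temp", "humidity", "lane")

#: Altitude bounds used for normalization and sweeps, fixed irrespective of
#: the altitudes actually visited so that all rinks share one scale (m).
ALTITUDE_BOUNDS = (0.0, 1500.0)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _normalize_minus(series: pd.Series) -> pd.Series:
    """Replace the Unicode minus (U+2212) so temperatures like '−7' parse."""
    if series.dtype == object:
        return series.astype(str).str.replace("−", "-", regex=False).str.strip()
    return series


def _parse_dates(raw: pd.Series) -> pd.Series:
    """Parse ISO-8601 dates; the compact 'YYYYMMDD' form is also accepted."""
    text = raw.astype(str).str.strip()
    compact = text.str.fullmatch(r"\d{8}")
    out = pd.to_datetime(text.where(~compact), errors="coerce", format="ISO8601")
    if compact.any():
        out = out.fillna(pd.to_datetime(text.where(compact), errors="coerce", format="%Y%m%d"))
    return out


def season_label(dates: pd.Series) -> pd.Series:
    """Season runs 1 July through 30 June, labelled '2016-2017' style."""
    start_year = dates.dt.year.where(dates.dt.month >= 7, dates.dt.year - 1)
    return start_year.astype(int).astype(str) + "-" + (start_year + 1).astype(int).astype(str)


def load_records(path_or_buffer, *, race_index_per_distance: bool = False) -> pd.DataFrame:
    """Read a race-record CSV into the canonical record table.

    Parameters
    ----------
    path_or_buffer : str, Path or file-like
        UTF-8 CSV with a header row and at least :data:`REQUIRED_COLUMNS`.
    race_index_per_distance : bool
        When recomputing a missing ``race_index``, count races separately per
        distance within a season instead of across all distances.

    Returns
    -------
    pandas.DataFrame
        Sorted by (skater_id, race_date), with ``season_label`` assigned and
        ``race_index`` present for every row.
    """
    df = pd.read_csv(path_or_buffer, dtype=str, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col, fill in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = fill

    if len(df) == 0:
        log.warning("input file contains a header but no rows")

    for col in NUMERIC_COLUMNS:
        cleaned = _normalize_minus(df[col]) if len(df) else df[col]
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"unparseable value {df[col][bad.idxmax()]!r} in column '{col}' at line {line}")
        df[col] = parsed

    dates = _parse_dates(df["race_date"])
    if dates.isna().any() and len(df):
        line = int(dates.isna().idxmax()) + 2
        raise SchemaError(f"unparseable race_date at line {line}")
    df["race_date"] = dates

    flag = df["anomaly_flag"]
    if flag.dtype == object:
        flag = flag.astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
    df["anomaly_flag"] = flag.fillna(False).astype(bool)

    if len(df):
        bad_t = df["t_abs"] <= 0
        if bad_t.any():
            raise DataError(f"non-positive t_abs at line {int(bad_t.idxmax()) + 2}")
        df["season_label"] = season_label(df["race_date"])
    else:
        df["season_label"] = pd.Series(dtype=str)

    df = df.sort_values(["skater_id", "race_date"], kind="stable").reset_index(drop=True)

    dup = df.duplicated(subset=["skater_id", "race_date", "distance"], keep=False)
    if dup.any():
        log.warning("%d duplicated (skater, date, distance) rows kept as-is", int(dup.sum()))

    # drop rows missing any of the three model factors
    factor_na = df[["altitude", "ice_temp"]].isna().any(axis=1)
    if factor_na.any():
        log.warning("dropping %d rows with missing altitude/ice_temp", int(factor_na.sum()))
        df = df[~factor_na].reset_index(drop=True)

    if df["race_index"].isna().any():
        group = ["skater_id", "season_label"]
        if race_index_per_distance:
            group.append("distance")
        recomputed = df.groupby(group, sort=False).cumcount() + 1
        df["race_index"] = df["race_index"].fillna(recomputed.astype(float))
    df["race_index"] = df["race_index"].astype(float)
    if len(df) and (df["race_index"] < 1).any():
        raise DataError("race_index must be >= 1")
    return df


def records_from_csv_text(text: str, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: parse records from an in-memory CSV string."""
    return load_records(io.StringIO(text), **kwargs)


# ---------------------------------------------------------------------------
# filtering and relative times
# ---------------------------------------------------------------------------

def filter_anomalies(records: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged as anomalous (injury, illness, cancelled result).

    Idempotent; logs the removal count. Flagging is a declarative input
    column — no automatic outlier detection is attempted.
    """
    flagged = records["anomaly_flag"].astype(bool)
    n = int(flagged.sum())
    if n:
        log.info("filter_anomalies removed %d of %d records", n, len(records))
    out = records.loc[~flagged].reset_index(drop=True)
    if len(out) == 0 and len(records) > 0:
        log.warning("all records were flagged as anomalous; empty output")
    return out


def compute_relative_times(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the relative final time ``t_rel`` to every record.

    Relative time is computed within (skater, season, distance): each
    absolute time is divided by the mean absolute time of that group, so the
    group mean of ``t_rel`` is exactly 1 and between-season career drift
    cancels out.
    """
    if len(records) == 0:
        out = records.copy()
        out["t_rel"] = pd.Series(dtype=float)
        return out
    if (records["t_abs"] <= 0).any():
        raise DataError("t_abs must be positive to form relative times")
    out = records.copy()
    season_mean = out.groupby(["skater_id", "season_label", "distance"])["t_abs"].transform("mean")
    out["t_rel"] = out["t_abs"] / season_mean
    return out


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Per-variable (min, max) pairs for [0, 1] min-max scaling.

    The spec is fit on the whole dataset (not a training split) so that the
    one-at-a-time prediction grids, which span each variable's full range,
    never leave [0, 1].
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if not (hi > lo):
                raise DataError(f"degenerate normalization range for '{name}': [{lo}, {hi}]")

    def scale(self, name: str, x):
        lo, hi = self._range(name)
        return (np.asarray(x, dtype=float) - lo) / (hi - lo)

    def inverse(self, name: str, x):
        lo, hi = self._range(name)
        return np.asarray(x, dtype=float) * (hi - lo) + lo

    def _range(self, name: str) -> tuple[float, float]:
        try:
            return self.ranges[name]
        except KeyError:
            raise DataError(f"no normalization range for variable '{name}'") from None


def minmax_scale(x, lo: float, hi: float):
    """Scale ``x`` to [0, 1] over the range [lo, hi]; X = (x - lo)/(hi - lo)."""
    if not (hi > lo):
        raise DataError(f"degenerate min-max range [{lo}, {hi}]")
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


def minmax_inverse(x, lo: float, hi: float):
    """Inverse of :func:`minmax_scale`; recovers the original units."""
    if not (hi > lo):
        raise DataError(f"degenerate min-max range [{lo}, {hi}]")
    return np.asarray(x, dtype=float) * (hi - lo) + lo


def _widen_if_degenerate(name: str, lo: float, hi: float) -> tuple[float, float]:
    if hi > lo:
        return float(lo), float(hi)
    # constant variable: open a ±5% band around the value so scaling stays
    # defined and a constant target can be represented tightly
    pad = 0.05 * max(1.0, abs(lo))
    log.warning("variable '%s' has a degenerate range [%s, %s]; widening by ±%s", name, lo, hi, pad)
    return float(lo) - pad, float(hi) + pad


# ---------------------------------------------------------------------------
# per-dataset statistics
# ---------------------------------------------------------------------------

@dataclass
class SkaterDataset:
    """All retained records for one (skater, distance) pair plus statistics.

    Attributes
    ----------
    records : pandas.DataFrame
        Canonical record table including ``t_rel``.
    a : int
        Number of retained races.
    t_ave : float
        Career mean absolute final time (s); rescales relative predictions
        back to seconds.
    t_con, r_con : float
        Mean ice temperature and mean race index; the "average conditions"
        at which non-swept factors are held during sensitivity sweeps.
    ranges : dict
        Sweep/normalization bounds: altitude fixed to (0, 1500) m, ice
        temperature from the data, race index from 1 to the observed max.
    """

    skater_id: str
    distance: float
    records: pd.DataFrame
    a: int
    t_ave: float
    t_con: float
    r_con: float
    ranges: dict[str, tuple[float, float]]

    def normalization_spec(self) -> NormalizationSpec:
        """Min-max spec over (altitude, ice_temp, race_index, t_rel)."""
        t_rel = self.records["t_rel"].to_numpy()
        ranges = dict(self.ranges)
        ranges["t_rel"] = _widen_if_degenerate("t_rel", t_rel.min(), t_rel.max())
        return NormalizationSpec(ranges)


def dataset_statistics(records: pd.DataFrame) -> dict:
    """Compute (t_ave, T_con, R_con, ranges) for one dataset.

    ``t_ave`` is the career mean of the absolute times; the constants are
    the means of ice temperature and race index. Altitude bounds are fixed
    to [0, 1500] m regardless of the altitudes observed; the race-index
    range starts at 1.
    """
    if len(records) == 0:
        raise DataError("cannot compute statistics of an empty dataset")
    t = records["ice_temp"].to_numpy(dtype=float)
    r = records["race_index"].to_numpy(dtype=float)
    ranges = {
        "altitude": ALTITUDE_BOUNDS,
        "ice_temp": _widen_if_degenerate("ice_temp", t.min(), t.max()),
        "race_index": (1.0, float(max(r.max(), 1.0 + 1e-9))),
    }
    return {
        "t_ave": float(records["t_abs"].mean()),
        "t_con": float(t.mean()),
        "r_con": float(r.mean()),
        "ranges": ranges,
    }


def build_datasets(records: pd.DataFrame, *, min_records: int = 13) -> list[SkaterDataset]:
    """Split a record table into per-(skater, distance) analysis datasets.

    Records are filtered for anomalies, relative times attached, and groups
    with fewer than ``min_records`` races dropped with a warning (13 is the
    smallest per-skater record count the method was developed on).
    """
    clean = compute_relative_times(filter_anomalies(records))
    out: list[SkaterDataset] = []
    for (skater, distance), group in clean.groupby(["skater_id", "distance"], sort=True):
        if len(group) < min_records:
            log.warning("skipping %s/%sm: only %d records (< %d)", skater, distance, len(group), min_records)
            continue
        group = group.reset_index(drop=True)
        stats = dataset_statistics(group)
        out.append(SkaterDataset(
            skater_id=str(skater), distance=float(distance), records=group,
            a=len(group), t_ave=stats["t_ave"], t_con=stats["t_con"],
            r_con=stats["r_con"], ranges=stats["ranges"],
        ))
    return out
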