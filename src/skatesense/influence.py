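"""Dimensionless influence values, tercile ratings and distance profiles.

Ensemble slopes K carry physical units (s/km, s/degC, s/game) and are not
comparable across factors or skaters. Across a study's c sample datasets
(one per skater x distance) each slope is made dimensionless:

    N_i = 100 * c * K_i / sum_j |K_j|

so that sum |N| = 100*c and the values are reported as rounded integers.
Ratings are terciles of |N| with fixed boundaries 20 and 100:
|N| <= 20 negligible, 20 < |N| <= 100 perceptible, |N| > 100 important.
A negative N means the factor speeds the skater up.

The module also ships a packaged reference table of published influence
values for 15 (skater, distance) samples of eight elite skaters; the
rating and profile operations reproduce the published summary tables from
it, which pins down the conventions above.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

RATINGS = ("negligible", "perceptible", "important")
DEFAULT_BOUNDARIES = (20.0, 100.0)
INFLUENCE_SCALE = 100.0

#: Influence-table column per sweep factor.
FACTOR_N_COLUMN = {"altitude": "N_altitude", "ice_temp": "N_ice_temp", "race_freq": "N_race_freq"}


def load_reference_influence_table() -> pd.DataFrame:
    """The packaged 15-sample reference influence table."""
    ref = importlib.resources.files("skatesense.data") / "reference_influence_values.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


# ---------------------------------------------------------------------------
# influence values
# ---------------------------------------------------------------------------

def influence_values(slopes, scale: float = INFLUENCE_SCALE, rounded: bool = True) -> np.ndarray:
    """Dimensionless influence values for one factor across c samples.

    N_i = scale * c * K_i / sum |K|, rounded to the nearest integer by
    default (the reporting convention of the reference table).
    """
    k = np.asarray(slopes, dtype=float)
    if k.size == 0:
        raise DataError("influence_values needs at least one slope")
    denom = np.abs(k).sum()
    if denom == 0:
        raise DataError("all slopes are zero; influence normalization undefined")
    n = scale * k.size * k / denom
    return np.round(n) if rounded else n


def rate_influence(n_value: float, boundaries=DEFAULT_BOUNDARIES, inclusive: bool = True) -> str:
    """Tercile rating of one influence value.

    With the default inclusive boundaries: |N| <= 20 -> negligible,
    20 < |N| <= 100 -> perceptible, |N| > 100 -> important.
    ``inclusive=False`` moves the boundary values up one class.
    """
    lower, upper = boundaries
    if not (lower < upper):
        raise DataError("rating boundaries must satisfy lower < upper")
    if not np.isfinite(n_value):
        raise DataError("non-finite influence value")
    a = abs(n_value)
    if a < lower or (inclusive and a == lower):
        return "negligible"
    if a < upper or (inclusive and a == upper):
        return "perceptible"
    return "important"


# ---------------------------------------------------------------------------
# influence tables
# ---------------------------------------------------------------------------

@dataclass
class InfluenceStudy:
    """Influence values and ratings for a collection of sample datasets."""

    table: pd.DataFrame  # one row per (skater, distance) sample
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES


def build_influence_table(
    samples: pd.DataFrame,
    boundaries=DEFAULT_BOUNDARIES,
    inclusive: bool = True,
    scale: float = INFLUENCE_SCALE,
) -> pd.DataFrame:
    """From per-sample ensemble slopes to influence values and ratings.

    ``samples`` needs columns skater_id, distance and K_altitude,
    K_ice_temp, K_race_freq (one row per sample dataset). Adds N_* and
    rating_* columns; c is the number of rows actually present.
    """
    out = samples.copy().reset_index(drop=True)
    for factor, n_col in FACTOR_N_COLUMN.items():
        k_col = "K_" + factor
        if k_col not in out.columns:
            raise DataError(f"missing slope column '{k_col}'")
        out[n_col] = influence_values(out[k_col].to_numpy(), scale=scale)
        out["rating_" + factor] = [
            rate_influence(v, boundaries, inclusive) for v in out[n_col]
        ]
    return out


def attach_ratings(table: pd.DataFrame, boundaries=DEFAULT_BOUNDARIES, inclusive: bool = True) -> pd.DataFrame:
    """Add rating_* columns to a table that already has N_* columns."""
    out = table.copy()
    for factor, n_col in FACTOR_N_COLUMN.items():
        if n_col not in out.columns:
            raise DataError(f"missing influence column '{n_col}'")
        out["rating_" + factor] = [rate_influence(v, boundaries, inclusive) for v in out[n_col]]
    return out


def summarize_ratings(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-factor count tables: rating x distance.

    Returns one DataFrame per factor, rows indexed negligible /
    perceptible / important, one column per distance; each column sums to
    the number of samples at that distance.
    """
    if len(table) == 0:
        raise DataError("cannot summarize an empty influence table")
    rated = table if "rating_altitude" in table.columns else attach_ratings(table)
    distances = sorted(rated["distance"].unique())
    out = {}
    for factor in FACTOR_N_COLUMN:
        counts = pd.DataFrame(0, index=list(RATINGS), columns=distances)
        grouped = rated.groupby(["distance", "rating_" + factor]).size()
        for (d, r), n in grouped.items():
            counts.loc[r, d] = int(n)
        out[factor] = counts
    return out


def distance_profile(table: pd.DataFrame, benchmark_distance: float = 3000) -> pd.DataFrame:
    """Normalized mean and SD of |N| per factor and distance.

    The mean absolute influence at the benchmark distance (3,000 m) is 1
    by construction for every factor; all other distances' means and SDs
    are expressed relative to that benchmark mean.
    """
    rated = table
    if benchmark_distance not in set(rated["distance"]):
        raise DataError(f"benchmark distance {benchmark_distance} absent from the table")
    rows = []
    for factor, n_col in FACTOR_N_COLUMN.items():
        if n_col not in rated.columns:
            raise DataError(f"missing influence column '{n_col}'")
        absn = rated[n_col].abs()
        bench = absn[rated["distance"] == benchmark_distance].mean()
        if bench == 0:
            raise DataError(f"benchmark mean influence is zero for factor '{factor}'")
        for d, group in rated.groupby("distance"):
            rows.append({
                "factor": factor,
                "distance": d,
                "norm_mean": float(group[n_col].abs().mean() / bench),
                "norm_sd": float(group[n_col].abs().std(ddof=1) / bench) if len(group) > 1 else 0.0,
            })
    return pd.DataFrame(rows)


def percent_difference(value_a: float, value_b: float, ndigits: int = 0) -> float:
    """|a - b| / |b| * 100, rounded for reporting (default nearest integer)."""
    if value_b == 0:
        raise DataError("percent_difference needs a nonzero reference value")
    return round(abs(value_a - value_b) / abs(value_b) * 100.0, ndigits)
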