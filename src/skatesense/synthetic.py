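"""Synthetic race-record generator with known ground-truth factor effects.

Real elite race records are scraped from federation result sites and are
not redistributable, so every pipeline stage is exercised on generated
data whose true altitude / ice-temperature / race-frequency effects are
known. The generator is deliberately the *inverse problem* of the
pipeline: times are affine in the three factors (with optional mild
temperature curvature), multiplied by a per-season "training years" drift
that the relative-time normalization must remove, plus Gaussian noise:

    t_abs = (base + bA*A_km + bT*T + bT2*T^2 + bR*R + eps) * drift^season

Default magnitudes mirror the scales seen in elite long-track data: base
time 70 s (a 1,000 m specialist), altitude effect -0.5 s/km (faster at
altitude), a small signed temperature response (the sign encodes a
skater's technical profile), -0.05 s per additional race in the season,
2% improvement per season, and 0.05 s timing noise. Venues are a 70/30
mix of low (0-100 m) and high (1,000-1,425 m) rinks, ice temperatures
uniform on [-12, -4] degC.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import season_label

DEFAULT_VENUE_MIX = ((0.7, (0.0, 100.0)), (0.3, (1000.0, 1425.0)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth generating parameters for one synthetic skater."""

    skater_id: str = "SYN-A"
    distance: float = 1000.0
    base_time: float = 70.0          # s
    beta_altitude: float = -0.5      # s/km
    beta_ice_temp: float = 0.05      # s/degC
    beta_ice_temp2: float = 0.0      # s/degC^2 curvature, off by default
    beta_race_freq: float = -0.05    # s/race
    season_drift: float = 0.98       # multiplicative factor per season
    noise_sd: float = 0.05           # s
    n_seasons: int = 5
    races_per_season: int = 20
    venue_mix: tuple = DEFAULT_VENUE_MIX
    temp_range: tuple[float, float] = (-12.0, -4.0)
    first_season_year: int = 2017
    seed: int = 0

    def __post_init__(self):
        if self.base_time <= 0:
            raise DataError("base_time must be positive")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")
        if self.races_per_season < 1 or self.n_seasons < 1:
            raise DataError("need at least one season with one race")
        weights = [w for w, _ in self.venue_mix]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise DataError("venue_mix weights must be non-negative and sum to 1")
        for _, (lo, hi) in self.venue_mix:
            if not (0 <= lo <= hi <= 1500):
                raise DataError("venue altitudes must lie within [0, 1500] m")

    def to_dict(self) -> dict:
        return asdict(self)


def true_slopes(truth: SyntheticTruth) -> dict[str, float]:
    """Ground-truth influence slopes in the pipeline's reporting units.

    The temperature slope is the marginal d(t)/dT at the middle of the
    temperature range when curvature is on.
    """
    t_mid = 0.5 * (truth.temp_range[0] + truth.temp_range[1])
    return {
        "altitude": truth.beta_altitude,
        "ice_temp": truth.beta_ice_temp + 2.0 * truth.beta_ice_temp2 * t_mid,
        "race_freq": truth.beta_race_freq,
    }


def _race_dates(truth: SyntheticTruth) -> pd.Series:
    """Race days spread over each season's November-March window."""
    dates = []
    for s in range(truth.n_seasons):
        start = pd.Timestamp(year=truth.first_season_year + s, month=11, day=1)
        span_days = 135  # through mid-March
        offsets = np.linspace(0, span_days, truth.races_per_season).round().astype(int)
        dates.extend(start + pd.to_timedelta(offsets, unit="D"))
    return pd.Series(dates)


def generate_dataset(truth: SyntheticTruth) -> pd.DataFrame:
    """Generate one skater's record table in the canonical schema.

    Deterministic given ``truth.seed``. ``anomaly_flag`` is False
    throughout; ambient temperature, humidity and lane are emitted but
    carry no effect on times.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed,)))
    n = truth.n_seasons * truth.races_per_season
    season_idx = np.repeat(np.arange(truth.n_seasons), truth.races_per_season)
    race_index = np.tile(np.arange(1, truth.races_per_season + 1), truth.n_seasons).astype(float)

    weights = np.array([w for w, _ in truth.venue_mix])
    bands = rng.choice(len(weights), size=n, p=weights)
    lo = np.array([b[0] for _, b in truth.venue_mix])[bands]
    hi = np.array([b[1] for _, b in truth.venue_mix])[bands]
    altitude = rng.uniform(lo, hi)

    t_lo, t_hi = truth.temp_range
    ice_temp = rng.uniform(t_lo, t_hi, size=n)
    noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else np.zeros(n)

    a_km = altitude / 1000.0
    clean = (
        truth.base_time
        + truth.beta_altitude * a_km
        + truth.beta_ice_temp * ice_temp
        + truth.beta_ice_temp2 * ice_temp**2
        + truth.beta_race_freq * race_index
    )
    t_abs = (clean + noise) * truth.season_drift**season_idx
    if np.any(t_abs <= 0):
        raise DataError("generated non-positive race time; check truth parameters")

    dates = _race_dates(truth)
    df = pd.DataFrame({
        "skater_id": truth.skater_id,
        "distance": truth.distance,
        "race_date": dates,
        "t_abs": t_abs,
        "altitude": altitude,
        "ice_temp": ice_temp,
        "race_index": race_index,
        "air_temp": rng.uniform(10.0, 18.0, size=n).round(1),
        "humidity": rng.uniform(30.0, 50.0, size=n).round(0),
        "lane": rng.integers(1, 3, size=n).astype(float),
        "anomaly_flag": False,
    })
    df["season_label"] = season_label(df["race_date"])
    return df


def inject_anomalies(
    records: pd.DataFrame,
    fraction: float,
    magnitude: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag a random subset of rows and inflate their times.

    Emulates injury/illness/disqualification races that the anomaly filter
    must drop: ``fraction`` of rows get ``anomaly_flag=True`` and
    ``magnitude`` seconds added to ``t_abs``.
    """
    if not (0 <= fraction < 1):
        raise DataError("fraction must be in [0, 1)")
    out = records.copy()
    n_flag = int(round(fraction * len(out)))
    if n_flag == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    idx = rng.choice(len(out), size=n_flag, replace=False)
    out.iloc[idx, out.columns.get_loc("t_abs")] += magnitude
    out.iloc[idx, out.columns.get_loc("anomaly_flag")] = True
    return out
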