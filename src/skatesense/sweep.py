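"""One-at-a-time prediction matrices and influence slopes.

For each factor a 500-point grid sweeps that factor uniformly from its
minimum to its maximum while the other two are pinned at reference
constants: altitude at A_con = 50 m ("low altitude") and ice temperature /
race index at their dataset means (T_con, R_con). Each retained model maps
the grid to predicted relative times, which are rescaled to absolute
seconds by the career mean time t_ave. The slope of that curve against the
swept factor is the model's influence slope k; the ensemble influence slope
K_b is the arithmetic mean of k over the b retained models.

Units: altitude slopes are reported in s/km (the per-metre OLS slope times
1,000), ice temperature in s/degC, race frequency in s/game.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .network import INPUT_COLUMNS, NetworkModel, TrainedModel
from .preprocess import NormalizationSpec, SkaterDataset

log = logging.getLogger(__name__)

FACTORS = ("altitude", "ice_temp", "race_freq")

#: Which record column each sweep factor varies.
FACTOR_COLUMN = {"altitude": "altitude", "ice_temp": "ice_temp", "race_freq": "race_index"}

FACTOR_UNITS = {"altitude": "s/km", "ice_temp": "s/degC", "race_freq": "s/game"}

#: Reference altitude (m) at which non-altitude sweeps are evaluated.
A_CON = 50.0

DEFAULT_GRID_POINTS = 500


@dataclass
class SweepMatrix:
    """One-at-a-time input grid for a single factor.

    ``grid`` is (n_points, 3) with columns ordered as
    (altitude, ice_temp, race_index); only the swept column varies and it
    includes both endpoints. ``step`` is the uniform grid increment.
    """

    factor: str
    grid: np.ndarray
    step: float

    @property
    def swept_values(self) -> np.ndarray:
        return self.grid[:, INPUT_COLUMNS.index(FACTOR_COLUMN[self.factor])]


@dataclass
class SweepResult:
    """Ensemble sweep output for one factor."""

    factor: str
    units: str
    curves: np.ndarray       # (n_models, n_points) predicted absolute times, s
    slopes: np.ndarray       # (n_models,) per-model slopes, factor units
    K: float                 # mean of slopes over the retained models
    slope_sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)


def build_sweep_matrix(
    factor: str,
    stats: SkaterDataset | dict,
    n_points: int = DEFAULT_GRID_POINTS,
    a_con: float = A_CON,
) -> SweepMatrix:
    """Build the prediction grid for one factor.

    ``stats`` is a SkaterDataset or a dataset_statistics() dict carrying
    t_con, r_con and the per-variable ranges. Altitude spans [0, 1500] m,
    ice temperature the observed range, race index [1, R_max].
    """
    if factor not in FACTORS:
        raise DataError(f"unknown sweep factor '{factor}'; expected one of {FACTORS}")
    if n_points < 2:
        raise DataError("a sweep needs at least 2 grid points")
    if isinstance(stats, dict):
        t_con, r_con, ranges = stats["t_con"], stats["r_con"], stats["ranges"]
    else:
        t_con, r_con, ranges = stats.t_con, stats.r_con, stats.ranges

    column = FACTOR_COLUMN[factor]
    lo, hi = ranges[column]
    if not (hi > lo):
        raise DataError(f"degenerate data range for factor '{factor}': [{lo}, {hi}]")
    swept = np.linspace(lo, hi, n_points)

    constants = {"altitude": a_con, "ice_temp": t_con, "race_index": r_con}
    grid = np.empty((n_points, len(INPUT_COLUMNS)))
    for j, col in enumerate(INPUT_COLUMNS):
        grid[:, j] = swept if col == column else constants[col]
    return SweepMatrix(factor=factor, grid=grid, step=float((hi - lo) / (n_points - 1)))


def predict_curve(
    model: NetworkModel | TrainedModel,
    matrix: SweepMatrix,
    norm: NormalizationSpec,
    t_ave: float,
) -> np.ndarray:
    """Predicted absolute final times (s) along a sweep grid.

    Each grid triple is min-max scaled, passed through the network,
    de-scaled back to a relative time and multiplied by t_ave. Grid values
    outside the normalization ranges are an error: the network is a pure
    interpolator and the scaling formula must not extrapolate.
    """
    if t_ave <= 0:
        raise DataError("t_ave must be positive")
    net = model.network if isinstance(model, TrainedModel) else model
    scaled = np.empty_like(matrix.grid)
    for j, col in enumerate(INPUT_COLUMNS):
        scaled[:, j] = norm.scale(col, matrix.grid[:, j])
    if scaled.min() < -1e-9 or scaled.max() > 1 + 1e-9:
        raise DataError(f"sweep grid for '{matrix.factor}' leaves the normalization range")
    t_rel = norm.inverse("t_rel", net.predict_scaled(scaled))
    return t_rel * t_ave


def slope_of_curve(y_hat: np.ndarray, matrix: SweepMatrix, method: str = "ols") -> float:
    """Slope of the predicted-time curve in reporting units.

    Default is the ordinary least-squares slope over all grid points (a
    global linear summary robust to mild curvature); ``method="endpoints"``
    uses the two-point finite difference instead. Altitude slopes are
    converted from s/m to s/km.
    """
    y = np.asarray(y_hat, dtype=float)
    x = matrix.swept_values
    if y.shape != x.shape:
        raise DataError("curve and grid lengths differ")
    if np.ptp(x) == 0:
        raise DataError("zero variance in the swept variable")
    if method == "ols":
        xc = x - x.mean()
        slope = float(xc @ (y - y.mean()) / (xc @ xc))
    elif method == "endpoints":
        slope = float((y[-1] - y[0]) / (x[-1] - x[0]))
    else:
        raise DataError(f"unknown slope method '{method}'")
    if matrix.factor == "altitude":
        slope *= 1000.0  # s/m -> s/km
    return slope


def aggregate_slopes(slopes, n_bins: int = 20) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean, SD and histogram of per-model slopes.

    The mean is the ensemble influence slope K_b; the SD and histogram
    summarize member dispersion for reporting.
    """
    k = np.asarray(slopes, dtype=float)
    if k.size == 0:
        raise DataError("no slopes to aggregate")
    if not np.all(np.isfinite(k)):
        raise DataError("non-finite slope in aggregation input")
    counts, edges = np.histogram(k, bins=n_bins)
    return float(k.mean()), float(k.std(ddof=0)), counts, edges


def sweep_factor(
    models: list[TrainedModel],
    factor: str,
    dataset: SkaterDataset,
    norm: NormalizationSpec | None = None,
    n_points: int = DEFAULT_GRID_POINTS,
    a_con: float = A_CON,
    slope_method: str = "ols",
) -> SweepResult:
    """Run one factor's sweep through every retained model and aggregate."""
    if not models:
        raise DataError("sweep needs at least one retained model")
    norm = norm or dataset.normalization_spec()
    matrix = build_sweep_matrix(factor, dataset, n_points=n_points, a_con=a_con)
    curves = np.stack([predict_curve(m, matrix, norm, dataset.t_ave) for m in models])
    slopes = np.array([slope_of_curve(c, matrix, method=slope_method) for c in curves])
    K, sd, counts, edges = aggregate_slopes(slopes)
    return SweepResult(
        factor=factor, units=FACTOR_UNITS[factor], curves=curves, slopes=slopes,
        K=K, slope_sd=sd, hist_counts=counts, hist_edges=edges,
    )


def sweep_all_factors(models, dataset, norm=None, **kwargs) -> dict[str, SweepResult]:
    """Sweeps for altitude, ice temperature and race frequency."""
    norm = norm or dataset.normalization_spec()
    return {f: sweep_factor(models, f, dataset, norm, **kwargs) for f in FACTORS}
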