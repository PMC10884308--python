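"""End-to-end orchestration: ingest -> ensemble -> sweeps -> influence.

`analyze_dataset` runs the whole method for one (skater, distance) sample
in memory; `run_pipeline` drives it over every sample in an input CSV and
writes tables, a manifest with content hashes, and (optionally) figures.
`parameter_recovery_study` and `drift_study` are the simulation harnesses
that check the pipeline against the synthetic generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import EnsembleResult, EnsembleSpec, build_ensemble, ensemble_manifest
from .errors import ConfigError, DataError
from .influence import (
    DEFAULT_BOUNDARIES,
    INFLUENCE_SCALE,
    build_influence_table,
    distance_profile,
    summarize_ratings,
)
from .network import Hyperparams, hidden_node_candidates, select_node_count
from .preprocess import SkaterDataset, build_datasets, load_records
from .sweep import A_CON, DEFAULT_GRID_POINTS, FACTORS, SweepResult, sweep_all_factors
from .synthetic import SyntheticTruth, generate_dataset, true_slopes

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; defaults are the study-scale
    settings (1,000 iterations, b = 200, 500-point grids, A_con = 50 m,
    rating boundaries 20/100, 10 repeats per node-count candidate)."""

    input_csv: str = ""
    output_dir: str = "skatesense_run"
    min_records: int = 13
    hidden_nodes: int | None = None     # None -> heuristic search
    node_repeats: int = 10
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    n_iterations: int = 1000
    b: int = 200
    grid_points: int = DEFAULT_GRID_POINTS
    a_con: float = A_CON
    slope_method: str = "ols"
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
    influence_scale: float = INFLUENCE_SCALE
    master_seed: int = 0
    figures: bool = False
    log_level: str = "INFO"

    @classmethod
    def test_profile(cls, **overrides) -> "PipelineConfig":
        """Scaled-down profile (200 iterations, b = 50) for desk runtime."""
        overrides.setdefault("n_iterations", 200)
        overrides.setdefault("b", 50)
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        hp = raw.pop("hyperparams", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "boundaries" in raw:
            raw["boundaries"] = tuple(raw["boundaries"])
        cfg = cls(**raw)
        if hp:
            cfg.hyperparams = Hyperparams(**hp)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["boundaries"] = list(self.boundaries)
        return d


# ---------------------------------------------------------------------------
# per-sample analysis
# ---------------------------------------------------------------------------

@dataclass
class SampleAnalysis:
    """Full method output for one (skater, distance) sample dataset."""

    dataset: SkaterDataset
    m_star: int
    node_deltas: dict[int, float]
    ensemble: EnsembleResult
    sweeps: dict[str, SweepResult]

    @property
    def slopes(self) -> dict[str, float]:
        return {f: self.sweeps[f].K for f in self.sweeps}


def analyze_dataset(dataset: SkaterDataset, config: PipelineConfig) -> SampleAnalysis:
    """Run node selection, population training, filtering and sweeps."""
    norm = dataset.normalization_spec()
    if config.hidden_nodes is not None:
        m_star, node_deltas = int(config.hidden_nodes), {}
    else:
        candidates = hidden_node_candidates(3, 1)
        m_star, node_deltas = select_node_count(
            dataset, candidates, repeats=config.node_repeats,
            seed=config.master_seed, hyperparams=config.hyperparams,
        )
        log.info("%s/%gm: selected m=%d", dataset.skater_id, dataset.distance, m_star)
    spec = EnsembleSpec(n_iterations=config.n_iterations, b=config.b)
    ens = build_ensemble(dataset, m_star, spec, config.master_seed,
                         hyperparams=config.hyperparams, norm=norm)
    sweeps = sweep_all_factors(
        ens.retained, dataset, norm,
        n_points=config.grid_points, a_con=config.a_con,
        slope_method=config.slope_method,
    )
    return SampleAnalysis(dataset=dataset, m_star=m_star, node_deltas=node_deltas,
                          ensemble=ens, sweeps=sweeps)


def analyze_records(records: pd.DataFrame, config: PipelineConfig) -> list[SampleAnalysis]:
    """Analyze every (skater, distance) sample in a record table."""
    datasets = build_datasets(records, min_records=config.min_records)
    if not datasets:
        raise DataError(f"no (skater, distance) group has >= {config.min_records} records")
    return [analyze_dataset(ds, config) for ds in datasets]


def influence_study(analyses: list[SampleAnalysis], config: PipelineConfig) -> pd.DataFrame:
    """Cross-sample influence table (values + ratings) from analyses."""
    rows = [
        {"skater_id": a.dataset.skater_id, "distance": a.dataset.distance,
         **{f"K_{f}": a.sweeps[f].K for f in FACTORS}}
        for a in analyses
    ]
    return build_influence_table(pd.DataFrame(rows), boundaries=config.boundaries,
                                 scale=config.influence_scale)


# ---------------------------------------------------------------------------
# full pipeline with on-disk artifacts
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the pipeline on ``config.input_csv`` and write a run directory.

    Artifacts: preprocessed records, per-sample statistics, node-selection
    results, ensemble manifests, sweep curves and slopes, the influence
    table, rating summaries, the distance profile when possible, and a
    manifest listing every file with its SHA-256 so a rerun can be checked
    for bit-identity.
    """
    if not config.input_csv:
        raise ConfigError("config.input_csv is required")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = load_records(config.input_csv)
    analyses = analyze_records(records, config)

    files: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        files.append(p)

    def save_json(obj, name: str):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        files.append(p)

    processed = pd.concat([a.dataset.records for a in analyses], ignore_index=True)
    save_df(processed, "records_preprocessed.csv")
    save_json([
        {"skater_id": a.dataset.skater_id, "distance": a.dataset.distance,
         "a": a.dataset.a, "t_ave": a.dataset.t_ave, "t_con": a.dataset.t_con,
         "r_con": a.dataset.r_con,
         "ranges": {k: list(v) for k, v in a.dataset.ranges.items()},
         "m_star": a.m_star, "node_mean_delta": {str(k): v for k, v in a.node_deltas.items()}}
        for a in analyses
    ], "dataset_statistics.json")
    save_json([
        {"skater_id": a.dataset.skater_id, "distance": a.dataset.distance,
         "n_trained": a.ensemble.n_trained, "n_filtered_out": a.ensemble.n_filtered_out,
         "retained": ensemble_manifest(a.ensemble)}
        for a in analyses
    ], "ensemble_manifest.json")

    sweep_rows, slope_rows = [], []
    for a in analyses:
        for f, sw in a.sweeps.items():
            q = np.quantile(sw.curves, [0.05, 0.5, 0.95], axis=0)
            for i, x in enumerate(_grid_values(a, f, config)):
                sweep_rows.append({
                    "skater_id": a.dataset.skater_id, "distance": a.dataset.distance,
                    "factor": f, "x": x, "y_mean": sw.mean_curve[i],
                    "y_q05": q[0, i], "y_q50": q[1, i], "y_q95": q[2, i],
                })
            slope_rows.append({
                "skater_id": a.dataset.skater_id, "distance": a.dataset.distance,
                "factor": f, "K": sw.K, "slope_sd": sw.slope_sd, "units": sw.units,
            })
    save_df(pd.DataFrame(sweep_rows), "sweep_curves.csv")
    save_df(pd.DataFrame(slope_rows), "ensemble_slopes.csv")

    table = influence_study(analyses, config)
    save_df(table, "influence_table.csv")
    for factor, counts in summarize_ratings(table).items():
        save_df(counts.rename_axis("rating").reset_index(), f"rating_summary_{factor}.csv")
    if 3000 in set(table["distance"]):
        save_df(distance_profile(table), "distance_profile.csv")

    if config.figures:
        files.extend(render_reports(out, analyses, table))

    manifest = {
        "config": config.to_dict(),
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _grid_values(analysis: SampleAnalysis, factor: str, config: PipelineConfig) -> np.ndarray:
    from .sweep import build_sweep_matrix

    return build_sweep_matrix(factor, analysis.dataset, n_points=config.grid_points,
                              a_con=config.a_con).swept_values


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def render_reports(out_dir: Path, analyses: list[SampleAnalysis],
                   table: pd.DataFrame) -> list[Path]:
    """Figures + markdown summary for a completed run (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not analyses or not analyses[0].ensemble.retained:
        raise DataError("reporting needs at least one analysis with retained models")
    out_dir = Path(out_dir)
    written: list[Path] = []

    a0 = analyses[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    deltas = a0.ensemble.deltas
    ax.plot(np.arange(1, len(deltas) + 1), deltas, lw=1.5)
    ax.set_xlabel("model rank (ascending delta)")
    ax.set_ylabel("delta = E + e (%)")
    ax.set_title(f"{a0.dataset.skater_id} {a0.dataset.distance:g} m: retained ensemble")
    p = out_dir / "ensemble_delta_curve.png"
    fig.savefig(p, dpi=120, bbox_inches="tight"); plt.close(fig)
    written.append(p)

    for factor in FACTORS:
        fig, ax = plt.subplots(figsize=(6, 4))
        sw = a0.sweeps[factor]
        ax.bar(0.5 * (sw.hist_edges[1:] + sw.hist_edges[:-1]), sw.hist_counts,
               width=np.diff(sw.hist_edges), edgecolor="k")
        ax.set_xlabel(f"slope ({sw.units})")
        ax.set_ylabel("frequency")
        ax.set_title(f"{factor} slope distribution")
        p = out_dir / f"slope_hist_{factor}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight"); plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(6, 4))
        n_col = {"altitude": "N_altitude", "ice_temp": "N_ice_temp", "race_freq": "N_race_freq"}[factor]
        ax.bar(np.arange(len(table)), table[n_col], edgecolor="k")
        for y in (20, 100):
            ax.axhline(y, color="gray", ls="--", lw=1)
            ax.axhline(-y, color="gray", ls="--", lw=1)
        ax.set_xlabel("sample")
        ax.set_ylabel("influence value N")
        ax.set_title(f"{factor} influence values (boundaries at 20 and 100)")
        p = out_dir / f"influence_{factor}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight"); plt.close(fig)
        written.append(p)

    if 3000 in set(table["distance"]):
        prof = distance_profile(table)
        fig, ax = plt.subplots(figsize=(6, 4))
        for factor, grp in prof.groupby("factor"):
            ax.errorbar(grp["distance"], grp["norm_mean"], yerr=grp["norm_sd"],
                        marker="o", capsize=3, label=factor)
        ax.set_xlabel("race distance (m)")
        ax.set_ylabel("normalized mean |N| (3,000 m = 1)")
        ax.legend()
        p = out_dir / "distance_profile.png"
        fig.savefig(p, dpi=120, bbox_inches="tight"); plt.close(fig)
        written.append(p)

    lines = ["# Run summary", "", "## Ensemble influence slopes", ""]
    for a in analyses:
        lines.append(f"- **{a.dataset.skater_id} {a.dataset.distance:g} m** (m*={a.m_star}): "
                     + ", ".join(f"K_{f}={a.sweeps[f].K:+.4f} {a.sweeps[f].units}" for f in FACTORS))
    lines += ["", "## Influence values", "", table.to_string(index=False)]
    p = out_dir / "summary.md"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# simulation harnesses
# ---------------------------------------------------------------------------

def recover_slopes(
    truth: SyntheticTruth,
    config: PipelineConfig,
) -> dict[str, float]:
    """Generate one synthetic dataset and return its ensemble slopes K."""
    records = generate_dataset(truth)
    datasets = build_datasets(records, min_records=config.min_records)
    if len(datasets) != 1:
        raise DataError("expected exactly one synthetic sample dataset")
    analysis = analyze_dataset(datasets[0], config)
    return analysis.slopes


def parameter_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Replicate-level recovery of the generator's true slopes.

    Each replicate draws a fresh synthetic dataset (seeded from ``seed``)
    and runs the scaled-down pipeline (200 trained, b = 50, fixed m = 10);
    returns one row per replicate x factor with the estimated K, the true
    slope, the sign agreement and the relative error.
    """
    base = truth or SyntheticTruth()
    cfg = config or PipelineConfig.test_profile(hidden_nodes=10)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % (2**31))
        t = dataclasses.replace(base, seed=rep_seed)
        c = dataclasses.replace(cfg, master_seed=rep_seed)
        slopes = recover_slopes(t, c)
        truths = true_slopes(t)
        for factor in FACTORS:
            k, b_true = slopes[factor], truths[factor]
            rows.append({
                "replicate": rep, "factor": factor, "K": k, "beta": b_true,
                "sign_correct": bool(np.sign(k) == np.sign(b_true)) if b_true != 0 else bool(abs(k) < 1e-6),
                "rel_error": abs(k - b_true) / abs(b_true) if b_true != 0 else np.nan,
            })
    return pd.DataFrame(rows)


def drift_study(
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Null-effect check: drift-only data should yield slopes near zero.

    All betas are zero and seasons improve by 2% each; after relative-time
    normalization the pipeline should see pure noise. Returns per-season
    relative-time means, the three ensemble slopes K, the per-model slope
    SDs, and the analytic noise-only OLS slope standard error per factor
    (noise_sd / (sd(x) * sqrt(n)), altitude in km) — the sampling scale
    against which "indistinguishable from zero" is judged.
    """
    truth = SyntheticTruth(beta_altitude=0.0, beta_ice_temp=0.0,
                           beta_race_freq=0.0, season_drift=0.98, seed=seed)
    cfg = config or PipelineConfig.test_profile(hidden_nodes=10, master_seed=seed)
    records = generate_dataset(truth)
    datasets = build_datasets(records, min_records=cfg.min_records)
    ds = datasets[0]
    season_means = ds.records.groupby("season_label")["t_rel"].mean()
    analysis = analyze_dataset(ds, cfg)
    n = len(ds.records)
    covariates = {
        "altitude": ds.records["altitude"].to_numpy() / 1000.0,
        "ice_temp": ds.records["ice_temp"].to_numpy(),
        "race_freq": ds.records["race_index"].to_numpy(),
    }
    noise_se = {f: truth.noise_sd / (np.std(x) * np.sqrt(n)) for f, x in covariates.items()}
    return {
        "season_t_rel_means": season_means.to_dict(),
        "K": analysis.slopes,
        "slope_sd": {f: analysis.sweeps[f].slope_sd for f in FACTORS},
        "noise_slope_se": noise_se,
        "truth": truth,
    }
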