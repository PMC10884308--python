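"""Train a population of networks, filter by the e/E rule, keep the top-b.

Single small networks on small race datasets are noisy, so the method
trains many (default 1,000) models on fresh random splits, removes those
whose training error exceeds their test error (e > E — members that got a
lucky hard split rather than a good fit), sorts survivors by
delta = E + e ascending, and retains the best b (default 200) for
aggregation of their sensitivity slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, NumericalError
from .network import Hyperparams, TrainedModel, train_model_batch
from .preprocess import NormalizationSpec, SkaterDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleSpec:
    """Population size and retention count for ensemble aggregation."""

    n_iterations: int = 1000
    b: int = 200
    batch_size: int = 250  # trainer batch granularity; no effect on results

    def __post_init__(self):
        if self.n_iterations < 1:
            raise DataError("n_iterations must be >= 1")
        if not (1 <= self.b <= self.n_iterations):
            raise DataError("need 1 <= b <= n_iterations")


@dataclass
class EnsembleResult:
    """Retained models sorted by ascending delta, plus bookkeeping counts."""

    retained: list[TrainedModel]
    n_trained: int
    n_filtered_out: int

    @property
    def deltas(self) -> np.ndarray:
        return np.array([m.delta for m in self.retained])


def train_population(
    dataset: SkaterDataset,
    m: int,
    spec: EnsembleSpec,
    master_seed: int,
    hyperparams: Hyperparams = Hyperparams(),
    norm: NormalizationSpec | None = None,
) -> list[TrainedModel]:
    """Train ``spec.n_iterations`` models with counter-derived seeds.

    Model i draws its split and initial weights from
    SeedSequence((master_seed, i)); a rerun with the same master seed is
    bit-identical and the result does not depend on batch boundaries.
    Individual training failures are skipped; more than 10% failures abort.
    """
    norm = norm or dataset.normalization_spec()
    models: list[TrainedModel] = []
    failures = 0
    for start in range(0, spec.n_iterations, spec.batch_size):
        seeds = list(range(start, min(start + spec.batch_size, spec.n_iterations)))
        try:
            batch = train_model_batch(dataset, m, seeds, hyperparams, norm,
                                      entropy_key=(master_seed,))
        except NumericalError:
            # retry one-by-one so a single diverging member doesn't sink the batch
            batch = []
            for s in seeds:
                try:
                    batch.extend(train_model_batch(dataset, m, [s], hyperparams, norm,
                                                   entropy_key=(master_seed,)))
                except NumericalError as exc:
                    failures += 1
                    log.warning("training iteration %d failed: %s", s, exc)
        models.extend(batch)
    if failures > 0.1 * spec.n_iterations:
        raise NumericalError(f"{failures}/{spec.n_iterations} training iterations failed")
    return models


def filter_and_rank(models: list[TrainedModel], spec: EnsembleSpec) -> EnsembleResult:
    """Drop models with e > E, sort by ascending delta, keep the first b.

    Ties in delta break by seed so the ordering is canonical. Models with
    e = E are kept. If fewer than b models survive the filter, all
    survivors are retained with a warning; zero survivors is an error.
    """
    if not models:
        raise DataError("filter_and_rank needs a non-empty model collection")
    survivors = [m for m in models if m.e <= m.E]
    if not survivors:
        raise DataError("no models survived the e <= E filter; train a larger population")
    survivors.sort(key=lambda m: (m.delta, m.seed))
    if len(survivors) < spec.b:
        log.warning("only %d survivors for b=%d; retaining all", len(survivors), spec.b)
    retained = survivors[: spec.b]
    return EnsembleResult(
        retained=retained,
        n_trained=len(models),
        n_filtered_out=len(models) - len(survivors),
    )


def build_ensemble(
    dataset: SkaterDataset,
    m: int,
    spec: EnsembleSpec,
    master_seed: int,
    hyperparams: Hyperparams = Hyperparams(),
    norm: NormalizationSpec | None = None,
) -> EnsembleResult:
    """Convenience: train the population then filter and rank."""
    models = train_population(dataset, m, spec, master_seed, hyperparams, norm)
    return filter_and_rank(models, spec)


def ensemble_manifest(result: EnsembleResult) -> list[dict]:
    """JSON-serializable per-model records (e, E, delta, seed)."""
    return [
        {"seed": m.seed, "e": m.e, "E": m.E, "delta": m.delta}
        for m in result.retained
    ]
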