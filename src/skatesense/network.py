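"""Single-hidden-layer back-propagation networks for relative race time.

The regressor is a 3-m-1 feed-forward network: inputs (altitude, ice
temperature, race index) min-max scaled to [0, 1], logistic sigmoid on both
the hidden and output layer, mean-squared-error loss, trained by full-batch
gradient descent with momentum. Model quality is scored with the mean
absolute percentage error (MAPE) on the de-normalized relative time: ``e``
on the training split, ``E`` on the held-out split, and the selection
statistic ``delta = E + e`` (lower is better).

Because ensemble aggregation needs hundreds of independently trained
members, the trainer is vectorized over a *batch* of models: every member
has its own train/test split and its own initial weights, but one gradient
loop updates them all. Results are identical for any batch composition up
to floating-point reduction order; reruns with the same seeds are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, NumericalError
from .preprocess import NormalizationSpec, SkaterDataset

log = logging.getLogger(__name__)

INPUT_COLUMNS = ("altitude", "ice_temp", "race_index")


# ---------------------------------------------------------------------------
# selection statistics
# ---------------------------------------------------------------------------

def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent.

    MAPE = (1/k) * sum |A_t - F_t| / |A_t| * 100.
    """
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if a.size == 0 or a.shape != f.shape:
        raise DataError("mape needs two equal-length, non-empty sequences")
    if np.any(a == 0):
        raise DataError("mape undefined when an actual value is zero")
    return float(np.mean(np.abs(a - f) / np.abs(a)) * 100.0)


def hidden_node_candidates(n_inputs: int, n_outputs: int) -> list[int]:
    """Candidate hidden-node counts: round(sqrt(n + l)) + alpha, alpha = 1..10.

    With 3 inputs and 1 output this yields 3 through 12.
    """
    if n_inputs < 1 or n_outputs < 1:
        raise DataError("layer sizes must be positive")
    base = int(round(float(np.sqrt(n_inputs + n_outputs))))
    return sorted({base + alpha for alpha in range(1, 11)})


# ---------------------------------------------------------------------------
# hyperparameters and model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparams:
    """Gradient-descent settings.

    learning_rate / momentum drive classic heavy-ball full-batch updates;
    training stops at ``max_epochs`` or once the training MSE improves by
    less than ``plateau_tol`` over ``plateau_window`` epochs. Weights start
    uniform in ±``init_scale``. ``test_fraction`` of rows is held out per
    model (fresh split per training, which is what makes ensemble members
    diverse).
    """

    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 5000
    plateau_tol: float = 1e-10
    plateau_window: int = 50
    init_scale: float = 0.5
    test_fraction: float = 0.2


@dataclass
class NetworkModel:
    """Weights of one 3-m-1 sigmoid network operating on [0,1]-scaled data."""

    w1: np.ndarray  # (n_in, m)
    b1: np.ndarray  # (m,)
    w2: np.ndarray  # (m, 1)
    b2: np.ndarray  # (1,)

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]

    def predict_scaled(self, x: np.ndarray) -> np.ndarray:
        """Forward pass; ``x`` is (k, n_in) in [0, 1], returns (k,) in (0, 1)."""
        h = _sigmoid(x @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)[:, 0]

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("w1", "b1", "w2", "b2")}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(**{k: np.asarray(d[k], dtype=float) for k in ("w1", "b1", "w2", "b2")})


@dataclass
class TrainedModel:
    """One fitted network plus its selection statistics.

    ``e``/``E`` are train/test MAPE in percent on de-normalized relative
    times; ``delta = E + e`` exactly.
    """

    network: NetworkModel
    e: float
    E: float
    seed: int
    split_id: int
    train_idx: np.ndarray = field(repr=False, default=None)
    test_idx: np.ndarray = field(repr=False, default=None)

    @property
    def delta(self) -> float:
        return self.E + self.e


# ---------------------------------------------------------------------------
# batched trainer
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def make_split(n_rows: int, test_fraction: float, rng: np.random.Generator):
    """Random train/test partition; both sides guaranteed non-empty."""
    if n_rows < 2:
        raise DataError("need at least 2 rows to split into train and test")
    n_test = int(round(n_rows * test_fraction))
    n_test = min(max(n_test, 1), n_rows - 1)
    perm = rng.permutation(n_rows)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _init_weights(rng: np.random.Generator, n_in: int, m: int, scale: float):
    w1 = rng.uniform(-scale, scale, size=(n_in, m))
    b1 = rng.uniform(-scale, scale, size=m)
    w2 = rng.uniform(-scale, scale, size=(m, 1))
    b2 = rng.uniform(-scale, scale, size=1)
    return w1, b1, w2, b2


def _train_weight_batch(x, y, w1, b1, w2, b2, hp: Hyperparams, record_loss: bool = False):
    """Train a batch of B independent networks by full-batch GD + momentum.

    x: (B, k, n_in), y: (B, k, 1); weight arrays carry a leading batch axis.
    Models whose training MSE plateaus are frozen in place. Returns the
    trained weights and, optionally, the per-epoch loss history (B, epochs).
    """
    B, k, _ = x.shape
    lr, mu = hp.learning_rate, hp.momentum
    vw1 = np.zeros_like(w1); vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2); vb2 = np.zeros_like(b2)
    active = np.ones(B, dtype=bool)
    win = hp.plateau_window
    ring = np.full((win, B), np.inf)
    history = [] if record_loss else None
    xt = np.swapaxes(x, 1, 2)  # (B, n_in, k)

    for epoch in range(hp.max_epochs):
        h = _sigmoid(x @ w1 + b1[:, None, :])          # (B, k, m)
        out = _sigmoid(h @ w2 + b2[:, None, :])        # (B, k, 1)
        err = out - y
        loss = np.mean(err * err, axis=(1, 2))         # (B,)
        if record_loss:
            history.append(loss.copy())
        if not np.all(np.isfinite(loss[active])):
            bad = active & ~np.isfinite(loss)
            raise NumericalError(f"non-finite training loss at epoch {epoch} for {int(bad.sum())} model(s)")
        # plateau check against the loss `win` epochs ago
        slot = epoch % win
        if epoch >= win:
            stalled = (ring[slot] - loss) < hp.plateau_tol
            active &= ~stalled
            if not active.any():
                ring[slot] = loss
                break
        ring[slot] = loss

        d2 = (2.0 / k) * err * out * (1.0 - out)       # (B, k, 1)
        gw2 = np.swapaxes(h, 1, 2) @ d2                # (B, m, 1)
        gb2 = d2.sum(axis=1)                           # (B, 1)
        d1 = (d2 @ np.swapaxes(w2, 1, 2)) * h * (1.0 - h)
        gw1 = xt @ d1                                  # (B, n_in, m)
        gb1 = d1.sum(axis=1)                           # (B, m)

        am = active[:, None, None]
        vw1 = mu * vw1 - lr * gw1; w1 = w1 + vw1 * am
        vb1 = mu * vb1[:, :] - lr * gb1; b1 = b1 + vb1 * active[:, None]
        vw2 = mu * vw2 - lr * gw2; w2 = w2 + vw2 * am
        vb2 = mu * vb2 - lr * gb2; b2 = b2 + vb2 * active[:, None]

    if record_loss:
        return (w1, b1, w2, b2), np.array(history).T
    return (w1, b1, w2, b2), None


def _dataset_arrays(dataset: SkaterDataset, spec: NormalizationSpec):
    """Scaled input matrix (a, 3), scaled target (a,), raw t_rel (a,)."""
    recs = dataset.records
    x = np.column_stack([spec.scale(c, recs[c].to_numpy(dtype=float)) for c in INPUT_COLUMNS])
    t_rel = recs["t_rel"].to_numpy(dtype=float)
    y = spec.scale("t_rel", t_rel)
    return x, y, t_rel


def train_model_batch(
    dataset: SkaterDataset,
    m: int,
    seeds: list[int] | np.ndarray,
    hyperparams: Hyperparams = Hyperparams(),
    spec: NormalizationSpec | None = None,
    entropy_key: tuple = (),
) -> list[TrainedModel]:
    """Train one network per seed, all with hidden width ``m``, in one batch.

    Each seed yields an independent split and weight initialization via
    ``SeedSequence((*entropy_key, seed))``, so results do not depend on how
    seeds are grouped into batches or on execution order.
    """
    if m < 1:
        raise DataError("hidden node count must be >= 1")
    spec = spec or dataset.normalization_spec()
    x_all, y_all, t_rel = _dataset_arrays(dataset, spec)
    n_rows = len(t_rel)
    seeds = [int(s) for s in seeds]
    B = len(seeds)
    if B == 0:
        raise DataError("no seeds supplied")

    splits = []
    w1 = np.empty((B, x_all.shape[1], m)); b1 = np.empty((B, m))
    w2 = np.empty((B, m, 1)); b2 = np.empty((B, 1))
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(np.random.SeedSequence((*entropy_key, s)))
        tr, te = make_split(n_rows, hyperparams.test_fraction, rng)
        splits.append((tr, te))
        w1[i], b1[i], w2[i], b2[i][:] = _init_weights(rng, x_all.shape[1], m, hyperparams.init_scale)

    xtr = np.stack([x_all[tr] for tr, _ in splits])
    ytr = np.stack([y_all[tr][:, None] for tr, _ in splits])
    (w1, b1, w2, b2), _ = _train_weight_batch(xtr, ytr, w1, b1, w2, b2, hyperparams)

    models = []
    for i, (s, (tr, te)) in enumerate(zip(seeds, splits)):
        net = NetworkModel(w1[i], b1[i], w2[i], b2[i])
        pred = spec.inverse("t_rel", net.predict_scaled(x_all))
        models.append(TrainedModel(
            network=net,
            e=mape(t_rel[tr], pred[tr]),
            E=mape(t_rel[te], pred[te]),
            seed=s, split_id=i, train_idx=tr, test_idx=te,
        ))
    return models


def train_network(
    dataset: SkaterDataset,
    m: int,
    seed: int,
    hyperparams: Hyperparams = Hyperparams(),
    spec: NormalizationSpec | None = None,
) -> TrainedModel:
    """Train a single 3-m-1 network; deterministic given (seed, hyperparams)."""
    return train_model_batch(dataset, m, [seed], hyperparams, spec)[0]


def training_loss_history(
    dataset: SkaterDataset,
    m: int,
    seed: int,
    hyperparams: Hyperparams = Hyperparams(),
) -> np.ndarray:
    """Per-epoch training MSE for one model (diagnostic; used in tests)."""
    spec = dataset.normalization_spec()
    x_all, y_all, _ = _dataset_arrays(dataset, spec)
    rng = np.random.default_rng(np.random.SeedSequence((seed,)))
    tr, _te = make_split(len(y_all), hyperparams.test_fraction, rng)
    w1, b1, w2, b2 = _init_weights(rng, x_all.shape[1], m, hyperparams.init_scale)
    _, hist = _train_weight_batch(
        x_all[None, tr], y_all[tr][None, :, None],
        w1[None], b1[None], w2[None], b2[None], hyperparams, record_loss=True,
    )
    return hist[0]


# ---------------------------------------------------------------------------
# hidden-node selection
# ---------------------------------------------------------------------------

def select_node_count(
    dataset: SkaterDataset,
    candidates: list[int] | None = None,
    repeats: int = 10,
    seed: int = 0,
    hyperparams: Hyperparams = Hyperparams(),
) -> tuple[int, dict[int, float]]:
    """Pick the hidden-node count with the smallest mean delta.

    Each candidate is trained ``repeats`` times on fresh random splits and
    scored by the mean of delta = E + e; ties break toward the smaller
    width. Candidates whose trainings all fail are excluded with a warning.
    """
    if candidates is None:
        candidates = hidden_node_candidates(len(INPUT_COLUMNS), 1)
    if not candidates:
        raise DataError("no hidden-node candidates supplied")
    spec = dataset.normalization_spec()
    mean_delta: dict[int, float] = {}
    for m in candidates:
        try:
            models = train_model_batch(
                dataset, m, list(range(repeats)), hyperparams, spec,
                entropy_key=(seed, m),
            )
        except NumericalError as exc:
            log.warning("candidate m=%d failed: %s", m, exc)
            continue
        mean_delta[m] = float(np.mean([mod.delta for mod in models]))
    if not mean_delta:
        raise NumericalError("every hidden-node candidate failed to train")
    best = min(sorted(mean_delta), key=lambda m: mean_delta[m])
    return best, mean_delta
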