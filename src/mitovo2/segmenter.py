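"""Start-point detection: a biLSTM per-sample labeler over mitoPO2 traces.

Each trace is z-scored (per trace), cut into overlapping 250-sample windows
at stride 10, and fed to a bidirectional LSTM whose per-sample softmax
assigns one of the three point classes (na / start / measurement).  At
inference the window probabilities are averaged where windows overlap before
the argmax, so a full trace of arbitrary length gets one label per sample.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``score`` / ``get_params``); a seeded configuration retrains to identical
weights and predictions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .io import LabelSeq, Trace, NA
from .nn import BiLSTMNetwork

__all__ = ["ModelConfig", "SEARCH_SPACE", "normalize", "make_windows",
           "WindowSet", "BiLstmSegmenter", "train", "predict", "tune",
           "save_checkpoint", "load_checkpoint"]

WINDOW = 250
STEP = 10

#: hyperparameter search box (the tuning contract); defaults in
#: :class:`ModelConfig` are the tuned operating point.
SEARCH_SPACE = {
    "hidden_units": (50, 80),
    "initial_learn_rate": (0.001, 1.0),
    "max_epochs": (2, 4),
    "mini_batch_size": (60, 100),
}


@dataclass(frozen=True)
class ModelConfig:
    hidden_units: int = 55
    initial_learn_rate: float = 0.0137
    max_epochs: int = 3
    mini_batch_size: int = 80
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_units < 1 or self.mini_batch_size < 1:
            raise ValueError("hidden_units and mini_batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (0 < self.initial_learn_rate <= 1):
            raise ValueError("initial_learn_rate must be in (0, 1]")

    def validate_in_search_box(self) -> None:
        self.validate()
        for name, (lo, hi) in SEARCH_SPACE.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside search range [{lo}, {hi}]")


def normalize(values: np.ndarray | Trace) -> np.ndarray:
    """Per-trace z-score: zero mean, unit (sample) standard deviation."""
    x = values.mitopo2 if isinstance(values, Trace) else np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant trace has zero variance; cannot z-score")
    return (x - x.mean()) / sd


@dataclass
class WindowSet:
    """Fixed-length windows with per-sample targets and provenance."""

    X: np.ndarray        # (n, WINDOW, 1) normalized values
    y: np.ndarray        # (n, WINDOW) integer classes
    weight: np.ndarray   # (n, WINDOW) 1.0 for real samples, 0.0 for padding
    offsets: np.ndarray  # (n,) window start offset within its trace
    trace_ids: list[str]

    def __len__(self) -> int:
        return self.X.shape[0]

    @staticmethod
    def concatenate(parts: Sequence["WindowSet"]) -> "WindowSet":
        return WindowSet(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            weight=np.concatenate([p.weight for p in parts]),
            offsets=np.concatenate([p.offsets for p in parts]),
            trace_ids=sum((p.trace_ids for p in parts), []),
        )


def window_offsets(n: int, window: int = WINDOW, step: int = STEP) -> list[int]:
    """All stride-``step`` offsets, plus a clamped tail window when the
    stride does not land on the last full window."""
    if n <= window:
        return [0]
    offs = list(range(0, n - window + 1, step))
    if offs[-1] != n - window:
        offs.append(n - window)
    return offs


def make_windows(trace: Trace | np.ndarray, labels: LabelSeq | None = None,
                 window: int = WINDOW, step: int = STEP,
                 normalized: np.ndarray | None = None) -> WindowSet:
    """Cut one trace into overlapping windows.

    Traces shorter than ``window`` produce a single window padded at the tail
    with the last value ('na' targets, zero loss weight).
    """
    if normalized is None:
        normalized = normalize(trace)
    n = normalized.size
    codes = labels.codes if labels is not None else np.zeros(n, dtype=np.int8)
    if labels is not None and len(labels) != n:
        raise ValueError("labels not aligned to trace")
    tid = trace.subject_id if isinstance(trace, Trace) else ""
    offs = window_offsets(n, window, step)
    X = np.empty((len(offs), window, 1))
    y = np.zeros((len(offs), window), dtype=np.int64)
    w = np.ones((len(offs), window))
    for k, o in enumerate(offs):
        chunk = normalized[o: o + window]
        if chunk.size < window:
            pad = window - chunk.size
            X[k, :, 0] = np.concatenate([chunk, np.full(pad, chunk[-1])])
            y[k, : chunk.size] = codes[o: o + window]
            y[k, chunk.size:] = NA
            w[k, chunk.size:] = 0.0
        else:
            X[k, :, 0] = chunk
            y[k] = codes[o: o + window]
    return WindowSet(X, y, w, np.asarray(offs), [tid] * len(offs))


def windows_from_cohort(traces: Sequence[Trace],
                        labels: Sequence[LabelSeq],
                        window: int = WINDOW, step: int = STEP) -> WindowSet:
    return WindowSet.concatenate(
        [make_windows(t, l, window, step) for t, l in zip(traces, labels)])


class BiLstmSegmenter(BaseEstimator):
    """Sequence-to-sequence point classifier for stop-flow traces.

    Parameters mirror the tuned training configuration: hidden units per
    LSTM direction, Adam learning rate, epochs and mini-batch size.  ``fit``
    takes a list of traces and aligned label sequences; ``predict`` labels
    whole traces of arbitrary length.
    """

    def __init__(self, hidden_units: int = 55, initial_learn_rate: float = 0.0137,
                 max_epochs: int = 3, mini_batch_size: int = 80, seed: int = 0,
                 window: int = WINDOW, step: int = STEP):
        self.hidden_units = hidden_units
        self.initial_learn_rate = initial_learn_rate
        self.max_epochs = max_epochs
        self.mini_batch_size = mini_batch_size
        self.seed = seed
        self.window = window
        self.step = step

    # ------------------------------------------------------------------ fit
    def fit(self, X: Sequence[Trace] | WindowSet,
            y: Sequence[LabelSeq] | None = None) -> "BiLstmSegmenter":
        """Train on traces + labels (or a prebuilt :class:`WindowSet`)."""
        config = ModelConfig(self.hidden_units, self.initial_learn_rate,
                             self.max_epochs, self.mini_batch_size, self.seed)
        config.validate()
        if isinstance(X, WindowSet):
            ws = X
        else:
            ws = windows_from_cohort(X, y, self.window, self.step)
        if len(ws) == 0:
            raise ValueError("empty window set")
        if not np.any(ws.y[ws.weight > 0] != NA):
            import warnings
            warnings.warn("all targets are 'na'; the classifier will be "
                          "degenerate", RuntimeWarning, stacklevel=2)
        rng = np.random.default_rng(self.seed)
        net = BiLSTMNetwork(self.hidden_units, n_classes=3, n_features=1,
                            seed=self.seed)
        self.loss_history_ = net.fit(
            ws.X, ws.y, ws.weight,
            learn_rate=self.initial_learn_rate, epochs=self.max_epochs,
            batch_size=self.mini_batch_size, rng=rng)
        self.net_ = net
        self.classes_ = np.array([0, 1, 2])
        self.n_features_in_ = 1
        return self

    # ------------------------------------------------------------- inference
    def predict_proba(self, trace: Trace | np.ndarray) -> np.ndarray:
        """Per-sample class probabilities (len(trace), 3); overlapping
        windows contribute the average of their softmax outputs."""
        self._check_fitted()
        values = trace.mitopo2 if isinstance(trace, Trace) else np.asarray(trace, float)
        norm = normalize(values)
        n = norm.size
        ws = make_windows(trace if isinstance(trace, Trace) else values,
                          None, self.window, self.step, normalized=norm)
        acc = np.zeros((n, 3))
        cover = np.zeros(n)
        chunk = 256  # bounded memory
        for lo in range(0, len(ws), chunk):
            probs = self.net_.predict_proba(ws.X[lo: lo + chunk])
            for k in range(probs.shape[0]):
                o = int(ws.offsets[lo + k])
                real = int(ws.weight[lo + k].sum())
                acc[o: o + real] += probs[k, :real]
                cover[o: o + real] += 1.0
        return acc / cover[:, None]

    def predict(self, X: Trace | np.ndarray | Sequence[Trace]):
        """Label one trace (returns a :class:`LabelSeq`) or a sequence of
        traces (returns a list)."""
        if isinstance(X, (Trace, np.ndarray)):
            return LabelSeq(np.argmax(self.predict_proba(X), axis=1))
        return [LabelSeq(np.argmax(self.predict_proba(t), axis=1)) for t in X]

    def score(self, X: Sequence[Trace], y: Sequence[LabelSeq]) -> float:
        """Mean per-sample classification accuracy over traces."""
        total = correct = 0
        for trace, lab in zip(X, y):
            pred = self.predict(trace)
            total += len(lab)
            correct += int(np.sum(pred.codes == lab.codes))
        return correct / total

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted; call fit() first")

    # ---------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self)

    @classmethod
    def load(cls, path: str | Path) -> "BiLstmSegmenter":
        return load_checkpoint(path)


def save_checkpoint(path: str | Path, model: BiLstmSegmenter) -> None:
    """Single-file checkpoint: configuration + weights (npz)."""
    model._check_fitted()
    cfg = {k: v for k, v in model.get_params().items()}
    weights = model.net_.get_weights()
    np.savez(path, _config=np.array([repr(cfg)]),
             **{f"w{i}": w for i, w in enumerate(weights)})


def load_checkpoint(path: str | Path) -> BiLstmSegmenter:
    import ast

    with np.load(path, allow_pickle=False) as data:
        cfg = ast.literal_eval(str(data["_config"][0]))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    model = BiLstmSegmenter(**cfg)
    net = BiLSTMNetwork(model.hidden_units, n_classes=3, n_features=1,
                        seed=model.seed)
    net.set_weights(weights)
    model.net_ = net
    model.classes_ = np.array([0, 1, 2])
    model.n_features_in_ = 1
    return model


# ----------------------------------------------------------------- wrappers
def train(windowset: WindowSet, config: ModelConfig) -> BiLstmSegmenter:
    """Train a segmenter on a prebuilt window set."""
    model = BiLstmSegmenter(config.hidden_units, config.initial_learn_rate,
                            config.max_epochs, config.mini_batch_size,
                            config.seed)
    return model.fit(windowset)


def predict(model: BiLstmSegmenter, trace: Trace) -> LabelSeq:
    return model.predict(trace)


def tune(cohort: Sequence[tuple[Trace, LabelSeq]], budget_trials: int,
         seed: int = 0, search_space: dict | None = None
         ) -> tuple[ModelConfig, list[dict]]:
    """Seeded random search over the hyperparameter box.

    Windows from the cohort are split 80/10/10 (train/validation/internal
    test); the objective is classification error on the validation split.
    Returns the best configuration and the per-trial records.
    """
    if budget_trials < 1:
        raise ValueError("budget_trials must be >= 1")
    space = dict(SEARCH_SPACE)
    if search_space:
        for k, (lo, hi) in search_space.items():
            slo, shi = SEARCH_SPACE[k]
            if lo < slo or hi > shi:
                raise ValueError(f"search range for {k} outside [{slo}, {shi}]")
            space[k] = (lo, hi)

    traces = [c[0] for c in cohort]
    labels = [c[1] for c in cohort]
    ws = windows_from_cohort(traces, labels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ws))
    n_train = int(0.8 * len(ws))
    n_val = int(0.1 * len(ws))
    idx_train = order[:n_train]
    idx_val = order[n_train: n_train + n_val]

    def subset(idx):
        return WindowSet(ws.X[idx], ws.y[idx], ws.weight[idx],
                         ws.offsets[idx], [ws.trace_ids[i] for i in idx])

    train_ws, val_ws = subset(idx_train), subset(idx_val)
    trials: list[dict] = []
    best: ModelConfig | None = None
    best_err = np.inf
    for k in range(budget_trials):
        cfg = ModelConfig(
            hidden_units=int(rng.integers(space["hidden_units"][0],
                                          space["hidden_units"][1] + 1)),
            initial_learn_rate=float(np.exp(rng.uniform(
                np.log(space["initial_learn_rate"][0]),
                np.log(space["initial_learn_rate"][1])))),
            max_epochs=int(rng.integers(space["max_epochs"][0],
                                        space["max_epochs"][1] + 1)),
            mini_batch_size=int(rng.integers(space["mini_batch_size"][0],
                                             space["mini_batch_size"][1] + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cfg.validate_in_search_box()
        model = train(train_ws, cfg)
        probs = [model.net_.predict_proba(val_ws.X[i: i + 1])[0]
                 for i in range(len(val_ws))]
        err_n = err_d = 0
        for i, pr in enumerate(probs):
            mask = val_ws.weight[i] > 0
            pred = pr.argmax(axis=1)
            err_n += int(np.sum(pred[mask] != val_ws.y[i][mask]))
            err_d += int(mask.sum())
        err = err_n / max(err_d, 1)
        trials.append({"config": asdict(cfg), "val_error": err})
        if err < best_err:
            best, best_err = cfg, err
    return best, trials
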