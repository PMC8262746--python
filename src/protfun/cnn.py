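"""Multi-kernel 1D-convolutional sequence classifier.

Architecture: a bank of parallel 1D convolutions over the one-hot encoded
sequence, one layer per kernel size (defaults 8, 16, …, 128; 512 filters
each).  Each filter is globally max-pooled — a single value saying whether
the filter fired anywhere along the sequence — the pooled vectors are
concatenated (16 × 512 = 8192 features at defaults) and fed to a single
fully connected layer with sigmoid units, one per vocabulary class, so the
output is a multi-label score matrix in (0, 1).

Training minimizes per-class binary cross-entropy with Adam, with an
early-stopping validation split.  Everything is plain NumPy: given the same
seed and data, initialization, training and prediction are bit-reproducible
on a single thread, and a saved checkpoint restores predictions exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ProtfunError
from .sequences import DEFAULT_ALPHABET, DEFAULT_MAX_LEN, EncodedBatch
from .ontology import AnnotationCorpus

logger = logging.getLogger(__name__)

DEFAULT_KERNEL_SIZES = tuple(range(8, 129, 8))  # 8, 16, ..., 128 (16 sizes)


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters.

    ``kernel_sizes`` must be strictly increasing and each ≤ ``max_len``.
    The loss, optimizer and early stopping are training-side choices; the
    architecture itself is fixed by kernel sizes, filter count and the
    vocabulary width.
    """

    vocabulary: list[str] = field(default_factory=list)
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    n_filters: int = 512
    max_len: int = DEFAULT_MAX_LEN
    alphabet: str = DEFAULT_ALPHABET
    conv_activation: str = "linear"  # "linear" or "relu"
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    valid_fraction: float = 0.1
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        if not self.vocabulary:
            raise ProtfunError("CNN vocabulary must be nonempty")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ProtfunError("CNN vocabulary contains duplicates")
        if list(self.kernel_sizes) != sorted(set(self.kernel_sizes)):
            raise ProtfunError("kernel sizes must be strictly increasing")
        if max(self.kernel_sizes) > self.max_len:
            raise ProtfunError(
                f"kernel size {max(self.kernel_sizes)} exceeds max_len "
                f"{self.max_len}")
        if self.conv_activation not in ("linear", "relu"):
            raise ProtfunError(
                f"unknown conv_activation {self.conv_activation!r}")

    @property
    def feature_dim(self) -> int:
        return len(self.kernel_sizes) * self.n_filters

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)


def label_matrix(corpus: AnnotationCorpus, proteins: list[str],
                 vocabulary: list[str]) -> np.ndarray:
    """{0,1} label matrix with rows = proteins, columns = vocabulary."""
    col = {c: j for j, c in enumerate(vocabulary)}
    y = np.zeros((len(proteins), len(vocabulary)), dtype=np.float64)
    for i, p in enumerate(proteins):
        for c in corpus.annotations.get(p, ()):
            j = col.get(c)
            if j is not None:
                y[i, j] = 1.0
    return y


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


class ProteinCNN:
    """The classifier: parameters + config + training history."""

    def __init__(self, config: CnnConfig):
        self.config = config
        self.history: dict[str, list[float]] = {"train_loss": [],
                                                "valid_loss": []}
        rng = np.random.default_rng(config.seed)
        a = len(config.alphabet)
        self.params: dict[str, np.ndarray] = {}
        for k in config.kernel_sizes:
            fan_in = k * a
            self.params[f"W{k}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, config.n_filters))
            self.params[f"b{k}"] = np.zeros(config.n_filters)
        self.params["V"] = rng.normal(
            0.0, np.sqrt(2.0 / config.feature_dim),
            size=(config.feature_dim, config.n_classes))
        self.params["c"] = np.zeros(config.n_classes)

    # -- forward / backward -------------------------------------------------

    def _check_batch(self, batch: EncodedBatch) -> None:
        if batch.alphabet != self.config.alphabet:
            raise ProtfunError("batch alphabet does not match the model's")
        if batch.max_len != self.config.max_len:
            raise ProtfunError(
                f"batch max_len {batch.max_len} does not match model "
                f"max_len {self.config.max_len}")

    def _forward(self, X: np.ndarray, keep_cache: bool):
        cfg = self.config
        n = X.shape[0]
        feats, caches = [], []
        for k in cfg.kernel_sizes:
            win = sliding_window_view(X, k, axis=1)      # (n, P, A, k)
            win = np.ascontiguousarray(
                win.transpose(0, 1, 3, 2)).reshape(n, -1, k * len(cfg.alphabet))
            conv = win @ self.params[f"W{k}"] + self.params[f"b{k}"]
            act = np.maximum(conv, 0.0) if cfg.conv_activation == "relu" \
                else conv
            arg = act.argmax(axis=1)                      # (n, F)
            pooled = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
            feats.append(pooled)
            caches.append((win, conv, arg) if keep_cache else None)
        feat = np.concatenate(feats, axis=1)
        logits = feat @ self.params["V"] + self.params["c"]
        probs = _sigmoid(logits)
        return probs, feat, caches

    def _gradients(self, X: np.ndarray, y: np.ndarray):
        cfg = self.config
        probs, feat, caches = self._forward(X, keep_cache=True)
        n = X.shape[0]
        dlogits = (probs - y) / (n * cfg.n_classes)
        grads = {
            "V": feat.T @ dlogits,
            "c": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.params["V"].T
        offset = 0
        for k, cache in zip(cfg.kernel_sizes, caches):
            win, conv, arg = cache
            dpool = dfeat[:, offset:offset + cfg.n_filters]
            offset += cfg.n_filters
            dact = np.zeros_like(conv)
            np.put_along_axis(dact, arg[:, None, :], dpool[:, None, :],
                              axis=1)
            if cfg.conv_activation == "relu":
                dact *= conv > 0
            n_pos = conv.shape[1]
            grads[f"W{k}"] = (win.reshape(n * n_pos, -1).T
                              @ dact.reshape(n * n_pos, cfg.n_filters))
            grads[f"b{k}"] = dact.sum(axis=(0, 1))
        return _bce(probs, y), grads

    # -- training -----------------------------------------------------------

    def fit(self, batch: EncodedBatch, labels: np.ndarray) -> "ProteinCNN":
        """Train with Adam + early stopping on a validation split.

        ``labels`` must be a propagated {0,1} matrix with rows aligned to
        the batch and columns aligned to the vocabulary.
        """
        cfg = self.config
        self._check_batch(batch)
        X = batch.matrix.astype(np.float64)
        if labels.shape != (X.shape[0], cfg.n_classes):
            raise ProtfunError(
                f"label matrix shape {labels.shape} does not match "
                f"(n_sequences={X.shape[0]}, n_classes={cfg.n_classes})")
        y = labels.astype(np.float64)

        rng = np.random.default_rng(cfg.seed + 1)
        perm = rng.permutation(X.shape[0])
        n_valid = int(round(X.shape[0] * cfg.valid_fraction))
        valid_idx, train_idx = perm[:n_valid], perm[n_valid:]
        if len(train_idx) == 0:
            raise ProtfunError("validation split leaves no training data")

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stale = 0

        for epoch in range(cfg.epochs):
            order = rng.permutation(train_idx)
            epoch_losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = self._gradients(X[idx], y[idx])
                epoch_losses.append(loss)
                step += 1
                for name, g in grads.items():
                    adam_m[name] = beta1 * adam_m[name] + (1 - beta1) * g
                    adam_v[name] = beta2 * adam_v[name] + (1 - beta2) * g * g
                    m_hat = adam_m[name] / (1 - beta1 ** step)
                    v_hat = adam_v[name] / (1 - beta2 ** step)
                    self.params[name] -= (cfg.learning_rate * m_hat
                                          / (np.sqrt(v_hat) + eps))
            train_loss = float(np.mean(epoch_losses))
            if len(valid_idx):
                vp, _, _ = self._forward(X[valid_idx], keep_cache=False)
                valid_loss = _bce(vp, y[valid_idx])
            else:
                valid_loss = train_loss
            self.history["train_loss"].append(train_loss)
            self.history["valid_loss"].append(valid_loss)
            logger.debug("epoch %d: train %.5f valid %.5f", epoch,
                         train_loss, valid_loss)
            if valid_loss < best_loss - 1e-9:
                best_loss = valid_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    logger.info("early stopping at epoch %d", epoch)
                    break
        self.params = best_params
        return self

    # -- inference ----------------------------------------------------------

    def predict(self, batch: EncodedBatch, chunk_size: int = 64) -> np.ndarray:
        """Scores in (0, 1), shape (n_sequences, n_classes), input order."""
        self._check_batch(batch)
        X = batch.matrix.astype(np.float64)
        out = np.empty((X.shape[0], self.config.n_classes))
        for start in range(0, X.shape[0], chunk_size):
            probs, _, _ = self._forward(X[start:start + chunk_size],
                                        keep_cache=False)
            out[start:start + chunk_size] = probs
        return np.clip(out, 1e-9, 1.0 - 1e-9)

    def predict_matrix(self, batch: EncodedBatch):
        """Predictions as a :class:`~protfun.ensemble.PredictionMatrix`."""
        from .ensemble import PredictionMatrix

        return PredictionMatrix.from_array(
            batch.identifiers, self.config.vocabulary, self.predict(batch))

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Checkpoint layout: weights.npz + config.yaml + vocabulary.txt."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        cfg = asdict(self.config)
        cfg.pop("vocabulary")
        cfg["kernel_sizes"] = list(self.config.kernel_sizes)
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        with open(directory / "vocabulary.txt", "w") as fh:
            fh.write("\n".join(self.config.vocabulary) + "\n")
        with open(directory / "history.json", "w") as fh:
            json.dump(self.history, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "ProteinCNN":
        directory = Path(directory)
        for fname in ("weights.npz", "config.yaml", "vocabulary.txt"):
            if not (directory / fname).exists():
                raise ProtfunError(
                    f"checkpoint is missing {fname} in {directory}")
        with open(directory / "config.yaml") as fh:
            cfg_dict = yaml.safe_load(fh)
        with open(directory / "vocabulary.txt") as fh:
            vocabulary = [line.strip() for line in fh if line.strip()]
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        config = CnnConfig(vocabulary=vocabulary, **cfg_dict)
        model = cls(config)
        with np.load(directory / "weights.npz") as npz:
            loaded = {k: npz[k] for k in npz.files}
        for name, value in model.params.items():
            if name not in loaded:
                raise ProtfunError(
                    f"checkpoint weights.npz is missing parameter {name}")
            if loaded[name].shape != value.shape:
                raise ProtfunError(
                    f"checkpoint parameter {name} has shape "
                    f"{loaded[name].shape}, config implies {value.shape}")
        model.params = loaded
        hist_path = directory / "history.json"
        if hist_path.exists():
            with open(hist_path) as fh:
                model.history = json.load(fh)
        return model
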