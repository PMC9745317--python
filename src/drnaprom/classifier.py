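"""Transformer promoter classifier with a scikit-learn estimator surface.

:class:`PromoterTransformer` is a binary classifier over fixed-length DNA
strings: a single-nucleotide tokenizer feeds a small transformer encoder
whose pooled representation drives a single-logit sigmoid head, trained
with binary cross-entropy and Adam. It follows the scikit-learn contract
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``), so it
composes with pipelines and model selection.

Determinism: bit-exact reproducibility is promised for single-threaded CPU
execution with a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import Vocabulary, encode_batch
from .metrics import MetricsReport, evaluate
from .nn import Adam, EncoderConfig, PRESETS, TransformerEncoder
from .io_formats import GenomeSequence, reverse_complement

log = logging.getLogger(__name__)


def sigmoid_probability(logit: float | np.ndarray) -> float | np.ndarray:
    """S(x) = 1 / (1 + e^(-x))."""
    return expit(logit)


def bce_loss(probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, probabilities clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 20
    early_stop_metric: str = "auroc"  # or "f1"
    patience: int = 4
    val_fraction: float = 0.1  # used when no validation set is supplied
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.early_stop_metric not in ("auroc", "f1"):
            raise ValueError("early_stop_metric must be 'auroc' or 'f1'")


class PromoterTransformer(BaseEstimator, ClassifierMixin):
    """Binary promoter classifier over fixed-length DNA sequences.

    Parameters mirror :class:`~drnaprom.nn.EncoderConfig` and
    :class:`TrainingConfig`; ``preset`` ("tiny" or "paper") fills the
    architecture fields unless they are given explicitly. ``max_len`` is
    inferred from the training sequences (L + 2 specials).

    Fitted attributes: ``encoder_`` (the numpy transformer), ``vocab_``,
    ``classes_``, ``history_`` (per-epoch loss and validation metrics),
    ``max_len_``.
    """

    def __init__(
        self,
        preset: str = "tiny",
        n_layers: int | None = None,
        n_heads: int | None = None,
        embed_dim: int | None = None,
        feedforward_dim: int | None = None,
        dropout: float = 0.1,
        pooling: str = "first_token",
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 20,
        early_stop_metric: str = "auroc",
        patience: int = 4,
        val_fraction: float = 0.1,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.preset = preset
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.embed_dim = embed_dim
        self.feedforward_dim = feedforward_dim
        self.dropout = dropout
        self.pooling = pooling
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_metric = early_stop_metric
        self.patience = patience
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _encoder_config(self, max_len: int) -> EncoderConfig:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        arch = dict(PRESETS[self.preset])
        for field in ("n_layers", "n_heads", "embed_dim", "feedforward_dim"):
            if getattr(self, field) is not None:
                arch[field] = getattr(self, field)
        return EncoderConfig(dropout=self.dropout, max_len=max_len,
                             pooling=self.pooling, **arch)

    def _coerce_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            mapping = {"non_promoter": 0, "promoter": 1}
            try:
                y = np.array([mapping[v] for v in y])
            except KeyError as err:
                raise ValueError(f"unknown string label {err.args[0]!r}") from None
        y = y.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary")
        return y

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: Sequence[str], y, X_val: Sequence[str] | None = None, y_val=None):
        """Train on sequences ``X`` with binary labels ``y``.

        If no validation set is supplied, a stratified ``val_fraction``
        slice of the training data is held out for early stopping.
        """
        X = list(X)
        y = self._coerce_labels(y)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        lengths = {len(s) for s in X}
        if len(lengths) != 1:
            raise ValueError("all training sequences must share one length")
        L = lengths.pop()
        self.max_len_ = L + 2
        self.vocab_ = Vocabulary()
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.seed)
        if X_val is None:
            idx = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            val_idx, train_idx = idx[:n_val], idx[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = y[val_idx]
            X_train = [X[i] for i in train_idx]
            y_train = y[train_idx]
        else:
            X_train, y_train = X, y
            X_val = list(X_val)
            y_val = self._coerce_labels(y_val)

        ids_tr, mask_tr = encode_batch(X_train, self.max_len_)
        ids_va, mask_va = encode_batch(X_val, self.max_len_)

        cfg = self._encoder_config(self.max_len_)
        enc = TransformerEncoder(cfg, self.vocab_.size, seed=self.seed)
        opt = Adam(enc.parameters(), lr=self.learning_rate)

        n = len(X_train)
        best_metric, best_state, best_epoch = -np.inf, None, -1
        history: list[dict] = []
        t0 = time.time()
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                b = order[start:start + self.batch_size]
                logits = enc.forward(ids_tr[b], mask_tr[b], train=True)
                probs = expit(logits)
                loss = bce_loss(probs, y_train[b])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: non-finite loss "
                        f"(lr={self.learning_rate}, batch={len(b)})"
                    )
                enc.zero_grad()
                enc.backward((probs - y_train[b]) / len(b))
                opt.step()
                epoch_loss += loss * len(b)
            epoch_loss /= n

            val_probs = _predict_encoder(enc, ids_va, mask_va, self.batch_size)
            report = evaluate(val_probs, y_val, self.threshold)
            metric = report.auroc if self.early_stop_metric == "auroc" else report.positive.f1
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss,
                 "val_auroc": report.auroc, "val_f1": report.positive.f1,
                 "val_loss": bce_loss(val_probs, y_val),
                 "elapsed_s": time.time() - t0}
            )
            log.info("epoch %d: loss %.4f, val %s %.4f", epoch, epoch_loss,
                     self.early_stop_metric, metric)
            if metric > best_metric:
                best_metric, best_epoch = metric, epoch
                best_state = {k: v.copy() for k, v in enc.state_dict().items()}
            elif epoch - best_epoch >= self.patience:
                break

        if best_state is not None:
            enc.load_state_dict(best_state)
        self.encoder_ = enc
        self.history_ = history
        self.best_epoch_ = best_epoch
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        ids, mask = encode_batch(list(X), self.max_len_)
        return _predict_logits(self.encoder_, ids, mask, self.batch_size)

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    # -- persistence -------------------------------------------------------
    def save(self, model_dir: str | Path) -> None:
        """Write vocabulary, configs, weights (npz) and training log."""
        check_is_fitted(self, "encoder_")
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        self.vocab_.to_json(model_dir / "vocab.json")
        with open(model_dir / "config.json", "w") as fh:
            json.dump(
                {"params": self.get_params(), "max_len": self.max_len_,
                 "encoder": asdict(self.encoder_.config)},
                fh, indent=2,
            )
        np.savez(model_dir / "weights.npz", **self.encoder_.state_dict())
        with open(model_dir / "training_log.json", "w") as fh:
            json.dump(self.history_, fh, indent=2)

    @classmethod
    def load(cls, model_dir: str | Path) -> "PromoterTransformer":
        model_dir = Path(model_dir)
        with open(model_dir / "config.json") as fh:
            meta = json.load(fh)
        est = cls(**meta["params"])
        est.vocab_ = Vocabulary.from_json(model_dir / "vocab.json")
        est.classes_ = np.array([0, 1])
        est.max_len_ = int(meta["max_len"])
        enc_cfg = EncoderConfig(**meta["encoder"])
        est.encoder_ = TransformerEncoder(enc_cfg, est.vocab_.size, seed=est.seed)
        with np.load(model_dir / "weights.npz") as npz:
            est.encoder_.load_state_dict({k: npz[k] for k in npz.files})
        log_path = model_dir / "training_log.json"
        est.history_ = json.loads(log_path.read_text()) if log_path.exists() else []
        est.best_epoch_ = est.history_[-1]["epoch"] if est.history_ else -1
        return est


def _predict_logits(enc: TransformerEncoder, ids: np.ndarray, mask: np.ndarray,
                    batch_size: int) -> np.ndarray:
    out = np.empty(ids.shape[0])
    for start in range(0, ids.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = enc.forward(ids[sl], mask[sl], train=False)
    return out


def _predict_encoder(enc, ids, mask, batch_size) -> np.ndarray:
    return expit(_predict_logits(enc, ids, mask, batch_size))


def train_classifier(
    train_table: pd.DataFrame,
    val_table: pd.DataFrame | None = None,
    estimator: PromoterTransformer | None = None,
    **params,
) -> PromoterTransformer:
    """Fit a classifier from dataset tables (columns ``sequence``, ``label``)."""
    est = estimator or PromoterTransformer(**params)
    kwargs = {}
    if val_table is not None:
        kwargs = {"X_val": val_table["sequence"].tolist(), "y_val": val_table["label"].to_numpy()}
    return est.fit(train_table["sequence"].tolist(), train_table["label"].to_numpy(), **kwargs)


def scan_region(
    model: PromoterTransformer,
    genome: GenomeSequence,
    window: int,
    stride: int = 1,
) -> pd.DataFrame:
    """Sliding-window promoter scores over both strands of a replicon.

    ``window`` must equal the training sequence length. Minus-strand
    windows are reverse complemented before scoring. Returns a table with
    columns replicon, start, end, strand, score (start 0-based, half-open),
    suitable for bedGraph export. Known caveat of regional scanning:
    AT-rich promoter-like background produces false positives, so scores
    rank candidate regions rather than assert promoters.
    """
    if window != model.max_len_ - 2:
        raise ValueError(
            f"window ({window}) must equal the training sequence length "
            f"({model.max_len_ - 2})"
        )
    if genome.length < window:
        raise ValueError("genome shorter than scan window")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = list(range(0, genome.length - window + 1, stride))
    rows = []
    for strand in ("+", "-"):
        seqs = []
        for s in starts:
            seq = genome.residues[s:s + window]
            seqs.append(reverse_complement(seq) if strand == "-" else seq)
        scores = model.predict_proba(seqs)[:, 1]
        for s, sc in zip(starts, scores):
            rows.append((genome.replicon_id, s, s + window, strand, float(sc)))
    return pd.DataFrame(rows, columns=["replicon", "start", "end", "strand", "score"])


def evaluate_table(model: PromoterTransformer, table: pd.DataFrame) -> MetricsReport:
    """Metric report of a fitted model on a dataset table."""
    probs = model.predict_proba(table["sequence"].tolist())[:, 1]
    y = model._coerce_labels(table["label"].to_numpy())
    return evaluate(probs, y, model.threshold)
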