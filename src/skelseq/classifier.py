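"""Transformer-encoder sequence classifier over numeric token sequences.

The model embeds each token id, adds learned positional embeddings, runs a
stack of self-attention encoder layers, takes the final-layer embedding at
the [CLS] position, and maps it through dropout and a linear head to class
logits. Training follows the fine-tuning recipe: AdamW at learning rate
2e-5, batch size 16, up to 20 epochs, cross-entropy loss, best epoch
selected by validation macro-F1.

:class:`TransformerSequenceClassifier` is a scikit-learn estimator
(``fit`` / ``predict`` / ``predict_proba``) so it composes with sklearn
pipelines and model selection; :func:`split_dataset` provides the
70/15/15 stratified (or source-grouped) partition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupShuffleSplit
from sklearn.utils.validation import check_is_fitted

from skelseq.nn import AdamW, Dropout, Linear, Module, RngRef, TransformerEncoder, no_grad
from skelseq.nn.autograd import Tensor, cross_entropy_logits


@dataclass(frozen=True)
class ModelConfig:
    """Encoder architecture.

    The default is the standard base transformer-encoder configuration
    (12 layers, 768 hidden units, 12 attention heads, 3072 feed-forward);
    the ``tiny`` preset (2 layers, 64 hidden, 4 heads, 128 feed-forward)
    exists so the full pipeline runs at desk scale on one CPU.
    """

    layers: int = 12
    hidden: int = 768
    heads: int = 12
    ffn_dim: int = 3072
    dropout_head: float = 0.1
    dropout_encoder: float = 0.1
    n_classes: int = 12
    max_len: int = 512
    vocab_size: int = 30_004  # numeric ids 0..30000 plus [PAD]/[CLS]/[SEP]

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError(f"hidden ({self.hidden}) must be divisible by heads ({self.heads})")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        base = dict(layers=2, hidden=64, heads=4, ffn_dim=128)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the fine-tuning recipe)."""

    epochs: int = 20
    learning_rate: float = 2e-5
    batch_size: int = 16
    optimizer: str = "adamw"
    weight_decay: float = 0.01
    seed: int = 0
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    split_mode: str = "window_random"  # or "grouped_by_source"
    class_weighting: bool = False  # imbalance is handled by GAN augmentation instead

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {self.split} must sum to 1")
        if self.optimizer.lower() != "adamw":
            raise ValueError("only the AdamW optimizer is supported")
        if self.split_mode not in ("window_random", "grouped_by_source"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")


class _ClassifierNet(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, rng_ref: RngRef):
        super().__init__()
        self.encoder = TransformerEncoder(
            vocab_size=cfg.vocab_size,
            max_len=cfg.max_len,
            hidden=cfg.hidden,
            layers=cfg.layers,
            heads=cfg.heads,
            ffn_dim=cfg.ffn_dim,
            dropout=cfg.dropout_encoder,
            rng=rng,
            rng_ref=rng_ref,
        )
        self.head_drop = Dropout(cfg.dropout_head, rng_ref)
        self.head = Linear(cfg.hidden, cfg.n_classes, rng)

    def forward(self, ids: np.ndarray) -> Tensor:
        hidden = self.encoder(ids)  # (B, T, H)
        cls_vec = hidden[:, 0, :]  # [CLS] pooling
        return self.head(self.head_drop(cls_vec))


def build_model(
    config: ModelConfig, seed: int = 0, rng_ref: RngRef | None = None
) -> _ClassifierNet:
    """Construct an initialized (untrained) classifier network."""
    rng = np.random.default_rng(seed)
    return _ClassifierNet(config, rng, rng_ref or RngRef(seed + 1))


class TransformerSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping the transformer encoder classifier.

    Parameters
    ----------
    model_config, train_config : frozen dataclasses
        Architecture and optimization settings; see :class:`ModelConfig`
        and :class:`TrainConfig`.

    Attributes
    ----------
    classes_ : ndarray
        Class labels seen in ``fit`` (activity ids 1..12 normally).
    net_ : the trained network
    history_ : DataFrame
        Per-epoch train loss and validation metrics.

    Notes
    -----
    ``fit`` accepts optional ``X_val``/``y_val``; when given, the epoch
    with the best validation macro-F1 is restored at the end of training.
    Input ``X`` is an integer token-id matrix from
    :class:`~skelseq.tokenization.MinMaxTokenizer`.
    """

    def __init__(
        self,
        model_config: ModelConfig = ModelConfig(),
        train_config: TrainConfig = TrainConfig(),
    ):
        self.model_config = model_config
        self.train_config = train_config

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, X_val=None, y_val=None) -> "TransformerSequenceClassifier":
        X = _check_ids(X, self.model_config)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        cfg, tcfg = self.model_config, self.train_config

        uniq = np.unique(y)
        if uniq.min() >= 1 and uniq.max() <= cfg.n_classes:
            # canonical activity ids 1..n_classes -> head index id-1
            self.classes_ = np.arange(1, cfg.n_classes + 1)
        else:
            if len(uniq) > cfg.n_classes:
                raise ValueError(f"{len(uniq)} classes exceed n_classes={cfg.n_classes}")
            self.classes_ = uniq
        y_idx = self._to_index(y)
        yv_idx = self._to_index(np.asarray(y_val)) if y_val is not None else None
        if X_val is not None:
            X_val = _check_ids(X_val, cfg)

        self._rng_ref = RngRef(tcfg.seed + 1)
        self.net_ = build_model(cfg, seed=tcfg.seed, rng_ref=self._rng_ref)
        opt = AdamW(
            list(self.net_.named_parameters()),
            lr=tcfg.learning_rate,
            weight_decay=tcfg.weight_decay,
        )
        order_rng = np.random.default_rng(tcfg.seed + 2)

        class_weights = None
        if tcfg.class_weighting:
            counts = np.bincount(y_idx, minlength=len(self.classes_)).astype(np.float64)
            class_weights = np.where(counts > 0, counts.sum() / np.maximum(counts, 1), 0.0)
            class_weights /= class_weights.mean()

        history: list[dict] = []
        best_f1, best_state = -np.inf, None
        n = X.shape[0]
        for epoch in range(tcfg.epochs):
            self.net_.train()
            perm = order_rng.permutation(n)
            total_loss, total_rows = 0.0, 0
            for start in range(0, n, tcfg.batch_size):
                idx = perm[start : start + tcfg.batch_size]
                logits = self.net_(X[idx])
                if class_weights is None:
                    loss = cross_entropy_logits(logits, y_idx[idx])
                else:
                    w = class_weights[y_idx[idx]]
                    onehot = np.zeros((len(idx), len(self.classes_)), dtype=np.float32)
                    onehot[np.arange(len(idx)), y_idx[idx]] = w
                    from skelseq.nn.autograd import softmax_cross_entropy_probs

                    loss = softmax_cross_entropy_probs(logits, onehot)
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, step {start // tcfg.batch_size}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                total_loss += loss.item() * len(idx)
                total_rows += len(idx)
            row = {"epoch": epoch, "train_loss": total_loss / max(total_rows, 1)}
            if X_val is not None and len(X_val):
                val_pred = self._predict_indices(X_val)
                row["val_macro_f1"] = f1_score(
                    yv_idx, val_pred, average="macro", zero_division=0
                )
                if row["val_macro_f1"] >= best_f1 + 1e-12:
                    best_f1 = row["val_macro_f1"]
                    best_state = self.net_.state_dict()
            history.append(row)
        if best_state is not None:
            self.net_.load_state_dict(best_state)
        self.history_ = pd.DataFrame(history)
        self.net_.eval()
        return self

    def _to_index(self, y: np.ndarray) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes_)}
        try:
            return np.asarray([lookup[v] for v in y.tolist()], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]} not among fitted classes") from exc

    # ------------------------------------------------------------- predict
    def _logits(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        self.net_.eval()
        out = []
        with no_grad():
            for start in range(0, X.shape[0], batch_size):
                out.append(self.net_(X[start : start + batch_size]).data)
        return np.vstack(out) if out else np.empty((0, len(self.classes_)))

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self._logits(X), axis=1)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = _check_ids(X, self.model_config)
        logits = self._logits(X)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = _check_ids(X, self.model_config)
        # argmax takes the first (lowest class id) on exact ties
        return self.classes_[self._predict_indices(X)]

    # --------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "net_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.state_dict())
        meta = {
            "model_config": asdict(self.model_config),
            "train_config": asdict(self.train_config),
            "classes": self.classes_.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TransformerSequenceClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        mc = ModelConfig(**meta["model_config"])
        tc_kwargs = dict(meta["train_config"])
        tc_kwargs["split"] = tuple(tc_kwargs["split"])
        est = cls(model_config=mc, train_config=TrainConfig(**tc_kwargs))
        est.classes_ = np.asarray(meta["classes"])
        est._rng_ref = RngRef(est.train_config.seed + 1)
        est.net_ = build_model(mc, seed=est.train_config.seed, rng_ref=est._rng_ref)
        with np.load(path.with_suffix(".npz")) as state:
            est.net_.load_state_dict(dict(state))
        est.net_.eval()
        est.history_ = pd.DataFrame()
        return est


def _check_ids(X, cfg: ModelConfig) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError(f"token-id matrix must be 2-D, got shape {X.shape}")
    if X.shape[0] and X.shape[1] > cfg.max_len:
        raise ValueError(f"sequence length {X.shape[1]} exceeds max_len {cfg.max_len}")
    if X.shape[0] and (X.min() < 0 or X.max() >= cfg.vocab_size):
        raise ValueError("token ids outside the embedding table")
    return X.astype(np.int64)


def split_dataset(
    windows: pd.DataFrame | Sequence,
    cfg: TrainConfig = TrainConfig(),
):
    """Partition windows into (train, val, test) per the 70/15/15 protocol.

    ``window_random`` stratifies by class label; classes with fewer than
    3 windows are kept whole in the training split (with a warning).
    ``grouped_by_source`` assigns whole ``source_id`` groups to one
    partition so overlapping windows cannot leak across splits.
    Deterministic given ``cfg.seed``.
    """
    df = windows if isinstance(windows, pd.DataFrame) else None
    if df is not None:
        labels = df["label"].to_numpy()
        sources = df["source_id"].to_numpy() if "source_id" in df else np.zeros(len(df))
        take = lambda idx: df.iloc[np.sort(idx)].reset_index(drop=True)
    else:
        windows = list(windows)
        labels = np.asarray([w.label for w in windows])
        sources = np.asarray([w.source_id for w in windows])
        take = lambda idx: [windows[i] for i in np.sort(idx)]

    n = len(labels)
    f_train, f_val, f_test = cfg.split
    idx = np.arange(n)

    if cfg.split_mode == "grouped_by_source":
        gss = GroupShuffleSplit(n_splits=1, train_size=f_train, random_state=cfg.seed)
        tr, rest = next(gss.split(idx, groups=sources))
        rel = f_test / (f_val + f_test)
        gss2 = GroupShuffleSplit(n_splits=1, test_size=rel, random_state=cfg.seed + 1)
        va_rel, te_rel = next(gss2.split(rest, groups=sources[rest]))
        return take(tr), take(rest[va_rel]), take(rest[te_rel])

    counts = pd.Series(labels).value_counts()
    tiny_classes = set(counts[counts < 3].index)
    if tiny_classes:
        warnings.warn(
            f"classes {sorted(tiny_classes)} have < 3 windows; kept whole in train",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    targets = _largest_remainder(n, cfg.split)
    parts: list[list[int]] = [[], [], []]
    for c in sorted(tiny_classes, key=str):
        parts[0].extend(idx[labels == c].tolist())
    deficits = [max(0, targets[0] - len(parts[0])), targets[1], targets[2]]

    # per-class floors, then leftovers assigned by global largest remainder
    alloc: dict = {}
    leftovers: list[tuple[float, int, object, int]] = []
    regular = [c for c in counts.index if c not in tiny_classes]
    for c in sorted(regular, key=str):
        n_c = int(counts[c])
        raw = [n_c * f for f in cfg.split]
        floors = [int(np.floor(r)) for r in raw]
        alloc[c] = floors
        for s in range(3):
            leftovers.append((raw[s] - floors[s], s, c, n_c))
    spare = {c: int(counts[c]) - sum(alloc[c]) for c in regular}
    for s in range(3):
        deficits[s] = max(0, deficits[s] - sum(alloc[c][s] for c in regular))
    for _, s, c, _ in sorted(leftovers, key=lambda t: -t[0]):
        if spare[c] > 0 and deficits[s] > 0:
            alloc[c][s] += 1
            spare[c] -= 1
            deficits[s] -= 1
    for c in regular:  # anything left lands in train
        alloc[c][0] += spare[c]

    for c in sorted(regular, key=str):
        c_idx = idx[labels == c]
        rng.shuffle(c_idx)
        a, b = alloc[c][0], alloc[c][0] + alloc[c][1]
        parts[0].extend(c_idx[:a].tolist())
        parts[1].extend(c_idx[a:b].tolist())
        parts[2].extend(c_idx[b : b + alloc[c][2]].tolist())
    return tuple(take(np.asarray(p, dtype=int)) for p in parts)


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    out = [int(np.floor(r)) for r in raw]
    order = np.argsort([-(r - o) for r, o in zip(raw, out)])
    for i in range(n - sum(out)):
        out[order[i]] += 1
    return out


def train(
    model: TransformerSequenceClassifier,
    X_train,
    y_train,
    X_val=None,
    y_val=None,
    cfg: TrainConfig | None = None,
) -> TransformerSequenceClassifier:
    """Functional wrapper: train (a clone of) ``model`` per ``cfg``."""
    if cfg is not None:
        model = TransformerSequenceClassifier(model.model_config, cfg)
    return model.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def predict(model: TransformerSequenceClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: (class probabilities, predicted labels)."""
    proba = model.predict_proba(X)
    return proba, model.classes_[np.argmax(proba, axis=1)]
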