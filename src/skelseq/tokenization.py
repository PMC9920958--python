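"""Numeric tokenization: map continuous features to integer token ids.

The classifier consumes each 153-float window as if it were a sentence.
Every feature value ``F`` is mapped to an integer token id by global
min-max scaling over a single scalar range ``[F_min, F_max]`` shared by
all features::

    id = floor(V * (F - F_min) / (F_max - F_min)),   V = 30,000 by default

keeping only the integer part, so ids span ``0..V`` inclusive (F = F_max
maps to V). Values outside the fitted range — possible when the scaler is
fitted on the training split only — are clamped to the boundary first.

Special tokens live above the numeric range in a from-scratch embedding
table: ``[PAD] = V+1``, ``[CLS] = V+2``, ``[SEP] = V+3`` (total vocabulary
V+4). A window encodes to ``[CLS] + 153 numeric ids + [SEP]`` = 155 ids
with an all-ones attention mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from skelseq.windowing import FeatureWindow

DEFAULT_VOCAB_NUMERIC = 30_000


class DegenerateScaleError(ValueError):
    """Raised when the fitted data has F_max == F_min."""


@dataclass(frozen=True)
class ScalerParams:
    """Fitted global min-max parameters plus the numeric vocabulary size."""

    f_min: float
    f_max: float
    vocab_numeric: int = DEFAULT_VOCAB_NUMERIC
    fit_scope: str = "train"

    def __post_init__(self) -> None:
        if not self.f_max > self.f_min:
            raise DegenerateScaleError(f"f_max ({self.f_max}) must exceed f_min ({self.f_min})")
        if self.vocab_numeric < 2:
            raise ValueError("vocab_numeric must be >= 2")

    # special token ids sit just above the numeric range
    @property
    def pad_id(self) -> int:
        return self.vocab_numeric + 1

    @property
    def cls_id(self) -> int:
        return self.vocab_numeric + 2

    @property
    def sep_id(self) -> int:
        return self.vocab_numeric + 3

    @property
    def vocab_size(self) -> int:
        """Total embedding-table size: numeric ids 0..V plus 3 specials."""
        return self.vocab_numeric + 4

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        return cls(**json.loads(Path(path).read_text()))


class MinMaxTokenizer(BaseEstimator, TransformerMixin):
    """Global min-max feature-to-token-id mapper.

    Parameters
    ----------
    vocab_numeric : int, default 30,000
        ``V`` in the mapping; numeric ids span ``0..V`` inclusive.
    fit_scope : {"train", "all"}, default "train"
        Bookkeeping tag: "train" means the scaler was fitted on the
        training split only (no leakage); "all" replicates fitting on the
        entire dataset. The tag does not change `fit` itself — the caller
        chooses which rows to pass.
    add_special_tokens : bool, default True
        Frame each encoded window with ``[CLS]``/``[SEP]``.

    Attributes
    ----------
    f_min_, f_max_ : float
        Global scalar minimum / maximum over every cell seen in `fit`.
    params_ : ScalerParams
        Frozen parameter bundle (JSON-serializable).
    """

    def __init__(
        self,
        vocab_numeric: int = DEFAULT_VOCAB_NUMERIC,
        fit_scope: str = "train",
        add_special_tokens: bool = True,
    ):
        self.vocab_numeric = vocab_numeric
        self.fit_scope = fit_scope
        self.add_special_tokens = add_special_tokens

    def fit(self, X, y=None) -> "MinMaxTokenizer":
        if self.fit_scope not in ("train", "all"):
            raise ValueError(f"fit_scope must be 'train' or 'all', got {self.fit_scope!r}")
        X = _as_matrix(X)
        if X.size == 0:
            raise ValueError("cannot fit scaler on an empty table")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in scaler input")
        self.f_min_ = float(X.min())
        self.f_max_ = float(X.max())
        if self.f_max_ == self.f_min_:
            raise DegenerateScaleError(
                f"degenerate scale: all {X.size} values equal {self.f_min_}"
            )
        self.params_ = ScalerParams(
            f_min=self.f_min_,
            f_max=self.f_max_,
            vocab_numeric=self.vocab_numeric,
            fit_scope=self.fit_scope,
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Map a feature matrix to token-id sequences.

        Returns an ``(n_rows, n_features + 2)`` int array when special
        tokens are enabled, else ``(n_rows, n_features)``.
        """
        check_is_fitted(self, "params_")
        X = _as_matrix(X)
        ids = tokenize(X, self.params_)
        if not self.add_special_tokens:
            return ids
        n = ids.shape[0]
        cls_col = np.full((n, 1), self.params_.cls_id, dtype=np.int64)
        sep_col = np.full((n, 1), self.params_.sep_id, dtype=np.int64)
        return np.hstack([cls_col, ids, sep_col])


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    return X


def fit_scaler(
    windows: pd.DataFrame | np.ndarray | Iterable[FeatureWindow],
    scope: str = "train",
    vocab_numeric: int = DEFAULT_VOCAB_NUMERIC,
) -> ScalerParams:
    """Fit the global min-max scaler over every cell of a feature table."""
    if not isinstance(windows, (pd.DataFrame, np.ndarray)):
        windows = np.vstack([np.asarray(w.features) for w in windows])
    tok = MinMaxTokenizer(vocab_numeric=vocab_numeric, fit_scope=scope).fit(windows)
    return tok.params_


def tokenize(value, params: ScalerParams) -> np.ndarray | int:
    """Map feature value(s) to integer token id(s) in ``[0, V]``.

    Clamps to ``[f_min, f_max]`` first (out-of-range values arise when the
    scaler was fitted on the training split only), scales to ``[0, V]``,
    and keeps the integer part.
    """
    arr = np.asarray(value, dtype=np.float64)
    scalar = arr.ndim == 0
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite feature value in tokenize")
    clamped = np.clip(arr, params.f_min, params.f_max)
    # ratio computed first so F = f_max gives exactly 1.0 (and id V) in
    # floating point; V*(F-min)/(max-min) can land a hair below V
    ratio = (clamped - params.f_min) / (params.f_max - params.f_min)
    ids = np.clip(np.floor(params.vocab_numeric * ratio).astype(np.int64), 0, params.vocab_numeric)
    return int(ids) if scalar else ids


def encode_window(
    window: FeatureWindow | np.ndarray,
    params: ScalerParams,
    add_special_tokens: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode one window to ``(ids, attention_mask)``.

    With special tokens the sequence is ``[CLS] + numeric ids + [SEP]``
    (155 ids for 153 features); the attention mask is all ones since the
    length is fixed — no ``[PAD]`` is needed.
    """
    feats = window.features if isinstance(window, FeatureWindow) else np.asarray(window)
    try:
        numeric = tokenize(feats.ravel(), params)
    except ValueError as exc:
        bad = np.flatnonzero(~np.isfinite(feats.ravel()))
        raise ValueError(f"non-finite feature at index {bad[:5].tolist()}: {exc}") from exc
    if add_special_tokens:
        ids = np.concatenate([[params.cls_id], numeric, [params.sep_id]]).astype(np.int64)
    else:
        ids = numeric.astype(np.int64)
    if ids.size > 512:
        raise ValueError(f"token sequence length {ids.size} exceeds the 512-token limit")
    return ids, np.ones_like(ids)
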