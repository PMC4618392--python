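"""Sequence-vs-shape site discrimination with ridge regression and AUROC.

Two feature encodings of the same oriented site windows are compared:
a binary one-hot sequence encoding, and the four predicted shape features
min-max scaled to [0, 1] over the training set.  An L2-regularized linear
regression on 0/1 class labels is scored by the area under the ROC curve
of cross-validated predictions; AUROC is rank-based, so regressing rather
than classifying does not change the statistic.  0.5 indicates a random
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .shape import FEATURES, ShapeTable, predict_shape

_BASE_COLS = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(site_sequences) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode equal-length sequences (4 columns per position, ACGT).

    Sequences containing N are dropped; returns (matrix, kept_index).
    """
    seqs = [s.upper() for s in site_sequences]
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be equal length")
    kept = []
    rows = []
    for i, s in enumerate(seqs):
        if "N" in s:
            continue
        row = np.zeros(4 * L)
        for pos, b in enumerate(s):
            row[4 * pos + _BASE_COLS[b]] = 1.0
        rows.append(row)
        kept.append(i)
    if len(kept) < len(seqs):
        warnings.warn(f"{len(seqs) - len(kept)} sequence(s) with N dropped")
    if not rows:
        raise ValueError("all sequences contained N")
    return np.array(rows), np.array(kept)


def decode_sequence(matrix: np.ndarray) -> list[str]:
    """Inverse of encode_sequence (for round-trip checking)."""
    bases = "ACGT"
    out = []
    for row in np.asarray(matrix):
        blocks = row.reshape(-1, 4)
        out.append("".join(bases[int(np.argmax(b))] for b in blocks))
    return out


@dataclass
class ShapeScaler:
    """Per-feature min/max learned on a training set."""

    lo: dict[str, float]
    hi: dict[str, float]


def encode_shape(
    site_sequences, table: ShapeTable, scaler: ShapeScaler | None = None
) -> tuple[np.ndarray, np.ndarray, ShapeScaler]:
    """Concatenated per-position shape features, min-max scaled to [0, 1].

    Each of the four features is scaled with its own training-set extremes;
    when a fitted ``scaler`` is supplied (held-out data) its extremes are
    reused and values may fall outside [0, 1] — they are kept unclipped.
    Edge positions that are NaN for every sequence are dropped as columns;
    sequences with any remaining NaN (interior N) are dropped as rows.
    """
    seqs = [s.upper() for s in site_sequences]
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be equal length")
    per_feature = {f: [] for f in FEATURES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seqs:
            pred = predict_shape(s, table)
            for f in FEATURES:
                per_feature[f].append(pred[f])
    blocks = []
    fit_lo, fit_hi = {}, {}
    valid_rows = np.ones(len(seqs), dtype=bool)
    for f in FEATURES:
        mat = np.array(per_feature[f])
        # drop the always-NaN margin columns
        col_ok = ~np.isnan(mat).all(axis=0)
        mat = mat[:, col_ok]
        valid_rows &= ~np.isnan(mat).any(axis=1)
        blocks.append(mat)
    rows_idx = np.flatnonzero(valid_rows)
    if not len(rows_idx):
        raise ValueError("no sequence has complete shape predictions")
    scaled_blocks = []
    for f, mat in zip(FEATURES, blocks):
        mat = mat[valid_rows]
        if scaler is None:
            lo = float(np.min(mat))
            hi = float(np.max(mat))
        else:
            lo, hi = scaler.lo[f], scaler.hi[f]
        fit_lo[f], fit_hi[f] = lo, hi
        span = hi - lo
        if span == 0:
            warnings.warn(f"constant shape feature {f}: scaled to 0")
            scaled_blocks.append(np.zeros_like(mat))
        else:
            scaled_blocks.append((mat - lo) / span)
    X = np.hstack(scaled_blocks)
    out_scaler = scaler if scaler is not None else ShapeScaler(fit_lo, fit_hi)
    return X, rows_idx, out_scaler


def ridge_auroc(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 1.0,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """AUROC of L2-regularized linear regression on 0/1 labels.

    Predictions are pooled over a seeded k-fold split and ranked against
    the labels (ties count half).  Returns both the cross-validated and
    the in-sample AUROC.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D with one row per label")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 sites per class")
    n_folds = min(folds, len(y))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty(len(y))
    for train, test in kf.split(X):
        model = Ridge(alpha=lam)
        model.fit(X[train], y[train])
        preds[test] = model.predict(X[test])
    model_full = Ridge(alpha=lam).fit(X, y)
    return {
        "auroc_cv": float(roc_auc_score(y, preds)),
        "auroc_train": float(roc_auc_score(y, model_full.predict(X))),
    }


def auroc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank AUROC: concordant pair fraction with ties counted half."""
    return float(roc_auc_score(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)))
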