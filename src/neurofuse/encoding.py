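"""Ridge encoding models with contiguous cross-validation.

Electrode activity in each time bin is predicted from model feature vectors
with ridge regression.  Events are split contiguously (in movie order) into
5 folds of 80% train / 10% validation / 10% test; the layer and ridge
penalty are chosen on the validation block and the Pearson correlation
between predicted and actual activity is reported per split, averaged over
folds.

The selection granularity is configurable.  ``selection="electrode"``
(default) picks one (layer, lambda) per electrode per fold by maximizing the
across-bin mean validation correlation; ``selection="bin"`` picks per bin.
Electrode-level selection decouples the hyperparameter choice from any
single bin's validation noise, which keeps the downstream validation-CI bin
filter calibrated when validation blocks are small (see docs/methods.md).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_LAMBDA_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0)

SPLITS = ("train", "validation", "test")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def block(self, split: str) -> np.ndarray:
        return getattr(self, "validation" if split == "validation" else split)


@dataclass(frozen=True)
class FoldPlan:
    n_events: int
    folds: tuple[Fold, ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def contiguous_folds(n_events: int, n_folds: int = 5) -> FoldPlan:
    """Rotating contiguous 80/10/10 split plan.

    Fold ``f`` holds out the ``f``-th of ``n_folds`` contiguous blocks; the
    block's first half is validation, second half is test, and the remaining
    events (before and after the block) are training data.  Every event is
    held out exactly once across folds.
    """
    if n_events < 10 * n_folds:
        raise ValueError(
            f"need at least {10 * n_folds} events for {n_folds} folds, got {n_events}"
        )
    edges = np.linspace(0, n_events, n_folds + 1).round().astype(int)
    all_idx = np.arange(n_events)
    folds = []
    for f in range(n_folds):
        block = all_idx[edges[f] : edges[f + 1]]
        half = len(block) // 2
        val, test = block[:half], block[half:]
        train = np.concatenate([all_idx[: edges[f]], all_idx[edges[f + 1] :]])
        folds.append(Fold(train=train, validation=val, test=test))
    return FoldPlan(n_events=n_events, folds=tuple(folds))


# ---------------------------------------------------------------------------
# ridge and Pearson primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RidgeFit:
    weights: np.ndarray
    intercept: float
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeFit:
    """Closed-form ridge solve: argmin ||y - Xw||^2 + lam ||w||^2.

    ``X`` is assumed standardized per column with training statistics; ``y``
    is centered internally and its training mean becomes the intercept.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ym = float(y.mean())
    g = X.T @ X + lam * np.eye(X.shape[1])
    w = np.linalg.solve(g, X.T @ (y - ym))
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("ridge solve produced non-finite coefficients")
    return RidgeFit(weights=w, intercept=ym, lam=float(lam))


def pearson_score(pred: np.ndarray, actual: np.ndarray) -> float:
    """Pearson r between two vectors; NaN (missing) if either is constant."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 samples")
    p = pred - pred.mean()
    a = actual - actual.mean()
    denom = np.sqrt((p @ p) * (a @ a))
    if denom < _EPS:
        return float("nan")
    return float(np.clip((p @ a) / denom, -1.0, 1.0))


def _pearson_columns(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r for (n, t) arrays; constant columns give NaN."""
    p = pred - pred.mean(axis=0)
    a = actual - actual.mean(axis=0)
    pn = np.sqrt(np.einsum("it,it->t", p, p))
    an = np.sqrt(np.einsum("it,it->t", a, a))
    denom = pn * an
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("it,it->t", p, a) / denom
    r[denom < _EPS] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _standardize(X: np.ndarray, train_idx: np.ndarray):
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd = np.where(sd < _EPS, 1.0, sd)
    return mu, sd


# ---------------------------------------------------------------------------
# bank encoder: many targets (electrode x bin columns) at once
# ---------------------------------------------------------------------------

@dataclass
class BankResult:
    """Cross-validated scores and selections for a bank of targets.

    Targets are columns of the response matrix (for a full responses array,
    electrode-major flattening of (electrode, bin)).  ``chosen_layer`` and
    ``chosen_lambda`` are (n_folds, n_targets) index arrays; -1 marks a
    degenerate fold with no usable fit.
    """

    fold_scores: dict[str, np.ndarray]  # split -> (n_folds, n_targets)
    chosen_layer: np.ndarray
    chosen_lambda: np.ndarray
    lambda_grid: tuple[float, ...]
    n_layers: int

    def scores(self, split: str) -> np.ndarray:
        """Per-target score: mean over non-missing folds (NaN if none)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.fold_scores[split], axis=0)


def _fold_layer_scores(
    X_layers: Sequence[np.ndarray],
    Y: np.ndarray,
    fold: Fold,
    lambda_grid: Sequence[float],
    splits: Sequence[str],
) -> dict[str, np.ndarray]:
    """Scores per (layer, lambda, target) for one fold.

    Returns split -> array (n_layers, n_lambdas, n_targets).
    """
    L, K, T = len(X_layers), len(lambda_grid), Y.shape[1]
    out = {s: np.full((L, K, T), np.nan) for s in splits}
    tr, va, te = fold.train, fold.validation, fold.test
    ymu = Y[tr].mean(axis=0)
    Ytr_c = Y[tr] - ymu
    idx = {"train": tr, "validation": va, "test": te}
    for li, X in enumerate(X_layers):
        mu, sd = _standardize(X, tr)
        Xtr = (X[tr] - mu) / sd
        G = Xtr.T @ Xtr
        XtY = Xtr.T @ Ytr_c
        eye = np.eye(X.shape[1])
        for ki, lam in enumerate(lambda_grid):
            W = np.linalg.solve(G + lam * eye, XtY)
            for split in splits:
                rows = idx[split]
                Xs = Xtr if split == "train" else (X[rows] - mu) / sd
                out[split][li, ki] = _pearson_columns(Xs @ W, Y[rows])
    return out


def _select(
    val_r: np.ndarray,
    selection: str,
    groups: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick (layer, lambda) per target maximizing validation r.

    ``val_r`` is (L, K, T).  For ``selection="electrode"`` the criterion is
    the across-target nanmean within each group (one group per electrode).
    Returns per-target layer and lambda index arrays; -1 where nothing fits.
    """
    L, K, T = val_r.shape
    flat = val_r.reshape(L * K, T)
    li = np.full(T, -1, dtype=np.int64)
    ki = np.full(T, -1, dtype=np.int64)
    if selection == "bin":
        crit = np.where(np.isnan(flat), -np.inf, flat)
        best = crit.argmax(axis=0)
        ok = crit.max(axis=0) > -np.inf
        li[ok] = best[ok] // K
        ki[ok] = best[ok] % K
    elif selection == "electrode":
        for g in np.unique(groups):
            cols = np.flatnonzero(groups == g)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                crit = np.nanmean(flat[:, cols], axis=1)
            if np.all(np.isnan(crit)):
                continue
            best = int(np.nanargmax(crit))
            # within the group, targets whose own column is all-NaN stay -1
            usable = ~np.all(np.isnan(flat[:, cols]), axis=0)
            li[cols[usable]] = best // K
            ki[cols[usable]] = best % K
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return li, ki


def encode_bank(
    X_layers: Sequence[np.ndarray],
    Y: np.ndarray,
    plan: FoldPlan,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    selection: str = "electrode",
    groups: np.ndarray | None = None,
    splits: Sequence[str] = SPLITS,
) -> BankResult:
    """Cross-validated ridge encoding of many response columns at once.

    Parameters
    ----------
    X_layers
        One (n_events, dims) matrix per candidate layer.
    Y
        (n_events, n_targets) responses; a target is one (electrode, bin).
    groups
        (n_targets,) electrode index per target, required for
        electrode-level selection with more than one electrode.
    """
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be (n_events, n_targets)")
    for X in X_layers:
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"event axis mismatch: features have {X.shape[0]}, responses {Y.shape[0]}"
            )
    if groups is None:
        groups = np.zeros(Y.shape[1], dtype=np.int64)
    if any(lam < 0 for lam in lambda_grid):
        raise ValueError("lambda grid must be non-negative")
    F, T = plan.n_folds, Y.shape[1]
    fold_scores = {s: np.full((F, T), np.nan) for s in splits}
    chosen_layer = np.full((F, T), -1, dtype=np.int64)
    chosen_lambda = np.full((F, T), -1, dtype=np.int64)
    for f, fold in enumerate(plan.folds):
        per = _fold_layer_scores(X_layers, Y, fold, lambda_grid, splits)
        li, ki = _select(per["validation"], selection, groups)
        ok = li >= 0
        cols = np.flatnonzero(ok)
        chosen_layer[f] = li
        chosen_lambda[f] = ki
        for split in splits:
            fold_scores[split][f, cols] = per[split][li[cols], ki[cols], cols]
    return BankResult(
        fold_scores=fold_scores,
        chosen_layer=chosen_layer,
        chosen_lambda=chosen_lambda,
        lambda_grid=tuple(lambda_grid),
        n_layers=len(X_layers),
    )


# ---------------------------------------------------------------------------
# single-electrode convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Per-bin encoding scores for one electrode.

    ``chosen_layer`` / ``chosen_lambda`` record the selection per (fold, bin)
    as ids / values (None / NaN where the fold was degenerate).
    """

    bank: BankResult
    layer_ids: tuple[str, ...]

    def scores(self, split: str) -> np.ndarray:
        return self.bank.scores(split)

    @property
    def fold_scores(self) -> dict[str, np.ndarray]:
        return self.bank.fold_scores

    @property
    def chosen_layer(self) -> np.ndarray:
        out = np.empty(self.bank.chosen_layer.shape, dtype=object)
        for idx, li in np.ndenumerate(self.bank.chosen_layer):
            out[idx] = self.layer_ids[li] if li >= 0 else None
        return out

    @property
    def chosen_lambda(self) -> np.ndarray:
        grid = np.array(self.bank.lambda_grid)
        ki = self.bank.chosen_lambda
        out = np.where(ki >= 0, grid[np.clip(ki, 0, None)], np.nan)
        return out


def encode_electrode(
    features,
    responses: np.ndarray,
    plan: FoldPlan,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    selection: str = "electrode",
) -> RegressionResult:
    """Encode one electrode's (n_events, n_bins) responses from a FeatureSet."""
    X_layers = features.matrices()
    layer_ids = tuple(features.layer_ids)
    bank = encode_bank(
        X_layers,
        np.asarray(responses, dtype=float),
        plan,
        lambda_grid=lambda_grid,
        selection=selection,
    )
    return RegressionResult(bank=bank, layer_ids=layer_ids)
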