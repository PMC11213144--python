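"""Bootstrap inference over events and bins, bin filtering, and FDR.

Event-level bootstrap: image-text pairs are resampled with replacement
(independently inside each contiguous train/validation/test block, so split
membership is preserved) and the regression is re-run on every resample,
giving percentile confidence intervals on the per-bin correlation for every
split.  The same resampled indices are used for every model and electrode so
that models can be compared resample-by-resample.

Bin-level (second-order) bootstrap: to compare two models on one electrode,
time bins are resampled with replacement, paired across the two models, and
the difference in mean test-split score is the statistic.  Benjamini-
Hochberg FDR is applied across electrodes within each test family.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .encoding import (
    SPLITS,
    BankResult,
    FoldPlan,
    _pearson_columns,
    _standardize,
    encode_bank,
    DEFAULT_LAMBDA_GRID,
)

_BLOCKS = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# event resamples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Resamples:
    """Shared bootstrap event draws: ``draws[fold][block]`` is (B, block_size)
    of absolute event indices.  Identical for identical (plan, B, seed), and
    the first ``b`` resamples are a prefix of any larger-B draw with the same
    seed, so CI stability can be checked across B."""

    plan: FoldPlan
    B: int
    seed: int
    draws: tuple[dict, ...]


def draw_resamples(n_events: int, plan: FoldPlan, B: int, seed: int) -> Resamples:
    """Draw B within-block event resamples, deterministically from ``seed``.

    Each resample draws, independently for every fold's train, validation
    and test block, that block's size of indices with replacement from the
    block.  Resamples are drawn resample-major so that the draw for resample
    ``b`` does not depend on B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if n_events != plan.n_events:
        raise ValueError(f"plan covers {plan.n_events} events, got n_events={n_events}")
    rng = np.random.default_rng(seed)
    per_fold: list[dict[str, list[np.ndarray]]] = [
        {blk: [] for blk in _BLOCKS} for _ in plan.folds
    ]
    for _ in range(B):
        for f, fold in enumerate(plan.folds):
            for blk in _BLOCKS:
                block = fold.block(blk)
                per_fold[f][blk].append(block[rng.integers(0, len(block), len(block))])
    draws = tuple(
        {blk: np.stack(per_fold[f][blk]) for blk in _BLOCKS}
        for f in range(plan.n_folds)
    )
    return Resamples(plan=plan, B=B, seed=seed, draws=draws)


# ---------------------------------------------------------------------------
# percentile confidence intervals
# ---------------------------------------------------------------------------

def percentile_ci(samples: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation.

    Missing (NaN) samples are ignored; fewer than 2 non-missing samples give
    a missing interval.
    """
    samples = np.asarray(samples, dtype=float)
    valid = samples[np.isfinite(samples)]
    if valid.size < 2:
        return (float("nan"), float("nan"))
    lo = (100.0 - level) / 2.0
    low, high = np.percentile(valid, [lo, 100.0 - lo], method="linear")
    return (float(low), float(high))


def _ci_rows(samples: np.ndarray, level: float, min_valid_frac: float) -> np.ndarray:
    """Row-wise percentile CI for a (T, B) array -> (T, 2); rows with fewer
    than ``min_valid_frac * B`` non-missing samples are missing."""
    T, B = samples.shape
    out = np.full((T, 2), np.nan)
    n_valid = np.isfinite(samples).sum(axis=1)
    ok = n_valid >= max(2, int(np.ceil(min_valid_frac * B)))
    lo = (100.0 - level) / 2.0
    for t in np.flatnonzero(ok):
        row = samples[t]
        out[t] = np.percentile(row[np.isfinite(row)], [lo, 100.0 - lo], method="linear")
    return out


# ---------------------------------------------------------------------------
# bootstrap encoding
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Resampled per-target scores and percentile CIs.

    ``scores[split]`` is (n_targets, B); ``ci[split]`` is (n_targets, 2).
    Targets follow the column layout of the response matrix handed to
    :func:`bootstrap_encode` (electrode-major (electrode, bin) for a full
    response bank).
    """

    scores: dict[str, np.ndarray]
    ci: dict[str, np.ndarray]
    B: int
    seed: int
    level: float = 95.0
    min_valid_frac: float = 0.8

    def mean(self, split: str) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.scores[split], axis=1)


def _batch_pearson(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Pearson r along axis 1 of (B, n, T) arrays -> (B, T); NaN if constant."""
    p = pred - pred.mean(axis=1, keepdims=True)
    a = actual - actual.mean(axis=1, keepdims=True)
    num = np.einsum("bnt,bnt->bt", p, a)
    den = np.sqrt(
        np.einsum("bnt,bnt->bt", p, p) * np.einsum("bnt,bnt->bt", a, a)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den < 1e-8] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _group_chunks(groups: np.ndarray, max_targets: int):
    """Column-index chunks covering whole groups (greedy packing)."""
    uniq = np.unique(groups)
    chunk: list[np.ndarray] = []
    size = 0
    for g in uniq:
        cols = np.flatnonzero(groups == g)
        if chunk and size + len(cols) > max_targets:
            yield np.concatenate(chunk)
            chunk, size = [], 0
        chunk.append(cols)
        size += len(cols)
    if chunk:
        yield np.concatenate(chunk)


def _refit_fold_scores(
    X_layers: list[np.ndarray],
    Y: np.ndarray,
    draws: dict,
    lambda_grid: Sequence[float],
    selection: str,
    groups: np.ndarray,
    splits: Sequence[str],
    dtype,
    max_chunk_floats: float = 5e7,
) -> dict[str, np.ndarray]:
    """One fold's bootstrap scores with per-resample refit + re-selection.

    Vectorized over resamples: for every target chunk the ridge systems of
    all B resamples are assembled and solved in one batched call per
    (layer, lambda).  Returns split -> (B, T).
    """
    L, K = len(X_layers), len(lambda_grid)
    B, n_tr = draws["train"].shape
    T = Y.shape[1]
    out = {s: np.full((B, T), np.nan, dtype=dtype) for s in splits}
    score_rows = {"train": draws["train"], "validation": draws["validation"],
                  "test": draws["test"]}
    # standardized designs per layer, shared across target chunks; the Gram
    # matrix is eigendecomposed once so every lambda is a diagonal rescale
    designs = []
    for X in X_layers:
        Xtr = X[draws["train"]]  # (B, n_tr, d)
        mu = Xtr.mean(axis=1, keepdims=True)
        sd = Xtr.std(axis=1, keepdims=True)
        sd[sd < _CHUNK_EPS] = 1.0
        Xs = (Xtr - mu) / sd
        G = Xs.transpose(0, 2, 1) @ Xs
        evals, V = np.linalg.eigh(G)  # (B, d), (B, d, d)
        evals = np.maximum(evals, 0.0)
        bases = {}
        for s in splits:
            Xo = Xs if s == "train" else (X[score_rows[s]] - mu) / sd
            U = Xo @ V  # (B, n_s, d): design rotated into the eigenbasis
            bases[s] = (
                U.transpose(0, 2, 1) @ U,  # UtU (B, d, d)
                U.sum(axis=1),  # u1 (B, d)
                U,
            )
        designs.append((Xs, V, evals, bases))
    max_targets = max(1, int(max_chunk_floats / max(B * n_tr, 1)))
    for tcols in _group_chunks(groups, max_targets):
        Tc = len(tcols)
        val_r = np.full((L, K, B, Tc), np.nan, dtype=dtype)
        split_r = {s: np.full((L, K, B, Tc), np.nan, dtype=dtype)
                   for s in splits if s != "validation"}
        Ysub = np.ascontiguousarray(Y[:, tcols])
        Ytr = Ysub[draws["train"]]  # (B, n_tr, Tc)
        Yc = Ytr - Ytr.mean(axis=1, keepdims=True)
        # centered actuals and their sum of squares per split
        actual = {}
        for s in splits:
            Ya = Yc if s == "train" else Ysub[score_rows[s]]
            Ac = Ya - Ya.mean(axis=1, keepdims=True)
            an = np.einsum("bnt,bnt->bt", Ac, Ac)
            actual[s] = (Ac, an, Ya.shape[1])
        for li, (Xs, V, evals, bases) in enumerate(designs):
            # ridge solution in the eigenbasis: W~ = Z / (evals + lam)
            XtY = Xs.transpose(0, 2, 1) @ Yc
            Z = V.transpose(0, 2, 1) @ XtY  # (B, d, Tc)
            uta = {s: bases[s][2].transpose(0, 2, 1) @ actual[s][0] for s in splits}
            for ki, lam in enumerate(lambda_grid):
                S = Z / (evals + dtype(lam))[:, :, None]  # (B, d, Tc)
                for s in splits:
                    UtU, u1, _ = bases[s]
                    Ac, an, n_s = actual[s]
                    # prediction moments without forming predictions:
                    # num = sum_n pred*Ac, sp = sum_n pred, spp = sum_n pred^2
                    num = np.einsum("bdt,bdt->bt", S, uta[s])
                    sp = np.einsum("bd,bdt->bt", u1, S)
                    spp = np.einsum("bdt,bdt->bt", S, UtU @ S)
                    var_p = spp - sp * sp / n_s
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = num / np.sqrt(var_p * an)
                    bad = (var_p < _CHUNK_EPS) | (an < _CHUNK_EPS)
                    r[bad] = np.nan
                    np.clip(r, -1.0, 1.0, out=r)
                    if s == "validation":
                        val_r[li, ki] = r
                    else:
                        split_r[s][li, ki] = r
        # per-resample selection on the resampled validation scores
        flat_val = val_r.reshape(L * K, B, Tc)
        crit = np.where(np.isnan(flat_val), -np.inf, flat_val)
        if selection == "bin":
            sel = crit.argmax(axis=0)  # (B, Tc)
            dead = crit.max(axis=0) == -np.inf
        elif selection == "electrode":
            sel = np.empty((B, Tc), dtype=np.int64)
            dead = np.zeros((B, Tc), dtype=bool)
            cg = groups[tcols]
            for g in np.unique(cg):
                cols = np.flatnonzero(cg == g)
                with np.errstate(invalid="ignore"):
                    gm = np.nanmean(
                        np.where(np.isinf(crit[:, :, cols]), np.nan, crit[:, :, cols]),
                        axis=2,
                    )  # (L*K, B)
                gm = np.where(np.isnan(gm), -np.inf, gm)
                best = gm.argmax(axis=0)  # (B,)
                sel[:, cols] = best[:, None]
                dead[:, cols] = (gm.max(axis=0) == -np.inf)[:, None]
            # a target whose own column never fit stays missing
            dead |= crit.max(axis=0) == -np.inf
        else:
            raise ValueError(f"unknown selection {selection!r}")
        for s in splits:
            arr = flat_val if s == "validation" else split_r[s].reshape(L * K, B, Tc)
            picked = np.take_along_axis(arr, sel[None], axis=0)[0]
            picked[dead] = np.nan
            out[s][:, tcols] = picked
    return out


_CHUNK_EPS = 1e-6


def bootstrap_encode(
    X_layers_or_features,
    Y: np.ndarray,
    plan: FoldPlan,
    resamples: Resamples | None = None,
    B: int = 1000,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    selection: str = "electrode",
    groups: np.ndarray | None = None,
    refit_selection: bool = True,
    splits: Sequence[str] = ("validation", "test"),
    level: float = 95.0,
    min_valid_frac: float = 0.8,
    base: BankResult | None = None,
    dtype=np.float32,
) -> BootstrapResult:
    """Event-bootstrap the full encoding procedure.

    By default (``refit_selection=True``) the whole per-fold procedure --
    standardization, ridge fits for every (layer, lambda), and the
    validation-based selection -- is re-run inside every resample, mirroring
    the original encoding exactly.  ``refit_selection=False`` freezes the
    (layer, lambda) selection made on the original data and refits only the
    ridge weights; see docs/methods.md for the calibration consequences.

    ``Y`` may be (n_events, n_targets) or (n_electrodes, n_events, n_bins);
    the latter is flattened electrode-major with matching ``groups``.
    """
    if hasattr(X_layers_or_features, "matrices"):
        X_layers = X_layers_or_features.matrices()
    else:
        X_layers = list(X_layers_or_features)
    Y = np.asarray(Y)
    if Y.ndim == 3:
        n_elec, n_events, n_bins = Y.shape
        groups = np.repeat(np.arange(n_elec), n_bins)
        Y = np.moveaxis(Y, 1, 0).reshape(n_events, n_elec * n_bins)
    if groups is None:
        groups = np.zeros(Y.shape[1], dtype=np.int64)
    if resamples is None:
        resamples = draw_resamples(Y.shape[0], plan, B, seed)
    B = resamples.B
    seed = resamples.seed

    X_layers = [np.ascontiguousarray(X, dtype=dtype) for X in X_layers]
    Y = np.ascontiguousarray(Y, dtype=dtype)
    T = Y.shape[1]
    F = plan.n_folds
    scores = {s: np.full((B, F, T), np.nan, dtype=dtype) for s in splits}

    if refit_selection:
        for f in range(F):
            per = _refit_fold_scores(
                X_layers, Y, resamples.draws[f], lambda_grid, selection,
                groups, splits, dtype,
            )
            for s in splits:
                scores[s][:, f, :] = per[s]
        return _finalize_bootstrap(scores, splits, B, seed, level, min_valid_frac)

    if base is None:
        base = encode_bank(
            X_layers, Y, plan, lambda_grid=lambda_grid, selection=selection,
            groups=groups,
        )
    score_splits = [s for s in splits if s != "train"]
    for b in range(B):
        for f in range(F):
            dr = resamples.draws[f]
            tr = dr["train"][b]
            idx = {"validation": dr["validation"][b], "test": dr["test"][b]}
            ymu = Y[tr].mean(axis=0)
            li_row = base.chosen_layer[f]
            ki_row = base.chosen_lambda[f]
            for li in np.unique(li_row[li_row >= 0]):
                tmask = li_row == li
                X = X_layers[li]
                mu, sd = _standardize(X, tr)
                Xtr = (X[tr] - mu) / sd
                G = Xtr.T @ Xtr
                eye = np.eye(X.shape[1], dtype=dtype)
                tcols = np.flatnonzero(tmask)
                Ytr_c = Y[np.ix_(tr, tcols)] - ymu[tcols]
                XtY = Xtr.T @ Ytr_c
                ks = ki_row[tcols]
                for ki in np.unique(ks):
                    sub = np.flatnonzero(ks == ki)
                    cols = tcols[sub]
                    lam = dtype(lambda_grid[ki])
                    W = np.linalg.solve(G + lam * eye, XtY[:, sub])
                    if "train" in splits:
                        scores["train"][b, f, cols] = _pearson_columns(
                            Xtr @ W, Y[np.ix_(tr, cols)]
                        )
                    for s in score_splits:
                        rows = idx[s]
                        Xs = (X[rows] - mu) / sd
                        scores[s][b, f, cols] = _pearson_columns(
                            Xs @ W, Y[np.ix_(rows, cols)]
                        )

    return _finalize_bootstrap(scores, splits, B, seed, level, min_valid_frac)


def _finalize_bootstrap(scores, splits, B, seed, level, min_valid_frac) -> BootstrapResult:
    import warnings

    final_scores = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for s in splits:
            # mean over folds within each resample, then (T, B)
            final_scores[s] = np.nanmean(scores[s], axis=1).T.astype(float)
    ci = {s: _ci_rows(final_scores[s], level, min_valid_frac) for s in splits}
    return BootstrapResult(
        scores=final_scores, ci=ci, B=B, seed=seed, level=level,
        min_valid_frac=min_valid_frac,
    )


# ---------------------------------------------------------------------------
# bin filtering and default winner
# ---------------------------------------------------------------------------

def filter_bins(boot: BootstrapResult, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Bins whose validation CI lower bound is strictly above zero.

    A lower bound exactly 0 counts as overlapping zero (filtered).  Returns
    a boolean array over targets, reshaped to ``shape`` (n_electrodes,
    n_bins) when given.
    """
    ci_low = boot.ci["validation"][:, 0]
    surviving = np.isfinite(ci_low) & (ci_low > 0)
    if shape is not None:
        surviving = surviving.reshape(shape)
    return surviving


def default_winner(
    surviving: Mapping[str, int | np.ndarray], min_bins: int = 10
) -> str | None:
    """The unique model with >= ``min_bins`` surviving bins, if exactly one.

    ``surviving`` maps model name to a surviving-bin count or boolean mask.
    """
    counts = {
        m: int(np.sum(v)) if isinstance(v, np.ndarray) else int(v)
        for m, v in surviving.items()
    }
    qualifying = [m for m, c in counts.items() if c >= min_bins]
    return qualifying[0] if len(qualifying) == 1 else None


# ---------------------------------------------------------------------------
# second-order (bin) bootstrap and FDR
# ---------------------------------------------------------------------------

@dataclass
class DiffTest:
    """Paired bin-bootstrap comparison of two models on shared bins."""

    model_a: str
    model_b: str
    n_bins: int
    mean_diff: float
    diffs: np.ndarray
    ci: tuple[float, float]
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def paired_bin_bootstrap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    B2: int = 1000,
    seed: int = 0,
    model_a: str = "a",
    model_b: str = "b",
) -> DiffTest:
    """Resample shared bins with replacement, paired across the two models.

    The statistic is mean(a) - mean(b) over the resampled bins; the p-value
    is the two-sided sign-based bootstrap p,
    ``2 * min(#{d* <= 0}, #{d* >= 0}) / B2`` clipped to [1/B2, 1].
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores_a and scores_b must be 1-d arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 shared bins")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B2, n))
    diffs = a[idx].mean(axis=1) - b[idx].mean(axis=1)
    n_le = int(np.sum(diffs <= 0))
    n_ge = int(np.sum(diffs >= 0))
    p = float(np.clip(2.0 * min(n_le, n_ge) / B2, 1.0 / B2, 1.0))
    return DiffTest(
        model_a=model_a,
        model_b=model_b,
        n_bins=n,
        mean_diff=float(a.mean() - b.mean()),
        diffs=diffs,
        ci=percentile_ci(diffs),
        p_value=p,
    )


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction over one test family.

    Returns (q_values, rejections).  ``q`` is the BH-adjusted p-value; the
    rejection set is the standard step-up set at level ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject
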