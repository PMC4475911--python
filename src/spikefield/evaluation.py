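"""Predictive-power scoring, nested cross-validation, and null controls.

Predictive power (PP) of a model for 1 ms spike/no-spike prediction is
2*AUC - 1 where AUC is the area under the *convex hull* of the ROC curve on
held-out data; 0 is chance, 1 is perfect prediction.  Models are evaluated
under a two-tier scheme: an outer 10-fold split reserves 10% of the data for
testing, and an inner random two-group split of the training data selects
the L2 penalty alpha from an 11-value grid (0 plus ten values log-spaced
over [1e-9, 1e2]) by generalization PP, averaging both fit/validate
directions.  Chance levels come from a permutation null in which covariates
are shuffled in 100 ms blocks relative to spiking, preserving their
autocorrelation but destroying their alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import _solver
from .core import BinnedSpikeTrain, FeatureBlock

#: ten base-10 log-spaced values over [1e-9, 1e2] plus the unpenalized fit
DEFAULT_ALPHA_GRID = (0.0,) + tuple(float(a) for a in np.logspace(-9, 2, 10))


@dataclass
class CVConfig:
    """Two-tier cross-validation settings."""

    outer_folds: int = 10
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    seed: int = 0
    fold_scheme: str = "contiguous"  # or "random"
    block_len_ms: int = 100
    n_perm: int = 20
    dtype: str = "float32"
    #: negatives subsampled (all spikes kept) when scoring the inner
    #: alpha-selection split; test-fold and pooled PP are always exact
    inner_neg_subsample: int = 20000

    def __post_init__(self) -> None:
        grid = tuple(float(a) for a in self.alpha_grid)
        if len(grid) != 11 or 0.0 not in grid or any(a < 0 for a in grid):
            raise ValueError(
                "alpha_grid must hold 11 non-negative values including 0"
            )
        self.alpha_grid = tuple(sorted(grid))
        if self.fold_scheme not in ("contiguous", "random"):
            raise ValueError("fold_scheme must be 'contiguous' or 'random'")


@dataclass
class CVResult:
    """Per-fold and pooled predictive power for one feature-set combination."""

    feature_set: str
    pp_per_fold: np.ndarray
    pp_pooled: float
    selected_alphas: list
    chance_pp_95: float | None = None
    unit: str = ""
    n_rows: int = 0
    n_spikes: int = 0


@dataclass
class ComparisonResult:
    """Nested-model comparison over a unit population."""

    base: str
    extended: str
    delta_pp_per_unit: np.ndarray
    mean_delta: float
    median_delta: float
    p_value: float
    n_tests_bonferroni: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05 / self.n_tests_bonferroni


def _upper_hull(fpr: np.ndarray, tpr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper convex hull of ROC points (fpr ascending, includes endpoints).

    Iteratively deletes every point lying on or below the chord of its
    current neighbours — such a point is below the concave majorant of the
    set and can never be a hull vertex, so simultaneous removal is safe —
    until the sequence is concave.
    """
    x, y = np.asarray(fpr, dtype=np.float64), np.asarray(tpr, dtype=np.float64)
    while x.size > 2:
        cross = (x[1:-1] - x[:-2]) * (y[2:] - y[:-2]) - (
            y[1:-1] - y[:-2]
        ) * (x[2:] - x[:-2])
        below = cross >= 0
        if not below.any():
            break
        keep = np.r_[True, ~below, True]
        x, y = x[keep], y[keep]
    return x, y


def _roc_points(y: np.ndarray, scores: np.ndarray):
    """ROC points (fpr, tpr) over all thresholds, fpr ascending."""
    order = np.argsort(scores, kind="stable")[::-1]
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.arange(1, ys.size + 1) - tps
    # keep only threshold boundaries (last index of each tied score run)
    s_sorted = scores[order]
    boundary = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tps, fps = tps[boundary], fps[boundary]
    fpr = np.r_[0.0, fps / fps[-1]]
    tpr = np.r_[0.0, tps / tps[-1]]
    return fpr, tpr


def roc_hull_pp(prob, Y) -> float:
    """Predictive power 2*AUC-1 from the ROC convex hull.

    ``prob`` may be any score monotone in the predicted spike probability
    (the ROC is rank-based).  Requires at least one spike and one non-spike.
    """
    y = Y.values if isinstance(Y, BinnedSpikeTrain) else np.asarray(Y)
    scores = np.asarray(prob)
    if y.size != scores.size:
        raise ValueError("prob and Y length mismatch")
    nsp = int(y.sum())
    if nsp == 0 or nsp == y.size:
        raise ValueError("degenerate spike train: PP undefined")
    fpr, tpr = _roc_points(np.asarray(y, dtype=np.float64), scores)
    # only points ending an upward move can be upper-hull vertices
    cand = np.r_[True, np.diff(tpr) > 0]
    cand[-1] = True
    hx, hy = _upper_hull(fpr[cand], tpr[cand])
    auc = float(np.trapezoid(hy, hx))
    return 2.0 * auc - 1.0


def _make_folds(T: int, config: CVConfig) -> list[np.ndarray]:
    idx = np.arange(T)
    if config.fold_scheme == "random":
        rng = np.random.default_rng([config.seed, 3])
        idx = rng.permutation(idx)
    return [np.sort(f) for f in np.array_split(idx, config.outer_folds)]


def _concat_blocks(blocks: list[FeatureBlock]):
    n_rows = {b.n_rows for b in blocks}
    if len(n_rows) != 1:
        raise ValueError("feature blocks do not share a time base")
    raw = np.hstack([b.values for b in blocks])
    labels = [lb for b in blocks for lb in b.labels]
    sd = raw.std(axis=0)
    keep = sd > 1e-12
    return raw[:, keep], [lb for lb, k in zip(labels, keep) if k]


def _zscored(raw: np.ndarray, rows, dtype, stats: tuple | None = None):
    """Intercept-augmented z-scored design over ``rows`` (float64 stats)."""
    sub = raw[rows]
    if stats is None:
        m = sub.mean(axis=0, dtype=np.float64)
        v = sub.var(axis=0, dtype=np.float64)
        s = np.sqrt(v)
        s = np.where(s > 1e-12, s, 1.0)
    else:
        m, s = stats
    X1 = np.empty((sub.shape[0], sub.shape[1] + 1), dtype=dtype)
    X1[:, 0] = 1.0
    X1[:, 1:] = (sub - m.astype(dtype)) / s.astype(dtype)
    return X1, (m, s)


def _fold_sums(raw: np.ndarray, folds: list[np.ndarray]):
    """Per-fold column sums and sums of squares (float64), one data pass."""
    sums, sqs = [], []
    for f in folds:
        sub = raw[f]
        sums.append(sub.sum(axis=0, dtype=np.float64))
        sqs.append((sub.astype(np.float64) ** 2).sum(axis=0))
    return np.array(sums), np.array(sqs)


def _train_stats(fold_sums, fold_sqs, counts, i):
    """Mean/sd over all folds except ``i`` from the precomputed sums."""
    n = counts.sum() - counts[i]
    m = (fold_sums.sum(axis=0) - fold_sums[i]) / n
    v = (fold_sqs.sum(axis=0) - fold_sqs[i]) / n - m**2
    s = np.sqrt(np.clip(v, 0.0, None))
    return m, np.where(s > 1e-12, s, 1.0)


def nested_cv_fit(
    blocks: list[FeatureBlock],
    Y: BinnedSpikeTrain,
    config: CVConfig,
    feature_set: str = "model",
    unit: str = "",
) -> CVResult:
    """Two-tier cross-validated predictive power for one feature set.

    Outer contiguous (default) 10-fold split; per fold the training data is
    split randomly into two equal groups, the alpha grid is fit on each
    group and scored on the other (averaged), the argmax-PP alpha is refit
    on all training data (z-scoring statistics from training only) and
    scored on the held-out fold.  Pooled PP concatenates the held-out scores
    of all folds — every bin is test data exactly once — and computes one
    ROC hull.
    """
    y = Y.values.astype(np.float64)
    T = y.size
    raw, labels = _concat_blocks(blocks)
    folds = _make_folds(T, config)
    dtype = np.float32 if config.dtype == "float32" else np.float64
    raw = np.ascontiguousarray(raw, dtype=dtype)
    grid = np.asarray(config.alpha_grid)
    K = grid.size
    # looser gradient tolerance for the inner (alpha-selection) fits; the
    # refit that produces reported scores converges tighter
    gfac_inner = 1e-3 if dtype == np.float32 else 1e-6
    gfac_refit = 1e-4 if dtype == np.float32 else 1e-8

    fold_sums, fold_sqs = _fold_sums(raw, folds)
    counts = np.array([f.size for f in folds])

    warm_inner: list[np.ndarray | None] = [None, None]
    warm_refit: np.ndarray | None = None
    precond: np.ndarray | None = None
    pp_per_fold = np.full(len(folds), np.nan)
    selected: list[float] = []
    scores_all = np.empty(T)

    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate(
            [f for j, f in enumerate(folds) if j != i]
        )
        # training-fold z-scoring statistics serve the whole fold: the inner
        # halves, the refit, and the held-out scoring (training stats only)
        stats_t = _train_stats(fold_sums, fold_sqs, counts, i)
        rng = np.random.default_rng([config.seed, 7, i])
        perm = rng.permutation(train_idx.size)
        # one gather per fold: training rows in permuted order, z-scored;
        # the two inner halves are then contiguous views and the refit sees
        # the same rows (row order is irrelevant to the objective)
        Xp, _ = _zscored(raw, train_idx[perm], dtype, stats=stats_t)
        yp = y[train_idx[perm]]
        half = train_idx.size // 2
        bounds = ((0, half), (half, train_idx.size))

        pp_sum = np.zeros(K)
        for d in (0, 1):
            (f0, f1), (v0, v1) = bounds[d], bounds[1 - d]
            W, info = _solver.fit_path(
                Xp[f0:f1], yp[f0:f1], grid,
                W0=warm_inner[d], precond=precond, gfac=gfac_inner,
            )
            warm_inner[d] = W
            precond = info["H0"]
            # score on the held half; negatives may be subsampled (the
            # selection compares alphas on a common subsample)
            yv = yp[v0:v1]
            neg = np.flatnonzero(yv == 0)
            nsub = config.inner_neg_subsample
            if nsub and neg.size > nsub:
                rsub = np.random.default_rng([config.seed, 13, i, d])
                pick = np.concatenate(
                    [np.flatnonzero(yv > 0),
                     rsub.choice(neg, size=nsub, replace=False)]
                )
                Psi = Xp[v0:v1][pick] @ W.astype(dtype)
                yv = yv[pick]
            else:
                Psi = Xp[v0:v1] @ W.astype(dtype)
            for k in range(K):
                pp_sum[k] += roc_hull_pp(Psi[:, k], yv)
        k_best = int(np.argmax(pp_sum))
        selected.append(float(grid[k_best]))

        W0 = warm_refit if warm_refit is not None else warm_inner[0][:, [k_best]]
        Wr, info = _solver.fit_path(
            Xp, yp, grid[[k_best]], W0=W0, precond=precond, gfac=gfac_refit
        )
        warm_refit = Wr
        precond = info["H0"]
        X1s, _ = _zscored(raw, test_idx, dtype, stats=stats_t)
        fold_scores = (X1s @ Wr.astype(dtype))[:, 0]
        scores_all[test_idx] = fold_scores
        nsp = y[test_idx].sum()
        if nsp < 10:
            warnings.warn(
                f"fold {i}: only {int(nsp)} spikes in the test fold; PP is "
                "unstable",
                stacklevel=2,
            )
        if 0 < nsp < test_idx.size:
            pp_per_fold[i] = roc_hull_pp(fold_scores, y[test_idx])

    pooled = roc_hull_pp(scores_all, y)
    return CVResult(
        feature_set=feature_set,
        pp_per_fold=pp_per_fold,
        pp_pooled=pooled,
        selected_alphas=selected,
        unit=unit,
        n_rows=T,
        n_spikes=int(y.sum()),
    )


def _ladder_parts(ladder: str) -> list[str]:
    parts = ladder.split("+")
    for p in parts:
        if p not in ("lfp", "kin", "hist"):
            raise ValueError(f"unknown ladder component {p!r}")
    return parts


def evaluate_population(
    kin_block: FeatureBlock | None,
    lfp_block: FeatureBlock | None,
    hist_blocks: list | None,
    Ys: list,
    config: CVConfig,
    ladders=("lfp", "kin", "kin+lfp", "kin+hist"),
) -> dict[str, list[CVResult]]:
    """Two-tier CV for several units and feature-set ladders at once.

    Produces the same per-unit results as calling :func:`nested_cv_fit`
    ladder by ladder (same folds, same inner splits, same alpha grid), but
    shares everything unit-independent across the population: the fold
    layout, the training-fold z-scoring statistics, and the gathered,
    z-scored shared design (kinematics + LFP columns) from which each
    ladder's matrix is a column slice.  Per-unit work reduces to the
    spike-history columns, the fits themselves, and the scoring.
    """
    shared = []
    if kin_block is not None:
        shared.append(kin_block)
    if lfp_block is not None:
        shared.append(lfp_block)
    raw_sh, _ = _concat_blocks(shared)
    dtype = np.float32 if config.dtype == "float32" else np.float64
    raw_sh = np.ascontiguousarray(raw_sh, dtype=dtype)
    n_kin = kin_block.n_cols if kin_block is not None else 0
    n_lfp = lfp_block.n_cols if lfp_block is not None else 0
    # shared layout after the intercept: [kin | lfp]; hist columns appended
    col_idx = {}
    for lad in ladders:
        parts = _ladder_parts(lad)
        cols = [0]
        if "kin" in parts:
            cols += list(range(1, 1 + n_kin))
        if "lfp" in parts:
            cols += list(range(1 + n_kin, 1 + n_kin + n_lfp))
        col_idx[lad] = (np.asarray(cols), "hist" in parts)

    n_units = len(Ys)
    T = Ys[0].n_bins
    folds = _make_folds(T, config)
    counts = np.array([f.size for f in folds])
    fs_sh, fq_sh = _fold_sums(raw_sh, folds)
    raws_h, fs_h, fq_h = [], [], []
    if hist_blocks is not None:
        for hb in hist_blocks:
            rh = np.ascontiguousarray(hb.values, dtype=dtype)
            raws_h.append(rh)
            a, b = _fold_sums(rh, folds)
            fs_h.append(a)
            fq_h.append(b)

    grid = np.asarray(config.alpha_grid)
    K = grid.size
    gfac_inner = 1e-3 if dtype == np.float32 else 1e-6
    gfac_refit = 1e-4 if dtype == np.float32 else 1e-8

    state = [
        {lad: {"inner": [None, None], "refit": None, "precond": None}
         for lad in ladders}
        for _ in range(n_units)
    ]
    scores_all = {
        lad: [np.empty(T, dtype=np.float32) for _ in range(n_units)]
        for lad in ladders
    }
    pp_fold = {lad: np.full((n_units, len(folds)), np.nan) for lad in ladders}
    selected = {lad: [[] for _ in range(n_units)] for lad in ladders}
    ys = [Y.values.astype(np.float64) for Y in Ys]

    def slice_cols(X, cols):
        lo, hi = cols[0], cols[-1] + 1
        if cols.size == hi - lo:
            # one contiguous copy here (no-op when full width) so the solver
            # never has to re-copy a strided view on every call
            return np.ascontiguousarray(X[:, lo:hi])
        return np.ascontiguousarray(X[:, cols])

    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate(
            [f for j, f in enumerate(folds) if j != i]
        )
        m_sh, s_sh = _train_stats(fs_sh, fq_sh, counts, i)
        rng = np.random.default_rng([config.seed, 7, i])
        perm = rng.permutation(train_idx.size)
        rows_p = train_idx[perm]
        Xp_sh, _ = _zscored(raw_sh, rows_p, dtype, stats=(m_sh, s_sh))
        Xs_sh, _ = _zscored(raw_sh, test_idx, dtype, stats=(m_sh, s_sh))
        half = train_idx.size // 2
        bounds = ((0, half), (half, train_idx.size))

        for u in range(n_units):
            yu = ys[u]
            yp = yu[rows_p]
            if hist_blocks is not None and any(c[1] for c in col_idx.values()):
                mh, sh = _train_stats(fs_h[u], fq_h[u], counts, i)
                Hp = ((raws_h[u][rows_p] - mh.astype(dtype))
                      / sh.astype(dtype))
                Hs = ((raws_h[u][test_idx] - mh.astype(dtype))
                      / sh.astype(dtype))
            for lad in ladders:
                cols, with_hist = col_idx[lad]
                if with_hist and hist_blocks is None:
                    raise ValueError(f"ladder {lad!r} needs history blocks")
                Xlad = slice_cols(Xp_sh, cols)
                Xtest = slice_cols(Xs_sh, cols)
                if with_hist:
                    Xlad = np.ascontiguousarray(np.hstack([Xlad, Hp]))
                    Xtest = np.hstack([Xtest, Hs])
                st = state[u][lad]
                if st["inner"][0] is None and u > 0:
                    prev = state[u - 1][lad]
                    st["inner"] = [
                        None if w is None else w.copy() for w in prev["inner"]
                    ]
                    st["precond"] = prev["precond"]

                pp_sum = np.zeros(K)
                for d in (0, 1):
                    (f0, f1), (v0, v1) = bounds[d], bounds[1 - d]
                    W, info = _solver.fit_path(
                        Xlad[f0:f1], yp[f0:f1], grid,
                        W0=st["inner"][d], precond=st["precond"],
                        gfac=gfac_inner,
                    )
                    st["inner"][d] = W
                    st["precond"] = info["H0"]
                    yv = yp[v0:v1]
                    neg = np.flatnonzero(yv == 0)
                    nsub = config.inner_neg_subsample
                    if nsub and neg.size > nsub:
                        rsub = np.random.default_rng(
                            [config.seed, 13, i, d]
                        )
                        pick = np.concatenate(
                            [np.flatnonzero(yv > 0),
                             rsub.choice(neg, size=nsub, replace=False)]
                        )
                        Psi = Xlad[v0:v1][pick] @ W.astype(dtype)
                        yvs = yv[pick]
                    else:
                        Psi = Xlad[v0:v1] @ W.astype(dtype)
                        yvs = yv
                    for k in range(K):
                        pp_sum[k] += roc_hull_pp(Psi[:, k], yvs)
                k_best = int(np.argmax(pp_sum))
                selected[lad][u].append(float(grid[k_best]))
                W0 = (st["refit"] if st["refit"] is not None
                      else st["inner"][0][:, [k_best]])
                Wr, info = _solver.fit_path(
                    Xlad, yp, grid[[k_best]], W0=W0,
                    precond=st["precond"], gfac=gfac_refit,
                )
                st["refit"] = Wr
                st["precond"] = info["H0"]
                fscore = (Xtest @ Wr.astype(dtype))[:, 0]
                scores_all[lad][u][test_idx] = fscore
                nsp = yu[test_idx].sum()
                if nsp < 10:
                    warnings.warn(
                        f"unit {u} fold {i}: only {int(nsp)} spikes in the "
                        "test fold; PP is unstable",
                        stacklevel=2,
                    )
                if 0 < nsp < test_idx.size:
                    pp_fold[lad][u, i] = roc_hull_pp(fscore, yu[test_idx])

    out: dict[str, list[CVResult]] = {}
    for lad in ladders:
        out[lad] = [
            CVResult(
                feature_set=lad,
                pp_per_fold=pp_fold[lad][u],
                pp_pooled=roc_hull_pp(scores_all[lad][u], ys[u]),
                selected_alphas=selected[lad][u],
                unit=Ys[u].label,
                n_rows=T,
                n_spikes=int(ys[u].sum()),
            )
            for u in range(n_units)
        ]
    return out


def block_shuffle(block, block_len_ms: int = 100, seed: int | None = None,
                  rng: np.random.Generator | None = None):
    """Permute contiguous ``block_len_ms`` chunks of rows uniformly at random.

    All columns move together, preserving within-chunk autocorrelation while
    destroying alignment with the spike train.  A trailing partial chunk
    participates in the permutation.  Accepts a FeatureBlock or an array.
    """
    values = block.values if isinstance(block, FeatureBlock) else np.asarray(block)
    T = values.shape[0]
    n_chunks = int(np.ceil(T / block_len_ms))
    if n_chunks < 2:
        warnings.warn("fewer than 2 chunks; returning input unchanged",
                      stacklevel=2)
        out = values.copy()
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        order = rng.permutation(n_chunks)
        chunks = [values[c * block_len_ms : (c + 1) * block_len_ms] for c in order]
        out = np.concatenate(chunks, axis=0)
    if isinstance(block, FeatureBlock):
        return FeatureBlock(out, list(block.labels), block.group)
    return out


def chance_level(
    blocks: list[FeatureBlock],
    Y: BinnedSpikeTrain,
    config: CVConfig,
    n_perm: int | None = None,
    *,
    shuffle_group: str = "lfp",
    alpha: float = 1e-2,
):
    """95th-percentile PP under the 100 ms block-shuffle null.

    Per permutation the ``shuffle_group`` blocks are chunk-permuted relative
    to spiking, one 90/10 train/test split (rotating over the outer folds)
    is fit at a fixed ``alpha`` and scored on its test fold.  Returns
    (threshold, null_pps).
    """
    n_perm = config.n_perm if n_perm is None else n_perm
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    y = Y.values.astype(np.float64)
    T = y.size
    folds = _make_folds(T, config)
    dtype = np.float32 if config.dtype == "float32" else np.float64
    gfac = 1e-4 if dtype == np.float32 else 1e-8

    if any(b.group != shuffle_group for b in blocks):
        raise ValueError(
            "chance_level shuffles every block; pass only the blocks of the "
            f"group being tested ({shuffle_group!r})"
        )
    raw, _ = _concat_blocks(blocks)
    raw = np.ascontiguousarray(raw, dtype=dtype)
    bl = config.block_len_ms
    n_chunks = int(np.ceil(T / bl))

    null_pps = np.empty(n_perm)
    warm = None
    precond = None
    for r in range(n_perm):
        rng = np.random.default_rng([config.seed, 11, r])
        order = rng.permutation(n_chunks)
        rows = np.concatenate(
            [np.arange(c * bl, min((c + 1) * bl, T)) for c in order]
        )
        shuf = raw[rows]
        test_idx = folds[r % len(folds)]
        train_idx = np.concatenate(
            [f for j, f in enumerate(folds) if j != r % len(folds)]
        )
        X1t, stats = _zscored(shuf, train_idx, dtype)
        W, info = _solver.fit_path(
            X1t, y[train_idx], np.array([alpha]), W0=warm,
            precond=precond, gfac=gfac,
        )
        warm, precond = W, info["H0"]
        X1s, _ = _zscored(shuf, test_idx, dtype, stats=stats)
        null_pps[r] = roc_hull_pp((X1s @ W.astype(dtype))[:, 0], y[test_idx])
    return float(np.percentile(null_pps, 95)), null_pps


def chance_population(
    blocks: list[FeatureBlock],
    Ys: list,
    config: CVConfig,
    n_perm: int | None = None,
    *,
    alphas=None,
):
    """Block-shuffle chance thresholds for several units sharing covariates.

    Same null as :func:`chance_level` (100 ms chunk permutations of the
    covariate blocks, one rotating 90/10 split fit per permutation), but the
    shuffled, z-scored designs are built once per permutation and reused for
    every unit.  ``alphas`` gives the fixed per-unit penalty (scalar or one
    value per unit).  Returns (thresholds, null_pps) with shapes (n_units,)
    and (n_units, n_perm).
    """
    n_perm = config.n_perm if n_perm is None else n_perm
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    n_units = len(Ys)
    if alphas is None:
        alphas = np.full(n_units, 1e-2)
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (n_units,))
    ys = [Y.values.astype(np.float64) for Y in Ys]
    T = Ys[0].n_bins
    folds = _make_folds(T, config)
    dtype = np.float32 if config.dtype == "float32" else np.float64
    gfac = 1e-4 if dtype == np.float32 else 1e-8

    raw, _ = _concat_blocks(blocks)
    raw = np.ascontiguousarray(raw, dtype=dtype)
    bl = config.block_len_ms
    n_chunks = int(np.ceil(T / bl))

    null_pps = np.empty((n_units, n_perm))
    warm = [None] * n_units
    precond = [None] * n_units
    for r in range(n_perm):
        rng = np.random.default_rng([config.seed, 11, r])
        order = rng.permutation(n_chunks)
        rows = np.concatenate(
            [np.arange(c * bl, min((c + 1) * bl, T)) for c in order]
        )
        shuf = raw[rows]
        fold_i = r % len(folds)
        test_idx = folds[fold_i]
        train_idx = np.concatenate(
            [f for j, f in enumerate(folds) if j != fold_i]
        )
        X1t, stats = _zscored(shuf, train_idx, dtype)
        X1s, _ = _zscored(shuf, test_idx, dtype, stats=stats)
        for u in range(n_units):
            W, info = _solver.fit_path(
                X1t, ys[u][train_idx], np.array([alphas[u]]),
                W0=warm[u], precond=precond[u], gfac=gfac,
            )
            warm[u], precond[u] = W, info["H0"]
            null_pps[u, r] = roc_hull_pp(
                (X1s @ W.astype(dtype))[:, 0], ys[u][test_idx]
            )
    thresholds = np.percentile(null_pps, 95, axis=1)
    return thresholds, null_pps


def compare_feature_sets(
    results: dict[str, list[CVResult]],
    base: str,
    extended: str,
    n_tests: int,
) -> ComparisonResult:
    """Per-unit Delta PP = PP(extended) - PP(base) with a Wilcoxon test.

    Uses pooled PP per unit.  The two-sided signed-rank p-value is reported
    together with the Bonferroni divisor ``n_tests``; identical PP vectors
    give the degenerate p = 1.
    """
    rb, re_ = results[base], results[extended]
    if len(rb) != len(re_) or any(
        a.unit != b.unit for a, b in zip(rb, re_)
    ):
        raise ValueError("base and extended unit lists do not match")
    if len(rb) < 6:
        raise ValueError("need >= 6 units for a meaningful signed-rank test")
    deltas = np.array([e.pp_pooled - b.pp_pooled for b, e in zip(rb, re_)])
    if np.allclose(deltas, 0.0):
        p = 1.0
    else:
        p = float(sstats.wilcoxon(deltas, alternative="two-sided").pvalue)
    return ComparisonResult(
        base=base,
        extended=extended,
        delta_pp_per_unit=deltas,
        mean_delta=float(deltas.mean()),
        median_delta=float(np.median(deltas)),
        p_value=p,
        n_tests_bonferroni=n_tests,
    )
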