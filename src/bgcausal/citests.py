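"""Conditional-independence tests with block-shuffle permutation significance.

Three statistics are provided behind one uniform interface
``ci_test(method, x, y, Z, options) -> CITestResult``:

``PC`` (partial correlation)
    Pearson correlation of the OLS residuals of ``x`` and ``y`` on
    ``[intercept, Z]``. Sensitive to linear dependence only.
``GPDC``
    Each of ``x`` and ``y`` is regressed on ``Z`` by Gaussian-process
    regression (squared-exponential kernel plus a white-noise term,
    hyperparameters fit by marginal likelihood); the statistic is the distance
    correlation between the two residual series. Detects smooth non-linear
    dependence in the conditional mean.
``CMIknn``
    k-nearest-neighbour estimate (in nats) of the conditional mutual
    information I(x; y | Z), Chebyshev metric on per-column standardized data.
    Model-free: also sensitive to "complex" dependence such as multiplicative
    noise, which leaves the conditional mean untouched.

Because BOLD series are autocorrelated, p-values never assume i.i.d. samples:
the null distribution is built by permuting contiguous blocks of one series
(block shuffle), with the block length chosen from the data's autocorrelation
unless given. Permutation blocks never cross the concatenation boundaries of
the group series when boundary metadata is supplied. For CMIknn with a
non-empty conditioning set, a nearest-neighbour-respecting local permutation
(shuffling x only among samples with similar Z) is the default, which
preserves the x-Z relation under the null.

Statistics are pure functions of their inputs and the seed carried in
``CITestOptions``; results are byte-stable and safe to evaluate in parallel.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma

logger = logging.getLogger(__name__)

METHODS = ("PC", "GPDC", "CMIknn")

__all__ = [
    "CITestOptions",
    "CITestResult",
    "parcorr",
    "gpdc",
    "cmiknn",
    "ci_test",
    "block_shuffle_pvalue",
    "default_block_length",
    "distance_correlation",
]


@dataclass(frozen=True)
class CITestOptions:
    """Options shared by all three tests.

    ``n_perm``            number of permutations (>= 99).
    ``block_len``         shuffle block length; ``None`` selects it from the
                          mean absolute autocorrelation of x and y (smallest
                          lag below 2/sqrt(n), clamped to [1, n/20]).
    ``boundaries``        start indices of concatenation blocks; permutation
                          blocks never cross them.
    ``k``                 neighbour count for CMIknn.
    ``knn_local_perm``    use the Z-neighbourhood-local permutation for CMIknn
                          when Z is non-empty (otherwise block shuffle).
    ``shuffle_neighbors`` neighbourhood size of the local permutation.
    ``analytic``          additionally attach a Student-t p-value (PC only),
                          as a cross-check; never the primary p.
    ``gp_max_train``      cap on GP training points (subsampled beyond it).
    ``cache_dir``         optional on-disk result cache (CMIknn is costly).
    """

    n_perm: int = 500
    block_len: int | None = None
    seed: int = 0
    boundaries: tuple[int, ...] = (0,)
    k: int = 10
    knn_local_perm: bool = True
    shuffle_neighbors: int = 5
    analytic: bool = False
    gp_max_train: int = 400
    gp_optimize: bool = True
    cache_dir: str | None = None


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test."""

    method: str
    statistic: float
    p_value: float
    n_effective: int
    condition_set: tuple = ()
    p_analytic: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _as_columns(Z, n: int) -> np.ndarray:
    if Z is None:
        return np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError(f"Z has {Z.shape[0]} rows, expected {n}")
    return Z


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    return x, y


def _drop_deficient_columns(Z: np.ndarray) -> tuple[np.ndarray, bool]:
    """Drop linearly dependent columns of Z (rank-revealing QR)."""
    if Z.shape[1] == 0:
        return Z, False
    q, r, piv = sla.qr(Z - Z.mean(axis=0), mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(Z.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = sorted(piv[diag > tol]) if diag.size else []
    if len(keep) == Z.shape[1]:
        return Z, False
    logger.warning("dropping %d rank-deficient conditioning column(s)",
                   Z.shape[1] - len(keep))
    return Z[:, keep], True


def default_block_length(arrays, n: int) -> int:
    """Smallest lag at which the mean |autocorrelation| of the given series
    drops below 2/sqrt(n), clamped to [1, n/20]."""
    from statsmodels.tsa.stattools import acf

    cap = max(1, n // 20)
    nlags = min(max(cap, 10), n - 2)
    thr = 2.0 / np.sqrt(n)
    acfs = np.mean(
        [np.abs(acf(np.asarray(a, dtype=float), nlags=nlags, fft=True)[1:])
         for a in arrays],
        axis=0,
    )
    below = np.nonzero(acfs < thr)[0]
    lag = int(below[0]) + 1 if below.size else nlags
    return int(np.clip(lag, 1, cap))


def _index_blocks(n: int, block_len: int, boundaries) -> list[np.ndarray]:
    """Contiguous index blocks of length ``block_len`` that never straddle a
    concatenation boundary."""
    bounds = sorted({int(b) for b in boundaries if 0 <= int(b) < n} | {0})
    edges = bounds + [n]
    out = []
    for s, e in zip(edges, edges[1:]):
        for st in range(s, e, block_len):
            out.append(np.arange(st, min(st + block_len, e)))
    return out


def _resolve_block_len(options: CITestOptions, x, y, n: int) -> int:
    block_len = options.block_len
    if block_len is None:
        block_len = default_block_length([x, y], n)
    if not (1 <= block_len <= n // 4):
        raise ValueError(
            f"block_len {block_len} outside [1, n/4] = [1, {n // 4}] (degenerate shuffle)"
        )
    return int(block_len)


def _perm_index_matrix(n, block_len, boundaries, n_perm, rng) -> np.ndarray:
    """(n_perm, n) permutation indices, one block shuffle per row, vectorized
    over rows (blocks may have unequal lengths at segment tails)."""
    blocks = _index_blocks(n, block_len, boundaries)
    nb = len(blocks)
    lengths = np.array([len(b) for b in blocks])
    starts = np.array([b[0] for b in blocks])
    orders = np.argsort(rng.random((n_perm, nb)), axis=1, kind="stable")
    flat_len = lengths[orders].ravel()
    rep_starts = np.repeat(starts[orders].ravel(), flat_len)
    run_ends = flat_len.cumsum()
    intra = np.arange(flat_len.sum()) - np.repeat(run_ends - flat_len, flat_len)
    return (rep_starts + intra).reshape(n_perm, n)


def block_shuffle_pvalue(
    statistic_fn,
    x,
    y,
    Z=None,
    n_perm: int = 500,
    block_len: int | None = None,
    seed: int = 0,
    boundaries=(0,),
    two_sided: bool = True,
):
    """Generic block-shuffle permutation p-value.

    ``x`` is cut into contiguous blocks of ``block_len`` which are permuted
    (``y`` and ``Z`` held fixed) and the statistic recomputed per permutation;
    p = (1 + #{|perm| >= |observed|}) / (n_perm + 1). Deterministic given the
    seed.
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    options = CITestOptions(block_len=block_len)
    block_len = _resolve_block_len(options, x, y, n)
    rng = np.random.default_rng(seed)
    obs = float(statistic_fn(x, y, Z))
    blocks = _index_blocks(n, block_len, boundaries)
    exceed = 0
    for _ in range(n_perm):
        order = rng.permutation(len(blocks))
        idx = np.concatenate([blocks[i] for i in order])
        s = float(statistic_fn(x[idx], y, Z))
        if two_sided:
            exceed += abs(s) >= abs(obs)
        else:
            exceed += s >= obs
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Partial correlation (PC)
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0.0:
        return 0.0
    return float(np.clip((a @ b) / den, -1.0, 1.0))


def parcorr(x, y, Z=None, options: CITestOptions = CITestOptions()) -> CITestResult:
    """Linear partial correlation with block-shuffle significance.

    With empty Z this is the plain Pearson correlation. The permutation
    engine permutes x in contiguous blocks and re-residualizes, exactly as
    for the observed statistic; the vectorized path below is numerically
    identical to calling the statistic per permutation.
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    Zd = _as_columns(Z, n)
    Zd, dropped = _drop_deficient_columns(Zd)
    if n < Zd.shape[1] + 10:
        raise ValueError(f"n = {n} too small for |Z| = {Zd.shape[1]}")
    flags = ("rank_deficient_Z_dropped",) if dropped else ()

    Zi = np.column_stack([np.ones(n), Zd])
    P = np.linalg.pinv(Zi)  # (m, n)
    rx = x - Zi @ (P @ x)
    ry = y - Zi @ (P @ y)
    stat = _pearson(rx, ry)

    block_len = _resolve_block_len(options, x, y, n)
    rng = np.random.default_rng(options.seed)
    idx = _perm_index_matrix(n, block_len, options.boundaries, options.n_perm, rng)
    Xp = x[idx]  # (n_perm, n)
    RXp = Xp - (Xp @ P.T) @ Zi.T
    RXp = RXp - RXp.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    num = RXp @ ryc
    den = np.sqrt(np.einsum("ij,ij->i", RXp, RXp) * (ryc @ ryc))
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_stats = np.where(den > 0, num / den, 0.0)
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(stat))) / (options.n_perm + 1.0)

    p_analytic = None
    if options.analytic:
        df = n - Zd.shape[1] - 2
        if df > 0 and abs(stat) < 1.0:
            t = stat * np.sqrt(df / (1.0 - stat**2))
            p_analytic = float(2.0 * stats.t.sf(abs(t), df))
    return CITestResult(
        method="PC", statistic=stat, p_value=float(p), n_effective=n,
        condition_set=tuple(range(Zd.shape[1])), p_analytic=p_analytic, flags=flags,
    )


# ---------------------------------------------------------------------------
# GPDC: Gaussian-process regression + distance correlation
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / (s if s > 0 else 1.0)


def _uniform_marginal(v: np.ndarray) -> np.ndarray:
    """Empirical-CDF (rank) transform to uniform marginals. The distance
    correlation is computed on rank-transformed residuals so that it probes
    the dependence structure rather than heavy marginal tails."""
    n = len(v)
    return stats.rankdata(v, method="average") / (n + 1.0)


def _centered_distance_matrix(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    d -= d.mean(axis=0, keepdims=True)
    d -= d.mean(axis=1, keepdims=True)
    d += d.mean()
    return d


def distance_correlation(a, b) -> float:
    """Sample distance correlation of two 1-D series (V-statistic form)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    A = _centered_distance_matrix(a)
    B = _centered_distance_matrix(b)
    dcov2 = (A * B).mean()
    dvar = np.sqrt((A * A).mean() * (B * B).mean())
    if dvar <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / dvar))


def _gp_residuals(v: np.ndarray, Zd: np.ndarray, options: CITestOptions, rng):
    """Residual of v after Gaussian-process regression on Z.

    Hyperparameters are fit by marginal-likelihood optimization on at most
    ``gp_max_train`` (sub-sampled) points; prediction covers all samples. On
    numerical failure a linear residualization is used and flagged.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    n, d = Zd.shape
    if n > options.gp_max_train:
        train = np.sort(rng.choice(n, size=options.gp_max_train, replace=False))
    else:
        train = np.arange(n)
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(np.sqrt(d), (1e-2, 1e2))
        + WhiteKernel(0.1, (1e-5, 1e1))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        optimizer="fmin_l_bfgs_b" if options.gp_optimize else None,
        n_restarts_optimizer=0,
        normalize_y=True,
        alpha=1e-10,
    )
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Zd[train], v[train])
            pred = gp.predict(Zd)
        return v - pred, ()
    except Exception as exc:  # pragma: no cover - rare numerical failure
        logger.warning("GP regression failed (%s); falling back to linear residuals", exc)
        Zi = np.column_stack([np.ones(n), Zd])
        beta, *_ = np.linalg.lstsq(Zi, v, rcond=None)
        return v - Zi @ beta, ("gp_fallback_linear",)


def gpdc(x, y, Z=None, options: CITestOptions = CITestOptions()) -> CITestResult:
    """Distance correlation of Gaussian-process residuals.

    With empty Z the regression step is skipped. The residuals are mapped to
    uniform marginals (empirical-CDF transform) before the distance
    correlation, as in the method's reference formulation: this makes the
    statistic probe the dependence structure rather than heavy marginal tails
    (without it, a few extreme residual pairs dominate the distance matrices
    and the test picks up noise-amplitude coupling it is not meant to target).
    The permutation null is
    built by block-shuffling the x-residual series; since a sample permutation
    only permutes rows/columns of the centered distance matrix, each
    permutation costs one matrix gather instead of a refit.
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    Zd = _as_columns(Z, n)
    Zd, dropped = _drop_deficient_columns(Zd)
    if n < Zd.shape[1] + 10:
        raise ValueError(f"n = {n} too small for |Z| = {Zd.shape[1]}")
    flags = ("rank_deficient_Z_dropped",) if dropped else ()
    rng = np.random.default_rng(options.seed)

    xs, ys = _standardize(x), _standardize(y)
    if Zd.shape[1] == 0:
        rx, ry = xs, ys
    else:
        Zs = (Zd - Zd.mean(axis=0)) / np.where(Zd.std(axis=0) > 0, Zd.std(axis=0), 1.0)
        rx, fx = _gp_residuals(xs, Zs, options, rng)
        ry, fy = _gp_residuals(ys, Zs, options, rng)
        flags = flags + fx + fy

    A = _centered_distance_matrix(_uniform_marginal(rx))
    B = _centered_distance_matrix(_uniform_marginal(ry))
    dvar = np.sqrt((A * A).mean() * (B * B).mean())
    dcov2 = (A * B).mean()
    stat = float(np.sqrt(max(dcov2, 0.0) / dvar)) if dvar > 0 else 0.0

    block_len = _resolve_block_len(options, x, y, n)
    idx_mat = _perm_index_matrix(n, block_len, options.boundaries, options.n_perm, rng)
    # permuting samples only permutes rows/columns of the centered distance
    # matrix, so each permutation is a gather instead of a refit; single
    # precision is ample for the permutation reference distribution
    A32 = A.astype(np.float32)
    B32 = B.astype(np.float32)
    exceed = 0
    for idx in idx_mat:
        dcov2_p = float((A32[np.ix_(idx, idx)] * B32).mean())
        stat_p = float(np.sqrt(max(dcov2_p, 0.0) / dvar)) if dvar > 0 else 0.0
        exceed += stat_p >= stat  # nonnegative statistic: two-sided == upper tail
    p = (1.0 + exceed) / (options.n_perm + 1.0)
    return CITestResult(
        method="GPDC", statistic=stat, p_value=float(p), n_effective=n,
        condition_set=tuple(range(Zd.shape[1])), flags=flags,
    )


# ---------------------------------------------------------------------------
# CMIknn: nearest-neighbour conditional mutual information
# ---------------------------------------------------------------------------

def _knn_cmi_estimate(x: np.ndarray, y: np.ndarray, z: np.ndarray | None, k: int) -> float:
    """Frenzel-Pompe / KSG estimate of I(x; y | z) in nats, Chebyshev metric.

    Counts include the query point itself, which supplies the ``+ 1`` of the
    digamma arguments.
    """
    n = len(x)
    cols = [x[:, None], y[:, None]] + ([z] if z is not None and z.shape[1] else [])
    joint = np.hstack(cols)
    tree = cKDTree(joint)
    eps = tree.query(joint, k=[k + 1], p=np.inf)[0][:, 0]
    r = np.nextafter(eps, 0.0)  # strictly-inside radius

    def count(points: np.ndarray) -> np.ndarray:
        t = cKDTree(points)
        return np.asarray(
            t.query_ball_point(points, r, p=np.inf, return_length=True), dtype=float
        )

    if z is None or z.shape[1] == 0:
        nx = count(x[:, None])
        ny = count(y[:, None])
        return float(digamma(k) + digamma(n) - np.mean(digamma(nx) + digamma(ny)))
    kxz = count(np.hstack([x[:, None], z]))
    kyz = count(np.hstack([y[:, None], z]))
    kz = count(z)
    return float(digamma(k) - np.mean(digamma(kxz) + digamma(kyz) - digamma(kz)))


try:  # the jitted kernel is the hot path of CMIknn permutation testing
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _cmi_perm_kernel_py(x, dother, dy, dz, mappings, k, use_z, dig):
    """Reference implementation of the permutation kernel (see the jitted
    version below); one CMI estimate per mapping row."""
    n_perm, n = mappings.shape
    out = np.empty(n_perm)
    dig_k = dig[k]
    dig_n = dig[n]
    for p in range(n_perm):
        xp = x[mappings[p]]
        s = 0.0
        for i in range(n):
            xi = xp[i]
            # kth smallest joint Chebyshev distance to any other sample
            best = np.full(k, np.inf)
            for j in range(n):
                if j == i:
                    continue
                d = abs(xi - xp[j])
                if dother[i, j] > d:
                    d = dother[i, j]
                if d < best[k - 1]:
                    # insertion into the sorted k-best buffer
                    pos = k - 1
                    while pos > 0 and best[pos - 1] > d:
                        best[pos] = best[pos - 1]
                        pos -= 1
                    best[pos] = d
            eps = best[k - 1]
            c1 = c2 = c3 = 0
            for j in range(n):
                dxij = abs(xi - xp[j])
                if use_z:
                    if (dxij if dxij > dz[i, j] else dz[i, j]) < eps:
                        c1 += 1
                    if dother[i, j] < eps:  # dother = max(dy, dz)
                        c2 += 1
                    if dz[i, j] < eps:
                        c3 += 1
                else:
                    if dxij < eps:
                        c1 += 1
                    if dy[i, j] < eps:
                        c2 += 1
            if use_z:
                s += dig[c1] + dig[c2] - dig[c3]
            else:
                s += dig[c1] + dig[c2]
        if use_z:
            out[p] = dig_k - s / n
        else:
            out[p] = dig_k + dig_n - s / n
    return out


if njit is not None:
    _cmi_perm_kernel = njit(cache=True)(_cmi_perm_kernel_py)
else:  # pragma: no cover
    _cmi_perm_kernel = _cmi_perm_kernel_py

#: above this sample count the O(n^2) distance matrices of the kernel stop
#: paying off against the KD-tree estimator
_CMI_KERNEL_MAX_N = 1_500


def _chebyshev_matrix(v: np.ndarray) -> np.ndarray:
    if v.ndim == 1:
        v = v[:, None]
    d = np.abs(v[:, None, :] - v[None, :, :]).max(axis=2)
    return d


def _local_perm_indices(z: np.ndarray, shuffle_neighbors: int, rng) -> np.ndarray:
    """Draw a permutation of x that only moves samples between Z-neighbours,
    preserving the x-Z relation under the conditional null."""
    n = len(z)
    m = min(shuffle_neighbors, n)
    tree = cKDTree(z)
    _, nbrs = tree.query(z, k=m, p=np.inf)
    order = rng.permutation(n)
    used = np.zeros(n, dtype=bool)
    mapping = np.empty(n, dtype=np.intp)
    for i in order:
        choice = -1
        for j in nbrs[i][rng.permutation(m)]:
            if not used[j]:
                choice = int(j)
                break
        if choice < 0:  # all neighbours taken: fall back to a random free slot
            free = np.flatnonzero(~used)
            choice = int(free[rng.integers(len(free))])
        mapping[i] = choice
        used[choice] = True
    return mapping


def cmiknn(x, y, Z=None, options: CITestOptions = CITestOptions()) -> CITestResult:
    """kNN conditional mutual information with permutation significance.

    The reported statistic is clipped at 0 (the estimator is asymptotically
    nonnegative but noisy around independence); the permutation comparison
    uses the raw value, upper tail, which is what a two-sided test reduces to
    for a nonnegative population quantity.
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    if options.k < 3:
        raise ValueError("k must be >= 3")
    Zd = _as_columns(Z, n)
    Zd, dropped = _drop_deficient_columns(Zd)
    if n < Zd.shape[1] + 10:
        raise ValueError(f"n = {n} too small for |Z| = {Zd.shape[1]}")
    flags = ("rank_deficient_Z_dropped",) if dropped else ()
    rng = np.random.default_rng(options.seed)

    xs, ys = _standardize(x), _standardize(y)
    if Zd.shape[1]:
        Zs = (Zd - Zd.mean(axis=0)) / np.where(Zd.std(axis=0) > 0, Zd.std(axis=0), 1.0)
    else:
        Zs = Zd
    joint = np.hstack([xs[:, None], ys[:, None]] + ([Zs] if Zs.shape[1] else []))
    if np.unique(joint, axis=0).shape[0] < n:
        logger.warning("duplicate points detected; applying 1e-10 jitter")
        flags = flags + ("tie_jitter",)
        jit = 1e-10 * rng.standard_normal(joint.shape)
        xs = xs + jit[:, 0]
        ys = ys + jit[:, 1]
        if Zs.shape[1]:
            Zs = Zs + jit[:, 2:]

    Zarg = Zs if Zs.shape[1] else None

    # permutation mappings of x: Z-local swaps under a conditional null,
    # plain block shuffle otherwise
    if Zarg is not None and options.knn_local_perm:
        mappings = np.stack([
            _local_perm_indices(Zarg, options.shuffle_neighbors, rng)
            for _ in range(options.n_perm)
        ])
    else:
        block_len = _resolve_block_len(options, x, y, n)
        mappings = _perm_index_matrix(n, block_len, options.boundaries,
                                      options.n_perm, rng)

    if n <= _CMI_KERNEL_MAX_N:
        # dense-distance kernel: only the x coordinate moves under the
        # permutations, so the y/z distance matrices are computed once
        dy = _chebyshev_matrix(ys)
        dz = _chebyshev_matrix(Zarg) if Zarg is not None else np.zeros((0, 0))
        dother = np.maximum(dy, dz) if Zarg is not None else dy
        dig = digamma(np.arange(0, n + 1) + 1e-300)  # index 0 never used
        all_maps = np.vstack([np.arange(n, dtype=np.intp)[None, :], mappings])
        vals = _cmi_perm_kernel(xs, dother, dy, dz,
                                all_maps.astype(np.int64), options.k,
                                Zarg is not None, dig)
        raw, perm_vals = float(vals[0]), vals[1:]
    else:
        raw = _knn_cmi_estimate(xs, ys, Zarg, options.k)
        perm_vals = np.array([
            _knn_cmi_estimate(xs[idx], ys, Zarg, options.k) for idx in mappings
        ])
    exceed = int(np.sum(perm_vals >= raw))
    p = (1.0 + exceed) / (options.n_perm + 1.0)
    return CITestResult(
        method="CMIknn", statistic=max(raw, 0.0), p_value=float(p), n_effective=n,
        condition_set=tuple(range(Zd.shape[1])), flags=flags,
    )


# ---------------------------------------------------------------------------
# Uniform dispatcher with optional on-disk cache
# ---------------------------------------------------------------------------

_DISPATCH = {"PC": parcorr, "GPDC": gpdc, "CMIknn": cmiknn}


def _cache_key(method, x, y, Zd, options: CITestOptions) -> str:
    h = hashlib.sha1()
    h.update(method.encode())
    for arr in (x, y, Zd):
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    rel = (options.n_perm, options.block_len, options.seed, options.k,
           options.knn_local_perm, options.shuffle_neighbors,
           options.gp_max_train, options.gp_optimize, tuple(options.boundaries))
    h.update(repr(rel).encode())
    return h.hexdigest()


def ci_test(method: str, x, y, Z=None, options: CITestOptions = CITestOptions()) -> CITestResult:
    """Run one conditional-independence test through the uniform interface."""
    if method not in _DISPATCH:
        raise ValueError(f"unknown CI method {method!r}; one of {METHODS}")
    x, y = _validate_xy(x, y)
    Zd = _as_columns(Z, len(x))
    cache_path = None
    if options.cache_dir is not None:
        cache_path = Path(options.cache_dir) / f"{_cache_key(method, x, y, Zd, options)}.json"
        if cache_path.exists():
            d = json.loads(cache_path.read_text())
            return CITestResult(
                method=d["method"], statistic=d["statistic"], p_value=d["p_value"],
                n_effective=d["n_effective"], condition_set=tuple(d["condition_set"]),
                p_analytic=d.get("p_analytic"), flags=tuple(d.get("flags", ())),
            )
    res = _DISPATCH[method](x, y, Zd if Zd.shape[1] else None, options)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(json.dumps({
            "method": res.method, "statistic": res.statistic, "p_value": res.p_value,
            "n_effective": res.n_effective, "condition_set": list(res.condition_set),
            "p_analytic": res.p_analytic, "flags": list(res.flags),
        }))
    return res
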