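"""Innovation-driven co-activation patterns (iCAPs).

From denoised, *unfiltered* BOLD series: (i) recover activity-inducing
signals per voxel by total-variation-regularized hemodynamic
deconvolution (an HRF forward model with sparsity on temporal
transitions); (ii) take temporal derivatives ("innovations") and keep
the frames whose transient activity is significant against
phase-randomized surrogates; (iii) cluster the retained frames with a
polarity-folded cosine K-means into K spatial co-activation maps; and
(iv) assess their stability by consensus clustering over random frame
subsamples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .errors import ContractError, EmptySelectionError
from .synth import hrf_kernel
from .types import BoldImage, as_mask

__all__ = [
    "ActivitySignals",
    "InnovationFrames",
    "ICAPSet",
    "tv_prox_1d",
    "deconvolve",
    "innovations",
    "select_significant_frames",
    "frame_matrix",
    "cluster_frames",
    "consensus_cluster",
]

try:  # numba accelerates the per-voxel TV prox; plain Python is the fallback
    from numba import njit, prange
except ImportError:  # pragma: no cover
    prange = range

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _tv1d(y, lam, x):
    """Condat's direct O(N) solver for min_x 0.5*||x-y||^2 + lam*TV(x)."""
    N = y.shape[0]
    if N == 1:
        x[0] = y[0]
        return
    k = 0
    k0 = 0
    kminus = 0
    kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == N - 1:
            if umin < 0.0:
                for i in range(k0, kminus + 1):
                    x[i] = vmin
                kminus += 1
                k = kminus
                k0 = kminus
                kplus = kminus
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            elif umax > 0.0:
                for i in range(k0, kplus + 1):
                    x[i] = vmax
                kplus += 1
                k = kplus
                k0 = kplus
                kminus = kplus
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            else:
                v = vmin + umin / (k - k0 + 1)
                for i in range(k0, N):
                    x[i] = v
                return
        if y[k + 1] + umin < vmin - lam:  # negative jump necessary
            for i in range(k0, kminus + 1):
                x[i] = vmin
            kminus += 1
            k = kminus
            k0 = kminus
            kplus = kminus
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:  # positive jump necessary
            for i in range(k0, kplus + 1):
                x[i] = vmax
            kplus += 1
            k = kplus
            k0 = kplus
            kminus = kplus
            vmin = y[k] - 2.0 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:  # no jump: accumulate
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


@njit(cache=True, parallel=True)
def _tv1d_rows(Y, lams, out):
    for v in prange(Y.shape[0]):
        _tv1d(Y[v], lams[v], out[v])


def tv_prox_1d(y: np.ndarray, lam: float | np.ndarray) -> np.ndarray:
    """Exact proximal operator of ``lam * TV`` along the last axis.

    Solves ``argmin_x 0.5*||x - y||^2 + lam * sum |x_{t+1} - x_t|`` per
    row via Condat's taut-string algorithm.
    """
    orig_1d = np.asarray(y).ndim == 1
    y = np.ascontiguousarray(np.atleast_2d(np.asarray(y, dtype=np.float64)))
    lams = np.broadcast_to(np.asarray(lam, dtype=np.float64).ravel(), (y.shape[0],))
    if (lams < 0).any():
        raise ContractError("lam must be nonnegative")
    out = np.empty_like(y)
    _tv1d_rows(y, np.ascontiguousarray(lams), out)
    return out[0] if orig_1d else out


@dataclass
class ActivitySignals:
    """Deconvolved activity-inducing signals for the voxels of a mask."""

    signals: np.ndarray  # (n_vox, T)
    mask: np.ndarray
    settings: dict = field(default_factory=dict)
    converged: np.ndarray | None = None
    objective_history: np.ndarray | None = None  # (n_vox, n_iter)


@dataclass
class InnovationFrames:
    """Temporal derivatives of activity signals, with significance info."""

    frames: np.ndarray  # (n_vox, T - 1)
    mask: np.ndarray
    selected: np.ndarray | None = None  # frame indices
    thresholds: np.ndarray | None = None  # (n_vox, 2) lower/upper

    def __post_init__(self) -> None:
        if self.selected is not None:
            sel = np.asarray(self.selected)
            n_frames = self.frames.shape[1]
            if sel.size and (sel.min() < 0 or sel.max() >= n_frames):
                raise ContractError("selected indices out of frame range")
            self.selected = sel


@dataclass
class ICAPSet:
    """K spatial co-activation maps with frame assignments and stability."""

    maps: np.ndarray  # (n_vox, K), z-scored
    assignments: np.ndarray  # (n_frames,) in 0..K-1
    signs: np.ndarray  # (n_frames,) polarity used for each frame
    K: int
    dispersion: float
    mask: np.ndarray | None = None
    consensus_scores: np.ndarray | None = None  # (K,)
    mean_consensus: float | None = None


def _hrf_matrix(hrf: np.ndarray, T: int) -> np.ndarray:
    """Causal HRF convolution matrix with a steady-state left boundary.

    Activity before the first sample is taken equal to the first sample,
    so the pre-scan HRF tail loads onto column 0; a constant activity
    then maps to an exactly constant signal (no ramp-in transient).
    """
    col = np.zeros(T)
    n = min(len(hrf), T)
    col[:n] = hrf[:n]
    H = toeplitz(col, np.zeros(T))
    tails = np.concatenate([np.cumsum(hrf[::-1])[::-1][1:], [0.0]])
    H[:, 0] += tails[: T] if len(tails) >= T else np.pad(tails, (0, T - len(tails)))
    return H


def _default_lambda(y: np.ndarray, scale: float) -> np.ndarray:
    """Per-voxel regularization from a robust noise estimate.

    sigma is estimated from the median absolute deviation of the
    first-difference (high-pass) residual; lambda = scale * sigma *
    sqrt(2 log T).  The default scale (0.25, a quarter of the universal
    threshold) is deliberately mild: full universal-threshold shrinkage
    suppresses weak or closely spaced transients.
    """
    d = np.diff(y, axis=1)
    mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1)
    sigma = mad / 0.6745 / np.sqrt(2.0)
    T = y.shape[1]
    lam = scale * sigma * np.sqrt(2.0 * np.log(T))
    return np.maximum(lam, 1e-12)


def deconvolve(
    img_denoised_unfiltered: BoldImage,
    mask: np.ndarray,
    lam: float | np.ndarray | None = None,
    hrf: np.ndarray | None = None,
    lambda_scale: float = 0.25,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ActivitySignals:
    """TV-regularized hemodynamic deconvolution, per voxel.

    Solves ``min_a 0.5*||y - H a||^2 + lam * TV(a)`` where ``H`` is
    causal convolution with the canonical double-gamma HRF and TV
    penalizes temporal transitions, by proximal gradient descent with
    the exact 1-D TV prox (monotone in the objective by construction).
    ``lam`` may be a scalar, per-voxel vector, or None (robust per-voxel
    noise estimate scaled by ``lambda_scale``).  Iteration stops when
    every voxel's relative objective change falls below ``tol`` or at
    ``max_iter``; voxels that did not converge are flagged.
    """
    mask = as_mask(mask, img_denoised_unfiltered.grid)
    Y = img_denoised_unfiltered.data[mask]  # (V, T)
    V, T = Y.shape
    if hrf is None:
        hrf = hrf_kernel(img_denoised_unfiltered.tr_seconds)
    H = _hrf_matrix(np.asarray(hrf, dtype=float), T)
    L = np.linalg.norm(H, 2) ** 2
    if lam is None:
        lams = _default_lambda(Y, lambda_scale)
    else:
        lams = np.broadcast_to(np.asarray(lam, dtype=float).ravel(), (V,)).copy()
        if (lams <= 0).any():
            raise ContractError("lam must be positive")

    def objective(A):
        R = A @ H.T - Y  # row convention: (Ha)_t = sum_s H[t, s] a_s
        return 0.5 * (R**2).sum(axis=1) + lams * np.abs(np.diff(A, axis=1)).sum(axis=1)

    def prox_grad_step(Z):
        G = (Z @ H.T - Y) @ H  # rows: H^T (H z - y)
        out = np.empty_like(Z)
        _tv1d_rows(np.ascontiguousarray(Z - G / L),
                   np.ascontiguousarray(lams / L), out)
        return out

    # monotone FISTA: accelerated proximal gradient whose accepted iterate
    # never increases the objective
    A = np.zeros_like(Y)
    Zm = A.copy()
    t_k = 1.0
    obj_hist = np.empty((V, max_iter))
    prev_obj = objective(A)
    converged = np.zeros(V, dtype=bool)
    n_done = 0
    for it in range(max_iter):
        U = prox_grad_step(Zm)
        obj_u = objective(U)
        take_u = obj_u <= prev_obj
        A_new = np.where(take_u[:, None], U, A)
        obj = np.where(take_u, obj_u, prev_obj)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k**2)) / 2.0
        Zm = A_new + (t_k / t_next) * (U - A_new) \
            + ((t_k - 1.0) / t_next) * (A_new - A)
        # restart momentum for voxels whose candidate was rejected: the
        # next step is then a plain descent step, which cannot stall
        if not take_u.all():
            Zm[~take_u] = A_new[~take_u]
        t_k = t_next
        A = A_new
        obj_hist[:, it] = obj
        rel = np.abs(prev_obj - obj) / np.maximum(np.abs(prev_obj), 1e-12)
        converged = converged | ((rel < tol) & take_u)  # sticky per voxel
        prev_obj = obj
        n_done = it + 1
        if converged.all():
            break
    if not converged.all():
        warnings.warn(
            f"deconvolution: {int((~converged).sum())}/{V} voxels not converged "
            f"after {max_iter} iterations", stacklevel=2,
        )
    return ActivitySignals(
        signals=A,
        mask=mask,
        settings={"lambda": lams, "lambda_scale": lambda_scale,
                  "max_iter": max_iter, "tol": tol, "n_iter": n_done},
        converged=converged,
        objective_history=obj_hist[:, :n_done],
    )


def innovations(activity: ActivitySignals) -> InnovationFrames:
    """Temporal derivative of the activity-inducing signals."""
    return InnovationFrames(np.diff(activity.signals, axis=1), activity.mask)


def _phase_randomize(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate series preserving each row's amplitude spectrum."""
    n = X.shape[-1]
    spec = np.fft.rfft(X, axis=-1)
    nf = spec.shape[-1]
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., nf - 1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n, axis=-1)


def select_significant_frames(
    inn: InnovationFrames,
    alpha: float = 0.05,
    n_surrogates: int = 100,
    min_active_fraction: float = 0.05,
    seed: int = 0,
) -> InnovationFrames:
    """Keep frames whose transient activity beats a surrogate null.

    Per voxel, a two-sided threshold is taken at the ``alpha/2`` and
    ``1 - alpha/2`` quantiles of innovation amplitudes from
    phase-randomized surrogates of that voxel's innovation series.  A
    frame is retained when its fraction of suprathreshold voxels is at
    least ``min_active_fraction``.
    """
    if n_surrogates < 20:
        raise ContractError("n_surrogates must be >= 20")
    if not (0 < alpha <= 1):
        raise ContractError("alpha must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    X = inn.frames
    V, F = X.shape
    surr = np.empty((V, n_surrogates * F), dtype=np.float32)
    for s in range(n_surrogates):
        surr[:, s * F : (s + 1) * F] = _phase_randomize(X, rng)
    lo = np.quantile(surr, alpha / 2, axis=1)
    hi = np.quantile(surr, 1 - alpha / 2, axis=1)
    active = (X < lo[:, None]) | (X > hi[:, None])
    fraction = active.mean(axis=0)
    selected = np.flatnonzero(fraction >= min_active_fraction)
    if selected.size == 0:
        raise EmptySelectionError(
            f"no frame reached min_active_fraction={min_active_fraction} "
            f"(max active fraction {fraction.max():.4f})"
        )
    return InnovationFrames(X, inn.mask, selected,
                            np.column_stack([lo, hi]))


def frame_matrix(inn: InnovationFrames) -> np.ndarray:
    """Selected innovation frames as a (n_frames, n_vox) matrix."""
    sel = inn.selected if inn.selected is not None else np.arange(inn.frames.shape[1])
    return inn.frames[:, sel].T.copy()


def _fold_kmeans_once(
    Xn: np.ndarray, K: int, rng: np.random.Generator, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, float]:
    """One restart of polarity-folded cosine K-means.

    A frame and its negation are equivalent: assignment maximizes
    |cosine| to the centroid, and each frame contributes to the centroid
    with the matching sign.  Returns (assignments, signs, dispersion).
    """
    F = Xn.shape[0]
    centroids = Xn[rng.choice(F, size=K, replace=False)].copy()
    assign = np.full(F, -1)
    repairs = 0
    for _ in range(max_iter):
        sims = Xn @ centroids.T  # (F, K)
        new_assign = np.argmax(np.abs(sims), axis=1)
        # repair empty clusters by re-seeding with the worst-fit frame
        for k in range(K):
            if not (new_assign == k).any():
                if repairs >= 10:
                    raise ContractError("could not repair empty cluster (10 attempts)")
                repairs += 1
                worst = np.argmin(np.max(np.abs(sims), axis=1))
                centroids[k] = Xn[worst]
                sims = Xn @ centroids.T
                new_assign = np.argmax(np.abs(sims), axis=1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        chosen = sims[np.arange(F), assign]
        signs = np.where(chosen >= 0, 1.0, -1.0)
        for k in range(K):
            members = assign == k
            c = (Xn[members] * signs[members, None]).sum(axis=0)
            norm = np.linalg.norm(c)
            if norm > 0:
                centroids[k] = c / norm
    sims = Xn @ centroids.T
    chosen = sims[np.arange(F), assign]
    signs = np.where(chosen >= 0, 1.0, -1.0)
    dispersion = float((1.0 - np.abs(chosen)).sum())
    return assign, signs, dispersion


def cluster_frames(
    frames: np.ndarray,
    K: int,
    n_restarts: int = 20,
    seed: int = 0,
    metric: str = "cosine",
    mask: np.ndarray | None = None,
) -> ICAPSet:
    """K-means of innovation frames into K co-activation patterns.

    Default metric is cosine distance on polarity-folded frames (a frame
    and its negation are the same transition); ``metric='euclidean'``
    runs plain K-means without folding.  The best of ``n_restarts``
    (lowest within-cluster dispersion) is kept.  Each cluster map is the
    z-scored mean of its sign-aligned member frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ContractError("frames must be (n_frames, n_vox)")
    F = frames.shape[0]
    if F < K:
        raise ContractError(f"need at least K={K} frames, got {F}")
    if metric not in ("cosine", "euclidean"):
        raise ContractError(f"unknown metric {metric!r}")
    norms = np.linalg.norm(frames, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = frames / safe[:, None]

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        if metric == "cosine":
            assign, signs, disp = _fold_kmeans_once(Xn, K, rng)
        else:
            assign, disp = _euclid_kmeans_once(frames, K, rng)
            signs = np.ones(F)
        if best is None or disp < best[2]:
            best = (assign, signs, disp)
    assign, signs, disp = best

    maps = np.zeros((frames.shape[1], K))
    for k in range(K):
        members = assign == k
        m = (frames[members] * signs[members, None]).mean(axis=0)
        sd = m.std(ddof=0)
        z = (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)
        # canonical polarity: the largest-magnitude voxel is positive, so
        # maps are invariant to wholesale negation of the input frames
        if z[np.argmax(np.abs(z))] < 0:
            z = -z
            signs[members] = -signs[members]
        maps[:, k] = z
    return ICAPSet(maps=maps, assignments=assign, signs=signs, K=K,
                   dispersion=disp, mask=mask)


def _euclid_kmeans_once(X, K, rng, max_iter=200):
    F = X.shape[0]
    centroids = X[rng.choice(F, size=K, replace=False)].copy()
    assign = np.full(F, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        for k in range(K):
            if not (new_assign == k).any():
                worst = np.argmax(np.min(d2, axis=1))
                centroids[k] = X[worst]
                d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
                new_assign = np.argmin(d2, axis=1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for k in range(K):
            centroids[k] = X[assign == k].mean(axis=0)
    d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    return assign, float(d2[np.arange(F), assign].sum())


def consensus_cluster(
    frames: np.ndarray,
    K: int,
    n_subsamples: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    n_restarts: int = 5,
    mask: np.ndarray | None = None,
) -> ICAPSet:
    """Consensus-clustering stability of the K-frame solution.

    Monti-style: recluster random frame subsamples; the consensus of a
    frame pair is its co-assignment frequency among subsamples
    containing both.  The per-cluster score is the mean pairwise
    consensus within each final cluster (1.0 for singletons); scores
    and their mean are attached to the returned :class:`ICAPSet`.
    """
    frames = np.asarray(frames, dtype=float)
    F = frames.shape[0]
    if n_subsamples < 1:
        raise ContractError("n_subsamples must be >= 1")
    if n_subsamples == 1:
        warnings.warn("n_subsamples=1: consensus scores are uninformative",
                      stacklevel=2)
    if not (0 < subsample_fraction <= 1):
        raise ContractError("subsample_fraction must lie in (0, 1]")
    final = cluster_frames(frames, K, n_restarts=20, seed=seed, mask=mask)
    rng = np.random.default_rng(seed)
    m = max(K, int(round(subsample_fraction * F)))
    M = np.zeros((F, F))
    I = np.zeros((F, F))
    for _ in range(n_subsamples):
        idx = rng.choice(F, size=m, replace=False)
        sub = cluster_frames(frames[idx], K, n_restarts=n_restarts,
                             seed=int(rng.integers(2**31)))
        same = sub.assignments[:, None] == sub.assignments[None, :]
        M[np.ix_(idx, idx)] += same
        I[np.ix_(idx, idx)] += 1.0
    consensus = np.divide(M, I, out=np.zeros_like(M), where=I > 0)
    scores = np.ones(K)
    for k in range(K):
        members = np.flatnonzero(final.assignments == k)
        if len(members) >= 2:
            block = consensus[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            scores[k] = float(block[iu].mean())
    final.consensus_scores = scores
    final.mean_consensus = float(scores.mean())
    return final
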