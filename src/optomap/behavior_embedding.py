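"""The 2D behavior space: KL distances, importance subsampling, t-SNE, re-embedding.

Pairwise distances between frames are Kullback-Leibler divergences of their
normalized mode-frequency spectra. Because full datasets are far too large
for a direct t-SNE minimization, a hierarchy of importance subsampling
rounds (600 exemplars per session, pooled into 36,000-point groups) distills
a training set, t-SNE is minimized once on that set, and every remaining
frame is re-embedded by minimizing its out-of-sample t-SNE cost against the
trained map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------

def _check_rows(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    rows = np.atleast_2d(p)
    if np.any(rows <= 0):
        raise ValueError(f"{name} must be strictly positive (apply the epsilon floor)")
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError(f"{name} rows must be normalized probability vectors")
    return p


def kl_distance(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence sum_i p_i log2(p_i / q_i), in bits (clamped at 0)."""
    p = _check_rows(p, "p")
    q = _check_rows(q, "q")
    return float(max(np.sum(p * np.log2(p / q)), 0.0))


def kl_distance_matrix(P: np.ndarray, Q: np.ndarray | None = None,
                       dtype=np.float64) -> np.ndarray:
    """All-pairs KL divergences D[i, j] = KL(P_i || Q_j), in bits.

    Evaluated as H_cross - H_self via a single matrix product so that
    millions of pairs are tractable. ``dtype=np.float32`` halves the cost
    of the product for bulk re-embedding (distances are O(1) numbers, so
    single precision is ample there).
    """
    P = np.atleast_2d(_check_rows(P, "P"))
    Q = P if Q is None else np.atleast_2d(_check_rows(Q, "Q"))
    Pd = P.astype(dtype, copy=False)
    logQ = np.log2(Q.astype(dtype, copy=False))
    self_terms = np.einsum("ij,ij->i", Pd, np.log2(Pd))
    D = self_terms[:, None] - Pd @ logQ.T
    np.maximum(D, 0.0, out=D)
    return D


# ---------------------------------------------------------------------------
# importance subsampling
# ---------------------------------------------------------------------------

def importance_subsample(session_features: np.ndarray, quota: int = 600,
                         seed: int = 0, max_embed: int = 5000,
                         method: str = "pca", grid_size: int = 30) -> np.ndarray:
    """Indices of ``quota`` exemplars covering occupied behavior space uniformly.

    A per-session mini-embedding (2D Hellinger PCA by default, i.e. PCA of
    the square-rooted probability rows; ``method="tsne"`` for a KL-distance
    t-SNE) is histogrammed, and exemplars are drawn without replacement
    with probability inversely proportional to their cell's occupancy
    count. Every occupied cell thereby contributes the same expected number
    of exemplars, up-weighting rare behaviors relative to uniform sampling.
    """
    X = np.atleast_2d(session_features)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if quota >= n:
        if quota > n:
            log.warning("quota %d exceeds session size %d; taking all rows", quota, n)
        return np.arange(n)

    sub = rng.choice(n, size=min(n, max_embed), replace=False) if n > max_embed else np.arange(n)
    if method == "tsne":
        D = kl_distance_matrix(X[sub])
        emb = TSNE(n_components=2, metric="precomputed", init="random",
                   random_state=seed, perplexity=min(30.0, (len(sub) - 1) / 3),
                   method="barnes_hut" if len(sub) > 50 else "exact").fit_transform(D)
    else:
        emb = PCA(n_components=2, random_state=seed).fit_transform(np.sqrt(X[sub]))
    H, xe, ye = np.histogram2d(emb[:, 0], emb[:, 1], bins=grid_size)
    ix = np.clip(np.searchsorted(xe, emb[:, 0]) - 1, 0, grid_size - 1)
    iy = np.clip(np.searchsorted(ye, emb[:, 1]) - 1, 0, grid_size - 1)
    w = 1.0 / H[ix, iy]
    w /= w.sum()
    chosen = rng.choice(len(sub), size=quota, replace=False, p=w)
    return np.sort(sub[chosen])


@dataclass
class TrainingSet:
    """Exemplar rows selected for t-SNE training, with provenance."""

    features: np.ndarray                 # (final_size, D)
    provenance: np.ndarray               # (final_size, 2): session index, row index
    per_session_quota: int = 600
    group_size: int = 36000
    final_size: int = 36000


def hierarchical_training_set(sessions: list[np.ndarray], quota: int = 600,
                              group_size: int = 36000, final: int = 36000,
                              seed: int = 0, method: str = "pca") -> TrainingSet:
    """Rounds of group-and-subsample until one pool of <= ``final`` rows remains.

    Round one draws ``quota`` exemplars per session; subsequent rounds pool
    exemplars into groups of ``group_size`` and subsample each group, keeping
    twice as many points as the previous round, until a single pool of at
    most ``final`` points is left.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rng = np.random.default_rng(seed)
    pool_feat, pool_prov = [], []
    for si, feats in enumerate(sessions):
        idx = importance_subsample(feats, quota=quota, seed=int(rng.integers(2 ** 31)),
                                   method=method)
        pool_feat.append(np.atleast_2d(feats)[idx])
        pool_prov.append(np.column_stack([np.full(len(idx), si), idx]))
    feats = np.vstack(pool_feat)
    prov = np.vstack(pool_prov)

    keep = quota * 2
    while len(feats) > final:
        # each group must shrink, or the pool would never reach `final`
        keep_now = min(keep, group_size // 2)
        order = rng.permutation(len(feats))
        feats, prov = feats[order], prov[order]
        new_f, new_p = [], []
        for g0 in range(0, len(feats), group_size):
            gf = feats[g0:g0 + group_size]
            gp = prov[g0:g0 + group_size]
            idx = importance_subsample(gf, quota=min(keep_now, len(gf)),
                                       seed=int(rng.integers(2 ** 31)), method=method)
            new_f.append(gf[idx])
            new_p.append(gp[idx])
        new_feats, new_prov = np.vstack(new_f), np.vstack(new_p)
        if len(new_feats) >= len(feats):  # no further shrink possible
            sel = importance_subsample(new_feats, quota=final,
                                       seed=int(rng.integers(2 ** 31)),
                                       method=method)
            feats, prov = new_feats[sel], new_prov[sel]
            break
        feats, prov = new_feats, new_prov
        keep *= 2
    return TrainingSet(features=feats, provenance=prov, per_session_quota=quota,
                       group_size=group_size, final_size=final)


# ---------------------------------------------------------------------------
# t-SNE training
# ---------------------------------------------------------------------------

@dataclass
class TrainingEmbedding:
    coords: np.ndarray        # (n, 2)
    perplexity: float
    max_iter: int
    seed: int
    cost: float               # KL cost at convergence

    @property
    def extent(self) -> float:
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(span.max())


def tsne_embed(training_features: np.ndarray, perplexity: float = 32.0,
               max_iter: int = 1000, seed: int = 0) -> TrainingEmbedding:
    """Minimize t-SNE over KL-divergence affinities of the training rows."""
    D = kl_distance_matrix(training_features)
    if not np.all(np.isfinite(D)):
        bad = np.unique(np.argwhere(~np.isfinite(D))[:, 0])[:10]
        raise ValueError(f"non-finite KL distances for rows {bad.tolist()}")
    n = D.shape[0]
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=min(perplexity, (n - 1) / 3.0), max_iter=max_iter,
                random_state=seed, method="barnes_hut" if n > 64 else "exact")
    coords = tsne.fit_transform(D)
    return TrainingEmbedding(coords=coords, perplexity=perplexity,
                             max_iter=max_iter, seed=seed,
                             cost=float(tsne.kl_divergence_))


# ---------------------------------------------------------------------------
# out-of-sample re-embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddedPoints:
    """Per-frame map coordinates; only valid frames carry coordinates."""

    coords: np.ndarray   # (T, 2), NaN where not embedded
    valid: np.ndarray    # (T,) bool
    frames: np.ndarray   # (T,) original frame indices


def _affinities_from_distances(D: np.ndarray, perplexity: float,
                               n_iter: int = 36) -> np.ndarray:
    """Row-wise Gaussian affinities at fixed perplexity (vectorized binary search)."""
    n, m = D.shape
    D2 = D ** 2
    target = np.log(perplexity)
    beta = np.ones(n)
    lo = np.full(n, 1e-12)
    hi = np.full(n, 1e12)
    for _ in range(n_iter):
        P = np.exp(-D2 * beta[:, None])
        P_sum = P.sum(axis=1) + 1e-300
        H = np.log(P_sum) + beta * (D2 * P).sum(axis=1) / P_sum
        too_high = H > target
        lo = np.where(too_high, beta, lo)
        hi = np.where(too_high, hi, beta)
        beta = np.where(np.isfinite(hi) & (hi < 1e12), (lo + hi) / 2, beta * np.where(too_high, 2.0, 0.5))
    P = np.exp(-D2 * beta[:, None])
    return P / (P.sum(axis=1, keepdims=True) + 1e-300)


def reembed(features: np.ndarray, training_features: np.ndarray,
            training_embedding: TrainingEmbedding, k_neighbors: int = 64,
            perplexity: float = 4.0, n_iter: int = 40, step: float = 1.0,
            momentum: float = 0.5, frames: np.ndarray | None = None,
            valid: np.ndarray | None = None, k_fallback: int = 10,
            grad_tol: float = 1e-3, chunk: int = 20000) -> EmbeddedPoints:
    """Place new rows in the trained map by minimizing their t-SNE cost.

    Each new point's affinity to the training set is computed from KL
    distances, restricted to its ``k_neighbors`` nearest training rows; its
    position is then optimized by momentum gradient descent on the
    out-of-sample t-SNE cost (training positions fixed). The out-of-sample
    kernel perplexity is deliberately sharper than the training perplexity
    so that a row near-identical to a training row is dominated by its
    twin; a row at zero KL distance from a training exemplar inherits that
    exemplar's trained position outright (the embedding is a function of
    the feature vector, so duplicates must coincide). Points failing the
    convergence test fall back to the median position of their
    ``k_fallback`` nearest training rows.
    """
    X = np.atleast_2d(features)
    T = X.shape[0]
    if frames is None:
        frames = np.arange(T)
    if valid is None:
        valid = np.ones(T, dtype=bool)
    Y_train = training_embedding.coords
    coords = np.full((T, 2), np.nan)
    ok = valid.copy()

    vi = np.flatnonzero(valid)
    for c0 in range(0, len(vi), chunk):
        rows = vi[c0:c0 + chunk]
        D = kl_distance_matrix(X[rows], training_features, dtype=np.float32)
        k = min(k_neighbors, D.shape[1])
        nn = np.argpartition(D, k - 1, axis=1)[:, :k] if D.shape[1] > k else \
            np.broadcast_to(np.arange(k), (len(rows), k)).copy()
        Dk = np.take_along_axis(D, nn, axis=1)
        P = _affinities_from_distances(Dk, min(perplexity, k / 3.0)).astype(np.float32)
        Ykx = Y_train[nn, 0].astype(np.float32)   # (n, k)
        Yky = Y_train[nn, 1].astype(np.float32)
        yx = np.einsum("nk,nk->n", P, Ykx)        # init: affinity-weighted mean
        yy = np.einsum("nk,nk->n", P, Yky)
        vx = np.zeros_like(yx)
        vy = np.zeros_like(yy)
        gx = gy = None
        for _ in range(n_iter):
            dx = yx[:, None] - Ykx
            dy = yy[:, None] - Yky
            w = 1.0 / (1.0 + dx * dx + dy * dy)
            Q = w / w.sum(axis=1, keepdims=True)
            coef = (P - Q) * w
            gx = 4.0 * np.einsum("nk,nk->n", coef, dx)
            gy = 4.0 * np.einsum("nk,nk->n", coef, dy)
            vx = momentum * vx - step * gx
            vy = momentum * vy - step * gy
            yx = yx + vx
            yy = yy + vy
        gnorm = np.sqrt(gx ** 2 + gy ** 2)
        y = np.column_stack([yx, yy]).astype(float)
        failed = gnorm > grad_tol * max(1.0, training_embedding.extent)
        if np.any(failed):
            kf = min(k_fallback, D.shape[1])
            nnf = np.argpartition(D[failed], kf - 1, axis=1)[:, :kf]
            y[failed] = np.median(Y_train[nnf], axis=1)
            log.info("re-embedding fallback for %d/%d points", failed.sum(), len(rows))
        # duplicates of training exemplars coincide with them exactly
        # (threshold covers the single-precision noise floor of the
        # distance computation; genuinely distinct rows sit far above it)
        jmin = np.argmin(Dk, axis=1)
        dmin = Dk[np.arange(len(rows)), jmin]
        exact = dmin <= 5e-5
        if np.any(exact):
            y[exact] = Y_train[nn[np.flatnonzero(exact), jmin[exact]]]
        coords[rows] = y
    return EmbeddedPoints(coords=coords, valid=ok, frames=frames)
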